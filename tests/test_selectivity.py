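import numpy as np
import pandas as pd
import pytest

import loopmap as lm
from loopmap import selectivity as sel
from loopmap import task
from loopmap.connectome import RegionClassification


def _poisson_unit(rng, rate_by_type, trials, unit_id=0):
    """Homogeneous Poisson unit with a per-type rate (Hz)."""
    dur = task.TRIAL_END_S - task.TRIAL_START_S
    spikes = {}
    for tid, ttype in zip(trials.trial_id, trials.trial_type):
        n = rng.poisson(rate_by_type[ttype] * dur)
        spikes[tid] = np.sort(rng.uniform(task.TRIAL_START_S,
                                          task.TRIAL_END_S, n))
    return sel.UnitRecording(unit_id, spikes)


def _trials(n_per_type):
    types = np.array(task.TRIAL_TYPES * n_per_type)
    return pd.DataFrame({"trial_id": np.arange(types.size),
                         "trial_type": types, "outcome": "correct",
                         "photostim": "none"})


class TestPSTH:
    def test_homogeneous_rate_recovered(self, rng):
        trials = _trials(40)
        unit = _poisson_unit(rng, {t: 10.0 for t in task.TRIAL_TYPES}, trials)
        _, traces = sel.psth(unit, trials, by_type=False)
        trace = traces["all"]
        # pooled across 80 trials: s.e. per 100-ms bin ≈ sqrt(10/(0.1*80))
        se = np.sqrt(10.0 / (0.1 * 80))
        assert np.all(np.abs(trace - 10.0) < 3 * se + 1)

    def test_zero_spikes_zero_trace(self):
        trials = _trials(2)
        unit = sel.UnitRecording(0, {t: np.empty(0) for t in trials.trial_id})
        _, traces = sel.psth(unit, trials)
        for tr in traces.values():
            assert np.all(tr == 0)

    def test_single_spike_unit_conversion(self):
        # one trial, one spike, 0.1-s bins, no smoothing → one 10-Hz bin
        trials = _trials(1).iloc[:1]
        unit = sel.UnitRecording(0, {0: np.array([-1.25])})
        t, traces = sel.psth(unit, trials, bin_s=0.1, smooth_s=0.0)
        trace = traces[trials.trial_type.iloc[0]]
        assert trace.max() == pytest.approx(10.0)
        assert (trace > 0).sum() == 1

    def test_empty_selection_errors(self):
        trials = _trials(2)
        unit = sel.UnitRecording(0, {t: np.empty(0) for t in trials.trial_id})
        with pytest.raises(ValueError):
            sel.psth(unit, trials, trial_ids=np.array([], dtype=int))


class TestEpochSelectivity:
    def test_known_rate_difference_recovered(self, rng):
        # 20 vs 10 Hz in every epoch: delay selectivity ≈ 10 Hz
        trials = _trials(30)
        vals, sig = [], []
        for i in range(40):
            unit = _poisson_unit(rng, {"lick-left": 20.0, "lick-right": 10.0},
                                 trials, i)
            r = sel.epoch_selectivity(unit, trials, "delay")
            assert r.usable
            vals.append(r.selectivity_hz)
            sig.append(r.significant)
            assert r.preferred == "lick-left"
        vals = np.asarray(vals)
        ci = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 10.0) < ci + 0.5
        assert np.mean(sig) > 0.95

    def test_preference_and_estimation_trials_disjoint(self, rng):
        trials = _trials(25)
        unit = _poisson_unit(rng, {t: 15.0 for t in task.TRIAL_TYPES}, trials)
        r = sel.epoch_selectivity(unit, trials, "delay")
        for t in r.pref_trials:
            assert not set(r.pref_trials[t]) & set(r.est_trials[t])

    def test_insufficient_trials_flags_unusable(self, rng):
        trials = _trials(10)  # fewer than the 15-trial preference subset
        unit = _poisson_unit(rng, {t: 15.0 for t in task.TRIAL_TYPES}, trials)
        r = sel.epoch_selectivity(unit, trials, "delay", n_pref_trials=15)
        assert not r.usable and "need 16" in r.reason

    def test_split_estimator_unbiased_nonsplit_biased(self, rng):
        # the point of held-out preference: on null units the split
        # estimator averages to 0 while preferring and estimating on the
        # same trials inflates selectivity
        trials = _trials(25)
        split_vals, nonsplit_vals = [], []
        for i in range(300):
            unit = _poisson_unit(rng, {t: 12.0 for t in task.TRIAL_TYPES},
                                 trials, i)
            r = sel.epoch_selectivity(unit, trials, "delay",
                                      compute_trace=False)
            split_vals.append(r.selectivity_hz)
            rates = {t: sel.epoch_rate(
                unit, trials[trials.trial_type == t].trial_id, "delay")
                for t in task.TRIAL_TYPES}
            means = sorted(v.mean() for v in rates.values())
            nonsplit_vals.append(means[1] - means[0])
        split_vals = np.asarray(split_vals)
        nonsplit_vals = np.asarray(nonsplit_vals)
        sem = split_vals.std(ddof=1) / np.sqrt(split_vals.size)
        assert abs(split_vals.mean()) < 2 * sem
        assert nonsplit_vals.mean() > 4 * sem  # positively biased

    def test_trace_antisymmetric_under_label_swap(self, rng):
        trials = _trials(30)
        unit = _poisson_unit(rng, {"lick-left": 20.0, "lick-right": 10.0},
                             trials)
        t, tr = sel.psth(unit, trials)
        diff = tr["lick-right"] - tr["lick-left"]
        swapped = trials.assign(trial_type=trials.trial_type.map(
            {"lick-left": "lick-right", "lick-right": "lick-left"}))
        _, tr2 = sel.psth(unit, swapped)
        np.testing.assert_allclose(tr2["lick-right"] - tr2["lick-left"], -diff)

    def test_grouping_by_instructed_type_includes_errors(self, rng):
        trials = _trials(20)
        trials.loc[trials.index[:8], "outcome"] = "error"
        unit = _poisson_unit(rng, {t: 15.0 for t in task.TRIAL_TYPES}, trials)
        r_all = sel.epoch_selectivity(unit, trials, "delay",
                                      correct_only=False, n_pref_trials=10)
        r_cor = sel.epoch_selectivity(unit, trials, "delay",
                                      correct_only=True, n_pref_trials=10)
        n_all = sum(v.size for v in r_all.pref_trials.values()) \
            + sum(v.size for v in r_all.est_trials.values())
        n_cor = sum(v.size for v in r_cor.pref_trials.values()) \
            + sum(v.size for v in r_cor.est_trials.values())
        assert n_all == len(trials) and n_cor == len(trials) - 8


class TestPopulationSelectivity:
    def test_single_unit_identity(self):
        tr = np.array([1.0, 2.0, 3.0])
        mean, sem = sel.population_selectivity([tr])
        np.testing.assert_array_equal(mean, tr)
        np.testing.assert_array_equal(sem, 0.0)

    def test_two_unit_closed_form(self):
        s1, s2 = np.array([1.0, 4.0]), np.array([3.0, 0.0])
        mean, sem = sel.population_selectivity([s1, s2])
        np.testing.assert_allclose(mean, (s1 + s2) / 2)
        np.testing.assert_allclose(sem, np.abs(s1 - s2) / 2)

    def test_matches_brute_force(self, rng):
        traces = [rng.normal(size=40) for _ in range(50)]
        mean, sem = sel.population_selectivity(traces)
        mat = np.vstack(traces)
        for j in range(40):
            col = mat[:, j]
            assert mean[j] == pytest.approx(col.mean())
            assert sem[j] == pytest.approx(col.std(ddof=1) / np.sqrt(50))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            sel.population_selectivity([])


class TestRamping:
    def _ramp_unit(self, rng, start_hz, end_hz, trials):
        """Rate ramps linearly through the delay epoch in lick-left trials."""
        d0, d1 = task.EPOCHS["delay"]
        edges = np.arange(task.TRIAL_START_S, task.TRIAL_END_S + 1e-9, 0.05)
        t = 0.5 * (edges[:-1] + edges[1:])
        base = np.full(t.size, start_hz, float)
        in_delay = (t >= d0) & (t < d1)
        ramp = base.copy()
        ramp[in_delay] = start_hz + (end_hz - start_hz) * \
            (t[in_delay] - d0) / (d1 - d0)
        ramp[t >= d1] = end_hz
        spikes = {}
        for tid, ttype in zip(trials.trial_id, trials.trial_type):
            r = ramp if ttype == "lick-left" else base
            counts = rng.poisson(r * 0.05)
            times = [rng.uniform(edges[i], edges[i + 1], c)
                     for i, c in enumerate(counts) if c]
            spikes[tid] = np.sort(np.concatenate(times)) if times \
                else np.empty(0)
        return sel.UnitRecording(0, spikes)

    def test_up_down_and_flat(self, rng):
        trials = _trials(40)
        up = sel.classify_ramping(self._ramp_unit(rng, 10, 25, trials), trials)
        down = sel.classify_ramping(self._ramp_unit(rng, 25, 10, trials),
                                    trials)
        flat = sel.classify_ramping(self._ramp_unit(rng, 10, 10, trials),
                                    trials)
        assert up.label == "up"
        assert down.label == "down"
        assert flat.label == "excluded"

    def test_silent_unit_excluded(self):
        trials = _trials(5)
        unit = sel.UnitRecording(0, {t: np.empty(0) for t in trials.trial_id})
        assert sel.classify_ramping(unit, trials).label == "excluded"


class TestAssignRegion:
    def test_lobule_split_and_group(self, atlas):
        cls = RegionClassification(
            {r: ("conjunction" if r.startswith("med-") or r == "Lob VII"
                 else "input-dominant")
             for r in atlas.region_labels("fastigial")}, 1e-11)
        box = atlas.lobule("Crus 1")
        y = 0.5 * sum(box.y_um)
        unit = sel.UnitRecording(0, {}, coords_um=(2000.0, y, 1000.0))
        label, group = sel.assign_region(unit, cls, atlas)
        assert label == "med-Crus 1" and group == "conjunction"
        unit_lat = sel.UnitRecording(0, {}, coords_um=(4000.0, y, 1000.0))
        assert sel.assign_region(unit_lat, cls, atlas)[0] == "lat-Crus 1"

    def test_outside_atlas_unassigned(self, atlas):
        unit = sel.UnitRecording(0, {}, coords_um=(30000.0, 0.0, 0.0))
        cls = RegionClassification({}, 1e-11)
        assert sel.assign_region(unit, cls, atlas) == ("unassigned",
                                                       "unassigned")
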