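"""Trial-type selectivity of single units in the delayed-response task.

Selectivity is the spike-rate difference between a unit's preferred and
non-preferred trial type.  To keep the estimator unbiased, the preferred type
is fixed on a held-out subset of trials (15 per type by default) and the
selectivity trace/amplitude is computed from the remaining trials only;
statistical significance uses epoch spike counts from all correct trials
(two-tailed t-test, P < 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import task
from .atlas import (AtlasSpec, LATERAL_PREFIX, MEDIAL_PREFIX, strip_sublobule)

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_N_PREF_TRIALS = 15


@dataclass
class UnitRecording:
    """Spike times of one unit, per trial, aligned to the go cue at t = 0.

    Purkinje units additionally carry a complex-spike stream in
    ``cs_spikes``; ``spikes`` then holds the simple spikes.
    """
    unit_id: int
    spikes: dict[int, np.ndarray]
    cs_spikes: dict[int, np.ndarray] | None = None
    coords_um: tuple[float, float, float] = (np.nan, np.nan, np.nan)
    region: str | None = None
    unit_class: str = "unknown"  # "ss-only" | "purkinje" | "unknown"
    meta: dict = field(default_factory=dict)


@dataclass
class SelectivityResult:
    unit_id: int
    epoch: str
    usable: bool
    reason: str = ""
    preferred: str | None = None
    selectivity_hz: float = np.nan  # epoch-mean rate, preferred − non-preferred
    p_value: float = np.nan
    significant: bool = False
    trace_t: np.ndarray | None = None
    trace_hz: np.ndarray | None = None  # S(t) from the estimation trials
    pref_trials: dict[str, np.ndarray] = field(default_factory=dict)
    est_trials: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class RampClass:
    unit_id: int
    label: str  # "up" | "down" | "excluded"
    delay_activity_hz: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)


# --------------------------------------------------------------------------
# rates and PSTHs
# --------------------------------------------------------------------------

def epoch_rate(unit: UnitRecording, trial_ids, epoch: str) -> np.ndarray:
    """Per-trial spike rate (Hz) within a named epoch."""
    lo, hi = task.epoch_window(epoch)
    dur = hi - lo
    return np.array([
        np.count_nonzero((unit.spikes[t] >= lo) & (unit.spikes[t] < hi)) / dur
        for t in trial_ids
    ])


def window_rate(unit: UnitRecording, trial_ids, lo: float, hi: float) -> np.ndarray:
    dur = hi - lo
    return np.array([
        np.count_nonzero((unit.spikes[t] >= lo) & (unit.spikes[t] < hi)) / dur
        for t in trial_ids
    ])


def _smooth(rate: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return rate
    kernel = np.ones(n)
    # boxcar average with edge renormalization
    return np.convolve(rate, kernel, "same") / np.convolve(
        np.ones_like(rate), kernel, "same")


def psth(
    unit: UnitRecording,
    trials: pd.DataFrame,
    bin_s: float = 0.1,
    smooth_s: float = 0.2,
    by_type: bool = True,
    trial_ids=None,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Trial-averaged spike rate trace(s), optionally per trial type.

    The histogram of spike counts is divided by bin width and trial count,
    then smoothed with a centered boxcar (default 200 ms).
    """
    edges = np.arange(task.TRIAL_START_S, task.TRIAL_END_S + bin_s / 2, bin_s)
    t = 0.5 * (edges[:-1] + edges[1:])
    n_smooth = max(1, int(round(smooth_s / bin_s)))
    if trial_ids is None:
        trial_ids = trials.trial_id.to_numpy()
    sub = trials[trials.trial_id.isin(trial_ids)]
    if len(sub) == 0:
        raise ValueError("empty trial selection")
    groups = (
        {k: g.trial_id.to_numpy() for k, g in sub.groupby("trial_type")}
        if by_type else {"all": sub.trial_id.to_numpy()}
    )
    out = {}
    for key, ids in groups.items():
        if ids.size == 0:
            raise ValueError(f"empty trial selection for {key!r}")
        counts = np.zeros(t.size)
        for tid in ids:
            counts += np.histogram(unit.spikes[tid], edges)[0]
        out[key] = _smooth(counts / (bin_s * ids.size), n_smooth)
    return t, out


def population_selectivity(traces: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean ± s.e.m. across units (denominator = number of units)."""
    if not traces:
        raise ValueError("population_selectivity requires at least one unit")
    mat = np.vstack(traces)
    mean = mat.mean(axis=0)
    if mat.shape[0] == 1:
        return mean, np.zeros_like(mean)
    sem = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
    return mean, sem


# --------------------------------------------------------------------------
# split-trial selectivity
# --------------------------------------------------------------------------

def split_trial_preference(
    values_by_type: dict[str, np.ndarray],
    n_pref: int,
) -> tuple[str, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Fix the preferred type on the first ``n_pref`` trials per type.

    Returns (preferred type, preference index sets, estimation index sets);
    the two index sets are disjoint by construction.
    """
    pref_idx = {k: np.arange(min(n_pref, v.size)) for k, v in values_by_type.items()}
    est_idx = {k: np.arange(pref_idx[k].size, v.size)
               for k, v in values_by_type.items()}
    means = {k: values_by_type[k][pref_idx[k]].mean() for k in values_by_type}
    preferred = max(means, key=means.get)
    return preferred, pref_idx, est_idx


def epoch_selectivity(
    unit: UnitRecording,
    trials: pd.DataFrame,
    epoch: str = "delay",
    n_pref_trials: int = DEFAULT_N_PREF_TRIALS,
    correct_only: bool = True,
    alpha: float = DEFAULT_ALPHA,
    bin_s: float = 0.1,
    smooth_s: float = 0.2,
    pref_selection: str = "first",
    seed: int | None = None,
    compute_trace: bool = True,
) -> SelectivityResult:
    """Held-out-preference selectivity of one unit in one epoch.

    Significance is a two-tailed Welch t-test on epoch spike counts across
    all included trials; the preferred type is determined on a held-out
    subset (default the first 15 trials per type, or a seeded random subset
    with ``pref_selection="random"``); the selectivity amplitude and trace
    use the remaining trials only.  With ``correct_only=False`` trials are
    grouped by instructed type regardless of outcome, as in the
    photostimulation analyses.
    """
    if epoch not in task.EPOCHS or epoch == "baseline":
        raise ValueError(f"epoch must be sample/delay/response, got {epoch!r}")
    sub = trials[trials.outcome == "correct"] if correct_only else trials
    ids_by_type = {
        k: g.sort_values("trial_id").trial_id.to_numpy()
        for k, g in sub.groupby("trial_type")
    }
    for ttype in task.TRIAL_TYPES:
        n = ids_by_type.get(ttype, np.empty(0)).size
        if n < n_pref_trials + 1:
            return SelectivityResult(
                unit.unit_id, epoch, usable=False,
                reason=f"only {n} usable {ttype} trials "
                       f"(need {n_pref_trials + 1})")

    if pref_selection == "random":
        rng = np.random.default_rng(seed)
        ids_by_type = {k: rng.permutation(v) for k, v in ids_by_type.items()}
    elif pref_selection != "first":
        raise ValueError("pref_selection must be 'first' or 'random'")

    rates = {k: epoch_rate(unit, v, epoch) for k, v in ids_by_type.items()}
    tt = stats.ttest_ind(*(rates[k] for k in task.TRIAL_TYPES), equal_var=False)
    preferred, pref_idx, est_idx = split_trial_preference(rates, n_pref_trials)
    nonpref = next(k for k in rates if k != preferred)
    sel = (rates[preferred][est_idx[preferred]].mean()
           - rates[nonpref][est_idx[nonpref]].mean())

    trace_t = trace = None
    if compute_trace:
        est_ids = np.concatenate([ids_by_type[k][est_idx[k]] for k in rates])
        trace_t, traces = psth(unit, trials, bin_s, smooth_s, trial_ids=est_ids)
        trace = traces[preferred] - traces[nonpref]

    return SelectivityResult(
        unit.unit_id, epoch, usable=True, preferred=preferred,
        selectivity_hz=float(sel), p_value=float(tt.pvalue),
        significant=bool(tt.pvalue < alpha),
        trace_t=trace_t, trace_hz=trace,
        pref_trials={k: ids_by_type[k][pref_idx[k]] for k in rates},
        est_trials={k: ids_by_type[k][est_idx[k]] for k in rates},
    )


# --------------------------------------------------------------------------
# ramping classification
# --------------------------------------------------------------------------

def classify_ramping(
    unit: UnitRecording,
    trials: pd.DataFrame,
    alpha: float = 0.05,
) -> RampClass:
    """Classify delay-epoch ramping as up, down or excluded.

    Delay activity is the per-trial difference between delay-epoch and
    baseline (500 ms pre-sample) rates.  A unit ramps if delay activity in at
    least one trial type differs significantly from 0 (Mann–Whitney U between
    the per-trial delay and baseline rate distributions, P < 0.05); the
    direction compares the last 500 ms of the delay against baseline for the
    type with the largest rate change.
    """
    sub = trials[trials.outcome == "correct"]
    delay_act, pvals = {}, {}
    for ttype, g in sub.groupby("trial_type"):
        ids = g.trial_id.to_numpy()
        delay = epoch_rate(unit, ids, "delay")
        base = epoch_rate(unit, ids, "baseline")
        if delay.sum() == 0 and base.sum() == 0:
            continue
        delay_act[ttype] = float(delay.mean() - base.mean())
        pvals[ttype] = float(stats.mannwhitneyu(
            delay, base, alternative="two-sided").pvalue)
    if not delay_act or min(pvals.values()) >= alpha:
        return RampClass(unit.unit_id, "excluded", delay_act, pvals)
    best = max(delay_act, key=lambda k: abs(delay_act[k]))
    ids = sub[sub.trial_type == best].trial_id.to_numpy()
    late = window_rate(unit, ids, task.GO_CUE_S - 0.5, task.GO_CUE_S)
    base = epoch_rate(unit, ids, "baseline")
    label = "up" if late.mean() > base.mean() else "down"
    return RampClass(unit.unit_id, label, delay_act, pvals)


# --------------------------------------------------------------------------
# anatomical assignment
# --------------------------------------------------------------------------

def assign_region(
    unit: UnitRecording,
    classification,
    atlas: AtlasSpec,
    pathway: str = "fastigial",
) -> tuple[str, str]:
    """(sub-)lobule and connectivity-region group of a unit's coordinates.

    Returns ``(label, group)`` where group is one of input-dominant /
    output-dominant / conjunction / excluded, or ``("unassigned",
    "unassigned")`` when the coordinates fall outside the atlas.
    """
    x, y, z = unit.coords_um
    lob = atlas.lobule_of(x, y, z)
    if lob is None:
        return "unassigned", "unassigned"
    thr = atlas.split_thresholds_um[pathway]
    if lob in thr:
        prefix = LATERAL_PREFIX if abs(x) >= thr[lob] else MEDIAL_PREFIX
        lob = prefix + lob
    return lob, classification.group_of(lob)


def selectivity_table(results: list[SelectivityResult]) -> pd.DataFrame:
    """Flatten per-unit results for CSV export."""
    return pd.DataFrame([{
        "unit_id": r.unit_id, "epoch": r.epoch, "usable": r.usable,
        "preferred": r.preferred, "selectivity_hz": r.selectivity_hz,
        "p_value": r.p_value, "significant": r.significant,
        "reason": r.reason,
    } for r in results])
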