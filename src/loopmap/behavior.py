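"""Photostimulation behavior statistics: Δperformance, bootstrap, BH.

Performance is the fraction of correct choices among scoreable trials
(early-lick and ignore trials are excluded from the denominator).  The effect
of stimulating a (spot, epoch) condition is the change in performance versus
control trials; its significance comes from a three-level hierarchical
bootstrap that resamples, with replacement, (1) mice, (2) sessions within
each resampled mouse and (3) trials within each resampled session, and scores
the one-sided p as the fraction of replicates whose Δperformance has the sign
opposite to the observed one.  The 16 grid locations are corrected with the
Benjamini–Hochberg step-up rule at α = 0.025.

Trial-level resampling is implemented through an exact distributional
equivalence: drawing n trials with replacement and counting category members
(correct / error / non-scoreable) is a multinomial draw, realized as two
chained binomials.  This is identical in law to index resampling for any
statistic that depends on trials only through those counts — performance
does — and makes large replicate counts cheap.  A literal index-resampling
reference implementation is retained for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_ALPHA = 0.025
DEFAULT_N_REPS = 10_000
SCOREABLE = ("correct", "error")


# --------------------------------------------------------------------------
# performance summaries
# --------------------------------------------------------------------------

def performance(trials: pd.DataFrame) -> pd.DataFrame:
    """Per (trial type × condition) performance summary.

    One row per (trial_type, stim_spot, stim_epoch): total trials, scoreable
    trials, fraction correct (NaN when no trial is scoreable, with
    ``undefined`` flagged), and early-lick / ignore fractions.
    """
    rows = []
    for (ttype, spot, epoch), g in trials.groupby(
            ["trial_type", "stim_spot", "stim_epoch"]):
        n = len(g)
        sco = g.outcome.isin(SCOREABLE).sum()
        cor = (g.outcome == "correct").sum()
        rows.append({
            "trial_type": ttype, "stim_spot": spot, "stim_epoch": epoch,
            "n_trials": n, "n_scoreable": int(sco),
            "performance": cor / sco if sco else np.nan,
            "undefined": sco == 0,
            "early_lick_frac": (g.outcome == "early-lick").mean(),
            "ignore_frac": (g.outcome == "ignore").mean(),
        })
    return pd.DataFrame(rows)


def _pooled_perf(df: pd.DataFrame) -> float:
    sco = df.outcome.isin(SCOREABLE).sum()
    return (df.outcome == "correct").sum() / sco if sco else np.nan


def observed_delta(
    trials: pd.DataFrame, spot: str, epoch: str, trial_type: str | None = None,
) -> float:
    """Δperformance (stim − control), as a fraction correct."""
    sub = trials if trial_type is None else trials[trials.trial_type == trial_type]
    ctl = sub[sub.stim_spot == "none"]
    stim = sub[(sub.stim_spot == spot) & (sub.stim_epoch == epoch)]
    if len(stim) == 0:
        raise ValueError(f"condition ({spot}, {epoch}) absent from dataset")
    return _pooled_perf(stim) - _pooled_perf(ctl)


# --------------------------------------------------------------------------
# hierarchical bootstrap
# --------------------------------------------------------------------------

@dataclass
class BootstrapEntry:
    spot: str
    epoch: str
    trial_type: str | None
    delta_performance: float  # stim − control, fraction correct
    p_value: float            # one-sided, floored at 0.5 / n_reps
    n_reps: int
    n_mice: int
    significant_bh: bool | None = None  # filled by bh_report
    deltas: np.ndarray | None = None    # replicate distribution, on request


def _session_stats(trials: pd.DataFrame, spot: str, epoch: str,
                   trial_type: str | None):
    """Per-(mouse, session) count table: total/scoreable/correct × {ctl, stim}."""
    sub = trials if trial_type is None else trials[trials.trial_type == trial_type]
    is_stim = (sub.stim_spot == spot) & (sub.stim_epoch == epoch)
    is_ctl = sub.stim_spot == "none"
    per_mouse = []
    for _, mg in sub.groupby("mouse_id"):
        rows = []
        for sid, sg in mg.groupby("session_id"):
            row = []
            for mask in (is_ctl.loc[sg.index], is_stim.loc[sg.index]):
                cell = sg[mask]
                row += [len(cell),
                        int(cell.outcome.isin(SCOREABLE).sum()),
                        int((cell.outcome == "correct").sum())]
            rows.append(row)
        per_mouse.append(np.array(rows, dtype=np.int64))
    return per_mouse


def _resample_counts(rng, tot, sco, cor):
    """Trial resampling of one condition cell: two chained binomials."""
    with np.errstate(invalid="ignore", divide="ignore"):
        p_sco = np.where(tot > 0, sco / np.maximum(tot, 1), 0.0)
    sco_r = rng.binomial(tot, p_sco)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_cor = np.where(sco > 0, cor / np.maximum(sco, 1), 0.0)
    cor_r = rng.binomial(sco_r, p_cor)
    return sco_r, cor_r


def hierarchical_bootstrap(
    trials: pd.DataFrame,
    spot: str,
    epoch: str,
    trial_type: str | None = None,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    keep_deltas: bool = False,
) -> BootstrapEntry:
    """Three-level (mice → sessions → trials) bootstrap of Δperformance.

    Each replicate draws as many mice as observed with replacement, then as
    many sessions as each resampled mouse has, then resamples trials within
    each (session × condition) cell, and recomputes the pooled Δperformance.
    The one-sided p is the fraction of replicates whose Δ has the opposite
    sign to the observed Δ (Δ = 0 replicates count one half); an exact zero
    is reported as ``0.5 / n_reps`` rather than 0.
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be >= 1000")
    obs = observed_delta(trials, spot, epoch, trial_type)
    per_mouse = _session_stats(trials, spot, epoch, trial_type)
    n_mice = len(per_mouse)
    if n_mice < 2:
        import warnings
        warnings.warn("hierarchical bootstrap with a single mouse", stacklevel=2)
    rng = np.random.default_rng(seed)

    sums = np.zeros((n_reps, 4))  # cor_ctl, sco_ctl, cor_stim, sco_stim
    mouse_pick = rng.integers(0, n_mice, size=(n_reps, n_mice))
    for m in range(n_mice):
        stats = per_mouse[m]
        n_sess = stats.shape[0]
        # every (replicate, slot) where mouse m was drawn
        rep_idx, n_slots = np.unique(
            np.repeat(np.arange(n_reps), n_mice)[
                (mouse_pick == m).ravel()], return_counts=True)
        if rep_idx.size == 0:
            continue
        # process each multiplicity separately to keep arrays rectangular
        for mult in np.unique(n_slots):
            reps_here = rep_idx[n_slots == mult]
            draw_shape = (reps_here.size, int(mult) * n_sess)
            sess = stats[rng.integers(0, n_sess, size=draw_shape)]
            for cols, out in (((0, 1, 2), (1, 0)), ((3, 4, 5), (3, 2))):
                tot, sco, cor = (sess[..., c] for c in cols)
                sco_r, cor_r = _resample_counts(rng, tot, sco, cor)
                sums[reps_here, out[0]] += sco_r.sum(axis=1)
                sums[reps_here, out[1]] += cor_r.sum(axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        perf_ctl = np.where(sums[:, 1] > 0, sums[:, 0] / np.maximum(sums[:, 1], 1),
                            np.nan)
        perf_stim = np.where(sums[:, 3] > 0, sums[:, 2] / np.maximum(sums[:, 3], 1),
                             np.nan)
    delta = perf_stim - perf_ctl
    delta = delta[np.isfinite(delta)]
    sign = 1.0 if obs >= 0 else -1.0
    p = (np.count_nonzero(sign * delta < 0) + 0.5 * np.count_nonzero(delta == 0)
         ) / delta.size
    p = max(p, 0.5 / n_reps)
    return BootstrapEntry(spot, epoch, trial_type, float(obs), float(p),
                          n_reps, n_mice,
                          deltas=delta if keep_deltas else None)


def hierarchical_bootstrap_reference(
    trials: pd.DataFrame,
    spot: str,
    epoch: str,
    trial_type: str | None = None,
    n_reps: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Literal index-resampling bootstrap (audit oracle; small inputs only).

    Returns the replicate Δperformance distribution produced by explicitly
    resampling mouse ids, session ids and trial indices with replacement.
    """
    sub = trials if trial_type is None else trials[trials.trial_type == trial_type]
    is_stim = (sub.stim_spot == spot) & (sub.stim_epoch == epoch)
    is_ctl = sub.stim_spot == "none"
    data = {}  # mouse → session → (ctl outcomes, stim outcomes)
    for m, mg in sub.groupby("mouse_id"):
        data[m] = {}
        for s, sg in mg.groupby("session_id"):
            data[m][s] = (
                sg.outcome[is_ctl.loc[sg.index]].to_numpy(),
                sg.outcome[is_stim.loc[sg.index]].to_numpy(),
            )
    mice = list(data)
    rng = np.random.default_rng(seed)
    deltas = np.empty(n_reps)
    for r in range(n_reps):
        cor = np.zeros(2)
        sco = np.zeros(2)
        for m in rng.choice(mice, len(mice), replace=True):
            sessions = list(data[m])
            for s in rng.choice(sessions, len(sessions), replace=True):
                for j, arr in enumerate(data[m][s]):
                    if arr.size == 0:
                        continue
                    res = arr[rng.integers(0, arr.size, arr.size)]
                    sco[j] += np.isin(res, SCOREABLE).sum()
                    cor[j] += (res == "correct").sum()
        perf = np.where(sco > 0, cor / np.maximum(sco, 1), np.nan)
        deltas[r] = perf[1] - perf[0]
    return deltas


# --------------------------------------------------------------------------
# Benjamini–Hochberg step-up
# --------------------------------------------------------------------------

def bh_correct(pvals, alpha: float = DEFAULT_ALPHA, m: int | None = None
               ) -> np.ndarray:
    """Step-up significance flags across the stimulation grid.

    Sorts the p-values ascending as P(1) ≤ … ≤ P(k), finds the largest i
    with P(i) ≤ α·i/m (m defaults to the number of comparisons), and flags
    the conditions of ranks 1..i, mapped back to the input order.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.zeros(0, bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = m if m is not None else p.size
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    passing = p[order] <= alpha * ranks / m
    flags = np.zeros(p.size, bool)
    if passing.any():
        i_star = ranks[passing].max()
        flags[order[:i_star]] = True
    return flags


def bh_report(entries: list[BootstrapEntry], alpha: float = DEFAULT_ALPHA,
              m: int | None = None) -> list[BootstrapEntry]:
    """Apply the BH rule across entries and fill their significance flags."""
    flags = bh_correct([e.p_value for e in entries], alpha,
                       m if m is not None else len(entries))
    for e, f in zip(entries, flags):
        e.significant_bh = bool(f)
    return entries
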