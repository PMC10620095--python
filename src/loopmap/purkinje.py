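"""Purkinje-cell identification and complex-spike response typing.

A Purkinje cell fires high-rate simple spikes (SS) and rare climbing-fiber
complex spikes (CS); a CS is followed by a characteristic SS pause.  The
pause in the SS×CS cross-correlogram is used to validate that an SS and a CS
cluster come from the same cell.  Validated cells are then typed by the
temporal profile of their CS activity: trial-pooled PSTHs are z-scored
against the pre-sample baseline, resampled onto a common 102-bin grid,
projected onto their top six principal components and clustered with k-means,
choosing the cluster number that maximizes the Euclidean silhouette over the
candidate range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from . import task
from .selectivity import UnitRecording

MIN_CS_EVENTS = 20
BASELINE_SD_FLOOR_HZ = 1e-6
N_PSTH_BINS = 102  # common PSTH length after downsampling


def psth_time_base(n_bins: int = N_PSTH_BINS) -> np.ndarray:
    """Bin centers (s, go-cue aligned) of the common 102-bin PSTH grid."""
    edges = np.linspace(task.TRIAL_START_S, task.TRIAL_END_S, n_bins + 1)
    return 0.5 * (edges[:-1] + edges[1:])


@dataclass
class Correlogram:
    lags_ms: np.ndarray
    ss_rate_hz: np.ndarray   # SS rate conditioned on a CS at lag 0
    baseline_hz: float       # mean SS rate at negative lags
    pause_ratio: float       # post-CS (0–10 ms) SS rate / baseline


@dataclass
class PauseValidation:
    accepted: bool | None    # None = indeterminate (too few CS)
    correlogram: Correlogram | None
    n_cs: int
    reason: str = ""


def _flatten(events) -> list[np.ndarray]:
    if isinstance(events, dict):
        return [np.asarray(v, float) for v in events.values()]
    return [np.asarray(events, float)]


def validate_cs_pause(
    ss_times,
    cs_times,
    pause_window_ms: float = 10.0,
    ratio_threshold: float = 0.5,
    corr_window_ms: float = 50.0,
    bin_ms: float = 1.0,
) -> PauseValidation:
    """Accept an SS/CS pair as one Purkinje cell if SS pause after CS.

    The pause statistic is the SS rate in the (0, ``pause_window_ms``] window
    after each CS divided by the baseline SS rate (negative lags of the
    cross-correlogram); the pair is accepted when the statistic falls below
    ``ratio_threshold``.  Fewer than 20 CS events → indeterminate, mirroring
    the practice of discarding ambiguous CS clusters.
    """
    ss_list, cs_list = _flatten(ss_times), _flatten(cs_times)
    n_cs = int(sum(c.size for c in cs_list))
    if n_cs < MIN_CS_EVENTS:
        return PauseValidation(None, None, n_cs,
                               f"only {n_cs} CS events (need {MIN_CS_EVENTS})")
    edges = np.arange(-corr_window_ms, corr_window_ms + bin_ms / 2, bin_ms)
    counts = np.zeros(edges.size - 1)
    for ss, cs in zip(ss_list, cs_list):
        for c in cs:
            counts += np.histogram((ss - c) * 1000.0, edges)[0]
    rate = counts / (n_cs * bin_ms / 1000.0)
    lags = 0.5 * (edges[:-1] + edges[1:])
    baseline = float(rate[lags < 0].mean())
    if baseline == 0:
        return PauseValidation(None, Correlogram(lags, rate, 0.0, np.nan),
                               n_cs, "no baseline SS activity")
    post = rate[(lags > 0) & (lags <= pause_window_ms)].mean()
    ratio = float(post / baseline)
    corr = Correlogram(lags, rate, baseline, ratio)
    return PauseValidation(bool(ratio < ratio_threshold), corr, n_cs)


# --------------------------------------------------------------------------
# z-scored PSTHs on the common 102-bin grid
# --------------------------------------------------------------------------

@dataclass
class TypedPSTH:
    unit_id: int
    condition: str           # "correct" | "error"
    z: np.ndarray | None     # (102,) z-scored rate, None when excluded
    excluded: bool = False
    reason: str = ""


def zscore_psth(
    unit: UnitRecording,
    trials: pd.DataFrame,
    condition: str = "correct",
    stream: str = "cs",
    bin_s: float = 0.2,
    n_bins: int = N_PSTH_BINS,
) -> TypedPSTH:
    """Trial-pooled, baseline-z-scored PSTH downsampled to 102 bins.

    Both trial types are pooled.  The PSTH is computed in 200-ms bins, then
    linearly interpolated onto ``n_bins`` evenly spaced bins; the z-score
    uses the mean and s.d. of the per-trial pre-sample baseline bin rates.
    """
    spikes = unit.cs_spikes if stream == "cs" else unit.spikes
    if spikes is None:
        return TypedPSTH(unit.unit_id, condition, None, True,
                         f"unit has no {stream} stream")
    ids = trials[trials.outcome == condition].trial_id.to_numpy()
    if ids.size == 0:
        return TypedPSTH(unit.unit_id, condition, None, True,
                         f"no {condition} trials")
    edges = np.arange(task.TRIAL_START_S, task.TRIAL_END_S + bin_s / 2, bin_s)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rates = np.vstack([np.histogram(spikes[t], edges)[0] / bin_s for t in ids])
    base_cols = centers < task.SAMPLE_START_S
    base = rates[:, base_cols].ravel()
    mu, sd = base.mean(), base.std(ddof=1)
    if sd < BASELINE_SD_FLOOR_HZ:
        return TypedPSTH(unit.unit_id, condition, None, True,
                         "baseline s.d. below floor")
    psth = rates.mean(axis=0)
    fine = np.linspace(centers[0], centers[-1], n_bins)
    z = np.interp(fine, centers, (psth - mu) / sd)
    return TypedPSTH(unit.unit_id, condition, z)


# --------------------------------------------------------------------------
# response-type clustering
# --------------------------------------------------------------------------

@dataclass
class ClusterModel:
    pc_scores: np.ndarray | None
    silhouettes: dict[int, float] = field(default_factory=dict)
    selected_k: int | None = None
    labels: np.ndarray | None = None
    degenerate: bool = False
    no_structure: bool = False
    reason: str = ""


def cluster_response_types(
    psths: np.ndarray,
    n_pcs: int = 6,
    k_range=range(1, 21),
    n_restarts: int = 50,
    seed: int = 0,
    min_silhouette: float = 0.25,
) -> ClusterModel:
    """Silhouette-selected k-means over top-6 principal-component scores.

    ``psths`` is an (n_units, n_bins) matrix of z-scored PSTHs.  For every
    candidate k >= 2 in ``k_range``, k-means (seeded, ``n_restarts``
    restarts) is scored by the mean Euclidean silhouette; the k with the
    largest silhouette is selected.  Silhouette is undefined at k = 1, so
    k = 1 ("no structure") is reported only when every candidate's
    silhouette falls below ``min_silhouette``.
    """
    X = np.asarray(psths, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 units")
    if np.allclose(X, X[0]):
        return ClusterModel(None, degenerate=True,
                            reason="all PSTHs identical")
    n_pcs = min(n_pcs, X.shape[0] - 1, X.shape[1])
    scores = PCA(n_components=n_pcs, random_state=seed).fit_transform(X)

    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if k < 2 or k > X.shape[0] - 1:
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        lab = km.fit_predict(scores)
        if np.unique(lab).size < 2:
            continue
        sil[k] = float(silhouette_score(scores, lab, metric="euclidean"))
        labels_by_k[k] = lab
    if not sil:
        return ClusterModel(scores, degenerate=True, reason="no valid k >= 2")
    best = max(sil, key=sil.get)
    if sil[best] < min_silhouette and 1 in k_range:
        return ClusterModel(scores, sil, selected_k=1,
                            labels=np.zeros(X.shape[0], int),
                            no_structure=True,
                            reason=f"max silhouette {sil[best]:.3f} < "
                                   f"{min_silhouette}")
    return ClusterModel(scores, sil, selected_k=best, labels=labels_by_k[best])
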