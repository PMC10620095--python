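"""Connectivity-density maps and region classification.

The mesoscale map is built from annotated point clouds: mossy-fiber terminals
(cortico-cerebellar *input* via the pons) and retrogradely labelled Purkinje
somata (cerebellar *output* to a deep nucleus).  For each mouse, the count in
every lobule is turned into a fraction of that mouse's total and divided by
the lobule volume (in 10-µm reference voxels), which compensates for both
infection-rate variability and lobule size.  Lobules whose cross-mouse mean
input/output densities exceed a threshold (default 1e-11 on the voxel-volume
scale) are classified as input-dominant, output-dominant or conjunction
regions; a voxel-level tessellation supports the connectivity→activity model
comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold, cross_val_predict
from sklearn.neighbors import KernelDensity

from .atlas import (AtlasSpec, AtlasError, LATERAL_PREFIX, MEDIAL_PREFIX,
                    default_atlas)

log = logging.getLogger(__name__)

DENSITY_THRESHOLD = 1e-11  # on fraction / (10-µm voxel count)
REGION_GROUPS = ("input-dominant", "output-dominant", "conjunction", "excluded")


# --------------------------------------------------------------------------
# normalized densities
# --------------------------------------------------------------------------

@dataclass
class ConnectivityProfile:
    """Per-mouse and cross-mouse normalized densities over a region set."""
    per_mouse: pd.DataFrame  # mouse_id, region, count, fraction, volume_voxels, density
    summary: pd.DataFrame    # region, mean_density, sem_density, n_mice
    regions: list[str]
    combine_hemispheres: bool


def normalized_density(
    points: pd.DataFrame,
    atlas: AtlasSpec | None = None,
    combine_hemispheres: bool = True,
    hemisphere: str = "R",
    pathway: str = "fastigial",
    label_col: str = "lobule",
    regions: list[str] | None = None,
) -> ConnectivityProfile:
    """Normalized per-lobule density profile, one row per (mouse, region).

    ``fraction`` is the mouse's count in the region divided by its total
    count over all regions; ``density = fraction / volume`` with volume in
    10-µm voxels.  Input maps combine hemispheres; output maps use a single
    hemisphere (``combine_hemispheres=False``), halving the region volumes.
    """
    atlas = atlas or default_atlas()
    if regions is None:
        has_split = points[label_col].astype(str).str.startswith(
            (MEDIAL_PREFIX, LATERAL_PREFIX)).any()
        regions = atlas.region_labels(pathway) if has_split else atlas.names
    unknown = set(points[label_col]) - set(regions)
    if unknown:
        raise AtlasError(f"labels outside the atlas vocabulary: {sorted(unknown)}")

    if not combine_hemispheres:
        points = points[points.hemisphere == hemisphere]
    volumes = {
        r: atlas.volume_voxels(r, pathway, single_hemisphere=not combine_hemispheres)
        for r in regions
    }

    rows = []
    for mouse, g in points.groupby("mouse_id"):
        total = len(g)
        if total == 0:
            log.warning("mouse %s has zero points; excluded", mouse)
            continue
        counts = g[label_col].value_counts()
        for r in regions:
            c = int(counts.get(r, 0))
            f = c / total
            rows.append({
                "mouse_id": mouse, "region": r, "count": c, "fraction": f,
                "volume_voxels": volumes[r], "density": f / volumes[r],
            })
    if not rows:
        raise ValueError("no mouse contributed any points")
    per_mouse = pd.DataFrame(rows)

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    summary = (per_mouse.groupby("region")["density"]
               .agg(mean_density="mean", sem_density=_sem, n_mice="size")
               .reindex(regions).reset_index())
    return ConnectivityProfile(per_mouse, summary, list(regions),
                               combine_hemispheres)


def kde_map(
    points: pd.DataFrame,
    kernel_widths_um: tuple[float, float, float] = (20.0, 20.0, 20.0),
) -> np.ndarray:
    """Cross-mouse average 3-D kernel density, evaluated at every point.

    A Gaussian product kernel with per-axis sigma equal to the stated kernel
    width is fitted separately per mouse (injection case), evaluated at all
    annotated points, and the per-mouse densities are averaged.  The returned
    array is aligned with the rows of ``points``.
    """
    w = np.asarray(kernel_widths_um, float)
    if np.any(w <= 0):
        raise ValueError("kernel widths must be positive")
    xyz = points[["x_um", "y_um", "z_um"]].to_numpy(float)
    scaled = xyz / w  # per-axis bandwidths via change of variables
    mouse_ids = points["mouse_id"].to_numpy()
    uniq = np.unique(mouse_ids)
    dens = np.zeros((uniq.size, len(points)))
    for i, m in enumerate(uniq):
        kde = KernelDensity(kernel="gaussian", bandwidth=1.0)
        kde.fit(scaled[mouse_ids == m])
        dens[i] = np.exp(kde.score_samples(scaled)) / np.prod(w)
    return dens.mean(axis=0)


def split_sublobules(
    points: pd.DataFrame,
    atlas: AtlasSpec | None = None,
    pathway: str = "fastigial",
    thresholds_um: dict[str, float] | None = None,
    label_col: str = "lobule",
) -> pd.DataFrame:
    """Relabel points in splittable lobules as ``med-X`` / ``lat-X``.

    The mediolateral distance from the midline is compared with the lobule's
    threshold; distance >= threshold is lateral (documented tie convention).
    """
    atlas = atlas or default_atlas()
    thr = (thresholds_um if thresholds_um is not None
           else atlas.split_thresholds_um[pathway])
    out = points.copy()
    ml = out.x_um.abs()
    for name, t in thr.items():
        mask = out[label_col] == name
        out.loc[mask, label_col] = np.where(
            ml[mask] >= t, LATERAL_PREFIX + name, MEDIAL_PREFIX + name)
    return out


# --------------------------------------------------------------------------
# region classification
# --------------------------------------------------------------------------

@dataclass
class RegionClassification:
    groups: dict[str, str]  # region label → group
    theta: float

    def group_of(self, label: str) -> str:
        try:
            return self.groups[label]
        except KeyError:
            raise AtlasError(f"label {label!r} not in the classification")

    def members(self, group: str) -> list[str]:
        return sorted(r for r, g in self.groups.items() if g == group)


def classify_regions(
    input_profile: ConnectivityProfile,
    output_profile: ConnectivityProfile,
    theta: float = DENSITY_THRESHOLD,
) -> RegionClassification:
    """Classify every region by thresholding cross-mouse mean densities.

    Both above the threshold → conjunction; input only → input-dominant;
    output only → output-dominant; neither → excluded.
    """
    if theta <= 0:
        raise ValueError("theta must be > 0")
    if set(input_profile.regions) != set(output_profile.regions):
        raise AtlasError("input and output profiles cover different region sets")
    mi = input_profile.summary.set_index("region")["mean_density"]
    mo = output_profile.summary.set_index("region")["mean_density"]
    groups = {}
    for r in input_profile.regions:
        above_in, above_out = mi[r] > theta, mo[r] > theta
        if above_in and above_out:
            groups[r] = "conjunction"
        elif above_in:
            groups[r] = "input-dominant"
        elif above_out:
            groups[r] = "output-dominant"
        else:
            groups[r] = "excluded"
    return RegionClassification(groups, theta)


# --------------------------------------------------------------------------
# voxel tessellation and the connectivity→activity model
# --------------------------------------------------------------------------

@dataclass
class VoxelGrid:
    edge_um: float
    table: pd.DataFrame  # one row per non-empty voxel


def _voxel_index(df: pd.DataFrame, edge: float) -> pd.DataFrame:
    idx = np.floor(df[["x_um", "y_um", "z_um"]].to_numpy(float) / edge).astype(int)
    return pd.DataFrame(idx, columns=["ix", "iy", "iz"])


def voxelize(
    inputs: pd.DataFrame,
    outputs: pd.DataFrame,
    units: pd.DataFrame | None = None,
    edge_um: float = 100.0,
) -> VoxelGrid:
    """Tessellate space into cubic voxels (default 100 µm) spanning lobules.

    Per voxel: raw input/output counts, counts normalized to the grand total
    of each marker, and — where recorded units fall inside — the number of
    units, the fraction with significant delay selectivity and their mean
    selectivity amplitude.  Activity fields are NaN in voxels without units.
    """
    if edge_um <= 0:
        raise ValueError("edge must be > 0")

    def _counts(df, name):
        if len(df) == 0:
            return pd.DataFrame(columns=["ix", "iy", "iz", name])
        v = _voxel_index(df, edge_um)
        return (v.groupby(["ix", "iy", "iz"]).size()
                .rename(name).reset_index())

    tab = _counts(inputs, "input_count").merge(
        _counts(outputs, "output_count"), on=["ix", "iy", "iz"], how="outer")

    if units is not None and len(units):
        v = _voxel_index(units, edge_um)
        u = units.assign(**{c: v[c].to_numpy() for c in ("ix", "iy", "iz")})
        agg = (u.groupby(["ix", "iy", "iz"])
               .agg(n_units=("significant", "size"),
                    frac_selective=("significant", "mean"),
                    mean_amplitude_hz=("selectivity_hz", "mean"))
               .reset_index())
        tab = tab.merge(agg, on=["ix", "iy", "iz"], how="outer")
    else:
        tab["n_units"] = np.nan
        tab["frac_selective"] = np.nan
        tab["mean_amplitude_hz"] = np.nan

    for c in ("input_count", "output_count"):
        tab[c] = tab[c].astype(float).fillna(0).astype(int)
        total = tab[c].sum()
        tab[c.replace("_count", "_norm")] = tab[c] / total if total else 0.0
    tab["n_units"] = tab["n_units"].fillna(0).astype(int)
    tab.loc[tab.n_units == 0, ["frac_selective", "mean_amplitude_hz"]] = np.nan
    return VoxelGrid(edge_um, tab.reset_index(drop=True))


@dataclass
class ModelComparison:
    """Cross-validated R² of single-predictor models of voxel activity."""
    r2: dict[str, dict[str, float]]  # measure → predictor → CV R²
    winner: dict[str, str | None] = field(default_factory=dict)
    n_voxels: int = 0


PREDICTORS = ("input", "output", "product")
ACTIVITY_MEASURES = ("frac_selective", "mean_amplitude_hz")


def connectivity_activity_model(
    grid: VoxelGrid,
    n_folds: int = 5,
    seed: int = 0,
    min_voxels: int = 10,
) -> ModelComparison:
    """Compare input, output and input×output as predictors of activity.

    For each activity measure, fits three single-predictor linear models on
    the voxels containing recorded units and reports the 5-fold
    cross-validated R² of each, plus the winning predictor.  A predictor with
    zero variance is reported as NaN (R² undefined).
    """
    tab = grid.table[grid.table.n_units > 0]
    if len(tab) < min_voxels:
        raise ValueError(f"need >= {min_voxels} voxels with units, got {len(tab)}")
    X = {
        "input": tab.input_norm.to_numpy(),
        "output": tab.output_norm.to_numpy(),
        "product": (tab.input_norm * tab.output_norm).to_numpy(),
    }
    cv = KFold(min(n_folds, len(tab)), shuffle=True, random_state=seed)
    r2: dict[str, dict[str, float]] = {}
    winner: dict[str, str | None] = {}
    for measure in ACTIVITY_MEASURES:
        y = tab[measure].to_numpy(float)
        r2[measure] = {}
        for name, x in X.items():
            if np.ptp(x) == 0:
                r2[measure][name] = np.nan
                continue
            yhat = cross_val_predict(LinearRegression(), x[:, None], y, cv=cv)
            ss_res = np.sum((y - yhat) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2[measure][name] = float(1.0 - ss_res / ss_tot)
        finite = {k: v for k, v in r2[measure].items() if np.isfinite(v)}
        winner[measure] = max(finite, key=finite.get) if finite else None
    return ModelComparison(r2, winner, len(tab))
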