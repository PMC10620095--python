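"""Parametric cerebellar atlas used by the density pipeline.

The real analysis assigns annotated points to lobules via the Allen reference
ontology at 10-µm voxel resolution.  Here the reference geometry is a
parametric stand-in: each lobule is an axis-aligned box with a realistic
CCF-scale volume (stored as a count of 10-µm voxels, the unit in which lobule
volume enters the normalized-density formula).  Boxes are mirror-symmetric
about the midline; coordinates are in µm with the mediolateral axis ``x``
signed (midline at ``x = 0``, right hemisphere positive), ``y`` increasing
anterior→posterior and ``z`` dorsoventral.  Boxes occupy disjoint ``(|x|, y)``
territories so that point→lobule lookup is unambiguous.

Hemispheric lobules (simplex, Crus 1/2, paramedian, copula, paraflocculus,
flocculus) can be split into medial/lateral sub-lobules at a pathway-specific
mediolateral threshold; sub-lobule volumes are prorated by the mediolateral
fraction of the parent box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VOXEL_UM = 10.0
VOXELS_PER_MM3 = 1_000_000  # (1000 µm / 10 µm)^3

#: mediolateral split thresholds, µm lateral from midline
SPLIT_THRESHOLDS_UM: dict[str, dict[str, float]] = {
    # ALM output defined via the fastigial nucleus
    "fastigial": {"SIM": 2500.0, "Crus 1": 3200.0, "Crus 2": 2700.0},
    # variant with output defined via the dentate nucleus
    "dentate": {"SIM": 2200.0, "Crus 1": 2200.0, "Crus 2": 1700.0, "PRM": 2200.0},
}

MEDIAL_PREFIX = "med-"
LATERAL_PREFIX = "lat-"


@dataclass(frozen=True)
class LobuleBox:
    """Axis-aligned, midline-symmetric box standing in for one lobule."""

    name: str
    volume_voxels: int  # 10-µm reference voxels, both hemispheres
    x_lat_um: tuple[float, float]  # |mediolateral| extent from midline
    y_um: tuple[float, float]  # anteroposterior extent
    z_um: tuple[float, float] = (0.0, 2500.0)

    def contains(self, x: float, y: float, z: float) -> bool:
        ax = abs(x)
        return (
            self.x_lat_um[0] <= ax <= self.x_lat_um[1]
            and self.y_um[0] <= y <= self.y_um[1]
            and self.z_um[0] <= z <= self.z_um[1]
        )


def _box(name, mm3, x_lat, y):
    return LobuleBox(name, int(round(mm3 * VOXELS_PER_MM3)), x_lat, y)


_DEFAULT_LOBULES: tuple[LobuleBox, ...] = (
    # vermis, anterior → posterior
    _box("Lob I", 0.4, (0.0, 1000.0), (0.0, 700.0)),
    _box("Lob II", 1.0, (0.0, 1000.0), (700.0, 1400.0)),
    _box("Lob III", 2.0, (0.0, 1000.0), (1400.0, 2100.0)),
    _box("Lob IV", 1.5, (0.0, 1000.0), (2100.0, 2800.0)),
    _box("Lob V", 2.0, (0.0, 1000.0), (2800.0, 3500.0)),
    _box("Lob VI", 2.6, (0.0, 1000.0), (3500.0, 4300.0)),
    _box("Lob VII", 1.5, (0.0, 1000.0), (4300.0, 5000.0)),
    _box("Lob VIII", 1.7, (0.0, 1000.0), (5000.0, 5700.0)),
    _box("Lob IX", 2.0, (0.0, 1000.0), (5700.0, 6500.0)),
    _box("Lob X", 1.0, (0.0, 1000.0), (6500.0, 7200.0)),
    # hemispheres, anterior → posterior
    _box("SIM", 3.1, (1000.0, 4200.0), (1500.0, 2600.0)),
    _box("Crus 1", 4.3, (1000.0, 4800.0), (2600.0, 3800.0)),
    _box("Crus 2", 3.4, (1000.0, 4500.0), (3800.0, 4800.0)),
    _box("PRM", 2.6, (1000.0, 4200.0), (4800.0, 5700.0)),
    _box("COPY", 1.4, (1000.0, 2400.0), (5700.0, 6400.0)),
    _box("PFL", 1.8, (3000.0, 5200.0), (6400.0, 7000.0)),
    _box("FL", 0.5, (3200.0, 5000.0), (7000.0, 7500.0)),
)


class AtlasError(ValueError):
    """Raised for unknown lobule labels or invalid atlas geometry."""


@dataclass(frozen=True)
class AtlasSpec:
    """Lobule geometry, volumes and mediolateral split thresholds."""

    lobules: tuple[LobuleBox, ...] = _DEFAULT_LOBULES
    split_thresholds_um: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in SPLIT_THRESHOLDS_UM.items()}
    )
    #: plane (µm, anteroposterior) onto which the optional posterior-tip
    #: collapse projects points, mimicking sections registered to the last
    #: available template section
    posterior_cap_um: float = 7000.0

    def __post_init__(self):
        names = [lb.name for lb in self.lobules]
        if len(set(names)) != len(names):
            raise AtlasError("lobule names must be unique")
        for lb in self.lobules:
            if lb.volume_voxels <= 0:
                raise AtlasError(f"{lb.name}: volume must be strictly positive")
        for pathway, thr in self.split_thresholds_um.items():
            for name, t in thr.items():
                lb = self.lobule(name)
                if not (lb.x_lat_um[0] < t < lb.x_lat_um[1]):
                    raise AtlasError(
                        f"{pathway}/{name}: split threshold {t} µm outside "
                        f"mediolateral extent {lb.x_lat_um}"
                    )

    # -- lookup ---------------------------------------------------------

    @property
    def names(self) -> list[str]:
        return [lb.name for lb in self.lobules]

    def lobule(self, name: str) -> LobuleBox:
        base = strip_sublobule(name)
        for lb in self.lobules:
            if lb.name == base:
                return lb
        raise AtlasError(f"unknown lobule {name!r}")

    def lobule_of(self, x: float, y: float, z: float) -> str | None:
        """Base lobule containing a point, or None if outside the atlas."""
        for lb in self.lobules:
            if lb.contains(x, y, z):
                return lb.name
        return None

    # -- sub-lobules and volumes ---------------------------------------

    def region_labels(self, pathway: str = "fastigial") -> list[str]:
        """Lobule vocabulary after mediolateral splitting for a pathway."""
        thr = self._thresholds(pathway)
        out: list[str] = []
        for lb in self.lobules:
            if lb.name in thr:
                out += [MEDIAL_PREFIX + lb.name, LATERAL_PREFIX + lb.name]
            else:
                out.append(lb.name)
        return out

    def _thresholds(self, pathway: str) -> dict[str, float]:
        try:
            return self.split_thresholds_um[pathway]
        except KeyError:
            raise AtlasError(
                f"unknown pathway {pathway!r}; expected one of "
                f"{sorted(self.split_thresholds_um)}"
            )

    def medial_fraction(self, name: str, pathway: str = "fastigial") -> float:
        """Mediolateral volume fraction of the medial sub-lobule."""
        lb = self.lobule(name)
        t = self._thresholds(pathway)[lb.name]
        lo, hi = lb.x_lat_um
        return (t - lo) / (hi - lo)

    def volume_voxels(
        self, label: str, pathway: str = "fastigial", single_hemisphere: bool = False
    ) -> float:
        """Volume (10-µm voxels) of a lobule or med-/lat- sub-lobule."""
        lb = self.lobule(label)
        v = float(lb.volume_voxels)
        if label.startswith(MEDIAL_PREFIX):
            v *= self.medial_fraction(lb.name, pathway)
        elif label.startswith(LATERAL_PREFIX):
            v *= 1.0 - self.medial_fraction(lb.name, pathway)
        if single_hemisphere:
            v /= 2.0
        return v

    # -- sampling support ----------------------------------------------

    def sample_box(self, label: str, pathway: str = "fastigial"):
        """(|x| range, y range, z range) of a lobule or sub-lobule box."""
        lb = self.lobule(label)
        lo, hi = lb.x_lat_um
        if label.startswith(MEDIAL_PREFIX):
            hi = self._thresholds(pathway)[lb.name]
        elif label.startswith(LATERAL_PREFIX):
            lo = self._thresholds(pathway)[lb.name]
        return (lo, hi), lb.y_um, lb.z_um


def strip_sublobule(label: str) -> str:
    """``med-Crus 1`` / ``lat-Crus 1`` → ``Crus 1``; base labels unchanged."""
    for prefix in (MEDIAL_PREFIX, LATERAL_PREFIX):
        if label.startswith(prefix):
            return label[len(prefix):]
    return label


def default_atlas() -> AtlasSpec:
    return AtlasSpec()


def lobules_of_points(atlas: AtlasSpec, xyz: np.ndarray) -> list[str | None]:
    """Vector convenience wrapper over :meth:`AtlasSpec.lobule_of`."""
    return [atlas.lobule_of(x, y, z) for x, y, z in np.asarray(xyz, float)]
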