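"""Point-source phantoms for SPECT resolution measurements.

Builds the voxelized activity and attenuation (mu) maps for the three
measurement configurations:

* **warm** - point sources inside a 22 cm water cylinder containing a low
  uniform background activity (source-to-background ratio > 50),
* **cold**  - same cylinder filled with non-radioactive water,
* **air**  - sources suspended with no surrounding medium.

Sources are coplanar in a single transverse plane at radii of a few cm from
the isocenter, with azimuths staggered so that neighbouring reconstructed
blobs do not overlap. Each source is smaller than a voxel and is deposited
with sub-voxel accuracy by bilinear weighting onto the four nearest voxel
centers, which conserves both total activity and the activity-weighted
centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .grid import GridSpec

GOLDEN_ANGLE_DEG = 180.0 * (3.0 - math.sqrt(5.0))  # ~137.5078 deg

#: water linear attenuation coefficient at 140 keV, 1/mm
MU_WATER_PER_MM = 0.015


class LayoutError(ValueError):
    """Raised when a source layout cannot satisfy its geometric constraints."""


@dataclass(frozen=True)
class PointSourceSpec:
    """A sub-voxel point source at polar position (radius, azimuth)."""

    radius_cm: float
    azimuth_deg: float
    activity_rel: float = 1.0
    extent_mm: float = 0.0  # < 1 mm: treated as a point

    @property
    def center_mm(self) -> tuple[float, float]:
        r = self.radius_cm * 10.0
        a = math.radians(self.azimuth_deg)
        return (r * math.cos(a), r * math.sin(a))


@dataclass(frozen=True)
class BackgroundSpec:
    """Surrounding-medium description for one experiment kind."""

    kind: str  # 'warm' | 'cold' | 'air'
    cylinder_diameter_mm: float = 220.0
    sbr: float = 500.0  # warm only; source-peak to background voxel ratio
    mu_water_per_mm: float = MU_WATER_PER_MM

    def __post_init__(self) -> None:
        if self.kind not in ("warm", "cold", "air"):
            raise ValueError(f"unknown background kind {self.kind!r}")
        if self.kind == "warm" and self.sbr <= 1:
            raise ValueError("warm background requires sbr > 1")

    @classmethod
    def warm(cls, sbr: float = 500.0) -> "BackgroundSpec":
        return cls("warm", sbr=sbr)

    @classmethod
    def cold(cls) -> "BackgroundSpec":
        return cls("cold")

    @classmethod
    def air(cls) -> "BackgroundSpec":
        return cls("air")


@dataclass
class PhantomImage:
    """Co-registered activity and attenuation grids plus source metadata."""

    activity: np.ndarray
    mu_map: np.ndarray
    grid: GridSpec
    sources: list[PointSourceSpec] = field(default_factory=list)
    background: BackgroundSpec | None = None

    def __post_init__(self) -> None:
        if self.activity.shape != self.mu_map.shape:
            raise ValueError("activity and mu_map shapes differ")
        if np.any(self.activity < 0):
            raise ValueError("activity must be nonnegative")
        if np.any(self.mu_map < 0):
            raise ValueError("mu_map must be nonnegative")

    @property
    def source_centers_mm(self) -> np.ndarray:
        return np.array([s.center_mm for s in self.sources], float).reshape(-1, 2)


def _pairwise_min_separation(centers: np.ndarray) -> float:
    if len(centers) < 2:
        return math.inf
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
    return float(d[np.triu_indices(len(centers), 1)].min())


def build_layout(
    radii_cm,
    grid: GridSpec,
    *,
    min_separation_mm: float = 40.0,
    azimuth0_deg: float = 20.0,
    stagger_step_deg: float = GOLDEN_ANGLE_DEG,
    adjust_step_deg: float = 15.0,
    edge_margin_mm: float = 4.0,
) -> list[PointSourceSpec]:
    """Place one source per radius with staggered azimuths.

    Azimuths follow golden-angle increments per radius; any source whose
    realized center comes closer than ``min_separation_mm`` to an
    already-placed one is rotated in ``adjust_step_deg`` increments until the
    constraint holds. Deterministic for fixed parameters.
    """
    radii = [float(r) for r in radii_cm]
    if len(set(radii)) != len(radii):
        raise LayoutError("radii must be distinct")
    limit = grid.fov_mm / 2.0 - edge_margin_mm
    for r in radii:
        if r < 0:
            raise LayoutError(f"radius {r} cm is negative")
        if r * 10.0 >= limit:
            raise LayoutError(
                f"radius {r} cm lies outside the usable field of view "
                f"(limit {limit / 10.0:.1f} cm)"
            )

    sources: list[PointSourceSpec] = []
    placed: list[tuple[float, float]] = []
    for k, r in enumerate(radii):
        base = azimuth0_deg + k * stagger_step_deg
        if r == 0.0:
            src = PointSourceSpec(0.0, base % 360.0)
            sources.append(src)
            placed.append(src.center_mm)
            continue
        n_try = max(1, int(math.ceil(360.0 / adjust_step_deg)))
        for attempt in range(n_try):
            src = PointSourceSpec(r, (base + attempt * adjust_step_deg) % 360.0)
            c = np.array([*placed, src.center_mm])
            if len(placed) == 0 or _pairwise_min_separation(c) >= min_separation_mm:
                break
        else:
            raise LayoutError(
                f"cannot place source at radius {r} cm with min separation "
                f"{min_separation_mm} mm; try a larger minimum-angle step or "
                "fewer radii"
            )
        sources.append(src)
        placed.append(src.center_mm)
    return sources


def deposit_point(activity: np.ndarray, grid: GridSpec, center_mm, weight: float) -> None:
    """Bilinear sub-voxel deposition of ``weight`` at a continuous position.

    The four bilinear weights sum to 1 and their intensity-weighted centroid
    is the continuous position, so total activity and centroid are preserved.
    """
    x, y = center_mm
    n = grid.n_xy
    cf = grid.mm_to_index(np.array([x, y]))
    jf, if_ = cf[0], cf[1]
    j0, i0 = int(np.floor(jf)), int(np.floor(if_))
    fj, fi = jf - j0, if_ - i0
    for di, wi in ((0, 1.0 - fi), (1, fi)):
        for dj, wj in ((0, 1.0 - fj), (1, fj)):
            i, j = i0 + di, j0 + dj
            w = wi * wj
            if w == 0.0:
                continue
            if not (0 <= i < n and 0 <= j < n):
                raise LayoutError(f"source at ({x:.1f}, {y:.1f}) mm falls off the grid")
            activity[i, j] += weight * w


def cylinder_mask(grid: GridSpec, diameter_mm: float) -> np.ndarray:
    """Boolean mask of voxel centers inside the phantom cylinder."""
    return grid.radius_map_mm() <= diameter_mm / 2.0


def compose_phantom(
    sources: list[PointSourceSpec],
    background: BackgroundSpec,
    grid: GridSpec,
) -> PhantomImage:
    """Deposit sources and background into activity and mu grids.

    For a warm background the uniform background level is set to
    ``min(source peak voxel value) / sbr`` so that *every* source satisfies
    the stated peak-to-background ratio before any blurring.
    """
    n = grid.n_xy
    activity = np.zeros((n, n), float)
    mu = np.zeros((n, n), float)

    if background.kind in ("warm", "cold"):
        rad = background.cylinder_diameter_mm / 2.0
        for s in sources:
            if math.hypot(*s.center_mm) >= rad:
                raise LayoutError(
                    f"source at radius {s.radius_cm} cm lies outside the "
                    f"{background.cylinder_diameter_mm / 10.0:.0f} cm cylinder"
                )

    peaks = []
    for s in sources:
        single = np.zeros((n, n), float)
        deposit_point(single, grid, s.center_mm, s.activity_rel)
        peaks.append(single.max())
        activity += single

    mask = cylinder_mask(grid, background.cylinder_diameter_mm)
    if background.kind == "warm" and peaks:
        activity[mask] += min(peaks) / background.sbr
    if background.kind in ("warm", "cold"):
        mu[mask] = background.mu_water_per_mm

    return PhantomImage(activity, mu, grid, list(sources), background)

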