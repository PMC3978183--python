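"""Tomographic reconstruction: FBP and OSEM with RR / AC / SC compensation.

``osem`` is a standard ordered-subsets expectation maximization with a
multiplicative EM update per subset,

    x <- x / (A_S^T 1) * A_S^T [ y_S / max(A_S x + s_S, eps) ],

where the system operator ``A`` includes the depth-dependent collimator PSF
when resolution recovery (rr) is on and attenuation factors when attenuation
correction (ac) is on, and ``s`` is the dual-energy-window scatter estimate
when scatter correction (sc) is on. Scatter enters the forward model
additively (no pre-subtraction), which keeps the Poisson statistics of the
measured counts valid. Views are assigned to subsets round-robin by view
index modulo SUB and subsets are visited in bit-reversed order; with SUB=1
the loop reduces exactly to classical MLEM.

``fbp`` is frequency-domain ramp filtering (optionally Hann-windowed, with a
configurable cutoff in cycles/mm) of each view, zero-padded to at least twice
the bin count, followed by pixel-driven backprojection with linear
interpolation and a pi/n_views scale. No attenuation or scatter compensation
is applied in FBP (its use case is sources in air).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import ndimage
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

from .acquisition import SinogramSet
from .grid import GridSpec
from .phantom import BackgroundSpec, cylinder_mask
from .projector import CollimatorResponse, OrbitGeometry, RotateProjector

_EPS = 1e-12
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: the iteration x subset ladder of the reference reconstruction study
IT_SUB_LADDER = ((1, 18), (10, 18), (20, 18), (30, 18), (30, 36), (30, 60), (30, 90))


@dataclass(frozen=True)
class ReconConfig:
    """Algorithm settings; deterministic (no random state)."""

    algorithm: str = "OSEM"  # 'OSEM' | 'FBP'
    iterations: int = 10
    subsets: int = 18
    rr: bool = True
    ac: bool = True
    sc: bool = True
    fbp_filter: str = "hann"  # 'ramp' | 'hann'
    fbp_cutoff_cyc_mm: float | None = None  # None -> Nyquist
    dew_k: float = 0.5

    def __post_init__(self) -> None:
        if self.algorithm not in ("OSEM", "FBP"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")
        if self.algorithm == "OSEM" and (self.iterations < 1 or self.subsets < 1):
            raise ValueError("OSEM requires iterations >= 1 and subsets >= 1")
        if self.fbp_filter not in ("ramp", "hann"):
            raise ValueError(f"unknown FBP filter {self.fbp_filter!r}")

    @property
    def it_sub(self) -> int:
        return self.iterations * self.subsets

    def label(self) -> str:
        if self.algorithm == "FBP":
            return f"fbp_{self.fbp_filter}"
        return f"osem_{self.iterations}x{self.subsets}"


@dataclass
class ReconVolume:
    """Reconstructed voxel grid with provenance."""

    values: np.ndarray
    grid: GridSpec
    provenance: dict = field(default_factory=dict)


def bit_reversed_order(n: int) -> list[int]:
    """Bit-reversal permutation of range(n), entries >= n dropped."""
    if n <= 1:
        return list(range(n))
    bits = max(1, int(np.ceil(np.log2(n))))
    order = []
    for i in range(1 << bits):
        r = int(f"{i:0{bits}b}"[::-1], 2)
        if r < n:
            order.append(r)
    return order


def subset_views(n_views: int, n_subsets: int) -> list[np.ndarray]:
    """Round-robin view partition: subset s holds views v with v % SUB == s."""
    if n_views % n_subsets:
        raise ValueError(f"{n_subsets} subsets do not divide {n_views} views")
    return [np.arange(s, n_views, n_subsets) for s in range(n_subsets)]


class SpectSystemModel:
    """System operator for reconstruction, with adjoint-matched subsets.

    The resolution-recovery PSF may use a collimator model different from the
    one that produced the data (``collimator`` argument), to probe the effect
    of model mismatch.
    """

    def __init__(
        self,
        grid: GridSpec,
        geometry: OrbitGeometry,
        collimator: CollimatorResponse | None = None,
        mu_map: np.ndarray | None = None,
        cache: bool = True,
    ) -> None:
        self.grid = grid
        self.geometry = geometry
        self._proj = RotateProjector(grid, geometry, collimator, mu_map, cache=cache)

    @property
    def n_views(self) -> int:
        return self.geometry.n_views

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.grid.n_xy, self.grid.n_xy)

    def project(self, x: np.ndarray, views=None) -> np.ndarray:
        return self._proj.project(x, views)

    def backproject(self, y: np.ndarray, views=None) -> np.ndarray:
        return self._proj.backproject(y, views)

    @classmethod
    def for_sinogram(
        cls,
        s: SinogramSet,
        cfg: ReconConfig,
        collimator: CollimatorResponse | None = None,
        mu_map: np.ndarray | None = None,
        background: BackgroundSpec | None = None,
    ) -> "SpectSystemModel":
        """Build the model a reconstruction config asks for.

        With ``ac`` on and no explicit mu_map, an analytic water-cylinder map
        (the stand-in for a CT-derived map) is generated from ``background``.
        """
        grid = GridSpec(s.geometry.n_bins, s.geometry.bin_mm)
        coll = (collimator or CollimatorResponse()) if cfg.rr else None
        mu = None
        if cfg.ac:
            if mu_map is not None:
                mu = mu_map
            elif background is not None and background.kind != "air":
                mu = np.where(cylinder_mask(grid, background.cylinder_diameter_mm),
                              background.mu_water_per_mm, 0.0)
        return cls(grid, s.geometry, coll, mu)


class MatrixModel:
    """Dense-matrix system model (rays x voxels) for small exact tests."""

    def __init__(self, A: np.ndarray) -> None:
        self.A = np.asarray(A, float)

    @property
    def n_views(self) -> int:
        return self.A.shape[0]

    @property
    def image_shape(self) -> tuple[int]:
        return (self.A.shape[1],)

    def project(self, x, views=None):
        rows = self.A if views is None else self.A[np.asarray(views)]
        return rows @ np.asarray(x, float)

    def backproject(self, y, views=None):
        rows = self.A if views is None else self.A[np.asarray(views)]
        return rows.T @ np.asarray(y, float)


def dew_scatter_estimate(
    lower: np.ndarray,
    cfg: ReconConfig,
    photopeak_width_rel: float = 0.15,
    lower_width_rel: float = 0.15,
    smooth_fwhm_mm: float = 0.0,
    bin_mm: float | None = None,
) -> np.ndarray:
    """Dual-energy-window photopeak scatter estimate.

    ``estimate = dew_k * lower * (photopeak width / lower width)``, optionally
    smoothed along the bin axis.
    """
    if cfg.dew_k <= 0:
        raise ValueError("dew_k must be positive")
    if lower_width_rel <= 0:
        raise ValueError("lower window width must be positive")
    est = cfg.dew_k * np.asarray(lower, float) * (photopeak_width_rel / lower_width_rel)
    if smooth_fwhm_mm > 0:
        if bin_mm is None:
            raise ValueError("bin_mm required for smoothing")
        est = ndimage.gaussian_filter1d(est, smooth_fwhm_mm * _FWHM_TO_SIGMA / bin_mm,
                                        axis=1, mode="constant", cval=0.0)
    return np.maximum(est, 0.0)


def osem(
    y: np.ndarray,
    model,
    cfg: ReconConfig,
    scatter: np.ndarray | None = None,
    callback: Callable[[int, np.ndarray], None] | None = None,
) -> np.ndarray:
    """Ordered-subsets EM on measured counts ``y`` (shape: views first).

    ``callback(it, x)`` runs after each full pass, enabling snapshots along an
    IT ladder from a single run. Voxels with zero total sensitivity stay 0.
    """
    y = np.asarray(y, float)
    if np.any(y < 0):
        raise ValueError("negative counts")
    subsets = subset_views(model.n_views, cfg.subsets)
    order = bit_reversed_order(cfg.subsets)
    if scatter is not None:
        scatter = np.asarray(scatter, float)
        if scatter.shape != y.shape:
            raise ValueError("scatter shape does not match data")

    sens = []
    for views in subsets:
        ones = np.ones_like(y[np.asarray(views)])
        sens.append(model.backproject(ones, views))
    total_sens = np.sum(sens, axis=0)
    alive = total_sens > 0

    x = np.where(alive, 1.0, 0.0)
    for it in range(cfg.iterations):
        for s_idx in order:
            views = subsets[s_idx]
            yhat = model.project(x, views)
            if scatter is not None:
                yhat = yhat + scatter[np.asarray(views)]
            ratio = y[np.asarray(views)] / np.maximum(yhat, _EPS)
            corr = model.backproject(ratio, views)
            with np.errstate(invalid="ignore", divide="ignore"):
                x = np.where(alive, x * corr / np.maximum(sens[s_idx], _EPS), 0.0)
            x = np.maximum(x, 0.0)
        if callback is not None:
            callback(it + 1, x)
    return x


def mlem(y, model, iterations, scatter=None, callback=None):
    """Classical MLEM = OSEM with a single subset."""
    cfg = ReconConfig(algorithm="OSEM", iterations=iterations, subsets=1)
    return osem(y, model, cfg, scatter=scatter, callback=callback)


def loglikelihood(x: np.ndarray, y: np.ndarray, model,
                  scatter: np.ndarray | None = None) -> float:
    """Poisson log-likelihood sum(y log yhat - yhat), 0*log0 := 0."""
    if np.any(np.asarray(x) < 0):
        raise ValueError("x must be nonnegative")
    y = np.asarray(y, float)
    if y.size == 0:
        return 0.0
    yhat = model.project(x)
    if scatter is not None:
        yhat = yhat + scatter
    if np.any((yhat == 0) & (y > 0)):
        return -np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(y > 0, y * np.log(np.where(yhat > 0, yhat, 1.0)), 0.0)
    return float(t.sum() - yhat.sum())


def _fbp_filter(n_bins: int, bin_mm: float, cfg: ReconConfig) -> tuple[np.ndarray, int]:
    nfft = next_fast_len(2 * n_bins)
    f = rfftfreq(nfft)  # cycles / sample
    nyquist_cyc_mm = 0.5 / bin_mm
    cutoff = cfg.fbp_cutoff_cyc_mm
    if cutoff is None:
        cutoff = nyquist_cyc_mm
    if cutoff > nyquist_cyc_mm * (1 + 1e-12):
        raise ValueError(
            f"cutoff {cutoff} cycles/mm exceeds Nyquist {nyquist_cyc_mm}")
    fc = cutoff * bin_mm  # cycles/sample
    H = f.copy()
    if cfg.fbp_filter == "hann":
        H = H * (0.5 + 0.5 * np.cos(np.pi * np.minimum(f / fc, 1.0)))
    H[f > fc] = 0.0
    return H, nfft


def fbp(s: SinogramSet, cfg: ReconConfig | None = None) -> ReconVolume:
    """Filtered back-projection of the photopeak sinogram."""
    cfg = cfg or ReconConfig(algorithm="FBP")
    if cfg.algorithm != "FBP":
        raise ValueError("fbp() requires an FBP config")
    geom = s.geometry
    n = geom.n_bins
    grid = GridSpec(n, geom.bin_mm)
    H, nfft = _fbp_filter(n, geom.bin_mm, cfg)
    spec = rfft(s.photopeak, nfft, axis=1)
    filtered = irfft(spec * H[None, :], nfft, axis=1)[:, :n]

    X, Y = grid.meshgrid_mm()
    out = np.zeros((n, n))
    bin_idx = np.arange(n, dtype=float)
    for v, ang in enumerate(np.radians(geom.angles_deg)):
        t = X * np.cos(ang) + Y * np.sin(ang)
        ti = grid.mm_to_index(t)
        out += np.interp(ti, bin_idx, filtered[v], left=0.0, right=0.0)
    out *= np.pi / geom.n_views
    return ReconVolume(out, grid, {"config": cfg, "algorithm": "FBP"})


def reconstruct(
    s: SinogramSet,
    cfg: ReconConfig,
    collimator: CollimatorResponse | None = None,
    mu_map: np.ndarray | None = None,
    background: BackgroundSpec | None = None,
    callback: Callable[[int, np.ndarray], None] | None = None,
) -> ReconVolume:
    """Reconstruct a SinogramSet per config (dispatches FBP / OSEM)."""
    if cfg.algorithm == "FBP":
        return fbp(s, cfg)
    model = SpectSystemModel.for_sinogram(s, cfg, collimator, mu_map, background)
    scatter = None
    if cfg.sc and s.lower is not None:
        w = s.windows
        pw = w.photopeak_width_rel if w is not None else 0.15
        lw = w.lower_width_rel if w is not None else 0.15
        scatter = dew_scatter_estimate(s.lower, cfg, pw, lw)
    x = osem(s.photopeak, model, cfg, scatter=scatter, callback=callback)
    prov = {"config": cfg, "algorithm": "OSEM", "seed": s.seed}
    return ReconVolume(x, model.grid, prov)
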