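"""Trend statistics over resolution measurements.

Linear FWHM-vs-radius fits (resolution varies linearly with distance from
isocenter in iterative reconstructions), power-law FWHM vs IT x SUB
convergence fits, a chi-square test of constancy across radius (the FBP
case), anisotropy (RR - TR) bookkeeping and a background noise metric.
Radius is carried in cm and FWHM in mm throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize, stats

from .metrics import ResolutionRecord


@dataclass
class LinearTrendFit:
    slope: float  # mm per cm
    intercept: float  # mm
    slope_ci95: tuple[float, float]
    intercept_ci95: tuple[float, float]
    residual_chisq: float
    n: int

    @property
    def dof(self) -> int:
        return self.n - 2

    def predict(self, r):
        return self.intercept + self.slope * np.asarray(r, float)

    def summary(self) -> str:
        return (f"FWHM(r) = {self.intercept:.2f} {self.slope:+.3f} r mm "
                f"(slope 95% CI [{self.slope_ci95[0]:.3f}, {self.slope_ci95[1]:.3f}], "
                f"n={self.n})")


@dataclass
class PowerLawFit:
    amplitude: float  # mm at IT x SUB = 1
    exponent: float  # > 0 means resolution improves with IT x SUB
    floor: float = 0.0
    rss_log: float = math.nan
    n: int = 0

    def predict(self, n_updates):
        n_updates = np.asarray(n_updates, float)
        return self.floor + self.amplitude * n_updates ** (-self.exponent)

    def summary(self) -> str:
        return (f"FWHM(n) = {self.amplitude:.2f} n^(-{self.exponent:.3f}) mm"
                + (f" + {self.floor:.2f}" if self.floor else ""))


@dataclass
class ConstancyTest:
    chisq: float
    dof: int
    p_value: float
    weighted_mean: float

    def rejects(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


def _component(records: Sequence[ResolutionRecord], component: str) -> np.ndarray:
    comp = component.lower()
    if comp in ("rr", "radial"):
        return np.array([r.rr_mm for r in records])
    if comp in ("tr", "tangential"):
        return np.array([r.tr_mm for r in records])
    if comp == "mean":
        return np.array([r.mean_mm for r in records])
    raise ValueError(f"unknown component {component!r}")


def _component_err(records: Sequence[ResolutionRecord], component: str) -> np.ndarray:
    comp = component.lower()
    if comp in ("rr", "radial"):
        return np.array([r.rr_err_mm for r in records])
    if comp in ("tr", "tangential"):
        return np.array([r.tr_err_mm for r in records])
    rr = np.array([r.rr_err_mm for r in records])
    tr = np.array([r.tr_err_mm for r in records])
    return 0.5 * np.sqrt(rr**2 + tr**2)


def fit_linear(records: Sequence[ResolutionRecord], component: str = "mean") -> LinearTrendFit:
    """Ordinary least squares of FWHM (mm) on radius (cm).

    Confidence intervals use the t distribution with n - 2 dof; the exact
    2-point interpolating line is returned with infinite intervals.
    """
    recs = [r for r in records if r.valid]
    if len(recs) < 2:
        raise ValueError("need at least 2 valid records")
    r = np.array([rec.radius_cm for rec in recs], float)
    if np.unique(r).size < 2:
        raise ValueError("all radii equal; slope undefined")
    y = _component(recs, component)
    n = len(recs)
    res = stats.linregress(r, y)
    resid = y - (res.intercept + res.slope * r)
    chisq = float(resid @ resid)
    if n > 2:
        tcrit = stats.t.ppf(0.975, n - 2)
        s_slope = res.stderr
        s_int = res.intercept_stderr
    else:
        tcrit, s_slope, s_int = math.inf, 0.0, 0.0
    d_slope = tcrit * s_slope if n > 2 else math.inf
    d_int = tcrit * s_int if n > 2 else math.inf
    return LinearTrendFit(
        slope=float(res.slope), intercept=float(res.intercept),
        slope_ci95=(res.slope - d_slope, res.slope + d_slope),
        intercept_ci95=(res.intercept - d_int, res.intercept + d_int),
        residual_chisq=chisq, n=n,
    )


def fit_powerlaw(pairs: Iterable[tuple[float, float]], floor: bool = False) -> PowerLawFit:
    """Fit FWHM(n) = a * n^(-b) (+ optional floor) to (IT x SUB, FWHM) pairs.

    Default is OLS of log(FWHM) on log(n); positive exponent b means the
    resolution improves (narrower FWHM) with more updates. The optional
    asymptote term uses nonlinear least squares seeded by the log-log fit.
    """
    arr = np.array(sorted(pairs), float)
    if arr.ndim != 2 or len(arr) < 3:
        raise ValueError("need at least 3 (n, FWHM) pairs")
    n_up, fw = arr[:, 0], arr[:, 1]
    if np.any(n_up <= 0) or np.any(fw <= 0):
        raise ValueError("IT x SUB and FWHM must be positive")
    ln, lf = np.log(n_up), np.log(fw)
    res = stats.linregress(ln, lf)
    a, b = float(np.exp(res.intercept)), float(-res.slope)
    rss = float(np.sum((lf - (res.intercept + res.slope * ln)) ** 2))
    if not floor:
        return PowerLawFit(a, b, 0.0, rss, len(arr))
    def model(n, a_, b_, f_):
        return f_ + a_ * n ** (-b_)
    popt, _ = optimize.curve_fit(model, n_up, fw, p0=[a, max(b, 0.01), fw.min() / 2],
                                 maxfev=5000)
    resid = fw - model(n_up, *popt)
    return PowerLawFit(float(popt[0]), float(popt[1]), float(popt[2]),
                       float(resid @ resid), len(arr))


def test_constancy(values: Sequence[float], sigmas: Sequence[float]) -> ConstancyTest:
    """Chi-square goodness of fit of a constant to values with uncertainties.

    chi2 = sum((y_i - ybar_w)^2 / sigma_i^2) with the inverse-variance
    weighted mean ybar_w, referred to chi-square with n - 1 dof.
    """
    y = np.asarray(values, float)
    s = np.asarray(sigmas, float)
    if y.shape != s.shape or y.size < 2:
        raise ValueError("need matching values/sigmas, n >= 2")
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        raise ValueError("all sigmas must be positive and finite")
    w = 1.0 / s**2
    ybar = float((w * y).sum() / w.sum())
    chisq = float(((y - ybar) ** 2 * w).sum())
    dof = y.size - 1
    return ConstancyTest(chisq, dof, float(stats.chi2.sf(chisq, dof)), ybar)


test_constancy.__test__ = False  # statistical test, not a pytest test


def constancy_from_records(records: Sequence[ResolutionRecord],
                           component: str) -> ConstancyTest:
    recs = [r for r in records if r.valid]
    return test_constancy(_component(recs, component), _component_err(recs, component))


@dataclass
class AnisotropySummary:
    radii_cm: np.ndarray
    delta_mm: np.ndarray  # RR - TR per radius
    majority_sign: int  # +1 tangential narrower, -1 radial narrower, 0 tie
    majority_fraction: float
    max_abs_delta_mm: float
    verdict: str

    def summary(self) -> str:
        return (f"{self.verdict}: sign agreement {self.majority_fraction:.0%}, "
                f"max |RR-TR| = {self.max_abs_delta_mm:.2f} mm")


def anisotropy_summary(records: Sequence[ResolutionRecord],
                       isotropy_tol_mm: float = 1e-9) -> AnisotropySummary:
    """Per-radius signed RR - TR differences and the overall sign verdict."""
    recs = [r for r in records if r.valid]
    if not recs:
        raise ValueError("no valid records")
    radii = np.array([r.radius_cm for r in recs])
    delta = np.array([r.rr_mm - r.tr_mm for r in recs])
    if np.all(np.abs(delta) <= isotropy_tol_mm):
        return AnisotropySummary(radii, delta, 0, 1.0, float(np.abs(delta).max()),
                                 "isotropic")
    n_pos = int((delta > 0).sum())
    n_neg = int((delta < 0).sum())
    if n_pos >= n_neg:
        sign, frac = 1, n_pos / len(delta)
        verdict = "tangential narrower" if frac > 0.5 else "mixed"
    else:
        sign, frac = -1, n_neg / len(delta)
        verdict = "radial narrower" if frac > 0.5 else "mixed"
    return AnisotropySummary(radii, delta, sign, float(frac),
                             float(np.abs(delta).max()), verdict)


def noise_metric(values: np.ndarray, mask: np.ndarray) -> float:
    """Coefficient of variation (std/mean) of voxels in a background mask."""
    v = np.asarray(values, float)[np.asarray(mask, bool)]
    if v.size == 0:
        raise ValueError("empty mask")
    m = v.mean()
    if m <= 0:
        raise ValueError("background mean must be positive")
    return float(v.std() / m)


def background_mask(grid, background, source_centers_mm,
                    keepout_mm: float = 20.0) -> np.ndarray:
    """Warm-background voxels at least ``keepout_mm`` from every source."""
    from .phantom import cylinder_mask

    mask = cylinder_mask(grid, background.cylinder_diameter_mm * 0.9)
    X, Y = grid.meshgrid_mm()
    for cx, cy in np.atleast_2d(source_centers_mm):
        mask &= (X - cx) ** 2 + (Y - cy) ** 2 > keepout_mm**2
    return mask
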