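"""Dose-response statistics over cohort tables: dosage normalization, the
compensation fraction, LOWESS trends with bootstrap confidence bands, and
Gaussian-moving-window variance profiles.

The LOWESS here is local linear regression with a tricube kernel whose
bandwidth at each evaluation point is the distance to the
``ceil(span * n)``-th nearest neighbour; confidence bands come from case
resampling. The moving-window variance weights each observation by a
Gaussian in dosage (sigma = half-width h) and reports the Sigma-w
normalized weighted variance of the phenotype against the weighted mean
dosage — phenotypic variance peaks where the dose-response curve is
steepest relative to the window width.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, ValidationError

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass
class CompensationResult:
    """Fraction of the hom/het signal gap recovered in het-over-null animals."""

    fraction: float
    ci_low: float | None
    ci_high: float | None
    flags: list[str]


@dataclass
class TrendFit:
    """LOWESS fit with a bootstrap 95% band on an evaluation grid."""

    x: np.ndarray
    fit: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    span: float
    n_boot: int
    seed: int | None
    kernel: str = "tricube"

    def to_arrays(self):
        return np.column_stack([self.x, self.fit, self.lower, self.upper])


@dataclass
class WindowStats:
    """Gaussian-window weighted mean dosage and phenotypic variance."""

    centers: np.ndarray
    mean_dosage: np.ndarray
    variance: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    half_width: float
    sigma: float
    n_boot: int
    seed: int | None
    flagged: np.ndarray


def compensation_fraction(
    x_hom: float,
    x_het_wt: float,
    x_het_null: float,
    sems: tuple[float, float, float] | None = None,
) -> CompensationResult:
    """(x_het_null - x_het_wt) / (x_hom - x_het_wt).

    0 means no compensation (tag-over-null expresses like tag-over-wild-type),
    1 means full compensation (like the homozygote). Values outside [0, 1]
    are kept and flagged. With per-genotype SEMs a delta-method 95% CI is
    propagated.
    """
    denom = x_hom - x_het_wt
    if denom <= 0:
        raise ValidationError("x_hom must exceed x_het_wt")
    frac = (x_het_null - x_het_wt) / denom
    flags = [] if 0.0 <= frac <= 1.0 else ["outside_unit_interval"]
    ci_low = ci_high = None
    if sems is not None:
        s_hom, s_hw, s_hn = sems
        num = x_het_null - x_het_wt
        d_hn = 1.0 / denom
        d_hom = -num / denom**2
        d_hw = (num - denom) / denom**2
        se = np.sqrt((d_hn * s_hn) ** 2 + (d_hom * s_hom) ** 2 + (d_hw * s_hw) ** 2)
        ci_low, ci_high = float(frac - 1.96 * se), float(frac + 1.96 * se)
    return CompensationResult(float(frac), ci_low, ci_high, flags)


def normalize_dosage(values, control_values) -> np.ndarray:
    """Divide by the mean of the control cohort (controls average to 1)."""
    control_values = np.asarray(control_values, dtype=float)
    if control_values.size == 0:
        raise ValidationError("empty control cohort")
    mean = control_values.mean()
    if mean <= 0:
        raise ValidationError("control mean must be positive")
    return np.asarray(values, dtype=float) / mean


def _lowess_eval(x, y, grid, span, kernel):
    """Local linear fit at each grid point; vectorized over the grid."""
    n = len(x)
    k = int(np.ceil(span * n))
    d = np.abs(grid[:, None] - x[None, :])  # (G, N)
    d_k = np.partition(d, k - 1, axis=1)[:, k - 1]  # bandwidth per grid point
    if kernel == "tricube":
        with np.errstate(divide="ignore", invalid="ignore"):
            u = np.where(d_k[:, None] > 0, d / d_k[:, None], np.where(d > 0, np.inf, 0.0))
        w = np.clip(1.0 - u**3, 0.0, None) ** 3
    elif kernel == "flat":
        w = (d <= d_k[:, None]).astype(float)
    else:
        raise ValidationError(f"unknown kernel {kernel!r}")
    sw = w.sum(axis=1)
    sx = w @ x
    sy = w @ y
    sxx = w @ (x * x)
    sxy = w @ (x * y)
    det = sw * sxx - sx * sx
    with np.errstate(divide="ignore", invalid="ignore"):
        xbar = sx / sw
        ybar = sy / sw
        slope = np.where(np.abs(det) > 1e-12 * np.maximum(sw * sxx, 1e-300), (sw * sxy - sx * sy) / det, 0.0)
    return ybar + slope * (grid - xbar)


def lowess_bootstrap(
    x,
    y,
    span: float = 0.3,
    n_boot: int = 1000,
    seed: int | None = None,
    grid=None,
    kernel: str = "tricube",
    n_grid: int = 100,
) -> TrendFit:
    """LOWESS trend with a bootstrap percentile 95% band.

    Local linear regression (tricube weights over the span-fraction nearest
    neighbours) evaluated on ``grid`` (default 100 points spanning the data);
    the band is the 2.5/97.5 percentile of fits over ``n_boot``
    case-resampled replicates, deterministic given ``seed``. With
    ``kernel="flat"`` and ``span=1`` every point is an ordinary
    least-squares fit (test hook).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and equal length")
    if not np.all(np.isfinite(x)):
        raise ValidationError("x must be finite")
    n = len(x)
    if span * n < 3:
        raise ValidationError("span * n must be at least 3")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant x: no trend to fit")
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    fit = _lowess_eval(x, y, grid, span, kernel)
    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, len(grid)))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        boots[b] = _lowess_eval(x[idx], y[idx], grid, span, kernel)
    lower = np.minimum(np.percentile(boots, 2.5, axis=0), fit)
    upper = np.maximum(np.percentile(boots, 97.5, axis=0), fit)
    return TrendFit(grid, fit, lower, upper, span, n_boot, seed, kernel)


def steepest_point(trend: TrendFit, window: int = 15) -> float:
    """Location of the maximum |slope| of a fitted trend.

    The derivative is estimated with a quadratic Savitzky-Golay filter over
    ``window`` grid points, which suppresses the grid-scale wiggle a raw
    finite difference would amplify.
    """
    from scipy.signal import savgol_filter

    if len(trend.x) < window:
        raise ValidationError("trend grid shorter than the derivative window")
    dx = float(trend.x[1] - trend.x[0])
    slope = savgol_filter(trend.fit, window, 2, deriv=1, delta=dx)
    return float(trend.x[int(np.argmax(np.abs(slope)))])


def _weighted_stats(x, y, centers, sigma):
    w = np.exp(-((x[None, :] - centers[:, None]) ** 2) / (2.0 * sigma**2))
    sw = w.sum(axis=1)
    ok = sw > 1e-12
    mean_x = np.full(len(centers), np.nan)
    var_y = np.full(len(centers), np.nan)
    mean_x[ok] = (w @ x)[ok] / sw[ok]
    ybar = np.where(ok, (w @ y) / np.where(ok, sw, 1.0), np.nan)
    var_y[ok] = (w @ (y * y))[ok] / sw[ok] - ybar[ok] ** 2
    var_y[ok] = np.maximum(var_y[ok], 0.0)
    return mean_x, var_y, ~ok


def gaussian_window_stats(
    x,
    y,
    h: float = 0.1,
    grid=None,
    n_boot: int = 1000,
    seed: int | None = None,
    n_grid: int = 100,
    half_width_is_fwhm: bool = False,
) -> WindowStats:
    """Gaussian moving-window phenotypic variance along the dosage axis.

    At each window centre x0 the weights are w_i = exp(-(x_i - x0)^2 /
    (2 sigma^2)); the Gaussian-weighted mean dosage is plotted against the
    Sigma-w-normalized weighted variance of y, with bootstrap percentile
    95% CIs. ``h`` is the Gaussian sigma (the "half-width"); set
    ``half_width_is_fwhm`` to treat it as half the full width at half
    maximum instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D and equal length")
    if len(x) < 10:
        raise ValidationError("need at least 10 observations")
    if h <= 0:
        raise ValidationError("half-width must be positive")
    sigma = (2.0 * h) / _FWHM_PER_SIGMA if half_width_is_fwhm else h
    if grid is None:
        grid = np.linspace(x.min(), x.max(), n_grid)
    else:
        grid = np.asarray(grid, dtype=float)
    mean_x, var_y, flagged = _weighted_stats(x, y, grid, sigma)
    rng = np.random.default_rng(seed)
    n = len(x)
    boots = np.empty((n_boot, len(grid)))
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        _, v, _ = _weighted_stats(x[idx], y[idx], grid, sigma)
        boots[b] = v
    ci_low = np.nanpercentile(boots, 2.5, axis=0)
    ci_high = np.nanpercentile(boots, 97.5, axis=0)
    ci_low = np.fmin(ci_low, var_y)
    ci_high = np.fmax(ci_high, var_y)
    return WindowStats(
        centers=grid,
        mean_dosage=mean_x,
        variance=var_y,
        ci_low=ci_low,
        ci_high=ci_high,
        half_width=h,
        sigma=sigma,
        n_boot=n_boot,
        seed=seed,
        flagged=flagged,
    )
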