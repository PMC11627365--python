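"""Embryo segmentation, cortex straightening and membrane/cytoplasm
profile decomposition.

The measurement chain mirrors standard cortical quantitation of the
*C. elegans* zygote midplane: find a subpixel closed contour of the cell
boundary, computationally straighten a wide band following the membrane,
apply a rolling average along the perimeter, then decompose each
cross-membrane linescan into a Gaussian membrane ridge plus an
error-function cytoplasmic step (see :mod:`parmap.profilemodel`). Membrane
concentration at each perimeter position is the Gaussian amplitude A(s);
regional cortical levels are means of A(s) over pole-centred arcs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import curve_fit, minimize_scalar, nnls
from scipy.special import erf as _scipy_erf
from skimage import draw, filters, measure

from .errors import (
    DegenerateFitError,
    FitError,
    SegmentationError,
    StraighteningError,
    ValidationError,
)
from .images import EmbryoImage
from .profilemodel import gauss_erf_profile

DEFAULT_WIDTH_PX = 50  # 12.8 um at 0.256 um/px
DEFAULT_SMOOTH_PX = 20  # 5.1 um rolling average along the perimeter


@dataclass
class BoundaryContour:
    """Closed subpixel embryo outline, uniformly parameterized in arc length.

    ``s`` in [0, 1) is the perimeter fraction with s = 0 anchored at the
    anterior pole; ``points`` are (row, col) pixel coordinates and
    ``normals`` the inward unit normals at those points. A dense polyline
    (``_dense``) backs interpolation at arbitrary s.
    """

    points: np.ndarray  # (n, 2) row/col
    normals: np.ndarray  # (n, 2) inward unit
    s: np.ndarray
    perimeter_um: float
    pixel_scale: float
    mask: np.ndarray
    flags: list[str] = field(default_factory=list)
    _dense: np.ndarray | None = None  # (m, 2), closed, starts at anterior pole
    _dense_arc: np.ndarray | None = None  # (m,) cumulative arc fraction

    @property
    def n_points(self) -> int:
        return len(self.points)

    def sample(self, s_values) -> tuple[np.ndarray, np.ndarray]:
        """Points and inward normals at arbitrary perimeter fractions."""
        s_values = np.asarray(s_values, dtype=float) % 1.0
        pts = np.column_stack(
            [
                np.interp(s_values, self._dense_arc, self._dense[:, 0], period=1.0),
                np.interp(s_values, self._dense_arc, self._dense[:, 1], period=1.0),
            ]
        )
        normals = _inward_normals(self._dense, self._dense_arc, s_values, self.mask)
        return pts, normals


@dataclass
class StraightenedCortex:
    """(n_positions, width_px) raster sampled along inward normals.

    ``x_um`` is the cross-membrane coordinate per column, increasing from
    outside the embryo to inside, zero on the contour.
    """

    raster: np.ndarray
    x_um: np.ndarray
    s: np.ndarray
    pixel_scale: float
    width_px: int
    smooth_window_px: int


@dataclass
class MembraneProfile:
    """Per-position membrane amplitude A(s) and cytoplasm plateau C(s).

    Widths and the flat offset are shared across positions (fitted once on
    the position-averaged profile); amplitude, plateau and centre are
    fitted per position. Flagged positions carry NaN."""

    s: np.ndarray
    amplitude: np.ndarray  # A(s)
    cytoplasm: np.ndarray  # C(s)
    center_um: np.ndarray  # c(s), relative to the contour
    ridge_width_um: float
    edge_width_um: float
    offset: float
    residual_rms: np.ndarray
    flagged: np.ndarray  # bool


@dataclass
class CortexMeasurement:
    """One embryo's dosage and regional cortical means (one channel)."""

    embryo_id: str
    dosage: float | None
    anterior_mean: float
    posterior_mean: float
    profile: MembraneProfile | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------


def _channel_array(image: EmbryoImage, channel) -> np.ndarray:
    """One channel, or the sum of several (e.g. aPAR + pPAR, whose ridges
    tile the whole perimeter and pin the membrane centre everywhere)."""
    if isinstance(channel, str):
        return np.asarray(image.channel(channel), dtype=float)
    arrs = [np.asarray(image.channel(c), dtype=float) for c in channel]
    return np.sum(arrs, axis=0)


def segment_embryo(
    image: EmbryoImage,
    channel="signal",
    n_points: int = 1000,
    blur_sigma: float = 2.0,
    min_area_px: int = 2000,
    refine: bool = True,
    anterior_marker: str | None = None,
    anterior_point: tuple[float, float] | None = None,
) -> BoundaryContour:
    """Segment the single dominant embryo and return its boundary contour.

    Otsu threshold on a Gaussian-blurred copy, hole filling, largest
    object; the marching-squares contour of the smoothed mask is then
    refined to the shared centre of the Gaussian + erf cross-membrane model
    (two passes), placing the contour on the membrane midline.

    The anterior pole (s = 0) is the long-axis end whose adjacent 20% arc
    has the higher mean in ``anterior_marker``; alternatively an explicit
    ``anterior_point`` (row, col) selects the nearest pole. With neither,
    the lower-column pole is used and the contour flagged
    ``orientation_default``.
    """
    img = _channel_array(image, channel)
    blurred = filters.gaussian(img, blur_sigma, preserve_range=True)
    if np.ptp(blurred) == 0:
        raise SegmentationError("blank image: no intensity variation")
    level = filters.threshold_otsu(blurred)
    binary = ndimage.binary_fill_holes(blurred > level)
    labels, n_lab = ndimage.label(binary)
    if n_lab == 0:
        raise SegmentationError("no object above threshold")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
    best = int(np.argmax(sizes)) + 1
    if sizes[best - 1] < min_area_px:
        raise SegmentationError(f"largest object below minimum area {min_area_px} px^2")
    mask0 = labels == best
    flags = []
    if _touches_border(mask0):
        flags.append("touches_border")

    maskf = filters.gaussian(mask0.astype(float), blur_sigma, preserve_range=True)
    contours = measure.find_contours(maskf, 0.5)
    if not contours:
        raise SegmentationError("no closed contour found")
    dense = _resample_closed(max(contours, key=len), 4096)

    if refine:
        dense, _ = _refine_to_membrane_center(img, dense, image.pixel_scale)
        for _ in range(3):
            dense, moved = _refine_to_membrane_center(
                img, dense, image.pixel_scale, per_position=True
            )
            if moved < 0.02:  # um; converged onto the membrane midline
                break
    dense = _smooth_closed(dense, window=33)
    dense = _resample_closed(dense, 8192)

    mask = draw.polygon2mask(img.shape, dense)
    dense, arc, perimeter_px = _arc_parameterize(dense)

    anchor_idx = _anterior_anchor(image, dense, arc, mask, anterior_marker, anterior_point, flags)
    dense = np.roll(dense, -anchor_idx, axis=0)
    dense, arc, perimeter_px = _arc_parameterize(dense)

    s = np.arange(n_points) / n_points
    contour = BoundaryContour(
        points=np.empty((n_points, 2)),
        normals=np.empty((n_points, 2)),
        s=s,
        perimeter_um=perimeter_px * image.pixel_scale,
        pixel_scale=image.pixel_scale,
        mask=mask,
        flags=flags,
        _dense=dense,
        _dense_arc=arc,
    )
    contour.points, contour.normals = contour.sample(s)
    return contour


def _touches_border(mask):
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n vertices uniform in arc length."""
    pts = np.asarray(points, dtype=float)
    if np.allclose(pts[0], pts[-1]):
        pts = pts[:-1]
    closed = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    targets = np.linspace(0.0, total, n, endpoint=False)
    return np.column_stack(
        [np.interp(targets, arc, closed[:, 0]), np.interp(targets, arc, closed[:, 1])]
    )


def _smooth_closed(points: np.ndarray, window: int) -> np.ndarray:
    """Circular moving-average smoothing of a closed polyline (odd window)."""
    return np.column_stack(
        [
            ndimage.uniform_filter1d(points[:, 0], window, mode="wrap"),
            ndimage.uniform_filter1d(points[:, 1], window, mode="wrap"),
        ]
    )


def _arc_parameterize(dense: np.ndarray):
    closed = np.vstack([dense, dense[:1]])
    seg = np.hypot(*np.diff(closed, axis=0).T)
    total = seg.sum()
    arc = np.concatenate([[0.0], np.cumsum(seg[:-1])]) / total
    return dense, arc, float(total)


def _inward_normals(dense, arc, s_values, mask):
    """Inward unit normals at perimeter fractions, from central differences
    of the dense polyline; 'inward' is resolved against the mask centroid."""
    m = len(dense)
    idx = np.clip(np.searchsorted(arc, np.asarray(s_values) % 1.0), 0, m - 1)
    nxt = dense[(idx + 8) % m]
    prv = dense[(idx - 8) % m]
    tangent = nxt - prv
    tangent /= np.linalg.norm(tangent, axis=1, keepdims=True)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    centroid = np.array(ndimage.center_of_mass(mask))
    to_center = centroid[None, :] - dense[idx]
    sign = np.sign(np.einsum("ij,ij->i", normal, to_center))
    sign[sign == 0] = 1.0
    return normal * sign[:, None]


def _refine_to_membrane_center(img, dense, pixel_scale, half_width_um=3.2, per_position=False):
    """Shift the contour onto the shared Gaussian/erf centre of the
    cross-membrane profile.

    First pass: one global shift from the position-averaged profile.
    Second pass (``per_position``): a per-position centre found with the
    same fixed-width decomposition used by :func:`fit_membrane_profiles`,
    circularly smoothed along the perimeter — needed because a threshold
    contour's offset from the membrane midline varies with local ridge
    amplitude.
    """
    step = max(len(dense) // 400, 1)
    sub = dense[::step]
    _, arc, _ = _arc_parameterize(dense)
    mask = draw.polygon2mask(img.shape, dense)
    s_sub = arc[::step][: len(sub)]
    normals = _inward_normals(dense, arc, s_sub, mask)
    n_samples = max(int(round(2 * half_width_um / pixel_scale)) | 1, 15)
    x_px = np.linspace(-half_width_um, half_width_um, n_samples) / pixel_scale
    coords = sub[:, None, :] + normals[:, None, :] * x_px[None, :, None]
    prof = ndimage.map_coordinates(
        img, [coords[..., 0].ravel(), coords[..., 1].ravel()], order=1, mode="nearest"
    ).reshape(len(sub), n_samples)
    x_um = x_px * pixel_scale
    c_bound = half_width_um - 0.5
    try:
        a_g, c_g, cen, w_g, w_e, offset = _fit_full_profile(
            x_um, prof.mean(axis=0), c_bound=c_bound
        )
    except (RuntimeError, DegenerateFitError):
        return dense, 0.0
    all_normals = _inward_normals(dense, arc, arc, mask)
    if not per_position:
        return dense + all_normals * (cen / pixel_scale), abs(cen)

    gauss_of = lambda c: np.exp(-((x_um - c) ** 2) / (2.0 * w_g**2))
    step_of = lambda c: 0.5 * (1.0 + _scipy_erf((x_um - c) / (w_e * np.sqrt(2.0))))
    lo, hi = cen - 1.5, cen + 1.5
    centers = np.empty(len(sub))
    for i, y in enumerate(prof):
        yy = y - offset

        def rss_at(c, _y=yy):
            design = np.column_stack([gauss_of(c), step_of(c)])
            _, r = nnls(design, _y)
            return r

        res = minimize_scalar(rss_at, bounds=(lo, hi), method="bounded", options={"xatol": 1e-3})
        centers[i] = res.x
    centers = ndimage.uniform_filter1d(centers, 15, mode="wrap")
    shift = np.interp(arc, s_sub, centers, period=1.0)
    return dense + all_normals * (shift / pixel_scale)[:, None], float(np.abs(shift).max())


def _anterior_anchor(image, dense, arc, mask, anterior_marker, anterior_point, flags):
    """Index of the dense vertex to anchor s = 0 on (the anterior pole)."""
    centered = dense - dense.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    candidates = [int(np.argmin(proj)), int(np.argmax(proj))]
    if anterior_point is not None:
        d = [np.hypot(*(dense[i] - np.asarray(anterior_point, float))) for i in candidates]
        return candidates[int(np.argmin(d))]
    if anterior_marker is not None:
        img = np.asarray(image.channel(anterior_marker), dtype=float)
        vals = ndimage.map_coordinates(img, [dense[:, 0], dense[:, 1]], order=1, mode="nearest")
        means = []
        for i in candidates:
            sel = np.abs((arc - arc[i] + 0.5) % 1.0 - 0.5) <= 0.10
            means.append(vals[sel].mean())
        return candidates[int(np.argmax(means))]
    flags.append("orientation_default")
    cols = dense[candidates, 1]
    return candidates[int(np.argmin(cols))]


# ---------------------------------------------------------------------------
# Straightening
# ---------------------------------------------------------------------------


def straighten_cortex(
    image: EmbryoImage,
    contour: BoundaryContour,
    channel="signal",
    width_px: int = DEFAULT_WIDTH_PX,
    smooth_window_px: int = DEFAULT_SMOOTH_PX,
    spacing_px: float = 1.0,
    n_positions: int | None = None,
    order: int = 3,
) -> StraightenedCortex:
    """Sample a ``width_px``-wide band along the contour's inward normals
    and apply a circular rolling average along the perimeter.

    Positions are spaced ``spacing_px`` pixels apart in arc length by
    default, so the default 20-position window is a 20-pixel (5.1 um)
    rolling average. Interpolation is bicubic by default (``order=1`` for
    bilinear; bilinear's implicit triangle-kernel smoothing broadens the
    ~2 px membrane ridge and biases fitted amplitudes low by ~2%).
    ``channel`` may be a list of roles, which are summed.
    """
    img = _channel_array(image, channel)
    if n_positions is None:
        n_positions = max(int(round(contour.perimeter_um / contour.pixel_scale / spacing_px)), 8)
    s = np.arange(n_positions) / n_positions
    pts, normals = contour.sample(s)
    x_px = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0
    coords = pts[:, None, :] + normals[:, None, :] * x_px[None, :, None]
    rr, cc = coords[..., 0], coords[..., 1]
    out = (rr < 0) | (rr > img.shape[0] - 1) | (cc < 0) | (cc > img.shape[1] - 1)
    if out.any():
        bad = s[out.any(axis=1)]
        raise StraighteningError(
            f"normal band leaves the image at {len(bad)} perimeter positions",
            positions=bad.tolist(),
        )
    raster = ndimage.map_coordinates(img, [rr.ravel(), cc.ravel()], order=order).reshape(
        n_positions, width_px
    )
    if smooth_window_px > 1:
        raster = ndimage.uniform_filter1d(raster, smooth_window_px, axis=0, mode="wrap")
    return StraightenedCortex(
        raster=raster,
        x_um=x_px * contour.pixel_scale,
        s=s,
        pixel_scale=contour.pixel_scale,
        width_px=width_px,
        smooth_window_px=smooth_window_px,
    )


# ---------------------------------------------------------------------------
# Profile decomposition
# ---------------------------------------------------------------------------


def _fit_full_profile(x, y, c_bound=2.0, width_bounds=(0.2, 2.0)):
    """Fit all six model parameters (A, C, c, w_g, w_e, O) to one profile."""
    if np.ptp(y) == 0:
        raise DegenerateFitError("flat profile")
    o0 = float(np.mean(y[:3]))
    c0 = float(np.clip(x[int(np.argmax(y))], -c_bound + 1e-6, c_bound - 1e-6))
    cyt0 = max(float(np.mean(y[-3:])) - o0, 1e-6)
    a0 = max(float(np.max(y)) - o0 - cyt0, 1e-6)
    w0 = float(np.clip(0.5, *width_bounds))
    p0 = [a0, cyt0, c0, w0, w0, o0]
    bounds = (
        [0.0, 0.0, -c_bound, width_bounds[0], width_bounds[0], -np.inf],
        [np.inf, np.inf, c_bound, width_bounds[1], width_bounds[1], np.inf],
    )
    popt, _ = curve_fit(
        gauss_erf_profile, x, y, p0=p0, bounds=bounds, xtol=1e-8, ftol=1e-8, max_nfev=2000
    )
    return popt


def _row_rss(x, y, w_g, w_e, offset, cen, c_halfrange, xatol=1e-3):
    """Best squared residual of one profile with (A, C, c) profiled out."""
    gauss_of = lambda c: np.exp(-((x - c) ** 2) / (2.0 * w_g**2))
    step_of = lambda c: 0.5 * (1.0 + _scipy_erf((x - c) / (w_e * np.sqrt(2.0))))
    yy = y - offset

    def rss_at(c):
        design = np.column_stack([gauss_of(c), step_of(c)])
        _, r = nnls(design, yy)
        return r

    res = minimize_scalar(
        rss_at,
        bounds=(cen - c_halfrange, cen + c_halfrange),
        method="bounded",
        options={"xatol": xatol},
    )
    return rss_at(float(res.x)) ** 2


def _fixed_center_rss(x, y, w_g, w_e, offset, c):
    gauss = np.exp(-((x - c) ** 2) / (2.0 * w_g**2))
    step = 0.5 * (1.0 + _scipy_erf((x - c) / (w_e * np.sqrt(2.0))))
    _, r = nnls(np.column_stack([gauss, step]), y - offset)
    return r**2


def _optimize_shared_params(x, rows, p0, cen, c_halfrange, width_bounds, fixed_centers=None):
    """Joint variable-projection fit of the shared (w_g, w_e, offset).

    Minimizes the summed residual over ``rows`` with per-row amplitude and
    plateau (and centre, unless ``fixed_centers`` pins it per row)
    profiled out. This is immune to the broadening that biases widths
    fitted on a position-averaged profile whenever the membrane centre
    wanders along the perimeter.
    """
    from scipy.optimize import minimize

    keep = [i for i, y in enumerate(rows) if np.all(np.isfinite(y))]
    if fixed_centers is not None:
        keep = [i for i in keep if np.isfinite(fixed_centers[i])]
    if not keep:
        return p0
    rows = [rows[i] for i in keep]

    def joint(params):
        w_g, w_e, off = params
        if not (
            width_bounds[0] <= w_g <= width_bounds[1]
            and width_bounds[0] <= w_e <= width_bounds[1]
        ):
            return 1e30
        if fixed_centers is not None:
            return sum(
                _fixed_center_rss(x, y, w_g, w_e, off, fixed_centers[keep[j]])
                for j, y in enumerate(rows)
            )
        return sum(_row_rss(x, y, w_g, w_e, off, cen, c_halfrange) for y in rows)

    res = minimize(
        joint,
        x0=list(p0),
        method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-9, "maxiter": 200},
    )
    if res.fun < joint(list(p0)):
        return tuple(float(v) for v in res.x)
    return p0


def fit_membrane_profiles(
    straightened: StraightenedCortex,
    c_halfrange_um: float = 2.0,
    width_bounds_um: tuple[float, float] = (0.2, 2.0),
    max_flagged_fraction: float = 0.2,
    fixed_center=None,
) -> MembraneProfile:
    """Decompose every cross-membrane profile into membrane + cytoplasm.

    The two widths and the flat offset are shared across positions (joint
    variable-projection fit over a row subset); per position the shared
    centre c is found by bounded scalar search (within ``c_halfrange_um``
    of the global centre) with an inner non-negative least-squares solve
    for the amplitude A and plateau C. Positions where the solve fails are
    flagged (NaN); more than ``max_flagged_fraction`` flagged is an error.

    ``fixed_center`` pins c(s) to an externally registered membrane
    midline (an array on this raster's s-grid, or a MembraneProfile from a
    channel whose ridge covers the whole perimeter — e.g. the aPAR + pPAR
    sum). Where a channel's own ridge is weak the centre is near-degenerate
    with the amplitude, so registering c on a bright shared-membrane
    channel removes that bias.
    """
    if straightened.width_px < 20:
        raise ValidationError("straightened band narrower than 20 px")
    x = straightened.x_um
    raster = straightened.raster
    n = raster.shape[0]
    _, _, cen_glob, w_g, w_e, offset = _fit_full_profile(
        x, raster.mean(axis=0), c_bound=c_halfrange_um, width_bounds=width_bounds_um
    )

    def per_position(w_g, w_e, offset, cen):
        gauss_of = lambda c: np.exp(-((x - c) ** 2) / (2.0 * w_g**2))
        step_of = lambda c: 0.5 * (1.0 + _scipy_erf((x - c) / (w_e * np.sqrt(2.0))))
        lo, hi = cen - c_halfrange_um, cen + c_halfrange_um
        amplitude = np.full(n, np.nan)
        cytoplasm = np.full(n, np.nan)
        center = np.full(n, np.nan)
        residual = np.full(n, np.nan)
        flagged = np.zeros(n, dtype=bool)
        for i in range(n):
            y = raster[i] - offset
            if not np.all(np.isfinite(y)):
                flagged[i] = True
                continue

            def rss_at(c, _y=y):
                design = np.column_stack([gauss_of(c), step_of(c)])
                _, r = nnls(design, _y)
                return r

            try:
                res = minimize_scalar(
                    rss_at, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
                )
                c_i = float(res.x)
                design = np.column_stack([gauss_of(c_i), step_of(c_i)])
                coef, r = nnls(design, y)
            except Exception:
                flagged[i] = True
                continue
            amplitude[i], cytoplasm[i], center[i] = coef[0], coef[1], c_i
            residual[i] = r / np.sqrt(len(y))
        return amplitude, cytoplasm, center, residual, flagged

    def per_position_fixed(w_g, w_e, offset, c_arr):
        gauss_of = lambda c: np.exp(-((x - c) ** 2) / (2.0 * w_g**2))
        step_of = lambda c: 0.5 * (1.0 + _scipy_erf((x - c) / (w_e * np.sqrt(2.0))))
        amplitude = np.full(n, np.nan)
        cytoplasm = np.full(n, np.nan)
        residual = np.full(n, np.nan)
        flagged = np.zeros(n, dtype=bool)
        for i in range(n):
            y = raster[i] - offset
            if not (np.all(np.isfinite(y)) and np.isfinite(c_arr[i])):
                flagged[i] = True
                continue
            design = np.column_stack([gauss_of(c_arr[i]), step_of(c_arr[i])])
            coef, r = nnls(design, y)
            amplitude[i], cytoplasm[i] = coef[0], coef[1]
            residual[i] = r / np.sqrt(len(y))
        return amplitude, cytoplasm, c_arr.copy(), residual, flagged

    # Widths fitted on the position-averaged profile are broadened wherever
    # the membrane centre c(s) wanders around the perimeter (residual
    # segmentation error), and a biased erf width inflates the fitted
    # amplitude where the ridge is weak; refine the shared parameters by
    # joint variable projection over a row subset instead.
    if fixed_center is not None:
        if isinstance(fixed_center, MembraneProfile):
            c_arr = np.interp(
                straightened.s, fixed_center.s, fixed_center.center_um, period=1.0
            )
        else:
            c_arr = np.asarray(fixed_center, dtype=float)
            if c_arr.shape != straightened.s.shape:
                raise ValidationError("fixed_center length must match the s-grid")
        sub = slice(None, None, max(n // 24, 1))
        w_g, w_e, offset = _optimize_shared_params(
            x,
            raster[sub],
            (w_g, w_e, offset),
            cen_glob,
            c_halfrange_um,
            width_bounds_um,
            fixed_centers=c_arr[sub],
        )
        amplitude, cytoplasm, center, residual, flagged = per_position_fixed(
            w_g, w_e, offset, c_arr
        )
    else:
        sub_rows = raster[:: max(n // 24, 1)]
        w_g, w_e, offset = _optimize_shared_params(
            x, sub_rows, (w_g, w_e, offset), cen_glob, c_halfrange_um, width_bounds_um
        )
        amplitude, cytoplasm, center, residual, flagged = per_position(
            w_g, w_e, offset, cen_glob
        )

    if flagged.mean() > max_flagged_fraction:
        raise FitError(f"{flagged.sum()}/{n} profile positions failed to fit")
    return MembraneProfile(
        s=straightened.s,
        amplitude=amplitude,
        cytoplasm=cytoplasm,
        center_um=center,
        ridge_width_um=float(w_g),
        edge_width_um=float(w_e),
        offset=float(offset),
        residual_rms=residual,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# Regional means, dosage, binned profiles
# ---------------------------------------------------------------------------


def arc_mask(s, center: float, fraction: float) -> np.ndarray:
    """Positions within ``fraction/2`` of ``center`` along the closed perimeter."""
    d = np.abs((np.asarray(s, float) - center + 0.5) % 1.0 - 0.5)
    return d <= fraction / 2.0


def cortical_mean(profile: MembraneProfile, region: str, fraction: float = 0.33) -> float:
    """Mean membrane amplitude over the pole-centred arc of the given
    perimeter ``fraction`` (anterior arc centred on s=0, posterior on s=0.5)."""
    if region not in ("anterior", "posterior"):
        raise ValidationError("region must be 'anterior' or 'posterior'")
    center = 0.0 if region == "anterior" else 0.5
    sel = arc_mask(profile.s, center, fraction) & ~profile.flagged
    if not sel.any():
        raise ValidationError(f"all positions in the {region} arc are flagged")
    return float(np.nanmean(profile.amplitude[sel]))


def whole_embryo_mean(
    image: EmbryoImage, mask: np.ndarray, channel: str = "signal", erode_px: int = 1
) -> float:
    """Mean in-mask intensity (mask eroded to stay inside the boundary)."""
    m = np.asarray(mask) > 0
    if erode_px > 0:
        m = ndimage.binary_erosion(m, iterations=erode_px)
    if not m.any():
        raise ValidationError("mask empty after erosion")
    return float(np.asarray(image.channel(channel), float)[m].mean())


def total_dosage(
    image: EmbryoImage,
    mask: np.ndarray,
    control_mean: float,
    channel: str = "signal",
    erode_px: int = 1,
) -> float:
    """Whole-embryo mean intensity normalized to the control-cohort mean
    (dosage ~ 1 for control embryos)."""
    if control_mean is None or control_mean <= 0:
        raise ValidationError("control_mean must be positive")
    return whole_embryo_mean(image, mask, channel, erode_px) / control_mean


@dataclass
class ProfileBin:
    level: float
    mean: np.ndarray
    sd: np.ndarray
    indices: list[int]


def average_profiles_by_dosage(
    profiles,
    dosages,
    levels=(1.0, 0.75, 0.5, 0.25),
    k: int = 7,
) -> dict[float, ProfileBin]:
    """For each dosage level, average the k embryos closest to it.

    ``profiles`` is (n_embryos, n_positions) on a common s-grid. Ties in
    |dosage - level| resolve by embryo order. SD is the population SD so a
    single-embryo bin reports zero spread.
    """
    profiles = np.asarray(profiles, dtype=float)
    dosages = np.asarray(dosages, dtype=float)
    if profiles.ndim != 2 or len(dosages) != profiles.shape[0]:
        raise ValidationError("profiles must be (n_embryos, n_positions) matching dosages")
    if profiles.shape[0] < k:
        raise ValidationError(f"need at least k={k} embryos, got {profiles.shape[0]}")
    out = {}
    for level in levels:
        order = np.argsort(np.abs(dosages - level), kind="stable")[:k]
        sel = profiles[order]
        out[level] = ProfileBin(
            level=float(level),
            mean=sel.mean(axis=0),
            sd=sel.std(axis=0),
            indices=[int(i) for i in order],
        )
    return out
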