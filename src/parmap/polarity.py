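"""Polarity asymmetry indices, domain geometry and domain-count calls.

The composite asymmetry index (ASI) combines anterior-PAR (aPAR) and
posterior-PAR (pPAR) signal into a single measure of polarity:

    ASI = ((A_A - A_P) - (P_A - P_P)) / (A_A + A_P + P_A + P_P)

where A_A, A_P are aPAR concentrations at the anterior and posterior poles
and P_A, P_P the pPAR concentrations, all normalized to the wild-type peak
for each protein. ASI is 1 for perfect complementary polarity, 0 for a
uniform embryo, and sign-flips if the axes are inverted. Single-protein
ASIs use semicircle means, signed so that correctly polarized embryos are
positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .cortex import BoundaryContour, MembraneProfile, arc_mask, cortical_mean
from .errors import ValidationError
from .images import EmbryoImage


@dataclass
class PolarityMeasurement:
    """Pole concentrations of an aPAR and a pPAR protein, wild-type-peak
    normalized. Negative (over-corrected) values are kept, not clipped."""

    apar_anterior: float
    apar_posterior: float
    ppar_anterior: float
    ppar_posterior: float


@dataclass
class DomainCall:
    """Domain-count classification of a closed membrane:cytoplasm trace."""

    category: str  # no_domains | unclear | monopolar | bipolar
    arcs: list[tuple[float, float, float]]  # (s_start, s_end, mean ratio)
    theta_high: float
    theta_low: float
    min_arc: float


@dataclass
class BoundaryEstimate:
    """Half-max domain boundary position (perimeter fraction from a pole)."""

    s_b: float  # NaN if no crossing
    from_pole: str
    flags: list[str] = field(default_factory=list)


def asi_composite(m: PolarityMeasurement) -> float:
    """Signal-weighted composite asymmetry index; range [-1, 1]."""
    num = (m.apar_anterior - m.apar_posterior) - (m.ppar_anterior - m.ppar_posterior)
    den = m.apar_anterior + m.apar_posterior + m.ppar_anterior + m.ppar_posterior
    if den == 0:
        raise ValidationError("composite ASI undefined: zero total signal")
    return float(num / den)


def asi_single(anterior_mean: float, posterior_mean: float, protein_side: str) -> float:
    """Single-protein asymmetry index from semicircle means.

    (A - P)/(A + P) for anterior-enriched proteins (e.g. MEX-5) and
    (P - A)/(A + P) for posterior-enriched ones (e.g. PAR-1), so a
    correctly polarized embryo always scores positive; the sign is kept,
    so inverted polarity scores negative.
    """
    if protein_side not in ("anterior", "posterior"):
        raise ValidationError("protein_side must be 'anterior' or 'posterior'")
    total = anterior_mean + posterior_mean
    if total <= 0:
        raise ValidationError("ASI undefined: non-positive total signal")
    diff = anterior_mean - posterior_mean
    return float(diff / total) if protein_side == "anterior" else float(-diff / total)


def gradient_magnitude(posterior_mean: float, anterior_mean: float) -> float:
    """Signed concentration difference P - A (intensity units); positive for
    posterior-enriched gradients."""
    return float(posterior_mean - anterior_mean)


def pole_concentrations(
    apar_profile: MembraneProfile,
    ppar_profile: MembraneProfile,
    apar_peak: float,
    ppar_peak: float,
    fraction: float = 0.33,
) -> PolarityMeasurement:
    """Composite-ASI inputs from fitted profiles: cortical-arc means over the
    anterior/posterior ``fraction`` arcs, normalized to wild-type peaks."""
    if apar_peak <= 0 or ppar_peak <= 0:
        raise ValidationError("wild-type peak normalizations must be positive")
    return PolarityMeasurement(
        apar_anterior=cortical_mean(apar_profile, "anterior", fraction) / apar_peak,
        apar_posterior=cortical_mean(apar_profile, "posterior", fraction) / apar_peak,
        ppar_anterior=cortical_mean(ppar_profile, "anterior", fraction) / ppar_peak,
        ppar_posterior=cortical_mean(ppar_profile, "posterior", fraction) / ppar_peak,
    )


def wildtype_peak(profiles: list[MembraneProfile]) -> float:
    """Normalization constant: cohort mean of each embryo's maximum A(s)."""
    if not profiles:
        raise ValidationError("empty wild-type cohort")
    return float(np.mean([np.nanmax(p.amplitude) for p in profiles]))


def semicircle_means(
    image: EmbryoImage, contour: BoundaryContour, channel: str = "signal"
) -> tuple[float, float]:
    """Mean pixel intensity in anterior and posterior half-embryo ROIs.

    The embryo mask is split by the transverse line through its centroid,
    perpendicular to the axis joining the centroid to the anterior pole
    (s = 0). Includes both membrane and cytoplasm signal.
    """
    img = np.asarray(image.channel(channel), dtype=float)
    mask = contour.mask
    centroid = np.array(ndimage.center_of_mass(mask))
    anterior_pt = contour.points[0]
    axis = anterior_pt - centroid
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValidationError("degenerate contour: anterior pole at centroid")
    axis /= norm
    rows, cols = np.nonzero(mask)
    proj = (rows - centroid[0]) * axis[0] + (cols - centroid[1]) * axis[1]
    vals = img[rows, cols]
    anterior = vals[proj > 0]
    posterior = vals[proj <= 0]
    if len(anterior) == 0 or len(posterior) == 0:
        raise ValidationError("semicircle ROI empty")
    return float(anterior.mean()), float(posterior.mean())


def domain_boundary(profile: MembraneProfile, from_pole: str = "anterior") -> BoundaryEstimate:
    """Half-max domain boundary: smallest arc distance from the stated pole
    at which A(s) crosses (A_max + A_min)/2, linearly interpolated.

    A uniform profile has no crossing and returns NaN with a ``no_boundary``
    flag; crossings beyond the first are reported via ``multiple_crossings``.
    """
    if from_pole not in ("anterior", "posterior"):
        raise ValidationError("from_pole must be 'anterior' or 'posterior'")
    s = profile.s[~profile.flagged]
    amp = profile.amplitude[~profile.flagged]
    if len(s) < 4:
        raise ValidationError("too few valid positions")
    if np.nanmax(amp) <= np.nanmin(amp):
        return BoundaryEstimate(np.nan, from_pole, ["no_boundary"])
    half = 0.5 * (np.nanmax(amp) + np.nanmin(amp))
    pole = 0.0 if from_pole == "anterior" else 0.5
    # order positions by signed arc offset from the pole, then walk outward
    offset = (s - pole + 0.5) % 1.0 - 0.5  # in (-0.5, 0.5]
    order = np.argsort(offset)
    off_sorted, amp_sorted = offset[order], amp[order]
    above = amp_sorted > half
    crossings = []
    for i in np.nonzero(above[:-1] != above[1:])[0]:
        x0, x1 = off_sorted[i], off_sorted[i + 1]
        y0, y1 = amp_sorted[i], amp_sorted[i + 1]
        xc = x0 + (half - y0) / (y1 - y0) * (x1 - x0)
        crossings.append(abs(xc))
    if not crossings:
        return BoundaryEstimate(np.nan, from_pole, ["no_boundary"])
    crossings.sort()
    flags = ["multiple_crossings"] if len(crossings) > 2 else []
    return BoundaryEstimate(float(crossings[0]), from_pole, flags)


def mem_cyt_ratio(
    image: EmbryoImage,
    linescan_start: tuple[float, float],
    linescan_end: tuple[float, float],
    cytoplasm_roi: np.ndarray,
    channel: str = "signal",
    line_width_px: int = 10,
    peak_pixels: int = 5,
) -> float:
    """Membrane:cytoplasm signal ratio.

    A ``line_width_px``-wide perpendicular linescan from ``linescan_start``
    to ``linescan_end`` (row, col; bisecting the domain, inside to outside)
    is averaged across its width; the membrane signal is the best mean over
    ``peak_pixels`` contiguous samples of that profile and is divided by
    the mean of ``cytoplasm_roi`` (an interior mask excluding the
    nuclear/spindle area, supplied by the caller).
    """
    img = np.asarray(image.channel(channel), dtype=float)
    roi = np.asarray(cytoplasm_roi) > 0
    if roi.shape != img.shape:
        raise ValidationError("cytoplasm ROI shape mismatch")
    if not roi.any():
        raise ValidationError("empty cytoplasm ROI")
    cyt = float(img[roi].mean())
    if cyt <= 0:
        raise ValidationError("cytoplasm mean must be positive")
    p0 = np.asarray(linescan_start, dtype=float)
    p1 = np.asarray(linescan_end, dtype=float)
    length = np.linalg.norm(p1 - p0)
    if length == 0:
        raise ValidationError("degenerate linescan")
    n = max(int(np.ceil(length)) + 1, peak_pixels)
    axis = (p1 - p0) / length
    perp = np.array([-axis[1], axis[0]])
    t = np.linspace(0.0, length, n)
    w = np.arange(line_width_px, dtype=float) - (line_width_px - 1) / 2.0
    coords = p0[None, None, :] + t[:, None, None] * axis[None, None, :] + w[None, :, None] * perp[None, None, :]
    prof = ndimage.map_coordinates(
        img, [coords[..., 0].ravel(), coords[..., 1].ravel()], order=1, mode="nearest"
    ).reshape(n, line_width_px).mean(axis=1)
    kernel = np.ones(peak_pixels) / peak_pixels
    membrane = float(np.convolve(prof, kernel, mode="valid").max())
    return membrane / cyt


def detect_domains(
    ratio,
    s=None,
    theta_high: float = 1.5,
    theta_low: float = 1.2,
    min_arc: float = 0.05,
) -> DomainCall:
    """Classify a closed membrane:cytoplasm ratio trace r(s) by domain count.

    Arcs where r > theta_high (merged across the s = 0 wrap, at least
    ``min_arc`` of the perimeter long) are domains: one arc is monopolar,
    two or more bipolar. With no arcs the call is ``no_domains`` if
    max r < theta_low, otherwise ``unclear``.
    """
    r = np.asarray(ratio, dtype=float)
    if r.ndim != 1 or len(r) < 8:
        raise ValidationError("ratio trace must be a 1-D closed trace")
    if s is None:
        s = np.arange(len(r)) / len(r)
    else:
        s = np.asarray(s, dtype=float)
        if len(s) != len(r):
            raise ValidationError("s and ratio lengths differ")
        if (s.max() - s.min()) < 0.9 - 1.0 / len(s):
            raise ValidationError("trace does not cover the closed perimeter")
    n = len(r)
    above = r > theta_high
    arcs = []
    if above.all():
        arcs = [(0.0, 1.0, float(r.mean()))]
    elif above.any():
        # runs of consecutive above-threshold samples, circularly
        shift = int(np.argmin(above))  # start scanning at a below-threshold sample
        rolled = np.roll(above, -shift)
        edges = np.nonzero(np.diff(rolled.astype(int)))[0]
        starts = edges[::2] + 1
        ends = edges[1::2] + 1 if len(edges) % 2 == 0 else np.append(edges[1::2] + 1, n)
        for a, b in zip(starts, ends):
            idx = (np.arange(a, b) + shift) % n
            frac = (b - a) / n
            if frac >= min_arc:
                arcs.append((float(s[idx[0]]), float(s[idx[-1]]), float(r[idx].mean())))
    if not arcs:
        category = "no_domains" if r.max() < theta_low else "unclear"
    elif len(arcs) == 1:
        category = "monopolar"
    else:
        category = "bipolar"
    return DomainCall(category, arcs, theta_high, theta_low, min_arc)


# Labeling thresholds for the bimodal asymmetry regimes: embryos with
# ASI above ASI_NORMAL behave like wild type; below ASI_REDUCED they belong
# to the reduced-asymmetry population. Used for labels only, never inference.
ASI_NORMAL = 0.9
ASI_REDUCED = 0.75


def classify_asi_regime(asi: float) -> str:
    if asi > ASI_NORMAL:
        return "normal"
    if asi < ASI_REDUCED:
        return "reduced"
    return "intermediate"
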