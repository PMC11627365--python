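"""Ground-truth synthetic data: embryo images, rundown cohorts, spindle
tracks and two-cell masks.

Everything the analysis pipeline estimates is generated here from an
explicit forward model, together with a :class:`GroundTruth` record of the
true values, so every downstream stage can be tested without microscopy
data.

The rendered embryo is an ellipse in the midplane. Each protein channel is
a membrane ridge (Gaussian cross-section centred on the cell boundary,
amplitude varying with perimeter position) over a cytoplasmic plateau
(error-function step across the boundary), plus a spectrally distinct
autofluorescence component that bleeds into the signal channels, plus
additive Gaussian noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import ellipe, expit

from .division import SpindleTrack
from .errors import SizingError, ValidationError
from .images import EmbryoImage
from .profilemodel import interior_step

# Defaults: 0.256 um/px back-computed from a 50 px == 12.8 um linescan
# width; 25 x 15 um semi-axes are a typical zygote midplane; 0.5 um ridge
# SD is PSF-like.
DEFAULT_PIXEL_SCALE = 0.256
DEFAULT_SEMI_AXES = (25.0, 15.0)
DEFAULT_RIDGE_WIDTH = 0.5


@dataclass
class MembraneModel:
    """Plateau model for one protein's membrane amplitude A(s).

    ``s`` is the perimeter fraction from the anterior pole (s = 0), with the
    posterior pole at s = 0.5. The amplitude interpolates between the
    anterior plateau and the posterior plateau through a logistic boundary
    at arc distance ``boundary`` from the anterior pole (on both sides,
    giving a symmetric domain). ``sharpness`` k sets the transition width:
    the 10-90% transition spans ~1.1/k of the perimeter (k = 20 -> ~5%).
    """

    anterior: float
    posterior: float
    boundary: float = 0.25
    sharpness: float = 20.0

    def validate(self):
        if self.anterior < 0 or self.posterior < 0:
            raise ValidationError("plateau levels must be >= 0")
        if not 0 <= self.boundary < 1:
            raise ValidationError("boundary must lie in [0, 1)")
        if self.sharpness <= 0:
            raise ValidationError("sharpness must be positive")

    def amplitude(self, s) -> np.ndarray:
        """True membrane amplitude A(s) at perimeter fractions ``s``."""
        s = np.asarray(s, dtype=float) % 1.0
        u = np.minimum(s, 1.0 - s)  # arc distance from the anterior pole
        anterior_weight = expit(4.0 * self.sharpness * (self.boundary - u))
        return self.posterior + (self.anterior - self.posterior) * anterior_weight


@dataclass
class SyntheticEmbryoSpec:
    """Full description of one rendered embryo.

    ``membrane_models`` / ``cytoplasm_levels`` map channel roles (e.g.
    ``"apar"``, ``"ppar"``) to per-protein parameters; one image channel is
    rendered per protein, plus an ``"af"`` autofluorescence channel.
    ``af_params`` is (af_mean, af_gradient, bleed_factor): the AF level
    inside the embryo is af_mean + af_gradient * (x/a) along the A-P axis,
    and bleed_factor of it leaks into every protein channel.
    """

    membrane_models: dict[str, MembraneModel]
    cytoplasm_levels: dict[str, float]
    semi_axes: tuple[float, float] = DEFAULT_SEMI_AXES
    pixel_scale: float = DEFAULT_PIXEL_SCALE
    ridge_width: float = DEFAULT_RIDGE_WIDTH  # Gaussian SD of the ridge, um
    edge_width: float = DEFAULT_RIDGE_WIDTH  # erf width of the cytoplasm step, um
    af_params: tuple[float, float, float] = (0.0, 0.0, 0.0)
    signal_offset: float = 0.0  # flat camera offset added to protein channels
    noise_sd: float = 0.0
    margin: float = 8.0  # um of canvas beyond the ellipse on each side
    shape: tuple[int, int] | None = None  # (H, W) px; default fits ellipse + margin
    seed: int = 0

    def validate(self):
        a, b = self.semi_axes
        if not a > b > 0:
            raise ValidationError("semi-axes must satisfy a > b > 0")
        if self.pixel_scale <= 0:
            raise ValidationError("pixel_scale must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.ridge_width <= 0 or self.edge_width <= 0:
            raise ValidationError("ridge/edge widths must be positive")
        if set(self.membrane_models) != set(self.cytoplasm_levels):
            raise ValidationError("membrane_models and cytoplasm_levels must share keys")
        if not self.membrane_models:
            raise ValidationError("at least one protein channel required")
        for model in self.membrane_models.values():
            model.validate()
        for level in self.cytoplasm_levels.values():
            if level < 0:
                raise ValidationError("cytoplasm levels must be >= 0")
        af_mean, af_gradient, bleed = self.af_params
        if af_mean - abs(af_gradient) < 0:
            raise ValidationError("autofluorescence would be negative at one pole")
        if bleed < 0:
            raise ValidationError("bleed_factor must be >= 0")


@dataclass
class GroundTruth:
    """True values behind a synthetic output; serializable to JSON.

    ``curves`` holds per-protein true A(s) on ``s_grid``; ``scalars`` holds
    every true scalar the pipeline later estimates. ``mask`` (interior
    pixels) is carried in memory but reconstructable, so it is dropped on
    serialization.
    """

    kind: str
    spec: dict
    scalars: dict = field(default_factory=dict)
    curves: dict = field(default_factory=dict)
    s_grid: np.ndarray | None = None
    mask: np.ndarray | None = None
    seed: int = 0

    def to_json(self, path=None) -> str:
        payload = {
            "kind": self.kind,
            "spec": self.spec,
            "scalars": self.scalars,
            "curves": {k: np.asarray(v).tolist() for k, v in self.curves.items()},
            "s_grid": None if self.s_grid is None else np.asarray(self.s_grid).tolist(),
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1, default=_json_default)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "GroundTruth":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            kind=payload["kind"],
            spec=payload["spec"],
            scalars=payload["scalars"],
            curves={k: np.asarray(v) for k, v in payload["curves"].items()},
            s_grid=None if payload["s_grid"] is None else np.asarray(payload["s_grid"]),
            seed=payload["seed"],
        )


def _json_default(obj):
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact ellipse perimeter via the complete elliptic integral."""
    return float(4.0 * a * ellipe(1.0 - (b / a) ** 2))


def _ellipse_boundary(a, b, n=4096):
    """Dense boundary polyline starting at the anterior pole (-a, 0),
    with arc-length fractions s for each vertex."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    x = -a * np.cos(t)
    y = -b * np.sin(t)
    pts = np.column_stack([x, y])
    seg = np.hypot(np.diff(x, append=x[:1]), np.diff(y, append=y[:1]))
    arc = np.concatenate([[0.0], np.cumsum(seg[:-1])])
    s = arc / seg.sum()
    return pts, s


def _arc_mask(s, center, fraction):
    """Boolean mask of perimeter fractions within ``fraction/2`` of ``center``."""
    d = np.abs((np.asarray(s) - center + 0.5) % 1.0 - 0.5)
    return d <= fraction / 2.0


def render_embryo(spec: SyntheticEmbryoSpec) -> tuple[EmbryoImage, GroundTruth]:
    """Render a multi-channel midplane image of one embryo.

    Returns the image (one channel per protein plus an ``"af"`` channel)
    and the ground truth (true A(s) per protein, cytoplasm plateaus,
    cortical-arc means, geometry, interior mask).
    """
    spec.validate()
    a, b = spec.semi_axes
    scale = spec.pixel_scale
    if spec.shape is None:
        H = int(np.ceil((2 * b + 2 * spec.margin) / scale))
        W = int(np.ceil((2 * a + 2 * spec.margin) / scale))
    else:
        H, W = spec.shape
    if W * scale < 2.2 * a or H * scale < 2.2 * b:
        raise SizingError("canvas cannot hold the ellipse plus a 10% margin")

    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    rows, cols = np.mgrid[0:H, 0:W]
    x = (cols - cx) * scale  # um along the A-P axis, anterior negative
    y = (rows - cy) * scale

    boundary, s_boundary = _ellipse_boundary(a, b)
    dist, idx = cKDTree(boundary).query(np.column_stack([x.ravel(), y.ravel()]))
    dist = dist.reshape(H, W)
    s_near = s_boundary[idx].reshape(H, W)
    inside = (x / a) ** 2 + (y / b) ** 2 < 1.0
    signed = np.where(inside, dist, -dist)

    step = interior_step(signed, spec.edge_width)
    ridge = np.exp(-(signed**2) / (2.0 * spec.ridge_width**2))

    af_mean, af_gradient, bleed = spec.af_params
    af_field = (af_mean + af_gradient * (x / a)) * step

    rng = np.random.default_rng(spec.seed)
    roles = sorted(spec.membrane_models)
    channels = []
    for role in roles:
        model = spec.membrane_models[role]
        cyt = spec.cytoplasm_levels[role]
        ch = model.amplitude(s_near) * ridge + cyt * step + bleed * af_field
        ch += spec.signal_offset
        if spec.noise_sd > 0:
            ch = ch + rng.normal(0.0, spec.noise_sd, size=ch.shape)
        channels.append(ch)
    af_ch = af_field.copy()
    if spec.noise_sd > 0:
        af_ch = af_ch + rng.normal(0.0, spec.noise_sd, size=af_ch.shape)
    channels.append(af_ch)

    channel_roles = {role: i for i, role in enumerate(roles)}
    channel_roles["af"] = len(roles)
    image = EmbryoImage(
        data=np.stack(channels),
        pixel_scale=scale,
        channel_roles=channel_roles,
        metadata={"generator": "parmap.synthetic.render_embryo", "seed": spec.seed},
    )

    s_grid = np.linspace(0.0, 1.0, 2048, endpoint=False)
    curves, scalars = {}, {}
    for role in roles:
        model = spec.membrane_models[role]
        amp = model.amplitude(s_grid)
        curves[f"amplitude_{role}"] = amp
        scalars[f"cytoplasm_{role}"] = spec.cytoplasm_levels[role]
        scalars[f"peak_{role}"] = float(amp.max())
        for region, center in (("anterior", 0.0), ("posterior", 0.5)):
            sel = _arc_mask(s_grid, center, 0.33)
            scalars[f"cortical_{region}_{role}"] = float(amp[sel].mean())
    if {"apar", "ppar"} <= set(roles):
        scalars["asi_true"] = _true_asi(scalars)
    scalars.update(
        perimeter_um=ellipse_perimeter(a, b),
        area_um2=float(np.pi * a * b),
        semi_axis_a=a,
        semi_axis_b=b,
        anterior_pole_xy_um=[-a, 0.0],
        af_mean=af_mean,
        af_gradient=af_gradient,
        bleed_factor=bleed,
        signal_offset=spec.signal_offset,
        noise_sd=spec.noise_sd,
        ridge_width=spec.ridge_width,
        edge_width=spec.edge_width,
        pixel_scale=scale,
    )
    truth = GroundTruth(
        kind="embryo",
        spec=_spec_dict(spec),
        scalars=scalars,
        curves=curves,
        s_grid=s_grid,
        mask=inside,
        seed=spec.seed,
    )
    return image, truth


def _true_asi(scalars) -> float:
    """Composite asymmetry index from true cortical-arc means, each protein
    normalized to the peak of its own true profile."""
    aa = scalars["cortical_anterior_apar"] / scalars["peak_apar"]
    ap = scalars["cortical_posterior_apar"] / scalars["peak_apar"]
    pa = scalars["cortical_anterior_ppar"] / scalars["peak_ppar"]
    pp = scalars["cortical_posterior_ppar"] / scalars["peak_ppar"]
    return float(((aa - ap) - (pa - pp)) / (aa + ap + pa + pp))


def _spec_dict(spec) -> dict:
    d = asdict(spec)
    d.pop("shape", None)
    return d


def polarized_embryo_spec(
    asi: float = 0.9,
    dosage: float = 1.0,
    peak: float = 100.0,
    cytoplasm: float = 50.0,
    boundary: float = 0.25,
    sharpness: float = 20.0,
    af_params: tuple[float, float, float] = (0.0, 0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    **kwargs,
) -> SyntheticEmbryoSpec:
    """Spec for a two-protein embryo with a prescribed composite asymmetry.

    Builds complementary aPAR/pPAR domains with plateau contrast beta =
    (1 - asi) / (1 + asi), so the nominal composite asymmetry index equals
    ``asi``; everything scales linearly with ``dosage``.
    """
    if not 0 <= asi <= 1:
        raise ValidationError("target asi must lie in [0, 1]")
    beta = (1.0 - asi) / (1.0 + asi)
    high = peak * dosage
    low = peak * dosage * beta
    return SyntheticEmbryoSpec(
        membrane_models={
            "apar": MembraneModel(high, low, boundary, sharpness),
            "ppar": MembraneModel(low, high, boundary, sharpness),
        },
        cytoplasm_levels={"apar": cytoplasm * dosage, "ppar": cytoplasm * dosage},
        af_params=af_params,
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )


def simulate_af_controls(
    n_embryos: int = 10,
    af_mean: float = 30.0,
    af_spread: float = 10.0,
    af_gradient_frac: float = 0.3,
    bleed_factor: float = 0.6,
    signal_offset: float = 10.0,
    noise_sd: float = 2.0,
    seed: int = 0,
    **kwargs,
) -> list[tuple[EmbryoImage, GroundTruth]]:
    """GFP-negative control embryos for autofluorescence calibration.

    Each control has zero protein signal; its green channel is purely
    ``bleed_factor * AF + signal_offset`` plus noise. AF levels vary between
    embryos (uniform +/- af_spread) and across each embryo (gradient), so a
    regression of green on AF recovers the bleed factor.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_embryos):
        mean_i = af_mean + rng.uniform(-af_spread, af_spread)
        spec = SyntheticEmbryoSpec(
            membrane_models={"signal": MembraneModel(0.0, 0.0)},
            cytoplasm_levels={"signal": 0.0},
            af_params=(mean_i, af_gradient_frac * mean_i, bleed_factor),
            signal_offset=signal_offset,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
            **kwargs,
        )
        out.append(render_embryo(spec))
    return out


# ---------------------------------------------------------------------------
# Dosage-rundown cohorts
# ---------------------------------------------------------------------------


@dataclass
class HillPhenotype:
    """Hill-type dosage -> phenotype map.

    p(d) = p_min + (p_wt - p_min) * d^n / (d^n + K^n). The default K = 0.5
    places the inflection near 50% depletion; n = 6 gives the steep,
    switch-like transition the rundown phenotypes show.
    """

    p_min: float
    p_wt: float
    K: float = 0.5
    n: float = 6.0

    def validate(self, d_max: float = 1.0):
        if not 0 < self.K < d_max:
            raise ValidationError("Hill K must lie in (0, d_max)")
        if self.n <= 0:
            raise ValidationError("Hill coefficient n must be positive")

    def __call__(self, dosage) -> np.ndarray:
        d = np.asarray(dosage, dtype=float)
        with np.errstate(divide="ignore"):
            frac = np.where(d > 0, d**self.n / (d**self.n + self.K**self.n), 0.0)
        return self.p_min + (self.p_wt - self.p_min) * frac


@dataclass
class CohortSpec:
    """Rundown cohort: dosages uniform on [0, dosage_max], Hill phenotype
    maps with additive measurement noise, and a bimodal asymmetry regime
    inside ``bimodal_window``: the probability of retaining near-wild-type
    asymmetry falls linearly from 1 at the window top to 0 at the bottom;
    non-retaining embryos have asymmetry reduced linearly with dosage."""

    n_embryos: int = 200
    dosage_max: float = 1.0
    phenotypes: dict[str, HillPhenotype] = field(
        default_factory=lambda: {
            "asynchrony_s": HillPhenotype(p_min=0.0, p_wt=120.0),
            "ab_fraction": HillPhenotype(p_min=0.5, p_wt=0.57),
        }
    )
    noise_sd: dict[str, float] = field(default_factory=dict)
    compensation_fraction_true: float = 0.3
    bimodal_window: tuple[float, float] = (0.25, 0.75)
    asi_high: float = 0.95
    asi_low_max: float = 0.7
    asi_noise_sd: float = 0.02
    seed: int = 0

    def validate(self):
        if self.n_embryos < 1:
            raise ValidationError("n_embryos must be >= 1")
        if self.dosage_max <= 0:
            raise ValidationError("dosage_max must be positive")
        for ph in self.phenotypes.values():
            ph.validate(self.dosage_max)
        lo, hi = self.bimodal_window
        if not 0 <= lo < hi:
            raise ValidationError("bimodal window must satisfy 0 <= lo < hi")
        if not 0 <= self.compensation_fraction_true <= 1:
            raise ValidationError("compensation_fraction_true must lie in [0, 1]")


def simulate_rundown_cohort(
    spec: CohortSpec, dosages: np.ndarray | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """One row per embryo: true dosage, noisy Hill phenotypes, bimodal ASI.

    ``dosages`` overrides the uniform draw (used for noiseless oracles).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    if dosages is None:
        d = rng.uniform(0.0, spec.dosage_max, spec.n_embryos)
    else:
        d = np.asarray(dosages, dtype=float)
    n = len(d)

    table = {"embryo_id": [f"e{i:04d}" for i in range(n)], "dosage_true": d}
    for name in sorted(spec.phenotypes):
        ph = spec.phenotypes[name]
        sd = spec.noise_sd.get(name, 0.0)
        vals = ph(d)
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, n)
        table[f"phenotype_{name}"] = vals

    lo, hi = spec.bimodal_window
    retain_p = np.clip((d - lo) / (hi - lo), 0.0, 1.0)
    retained = rng.uniform(size=n) < retain_p
    asi_low = spec.asi_low_max * np.clip(d / hi, 0.0, 1.0)
    asi = np.where(retained, spec.asi_high, asi_low)
    if spec.asi_noise_sd > 0:
        asi = asi + rng.normal(0.0, spec.asi_noise_sd, n)
    table["asi_true"] = np.clip(asi, -1.0, 1.0)
    table["retained_polarity"] = retained
    table["seed"] = spec.seed

    truth = GroundTruth(
        kind="rundown_cohort",
        spec=asdict(spec),
        scalars={"n_embryos": n, "retain_fraction": float(retained.mean())},
        curves={
            f"hill_{name}": spec.phenotypes[name](np.linspace(0, spec.dosage_max, 512))
            for name in sorted(spec.phenotypes)
        },
        s_grid=np.linspace(0, spec.dosage_max, 512),
        seed=spec.seed,
    )
    return pd.DataFrame(table), truth


def simulate_genotype_cohorts(
    compensation_fraction_true: float = 0.3,
    x_hom: float = 1.0,
    x_het_wt: float = 0.5,
    noise_sd: float = 0.05,
    n_per_genotype: int = 20,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], GroundTruth]:
    """Whole-embryo signal for the three genotypes of a compensation assay:
    xfp/xfp, xfp/+ and xfp/null. The null-over-tag mean sits a fraction
    ``compensation_fraction_true`` of the way from xfp/+ up to xfp/xfp."""
    if not 0 <= compensation_fraction_true <= 1:
        raise ValidationError("compensation fraction must lie in [0, 1]")
    if x_hom <= x_het_wt:
        raise ValidationError("homozygous mean must exceed heterozygous mean")
    rng = np.random.default_rng(seed)
    x_het_null = x_het_wt + compensation_fraction_true * (x_hom - x_het_wt)
    cohorts = {
        "hom": x_hom + rng.normal(0, noise_sd, n_per_genotype),
        "het_wt": x_het_wt + rng.normal(0, noise_sd, n_per_genotype),
        "het_null": x_het_null + rng.normal(0, noise_sd, n_per_genotype),
    }
    truth = GroundTruth(
        kind="genotype_cohorts",
        spec={
            "compensation_fraction_true": compensation_fraction_true,
            "x_hom": x_hom,
            "x_het_wt": x_het_wt,
            "x_het_null": x_het_null,
            "noise_sd": noise_sd,
            "n_per_genotype": n_per_genotype,
        },
        scalars={"compensation_fraction_true": compensation_fraction_true},
        seed=seed,
    )
    return cohorts, truth


# ---------------------------------------------------------------------------
# Spindle tracks and two-cell masks
# ---------------------------------------------------------------------------


@dataclass
class TrackSpec:
    """Spindle-pole trajectory generator parameters.

    y(t) = amplitude * sin(2 pi f t) + noise per pole; x(t) drifts at a
    constant velocity from ``x0``. Event annotations are given in seconds
    and converted to frames.
    """

    duration_s: float = 180.0
    frame_interval_s: float = 0.1
    amplitude_um: dict[str, float] = field(default_factory=lambda: {"A": 1.0, "P": 3.0})
    frequency_hz: float = 0.05
    drift_um_s: dict[str, float] = field(default_factory=lambda: {"A": 0.0, "P": 0.0})
    x0_um: dict[str, float] = field(default_factory=lambda: {"A": 20.0, "P": 30.0})
    noise_sd_um: float = 0.0
    embryo_length_um: float = 50.0
    events_s: dict[str, float] | None = None
    embryo_id: str = "sim"
    seed: int = 0

    def validate(self):
        if self.frame_interval_s <= 0:
            raise ValidationError("frame interval must be positive")
        if self.duration_s <= 0:
            raise ValidationError("duration must be positive")
        if self.noise_sd_um < 0:
            raise ValidationError("noise_sd must be >= 0")


def simulate_spindle_track(spec: TrackSpec) -> tuple[SpindleTrack, GroundTruth]:
    """Simulate (t, x, y) per pole with sinusoidal transverse oscillations."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s / spec.frame_interval_s)) + 1
    t = np.arange(n) * spec.frame_interval_s
    x, y = {}, {}
    for pole in sorted(spec.amplitude_um):
        amp = spec.amplitude_um[pole]
        drift = spec.drift_um_s.get(pole, 0.0)
        x0 = spec.x0_um.get(pole, 0.0)
        yy = amp * np.sin(2 * np.pi * spec.frequency_hz * t)
        xx = x0 + drift * t
        if spec.noise_sd_um > 0:
            xx = xx + rng.normal(0, spec.noise_sd_um, n)
            yy = yy + rng.normal(0, spec.noise_sd_um, n)
        x[pole], y[pole] = xx, yy
    events_s = spec.events_s or {
        "prometaphase_start": 0.0,
        "anaphase_onset": spec.duration_s / 2,
        "telophase": spec.duration_s,
    }
    annotations = {
        name: min(int(round(ts / spec.frame_interval_s)), n - 1)
        for name, ts in events_s.items()
    }
    track = SpindleTrack(
        t=t,
        x=x,
        y=y,
        frame_interval=spec.frame_interval_s,
        embryo_length=spec.embryo_length_um,
        annotations=annotations,
        embryo_id=spec.embryo_id,
    )
    truth = GroundTruth(
        kind="spindle_track",
        spec=asdict(spec) | {"events_s": events_s},
        scalars={
            f"oscillation_sd_{pole}": spec.amplitude_um[pole] / np.sqrt(2.0)
            for pole in spec.amplitude_um
        }
        | {
            f"drift_velocity_{pole}": spec.drift_um_s.get(pole, 0.0)
            for pole in spec.amplitude_um
        },
        seed=spec.seed,
    )
    return track, truth


@dataclass
class TwoCellSpec:
    """Two-cell stage: AB/P1 masks on an elliptical midplane plus division
    event times (~2 min AB-to-P1 asynchrony in wild type)."""

    ab_fraction: float = 0.57
    asynchrony_s: float = 120.0
    frame_interval_s: float = 15.0
    t_ab_s: float = 600.0
    semi_axes: tuple[float, float] = DEFAULT_SEMI_AXES
    pixel_scale: float = DEFAULT_PIXEL_SCALE
    shape: tuple[int, int] | None = None
    seed: int = 0

    def validate(self):
        if not 0 < self.ab_fraction < 1:
            raise ValidationError("ab_fraction must lie in (0, 1)")
        if self.frame_interval_s <= 0:
            raise ValidationError("frame interval must be positive")


def simulate_two_cell(spec: TwoCellSpec) -> tuple[dict[str, np.ndarray], dict, GroundTruth]:
    """Labeled AB/P1 midplane masks plus furrow-ingression event times.

    The AB/P1 boundary is a transverse chord; its column is chosen to make
    the pixel-counted AB area fraction as close as possible to the target
    (quantization error is below one chord's worth of pixels / total area).
    """
    spec.validate()
    a, b = spec.semi_axes
    scale = spec.pixel_scale
    if spec.shape is None:
        H = int(np.ceil(2.4 * b / scale))
        W = int(np.ceil(2.4 * a / scale))
    else:
        H, W = spec.shape
    if W * scale < 2.2 * a or H * scale < 2.2 * b:
        raise SizingError("canvas cannot hold the two-cell ellipse")
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    rows, cols = np.mgrid[0:H, 0:W]
    x = (cols - cx) * scale
    y = (rows - cy) * scale
    whole = (x / a) ** 2 + (y / b) ** 2 < 1.0
    total = whole.sum()
    # anterior (AB) is on the low-column side; scan the cut column for the
    # best pixel-count match to the target fraction
    col_counts = whole.sum(axis=0)
    cum = np.cumsum(col_counts)
    frac_by_cut = cum / total
    cut = int(np.argmin(np.abs(frac_by_cut - spec.ab_fraction)))
    mask_ab = whole & (cols <= cut)
    mask_p1 = whole & (cols > cut)

    frame_ab = int(round(spec.t_ab_s / spec.frame_interval_s))
    frame_p1 = frame_ab + int(round(spec.asynchrony_s / spec.frame_interval_s))
    events = {
        "furrow_ab_frame": frame_ab,
        "furrow_p1_frame": frame_p1,
        "t_ab_s": frame_ab * spec.frame_interval_s,
        "t_p1_s": frame_p1 * spec.frame_interval_s,
    }
    truth = GroundTruth(
        kind="two_cell",
        spec=asdict(spec),
        scalars={
            "ab_fraction_true": spec.ab_fraction,
            "ab_fraction_rendered": float(mask_ab.sum() / total),
            "asynchrony_true_s": spec.asynchrony_s,
            "asynchrony_rendered_s": events["t_p1_s"] - events["t_ab_s"],
        },
        mask=whole,
        seed=spec.seed,
    )
    masks = {"AB": mask_ab, "P1": mask_p1, "whole": whole}
    return masks, events, truth
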