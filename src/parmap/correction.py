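"""Spectral autofluorescence correction and flat background subtraction.

Embryonic autofluorescence excited at 488 nm has a much broader emission
spectrum than GFP, so its level can be gauged in a parallel red-shifted
channel. On GFP-negative control embryos the green channel is purely
autofluorescence (plus camera offset), giving a calibration line

    green = m * AF + b

whose prediction is subtracted from the green channel of labeled embryos,
pixel-by-pixel or embryo-by-embryo. Channels acquired in configurations
with negligible autofluorescence (mNG at 514 nm excitation, mCherry) are
instead corrected by subtracting a flat mean background measured on
unlabeled embryos. Corrected intensities may be negative and are never
clipped (clipping would bias cohort means).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from .errors import DegenerateFitError, ValidationError
from .images import EmbryoImage


@dataclass
class AFModel:
    """Linear autofluorescence calibration green = slope * AF + intercept."""

    slope: float
    intercept: float
    mode: str
    n_embryos: int
    n_samples: int
    residual_sd: float

    def predict(self, af):
        return self.slope * np.asarray(af, dtype=float) + self.intercept

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "AFModel":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(**payload)


@dataclass
class FlatBackground:
    """Per-channel mean background measured on unlabeled embryos."""

    levels: dict[str, float]
    n_embryos: int

    def __post_init__(self):
        if self.n_embryos < 1:
            raise ValidationError("flat background needs >= 1 control embryo")


_MAX_PIXELS = 100_000


def fit_af_model(
    control_images: list[EmbryoImage],
    masks: list[np.ndarray],
    mode: str = "pixel",
    green_role: str = "signal",
    af_role: str = "af",
) -> AFModel:
    """Least-squares line green = m * AF + b over GFP-negative controls.

    ``mode="pixel"`` pools in-mask pixels across embryos (deterministically
    strided down to at most 1e5 samples); ``mode="embryo"`` regresses
    per-embryo in-mask means (needs >= 2 embryos).
    """
    if not control_images:
        raise ValidationError("at least one control embryo required")
    if len(masks) != len(control_images):
        raise ValidationError("one mask per control image required")
    greens, afs = [], []
    for img, mask in zip(control_images, masks):
        m = np.asarray(mask) > 0
        if m.shape != img.shape:
            raise ValidationError("mask shape does not match image")
        g = img.channel(green_role)[m]
        a = img.channel(af_role)[m]
        if mode == "pixel":
            greens.append(g)
            afs.append(a)
        elif mode == "embryo":
            greens.append(np.array([g.mean()]))
            afs.append(np.array([a.mean()]))
        else:
            raise ValidationError("mode must be 'pixel' or 'embryo'")
    green = np.concatenate(greens)
    af = np.concatenate(afs)
    if mode == "embryo" and len(green) < 2:
        raise ValidationError("embryo-mode regression needs >= 2 control embryos")
    if mode == "pixel" and len(green) > _MAX_PIXELS:
        stride = int(np.ceil(len(green) / _MAX_PIXELS))
        green, af = green[::stride], af[::stride]
    if np.ptp(af) == 0:
        raise DegenerateFitError("AF channel has zero variance; slope unidentifiable")
    slope, intercept = np.polyfit(af, green, 1)
    resid = green - (slope * af + intercept)
    return AFModel(
        slope=float(slope),
        intercept=float(intercept),
        mode=mode,
        n_embryos=len(control_images),
        n_samples=len(green),
        residual_sd=float(resid.std()),
    )


def correct_image(
    image: EmbryoImage,
    model: AFModel,
    mode: str = "pixel",
    green_role: str = "signal",
    af_role: str = "af",
    mask: np.ndarray | None = None,
    local_bg: np.ndarray | None = None,
) -> EmbryoImage:
    """Subtract the inferred autofluorescence from the green channel.

    Pixel mode subtracts ``m * AF + b`` pixelwise (spatial correction);
    embryo mode subtracts the scalar ``m * mean(AF in mask) + b``, which is
    what whole-embryo quantitation uses. An optional ``local_bg`` image
    (empty field of view) is subtracted from both channels first.
    """
    green = np.asarray(image.channel(green_role), dtype=float)
    af = np.asarray(image.channel(af_role), dtype=float)
    if green.shape != af.shape:
        raise ValidationError("green/AF channel shapes differ")
    if local_bg is not None:
        local_bg = np.asarray(local_bg, dtype=float)
        if local_bg.shape != green.shape:
            raise ValidationError("local background shape mismatch")
        green = green - local_bg
        af = af - local_bg
    if mode == "pixel":
        corrected = green - model.predict(af)
    elif mode == "embryo":
        if mask is None:
            raise ValidationError("embryo-mode correction requires a mask")
        m = np.asarray(mask) > 0
        corrected = green - float(model.predict(af[m].mean()))
    else:
        raise ValidationError("mode must be 'pixel' or 'embryo'")
    return image.with_channel(
        green_role,
        corrected,
        af_correction={"mode": mode, "slope": model.slope, "intercept": model.intercept,
                       "channel": green_role},
    )


def measure_flat_background(
    control_images: list[EmbryoImage],
    masks: list[np.ndarray],
    roles: list[str],
) -> FlatBackground:
    """Mean in-mask background per channel over unlabeled embryos."""
    if not control_images:
        raise ValidationError("at least one control embryo required")
    levels = {}
    for role in roles:
        vals = [
            img.channel(role)[np.asarray(mask) > 0].mean()
            for img, mask in zip(control_images, masks)
        ]
        levels[role] = float(np.mean(vals))
    return FlatBackground(levels=levels, n_embryos=len(control_images))


def subtract_flat_background(image: EmbryoImage, bg: FlatBackground) -> EmbryoImage:
    """Subtract each channel's scalar background level."""
    out = image
    for role, level in bg.levels.items():
        if role not in image.channel_roles:
            raise ValidationError(f"image has no channel {role!r} to background-correct")
        out = out.with_channel(
            role, out.channel(role) - level, flat_background={role: level}
        )
    return out
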