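"""Multi-channel embryo image container and TIFF I/O.

Images are midplane, single-embryo, multi-channel rasters. Channels are
addressed by *role* (e.g. ``"apar"``, ``"ppar"``, ``"af"``) rather than by
index, so downstream stages never need to know the acquisition order.
Multi-page TIFFs store one channel per page with the role map and pixel
scale in the ImageDescription tag as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import ValidationError


@dataclass
class EmbryoImage:
    """A (n_channels, H, W) float raster with pixel scale and channel roles.

    Parameters
    ----------
    data : ndarray
        Intensities, shape ``(n_channels, H, W)``.
    pixel_scale : float
        Microns per pixel (isotropic).
    channel_roles : dict
        Maps role name to channel index.
    metadata : dict
        Free-form provenance (corrections applied, generator seed, ...).
    """

    data: np.ndarray
    pixel_scale: float
    channel_roles: dict[str, int]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("image data must be (n_channels, H, W)")
        if self.pixel_scale <= 0:
            raise ValidationError("pixel_scale must be positive")
        n = self.data.shape[0]
        for role, idx in self.channel_roles.items():
            if not 0 <= idx < n:
                raise ValidationError(f"channel role {role!r} -> index {idx} out of range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def channel(self, role: str) -> np.ndarray:
        if role not in self.channel_roles:
            raise ValidationError(f"image has no channel with role {role!r}")
        return self.data[self.channel_roles[role]]

    def with_channel(self, role: str, values: np.ndarray, **extra_meta) -> "EmbryoImage":
        """Return a copy with one channel replaced (used by corrections)."""
        values = np.asarray(values, dtype=float)
        if values.shape != self.shape:
            raise ValidationError("replacement channel shape mismatch")
        data = self.data.copy()
        data[self.channel_roles[role]] = values
        meta = dict(self.metadata)
        meta.update(extra_meta)
        return replace(self, data=data, metadata=meta)


def write_tiff(path, image: EmbryoImage) -> None:
    """Write one page per channel; roles and pixel scale go in the description."""
    desc = json.dumps(
        {
            "pixel_scale": image.pixel_scale,
            "channel_roles": image.channel_roles,
            "metadata": _jsonable(image.metadata),
        }
    )
    tifffile.imwrite(path, image.data.astype(np.float32), description=desc)


def read_tiff(path, pixel_scale=None, channel_roles=None) -> EmbryoImage:
    """Read a multi-page TIFF written by :func:`write_tiff`.

    ``pixel_scale`` / ``channel_roles`` override (or supply, for foreign
    files) the values from the description tag.
    """
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description
    if data.ndim == 2:
        data = data[None]
    meta = {}
    if desc:
        try:
            parsed = json.loads(desc)
            pixel_scale = pixel_scale or parsed.get("pixel_scale")
            channel_roles = channel_roles or parsed.get("channel_roles")
            meta = parsed.get("metadata", {})
        except (json.JSONDecodeError, AttributeError):
            pass
    if pixel_scale is None:
        raise ValidationError(f"{path}: no pixel scale in file; pass pixel_scale=")
    if channel_roles is None:
        channel_roles = {f"ch{i}": i for i in range(data.shape[0])}
    return EmbryoImage(
        data=np.asarray(data, dtype=float),
        pixel_scale=float(pixel_scale),
        channel_roles={k: int(v) for k, v in channel_roles.items()},
        metadata=meta,
    )


def write_mask_tiff(path, mask: np.ndarray) -> None:
    tifffile.imwrite(path, (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
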