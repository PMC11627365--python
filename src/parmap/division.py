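"""Asymmetric-division phenotypes: size asymmetry, division asynchrony and
spindle-pole track metrics.

The zygote divides into a larger anterior cell (AB) and a smaller posterior
cell (P1). Fate asymmetry is read out as the ~2 min delay between AB and P1
cleavage furrow ingression; spindle-positioning outputs are read out from
pole trajectories: transverse oscillation magnitude, final pole positions
along the anterior-posterior (A-P) axis, and maximum outward velocities
after midzone severing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

POLES = ("A", "P")


@dataclass
class SpindleTrack:
    """Per-frame pole coordinates in the embryo frame.

    ``x`` runs along the A-P axis from the anterior pole of the embryo;
    ``y`` is the signed displacement off the central A-P axis (y = 0).
    ``annotations`` maps event names (``prometaphase_start``,
    ``anaphase_onset``, ``telophase``, ...) to frame indices.
    """

    t: np.ndarray  # seconds, strictly increasing
    x: dict[str, np.ndarray]  # pole -> positions (um)
    y: dict[str, np.ndarray]
    frame_interval: float  # seconds
    embryo_length: float | None = None  # um
    annotations: dict[str, int] = field(default_factory=dict)
    embryo_id: str = "embryo"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValidationError("track needs >= 2 frames")
        if np.any(np.diff(self.t) <= 0):
            raise ValidationError("track times must be strictly increasing")
        for pole in self.x:
            self.x[pole] = np.asarray(self.x[pole], dtype=float)
            self.y[pole] = np.asarray(self.y[pole], dtype=float)
            if len(self.x[pole]) != len(self.t) or len(self.y[pole]) != len(self.t):
                raise ValidationError(f"pole {pole}: coordinate/time length mismatch")
        for event, frame in self.annotations.items():
            if not 0 <= frame < len(self.t):
                raise ValidationError(f"annotation {event!r} frame {frame} outside track")

    @property
    def n_frames(self) -> int:
        return len(self.t)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for pole in self.x:
            for i, t in enumerate(self.t):
                rows.append(
                    {
                        "embryo_id": self.embryo_id,
                        "pole": pole,
                        "frame": i,
                        "t_s": t,
                        "x_um": self.x[pole][i],
                        "y_um": self.y[pole][i],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        frame_interval: float | None = None,
        embryo_length: float | None = None,
        annotations: dict[str, int] | None = None,
    ) -> "SpindleTrack":
        required = {"embryo_id", "pole", "frame", "t_s", "x_um", "y_um"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"track table missing columns: {sorted(missing)}")
        ids = df["embryo_id"].unique()
        if len(ids) != 1:
            raise ValidationError("one track per call; filter by embryo_id first")
        x, y, t = {}, {}, None
        for pole, sub in df.groupby("pole"):
            sub = sub.sort_values("frame")
            x[pole] = sub["x_um"].to_numpy()
            y[pole] = sub["y_um"].to_numpy()
            t = sub["t_s"].to_numpy()
        if frame_interval is None:
            frame_interval = float(np.median(np.diff(t)))
        return cls(
            t=t,
            x=x,
            y=y,
            frame_interval=frame_interval,
            embryo_length=embryo_length,
            annotations=annotations or {},
            embryo_id=str(ids[0]),
        )


@dataclass
class DivisionOutcome:
    """Bundle of division metrics for one embryo."""

    ab_fraction: float | None = None
    asynchrony_s: float | None = None
    oscillation_sd: dict[str, float] | None = None
    final_positions: dict[str, float] | None = None
    severing_vmax: dict[str, float] | None = None
    delta_vmax: float | None = None
    flags: list[str] = field(default_factory=list)


def size_asymmetry(mask_ab: np.ndarray, mask_whole: np.ndarray) -> float:
    """AB area divided by whole-embryo area on a midplane section."""
    mask_ab = np.asarray(mask_ab) > 0
    mask_whole = np.asarray(mask_whole) > 0
    if mask_ab.shape != mask_whole.shape:
        raise ValidationError("masks must have the same shape")
    whole = mask_whole.sum()
    if whole == 0:
        raise ValidationError("whole-embryo mask is empty")
    if np.any(mask_ab & ~mask_whole):
        raise ValidationError("AB mask is not contained in the whole-embryo mask")
    return float(mask_ab.sum() / whole)


def division_asynchrony(t_ab: float, t_p1: float) -> float:
    """Signed furrow-ingression lag t_P1 - t_AB in seconds (positive in wild type)."""
    if t_ab is None or t_p1 is None or not (np.isfinite(t_ab) and np.isfinite(t_p1)):
        raise ValidationError("both furrow times are required")
    return float(t_p1 - t_ab)


def _window_slice(track: SpindleTrack, start_event: str, end_event: str) -> slice:
    for event in (start_event, end_event):
        if event not in track.annotations:
            raise ValidationError(f"track missing annotation {event!r}")
    i0 = track.annotations[start_event]
    i1 = track.annotations[end_event]
    if i1 < i0:
        raise ValidationError("window end precedes window start")
    return slice(i0, i1 + 1)


def oscillation_magnitude(
    track: SpindleTrack,
    start_event: str = "prometaphase_start",
    end_event: str = "telophase",
) -> dict[str, float]:
    """Transverse oscillation magnitude per pole.

    Population standard deviation of the off-axis displacement ``y`` over
    the prometaphase-to-telophase window.
    """
    win = _window_slice(track, start_event, end_event)
    if win.stop - win.start < 5:
        raise ValidationError("oscillation window must contain >= 5 frames")
    return {pole: float(np.std(track.y[pole][win])) for pole in track.y}


def final_pole_positions(track: SpindleTrack, event: str = "telophase") -> dict[str, float]:
    """Pole x at telophase as a fraction of embryo length."""
    if event not in track.annotations:
        raise ValidationError(f"track missing annotation {event!r}")
    if track.embryo_length is None or track.embryo_length <= 0:
        raise ValidationError("embryo_length required to normalize pole positions")
    i = track.annotations[event]
    return {pole: float(track.x[pole][i] / track.embryo_length) for pole in track.x}


def _moving_average(v: np.ndarray, n: int) -> np.ndarray:
    if n <= 1:
        return v
    return np.convolve(v, np.ones(n) / n, mode="valid")


def severing_max_velocity(
    track: SpindleTrack, smooth_frames: int = 10, window_s: float = 1.0
) -> tuple[dict[str, float], float]:
    """Maximum pole speed after spindle-midzone severing.

    x and y are smoothed with a ``smooth_frames`` moving average; Euclidean
    displacements are measured over rolling windows of ``window_s`` seconds
    and the maximum displacement defines the maximum velocity per pole.
    Returns ``(vmax_per_pole, delta_v)`` with ``delta_v = vmax(P) - vmax(A)``
    (None if either pole is absent).
    """
    w = int(round(window_s / track.frame_interval))
    if w < 1:
        raise ValidationError("window_s shorter than one frame interval")
    vmax = {}
    for pole in track.x:
        xs = _moving_average(track.x[pole], smooth_frames)
        ys = _moving_average(track.y[pole], smooth_frames)
        if len(xs) <= w:
            raise ValidationError(
                f"pole {pole}: track too short for smoothing ({smooth_frames}) "
                f"plus a {window_s} s window"
            )
        disp = np.hypot(xs[w:] - xs[:-w], ys[w:] - ys[:-w])
        vmax[pole] = float(disp.max() / (w * track.frame_interval))
    delta = vmax["P"] - vmax["A"] if "A" in vmax and "P" in vmax else None
    return vmax, delta
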