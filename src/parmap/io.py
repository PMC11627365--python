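"""Table I/O with schema checks: cohorts, tracks, events, contours,
profiles, trend fits and window statistics.

All tables are UTF-8 CSV with a header row and '.' decimals; floats are
written at full precision (Python repr) so write -> read round trips are
lossless.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .cortex import BoundaryContour, MembraneProfile
from .doseresponse import TrendFit, WindowStats
from .errors import SchemaError

COHORT_REQUIRED = ["embryo_id"]
TRACK_REQUIRED = ["embryo_id", "pole", "frame", "t_s", "x_um", "y_um"]
EVENT_REQUIRED = ["embryo_id", "event", "frame"]


def _check_columns(df: pd.DataFrame, required, known, name: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table missing required column(s): {missing}")
    if known is not None:
        unknown = [c for c in df.columns if c not in known and not _known_prefix(c, known)]
        if unknown:
            warnings.warn(f"{name} table has unknown column(s): {unknown}", stacklevel=3)


def _known_prefix(col, known):
    return any(col.startswith(k[:-1]) for k in known if k.endswith("*"))


def write_cohort(path, df: pd.DataFrame) -> None:
    _check_columns(df, COHORT_REQUIRED, None, "cohort")
    df.to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, COHORT_REQUIRED, None, "cohort")
    return df


def write_tracks(path, df: pd.DataFrame) -> None:
    _check_columns(df, TRACK_REQUIRED, TRACK_REQUIRED, "track")
    df.to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, TRACK_REQUIRED, TRACK_REQUIRED, "track")
    return df


def write_events(path, df: pd.DataFrame) -> None:
    _check_columns(df, EVENT_REQUIRED, EVENT_REQUIRED, "event")
    df.to_csv(path, index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, EVENT_REQUIRED, EVENT_REQUIRED, "event")
    return df


def events_for(df_events: pd.DataFrame, embryo_id: str) -> dict[str, int]:
    sub = df_events[df_events["embryo_id"] == embryo_id]
    return {str(r["event"]): int(r["frame"]) for _, r in sub.iterrows()}


def write_contour(path, contour: BoundaryContour) -> None:
    pd.DataFrame(
        {"s": contour.s, "row": contour.points[:, 0], "col": contour.points[:, 1]}
    ).to_csv(path, index=False)


def read_contour_points(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["s", "row", "col"], ["s", "row", "col"], "contour")
    return df


def write_profile(path, profile: MembraneProfile) -> None:
    pd.DataFrame(
        {
            "s": profile.s,
            "A": profile.amplitude,
            "C": profile.cytoplasm,
            "c_um": profile.center_um,
            "flag": profile.flagged.astype(int),
        }
    ).to_csv(path, index=False)


def read_profile(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    _check_columns(df, ["s", "A", "C"], ["s", "A", "C", "c_um", "flag"], "profile")
    return df


def write_trend(path, trend: TrendFit) -> None:
    pd.DataFrame(
        {"x": trend.x, "fit": trend.fit, "lo": trend.lower, "hi": trend.upper}
    ).to_csv(path, index=False)


def write_window_stats(path, ws: WindowStats) -> None:
    pd.DataFrame(
        {
            "x": ws.centers,
            "mean_dosage": ws.mean_dosage,
            "variance": ws.variance,
            "lo": ws.ci_low,
            "hi": ws.ci_high,
        }
    ).to_csv(path, index=False)


def read_xy_table(path, x_col: str, y_col: str) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in (x_col, y_col):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    sub = df[[x_col, y_col]].dropna()
    return sub[x_col].to_numpy(float), sub[y_col].to_numpy(float)
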