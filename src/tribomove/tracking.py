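"""Domain containers and I/O for multi-animal tracking exports.

Coordinate convention (fixed, not configurable): x increases rightward, y
increases downward — the usual image convention of video trackers — and
frame indices are 0-based integers. Gaps inside a track (missing frames)
are permitted: a step spanning a gap contributes its straight-line chord
to distance and its true elapsed time to duration.

The on-disk contract is two tidy CSV files:

* tracking table: ``replicate_id, track_id, frame, x, y`` — one row per
  detection, coordinates in pixels;
* metadata table: ``replicate_id, line_id, regime, block_id, camera_id``
  plus optional ``fps`` (default 25) and ``mm_per_px``.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigError, FormatError

REGIMES = ("high", "low", "control")

TRACKING_COLUMNS = ("replicate_id", "track_id", "frame", "x", "y")
METADATA_COLUMNS = ("replicate_id", "line_id", "regime", "block_id", "camera_id")
#: metadata fields addressable by exclusion rules
EXCLUDABLE_FIELDS = ("replicate_id", "line_id", "regime", "block_id", "camera_id")

DEFAULT_FPS = 25.0


@dataclass(frozen=True)
class Track:
    """One individual's time-ordered pixel coordinates within a recording.

    Parameters
    ----------
    track_id : str
        Opaque identifier assigned by the tracker.
    frames : ndarray of int
        Strictly increasing frame indices.
    xy : ndarray, shape (n, 2)
        Pixel coordinates, one row per frame index.
    """

    track_id: str
    frames: np.ndarray
    xy: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        xy = np.asarray(self.xy, dtype=float)
        if xy.ndim != 2 or xy.shape[1] != 2:
            raise ValueError(f"track {self.track_id!r}: xy must have shape (n, 2)")
        if len(frames) != len(xy):
            raise ValueError(
                f"track {self.track_id!r}: {len(frames)} frames but {len(xy)} coordinates"
            )
        if len(frames) > 1 and not np.all(np.diff(frames) > 0):
            raise ValueError(f"track {self.track_id!r}: frames not strictly increasing")
        if not np.all(np.isfinite(xy)):
            raise ValueError(f"track {self.track_id!r}: non-finite coordinate")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "xy", xy)

    @property
    def n(self) -> int:
        return len(self.frames)

    def duration_s(self, fps: float) -> float:
        """Elapsed time from first to last detection, in seconds."""
        if self.n < 2:
            return 0.0
        return float(self.frames[-1] - self.frames[0]) / fps


@dataclass
class ReplicateRecording:
    """A replicate recording: all tracks from one arena plus design metadata."""

    replicate_id: str
    line_id: str
    regime: str
    block_id: str
    camera_id: str
    fps: float = DEFAULT_FPS
    mm_per_px: float | None = None
    tracks: list[Track] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(
                f"replicate {self.replicate_id!r}: regime {self.regime!r} "
                f"not one of {REGIMES}"
            )
        if not self.fps > 0:
            raise ValueError(f"replicate {self.replicate_id!r}: fps must be > 0")
        if self.mm_per_px is not None and not self.mm_per_px > 0:
            raise ValueError(f"replicate {self.replicate_id!r}: mm_per_px must be > 0")

    @property
    def n_detections(self) -> int:
        return sum(t.n for t in self.tracks)

    def all_xy(self) -> np.ndarray:
        """All detections pooled over tracks, shape (N, 2)."""
        if not self.tracks:
            return np.empty((0, 2))
        return np.concatenate([t.xy for t in self.tracks])


@dataclass(frozen=True)
class ArenaBounds:
    """Arena extent inferred from the coordinate extremes of a recording."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float

    def __post_init__(self) -> None:
        if self.xmax < self.xmin or self.ymax < self.ymin:
            raise ValueError("inverted arena bounds")

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def degenerate(self) -> bool:
        """True when the observed extent collapses in either axis."""
        return self.width == 0.0 or self.height == 0.0


@dataclass
class MovementSummary:
    """Per-replicate activity metrics (population level).

    ``path_length_px_per_s`` is the duration-weighted mean speed (total
    distance over total tracked time, pixels/s); ``sinuosity`` maps each
    rediscretization step length p to the mean estimate over tracks (in
    pixel^-1/2); ``edge_affinity`` is the pooled proportion of detections
    within the edge margin. Undefined components are ``None`` with the
    reason recorded in ``notes``.
    """

    replicate_id: str
    path_length_px_per_s: float | None
    sinuosity: dict[float, float | None]
    edge_affinity: float | None
    n_tracks: int
    total_tracked_seconds: float
    n_tracks_used: dict[str, int] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


def arena_bounds(rec: ReplicateRecording) -> ArenaBounds:
    """Componentwise min/max over every detection of every track.

    Raises ``ValueError`` for an empty replicate. A single detection (or a
    perfectly collinear axis) yields degenerate bounds, flagged via
    :attr:`ArenaBounds.degenerate`; edge affinity is undefined downstream.
    """
    xy = rec.all_xy()
    if len(xy) == 0:
        raise ValueError(f"replicate {rec.replicate_id!r} has no detections")
    return ArenaBounds(
        xmin=float(xy[:, 0].min()),
        xmax=float(xy[:, 0].max()),
        ymin=float(xy[:, 1].min()),
        ymax=float(xy[:, 1].max()),
    )


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{what} is missing required column {col!r}")


def read_tracking_table(
    tracking: "str | io.TextIOBase",
    metadata: "str | io.TextIOBase | pd.DataFrame",
) -> list[ReplicateRecording]:
    """Read a tracking CSV plus a metadata CSV into replicate recordings.

    Tracks are grouped per replicate and sorted by frame; duplicate
    (track, frame) rows and non-numeric coordinates are rejected with an
    error naming the offending row (1-based file line, counting the
    header).
    """
    df = pd.read_csv(
        tracking,
        dtype={"replicate_id": str, "track_id": str},
        float_precision="round_trip",  # exact write->read coordinate identity
    )
    _require_columns(df, TRACKING_COLUMNS, "tracking table")

    for col in ("frame", "x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if df[col].isna().any():
            bad |= df[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(
                f"non-numeric or missing value in column {col!r} at file line "
                f"{row + 2} (value {df[col].iloc[row]!r})"
            )
        df[col] = vals

    dup = df.duplicated(subset=["replicate_id", "track_id", "frame"], keep=False)
    if dup.any():
        first = df.loc[dup].iloc[0]
        raise FormatError(
            "duplicate detection for replicate "
            f"{first['replicate_id']!r}, track {first['track_id']!r}, "
            f"frame {int(first['frame'])}"
        )

    if isinstance(metadata, pd.DataFrame):
        meta = metadata.copy()
    else:
        meta = pd.read_csv(metadata)
    for col in ("replicate_id", "line_id", "regime", "block_id", "camera_id"):
        if col in meta.columns:
            meta[col] = meta[col].astype(str)
    _require_columns(meta, METADATA_COLUMNS, "metadata table")
    if meta["replicate_id"].duplicated().any():
        raise FormatError("metadata table has duplicated replicate_id rows")
    meta = meta.set_index("replicate_id")

    recs: list[ReplicateRecording] = []
    for rep_id, rep_df in df.groupby("replicate_id", sort=True):
        if rep_id not in meta.index:
            raise FormatError(f"replicate {rep_id!r} has no metadata row")
        row = meta.loc[rep_id]
        fps = float(row["fps"]) if "fps" in meta.columns and pd.notna(row.get("fps")) else DEFAULT_FPS
        scale = None
        if "mm_per_px" in meta.columns and pd.notna(row.get("mm_per_px")):
            scale = float(row["mm_per_px"])
        tracks = []
        for tid, t_df in rep_df.groupby("track_id", sort=True):
            t_df = t_df.sort_values("frame")
            tracks.append(
                Track(
                    track_id=str(tid),
                    frames=t_df["frame"].to_numpy(dtype=np.int64),
                    xy=t_df[["x", "y"]].to_numpy(dtype=float),
                )
            )
        recs.append(
            ReplicateRecording(
                replicate_id=str(rep_id),
                line_id=str(row["line_id"]),
                regime=str(row["regime"]),
                block_id=str(row["block_id"]),
                camera_id=str(row["camera_id"]),
                fps=fps,
                mm_per_px=scale,
                tracks=tracks,
            )
        )
    return recs


def tracking_frame(recs: Iterable[ReplicateRecording]) -> pd.DataFrame:
    """Flatten recordings back to the tidy tracking-table layout."""
    parts = []
    for rec in recs:
        for t in rec.tracks:
            parts.append(
                pd.DataFrame(
                    {
                        "replicate_id": rec.replicate_id,
                        "track_id": t.track_id,
                        "frame": t.frames,
                        "x": t.xy[:, 0],
                        "y": t.xy[:, 1],
                    }
                )
            )
    if not parts:
        return pd.DataFrame(columns=list(TRACKING_COLUMNS))
    return pd.concat(parts, ignore_index=True)


def metadata_frame(recs: Iterable[ReplicateRecording]) -> pd.DataFrame:
    """Metadata-table layout for a collection of recordings."""
    return pd.DataFrame(
        [
            {
                "replicate_id": r.replicate_id,
                "line_id": r.line_id,
                "regime": r.regime,
                "block_id": r.block_id,
                "camera_id": r.camera_id,
                "fps": r.fps,
                "mm_per_px": r.mm_per_px,
            }
            for r in recs
        ]
    )


def write_tracking_table(recs: Iterable[ReplicateRecording], tracking_path, metadata_path) -> None:
    recs = list(recs)
    tracking_frame(recs).to_csv(tracking_path, index=False)
    metadata_frame(recs).to_csv(metadata_path, index=False)


@dataclass
class ExclusionLog:
    """Record of replicates dropped by exclusion rules."""

    rules: list[tuple[str, str]]
    removed: list[str]

    @property
    def n_removed(self) -> int:
        return len(self.removed)


def exclude_records(
    recs: Sequence[ReplicateRecording],
    exclusions: Sequence[tuple[str, object]],
) -> tuple[list[ReplicateRecording], ExclusionLog]:
    """Drop every replicate matching any (field, value) rule.

    Values are compared as strings so config-file rules like
    ``(camera_id, 11)`` match regardless of how the id was typed. An empty
    rule list is the identity. Exclusion rules belong in the run config —
    never hard-code an omission.
    """
    norm_rules: list[tuple[str, str]] = []
    for field_name, value in exclusions:
        if field_name not in EXCLUDABLE_FIELDS:
            raise ConfigError(
                f"exclusion rule names unknown field {field_name!r}; "
                f"valid fields: {', '.join(EXCLUDABLE_FIELDS)}"
            )
        norm_rules.append((field_name, str(value)))

    kept, removed = [], []
    for rec in recs:
        if any(str(getattr(rec, f)) == v for f, v in norm_rules):
            removed.append(rec.replicate_id)
        else:
            kept.append(rec)
    return kept, ExclusionLog(rules=norm_rules, removed=removed)
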