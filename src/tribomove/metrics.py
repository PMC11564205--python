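"""Per-replicate activity metrics: path length, sinuosity, edge affinity.

Path length is the total Euclidean distance travelled in pixels per
second. Sinuosity follows Benhamou's estimator for the tortuosity of a
discretized path,

    S = 2 * [ p * ( (1 + c) / (1 - c) + b**2 ) ] ** (-1/2)

where p is the constant step length after rediscretization, c the mean
cosine of the turning angles and b the coefficient of variation of step
lengths (identically 0 on a rediscretized path). S has units of
length^-1/2 in the coordinate unit (here pixel^-1/2); a straight path has
S = 0 and S grows as turning becomes less concentrated.

Rediscretization resamples a polyline into points separated by a constant
chord length p, which removes the dependence of turning-angle statistics
on the video frame rate. The construction is chord-based: starting from
the first detection, each subsequent point is the first intersection,
walking forward along the polyline, of the polyline with the circle of
radius p centred on the previous resampled point.

Edge affinity (thigmotaxis) is the proportion of detections within a
physical margin (default 10 mm) of the arena boundary, the boundary being
the min/max coordinate extremes of the whole replicate recording.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateArenaError, DegeneratePathError, MissingScaleError
from .tracking import ArenaBounds, MovementSummary, ReplicateRecording, Track, arena_bounds

DEFAULT_P_VALUES = (10.0, 20.0)
DEFAULT_EDGE_MARGIN_MM = 10.0


@dataclass(frozen=True)
class RediscretizedPath:
    """A polyline resampled to constant chord length ``p`` (pixels)."""

    points: np.ndarray
    p: float

    @property
    def n(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class TurningStats:
    """Turning-angle statistics of a (rediscretized) path.

    ``angles`` are signed heading changes wrapped to (-pi, pi]; ``c`` is
    their mean cosine; ``b`` the coefficient of variation of step lengths
    (0 for constant-step input).
    """

    angles: np.ndarray
    c: float
    b: float


def path_length(track: Track) -> float:
    """Total Euclidean distance travelled, in pixels."""
    if track.n < 2:
        raise DegeneratePathError(
            f"track {track.track_id!r}: need >= 2 detections for path length"
        )
    steps = np.diff(track.xy, axis=0)
    return float(np.hypot(steps[:, 0], steps[:, 1]).sum())


def path_length_rate(track: Track, fps: float) -> float:
    """Distance travelled per second (pixels/s), first to last detection."""
    if fps <= 0:
        raise ValueError("fps must be > 0")
    dist = path_length(track)
    dur = track.duration_s(fps)
    if dur <= 0:
        raise DegeneratePathError(
            f"track {track.track_id!r}: zero elapsed time between detections"
        )
    return dist / dur


def _as_xy(track) -> np.ndarray:
    if isinstance(track, Track):
        return track.xy
    if isinstance(track, RediscretizedPath):
        return track.points
    return np.asarray(track, dtype=float)


def rediscretize(track, p: float) -> RediscretizedPath:
    """Resample a polyline at constant chord length ``p``.

    Walks forward along the polyline; each new point is the first
    intersection of the polyline with the circle of radius p centred on
    the previous point; stops when no further intersection exists. A path
    from which no step of length p can be taken is degenerate.

    A path that already has constant step length p is returned unchanged
    (up to truncation of a trailing partial step).
    """
    if not p > 0:
        raise ValueError("rediscretization distance p must be > 0")
    xy = _as_xy(track)
    if len(xy) < 2:
        raise DegeneratePathError("need >= 2 points to rediscretize")

    # plain-float inner loop: this runs over millions of segments
    xs = xy[:, 0].tolist()
    ys = xy[:, 1].tolist()
    n = len(xs)
    p2 = p * p
    # reach test tolerates 1e-9 relative (matching the constant-chord
    # contract) so an already-constant-step-p polyline is returned
    # vertex-for-vertex instead of having its corners cut by float noise
    # in large-magnitude coordinates
    p2_reach = p2 * (1.0 - 2e-9)
    cx, cy = xs[0], ys[0]
    ax, ay = cx, cy
    i = 0
    out_x = [cx]
    out_y = [cy]
    while True:
        bx = by = 0.0
        found = False
        while i + 1 < n:
            bx = xs[i + 1]
            by = ys[i + 1]
            ex = bx - cx
            ey = by - cy
            if ex * ex + ey * ey >= p2_reach:
                found = True
                break
            ax, ay = bx, by
            i += 1
        if not found:
            break
        dx = bx - ax
        dy = by - ay
        fx = ax - cx
        fy = ay - cy
        a2 = dx * dx + dy * dy
        fd = fx * dx + fy * dy
        disc = fd * fd - a2 * (fx * fx + fy * fy - p2)
        # a lies inside the circle, b on/outside: exactly one forward root
        t = (-fd + math.sqrt(disc)) / a2
        cx = ax + t * dx
        cy = ay + t * dy
        out_x.append(cx)
        out_y.append(cy)
        ax, ay = cx, cy

    if len(out_x) < 2:
        raise DegeneratePathError(
            f"no rediscretized step possible at p={p} (path too short or folded)"
        )
    return RediscretizedPath(points=np.column_stack([out_x, out_y]), p=p)


def wrap_angle(a):
    """Wrap angles to the interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a, dtype=float), 2.0 * np.pi)


def turning_stats(path) -> TurningStats:
    """Signed turning angles, their mean cosine c and the step-length CV b."""
    xy = _as_xy(path)
    if len(xy) < 3:
        raise DegeneratePathError("need >= 3 points for turning statistics")
    steps = np.diff(xy, axis=0)
    lengths = np.hypot(steps[:, 0], steps[:, 1])
    if np.any(lengths == 0):
        raise DegeneratePathError("zero-length step: heading undefined")
    headings = np.arctan2(steps[:, 1], steps[:, 0])
    angles = wrap_angle(np.diff(headings))
    c = float(np.mean(np.cos(angles)))
    mean_len = float(lengths.mean())
    sd_len = float(lengths.std(ddof=1)) if len(lengths) > 1 else 0.0
    b = sd_len / mean_len
    if np.allclose(lengths, mean_len, rtol=1e-9, atol=0.0):
        b = 0.0  # constant-step path, e.g. after rediscretization
    return TurningStats(angles=angles, c=c, b=b)


def sinuosity(track, p: float) -> float:
    """Benhamou sinuosity of a track at rediscretization distance ``p``.

    Units: (coordinate unit)^-1/2. Returns the limit 0 for an effectively
    straight path (c -> 1). A maximally anti-correlated constant-step path
    (c = -1, b = 0) is degenerate and raises.
    """
    rp = rediscretize(track, p)
    ts = turning_stats(rp)
    return sinuosity_from_stats(p, ts.c, ts.b)


def sinuosity_from_stats(p: float, c: float, b: float = 0.0) -> float:
    """Evaluate S = 2 [p((1+c)/(1-c) + b^2)]^(-1/2) with its limits."""
    if c >= 1.0 - 1e-12:
        return 0.0
    if c <= -1.0 + 1e-12 and b == 0.0:
        raise DegeneratePathError(
            "degenerate path: perfectly anti-correlated constant-step turns (c = -1, b = 0)"
        )
    return 2.0 / math.sqrt(p * ((1.0 + c) / (1.0 - c) + b * b))


def edge_affinity(
    rec: ReplicateRecording,
    margin_mm: float = DEFAULT_EDGE_MARGIN_MM,
    bounds: ArenaBounds | None = None,
) -> float:
    """Proportion of detections within ``margin_mm`` of the arena edge.

    Detections are pooled over tracks. The arena boundary is taken from
    the coordinate extremes of the recording (``bounds`` may be supplied
    to reuse a precomputed extent). Requires the replicate's mm-per-pixel
    scale; there is no default calibration.
    """
    if rec.mm_per_px is None:
        raise MissingScaleError(
            f"replicate {rec.replicate_id!r}: edge affinity needs mm_per_px; "
            "supply the scale in the metadata table"
        )
    if bounds is None:
        bounds = arena_bounds(rec)
    if bounds.degenerate:
        raise DegenerateArenaError(
            f"replicate {rec.replicate_id!r}: arena bounds are degenerate; "
            "edge affinity undefined"
        )
    m = margin_mm / rec.mm_per_px
    xy = rec.all_xy()
    x, y = xy[:, 0], xy[:, 1]
    near = (
        (x <= bounds.xmin + m)
        | (x >= bounds.xmax - m)
        | (y <= bounds.ymin + m)
        | (y >= bounds.ymax - m)
    )
    return float(near.mean())


def summarize_replicate(
    rec: ReplicateRecording,
    p_values=DEFAULT_P_VALUES,
    edge_margin_mm: float = DEFAULT_EDGE_MARGIN_MM,
    min_track_points: int = 2,
) -> MovementSummary:
    """Aggregate tracks to population-level metrics for one replicate.

    Path rate is duration-weighted (total distance / total tracked time),
    so it is a true population-level rate; sinuosity is the unweighted
    mean over tracks with a defined estimate (it is scale-free per track);
    edge affinity pools detections. Undefined components become ``None``
    with the reason logged in ``notes`` — missingness is data, not
    failure.
    """
    notes: list[str] = []
    used: dict[str, int] = {}

    total_dist = 0.0
    total_sec = 0.0
    n_rate = 0
    for t in rec.tracks:
        if t.n < max(2, min_track_points):
            notes.append(f"track {t.track_id}: < {max(2, min_track_points)} points, skipped")
            continue
        dur = t.duration_s(rec.fps)
        if dur <= 0:
            notes.append(f"track {t.track_id}: zero duration, skipped")
            continue
        total_dist += path_length(t)
        total_sec += dur
        n_rate += 1
    rate = total_dist / total_sec if n_rate else None
    if rate is None:
        notes.append("path rate undefined: no usable track")
    used["path_length"] = n_rate

    sinu: dict[float, float | None] = {}
    for p in p_values:
        vals = []
        for t in rec.tracks:
            try:
                vals.append(sinuosity(t, p))
            except DegeneratePathError:
                continue
        used[f"sinuosity_p{p:g}"] = len(vals)
        if vals:
            sinu[p] = float(np.mean(vals))
        else:
            sinu[p] = None
            notes.append(f"sinuosity undefined at p={p:g}: no track long enough")

    try:
        edge = edge_affinity(rec, margin_mm=edge_margin_mm)
    except (MissingScaleError, DegenerateArenaError) as exc:
        edge = None
        notes.append(f"edge affinity undefined: {exc}")

    return MovementSummary(
        replicate_id=rec.replicate_id,
        path_length_px_per_s=rate,
        sinuosity=sinu,
        edge_affinity=edge,
        n_tracks=len(rec.tracks),
        total_tracked_seconds=total_sec,
        n_tracks_used=used,
        notes=notes,
    )


@dataclass(frozen=True)
class GroundTruthAgreement:
    """Pearson agreement between automated and manually annotated distances."""

    r: float
    ci_low: float
    ci_high: float
    n: int


def ground_truth_agreement(auto, manual, confidence: float = 0.95) -> GroundTruthAgreement:
    """Pearson correlation (with Fisher-z CI) between paired distance vectors.

    Used to ground-truth a tracking model against human-annotated clips.
    """
    auto = np.asarray(auto, dtype=float)
    manual = np.asarray(manual, dtype=float)
    if auto.shape != manual.shape or auto.ndim != 1:
        raise ValueError("auto and manual must be paired 1-d vectors")
    n = len(auto)
    if n < 3:
        raise ValueError("need n >= 3 pairs")
    if np.std(auto) == 0 or np.std(manual) == 0:
        raise ValueError("zero variance in one of the vectors; correlation undefined")
    r = float(stats.pearsonr(auto, manual).statistic)
    if abs(r) >= 1.0 - 1e-15:
        return GroundTruthAgreement(r=r, ci_low=r, ci_high=r, n=n)
    if n == 3:  # Fisher z SE is 1/sqrt(n-3): no finite CI at n = 3
        return GroundTruthAgreement(r=r, ci_low=-1.0, ci_high=1.0, n=n)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zcrit = float(stats.norm.ppf(0.5 + confidence / 2.0))
    return GroundTruthAgreement(
        r=r, ci_low=math.tanh(z - zcrit * se), ci_high=math.tanh(z + zcrit * se), n=n
    )
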