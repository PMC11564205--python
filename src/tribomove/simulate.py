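"""Synthetic study generator: every input the pipeline consumes, with
known ground truth.

The generator emulates the four input kinds of the selection-line study:

* **movement**: bounded correlated random walks (CRWs) — von Mises
  heading increments with concentration ``kappa``, Gamma step lengths,
  specular reflection at the square arena walls — recorded as pixel
  tracks at a fixed frame rate. Optionally a wall-following probability
  emulates thigmotaxis (off by default).
* **dispersal assays**: per individual, dispersals ~ Binomial(3, p) with
  a regime-specific p, tallied per line; the expected line mean is 3p.
* **surface assays**: beetles on the fodder surface ~ Binomial(n, p) per
  replicate, including the parent/offspring single-generation selection
  design.
* **morphometrics**: a latent size factor z ~ Normal(regime + sex + line
  shifts, 1); each trait is a linear loading on z plus trait noise and
  measurement error, with femur values missing completely at random and
  a re-measured subset whose first-tarsus error is inflated to emulate
  that trait's low repeatability.

Defaults reproduce the study design: populations of 10 beetles recorded
for 600 s at 25 frames/s; 16 high, 16 low and 12 control lines in two
temporal blocks over 12 cameras; dispersal and surface populations of
200; morphology with 15 beetles per sex for lines 1-10 (high, low) and
1-6 (control). Two named scenarios are shipped: ``paper_like`` (regime
effects mimicking the printed regime means) and ``null`` (all regime
effects zero, for calibration).

Determinism contract: identical seed and parameters give byte-identical
outputs; child seeds are spawned per replicate so subsets reproduce
independently.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .assays import DispersalAssayResult, SurfaceAssayResult
from .tracking import ReplicateRecording, Track

SCENARIOS = ("paper_like", "null")


def as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class CrwParams:
    """Correlated-random-walk and recording parameters for one replicate.

    ``kappa`` >= 0 is the von Mises turning concentration (0 = uniform
    turns); ``step_mm_per_frame`` the mean step; ``step_cv`` the
    step-length coefficient of variation (0 = constant steps);
    ``wall_follow`` the per-frame probability, while inside
    ``wall_margin_mm`` of a wall, of aligning the heading with the
    nearest wall tangent (thigmotaxis; 0 disables).
    """

    kappa: float = 2.5
    step_mm_per_frame: float = 1.0
    step_cv: float = 0.3
    arena_mm: float = 130.0
    fps: float = 25.0
    duration_s: float = 600.0
    n_individuals: int = 10
    mm_per_px: float = 0.2
    wall_follow: float = 0.0
    wall_margin_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.kappa < 0 or self.step_cv < 0:
            raise ValueError("kappa and step_cv must be >= 0")
        for name in ("step_mm_per_frame", "arena_mm", "fps", "duration_s", "mm_per_px"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.arena_mm <= self.step_mm_per_frame:
            raise ValueError("arena smaller than one step")


def _fold(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect coordinates into [lo, hi] (specular wall reflection)."""
    span = hi - lo
    v = np.mod(u - lo, 2.0 * span)
    return lo + np.where(v <= span, v, 2.0 * span - v)


def _step_lengths(params: CrwParams, n: int, rng: np.random.Generator) -> np.ndarray:
    if params.step_cv == 0.0:
        return np.full(n, params.step_mm_per_frame)
    shape = 1.0 / params.step_cv**2
    scale = params.step_mm_per_frame * params.step_cv**2
    return rng.gamma(shape, scale, size=n)


def gen_crw_track(params: CrwParams, rng, track_id: str = "t0") -> Track:
    """One CRW track in pixel coordinates at the recording frame rate."""
    rng = as_rng(rng)
    n_frames = int(round(params.duration_s * params.fps))
    n_steps = n_frames - 1
    if n_steps < 1:
        raise ValueError("duration too short for a single step")
    turns = rng.vonmises(0.0, params.kappa, size=n_steps)
    turns[0] = rng.uniform(-np.pi, np.pi)  # initial heading
    steps = _step_lengths(params, n_steps, rng)
    start = rng.uniform(0.0, params.arena_mm, size=2)

    if params.wall_follow > 0.0:
        xy = _walk_wall_follow(params, start, turns, steps, rng)
    else:
        headings = np.cumsum(turns)
        dx = steps * np.cos(headings)
        dy = steps * np.sin(headings)
        x = _fold(start[0] + np.concatenate([[0.0], np.cumsum(dx)]), 0.0, params.arena_mm)
        y = _fold(start[1] + np.concatenate([[0.0], np.cumsum(dy)]), 0.0, params.arena_mm)
        xy = np.column_stack([x, y])

    return Track(
        track_id=track_id,
        frames=np.arange(n_frames, dtype=np.int64),
        xy=xy / params.mm_per_px,
    )


def _walk_wall_follow(params, start, turns, steps, rng) -> np.ndarray:
    """Stepwise walk with probabilistic wall-tangent alignment near walls."""
    L = params.arena_mm
    m = params.wall_margin_mm
    n = len(turns)
    follow = rng.random(n) < params.wall_follow
    xy = np.empty((n + 1, 2))
    x, y = float(start[0]), float(start[1])
    xy[0] = x, y
    h = 0.0
    for i in range(n):
        h += turns[i]
        near = min(x, L - x, y, L - y) < m
        if near and follow[i]:
            # nearest wall decides tangent axis; keep the closer direction
            if min(x, L - x) <= min(y, L - y):
                h = math.pi / 2 if math.sin(h) >= 0 else -math.pi / 2
            else:
                h = 0.0 if math.cos(h) >= 0 else math.pi
        x += steps[i] * math.cos(h)
        y += steps[i] * math.sin(h)
        if not 0.0 <= x <= L:
            x = L - abs((x % (2 * L)) - L)
        if not 0.0 <= y <= L:
            y = L - abs((y % (2 * L)) - L)
        xy[i + 1] = x, y
    return xy


def gen_crw_replicate(
    params: CrwParams,
    meta: Mapping[str, str],
    rng,
) -> ReplicateRecording:
    """A replicate recording of ``n_individuals`` independent CRWs.

    ``meta`` supplies replicate_id, line_id, regime, block_id, camera_id.
    """
    rng = as_rng(rng)
    tracks = [
        gen_crw_track(params, rng, track_id=f"t{i}")
        for i in range(params.n_individuals)
    ]
    return ReplicateRecording(
        replicate_id=str(meta["replicate_id"]),
        line_id=str(meta["line_id"]),
        regime=str(meta["regime"]),
        block_id=str(meta["block_id"]),
        camera_id=str(meta["camera_id"]),
        fps=params.fps,
        mm_per_px=params.mm_per_px,
        tracks=tracks,
    )


# ---------------------------------------------------------------------------
# regime-level effect configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegimeEffects:
    """Per-regime effect sizes driving every generator.

    The ``paper_like`` defaults mimic the printed regime means of the
    study: dispersal probabilities 3p = mean dispersals (2.44 / 0.70 /
    1.94), path speeds in px/s (129 / 111 / 125), surface proportions
    (counts of 200: 157 / 57.9 / 99.2) and the 0.15 offspring surface
    shift. Line-level jitter magnitudes are set so that simulated
    standard errors resemble the printed ones.
    """

    dispersal_p: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.813, "low": 0.233, "control": 0.647}
    )
    line_dispersal_sd: float = 0.05
    speed_px_s: Mapping[str, float] = field(
        default_factory=lambda: {"high": 129.0, "low": 111.0, "control": 125.0}
    )
    line_speed_sd_px_s: float = 4.0
    camera_speed_sd_px_s: float = 2.0
    block_speed_sd_px_s: float = 2.0
    kappa: Mapping[str, float] = field(
        default_factory=lambda: {"high": 3.0, "low": 2.0, "control": 2.8}
    )
    surface_p: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.785, "low": 0.290, "control": 0.496}
    )
    line_surface_sd: float = 0.07
    surface_offspring_base: float = 0.45
    surface_heritability_shift: float = 0.15
    size_shift: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.52, "low": -0.70, "control": 0.45}
    )
    sex_shift: Mapping[str, float] = field(
        default_factory=lambda: {"F": 0.39, "M": -0.42}
    )
    line_size_sd: float = 0.2
    wall_follow: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.25, "low": 0.30, "control": 0.25}
    )


def paper_like_effects() -> RegimeEffects:
    return RegimeEffects()


def null_effects() -> RegimeEffects:
    """All regime effects equal: the calibration scenario."""
    return RegimeEffects(
        dispersal_p={r: 0.5 for r in ("high", "low", "control")},
        speed_px_s={r: 120.0 for r in ("high", "low", "control")},
        kappa={r: 2.5 for r in ("high", "low", "control")},
        surface_p={r: 0.5 for r in ("high", "low", "control")},
        surface_heritability_shift=0.0,
        size_shift={r: 0.0 for r in ("high", "low", "control")},
        sex_shift={"F": 0.0, "M": 0.0},
        wall_follow={r: 0.0 for r in ("high", "low", "control")},
    )


def scenario_effects(name: str) -> RegimeEffects:
    if name == "paper_like":
        return paper_like_effects()
    if name == "null":
        return null_effects()
    raise ValueError(f"unknown scenario {name!r}; available: {SCENARIOS}")


def study_lines(n_high: int = 16, n_low: int = 16, n_control: int = 12) -> pd.DataFrame:
    """The line design: ids, regimes and the two temporal blocks.

    Block 1 holds high/low lines 1-8 and control lines 1-6; block 2 the
    remainder — the split used in the study.
    """
    rows = []
    for regime, prefix, n in (("high", "H", n_high), ("low", "L", n_low),
                              ("control", "C", n_control)):
        for i in range(1, n + 1):
            block = "1" if i <= (n + 1) // 2 else "2"
            rows.append({"line_id": f"{prefix}{i:02d}", "regime": regime, "block_id": block})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# assay generators
# ---------------------------------------------------------------------------

def _jitter_p(p: float, sd: float, rng) -> float:
    return float(np.clip(p + rng.normal(0.0, sd), 0.005, 0.995)) if sd > 0 else p


def gen_dispersal_assays(
    effects: RegimeEffects,
    rng,
    n: int = 200,
    lines: pd.DataFrame | None = None,
) -> list[DispersalAssayResult]:
    """Binomial(3, p) dispersal tallies per line; expected line mean 3p."""
    rng = as_rng(rng)
    if lines is None:
        lines = study_lines()
    out = []
    for _, row in lines.iterrows():
        p = _jitter_p(effects.dispersal_p[row["regime"]], effects.line_dispersal_sd, rng)
        pmf = np.array([math.comb(3, k) * p**k * (1 - p) ** (3 - k) for k in range(4)])
        counts = rng.multinomial(n, pmf / pmf.sum())
        out.append(
            DispersalAssayResult(
                line_id=row["line_id"], regime=row["regime"], n_individuals=n,
                counts={k: int(c) for k, c in enumerate(counts)},
            )
        )
    return out


def gen_surface_assays(
    effects: RegimeEffects,
    rng,
    n: int = 200,
    lines: pd.DataFrame | None = None,
    reps_per_line: int = 1,
) -> list[SurfaceAssayResult]:
    """Population surface-affinity counts: Binomial(n, p_regime) per replicate."""
    rng = as_rng(rng)
    if lines is None:
        lines = study_lines()
    out = []
    for _, row in lines.iterrows():
        p_line = _jitter_p(effects.surface_p[row["regime"]], effects.line_surface_sd, rng)
        for r in range(reps_per_line):
            out.append(
                SurfaceAssayResult(
                    population_id=f"{row['line_id']}_s{r}",
                    label=row["regime"],
                    block_id=row["block_id"],
                    n_total=n,
                    n_on_surface=int(rng.binomial(n, p_line)),
                )
            )
    return out


def gen_surface_selection(
    effects: RegimeEffects,
    rng,
    n: int = 200,
    reps_per_class: int = 10,
    n_blocks: int = 2,
) -> tuple[list[SurfaceAssayResult], list[SurfaceAssayResult]]:
    """Offspring surface assays for the one-generation selection design.

    Offspring of surface-collected parents have probability
    base + shift/2; offspring of sub-surface parents base - shift/2, so
    the true class difference is ``surface_heritability_shift``.
    """
    rng = as_rng(rng)
    half = effects.surface_heritability_shift / 2.0
    groups = {"surface": effects.surface_offspring_base + half,
              "not_surface": effects.surface_offspring_base - half}
    out = {k: [] for k in groups}
    for label, p in groups.items():
        for r in range(reps_per_class):
            out[label].append(
                SurfaceAssayResult(
                    population_id=f"{label}_o{r}",
                    label=label,
                    block_id=str(r % n_blocks + 1),
                    n_total=n,
                    n_on_surface=int(rng.binomial(n, p)),
                )
            )
    return out["surface"], out["not_surface"]


# ---------------------------------------------------------------------------
# morphology generator
# ---------------------------------------------------------------------------

#: plausible adult trait baselines (mm) and per-trait scale of variation
TRAIT_BASE_MM = {
    "elytron_len": 2.80, "femur_len": 0.95, "femur_width": 0.30,
    "tibia_len": 0.72, "tarsus1_len": 0.25,
}
TRAIT_SCALE_MM = {
    "elytron_len": 0.08, "femur_len": 0.03, "femur_width": 0.012,
    "tibia_len": 0.025, "tarsus1_len": 0.010,
}
#: common loading of each trait on the latent size factor (in units of the
#: per-trait residual SD); high enough that PC1 recovers the factor reliably
SIZE_LOADING = 1.55
#: measurement error as a fraction of between-individual trait SD;
#: tarsus inflated to emulate its low repeatability (~0.73 vs ~0.97)
MEASUREMENT_ERROR_RATIO = {
    "elytron_len": 0.176, "femur_len": 0.176, "femur_width": 0.176,
    "tibia_len": 0.176, "tarsus1_len": 0.608,
}
DEFAULT_MISSING_FEMUR_RATE = 0.577


def morphology_lines() -> pd.DataFrame:
    """The dissected subset: lines 1-10 high, 1-10 low, 1-6 control."""
    lines = study_lines()
    keep = [f"H{i:02d}" for i in range(1, 11)] + [f"L{i:02d}" for i in range(1, 11)] \
        + [f"C{i:02d}" for i in range(1, 7)]
    return lines[lines["line_id"].isin(keep)].reset_index(drop=True)


def gen_morphology(
    effects: RegimeEffects,
    rng,
    n_per_cell: int = 15,
    missing_femur_rate: float = DEFAULT_MISSING_FEMUR_RATE,
    n_repeat: int = 90,
    loading: float = SIZE_LOADING,
    measurement_error_scale: float = 1.0,
) -> pd.DataFrame:
    """Morphometrics table with latent ground truth and a repeat subset.

    One row per measurement session (``repeat_index`` 1, plus 2 for the
    re-measured subset). The ``latent_size`` column carries the
    generator's ground truth for recovery tests. Femur length is set
    missing completely at random at ``missing_femur_rate`` (primary
    measurements only).
    """
    if not 0.0 <= missing_femur_rate <= 1.0:
        raise ValueError("missing_femur_rate must be in [0, 1]")
    rng = as_rng(rng)
    lines = morphology_lines()
    rows = []
    for _, lrow in lines.iterrows():
        line_eff = rng.normal(0.0, effects.line_size_sd)
        for sex in ("F", "M"):
            mu = effects.size_shift[lrow["regime"]] + effects.sex_shift[sex] + line_eff
            z = rng.normal(mu, 1.0, size=n_per_cell)
            for j in range(n_per_cell):
                rows.append({
                    "individual_id": f"{lrow['line_id']}_{sex}{j:02d}",
                    "line_id": lrow["line_id"], "regime": lrow["regime"],
                    "sex": sex, "latent_size": z[j],
                })
    ind = pd.DataFrame(rows)
    n = len(ind)

    true_vals = {}
    for trait, base in TRAIT_BASE_MM.items():
        scale = TRAIT_SCALE_MM[trait]
        true_vals[trait] = base + scale * (
            loading * ind["latent_size"].to_numpy() + rng.normal(0.0, 1.0, size=n)
        )

    def measure(idx: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for trait, vals in true_vals.items():
            sigma_b = TRAIT_SCALE_MM[trait] * math.sqrt(loading**2 + 1.0)
            ratio = MEASUREMENT_ERROR_RATIO[trait] * measurement_error_scale
            err = rng.normal(0.0, ratio * sigma_b, size=len(idx))
            out[trait] = vals[idx] + err
        return out

    all_idx = np.arange(n)
    first = measure(all_idx)
    df1 = ind.copy()
    for trait, vals in first.items():
        df1[trait] = vals
    df1["repeat_index"] = 1
    if missing_femur_rate > 0:
        miss = rng.random(n) < missing_femur_rate
        df1.loc[miss, "femur_len"] = np.nan

    repeat_idx = rng.choice(all_idx, size=min(n_repeat, n), replace=False)
    repeat_idx.sort()
    second = measure(repeat_idx)
    df2 = ind.iloc[repeat_idx].copy()
    for trait, vals in second.items():
        df2[trait] = vals
    df2["repeat_index"] = 2

    return pd.concat([df1, df2], ignore_index=True)


# ---------------------------------------------------------------------------
# movement dataset and whole-study bundle
# ---------------------------------------------------------------------------

def gen_movement_dataset(
    effects: RegimeEffects,
    rng,
    lines: pd.DataFrame | None = None,
    reps_per_line: int = 2,
    crw: CrwParams = CrwParams(),
    n_cameras: int = 12,
) -> list[ReplicateRecording]:
    """Replicate recordings for every line: regime-specific speed and
    turning concentration, line/camera/block speed effects, cameras
    cycling through the camera bank."""
    rng = as_rng(rng)
    if lines is None:
        lines = study_lines()
    camera_eff = {str(c + 1): rng.normal(0.0, effects.camera_speed_sd_px_s)
                  for c in range(n_cameras)}
    block_eff = {b: rng.normal(0.0, effects.block_speed_sd_px_s)
                 for b in sorted(lines["block_id"].unique())}
    recs = []
    cam_counter = 0
    for _, lrow in lines.iterrows():
        regime = lrow["regime"]
        line_speed = effects.speed_px_s[regime] + rng.normal(0.0, effects.line_speed_sd_px_s)
        for r in range(reps_per_line):
            cam = str(cam_counter % n_cameras + 1)
            cam_counter += 1
            speed = max(line_speed + camera_eff[cam] + block_eff[lrow["block_id"]], 10.0)
            params = replace(
                crw,
                kappa=effects.kappa[regime],
                step_mm_per_frame=speed * crw.mm_per_px / crw.fps,
                wall_follow=effects.wall_follow[regime],
            )
            meta = {
                "replicate_id": f"{lrow['line_id']}_r{r}",
                "line_id": lrow["line_id"], "regime": regime,
                "block_id": lrow["block_id"], "camera_id": cam,
            }
            recs.append(gen_crw_replicate(params, meta, rng))
    return recs


@dataclass
class StudyBundle:
    """Everything one simulated study produces, ready for the pipeline."""

    recordings: list[ReplicateRecording]
    dispersal: list[DispersalAssayResult]
    surface_pop: list[SurfaceAssayResult]
    surface_offspring: tuple[list[SurfaceAssayResult], list[SurfaceAssayResult]]
    morphology: pd.DataFrame
    effects: RegimeEffects
    seed: int | None


def simulate_study(
    scenario: str = "paper_like",
    seed: int | None = 0,
    reps_per_line: int = 2,
    crw: CrwParams = CrwParams(),
    n_dispersal: int = 200,
    n_surface: int = 200,
    surface_reps_per_class: int = 10,
    n_per_cell: int = 15,
) -> StudyBundle:
    """Generate a full synthetic study under a named scenario.

    One run seed is spawned into independent child streams per stage, so
    each stage is reproducible on its own.
    """
    effects = scenario_effects(scenario)
    children = np.random.SeedSequence(seed).spawn(5)
    rngs = [np.random.default_rng(c) for c in children]
    return StudyBundle(
        recordings=gen_movement_dataset(effects, rngs[0], reps_per_line=reps_per_line, crw=crw),
        dispersal=gen_dispersal_assays(effects, rngs[1], n=n_dispersal),
        surface_pop=gen_surface_assays(effects, rngs[2], n=n_surface),
        surface_offspring=gen_surface_selection(
            effects, rngs[3], n=n_surface, reps_per_class=surface_reps_per_class
        ),
        morphology=gen_morphology(effects, rngs[4], n_per_cell=n_per_cell),
        effects=effects,
        seed=seed,
    )
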