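"""End-to-end pipeline: simulate/load -> metrics -> scores -> morphometrics
-> model battery -> report, with a reproducibility manifest.

All artefacts are plain-text CSV/YAML/JSON; each stage can be re-run from
its predecessor's CSVs with identical results under the same seed.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from . import __version__
from .assays import dispersal_frame, surface_frame, surface_selection_response
from .exceptions import ConfigError
from .metrics import DEFAULT_EDGE_MARGIN_MM, DEFAULT_P_VALUES, summarize_replicate
from .morphology import PCA_TRAITS, leg_length, repeatability, size_pca
from .regime import BatteryReport, run_table1_battery
from .simulate import CrwParams, simulate_study
from .tracking import (
    ReplicateRecording,
    exclude_records,
    metadata_frame,
    read_tracking_table,
    write_tracking_table,
)

# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA: dict[str, object] = {
    "seed": int,
    "scenario": str,
    "exclusions": list,
    "simulate": {
        "reps_per_line": int,
        "duration_s": (int, float),
        "n_individuals": int,
        "fps": (int, float),
        "arena_mm": (int, float),
        "mm_per_px": (int, float),
        "n_dispersal": int,
        "n_surface": int,
        "surface_reps_per_class": int,
        "n_per_cell": int,
    },
    "metrics": {
        "p_values": list,
        "edge_margin_mm": (int, float),
        "min_track_points": int,
    },
    "models": {"prune_alpha": (int, float)},
}

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "scenario": "paper_like",
    "exclusions": [],
    "simulate": {
        "reps_per_line": 2,
        "duration_s": 600.0,
        "n_individuals": 10,
        "fps": 25.0,
        "arena_mm": 130.0,
        "mm_per_px": 0.2,
        "n_dispersal": 200,
        "n_surface": 200,
        "surface_reps_per_class": 10,
        "n_per_cell": 15,
    },
    "metrics": {
        "p_values": [10.0, 20.0],
        "edge_margin_mm": DEFAULT_EDGE_MARGIN_MM,
        "min_track_points": 2,
    },
    "models": {"prune_alpha": 0.05},
}


def validate_config(config: dict, schema=None, path: str = "") -> None:
    """Reject unknown keys or wrongly typed values before any compute."""
    schema = _CONFIG_SCHEMA if schema is None else schema
    for key, value in config.items():
        where = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(f"unknown config key {where!r}")
        expect = schema[key]
        if isinstance(expect, dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key {where!r} must be a mapping")
            validate_config(value, expect, where)
        elif not isinstance(value, expect) or isinstance(value, bool):
            raise ConfigError(f"config key {where!r} has invalid type {type(value).__name__}")


def load_config(path=None) -> dict:
    """Load a YAML run config, merged over defaults, validated."""
    config = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        validate_config(user)
        for key, value in user.items():
            if isinstance(value, dict):
                config[key].update(value)
            else:
                config[key] = value
    return config


# ---------------------------------------------------------------------------
# stage functions (each reads/writes tidy CSVs)
# ---------------------------------------------------------------------------

def metrics_table(
    recs: Iterable[ReplicateRecording],
    p_values: Sequence[float] = DEFAULT_P_VALUES,
    edge_margin_mm: float = DEFAULT_EDGE_MARGIN_MM,
    min_track_points: int = 2,
) -> tuple[pd.DataFrame, list[str]]:
    """One MovementSummary row per replicate, plus the pooled notes log."""
    rows, notes = [], []
    for rec in recs:
        s = summarize_replicate(
            rec, p_values=p_values, edge_margin_mm=edge_margin_mm,
            min_track_points=min_track_points,
        )
        row = {
            "replicate_id": rec.replicate_id,
            "line_id": rec.line_id,
            "regime": rec.regime,
            "block_id": rec.block_id,
            "camera_id": rec.camera_id,
            "n_tracks": s.n_tracks,
            "total_tracked_seconds": s.total_tracked_seconds,
            "path_length_px_per_s": s.path_length_px_per_s,
            "edge_affinity": s.edge_affinity,
        }
        for p, val in s.sinuosity.items():
            row[f"sinuosity_p{p:g}"] = val
        rows.append(row)
        notes.extend(f"{rec.replicate_id}: {n}" for n in s.notes)
    return pd.DataFrame(rows), notes


def morphology_tables(morph: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Repeatability screen, PCA condensation and leg length in one pass.

    Returns ``repeatability`` (per-trait), ``scores`` (per individual:
    PC1, leg length, labels) and ``pca`` (loadings / variance fractions).
    """
    rep = repeatability(morph)
    primary = morph[morph["repeat_index"] == 1].copy()
    pca_traits = [t for t in PCA_TRAITS if t in rep.retained]
    scores = size_pca(primary, traits=pca_traits)
    primary["pc1"] = scores.pc1  # aligned by index; non-complete rows NaN
    primary["leg_len"] = leg_length(primary)
    pca = pd.DataFrame(
        {
            "component": [f"PC{i+1}" for i in range(len(scores.variance_fractions))],
            "eigenvalue": scores.eigenvalues,
            "variance_fraction": scores.variance_fractions,
        }
    )
    loadings = scores.loadings.rename_axis("trait").reset_index(name="pc1_loading")
    keep = ["individual_id", "line_id", "regime", "sex", "pc1", "leg_len"]
    if "latent_size" in primary.columns:
        keep.append("latent_size")
    return {
        "repeatability": rep.to_frame(),
        "scores": primary[keep],
        "pca": pca,
        "loadings": loadings,
    }


def build_bundle(
    movement: pd.DataFrame | None = None,
    dispersal: pd.DataFrame | None = None,
    surface_pop: pd.DataFrame | None = None,
    surface_genetic: pd.DataFrame | None = None,
    morphology_scores: pd.DataFrame | None = None,
) -> dict[str, pd.DataFrame]:
    """Assemble the battery input bundle from whichever tables exist."""
    bundle: dict[str, pd.DataFrame] = {}
    if movement is not None:
        bundle["movement"] = movement
    if dispersal is not None:
        bundle["dispersal"] = dispersal
    if surface_pop is not None:
        df = surface_pop.rename(columns={"label": "regime"})
        bundle["surface_pop"] = df
    if surface_genetic is not None:
        df = surface_genetic.rename(columns={"label": "parent_class"})
        bundle["surface_genetic"] = df
    if morphology_scores is not None:
        bundle["morphology"] = morphology_scores
    return bundle


def regime_summary(bundle: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Mean and SE per regime of each headline metric (a numeric analogue
    of the study's multi-panel trait figure)."""
    rows = []

    def add(metric, df, value_col, group_col="regime"):
        for level, grp in df.groupby(group_col):
            v = grp[value_col].dropna()
            if len(v) == 0:
                continue
            rows.append(
                {
                    "metric": metric,
                    "group": level,
                    "mean": float(v.mean()),
                    "se": float(v.std(ddof=1) / len(v) ** 0.5) if len(v) > 1 else float("nan"),
                    "n": int(len(v)),
                }
            )

    if "dispersal" in bundle:
        add("mean_dispersals", bundle["dispersal"], "mean_dispersals")
    if "movement" in bundle:
        add("path_length_px_per_s", bundle["movement"], "path_length_px_per_s")
        for col in bundle["movement"].columns:
            if col.startswith("sinuosity_p"):
                add(col, bundle["movement"], col)
        add("edge_affinity", bundle["movement"], "edge_affinity")
    if "surface_pop" in bundle:
        add("surface_proportion", bundle["surface_pop"], "proportion")
    if "surface_genetic" in bundle:
        add("offspring_surface_proportion", bundle["surface_genetic"], "proportion",
            group_col="parent_class")
    if "morphology" in bundle:
        add("pc1", bundle["morphology"], "pc1")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config hash, seed, per-file checksums."""

    config_hash: str
    seed: int | None
    version: str = __version__
    files: dict[str, str] = field(default_factory=dict)
    row_counts: dict[str, int] = field(default_factory=dict)
    exclusions: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)
    complete: bool = True

    def add_file(self, path: Path, rows: int | None = None) -> None:
        self.files[path.name] = _sha256(path)
        if rows is not None:
            self.row_counts[path.name] = rows

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def config_hash(config: dict) -> str:
    canon = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------

def run_pipeline(config: dict, outdir: Path) -> RunManifest:
    """Simulate a study under the configured scenario and analyse it
    end-to-end, writing every table, the battery report and a manifest."""
    validate_config(config)
    merged = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    for key, value in config.items():
        if isinstance(value, dict):
            merged[key].update(value)
        else:
            merged[key] = value
    config = merged

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(config), seed=config["seed"])

    sim = config["simulate"]
    crw = CrwParams(
        duration_s=float(sim["duration_s"]),
        n_individuals=int(sim["n_individuals"]),
        fps=float(sim["fps"]),
        arena_mm=float(sim["arena_mm"]),
        mm_per_px=float(sim["mm_per_px"]),
    )
    bundle_sim = simulate_study(
        scenario=config["scenario"],
        seed=config["seed"],
        reps_per_line=int(sim["reps_per_line"]),
        crw=crw,
        n_dispersal=int(sim["n_dispersal"]),
        n_surface=int(sim["n_surface"]),
        surface_reps_per_class=int(sim["surface_reps_per_class"]),
        n_per_cell=int(sim["n_per_cell"]),
    )

    # ---- write raw inputs (the same schemas the real-data readers accept)
    write_tracking_table(bundle_sim.recordings, outdir / "tracking.csv", outdir / "metadata.csv")
    disp_df = dispersal_frame(bundle_sim.dispersal)
    disp_df.to_csv(outdir / "dispersal.csv", index=False)
    surf_df = surface_frame(bundle_sim.surface_pop)
    surf_df.to_csv(outdir / "surface_population.csv", index=False)
    off_s, off_n = bundle_sim.surface_offspring
    surf_gen_df = surface_frame([*off_s, *off_n])
    surf_gen_df.to_csv(outdir / "surface_genetic.csv", index=False)
    bundle_sim.morphology.to_csv(outdir / "morphology.csv", index=False)

    # ---- exclusions + movement metrics
    recs = bundle_sim.recordings
    rules = [(r["field"], r["value"]) for r in config["exclusions"]]
    recs, excl = exclude_records(recs, rules)
    manifest.exclusions = excl.removed

    mcfg = config["metrics"]
    movement, notes = metrics_table(
        recs,
        p_values=[float(p) for p in mcfg["p_values"]],
        edge_margin_mm=float(mcfg["edge_margin_mm"]),
        min_track_points=int(mcfg["min_track_points"]),
    )
    manifest.notes.extend(notes)
    movement.to_csv(outdir / "movement_metrics.csv", index=False)

    # ---- morphology condensation
    morpho = morphology_tables(bundle_sim.morphology)
    morpho["repeatability"].to_csv(outdir / "repeatability.csv", index=False)
    morpho["pca"].to_csv(outdir / "pca_components.csv", index=False)
    morpho["loadings"].to_csv(outdir / "pca_loadings.csv", index=False)
    morpho["scores"].to_csv(outdir / "morphology_scores.csv", index=False)

    # ---- selection response + battery
    response = surface_selection_response(off_s, off_n)
    bundle = build_bundle(
        movement=movement,
        dispersal=disp_df,
        surface_pop=surf_df,
        surface_genetic=surf_gen_df,
        morphology_scores=morpho["scores"],
    )
    report = run_table1_battery(bundle, prune_alpha=float(config["models"]["prune_alpha"]))
    report.contrasts_frame().to_csv(outdir / "battery_contrasts.csv", index=False)
    (outdir / "battery_report.txt").write_text(
        report.summary()
        + "\n\nSurface selection response: "
        + f"surface {response.mean_surface:.3f} vs not_surface "
        + f"{response.mean_not_surface:.3f}, difference {response.difference:.3f}\n"
    )
    regime_summary(bundle).to_csv(outdir / "regime_summary.csv", index=False)

    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)

    for name in (
        "tracking.csv", "metadata.csv", "dispersal.csv", "surface_population.csv",
        "surface_genetic.csv", "morphology.csv", "movement_metrics.csv",
        "repeatability.csv", "pca_components.csv", "pca_loadings.csv",
        "morphology_scores.csv", "battery_contrasts.csv", "battery_report.txt",
        "regime_summary.csv", "config.yaml",
    ):
        path = outdir / name
        rows = None
        if name.endswith(".csv"):
            rows = sum(1 for _ in open(path)) - 1
        manifest.add_file(path, rows)
    manifest.write(outdir / "manifest.json")
    return manifest


def load_recordings(tracking_csv, metadata_csv, exclusions=()) -> list[ReplicateRecording]:
    """Read tracking + metadata CSVs and apply config exclusion rules."""
    recs = read_tracking_table(tracking_csv, metadata_csv)
    recs, _ = exclude_records(recs, exclusions)
    return recs
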