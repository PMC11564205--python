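"""Scoring of dispersal-propensity and surface-affinity assays.

Dispersal propensity of a line is the mean number of realised dispersals
per individual out of three standardized opportunities (range 0–3),
scored at the population level because density dependence makes
individual events non-independent. Individuals dispersing 3/3 times are
the dispersive phenotype, 0/3 the non-dispersive phenotype; intermediates
are discarded when phenotype classes are needed.

Surface affinity is the number of beetles (out of a population, 200 in
the standard design) remaining on the fodder surface after 2 h. The count
is a stated minimum — individuals obscured by the medium are missed — and
is carried as-is; see :attr:`SurfaceAssayResult.CAVEAT`.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

DISPERSAL_OPPORTUNITIES = 3

PHENOTYPE_DISPERSIVE = "dispersive"
PHENOTYPE_NOT_DISPERSIVE = "not_dispersive"
PHENOTYPE_INTERMEDIATE = "intermediate"


def score_dispersal(counts: Mapping[int, int], n: int) -> float:
    """Mean dispersals per individual from class tallies over {0, 1, 2, 3}.

    ``counts[k]`` is the number of individuals achieving k dispersals;
    tallies must sum to ``n``.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    bad = [k for k in counts if k not in range(DISPERSAL_OPPORTUNITIES + 1)]
    if bad:
        raise ValueError(f"dispersal classes outside 0..3: {bad}")
    total = sum(counts.values())
    if total != n:
        raise ValueError(f"tallies sum to {total}, expected n = {n}")
    return sum(k * v for k, v in counts.items()) / n


def tally_dispersals(events_per_individual: Iterable[int]) -> dict[int, int]:
    """Collapse a per-individual long format into class tallies."""
    counts = {k: 0 for k in range(DISPERSAL_OPPORTUNITIES + 1)}
    for k in events_per_individual:
        if k not in counts:
            raise ValueError(f"dispersal count {k} outside 0..{DISPERSAL_OPPORTUNITIES}")
        counts[k] += 1
    return counts


def classify_phenotype(k: int) -> str:
    """Phenotype class from the number of dispersals out of three."""
    if k not in range(DISPERSAL_OPPORTUNITIES + 1):
        raise ValueError(f"dispersal count {k} outside 0..{DISPERSAL_OPPORTUNITIES}")
    if k == DISPERSAL_OPPORTUNITIES:
        return PHENOTYPE_DISPERSIVE
    if k == 0:
        return PHENOTYPE_NOT_DISPERSIVE
    return PHENOTYPE_INTERMEDIATE


@dataclass(frozen=True)
class DispersalAssayResult:
    """Dispersal tallies for one line: counts over 0–3 dispersals."""

    line_id: str
    regime: str
    n_individuals: int
    counts: Mapping[int, int]

    def __post_init__(self) -> None:
        score_dispersal(self.counts, self.n_individuals)  # validates

    @property
    def mean_dispersals(self) -> float:
        return score_dispersal(self.counts, self.n_individuals)


@dataclass(frozen=True)
class SurfaceAssayResult:
    """Surface count for one population (a line replicate or offspring group).

    ``label`` is the dispersal regime or the parent class
    (surface / not_surface) in the single-generation selection design.
    """

    CAVEAT = (
        "surface counts are minima: individuals obscured by the medium are "
        "not counted; no correction is applied"
    )

    population_id: str
    label: str
    n_total: int
    n_on_surface: int
    block_id: str | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.n_on_surface <= self.n_total:
            raise ValueError(
                f"population {self.population_id!r}: n_on_surface "
                f"{self.n_on_surface} outside 0..{self.n_total}"
            )

    @property
    def proportion(self) -> float:
        return self.n_on_surface / self.n_total


@dataclass(frozen=True)
class SelectionResponse:
    """One-generation response of surface affinity to truncation selection."""

    mean_surface: float
    mean_not_surface: float
    difference: float
    contrast: "object | None"  # ContrastResult from regime.py when fitted


def surface_selection_response(
    offspring_of_surface: Sequence[SurfaceAssayResult],
    offspring_of_not_surface: Sequence[SurfaceAssayResult],
    fit: bool = True,
) -> SelectionResponse:
    """Compare surface affinity of offspring of surface vs sub-surface parents.

    Returns the class mean proportions and their difference; when ``fit``
    is true, also the fixed-effect contrast from the model
    ``proportion ~ parent_class`` with a block random intercept when more
    than one block is present.
    """
    if not offspring_of_surface or not offspring_of_not_surface:
        raise ValueError("need at least one replicate per parent class")
    ps = [r.proportion for r in offspring_of_surface]
    pn = [r.proportion for r in offspring_of_not_surface]
    mean_s, mean_n = float(np.mean(ps)), float(np.mean(pn))

    contrast = None
    if fit:
        from .regime import ModelSpec, RegimeModel

        rows = [
            {
                "proportion": r.proportion,
                "parent_class": r.label,
                "block_id": r.block_id or "1",
            }
            for r in (*offspring_of_surface, *offspring_of_not_surface)
        ]
        df = pd.DataFrame(rows)
        random = ["block_id"] if df["block_id"].nunique() > 1 else []
        spec = ModelSpec(
            response="proportion", fixed=["parent_class"], random=random,
            name="surface selection response",
        )
        res = RegimeModel(spec, df).fit()
        contrast = res.contrast("parent_class", "surface", "not_surface")

    return SelectionResponse(
        mean_surface=mean_s,
        mean_not_surface=mean_n,
        difference=mean_s - mean_n,
        contrast=contrast,
    )


def dispersal_frame(results: Iterable[DispersalAssayResult]) -> pd.DataFrame:
    """Tidy per-line dispersal table (c0..c3 tallies plus the mean score)."""
    rows = []
    for r in results:
        row = {"line_id": r.line_id, "regime": r.regime, "n": r.n_individuals}
        for k in range(DISPERSAL_OPPORTUNITIES + 1):
            row[f"c{k}"] = r.counts.get(k, 0)
        row["mean_dispersals"] = r.mean_dispersals
        rows.append(row)
    return pd.DataFrame(rows)


def surface_frame(results: Iterable[SurfaceAssayResult]) -> pd.DataFrame:
    """Tidy surface-assay table."""
    return pd.DataFrame(
        [
            {
                "population_id": r.population_id,
                "label": r.label,
                "block_id": r.block_id,
                "n_total": r.n_total,
                "n_on_surface": r.n_on_surface,
                "proportion": r.proportion,
            }
            for r in results
        ]
    )
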