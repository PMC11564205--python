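"""Morphometric condensation: repeatability screening, correlation-matrix
PCA for a body-size axis, and the relative-leg-length construct.

The morphometrics table is tidy, one row per measurement session:
``individual_id, line_id, regime, sex, repeat_index`` plus the five trait
columns (mm): ``elytron_len, femur_len, femur_width, tibia_len,
tarsus1_len``. ``repeat_index`` is 1 for the primary measurement and 2
for the re-measurement subset used for repeatability.

Traits whose rank-correlation repeatability falls below the retention
threshold are flagged for exclusion before condensation. The size axis is
the leading component of the trait correlation matrix (PCA on
standardized traits — equivalent to ``prcomp(..., scale.=TRUE)``), with
the sign fixed so that the sum of PC1 loadings is positive, i.e. larger
scores mean larger bodies.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRAITS = ("elytron_len", "femur_len", "femur_width", "tibia_len", "tarsus1_len")
#: traits entering the size PCA after the repeatability screen
PCA_TRAITS = ("elytron_len", "femur_len", "femur_width", "tibia_len")
DEFAULT_RETENTION_THRESHOLD = 0.9


@dataclass(frozen=True)
class TraitRepeatability:
    trait: str
    rho: float
    p_value: float
    n_pairs: int
    retained: bool


@dataclass
class RepeatabilityResult:
    """Per-trait Spearman repeatability and the retained-trait list."""

    per_trait: list[TraitRepeatability]
    threshold: float

    @property
    def retained(self) -> list[str]:
        return [t.trait for t in self.per_trait if t.retained]

    @property
    def dropped(self) -> list[str]:
        return [t.trait for t in self.per_trait if not t.retained]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "trait": t.trait,
                    "rho": t.rho,
                    "p_value": t.p_value,
                    "n_pairs": t.n_pairs,
                    "retained": t.retained,
                }
                for t in self.per_trait
            ]
        )


def repeatability(
    records: pd.DataFrame,
    traits=TRAITS,
    threshold: float = DEFAULT_RETENTION_THRESHOLD,
) -> RepeatabilityResult:
    """Spearman rank correlation between first and repeat measurements.

    Pairs rows by ``individual_id`` across ``repeat_index`` 1 and 2
    (ties handled by midranks, scipy's default). Individuals present in
    the repeat subset without a matching first measurement are an error.
    Traits with rho below ``threshold`` are flagged for exclusion.
    """
    first = records[records["repeat_index"] == 1].set_index("individual_id")
    second = records[records["repeat_index"] == 2].set_index("individual_id")
    if second.empty:
        raise ValueError("no repeat measurements (repeat_index == 2) in table")
    unpaired = sorted(set(second.index) - set(first.index))
    if unpaired:
        raise ValueError(f"repeat measurements without a first measurement: {unpaired}")

    out = []
    for trait in traits:
        a = first.loc[second.index, trait].to_numpy(dtype=float)
        b = second[trait].to_numpy(dtype=float)
        ok = np.isfinite(a) & np.isfinite(b)
        n = int(ok.sum())
        if n < 5:
            raise ValueError(f"trait {trait!r}: only {n} complete pairs (< 5)")
        rho, p = stats.spearmanr(a[ok], b[ok])
        out.append(
            TraitRepeatability(
                trait=trait, rho=float(rho), p_value=float(p), n_pairs=n,
                retained=bool(rho >= threshold - 1e-12),
            )
        )
    return RepeatabilityResult(per_trait=out, threshold=threshold)


def complete_cases(records: pd.DataFrame, traits=PCA_TRAITS) -> pd.DataFrame:
    """Rows with every listed trait measured (PCA cannot handle gaps)."""
    if not len(traits):
        raise ValueError("trait list must be non-empty")
    mask = records[list(traits)].notna().all(axis=1)
    return records.loc[mask].copy()


@dataclass
class SizeScores:
    """Outcome of the size PCA on the trait correlation matrix.

    ``pc1`` holds per-individual scores on the (sign-fixed) leading
    component, indexed like the input rows; ``loadings`` the PC1 weight of
    each trait; ``variance_fractions[i]`` = eigenvalue_i / n_traits.
    """

    pc1: pd.Series
    loadings: pd.Series
    variance_fractions: np.ndarray
    eigenvalues: np.ndarray
    n_complete: int


def size_pca(records: pd.DataFrame, traits=PCA_TRAITS) -> SizeScores:
    """PCA of the trait correlation matrix with a fixed sign convention.

    Rows with any missing listed trait are dropped first. Traits are
    standardized (sample SD), the correlation matrix eigen-decomposed,
    and scores formed as standardized traits times loadings. PC1's sign
    is flipped if needed so its loadings sum positive — scores then
    increase with overall body size regardless of the eigen-solver's
    arbitrary sign.
    """
    traits = list(traits)
    if len(traits) < 2:
        raise ValueError("need >= 2 traits")
    cc = complete_cases(records, traits)
    X = cc[traits].to_numpy(dtype=float)
    n = len(X)
    if n <= len(traits):
        raise ValueError(f"need more complete cases ({n}) than traits ({len(traits)})")
    sd = X.std(axis=0, ddof=1)
    zero = [t for t, s in zip(traits, sd) if s == 0]
    if zero:
        raise ValueError(f"zero-variance trait(s): {zero}")
    Z = (X - X.mean(axis=0)) / sd
    corr = (Z.T @ Z) / (n - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    v1 = eigvec[:, 0]
    if v1.sum() < 0:
        v1 = -v1
    scores = Z @ v1
    return SizeScores(
        pc1=pd.Series(scores, index=cc.index, name="pc1"),
        loadings=pd.Series(v1, index=traits, name="pc1_loading"),
        variance_fractions=eigval / len(traits),
        eigenvalues=eigval,
        n_complete=n,
    )


def leg_length(records: pd.DataFrame) -> pd.Series:
    """Leg length = femur length + tibia length (mm); NaN when either is missing."""
    return (records["femur_len"] + records["tibia_len"]).rename("leg_len")
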