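"""Group-comparison models for selection-regime effects.

A :class:`RegimeModel` is built from a tidy DataFrame and a
:class:`ModelSpec` (response, fixed terms, random intercept factors);
``fit()`` returns a :class:`RegimeResults` carrying coefficient
estimates, standard errors, p-values, variance components and contrast
machinery, statsmodels-style.

Models with only fixed factors are ordinary least squares; models with
random factors are Gaussian linear mixed models fitted by REML with
independent random intercepts per factor (crossed factors are handled as
variance components under a single all-encompassing group). All responses
are modelled on the identity scale, proportions included; p-values for
mixed fits are Wald z based.

``run_table1_battery`` runs the full battery of eight analyses —
dispersal propensity, the three movement metrics, the two surface-affinity
designs, overall body size and relative leg length — applying the
interaction-pruning rule (drop all interaction terms and refit when none
is significant) where interactions are specified.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .tracking import REGIMES

#: pairwise regime contrasts reported throughout, in reporting order
REGIME_PAIRS = (("low", "high"), ("low", "control"), ("high", "control"))

DEFAULT_PRUNE_ALPHA = 0.05
_SINGULAR_TOL = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """Declarative model structure: response ~ fixed, (random intercepts).

    ``fixed`` terms use formula syntax (``"regime"``, ``"regime*sex"``,
    ``"pc1"``); ``random`` lists grouping factors, each contributing an
    independent random intercept. Empty ``random`` means a plain linear
    model.
    """

    response: str
    fixed: tuple[str, ...] | list[str]
    random: tuple[str, ...] | list[str] = ()
    name: str | None = None

    @property
    def formula(self) -> str:
        return f"{self.response} ~ {' + '.join(self.fixed)}"

    @property
    def is_mixed(self) -> bool:
        return len(self.random) > 0

    def describe(self) -> str:
        rand = " + ".join(f"(1 | {g})" for g in self.random)
        return self.formula + (f" + {rand}" if rand else "")


@dataclass(frozen=True)
class ContrastResult:
    """A single fixed-effect contrast: estimate (beta), SE, p-value."""

    term: str
    estimate: float
    se: float
    p_value: float
    reference_level: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.term}: beta = {self.estimate:.4g}, "
            f"SE = {self.se:.3g}, p = {self.p_value:.3g}"
        )


def _term_variables(term: str) -> list[str]:
    import re

    return [v for v in re.split(r"[*:+\s()]+", term) if v and not v.isdigit()]


class RegimeModel:
    """Linear (mixed) model for a regime comparison, built from a DataFrame."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        missing = [
            v
            for v in {spec.response, *sum((_term_variables(t) for t in spec.fixed), []),
                      *spec.random}
            if v not in data.columns
        ]
        if missing:
            raise ValueError(f"model terms not in data: {sorted(missing)}")
        use_cols = sorted(
            {spec.response, *sum((_term_variables(t) for t in spec.fixed), []), *spec.random}
        )
        data = data.dropna(subset=use_cols).copy()
        for g in spec.random:
            if data[g].nunique() < 2:
                raise ValueError(f"random factor {g!r} has < 2 levels")
        self.spec = spec
        self.data = data

    @classmethod
    def from_formula(
        cls, formula: str, data: pd.DataFrame, random: Sequence[str] = (), name: str | None = None
    ) -> "RegimeModel":
        """Build from an ``"y ~ a*b + c"`` style fixed-effects formula."""
        lhs, rhs = (s.strip() for s in formula.split("~", 1))
        fixed = tuple(t.strip() for t in rhs.split("+") if t.strip())
        return cls(ModelSpec(response=lhs, fixed=fixed, random=tuple(random), name=name), data)

    def fit(self, reml: bool = True) -> "RegimeResults":
        """Fit by OLS (no random terms) or REML mixed model (otherwise).

        A singular mixed fit (some variance component estimated at zero)
        is retained, flagged on the results, with the solver's warnings
        recorded.
        """
        caught: list[str] = []
        if not self.spec.is_mixed:
            res = smf.ols(self.spec.formula, data=self.data).fit()
            return RegimeResults(self, res, singular=False, warnings=caught)

        df = self.data.copy()
        df["_group"] = 1
        vc = {g: f"0 + C({g})" for g in self.spec.random}
        with warnings.catch_warnings(record=True) as wlist:
            warnings.simplefilter("always")
            model = smf.mixedlm(
                self.spec.formula, df, groups="_group", vc_formula=vc, re_formula="0"
            )
            res = model.fit(reml=reml)
        caught = [str(w.message) for w in wlist if issubclass(w.category, (ConvergenceWarning, UserWarning))]
        vcomp = dict(zip(model.exog_vc.names, np.asarray(res.vcomp, dtype=float)))
        singular = any(v <= _SINGULAR_TOL * max(res.scale, 1e-300) for v in vcomp.values())
        return RegimeResults(self, res, singular=singular, warnings=caught, vcomp=vcomp)


class RegimeResults:
    """Fitted regime model: coefficient table, contrasts, summary."""

    def __init__(self, model: RegimeModel, smres, singular: bool,
                 warnings: list[str], vcomp: dict[str, float] | None = None):
        self.model = model
        self.spec = model.spec
        self._res = smres
        self.singular = singular
        self.fit_warnings = warnings
        self.vcomp = vcomp or {}

    # -- statsmodels-flavoured accessors (fixed effects only) ------------
    @property
    def exog_names(self) -> list[str]:
        return list(self._res.model.exog_names)

    @property
    def params(self) -> pd.Series:
        if self.spec.is_mixed:
            return self._res.fe_params
        return self._res.params

    @property
    def bse(self) -> pd.Series:
        bse = self._res.bse
        return bse.loc[self.exog_names] if self.spec.is_mixed else bse

    @property
    def pvalues(self) -> pd.Series:
        pv = self._res.pvalues
        return pv.loc[self.exog_names] if self.spec.is_mixed else pv

    @property
    def scale(self) -> float:
        return float(self._res.scale)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    # -- contrasts -------------------------------------------------------
    def _level_column(self, factor: str, level: str) -> str | None:
        for pat in (f"{factor}[T.{level}]", f"C({factor})[T.{level}]"):
            if pat in self.exog_names:
                return pat
        return None

    def contrast(self, factor: str, level_a: str, level_b: str) -> ContrastResult:
        """Estimate ``level_a - level_b`` for ``factor`` with SE and p-value.

        Computed as a linear combination of fitted coefficients (no
        refit); with interactions in the model this is the simple
        contrast at the reference level of the interacting factor(s).
        """
        names = self.exog_names
        L = np.zeros((1, len(names)))
        hit = False
        for level, sign in ((level_a, 1.0), (level_b, -1.0)):
            col = self._level_column(factor, level)
            if col is not None:
                L[0, names.index(col)] = sign
                hit = True
            else:
                levels = set(self.model.data[factor].astype(str))
                if level not in levels:
                    raise ValueError(f"{factor!r} has no level {level!r} in the data")
        if not hit:
            raise ValueError(f"both levels are the reference level of {factor!r}")
        tt = self._res.t_test(L)
        return ContrastResult(
            term=f"{factor}: {level_a} - {level_b}",
            estimate=float(np.ravel(tt.effect)[0]),
            se=float(np.ravel(tt.sd)[0]),
            p_value=float(np.ravel(tt.pvalue)[0]),
            reference_level=level_b,
        )

    def pairwise_contrasts(self, factor: str = "regime",
                           pairs: Sequence[tuple[str, str]] | None = None) -> list[ContrastResult]:
        """All pairwise contrasts of ``factor`` (regime: low-high, low-control, high-control)."""
        if pairs is None:
            levels = list(dict.fromkeys(self.model.data[factor].astype(str)))
            if set(levels) == set(REGIMES):
                pairs = REGIME_PAIRS
            else:
                pairs = [(a, b) for i, a in enumerate(levels) for b in levels[i + 1:]]
        return [self.contrast(factor, a, b) for a, b in pairs]

    # -- interaction machinery ------------------------------------------
    def interaction_terms(self) -> list[str]:
        di = self._res.model.data.design_info
        return [t for t in di.term_name_slices if ":" in t]

    def term_pvalue(self, term_name: str) -> float:
        """Joint Wald p-value for all columns of a design term."""
        di = self._res.model.data.design_info
        sl = di.term_name_slices[term_name]
        width = len(self._res.params)
        M = np.zeros((sl.stop - sl.start, width))
        for i, j in enumerate(range(sl.start, sl.stop)):
            M[i, j] = 1.0
        if self.spec.is_mixed:
            wt = self._res.wald_test(M, scalar=True)
        else:
            wt = self._res.f_test(M)
        return float(wt.pvalue)

    def summary(self) -> str:
        """Human-readable fit summary (coefficients, contrasts, components)."""
        lines = []
        title = self.spec.name or self.spec.response
        lines.append(f"Model: {title}")
        lines.append(f"  formula: {self.spec.describe()}")
        kind = "LMM (REML)" if self.spec.is_mixed else "OLS"
        lines.append(f"  fit: {kind}, n = {self.nobs}"
                     + (", SINGULAR (a variance component is ~0)" if self.singular else ""))
        lines.append("  coefficients:")
        for name in self.exog_names:
            lines.append(
                f"    {name:<32s} beta = {self.params[name]: .4g}  "
                f"SE = {self.bse[name]:.3g}  p = {self.pvalues[name]:.3g}"
            )
        if self.vcomp:
            lines.append("  variance components:")
            for k, v in self.vcomp.items():
                lines.append(f"    {k:<32s} var = {v:.4g}")
            lines.append(f"    {'residual':<32s} var = {self.scale:.4g}")
        return "\n".join(lines)


def fit_model(spec: ModelSpec, data: pd.DataFrame, reml: bool = True) -> RegimeResults:
    """Convenience wrapper: build and fit in one call."""
    return RegimeModel(spec, data).fit(reml=reml)


def prune_interactions(
    model: RegimeModel, alpha: float = DEFAULT_PRUNE_ALPHA, reml: bool = True
) -> tuple[RegimeResults, bool, dict[str, float]]:
    """Apply the interaction-pruning rule.

    Fits the full model; if *every* interaction term has a joint Wald
    p-value >= ``alpha``, all interaction terms are dropped and the model
    refitted so main effects are tested independently. Returns the final
    results, whether pruning happened, and the interaction p-values from
    the full fit. ``alpha = 1.0`` always prunes (boundary behaviour).
    """
    full = model.fit(reml=reml)
    inter = full.interaction_terms()
    if not inter:
        raise ValueError("model spec contains no interaction term")
    pvals = {t: full.term_pvalue(t) for t in inter}
    # alpha >= 1 prunes unconditionally (nothing is significant at level 1)
    if alpha < 1.0 and any(p < alpha for p in pvals.values()):
        return full, False, pvals
    di = full._res.model.data.design_info
    kept = [t for t in di.term_name_slices if ":" not in t and t != "Intercept"]
    pruned_spec = replace(model.spec, fixed=tuple(kept))
    res = RegimeModel(pruned_spec, model.data).fit(reml=reml)
    return res, True, pvals


# ---------------------------------------------------------------------------
# The battery of eight regime analyses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BatteryRowSpec:
    name: str
    bundle_key: str
    response: str
    fixed: tuple[str, ...]
    random: tuple[str, ...]
    contrast_factor: str = "regime"
    prune: bool = False


TABLE1_ROWS: tuple[BatteryRowSpec, ...] = (
    BatteryRowSpec("dispersal", "dispersal", "mean_dispersals", ("regime",), ()),
    BatteryRowSpec("path_length", "movement", "path_length_px_per_s", ("regime",),
                   ("block_id", "line_id", "camera_id")),
    BatteryRowSpec("sinuosity", "movement", "sinuosity_p10", ("regime",),
                   ("line_id", "camera_id")),
    BatteryRowSpec("edge_affinity", "movement", "edge_affinity", ("regime",),
                   ("line_id", "camera_id")),
    BatteryRowSpec("surface_population", "surface_pop", "n_on_surface", ("regime",),
                   ("block_id",)),
    BatteryRowSpec("surface_genetic", "surface_genetic", "proportion", ("parent_class",),
                   ("block_id",), contrast_factor="parent_class"),
    BatteryRowSpec("body_size", "morphology", "pc1", ("regime*sex",), ("line_id",),
                   prune=True),
    BatteryRowSpec("leg_length", "morphology", "leg_len", ("regime*sex", "pc1"),
                   ("line_id",), prune=True),
)


@dataclass
class BatteryRow:
    """Outcome of one battery analysis (or the reason it was skipped)."""

    name: str
    formula: str | None = None
    results: RegimeResults | None = None
    contrasts: list[ContrastResult] = field(default_factory=list)
    pruned: bool | None = None
    interaction_pvalues: dict[str, float] = field(default_factory=dict)
    skipped_reason: str | None = None

    @property
    def skipped(self) -> bool:
        return self.skipped_reason is not None


@dataclass
class BatteryReport:
    rows: list[BatteryRow]

    def row(self, name: str) -> BatteryRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)

    def contrasts_frame(self) -> pd.DataFrame:
        """All contrasts of all fitted rows as one tidy table."""
        out = []
        for r in self.rows:
            for c in r.contrasts:
                out.append(
                    {
                        "analysis": r.name,
                        "contrast": c.term,
                        "estimate": c.estimate,
                        "se": c.se,
                        "p_value": c.p_value,
                        "singular": r.results.singular if r.results else None,
                    }
                )
        return pd.DataFrame(out)

    def summary(self) -> str:
        blocks = []
        for r in self.rows:
            if r.skipped:
                blocks.append(f"Model: {r.name}\n  SKIPPED: {r.skipped_reason}")
                continue
            lines = [r.results.summary()]
            if r.pruned is not None:
                state = "pruned (all p >= alpha)" if r.pruned else "retained"
                lines.append(f"  interactions {state}: "
                             + ", ".join(f"{k} p={v:.3g}" for k, v in r.interaction_pvalues.items()))
            lines.append("  pairwise contrasts:")
            for c in r.contrasts:
                lines.append(f"    {c}")
            blocks.append("\n".join(lines))
        return "\n\n".join(blocks)


def run_table1_battery(
    bundle: Mapping[str, pd.DataFrame],
    prune_alpha: float = DEFAULT_PRUNE_ALPHA,
) -> BatteryReport:
    """Run all eight regime analyses on a dataset bundle.

    ``bundle`` maps table names to tidy DataFrames: ``dispersal`` (per
    line), ``movement`` (per replicate), ``surface_pop`` and
    ``surface_genetic`` (per assay replicate), ``morphology`` (per
    individual, with ``pc1`` and ``leg_len`` already attached). Missing
    tables skip their rows with a logged reason rather than failing the
    battery.
    """
    rows: list[BatteryRow] = []
    for rs in TABLE1_ROWS:
        if rs.bundle_key not in bundle:
            rows.append(BatteryRow(name=rs.name,
                                   skipped_reason=f"input table {rs.bundle_key!r} missing"))
            continue
        data = bundle[rs.bundle_key]
        spec = ModelSpec(response=rs.response, fixed=rs.fixed, random=rs.random, name=rs.name)
        try:
            model = RegimeModel(spec, data)
            if rs.prune:
                res, pruned, ipv = prune_interactions(model, alpha=prune_alpha)
            else:
                res, pruned, ipv = model.fit(), None, {}
            contrasts = res.pairwise_contrasts(rs.contrast_factor)
        except (ValueError, KeyError) as exc:
            rows.append(BatteryRow(name=rs.name, skipped_reason=str(exc)))
            continue
        rows.append(
            BatteryRow(
                name=rs.name,
                formula=res.spec.describe(),
                results=res,
                contrasts=contrasts,
                pruned=pruned,
                interaction_pvalues=ipv,
            )
        )
    return BatteryReport(rows=rows)
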