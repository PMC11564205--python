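"""Regime-comparison models: OLS/LMM fitting, contrasts, pruning, battery."""
import numpy as np
import pandas as pd
import pytest

from tribomove.regime import (
    ModelSpec,
    RegimeModel,
    fit_model,
    prune_interactions,
    run_table1_battery,
)


def balanced_groups(means, n_per=10, jitter=None, rng=None, factor="regime"):
    rows = []
    for level, mu in means.items():
        for i in range(n_per):
            eps = rng.normal(0, jitter) if jitter else (0.1 if i % 2 else -0.1)
            rows.append({factor: level, "y": mu + eps, "line_id": f"{level}{i % 4}"})
    return pd.DataFrame(rows)


class TestFitModel:
    def test_balanced_ols_equals_group_mean_difference(self):
        df = balanced_groups({"low": 1.0, "high": 3.0, "control": 2.0})
        res = fit_model(ModelSpec("y", ("regime",)), df)
        gm = df.groupby("regime")["y"].mean()
        c = res.contrast("regime", "low", "high")
        assert c.estimate == pytest.approx(gm["low"] - gm["high"], abs=1e-12)

    def test_zero_variance_random_term_matches_ols(self, rng):
        df = balanced_groups({"low": 0.0, "high": 1.0}, n_per=12, jitter=1.0, rng=rng)
        df["camera_id"] = [f"c{i % 3}" for i in range(len(df))]
        # response has no camera structure: vcomp ~ 0, coefficients ~ OLS
        ols = fit_model(ModelSpec("y", ("regime",)), df)
        mixed = fit_model(ModelSpec("y", ("regime",), ("camera_id",)), df)
        assert mixed.params["regime[T.low]"] == pytest.approx(
            ols.params["regime[T.low]"], abs=1e-4
        )

    def test_singular_fit_flagged_not_fatal(self, rng):
        df = balanced_groups({"low": 0.0, "high": 0.0}, n_per=10, jitter=1.0, rng=rng)
        df["camera_id"] = "c1"
        df.loc[df.index[:10], "camera_id"] = "c2"
        res = fit_model(ModelSpec("y", ("regime",), ("camera_id",)), df)
        assert res.singular in (True, False)  # fit retained either way
        assert np.isfinite(res.params).all()

    def test_mixed_simulation_recovery(self):
        rng = np.random.default_rng(42)
        rows = []
        for regime, mu in (("high", 1.0), ("low", 0.0)):
            for l in range(16):
                line_eff = rng.normal(0, 0.5)
                for _ in range(3):
                    rows.append({"regime": regime, "line_id": f"{regime}{l}",
                                 "y": mu + line_eff + rng.normal(0, 1.0)})
        df = pd.DataFrame(rows)
        res = fit_model(ModelSpec("y", ("regime",), ("line_id",)), df)
        c = res.contrast("regime", "high", "low")
        assert abs(c.estimate - 1.0) < 3 * c.se

    def test_missing_term_rejected(self):
        df = balanced_groups({"low": 0.0, "high": 1.0})
        with pytest.raises(ValueError, match="not in data"):
            RegimeModel(ModelSpec("y", ("regime", "sex")), df)

    def test_few_level_random_factor_rejected(self):
        df = balanced_groups({"low": 0.0, "high": 1.0})
        df["block_id"] = "1"
        with pytest.raises(ValueError, match="< 2 levels"):
            RegimeModel(ModelSpec("y", ("regime",), ("block_id",)), df)


class TestContrasts:
    def test_three_group_worked_example(self):
        # groups at the regime means reported for dispersal propensity
        df = balanced_groups({"low": 0.70, "high": 2.44, "control": 1.94}, n_per=16)
        res = fit_model(ModelSpec("y", ("regime",)), df)
        cs = {c.term: c.estimate for c in res.pairwise_contrasts()}
        assert cs["regime: low - high"] == pytest.approx(-1.74, abs=1e-12)
        assert cs["regime: low - control"] == pytest.approx(-1.24, abs=1e-12)
        assert cs["regime: high - control"] == pytest.approx(0.50, abs=1e-12)

    def test_identical_groups_zero_contrasts(self):
        df = balanced_groups({"low": 1.0, "high": 1.0, "control": 1.0})
        res = fit_model(ModelSpec("y", ("regime",)), df)
        for c in res.pairwise_contrasts():
            assert c.estimate == pytest.approx(0.0, abs=1e-12)

    def test_contrast_linearity(self, rng):
        df = balanced_groups({"low": 0.3, "high": 2.1, "control": 1.1},
                             n_per=8, jitter=0.5, rng=rng)
        res = fit_model(ModelSpec("y", ("regime",)), df)
        cs = {c.term: c.estimate for c in res.pairwise_contrasts()}
        assert cs["regime: low - high"] == pytest.approx(
            cs["regime: low - control"] - cs["regime: high - control"], abs=1e-10
        )

    def test_reference_level_invariance(self, rng):
        df = balanced_groups({"low": 0.3, "high": 2.1, "control": 1.1},
                             n_per=8, jitter=0.5, rng=rng)
        res = fit_model(ModelSpec("y", ("regime",)), df)
        c_ab = res.contrast("regime", "low", "high")
        c_ba = res.contrast("regime", "high", "low")
        assert c_ab.estimate == pytest.approx(-c_ba.estimate, abs=1e-12)
        assert c_ab.se == pytest.approx(c_ba.se, abs=1e-12)

    def test_unknown_level_rejected(self):
        df = balanced_groups({"low": 0.0, "high": 1.0})
        res = fit_model(ModelSpec("y", ("regime",)), df)
        with pytest.raises(ValueError, match="no level"):
            res.contrast("regime", "low", "medium")


class TestPruning:
    @staticmethod
    def _sim(rng, interaction=0.0, n_per=30):
        rows = []
        for regime in ("high", "low"):
            for sex in ("F", "M"):
                mu = (regime == "high") * 1.0 + (sex == "M") * 0.5
                if regime == "high" and sex == "M":
                    mu += interaction
                for _ in range(n_per):
                    rows.append({"regime": regime, "sex": sex,
                                 "y": mu + rng.normal(0, 1.0)})
        return pd.DataFrame(rows)

    def test_zero_interaction_pruned(self, rng):
        model = RegimeModel(ModelSpec("y", ("regime*sex",)), self._sim(rng, 0.0))
        res, pruned, pvals = prune_interactions(model)
        assert pruned
        assert "regime:sex" in pvals
        assert all(":" not in t for t in res.spec.fixed)

    def test_strong_interaction_retained(self, rng):
        model = RegimeModel(ModelSpec("y", ("regime*sex",)), self._sim(rng, 2.0))
        res, pruned, pvals = prune_interactions(model)
        assert not pruned
        assert pvals["regime:sex"] < 0.05

    def test_alpha_one_always_prunes(self, rng):
        model = RegimeModel(ModelSpec("y", ("regime*sex",)), self._sim(rng, 2.0))
        _, pruned, _ = prune_interactions(model, alpha=1.0)
        assert pruned

    def test_no_interaction_spec_rejected(self, rng):
        model = RegimeModel(ModelSpec("y", ("regime",)), self._sim(rng))
        with pytest.raises(ValueError, match="no interaction"):
            prune_interactions(model)


@pytest.fixture(scope="module")
def bundle():
    from tribomove.assays import dispersal_frame, surface_frame
    from tribomove.pipeline import build_bundle, metrics_table, morphology_tables
    from tribomove.simulate import CrwParams, simulate_study

    sim = simulate_study(seed=11, reps_per_line=1,
                         crw=CrwParams(duration_s=10.0, n_individuals=3),
                         surface_reps_per_class=6, n_per_cell=8)
    movement, _ = metrics_table(sim.recordings, p_values=(10.0,))
    morpho = morphology_tables(sim.morphology)
    off_s, off_n = sim.surface_offspring
    return build_bundle(
        movement=movement,
        dispersal=dispersal_frame(sim.dispersal),
        surface_pop=surface_frame(sim.surface_pop),
        surface_genetic=surface_frame([*off_s, *off_n]),
        morphology_scores=morpho["scores"],
    )


class TestBattery:
    def test_full_bundle_produces_all_eight_rows(self, bundle):
        report = run_table1_battery(bundle)
        assert len(report.rows) == 8
        assert all(not r.skipped for r in report.rows)
        frame = report.contrasts_frame()
        assert set(frame.analysis) == {r.name for r in report.rows}
        # each regime analysis carries the three pairwise contrasts
        assert (frame.analysis == "dispersal").sum() == 3
        assert (frame.analysis == "surface_genetic").sum() == 1

    def test_missing_morphology_skips_two_rows(self, bundle):
        partial = {k: v for k, v in bundle.items() if k != "morphology"}
        report = run_table1_battery(partial)
        skipped = [r.name for r in report.rows if r.skipped]
        assert skipped == ["body_size", "leg_length"]
        assert sum(not r.skipped for r in report.rows) == 6

    def test_summary_mentions_every_analysis(self, bundle):
        report = run_table1_battery(bundle)
        text = report.summary()
        for name in ("dispersal", "path_length", "sinuosity", "edge_affinity",
                     "surface_population", "surface_genetic", "body_size", "leg_length"):
            assert name in text
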