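"""Design construction, OLS marginal effects, and significance flags."""

import dataclasses

import numpy as np
import pytest

from hhrineq import schema
from hhrineq.exceptions import (
    ConfigurationError,
    EstimationError,
    SchemaError,
    ValidationError,
)
from hhrineq.regression import (
    CategoricalSpec,
    ModelSpec,
    build_design,
    fit_ols,
    significance_stars,
)
from hhrineq.synthetic import SyntheticConfig, default_study_config, generate_cities


class TestModelSpec:
    def test_outcome_cannot_be_covariate(self):
        with pytest.raises(ConfigurationError):
            ModelSpec(outcome="pergdp", continuous=("pergdp",))

    def test_reference_must_be_a_level(self):
        with pytest.raises(ConfigurationError):
            CategoricalSpec("region", schema.REGIONS, reference="Atlantis")

    def test_default_spec_design_columns_are_deterministic(self):
        spec = ModelSpec.default("doctors_per_10k")
        cols = spec.design_columns()
        assert cols == ModelSpec.default("doctors_per_10k").design_columns()
        assert cols[: len(schema.CONTINUOUS_COLUMNS)] == schema.CONTINUOUS_COLUMNS
        # 7 continuous + (7-1) region + 2x(2+2+1+1+3) official indicators
        assert len(cols) == 7 + 6 + 2 * 9


class TestBuildDesign:
    def test_region_expands_to_six_indicators(self, small_table):
        spec = ModelSpec(
            outcome="doctors_per_10k",
            categoricals=(CategoricalSpec("region", schema.REGIONS, "East China"),),
        )
        design = build_design(small_table, spec)
        assert design.matrix.shape[1] == 6
        assert "region=East China" not in design.matrix.columns

    def test_two_level_indicator(self, small_table):
        spec = ModelSpec(
            outcome="doctors_per_10k",
            categoricals=(CategoricalSpec("mayor_sex", schema.SEX_LEVELS, "Men"),),
        )
        X = build_design(small_table, spec).matrix
        women = (small_table["mayor_sex"] == "Women").to_numpy(dtype=float)
        np.testing.assert_array_equal(X["mayor_sex=Women"].to_numpy(), women)

    def test_single_region_table_drops_degenerate_indicators(self, small_table):
        table = small_table.copy()
        table["region"] = "East China"
        spec = ModelSpec(
            outcome="doctors_per_10k",
            continuous=("pergdp",),
            categoricals=(CategoricalSpec("region", schema.REGIONS, "East China"),),
        )
        with pytest.warns(UserWarning, match="degenerate"):
            design = build_design(table, spec)
        assert len(design.dropped) == 6
        assert list(design.matrix.columns) == ["pergdp"]

    def test_unknown_level_names_column_and_value(self, small_table):
        table = small_table.copy()
        table.loc[table.index[3], "region"] = "Middle Earth"
        spec = ModelSpec.default("doctors_per_10k")
        with pytest.raises(ValidationError, match="region.*Middle Earth"):
            build_design(table, spec)

    def test_missing_column_is_schema_error(self, small_table):
        spec = ModelSpec.default("doctors_per_10k")
        with pytest.raises(SchemaError, match="urbanization"):
            build_design(small_table.drop(columns=["urbanization"]), spec)


class TestFitOLS:
    def test_noiseless_coefficients_recovered_exactly(self):
        coefs = {
            "pergdp": 2.0e-4,
            "urbanization": -0.08,
            schema.indicator_name("region", "Southwest China"): -5.0,
            schema.indicator_name("mayor_sex", "Women"): 1.5,
        }
        cfg = SyntheticConfig(
            n_cities=400, seed=3, intercept=12.0, coefficients=coefs, noise_sd=0.0
        )
        table = generate_cities(cfg)
        spec = ModelSpec(
            outcome="doctors_per_10k",
            continuous=("pergdp", "urbanization"),
            categoricals=(
                CategoricalSpec("region", schema.REGIONS, "East China"),
                CategoricalSpec("mayor_sex", schema.SEX_LEVELS, "Men"),
            ),
        )
        res = fit_ols(table, spec)
        assert res.intercept == pytest.approx(12.0, abs=1e-8)
        for term, beta in coefs.items():
            assert res.effects[term] == pytest.approx(beta, abs=1e-8), term
        for term in res.terms:
            if term not in coefs:
                assert res.effects[term] == pytest.approx(0.0, abs=1e-8)

    def test_residuals_and_fit_identities(self, study_table):
        spec = ModelSpec.default("nurses_per_10k")
        res = fit_ols(study_table, spec)
        y = study_table["nurses_per_10k"].to_numpy()
        assert abs(res.residuals.sum()) < 1e-8 * len(y) * np.abs(y).mean()
        np.testing.assert_allclose(res.fitted + res.residuals, y, rtol=1e-10)

    def test_outcome_shift_moves_only_the_intercept(self, study_table):
        spec = ModelSpec.default("doctors_per_10k")
        base = fit_ols(study_table, spec)
        shifted_table = study_table.copy()
        shifted_table["doctors_per_10k"] = shifted_table["doctors_per_10k"] + 100.0
        shifted = fit_ols(shifted_table, spec)
        assert shifted.intercept - base.intercept == pytest.approx(100.0, abs=1e-8)
        for t in base.terms:
            assert shifted.effects[t] == pytest.approx(base.effects[t], abs=1e-10)

    def test_refitting_is_stateless(self, study_table):
        full = ModelSpec.default("doctors_per_10k")
        reduced = dataclasses.replace(full, continuous=full.continuous[:-1])
        first = fit_ols(study_table, full)
        fit_ols(study_table, reduced)  # interleaved fit must not perturb anything
        second = fit_ols(study_table, full)
        assert first.effects == second.effects
        assert first.std_errors == second.std_errors

    def test_collinear_design_is_reported(self, small_table):
        table = small_table.copy()
        table["population_size"] = 2.0 * table["population_density"]
        spec = ModelSpec(
            outcome="doctors_per_10k",
            continuous=("population_density", "population_size"),
        )
        with pytest.raises(EstimationError, match="population_size"):
            fit_ols(table, spec)

    def test_robust_and_classical_se_agree_under_homoskedasticity(self):
        cfg = SyntheticConfig(
            n_cities=2000,
            seed=8,
            intercept=20.0,
            coefficients={"pergdp": 1e-4, "urbanization": -0.05},
            noise_sd=4.0,
        )
        table = generate_cities(cfg)
        spec = ModelSpec(
            outcome="doctors_per_10k", continuous=("pergdp", "urbanization")
        )
        robust = fit_ols(table, spec, cov_type="HC1")
        classical = fit_ols(table, spec, cov_type="nonrobust")
        for t in robust.terms:
            assert robust.std_errors[t] == pytest.approx(
                classical.std_errors[t], rel=0.15
            )

    def test_null_model_star_rate_is_nominal(self):
        """With an outcome independent of every covariate, ~5% of terms
        should flag at the 0.05 level (pooled over seeded replicates)."""
        flagged = 0
        total = 0
        spec = ModelSpec.default("doctors_per_10k")
        base = dataclasses.replace(
            default_study_config(seed=0),
            n_cities=400,
            coefficients={},
            noise_sd=5.0,
            intercept=20.0,
        )
        for rep in range(40):
            table = generate_cities(dataclasses.replace(base, seed=1000 + rep))
            res = fit_ols(table, spec)
            total += len(res.terms)
            flagged += sum(1 for t in res.terms if res.pvalues[t] < 0.05)
        assert 0.02 < flagged / total < 0.09

    def test_summary_layout(self, study_table):
        res = fit_ols(study_table, ModelSpec.default("doctors_per_10k"))
        text = res.summary()
        assert "dy/dx" in text and "Std. Err." in text
        assert "Ref" in text  # reference levels are shown
        assert "East China" in text


@pytest.mark.parametrize(
    "p,expected",
    [
        (0.04, "*"),
        (0.05, "ns"),  # strict inequality at the boundary
        (0.01, "*"),
        (0.009, "**"),
        (0.001, "**"),
        (0.0005, "***"),
        (0.5, "ns"),
    ],
)
def test_significance_stars(p, expected):
    assert significance_stars(p) == expected


def test_significance_stars_rejects_bad_p():
    with pytest.raises(ValidationError):
        significance_stars(1.2)
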