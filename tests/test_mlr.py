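import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from tbarskinetics import (
    DataError,
    build_design_matrix,
    fit_mlr,
    generate_study,
    published_study_spec,
    rank_extracts,
)
from tbarskinetics.mlr import CollinearityError, DesignMatrix, DummyVariableMLR

from conftest import make_design


class TestBuildDesignMatrix:
    def test_fourteen_groups_give_thirteen_dummies(self, study_seed7):
        design = build_design_matrix(study_seed7, "Control")
        assert len(design.dummy_names) == 13
        assert design.dummy_names == sorted(design.dummy_names)
        assert "Control" not in design.dummy_names

    def test_control_only_dataset_has_no_dummies(self, study_seed7):
        controls = [s for s in study_seed7 if s.sample_label == "Control"]
        design = build_design_matrix(controls, "Control")
        assert design.dummy_names == []
        assert list(design.columns.columns) == ["intercept", "time", "temperature"]

    def test_reference_rows_have_all_zero_dummies(self, study_seed7):
        design = build_design_matrix(study_seed7, "Control")
        X = design.columns
        control_rows = X[X[design.dummy_names].sum(axis=1) == 0]
        assert len(control_rows) > 0
        # every row carries at most one active indicator
        assert (X[design.dummy_names].sum(axis=1) <= 1).all()

    def test_temperature_column_in_celsius(self, study_seed7):
        design = build_design_matrix(study_seed7, "Control")
        temps = sorted(design.columns["temperature"].unique())
        assert temps == pytest.approx([4, 8, 12, 16, 20])

    def test_absent_reference_rejected(self, study_seed7):
        with pytest.raises(DataError):
            build_design_matrix(study_seed7, "Vanilla")


class TestFitMLR:
    def test_noiseless_recovery_to_1e8(self):
        design = make_design(seed=1, n_groups=3, sigma=0.0)
        result = fit_mlr(design)
        assert result.coefficients["intercept"] == pytest.approx(4.4, abs=1e-8)
        assert result.coefficients["time"] == pytest.approx(0.126, abs=1e-8)
        assert result.coefficients["temperature"] == pytest.approx(0.044, abs=1e-8)
        for d in result.dummy_names:
            assert result.coefficients[d] == pytest.approx(0.0, abs=1e-8)

    def test_known_group_offset_matches_normal_equations_oracle(self):
        design = make_design(seed=1, n_groups=2, effects={"G1": -0.5}, sigma=0.01)
        result = fit_mlr(design)
        # independent oracle: solve the normal equations directly
        M = design.columns.to_numpy()
        beta = np.linalg.solve(M.T @ M, M.T @ design.response)
        names = list(design.columns.columns)
        for name, b in zip(names, beta):
            assert result.coefficients[name] == pytest.approx(b, abs=1e-10)
        i = names.index("G1")
        assert abs(result.coefficients["G1"] - (-0.5)) < 3 * result.standard_errors["G1"]

    def test_inference_matches_statsmodels(self):
        design = make_design(seed=9, n_groups=4, effects={"G2": 0.3}, sigma=0.2)
        result = fit_mlr(design)
        ols = sm.OLS(design.response, design.columns.to_numpy()).fit()
        names = list(design.columns.columns)
        np.testing.assert_allclose(
            [result.coefficients[n] for n in names], ols.params, atol=1e-10
        )
        np.testing.assert_allclose(
            [result.standard_errors[n] for n in names], ols.bse, atol=1e-10
        )
        np.testing.assert_allclose(
            [result.p_values[n] for n in names], ols.pvalues, atol=1e-10
        )

    def test_duplicated_column_raises_collinearity_error(self):
        design = make_design(seed=2, n_groups=2)
        cols = design.columns.copy()
        cols["time_copy"] = cols["time"]
        bad = DesignMatrix(design.response, cols, "Control")
        with pytest.raises(CollinearityError) as err:
            fit_mlr(bad)
        assert "time" in str(err.value)

    def test_residuals_orthogonal_to_design(self):
        design = make_design(seed=4, n_groups=5, sigma=0.3)
        est = DummyVariableMLR().fit(design)
        resid = design.response - est.predict(design)
        M = design.columns.to_numpy()
        Mstd = M / np.linalg.norm(M, axis=0)
        assert np.max(np.abs(Mstd.T @ resid)) < 1e-8


class TestRankExtracts:
    def test_constructed_ordering_is_recovered(self):
        effects = {"Clove": -0.5, "Caraway": -0.3, "Onion": 0.05}
        rng = np.random.default_rng(0)
        rows, y = [], []
        labels = ["Control", "Caraway", "Clove", "Onion"]
        for g in labels:
            for _ in range(20):
                t, T = rng.uniform(0, 13), rng.uniform(4, 20)
                row = {"intercept": 1.0, "time": t, "temperature": T}
                for lab in sorted(labels[1:]):
                    row[lab] = 1.0 if g == lab else 0.0
                rows.append(row)
                y.append(4.4 + 0.126 * t + 0.044 * T + effects.get(g, 0) + rng.normal(0, 0.02))
        design = DesignMatrix(
            np.asarray(y),
            pd.DataFrame(rows, columns=["intercept", "time", "temperature",
                                        "Caraway", "Clove", "Onion"]),
            "Control",
        )
        ranking = rank_extracts(fit_mlr(design), alpha=0.05)
        assert [r[0] for r in ranking] == ["Clove", "Caraway", "Onion"]
        assert ranking[0][2] and ranking[1][2]  # strong effects significant

    def test_alpha_one_flags_everything(self):
        design = make_design(seed=6, n_groups=3, sigma=0.1)
        ranking = rank_extracts(fit_mlr(design), alpha=1.0)
        assert all(sig for _, _, sig in ranking)

    def test_no_dummies_rejected(self):
        design = make_design(seed=6, n_groups=1, sigma=0.1)
        with pytest.raises(DataError):
            rank_extracts(fit_mlr(design))


class TestFullStudyRegression:
    def test_effect_recovery_on_generated_study(self):
        # rates differ by group, so group indicators pick up slope offsets;
        # clove (lowest Ea at chill temperatures ~ slowest oxidation at 4 degC)
        # must rank below onion (fastest extract-treated group)
        study = generate_study(published_study_spec(seed=3))
        result = fit_mlr(build_design_matrix(study, "Control"))
        ranking = {name: coef for name, coef, _ in rank_extracts(result)}
        assert ranking["Clove"] < ranking["Onion"]
        assert result.coefficients["time"] > 0
        assert result.r2 > 0.5
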