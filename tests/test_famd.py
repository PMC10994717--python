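import numpy as np
import pandas as pd
import pytest

from trajconsensus.famd import (
    FAMDModel,
    encode_mixed,
    fit_famd,
    reduce_by_groups,
    regress_out_covariates,
    transform_famd,
)
from trajconsensus.io_model import ConfigurationError, VariableSpec
from trajconsensus.simulate import SimulationConfig, simulate_longitudinal_mixed


def famd_oracle(Z: np.ndarray):
    """Independent eigen-decomposition of the explicitly built weighted
    indicator matrix: eigenvalues/vectors of Z'Z / n."""
    n = Z.shape[0]
    evals, evecs = np.linalg.eigh(Z.T @ Z / n)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


def build_oracle_matrix(df: pd.DataFrame, variables):
    """Hand-build the FAMD design: standardize continuous columns, expand
    categoricals to centered indicators divided by sqrt(level proportion)."""
    cols = []
    for v in variables:
        if v.kind == "continuous":
            x = df[v.name].to_numpy(dtype=float)
            cols.append((x - x.mean()) / x.std())
        else:
            vals = df[v.name].astype(str).to_numpy()
            for level in v.levels:
                ind = (vals == level).astype(float)
                p = ind.mean()
                cols.append((ind - p) / np.sqrt(p))
    return np.column_stack(cols)


@pytest.fixture
def mixed_specs():
    return [
        VariableSpec("x1", "continuous"),
        VariableSpec("x2", "continuous"),
        VariableSpec("x3", "continuous"),
        VariableSpec("c1", "categorical", ("hi", "lo", "mid")),
    ]


class TestFitFAMD:
    def test_all_continuous_equals_standardized_pca(self, mixed_rows):
        df = mixed_rows[["x1", "x2", "x3"]]
        model = fit_famd(df)
        X = df.to_numpy()
        Z = (X - X.mean(0)) / X.std(0)
        evals, evecs = famd_oracle(Z)
        np.testing.assert_allclose(model.eigenvalues, evals[: len(model.eigenvalues)], atol=1e-10)
        for k in range(model.n_components):
            oracle_scores = Z @ evecs[:, k]
            got = model.scores[:, k]
            sign = np.sign(np.dot(oracle_scores, got)) or 1.0
            np.testing.assert_allclose(got, sign * oracle_scores, atol=1e-8)

    def test_eigenvalue_sum_identity_mixed(self, mixed_rows, mixed_specs):
        model = fit_famd(mixed_rows, variables=mixed_specs)
        # 3 continuous + one 3-level categorical: total inertia 3 + (3-1) = 5
        assert model.total_inertia == pytest.approx(5.0, abs=1e-10)

    def test_matches_explicit_indicator_oracle(self, mixed_rows, mixed_specs):
        model = fit_famd(mixed_rows, variables=mixed_specs)
        Z = build_oracle_matrix(mixed_rows, mixed_specs)
        evals, _ = famd_oracle(Z)
        np.testing.assert_allclose(
            np.sort(model.eigenvalues)[::-1], evals[: len(model.eigenvalues)], atol=1e-8
        )

    def test_single_binary_categorical_has_one_component(self):
        df = pd.DataFrame({"c": ["a", "b", "a", "a", "b", "b", "a", "b"]})
        spec = [VariableSpec("c", "categorical", ("a", "b"))]
        model = fit_famd(df, variables=spec)
        nonzero = model.eigenvalues[model.eigenvalues > 1e-10]
        assert len(nonzero) == 1
        # scores proportional to the centered indicator of one level
        ind = (df["c"] == "a").astype(float).to_numpy()
        centered = ind - ind.mean()
        corr = np.corrcoef(model.scores[:, 0], centered)[0, 1]
        assert abs(corr) == pytest.approx(1.0, abs=1e-10)

    def test_model_invariants(self, mixed_rows, mixed_specs):
        model = fit_famd(mixed_rows, variables=mixed_specs)
        assert np.all(model.eigenvalues >= -1e-12)
        assert np.all(np.diff(model.eigenvalues) <= 1e-12)
        np.testing.assert_allclose(model.scores.mean(axis=0), 0.0, atol=1e-8)
        cov = model.scores.T @ model.scores / len(mixed_rows)
        np.testing.assert_allclose(
            cov, np.diag(model.eigenvalues[: model.n_components]),
            atol=1e-6 * max(1.0, model.eigenvalues[0]),
        )

    def test_constant_continuous_named_in_error(self, mixed_rows):
        df = mixed_rows.assign(flat=1.0)
        with pytest.raises(ConfigurationError, match="flat"):
            fit_famd(df[["x1", "flat"]])

    def test_unobserved_level_rejected(self, mixed_rows):
        spec = [VariableSpec("c1", "categorical", ("hi", "lo", "mid", "ghost"))]
        with pytest.raises(ConfigurationError, match="ghost"):
            fit_famd(mixed_rows[["c1"]], variables=spec)

    def test_n_components_beyond_rank_rejected(self, mixed_rows):
        with pytest.raises(ConfigurationError):
            fit_famd(mixed_rows[["x1", "x2"]], n_components=3)

    def test_row_order_invariance(self, mixed_rows, mixed_specs):
        model = fit_famd(mixed_rows, variables=mixed_specs)
        perm = np.random.default_rng(7).permutation(len(mixed_rows))
        model_p = fit_famd(mixed_rows.iloc[perm].reset_index(drop=True), variables=mixed_specs)
        np.testing.assert_allclose(model_p.scores, model.scores[perm], atol=1e-8)


class TestTransform:
    def test_training_rows_reproduce_training_scores(self, mixed_rows, mixed_specs):
        model = fit_famd(mixed_rows, variables=mixed_specs)
        np.testing.assert_allclose(transform_famd(model, mixed_rows), model.scores, atol=1e-8)

    def test_mean_profile_row_scores_zero(self, mixed_rows, mixed_specs):
        # continuous at means and indicators at proportions encode to the
        # zero vector, hence zero scores on every component
        model = fit_famd(mixed_rows, variables=mixed_specs)
        row = pd.DataFrame({
            "x1": [model.continuous_means["x1"]],
            "x2": [model.continuous_means["x2"]],
            "x3": [model.continuous_means["x3"]],
            "c1": [list(model.level_proportions["c1"])[0]],
        })
        Z, _ = encode_mixed(row, model.variables, model.continuous_means,
                            model.continuous_sds, model.level_proportions)
        Z_cat = Z[:, 3:]
        # fractional indicator at proportions: z = (p - p)/sqrt(p) = 0
        props = model.level_proportions["c1"]
        fractional = np.array([
            (props[l] - props[l]) / np.sqrt(props[l]) for l in model.variables[3].levels
        ])
        full = np.concatenate([np.zeros(3), fractional])
        np.testing.assert_allclose(full @ model.loadings, 0.0, atol=1e-12)

    def test_held_out_row_matches_matrix_product_oracle(self, mixed_rows, mixed_specs):
        train = mixed_rows.iloc[:-1]
        held = mixed_rows.iloc[[-1]]
        model = fit_famd(train, variables=mixed_specs)
        got = transform_famd(model, held)
        z = build_oracle_matrix(
            pd.concat([train, held], ignore_index=True), mixed_specs
        )
        # rebuild the held-out encoded row with *training* parameters
        zh, _ = encode_mixed(held, model.variables, model.continuous_means,
                             model.continuous_sds, model.level_proportions)
        np.testing.assert_allclose(got, zh @ model.loadings, atol=1e-10)

    def test_unseen_level_raises_naming_level(self, mixed_rows, mixed_specs):
        model = fit_famd(mixed_rows, variables=mixed_specs)
        bad = mixed_rows.iloc[[0]].assign(c1="novel")
        with pytest.raises(ConfigurationError, match="novel"):
            transform_famd(model, bad)


class TestReduceByGroups:
    def test_shape_contract_two_groups(self, simulated_two_group):
        _, ds, _ = simulated_two_group
        reduced, models = reduce_by_groups(ds, n_components=2)
        assert len(reduced.data) == len(ds.data)
        assert reduced.variable_names == [
            "scale1_dim1", "scale1_dim2", "scale2_dim1", "scale2_dim2",
        ]
        assert all(v.is_continuous for v in reduced.variables)

    def test_single_group_equals_plain_famd(self, mixed_rows, mixed_specs):
        from trajconsensus.io_model import LongitudinalDataset
        frame = mixed_rows.copy()
        frame.insert(0, "pid", [f"s{i}" for i in range(len(frame))])
        frame.insert(1, "t", 0.0)
        ds = LongitudinalDataset(frame, "pid", "t", tuple(mixed_specs))
        reduced, models = reduce_by_groups(
            ds, {v.name: "all" for v in mixed_specs}, n_components=2
        )
        plain = fit_famd(mixed_rows, 2, variables=mixed_specs)
        np.testing.assert_allclose(
            reduced.values().to_numpy(), plain.scores, atol=1e-10
        )

    def test_within_group_scores_orthogonal(self, simulated_two_group):
        _, ds, _ = simulated_two_group
        reduced, _ = reduce_by_groups(ds, n_components=3)
        for g in ("scale1", "scale2"):
            S = reduced.data[[f"{g}_dim{k}" for k in (1, 2, 3)]].to_numpy()
            C = S.T @ S / len(S)
            off = C - np.diag(np.diag(C))
            assert np.max(np.abs(off)) < 1e-8 * max(1.0, np.abs(C).max())

    def test_variable_in_no_group_rejected(self, simulated_two_group):
        _, ds, _ = simulated_two_group
        groups = dict(ds.groups)
        dropped = next(iter(groups))
        del groups[dropped]
        with pytest.raises(ConfigurationError, match="no group"):
            reduce_by_groups(ds, groups, n_components=2)

    def test_auto_rule_explains_70_percent(self, simulated_two_group):
        _, ds, _ = simulated_two_group
        reduced, models = reduce_by_groups(ds, n_components="auto")
        for model in models.values():
            share = np.cumsum(model.eigenvalues) / model.total_inertia
            m = model.n_components
            assert share[m - 1] >= 0.70
            assert m == 1 or share[m - 2] < 0.70


class TestRegressOutCovariates:
    def test_constructed_age_effect_removed(self):
        # closed-form OLS oracle: residuals of 2*age + noise on age are
        # exactly uncorrelated with age
        rng = np.random.default_rng(3)
        age = rng.uniform(20, 60, size=200)
        noise = rng.normal(size=200)
        scores = pd.DataFrame({"dim1": 2.0 * age + noise, "dim2": rng.normal(size=200)})
        cov = pd.DataFrame({"age": age})
        resid = regress_out_covariates(scores, cov)
        X = np.column_stack([np.ones(200), age])
        beta = np.linalg.lstsq(X, scores.to_numpy(), rcond=None)[0]
        np.testing.assert_allclose(resid.to_numpy(), scores.to_numpy() - X @ beta, atol=1e-10)
        for col in resid:
            assert abs(np.corrcoef(resid[col], age)[0, 1]) < 1e-8

    def test_empty_covariates_center_scores(self):
        scores = pd.DataFrame({"dim1": [1.0, 2.0, 6.0]})
        out = regress_out_covariates(scores, None)
        np.testing.assert_allclose(out["dim1"], [-2.0, -1.0, 3.0])

    def test_zero_variance_covariate_rejected(self):
        scores = pd.DataFrame({"dim1": [1.0, 2.0, 3.0]})
        with pytest.raises(ConfigurationError, match="rank deficient"):
            regress_out_covariates(scores, pd.DataFrame({"c": [5.0, 5.0, 5.0]}))

    def test_categorical_covariate_expanded(self):
        rng = np.random.default_rng(5)
        site = rng.choice(["A", "B"], size=100)
        shift = np.where(site == "A", 3.0, -3.0)
        scores = pd.DataFrame({"dim1": shift + rng.normal(size=100)})
        resid = regress_out_covariates(scores, pd.DataFrame({"site": site}))
        means = pd.Series(resid["dim1"].to_numpy()).groupby(site).mean()
        np.testing.assert_allclose(means.to_numpy(), 0.0, atol=1e-10)


class TestSerialization:
    def test_json_round_trip_projects_identically(self, mixed_rows, mixed_specs, tmp_path):
        model = fit_famd(mixed_rows, 2, variables=mixed_specs)
        path = tmp_path / "famd.json"
        model.save(path)
        back = FAMDModel.load(path)
        np.testing.assert_allclose(
            transform_famd(back, mixed_rows), model.scores, atol=1e-10
        )
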