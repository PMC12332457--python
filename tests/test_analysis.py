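import numpy as np
import pandas as pd
import pytest
from scipy import stats

from rhythmkit.analysis import (
    GROUP_ORDER,
    build_feature_table,
    classify_frailty,
    classify_frailty_table,
    correlation_matrix,
    kruskal_dunn,
    linear_model_wlm,
    multinomial_frailty_model,
    _nagelkerke,
)
from rhythmkit.io import QUESTIONNAIRE_ITEMS


class TestClassifyFrailty:
    @pytest.mark.parametrize(
        "items,score,group",
        [
            ((0, 0, 0, 0, 0), 0, "robust"),
            ((1, 0, 0, 0, 0), 1, "prefrail"),
            ((0, 1, 1, 0, 0), 2, "frail"),
            ((1, 1, 1, 1, 1), 5, "frail"),
        ],
    )
    def test_score_rules(self, items, score, group):
        got_score, got_group = classify_frailty(items)
        assert got_score == score and got_group == group

    def test_missing_item_gives_missing_class(self):
        score, group = classify_frailty((1, np.nan, 0, 0, 0))
        assert np.isnan(score) and group is None

    def test_table_classification(self):
        q = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                **{item: [0, 1] for item in QUESTIONNAIRE_ITEMS},
            }
        )
        out = classify_frailty_table(q)
        assert list(out["group"].astype(str)) == ["robust", "frail"]


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self, rng):
        df = pd.DataFrame({"x": rng.normal(0, 1, 40), "y": rng.normal(0, 1, 40)})
        out = correlation_matrix(df)
        assert out.r.loc["x", "x"] == 1.0

    def test_monotone_transform_spearman_one(self, rng):
        x = rng.exponential(2.0, 50)  # skewed, fails the normality gate
        df = pd.DataFrame({"x": x, "y": np.exp(x)})
        out = correlation_matrix(df)
        assert out.method.loc["x", "y"] == "spearman"
        assert out.r.loc["x", "y"] == pytest.approx(1.0)

    def test_normal_pair_uses_pearson(self, rng):
        x = rng.normal(0, 1, 200)
        df = pd.DataFrame({"x": x, "y": x + rng.normal(0, 1, 200)})
        out = correlation_matrix(df)
        assert out.method.loc["x", "y"] == "pearson"

    def test_skewed_table_matches_rank_oracle(self, rng):
        x = rng.lognormal(0, 1.2, 30) ** 2  # heavy skew fails the gate
        y = np.sqrt(x) + rng.exponential(1.0, 30)
        df = pd.DataFrame({"x": x, "y": y})
        out = correlation_matrix(df)
        assert out.method.loc["x", "y"] == "spearman"
        # independent oracle: Pearson correlation of midranks
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        oracle = np.corrcoef(rx, ry)[0, 1]
        assert out.r.loc["x", "y"] == pytest.approx(oracle)

    def test_constant_variable_cell_missing(self, rng):
        df = pd.DataFrame({"x": rng.normal(0, 1, 30), "c": np.ones(30)})
        out = correlation_matrix(df)
        assert np.isnan(out.r.loc["x", "c"])

    def test_pairwise_complete_minimum(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, np.nan], "y": [2.0, 1, np.nan, 5]})
        out = correlation_matrix(df, min_pairs=4)
        assert np.isnan(out.r.loc["x", "y"])


def _grouped_frame(rng, shift=(0.0, 0.0, 0.0), n=(12, 14, 10)):
    rows = []
    for g, mu, k in zip(GROUP_ORDER, shift, n):
        for v in rng.normal(mu, 1.0, k):
            rows.append({"group": g, "v": v})
    return pd.DataFrame(rows)


class TestKruskalDunn:
    def test_identical_values_h_zero_p_one(self):
        df = pd.DataFrame({"group": ["robust"] * 3 + ["prefrail"] * 3 + ["frail"] * 3,
                           "v": [5.0] * 9})
        (res,) = kruskal_dunn(df, df["group"], ["v"])
        assert res.h_statistic == 0.0 and res.p_overall == 1.0

    def test_matches_independent_rank_oracle(self):
        data = {
            "robust": [1.2, 3.4, 2.2, 5.0, 0.7],
            "prefrail": [4.4, 6.1, 5.5, 7.2, 4.9],
            "frail": [8.0, 9.1, 7.7, 8.8, 10.2],
        }
        df = pd.DataFrame(
            [(g, v) for g, vals in data.items() for v in vals], columns=["group", "v"]
        )
        (res,) = kruskal_dunn(df, df["group"], ["v"])
        h_oracle, p_oracle = stats.kruskal(*data.values())
        assert res.h_statistic == pytest.approx(h_oracle)
        assert res.p_overall == pytest.approx(p_oracle)
        # Dunn z oracle, hand-computed from joint ranks (no ties here)
        all_vals = np.concatenate(list(data.values()))
        ranks = stats.rankdata(all_vals)
        rbar = {g: ranks[i * 5 : (i + 1) * 5].mean() for i, g in enumerate(data)}
        n = len(all_vals)
        se = np.sqrt(n * (n + 1) / 12 * (1 / 5 + 1 / 5))
        z = (rbar["robust"] - rbar["frail"]) / se
        p_raw = 2 * stats.norm.sf(abs(z))
        assert res.pairwise_p[("robust", "frail")] == pytest.approx(min(1, 3 * p_raw))

    def test_adjusted_p_at_least_raw_and_capped(self, rng):
        df = _grouped_frame(rng, shift=(0, 0.5, 1.0))
        (res,) = kruskal_dunn(df, df["group"], ["v"])
        for pair, adj in res.pairwise_p.items():
            assert adj >= res.pairwise_p_raw[pair] - 1e-15
            assert 0 <= adj <= 1

    def test_small_group_skipped(self, rng):
        df = _grouped_frame(rng, n=(10, 10, 1))
        assert kruskal_dunn(df, df["group"], ["v"]) == []

    def test_medians_and_iqrs_reported(self, rng):
        df = _grouped_frame(rng)
        (res,) = kruskal_dunn(df, df["group"], ["v"])
        sub = df[df["group"] == "robust"]["v"]
        assert res.medians["robust"] == pytest.approx(sub.median())
        assert res.iqrs["robust"] == pytest.approx(
            sub.quantile(0.75) - sub.quantile(0.25)
        )


class TestLinearModel:
    def test_noise_free_exact_fit(self):
        x = np.linspace(50, 150, 40)
        df = pd.DataFrame({"icv100": x / 100.0, "wlm": 2.0 - 0.04 * x})
        out = linear_model_wlm(df, ["icv100"], scales={"icv100": 100})
        slope = out.terms.set_index("term").loc["icv100 x 100", "beta"]
        assert slope == pytest.approx(-0.04)
        assert out.fit["r2"] == pytest.approx(1.0)

    def test_intercept_only_r2_zero(self, rng):
        df = pd.DataFrame({"wlm": rng.normal(12, 3, 30)})
        out = linear_model_wlm(df, [])
        assert out.fit["r2"] == pytest.approx(0.0)

    def test_collinear_terms_rejected(self, rng):
        a = rng.normal(0, 1, 30)
        df = pd.DataFrame({"a": a, "b": 2 * a, "wlm": rng.normal(12, 3, 30)})
        with pytest.raises(ValueError, match="rank-deficient"):
            linear_model_wlm(df, ["a", "b"])

    def test_ci_brackets_estimate(self, rng):
        df = pd.DataFrame(
            {"x": rng.normal(0, 1, 60), "wlm": rng.normal(12, 3, 60)}
        )
        out = linear_model_wlm(df, ["x"])
        for _, row in out.terms.iterrows():
            assert row["ci_low"] <= row["beta"] <= row["ci_high"]


def _toy_multinomial_frame(rng, n=400, beta_frail=1.2):
    x1 = rng.integers(0, 2, n).astype(float)
    x2 = rng.integers(0, 2, n).astype(float)
    eta = np.column_stack(
        [np.zeros(n), 0.3 + 0.5 * x1, -0.4 + beta_frail * x1 - 0.6 * x2]
    )
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    codes = (rng.random(n)[:, None] > p.cumsum(axis=1)).sum(axis=1)
    return pd.DataFrame(
        {
            "x1": x1,
            "x2": x2,
            "group": pd.Categorical.from_codes(codes, categories=list(GROUP_ORDER)),
        }
    )


class TestMultinomialModel:
    def test_or_equals_exp_beta_to_4dp(self, rng):
        df = _toy_multinomial_frame(rng)
        out = multinomial_frailty_model(df, ["x1", "x2"])
        for _, row in out.terms.iterrows():
            assert row["or"] == pytest.approx(np.exp(row["beta"]), abs=5e-5)
            assert row["or_ci_low"] <= row["or"] <= row["or_ci_high"]

    def test_null_predictor_or_near_one(self, rng):
        df = _toy_multinomial_frame(rng, n=2000, beta_frail=0.0)
        df["noise"] = rng.normal(0, 1, len(df))
        out = multinomial_frailty_model(df, ["noise"])
        rows = out.terms[out.terms["term"] == "noise"]
        for _, row in rows.iterrows():
            assert row["or_ci_low"] < 1.0 < row["or_ci_high"]

    def test_matches_independent_likelihood_oracle(self, rng):
        from scipy.optimize import minimize

        df = _toy_multinomial_frame(rng, n=250)
        out = multinomial_frailty_model(df, ["x1", "x2"])
        X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
        codes = df["group"].cat.codes.to_numpy()

        def nll(theta):
            b = theta.reshape(3, 2)
            eta = np.column_stack([np.zeros(len(df)), X @ b])
            eta -= eta.max(axis=1, keepdims=True)
            logp = eta - np.log(np.exp(eta).sum(axis=1, keepdims=True))
            return -logp[np.arange(len(df)), codes].sum()

        res = minimize(nll, np.zeros(6), method="BFGS")
        assert -res.fun == pytest.approx(out.fit["ll"], abs=1e-4)
        oracle = res.x.reshape(3, 2)
        fitted = out.terms.pivot(index="term", columns="outcome", values="beta")
        for k, term in enumerate(["const", "x1", "x2"]):
            assert fitted.loc[term, "prefrail"] == pytest.approx(oracle[k, 0], abs=1e-3)
            assert fitted.loc[term, "frail"] == pytest.approx(oracle[k, 1], abs=1e-3)

    def test_adjusted_and_unadjusted_effects_share_sign(self, rng):
        df = _toy_multinomial_frame(rng, n=600)
        df["age"] = rng.normal(77, 5, len(df))
        df["sex"] = np.where(rng.random(len(df)) < 0.9, "female", "male")
        raw = multinomial_frailty_model(df, ["x1"])
        adj = multinomial_frailty_model(df, ["x1"], adjust="age_sex")
        for outcome in ("prefrail", "frail"):
            b_raw = raw.terms.query("term == 'x1' and outcome == @outcome")["beta"].item()
            b_adj = adj.terms.query("term == 'x1' and outcome == @outcome")["beta"].item()
            assert np.sign(b_raw) == np.sign(b_adj)

    def test_separation_flagged(self):
        df = pd.DataFrame(
            {
                "x": np.concatenate([np.zeros(20), np.ones(20), np.full(20, 2.0)]),
                "group": ["robust"] * 20 + ["prefrail"] * 20 + ["frail"] * 20,
            }
        )
        out = multinomial_frailty_model(df, ["x"])
        assert out.flagged
        assert out.terms["beta"].isna().all()

    def test_nagelkerke_bounds(self):
        assert _nagelkerke(-50.0, -50.0, 100) == pytest.approx(0.0)
        assert 0 < _nagelkerke(-40.0, -50.0, 100) < 1


class TestBuildFeatureTable:
    def _inputs(self):
        features = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "included": [True, True, False],
                "ICV.st": [1.0, 1.2, 1.4],
            }
        )
        questionnaire = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c", "orphan"],
                **{item: [0, 1, 1, 0] for item in QUESTIONNAIRE_ITEMS},
            }
        )
        return features, questionnaire

    def test_excluded_and_orphan_rows_dropped(self):
        features, questionnaire = self._inputs()
        table = build_feature_table(features, questionnaire)
        assert list(table["participant_id"]) == ["a", "b"]
        assert list(table["group"].astype(str)) == ["robust", "frail"]

    def test_duplicate_ids_rejected(self):
        features, questionnaire = self._inputs()
        dup = pd.concat([features, features.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            build_feature_table(dup, questionnaire)

    def test_empty_feature_store(self):
        _, questionnaire = self._inputs()
        out = build_feature_table(pd.DataFrame({"participant_id": []}), questionnaire)
        assert out.empty
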