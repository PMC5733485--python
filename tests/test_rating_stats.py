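import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dyadmotion.rating_stats import (
    CompositeDef,
    RatingStatsError,
    benjamini_hochberg,
    composite_scores,
    correlation_table,
    cronbach_alpha,
    icc_2_1,
    parse_composite_map,
    spearman,
)


def ratings_frame():
    return pd.DataFrame(
        {
            "Overriding": [3, 1, 5],
            "Fluency": [2, 4, 3],
            "Dyadic reciprocity": [4, 4, 1],
            "Fatigue": [5, 1, 3],
        },
        index=pd.Index(["d1", "d2", "d3"], name="dyad_id"),
    )


class TestComposites:
    def test_single_scale_passes_through(self):
        comps = [CompositeDef("Maternal intrusiveness", ["Overriding"])]
        out = composite_scores(ratings_frame(), comps)
        assert out["Maternal intrusiveness"].tolist() == [3.0, 1.0, 5.0]

    def test_mean_of_two_scales(self):
        comps = [CompositeDef("Dyadic reciprocity", ["Fluency", "Dyadic reciprocity"])]
        out = composite_scores(ratings_frame(), comps)
        assert out["Dyadic reciprocity"].tolist() == [3.0, 4.0, 2.0]

    def test_reversed_scale_maps_5_to_1(self):
        comps = [CompositeDef("Involvement", ["Fatigue"], reversed_scales={"Fatigue"})]
        out = composite_scores(ratings_frame(), comps)
        assert out["Involvement"].tolist() == [1.0, 5.0, 3.0]

    def test_missing_scale_raises_naming_both(self):
        comps = [CompositeDef("Sensitivity", ["Acknowledgement"])]
        with pytest.raises(RatingStatsError, match="Sensitivity.*Acknowledgement"):
            composite_scores(ratings_frame(), comps)

    def test_bounded_by_constituent_min_max(self, rng):
        scales = [f"s{i}" for i in range(4)]
        df = pd.DataFrame(rng.integers(1, 6, (20, 4)), columns=scales)
        out = composite_scores(df, [CompositeDef("c", scales)])
        assert (out["c"] >= df.min(axis=1)).all() and (out["c"] <= df.max(axis=1)).all()

    def test_out_of_scale_values_rejected(self):
        df = pd.DataFrame({"a": [0, 3], "b": [2, 2]})
        with pytest.raises(RatingStatsError, match="1-5"):
            composite_scores(df, [CompositeDef("c", ["a", "b"])])

    def test_parse_composite_map_with_reversed_entry(self):
        raw = {"13m": {"Involvement": ["Alert", {"scale": "Fatigue", "reversed": True}]}}
        comps = parse_composite_map(raw)["13m"]
        assert comps[0].scales == ["Alert", "Fatigue"]
        assert comps[0].reversed_scales == {"Fatigue"}

    def test_shipped_default_map_loads(self):
        import importlib.resources
        import yaml

        text = (
            importlib.resources.files("dyadmotion") / "data" / "cib_composites.yaml"
        ).read_text()
        parsed = parse_composite_map(yaml.safe_load(text))
        assert set(parsed) == {"4m", "13m"}
        names_13m = {c.name for c in parsed["13m"]}
        assert "Maternal limit-setting" in names_13m and "Infant compliance" in names_13m


def alpha_oracle(x):
    """Spreadsheet-style direct evaluation of Cronbach's alpha."""
    x = np.asarray(x, float)
    k = x.shape[1]
    item_vars = [np.var(x[:, j], ddof=1) for j in range(k)]
    total_var = np.var(x.sum(axis=1), ddof=1)
    return k / (k - 1) * (1 - sum(item_vars) / total_var)


class TestCronbachAlpha:
    def test_identical_items_alpha_one(self):
        col = np.array([1.0, 2, 3, 4, 5])
        x = np.column_stack([col, col, col])
        assert cronbach_alpha(x) == pytest.approx(1.0)

    def test_hand_built_4x3_matches_direct_formula(self):
        x = np.array([[1, 2, 3], [2, 4, 5], [3, 3, 4], [4, 5, 5]], float)
        assert cronbach_alpha(x) == pytest.approx(alpha_oracle(x), abs=1e-12)

    def test_independent_noise_items_alpha_near_zero(self):
        rng = np.random.default_rng(0)
        alphas = [cronbach_alpha(rng.normal(size=(500, 2))) for _ in range(200)]
        assert abs(np.mean(alphas)) < 0.05

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.integers(1, 6, (12, 4)).astype(float)
        ours = cronbach_alpha(x)
        theirs = pingouin.cronbach_alpha(data=pd.DataFrame(x))[0]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(RatingStatsError):
            cronbach_alpha(np.ones((5, 3)))
        with pytest.raises(RatingStatsError):
            cronbach_alpha(np.ones((1, 3)))


def icc_oracle(x):
    """Direct two-way ANOVA evaluation of ICC(2,1)."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    sse = np.sum((x - x.mean(axis=1, keepdims=True) - x.mean(axis=0) + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_perfect_agreement_is_one(self):
        col = np.array([1.0, 3, 2, 5, 4])
        icc, (lo, hi) = icc_2_1(np.column_stack([col, col]))
        assert icc == pytest.approx(1.0)

    def test_hand_built_10x2_matches_direct_anova(self, rng):
        base = rng.integers(1, 6, 10).astype(float)
        x = np.column_stack([base, base + rng.normal(0, 0.5, 10)])
        icc, _ = icc_2_1(x)
        assert icc == pytest.approx(icc_oracle(x), abs=1e-12)

    def test_coder_bias_penalized_and_monotone(self, rng):
        base = rng.normal(3, 1, 20)
        iccs = []
        for bias in (0.0, 0.5, 1.0, 2.0):
            icc, _ = icc_2_1(np.column_stack([base, base + bias]))
            iccs.append(icc)
        assert iccs[0] == pytest.approx(1.0)
        assert all(a > b for a, b in zip(iccs, iccs[1:]))

    def test_permuted_coder_near_zero_on_average(self):
        rng = np.random.default_rng(1)
        vals = []
        for _ in range(200):
            a = rng.normal(size=15)
            vals.append(icc_2_1(np.column_stack([a, rng.permutation(a)]))[0])
        assert abs(np.mean(vals)) < 0.05

    def test_matches_pingouin_icc2_with_ci(self, rng):
        pingouin = pytest.importorskip("pingouin")
        x = rng.normal(3, 1, (12, 3)) + rng.normal(0, 0.3, (12, 1))
        icc, (lo, hi) = icc_2_1(x)
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 3),
                "raters": np.tile(np.arange(3), 12),
                "scores": x.ravel(),
            }
        )
        res = pingouin.intraclass_corr(long, targets="targets", raters="raters", ratings="scores")
        row = res[res.Type.isin(["ICC2", "ICC(A,1)"])].iloc[0]
        assert icc == pytest.approx(row.ICC, abs=1e-9)
        ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
        # pingouin rounds the interval to two decimals
        assert lo == pytest.approx(row[ci_col][0], abs=6e-3)
        assert hi == pytest.approx(row[ci_col][1], abs=6e-3)


def spearman_oracle(x, y):
    """Brute force: average-tied ranks, then Pearson correlation."""
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearman:
    def test_monotone_pairs(self, rng):
        x = np.sort(rng.normal(size=20))
        assert spearman(x, np.exp(x))[0] == pytest.approx(1.0)
        assert spearman(x, -(x**3))[0] == pytest.approx(-1.0)

    def test_tied_vector_matches_oracle(self):
        x = np.array([1.0, 2, 2, 3, 4, 5, 6, 7])
        y = np.array([2.0, 1, 4, 3, 3, 6, 5, 8])
        assert spearman(x, y)[0] == pytest.approx(spearman_oracle(x, y), abs=1e-12)

    def test_symmetric_and_monotone_invariant(self, rng):
        x, y = rng.normal(size=30), rng.normal(size=30)
        r1, p1 = spearman(x, y)
        r2, p2 = spearman(y, x)
        assert r1 == pytest.approx(r2) and p1 == pytest.approx(p2)
        r3, _ = spearman(np.exp(x), y**3)
        assert r3 == pytest.approx(r1)

    def test_constant_vector_undefined(self):
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isnan(rho) and math.isnan(p)

    def test_pairwise_complete_deletion(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [1.0, 3.0, 2.0, np.nan, 7.0]
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(spearman([1, 2, 5], [1, 3, 7])[0])

    def test_exact_permutation_p_small_n(self):
        x = [1.0, 2, 3, 4, 5]
        y = [1.0, 2, 3, 5, 4]
        rho_t, _ = spearman(x, y, method="t")
        rho_e, p_e = spearman(x, y, method="exact")
        assert rho_e == pytest.approx(rho_t, abs=1e-12)
        # enumeration oracle: fraction of the 120 permutations at least as extreme
        from itertools import permutations

        count = sum(
            abs(spearman_oracle(x, list(perm))) >= abs(rho_e) - 1e-12
            for perm in permutations(y)
        )
        assert p_e == pytest.approx(count / math.factorial(5))

    def test_t_approximation_p_matches_scipy(self, rng):
        x, y = rng.normal(size=19), rng.normal(size=19)
        rho, p = spearman(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)


class TestCorrelationTable:
    def features_df(self, rng, n=20):
        return pd.DataFrame(
            {
                "dyad_id": [f"d{i}" for i in range(n)],
                "body_part": ["arms"] * n,
                "silence_ratio": rng.uniform(0, 1, n),
                "overlap_ratio": np.nan,
            }
        )

    def test_monotone_feature_gives_rho_one(self, rng):
        feats = self.features_df(rng)
        comps = pd.DataFrame(
            {"comp": np.argsort(np.argsort(feats.silence_ratio.to_numpy())) + 1.0},
            index=pd.Index(feats.dyad_id, name="dyad_id"),
        )
        table = correlation_table(feats, comps, feature_names=["silence_ratio"])
        assert table.iloc[0].rho == pytest.approx(1.0)
        assert table.iloc[0].n == 20

    def test_missing_feature_column_gives_missing_cells(self, rng):
        feats = self.features_df(rng)
        comps = pd.DataFrame({"comp": rng.normal(size=20)},
                             index=pd.Index(feats.dyad_id, name="dyad_id"))
        table = correlation_table(feats, comps, feature_names=["overlap_ratio"])
        assert math.isnan(table.iloc[0].rho) and table.iloc[0].n == 0

    def test_no_overlapping_dyads_empty_with_warning(self, rng):
        feats = self.features_df(rng)
        comps = pd.DataFrame({"comp": [1.0, 2.0]}, index=["x1", "x2"])
        table = correlation_table(feats, comps)
        assert table.empty

    def test_bh_adjustment_monotone_and_bounded(self, rng):
        feats = self.features_df(rng)
        comps = pd.DataFrame({"comp": rng.normal(size=20)},
                             index=pd.Index(feats.dyad_id, name="dyad_id"))
        table = correlation_table(feats, comps, feature_names=["silence_ratio"],
                                  bh_correction=True)
        ok = table.dropna(subset=["p"])
        assert (ok.p_adj >= ok.p - 1e-12).all() and (ok.p_adj <= 1).all()

    def test_bh_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(0, 1, 25)
        ours = benjamini_hochberg(p)
        theirs = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, theirs)
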