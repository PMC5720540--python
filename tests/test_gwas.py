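import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from namqtl import gwas
from namqtl.gwas import (
    GwasError,
    filter_snps,
    holm_adjust,
    impute_dosages,
    multi_marker_r2_adj,
    sbc,
    scan,
    select_cofactors,
    snp_r2,
)


def brute_force_holm(p):
    """Independent step-down implementation straight from the definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, min(1.0, (m - rank) * p[idx]))
        adj[idx] = running
    return adj


def exhaustive_sbc_minimum(G, y):
    """Best SBC over every subset of SNP columns (the selection oracle)."""
    n = len(y)
    best = np.inf
    yv = y.to_numpy()
    for k in range(len(G.columns) + 1):
        for subset in itertools.combinations(G.columns, k):
            X = np.hstack([np.ones((n, 1)), G[list(subset)].to_numpy(float)])
            beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
            rss = float(np.sum((yv - X @ beta) ** 2))
            tss = float(np.sum((yv - yv.mean()) ** 2))
            best = min(best, sbc(rss, n, X.shape[1], tss))
    return best


def random_design(rng, n=60, p=6, causal=(0, 2), betas=(1.0, 0.6), noise=0.5):
    G = pd.DataFrame(
        rng.integers(0, 3, size=(n, p)).astype(float),
        index=[f"L{i}" for i in range(n)],
        columns=[f"s{j}" for j in range(p)],
    )
    y = rng.normal(0, noise, n)
    for j, b in zip(causal, betas):
        y = y + b * G.iloc[:, j].to_numpy()
    return G, pd.Series(y, index=G.index)


class TestFilterSnps:
    def make(self, column, n):
        return pd.DataFrame({"s": column}, index=[f"L{i}" for i in range(n)])

    def test_monomorphic_removed(self):
        geno = self.make([0.0] * 20, 20)
        geno["t"] = [0.0] * 10 + [2.0] * 10
        assert list(filter_snps(geno)) == ["t"]

    def test_monomorphic_within_every_family_removed(self):
        # polymorphic overall but constant inside each family
        geno = pd.DataFrame(
            {"s": [0.0] * 10 + [2.0] * 10, "t": [0, 2] * 10},
            index=[f"L{i}" for i in range(20)],
        )
        fams = pd.Series(["A"] * 10 + ["B"] * 10, index=geno.index)
        assert list(filter_snps(geno, fams)) == ["t"]

    def test_missingness_boundary_strict(self):
        n = 1000
        col_10pct = [np.nan] * 100 + [0.0, 2.0] * 450
        col_9_9pct = [np.nan] * 99 + [0.0] + [0.0, 2.0] * 450
        geno = pd.DataFrame(
            {"at": col_10pct, "below": col_9_9pct}, index=[f"L{i}" for i in range(n)]
        )
        assert list(filter_snps(geno)) == ["below"]

    def test_heterozygosity_boundary(self):
        n = 200
        het13 = [1.0] * 26 + [0.0, 2.0] * 87  # 13% >= 12.5% -> removed
        het12 = [1.0] * 24 + [0.0, 2.0] * 88  # 12% < 12.5% -> retained
        geno = pd.DataFrame({"hi": het13, "lo": het12}, index=[f"L{i}" for i in range(n)])
        assert list(filter_snps(geno)) == ["lo"]

    def test_empty_matrix_rejected(self):
        with pytest.raises(GwasError):
            filter_snps(pd.DataFrame())


class TestImpute:
    def test_family_mean_imputation(self):
        geno = pd.DataFrame(
            {"s": [0.0, 2.0, np.nan, 2.0, 2.0, np.nan]},
            index=[f"L{i}" for i in range(6)],
        )
        fams = pd.Series(["A"] * 3 + ["B"] * 3, index=geno.index)
        out = impute_dosages(geno, fams)
        assert out.loc["L2", "s"] == pytest.approx(1.0)  # mean of family A
        assert out.loc["L5", "s"] == pytest.approx(2.0)  # mean of family B

    def test_fallback_to_overall_mean(self):
        geno = pd.DataFrame(
            {"s": [np.nan, np.nan, 2.0, 0.0]}, index=[f"L{i}" for i in range(4)]
        )
        fams = pd.Series(["A", "A", "B", "B"], index=geno.index)
        out = impute_dosages(geno, fams)
        assert out.loc["L0", "s"] == pytest.approx(1.0)


class TestHolm:
    def test_singleton_unchanged(self):
        np.testing.assert_allclose(holm_adjust([0.04]), [0.04])

    def test_three_value_example(self):
        np.testing.assert_allclose(holm_adjust([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    def test_capped_at_one(self):
        np.testing.assert_allclose(holm_adjust([0.5, 0.9]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(GwasError):
            holm_adjust([0.5, 1.2])
        with pytest.raises(GwasError):
            holm_adjust([-0.1])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0, allow_nan=False), min_size=1, max_size=50)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_and_invariants(self, p):
        p = np.asarray(p)
        adj = holm_adjust(p)
        np.testing.assert_allclose(adj, brute_force_holm(p), atol=1e-14)
        assert (adj >= p - 1e-14).all()
        assert (adj <= np.minimum(1.0, len(p) * p) + 1e-14).all()
        # monotone in the sorted order
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-14).all()


class TestSelectCofactors:
    def test_constant_blues_select_nothing(self):
        rng = np.random.default_rng(0)
        G, _ = random_design(rng)
        y = pd.Series(2.0, index=G.index)
        assert select_cofactors(G, y) == []

    def test_noiseless_single_causal_snp(self):
        rng = np.random.default_rng(1)
        G, _ = random_design(rng, p=8)
        y = pd.Series(1.5 * G["s3"].to_numpy(), index=G.index)
        assert select_cofactors(G, y) == ["s3"]

    def test_too_few_lines_rejected(self):
        rng = np.random.default_rng(2)
        G, y = random_design(rng, n=2, p=3)
        with pytest.raises(GwasError):
            select_cofactors(G, y)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_sbc_minimum(self, seed):
        rng = np.random.default_rng(100 + seed)
        G, y = random_design(rng, n=50, p=7)
        selected = select_cofactors(G, y)
        n = len(y)
        X = np.hstack([np.ones((n, 1)), G[selected].to_numpy(float)])
        beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
        rss = float(np.sum((y.to_numpy() - X @ beta) ** 2))
        tss = float(np.sum((y.to_numpy() - y.mean()) ** 2))
        achieved = sbc(rss, n, X.shape[1], tss)
        assert achieved == pytest.approx(exhaustive_sbc_minimum(G, y), abs=1e-8)


class TestScan:
    def test_perfect_association_attains_min_p(self):
        rng = np.random.default_rng(3)
        G, _ = random_design(rng, p=6)
        y = pd.Series(G["s2"].to_numpy(), index=G.index)
        res = scan(G, y)
        assert res.loc[res["p_value"].idxmin(), "snp_id"] == "s2"

    def test_effect_is_twice_alpha(self):
        rng = np.random.default_rng(4)
        G, y = random_design(rng)
        res = scan(G, y)
        np.testing.assert_allclose(res["effect"], 2.0 * res["alpha"])

    def test_alpha_recovers_known_coefficient(self):
        # allele substitution effect 2.54 corresponds to alpha 1.27
        rng = np.random.default_rng(5)
        G, _ = random_design(rng, p=4)
        y = pd.Series(0.7 + 1.27 * G["s1"].to_numpy(), index=G.index)
        res = scan(G, y).set_index("snp_id")
        assert res.loc["s1", "alpha"] == pytest.approx(1.27, abs=1e-10)
        assert res.loc["s1", "effect"] == pytest.approx(2.54, abs=1e-10)

    def test_f_test_matches_rss_oracle_on_toy_table(self):
        # fixed 12-line table; oracle computes both RSS values explicitly
        d = pd.Series([0, 0, 1, 2, 1, 0, 2, 2, 1, 0, 0, 2], dtype=float)
        y = pd.Series([1.2, 1.0, 2.1, 3.3, 1.9, 0.8, 3.6, 2.9, 2.2, 1.1, 1.4, 3.1])
        G = pd.DataFrame({"s": d.to_numpy()}, index=[f"L{i}" for i in range(12)])
        yy = pd.Series(y.to_numpy(), index=G.index)
        res = scan(G, yy).set_index("snp_id")

        n = 12
        rss_red = float(np.sum((y - y.mean()) ** 2))
        slope = np.sum((d - d.mean()) * (y - y.mean())) / np.sum((d - d.mean()) ** 2)
        inter = y.mean() - slope * d.mean()
        rss_full = float(np.sum((y - inter - slope * d) ** 2))
        f = (rss_red - rss_full) / (rss_full / (n - 2))
        p_oracle = float(stats.f.sf(f, 1, n - 2))
        assert res.loc["s", "p_value"] == pytest.approx(p_oracle, abs=1e-10)
        assert res.loc["s", "alpha"] == pytest.approx(slope, abs=1e-10)

    def test_collinear_snp_flagged_degenerate(self):
        rng = np.random.default_rng(6)
        G, y = random_design(rng, p=4)
        G["dup"] = G["s0"]
        res = scan(G, y, cofactors=["s0"]).set_index("snp_id")
        assert res.loc["dup", "degenerate"]
        assert res.loc["dup", "p_value"] == 1.0
        assert res.loc["dup", "alpha"] == 0.0
        assert not res.loc["dup", "significant"]

    def test_cofactor_tested_against_others_only(self):
        # a cofactor SNP is dropped from its own reduced model: its p must
        # equal a scan where the remaining cofactors form the background
        rng = np.random.default_rng(7)
        G, y = random_design(rng, p=5)
        res_all = scan(G, y, cofactors=["s0", "s1"]).set_index("snp_id")
        res_ref = scan(G, y, cofactors=["s1"]).set_index("snp_id")
        assert res_all.loc["s0", "p_value"] == pytest.approx(
            res_ref.loc["s0", "p_value"], abs=1e-12
        )

    def test_cofactor_window_excludes_linked_cofactors(self):
        from namqtl.nam_sim import GeneticMap

        rng = np.random.default_rng(13)
        G, y = random_design(rng, p=5)
        gmap = GeneticMap(
            pd.DataFrame(
                {
                    "snp_id": list(G.columns),
                    "chromosome": "1H",
                    "position_cm": np.arange(5) * 10.0,
                }
            )
        )
        # one-chromosome map with an oversized window: every cofactor is
        # excluded from every reduced model, so the scan equals the
        # cofactor-free scan
        res = scan(G, y, ["s0", "s3"], gmap=gmap, cofactor_window_cm=1e9)
        res0 = scan(G, y, gmap=gmap)
        np.testing.assert_allclose(res["p_value"], res0["p_value"], atol=1e-12)
        # a tight window keeps the distant cofactor in the background
        res_tight = scan(G, y, ["s0", "s3"], gmap=gmap, cofactor_window_cm=5.0)
        assert not np.allclose(res_tight["p_value"], res0["p_value"])

    def test_missing_dosages_rejected(self):
        G = pd.DataFrame({"s": [0.0, np.nan, 2.0]}, index=["a", "b", "c"])
        y = pd.Series([1.0, 2.0, 3.0], index=G.index)
        with pytest.raises(GwasError, match="impute"):
            scan(G, y)


class TestR2:
    def test_perfect_fit_gives_one(self):
        d = pd.Series([0.0, 1.0, 2.0, 1.0], index=list("abcd"))
        y = 3.0 - 2.0 * d
        assert snp_r2(d, y) == pytest.approx(1.0)

    def test_orthogonal_gives_zero(self):
        d = pd.Series([0.0, 2.0, 0.0, 2.0], index=list("abcd"))
        y = pd.Series([1.0, 1.0, -1.0, -1.0], index=list("abcd"))
        assert snp_r2(d, y) == pytest.approx(0.0, abs=1e-12)

    def test_equals_squared_pearson(self):
        rng = np.random.default_rng(8)
        d = pd.Series(rng.integers(0, 3, 40).astype(float), index=range(40))
        y = pd.Series(rng.normal(size=40), index=range(40))
        r = np.corrcoef(d, y)[0, 1]
        assert snp_r2(d, y) == pytest.approx(r * r, abs=1e-12)

    def test_constant_column_raises_or_nan(self):
        d = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(GwasError):
            snp_r2(d, y)
        assert np.isnan(snp_r2(d, y, strict=False))

    def test_joint_adjusted_r2_noiseless(self):
        rng = np.random.default_rng(9)
        G, _ = random_design(rng, p=4)
        y = pd.Series(1.0 * G["s0"] + 0.5 * G["s1"], index=G.index)
        assert multi_marker_r2_adj(G, y, ["s0", "s1"]) == pytest.approx(1.0)

    def test_joint_adjusted_r2_matches_oracle(self):
        rng = np.random.default_rng(10)
        G, y = random_design(rng, n=80, p=6)
        snps = ["s0", "s2", "s4"]
        n, k = len(y), len(snps)
        X = np.hstack([np.ones((n, 1)), G[snps].to_numpy(float)])
        beta = np.linalg.solve(X.T @ X, X.T @ y.to_numpy())
        rss = float(np.sum((y.to_numpy() - X @ beta) ** 2))
        tss = float(np.sum((y.to_numpy() - y.mean()) ** 2))
        oracle = 1.0 - (1.0 - (1.0 - rss / tss)) * (n - 1) / (n - k - 1)
        assert multi_marker_r2_adj(G, y, snps) == pytest.approx(oracle, abs=1e-12)

    def test_single_snp_limit_approaches_snp_r2(self):
        rng = np.random.default_rng(11)
        G, y = random_design(rng, n=500, p=3)
        joint = multi_marker_r2_adj(G, y, ["s0"])
        assert joint == pytest.approx(snp_r2(G["s0"], y), abs=0.01)

    def test_saturated_model_rejected(self):
        rng = np.random.default_rng(12)
        G, y = random_design(rng, n=5, p=4)
        with pytest.raises(GwasError):
            multi_marker_r2_adj(G, y, list(G.columns))


class TestCausalRecovery:
    def test_peak_near_qtl_and_sign(self, tiny_analysis):
        ds, G, blues = tiny_analysis
        cof = gwas.select_cofactors(G, blues)
        res = scan(G, blues, cof, gmap=ds.gmap, cofactor_window_cm=26.0)
        peak = res.loc[res["p_value"].idxmin()]
        assert peak["chromosome"] == "4H"
        assert abs(peak["position_cm"] - 111.3) <= 5.0
        assert res.set_index("snp_id").loc[ds.causal_snp, "alpha"] > 0
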