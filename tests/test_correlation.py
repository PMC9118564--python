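"""Stage-2 spatial correlation: oracles, invariances, Bonferroni family."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import braintmap as bt
from braintmap.correlation import MIN_PAIRS, _p_from_r
from braintmap.datatypes import EffectMap
from braintmap.errors import InputError, StatisticalError

# worked 10-element fixture with a moderate correlation
X10 = np.array([0.8, 1.9, 3.1, 4.2, 4.8, 6.1, 7.3, 7.9, 9.2, 10.1])
Y10 = np.array([0.57, 2.22, 9.54, 7.21, 8.7, 6.46, 10.47, 5.51, 4.8, 8.02])


def direct_formula_oracle(x, y):
    """Pearson r from raw sums of squares/cross-products, and its two-sided
    p by numerical integration of the t density."""
    n = len(x)
    sx, sy = x.sum(), y.sum()
    sxx, syy, sxy = (x * x).sum(), (y * y).sum(), (x * y).sum()
    r = (n * sxy - sx * sy) / np.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
    t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
    dof = n - 2

    def t_density(u):
        from scipy.special import gammaln

        return np.exp(
            gammaln((dof + 1) / 2)
            - gammaln(dof / 2)
            - 0.5 * np.log(dof * np.pi)
            - (dof + 1) / 2 * np.log1p(u**2 / dof)
        )

    from scipy.integrate import quad

    tail, _ = quad(t_density, abs(t), np.inf)
    return r, 2 * tail


class TestPearsonWithP:
    def test_identity_and_reversal(self):
        assert bt.pearson_with_p([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])["r"] == 1.0
        assert bt.pearson_with_p([1, 2, 3], [3, 2, 1])["r"] == -1.0

    def test_perfect_correlation_floors_p(self):
        res = bt.pearson_with_p([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res["p"] == 1e-300

    def test_worked_fixture_against_direct_formula(self):
        res = bt.pearson_with_p(X10, Y10)
        r, p = direct_formula_oracle(X10, Y10)
        assert res["r"] == pytest.approx(r, abs=1e-12)
        assert res["p"] == pytest.approx(p, abs=1e-12)
        assert res["n_used"] == 10

    def test_worked_fixture_against_permutation_null(self):
        """p from the t transform agrees with the permutation distribution
        of r (1e5 draws) within Monte-Carlo error."""
        res = bt.pearson_with_p(X10, Y10)
        rng = np.random.default_rng(2024)
        B = 100_000
        perms = rng.permuted(np.tile(Y10, (B, 1)), axis=1)
        xc = X10 - X10.mean()
        pc = perms - perms.mean(axis=1, keepdims=True)
        r_perm = (pc @ xc) / (
            np.sqrt(xc @ xc) * np.sqrt((pc**2).sum(axis=1))
        )
        p_emp = float((np.abs(r_perm) >= abs(res["r"]) - 1e-12).mean())
        se = np.sqrt(res["p"] * (1 - res["p"]) / B)
        assert abs(p_emp - res["p"]) <= 3 * se

    def test_pairwise_complete_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([2.0, np.nan, 3.0, 8.0, 10.0, 12.0])
        res = bt.pearson_with_p(x, y)
        assert res["n_used"] == 4
        expected = stats.pearsonr([1, 4, 5, 6], [2, 8, 10, 12])
        assert res["r"] == pytest.approx(expected.statistic, abs=1e-12)

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1.0, 2.0], [3.0, 4.0]),  # too few pairs
            ([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]),  # zero variance
            ([np.nan, np.nan, 1.0, 2.0], [1.0, 2.0, np.nan, np.nan]),
        ],
    )
    def test_unusable_inputs_flagged(self, x, y):
        res = bt.pearson_with_p(x, y)
        assert not res["usable"]
        assert np.isnan(res["r"])

    @given(
        a=st.floats(0.01, 50), b=st.floats(-100, 100),
        c=st.floats(0.01, 50), d=st.floats(-100, 100),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_affine_invariance_and_sign_flip(self, a, b, c, d):
        base = bt.pearson_with_p(X10, Y10)["r"]
        same = bt.pearson_with_p(a * X10 + b, c * Y10 + d)["r"]
        flipped = bt.pearson_with_p(-a * X10 + b, c * Y10 + d)["r"]
        assert same == pytest.approx(base, abs=1e-9)
        assert flipped == pytest.approx(-base, abs=1e-9)


class TestCorrelateGenes:
    def _toy_map(self, labels, p_values, betas=None):
        p = np.asarray(p_values, float)
        betas = np.ones_like(p) if betas is None else np.asarray(betas, float)
        table = pd.DataFrame(
            {
                "beta": betas,
                "se": np.ones_like(p),
                "t": betas,
                "p": p,
                "neglog10p": -np.log10(p),
            },
            index=pd.Index(labels, name="roi_label"),
        )
        return EffectMap(bt.DiagnosisContrast(cases=("AD",)), table)

    def test_exact_expression_match_gives_r_one(self):
        labels = [f"L_A{i}_ROI" for i in range(8)]
        p = np.array([0.5, 0.2, 0.01, 0.3, 0.001, 0.7, 0.04, 0.15])
        effmap = self._toy_map(labels, p)
        expr = bt.ExpressionMatrix(
            pd.DataFrame([-np.log10(p)], index=["G1"], columns=labels)
        )
        out = bt.correlate_genes(expr, effmap)
        assert out.loc[0, "r"] == pytest.approx(1.0, abs=1e-12)

    def test_matches_scalar_pearson_per_gene(self, small_dataset, small_effect_maps):
        expr = small_dataset[2]
        effmap = small_effect_maps[0]
        out = bt.correlate_genes(expr, effmap).set_index("gene")
        y = effmap.table.loc[expr.roi_labels, "neglog10p"].to_numpy()
        rng = np.random.default_rng(8)
        for gene in rng.choice(expr.gene_symbols, 25, replace=False):
            scalar = bt.pearson_with_p(expr.frame.loc[gene].to_numpy(), y)
            assert out.loc[gene, "r"] == pytest.approx(scalar["r"], abs=1e-10)
            assert out.loc[gene, "p"] == pytest.approx(scalar["p"], rel=1e-9)
            assert out.loc[gene, "n_used"] == scalar["n_used"]

    def test_null_genes_match_t_transform_distribution(self):
        """r values of spatially independent genes follow the null r
        density implied by the t transform (Q-Q agreement via KS)."""
        cfg = bt.SyntheticConfig(
            group_sizes={"CN": 50, "AD": 50},
            n_rois=120, n_genes=2000, n_signal_genes=0,
            effect_sizes={"EMCI": 0.0, "LMCI": 0.0, "AD": 0.0},
            expression_missing_rate=0.0, seed=13,
        )
        pheno, imaging, expr, _ = bt.generate_dataset(cfg)
        effmap = bt.effect_map(pheno, imaging, bt.DiagnosisContrast(cases=("AD",)))
        out = bt.correlate_genes(expr, effmap)
        # under the null, the correlation p values are uniform
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_no_common_rois_rejected(self, small_effect_maps):
        expr = bt.ExpressionMatrix(
            pd.DataFrame([[1.0, 2.0, 3.0]], index=["G1"],
                         columns=["L_X1_ROI", "L_X2_ROI", "L_X3_ROI"])
        )
        with pytest.raises(InputError, match="share only 0"):
            bt.correlate_genes(expr, small_effect_maps[0])

    def test_constant_gene_excluded_not_zeroed(self):
        labels = [f"L_A{i}_ROI" for i in range(6)]
        effmap = self._toy_map(labels, [0.5, 0.2, 0.01, 0.3, 0.1, 0.04])
        expr = bt.ExpressionMatrix(
            pd.DataFrame(
                [[3.0] * 6, [1, 2, 3, 4, 5, 6]], index=["CONST", "G2"],
                columns=labels,
            )
        )
        out = bt.correlate_genes(expr, effmap).set_index("gene")
        assert not out.loc["CONST", "usable"]
        assert np.isnan(out.loc["CONST", "r"])
        assert out.loc["G2", "usable"]


class TestBonferroniFamily:
    def test_identity_family(self):
        df = pd.DataFrame(
            {"gene": ["G1"], "contrast": ["CN_vs_AD"], "r": [0.5],
             "n_used": [100], "p": [0.01], "usable": [True]}
        )
        adj, family = bt.bonferroni_family(df, alpha=0.05)
        assert family == 1
        assert adj["p_adjusted"].iloc[0] == pytest.approx(0.01)

    def test_cap_at_one(self):
        df = pd.DataFrame(
            {"gene": [f"G{i}" for i in range(10)],
             "contrast": ["CN_vs_AD"] * 10, "r": [0.1] * 10,
             "n_used": [100] * 10, "p": [0.2] * 10, "usable": [True] * 10}
        )
        adj, family = bt.bonferroni_family(df, alpha=0.05)
        assert family == 10
        assert (adj["p_adjusted"] == 1.0).all()

    def test_family_counts_only_usable_tests(self):
        df = pd.DataFrame(
            {"gene": ["G1", "G2", "G3"], "contrast": ["CN_vs_AD"] * 3,
             "r": [0.5, np.nan, 0.4], "n_used": [100, 2, 100],
             "p": [0.001, np.nan, 0.002], "usable": [True, False, True]}
        )
        adj, family = bt.bonferroni_family(df, alpha=0.05)
        assert family == 2
        assert len(adj) == 2

    def test_empty_family_rejected(self):
        with pytest.raises(StatisticalError):
            bt.bonferroni_family(pd.DataFrame(), alpha=0.05)

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=30))
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_adjusted_p_monotone_and_never_below_raw(self, ps):
        df = pd.DataFrame(
            {"gene": [f"G{i}" for i in range(len(ps))],
             "contrast": ["CN_vs_AD"] * len(ps), "r": [0.1] * len(ps),
             "n_used": [50] * len(ps), "p": ps, "usable": [True] * len(ps)}
        )
        adj, _ = bt.bonferroni_family(df, alpha=0.05)
        merged = adj.sort_values("p")
        assert (merged["p_adjusted"].to_numpy() >= merged["p"].to_numpy()).all()
        assert (np.diff(merged["p_adjusted"].to_numpy()) >= -1e-15).all()


class TestIntersectionAndPartition:
    def _adjusted(self, rows):
        return pd.DataFrame(
            rows, columns=["gene", "contrast", "significant"]
        ).assign(r=0.5, n_used=100, p=0.001, p_adjusted=0.01)

    def test_all_contrast_gene_included_partial_excluded(self):
        contrasts = [c.name for c in bt.build_contrasts()]
        rows = [("G1", c, True) for c in contrasts]
        rows += [("G2", c, c != "CN_vs_AD") for c in contrasts]
        out = bt.intersect_across_contrasts(self._adjusted(rows))
        assert out == ["G1"]

    def test_intersection_subset_of_every_contrast(self, small_dataset, small_effect_maps):
        expr = small_dataset[2]
        res = bt.SpatialCorrelationModel(expr, small_effect_maps).fit()
        inter = set(res.intersection())
        for c in res.contrasts:
            assert inter <= res.significant_genes(c)

    def test_partition_membership_and_case(self):
        known = bt.GeneSet(["AQP9"])
        k, n = bt.partition_by_annotation(["AQP9", "SPRN"], known)
        assert (k, n) == (["AQP9"], ["SPRN"])
        k, n = bt.partition_by_annotation(["aqp9".upper(), "SPRN"], bt.GeneSet(["aqp9"]))
        assert k == ["AQP9"]

    def test_empty_known_set_all_novel(self):
        k, n = bt.partition_by_annotation(["B1", "A2"], bt.GeneSet())
        assert k == []
        assert n == ["A2", "B1"]


def test_signed_target_flips_with_beta_sign():
    labels = [f"L_A{i}_ROI" for i in range(8)]
    p = np.array([0.5, 0.2, 0.01, 0.3, 0.001, 0.7, 0.04, 0.15])
    betas = np.array([1, -1, 1, -1, 1, -1, 1, -1], float)
    table = pd.DataFrame(
        {"beta": betas, "se": 1.0, "t": betas, "p": p, "neglog10p": -np.log10(p)},
        index=pd.Index(labels, name="roi_label"),
    )
    effmap = EffectMap(bt.DiagnosisContrast(cases=("AD",)), table)
    expr = bt.ExpressionMatrix(
        pd.DataFrame([betas * -np.log10(p)], index=["G1"], columns=labels)
    )
    unsigned = bt.correlate_genes(expr, effmap, target="neglog10p")
    signed = bt.correlate_genes(expr, effmap, target="signed")
    assert signed.loc[0, "r"] == pytest.approx(1.0, abs=1e-12)
    assert unsigned.loc[0, "r"] < 1.0
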