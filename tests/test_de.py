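"""Unit, oracle and property tests for the NB differential expression stack."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import statsmodels.api as sm

from conftest import blocked_labels, make_count_matrix
from elastomics.de import (
    CountMatrix,
    bh_adjust,
    design_matrix,
    estimate_dispersion,
    fit_nb_glm,
    loo_stable_genes,
    run_de,
    size_factors,
    transform_counts,
    wald_test,
)
from elastomics.simulate import SimulationConfig, simulate_counts


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        sf = size_factors(counts)
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubled_sample_gets_doubled_factor(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        sf = size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0)

    def test_hand_computed_median_of_ratios(self):
        # genes x samples; geometric means (2, 6, 50); per-sample ratio
        # medians computed by hand, then rescaled to geometric mean 1
        counts = pd.DataFrame({"s1": [1, 4, 25], "s2": [4, 9, 100]})
        gm = np.array([2.0, 6.0, 50.0])
        raw = np.array(
            [np.median(counts["s1"] / gm), np.median(counts["s2"] / gm)]
        )
        expected = raw / np.exp(np.mean(np.log(raw)))
        sf = size_factors(counts)
        assert np.allclose(sf, expected)

    def test_no_common_gene_errors_and_pseudo_reference_works(self):
        counts = pd.DataFrame({"s1": [5, 0], "s2": [0, 7]})
        with pytest.raises(ValueError, match="pseudo_reference"):
            size_factors(counts)
        sf = size_factors(counts, pseudo_reference=True)
        assert (sf > 0).all()


class TestDispersion:
    def _fixture(self, alpha, n=50, seed=0):
        rng = np.random.default_rng(seed)
        mu = rng.uniform(20, 200, 300)
        if alpha == 0:
            counts = rng.poisson(mu[:, None], (300, n))
        else:
            lam = rng.gamma(1 / alpha, alpha * mu[:, None], (300, n))
            counts = rng.poisson(lam)
        df = pd.DataFrame(counts, columns=[f"s{j}" for j in range(n)])
        X = np.ones((n, 1))
        sf = pd.Series(np.ones(n), index=df.columns)
        return df, sf, X

    def test_poisson_genes_get_small_alpha(self):
        df, sf, X = self._fixture(alpha=0)
        disp = estimate_dispersion(df, sf, X)
        assert disp["dispersion"].median() < 0.05

    def test_nb_alpha_recovered_within_band(self):
        df, sf, X = self._fixture(alpha=0.2)
        disp = estimate_dispersion(df, sf, X)
        assert 0.1 <= disp["dispersion"].median() <= 0.4

    def test_constant_gene_falls_back_to_trend(self):
        df, sf, X = self._fixture(alpha=0.1)
        df.iloc[0] = 7  # zero-variance gene
        disp = estimate_dispersion(df, sf, X)
        assert bool(disp["trend_fallback"].iloc[0])
        assert disp["dispersion"].iloc[0] > 0


class TestNBGLM:
    def test_flat_counts_give_zero_fold_change(self):
        labels = blocked_labels(2, 4)
        meta = pd.DataFrame(
            {"patient_id": [v[0] for v in labels.values()],
             "mre_label": [v[1] for v in labels.values()]},
            index=list(labels),
        )
        X, names, li = design_matrix(meta)
        y = np.full((1, len(meta)), 50.0)
        fit = fit_nb_glm(y, X, np.ones(len(meta)), np.array([0.1]), names, li)
        assert fit.label_log2fc[0] == pytest.approx(0.0, abs=1e-9)

    def test_recovers_planted_log2fc(self):
        rng = np.random.default_rng(3)
        n = 16
        labels = np.tile([1, 0], n // 2)
        X = np.column_stack([np.ones(n), labels])
        alpha = 0.1
        mu = 100 * 2.0 ** labels  # true log2FC = 1
        G = 200
        lam = rng.gamma(1 / alpha, alpha * np.tile(mu, (G, 1)))
        counts = rng.poisson(lam)
        fit = fit_nb_glm(counts, X, np.ones(n), np.full(G, alpha), label_index=1)
        est = fit.label_log2fc
        assert abs(est[0] - 1.0) < 0.5
        assert abs(est.mean() - 1.0) < 0.1

    def test_matches_statsmodels_negative_binomial(self):
        rng = np.random.default_rng(4)
        labels = blocked_labels(3, 4)
        meta = pd.DataFrame(
            {"patient_id": [v[0] for v in labels.values()],
             "mre_label": [v[1] for v in labels.values()]},
            index=list(labels),
        )
        X, names, li = design_matrix(meta)
        sf = np.exp(rng.normal(0, 0.2, len(meta)))
        alpha = 0.15
        counts = rng.poisson(
            rng.gamma(1 / alpha, alpha * 80.0, (3, len(meta))) * sf
        )
        fit = fit_nb_glm(counts, X, sf, np.full(3, alpha), names, li)
        for g in range(3):
            ref = sm.GLM(
                counts[g], X, family=sm.families.NegativeBinomial(alpha=alpha),
                offset=np.log(sf),
            ).fit()
            assert np.allclose(fit.coef[g], ref.params, atol=1e-5)
            assert np.allclose(fit.se[g], ref.bse, atol=1e-4)

    def test_poisson_limit_matches_poisson_glm(self):
        rng = np.random.default_rng(5)
        n = 12
        X = np.column_stack([np.ones(n), np.tile([0, 1], n // 2)])
        counts = rng.poisson(60, (1, n))
        fit = fit_nb_glm(counts, X, np.ones(n), np.array([1e-8]), label_index=1)
        ref = sm.GLM(counts[0], X, family=sm.families.Poisson()).fit()
        assert np.allclose(fit.coef[0], ref.params, atol=1e-6)


class TestWald:
    def _fit(self, coef, se):
        from elastomics.de import NBFit

        return NBFit(
            coef=np.array([[0.0, coef]]),
            se=np.array([[1.0, se]]),
            converged=np.array([True]),
            term_names=["intercept", "label[stiff]"],
            label_index=1,
        )

    def test_zero_coefficient_gives_p_one(self):
        assert wald_test(self._fit(0.0, 1.0))["pvalue"][0] == pytest.approx(1.0)

    def test_z_196_gives_p_005(self):
        p = wald_test(self._fit(1.959964, 1.0))["pvalue"][0]
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_zero_se_flagged(self):
        res = wald_test(self._fit(1.0, 0.0))
        assert not res["tested"][0] and np.isnan(res["pvalue"][0])


def bh_oracle(p):
    """Brute-force step-up BH."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


class TestBH:
    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_adjust([0.3, 0.3, 0.3]), 0.3)

    def test_hand_case(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), 0.04)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None)
    def test_matches_brute_force_and_bounds(self, p):
        adj = bh_adjust(p)
        assert np.allclose(adj, bh_oracle(p))
        assert (adj >= np.asarray(p) - 1e-12).all() and (adj <= 1.0).all()


class TestRunDE:
    def test_planted_genes_recovered(self, planted_counts):
        cm, truth = planted_counts
        res = run_de(cm)
        sig = set(res.index[res["padj"] < 0.05])
        planted = set(truth.signature_gene_ids)
        assert len(sig & planted) / len(planted) >= 0.7

    def test_label_swap_negates_fold_changes(self, planted_counts):
        cm, _ = planted_counts
        res_a = run_de(cm)
        flipped = cm.metadata.copy()
        flipped["mre_label"] = flipped["mre_label"].map(
            {"stiff": "soft", "soft": "stiff"}
        )
        res_b = run_de(CountMatrix(cm.counts.copy(), flipped))
        both = res_a["tested"] & res_b["tested"]
        assert np.allclose(
            res_a.loc[both, "log2FoldChange"],
            -res_b.loc[both, "log2FoldChange"],
            atol=1e-6,
        )
        assert np.allclose(
            res_a.loc[both, "pvalue"], res_b.loc[both, "pvalue"], atol=1e-8
        )

    def test_patient_missing_a_label_is_an_error(self):
        counts = np.full((5, 4), 10)
        cm_bad_meta = pd.DataFrame(
            {"patient_id": ["a", "a", "b", "b"],
             "mre_label": ["stiff", "soft", "soft", "soft"]},
            index=[f"s{j}" for j in range(4)],
        )
        cm = CountMatrix(
            pd.DataFrame(counts, columns=cm_bad_meta.index), cm_bad_meta
        )
        with pytest.raises(ValueError, match="lacking both"):
            run_de(cm)


class TestLOOStability:
    def test_single_patient_driven_gene_excluded(self):
        cfg = SimulationConfig(n_genes=400, n_signature_genes=20, rng_seed=21)
        cm, truth = simulate_counts(blocked_labels(6, 4), cfg, np.random.default_rng(21))
        # plant a gene whose stiff/soft difference lives only in patient P0
        counts = cm.counts.copy()
        p0_stiff = cm.metadata.index[
            (cm.metadata["patient_id"] == "P0") & (cm.metadata["mre_label"] == "stiff")
        ]
        driven = counts.index[0]
        assert driven not in truth.signature_gene_ids
        counts.loc[driven, p0_stiff] = counts.loc[driven, p0_stiff] * 60 + 500
        cm2 = CountMatrix(counts, cm.metadata.copy())
        full = run_de(cm2)
        stable = loo_stable_genes(cm2)
        if full.loc[driven, "padj"] < 0.05:  # the gene is findable on full data
            assert driven not in stable.genes

    def test_stable_set_within_full_significant_set(self, planted_counts):
        cm, _ = planted_counts
        full = run_de(cm)
        stable = loo_stable_genes(cm)
        sig = set(full.index[full["padj"] < 0.05])
        # dominance: stable genes are found in (nearly) every context; allow
        # the odd borderline gene that dips in/out at the threshold
        overlap = len(set(stable.genes) & sig) / max(len(stable.genes), 1)
        assert overlap >= 0.9

    def test_patient_order_permutation_invariant(self, planted_counts):
        cm, _ = planted_counts
        stable_a = loo_stable_genes(cm)
        perm = list(cm.counts.columns)[::-1]
        stable_b = loo_stable_genes(cm.subset_samples(perm))
        assert stable_a.stiff_associated == stable_b.stiff_associated
        assert stable_a.soft_associated == stable_b.soft_associated

    def test_needs_three_patients(self):
        cm = make_count_matrix(
            np.full((3, 4), 9),
            ["a", "a", "b", "b"],
            ["stiff", "soft", "stiff", "soft"],
        )
        with pytest.raises(ValueError, match=">= 3 patients"):
            loo_stable_genes(cm)


class TestTransformCounts:
    def test_values(self):
        counts = pd.DataFrame({"s1": [0, 3]})
        sf = pd.Series([1.0], index=["s1"])
        out = transform_counts(counts, sf)
        assert out["s1"].tolist() == [0.0, 2.0]

    def test_joint_doubling_invariance(self):
        counts = pd.DataFrame({"s1": [4, 8], "s2": [2, 6]})
        sf = pd.Series([1.0, 0.5], index=["s1", "s2"])
        a = transform_counts(counts, sf)
        b = transform_counts(counts * 2, sf * 2)
        assert np.allclose(a, b)
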