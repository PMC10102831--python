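"""Tests for the synthetic cohort generator against its declared truth."""

import math

import numpy as np
import pytest

from elastomics import mre
from elastomics.mre import StiffnessVolume
from elastomics.simulate import (
    SimulationConfig,
    place_biopsies,
    simulate_cohort,
    simulate_counts,
    simulate_external_cohort,
    simulate_stiffness_volume,
)
from elastomics.survival import cox_fit


def quiet_config(**kw):
    """No noise, no heterogeneity: habitat means are exact."""
    base = dict(intra_habitat_sd=0.0, smoothness_sigma=0.0,
                nawm_stiffness_kpa=(2.7, 0.0), nawm_phase_rad=(0.85, 0.0))
    base.update(kw)
    return SimulationConfig(**base)


class TestVolumes:
    def test_habitat_means_match_configured_factors(self):
        cfg = quiet_config()
        vol = simulate_stiffness_volume(cfg, 0, np.random.default_rng(0))
        nawm = mre.nawm_reference_mean(vol)
        for name, lab in (("CE", mre.CE), ("necrosis", mre.NECROSIS), ("FLAIR", mre.FLAIR)):
            ratio = vol.gstar[vol.segmentation == lab].mean() / nawm
            assert ratio == pytest.approx(cfg.habitat_stiffness_factors[name], abs=1e-9)
        for name, lab in (("CE", mre.CE), ("necrosis", mre.NECROSIS), ("FLAIR", mre.FLAIR)):
            ratio = vol.phi[vol.segmentation == lab].mean() / mre.nawm_reference_mean(vol, "phi")
            assert ratio == pytest.approx(cfg.habitat_phase_factors[name], abs=1e-9)

    def test_noisy_habitat_means_within_monte_carlo_tolerance(self):
        cfg = SimulationConfig(intra_habitat_sd=0.0, smoothness_sigma=0.0)
        vol = simulate_stiffness_volume(cfg, 0, np.random.default_rng(1))
        sd = cfg.nawm_stiffness_kpa[1]
        for name, lab in (("CE", mre.CE), ("necrosis", mre.NECROSIS)):
            mask = vol.segmentation == lab
            mean = vol.gstar[mask].mean()
            expected = cfg.nawm_stiffness_kpa[0] * cfg.habitat_stiffness_factors[name]
            tol = 3 * sd / math.sqrt(mask.sum())
            assert abs(mean - expected) < tol + 1e-9

    def test_unit_factors_no_noise_gives_constant_foreground(self):
        cfg = quiet_config(
            habitat_stiffness_factors={"NAWM-GM": 1.0, "FLAIR": 1.0, "CE": 1.0, "necrosis": 1.0},
        )
        vol = simulate_stiffness_volume(cfg, 0, np.random.default_rng(2))
        fg = vol.segmentation != mre.BACKGROUND
        assert np.unique(vol.gstar[fg]).size == 1

    def test_fixed_seed_bit_identical(self):
        cfg = SimulationConfig()
        a = simulate_stiffness_volume(cfg, 0, np.random.default_rng(3))
        b = simulate_stiffness_volume(cfg, 0, np.random.default_rng(3))
        assert np.array_equal(a.gstar, b.gstar)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.segmentation, b.segmentation)

    def test_grid_too_small_errors(self):
        with pytest.raises(ValueError, match="too small|within"):
            cfg = SimulationConfig(grid_shape=(4, 4, 2))
            simulate_stiffness_volume(cfg, 0, np.random.default_rng(4))

    def test_segmentation_partitions_grid_and_contralateral_nonempty(self):
        vol = simulate_stiffness_volume(SimulationConfig(), 0, np.random.default_rng(5))
        labels = set(np.unique(vol.segmentation))
        assert labels <= {0, 1, 2, 3, 4, 5}
        assert mre.contralateral_nawm_mask(vol).sum() > 0


class TestBiopsies:
    def test_count_membership_distinct(self):
        vol = simulate_stiffness_volume(SimulationConfig(), 0, np.random.default_rng(6))
        samples = place_biopsies(vol, 3, np.random.default_rng(7))
        assert len(samples) == 3
        seeds = {s.seed_voxel for s in samples}
        assert len(seeds) == 3
        for s in samples:
            assert int(vol.segmentation[s.seed_voxel]) in (3, 4, 5)
            assert s.radiological_class in ("CE", "necrosis", "FLAIR")

    def test_exhaustion_takes_all_eligible_voxels(self):
        # volume with exactly three interior FLAIR voxels
        shape = (12, 12, 6)
        seg = np.ones(shape, dtype=np.int16)
        seg[5, 5, 2] = seg[5, 6, 2] = seg[6, 5, 2] = 3
        vol = StiffnessVolume(
            np.full(shape, 2.0), np.full(shape, 0.8), seg, (3.1, 3.1, 3.1), "E"
        )
        samples = place_biopsies(vol, 3, np.random.default_rng(8))
        assert {s.seed_voxel for s in samples} == {(5, 5, 2), (5, 6, 2), (6, 5, 2)}
        with pytest.raises(ValueError, match="eligible"):
            place_biopsies(vol, 4, np.random.default_rng(8))

    def test_seeded_runs_identical(self):
        vol = simulate_stiffness_volume(SimulationConfig(), 0, np.random.default_rng(9))
        a = place_biopsies(vol, 5, np.random.default_rng(10))
        b = place_biopsies(vol, 5, np.random.default_rng(10))
        assert [s.seed_voxel for s in a] == [s.seed_voxel for s in b]


class TestCohort:
    def test_every_patient_has_two_to_seven_labeled_biopsies(self):
        cfg = SimulationConfig(n_patients=5, rng_seed=12)
        _, samples = simulate_cohort(cfg)
        by_pat = {}
        for s in samples:
            by_pat.setdefault(s.patient_id, []).append(s)
        assert len(by_pat) == 5
        for pid, ss in by_pat.items():
            assert 2 <= len(ss) <= 7
            labels = {s.mre_label for s in ss}
            assert labels == {"stiff", "soft"}

    def test_heterogeneity_ratio_near_printed_median(self):
        # cohort median of per-patient max/min ratios targets ~1.6
        medians = []
        for seed in range(25):
            cfg = SimulationConfig(rng_seed=seed)
            _, samples = simulate_cohort(cfg)
            by_pat = {}
            for s in samples:
                by_pat.setdefault(s.patient_id, []).append(s)
            medians.append(mre.heterogeneity_ratio(by_pat).cohort_median)
        assert abs(float(np.median(medians)) - 1.6) < 0.2


def blocked(n_pat, n_b):
    return {
        f"P{p}_s{b}": (f"P{p}", "stiff" if b == 0 else "soft")
        for p in range(n_pat)
        for b in range(n_b)
    }


class TestCounts:
    def test_planted_group_ratio_near_two_at_log2fc_one(self):
        # many samples, no nuisance variation: realized stiff/soft mean
        # ratio of a planted gene converges to 2^log2fc
        cfg = SimulationConfig(
            n_genes=50, n_signature_genes=10, signature_log2fc=1.0,
            patient_effect_sd=0.0, library_size_sd=0.0, rng_seed=13,
        )
        labels = {}
        for p in range(2):
            for b in range(400):
                labels[f"P{p}_s{b}"] = (f"P{p}", "stiff" if b % 2 == 0 else "soft")
        cm, truth = simulate_counts(labels, cfg, np.random.default_rng(13))
        stiff = cm.metadata["mre_label"] == "stiff"
        up_genes = [g for g, fc in truth.per_gene_log2fc.items() if fc > 0]
        ratios = []
        for g in up_genes:
            row = cm.counts.loc[g]
            ratios.append(row[stiff.to_numpy()].mean() / row[(~stiff).to_numpy()].mean())
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.1)

    def test_null_configuration_has_empty_truth(self):
        cfg = SimulationConfig(n_genes=100, n_signature_genes=0, rng_seed=14)
        _, truth = simulate_counts(blocked(3, 3), cfg, np.random.default_rng(14))
        assert truth.signature_gene_ids == []
        assert all(v == 0 for v in truth.per_gene_log2fc.values())

    def test_poisson_limit_variance_over_mean_near_one(self):
        cfg = SimulationConfig(
            n_genes=200, n_signature_genes=0, rng_seed=15,
            dispersion_trend=(1e-10, 0.0), patient_effect_sd=0.0, library_size_sd=0.0,
        )
        labels = {f"P0_s{b}": ("P0", "stiff" if b % 2 else "soft") for b in range(200)}
        labels.update({f"P1_s{b}": ("P1", "stiff" if b % 2 else "soft") for b in range(4)})
        cm, _ = simulate_counts(labels, cfg, np.random.default_rng(15))
        p0 = cm.counts.loc[:, [s for s in cm.counts.columns if s.startswith("P0")]]
        ratio = (p0.var(axis=1) / p0.mean(axis=1)).median()
        assert ratio == pytest.approx(1.0, abs=0.15)

    def test_counts_are_nonnegative_integers_and_deterministic(self):
        cfg = SimulationConfig(n_genes=80, n_signature_genes=8, rng_seed=16)
        a, _ = simulate_counts(blocked(3, 3), cfg, np.random.default_rng(16))
        b, _ = simulate_counts(blocked(3, 3), cfg, np.random.default_rng(16))
        assert (a.counts.to_numpy() >= 0).all()
        assert np.issubdtype(a.counts.to_numpy().dtype, np.integer)
        assert a.counts.equals(b.counts)

    def test_single_patient_rejected(self):
        cfg = SimulationConfig(n_genes=10, n_signature_genes=2, rng_seed=17)
        with pytest.raises(ValueError, match="2 patients"):
            simulate_counts(blocked(1, 4), cfg, np.random.default_rng(17))


class TestExternalCohort:
    def test_large_sample_recovers_log_hazard_ratio(self):
        cfg = SimulationConfig(
            n_genes=5, n_signature_genes=2, external_n=10_000,
            censoring_rate=0.0, rng_seed=19,
        )
        _, cohort, truth = simulate_external_cohort(cfg, rng=np.random.default_rng(19))
        # fit on the true classes
        fit = cox_fit(cohort)
        beta = fit.loc["signature[signal]", "beta"]
        assert beta == pytest.approx(math.log(1.45), abs=0.05)

    def test_no_censoring_all_events(self):
        cfg = SimulationConfig(n_genes=5, n_signature_genes=2, external_n=50, censoring_rate=0.0, rng_seed=19)
        _, cohort, _ = simulate_external_cohort(cfg, rng=np.random.default_rng(19))
        assert (cohort.table["event"] == 1).all()

    def test_null_hazard_gives_small_effect(self):
        cfg = SimulationConfig(
            n_genes=5, n_signature_genes=2, external_n=3000, true_log_hr=0.0,
            censoring_rate=0.0, rng_seed=20,
        )
        _, cohort, _ = simulate_external_cohort(cfg, rng=np.random.default_rng(20))
        beta = cox_fit(cohort).loc["signature[signal]", "beta"]
        assert abs(beta) < 0.12

    def test_censoring_rate_roughly_respected(self):
        cfg = SimulationConfig(n_genes=5, n_signature_genes=2, external_n=2000, censoring_rate=0.3, rng_seed=21)
        _, cohort, _ = simulate_external_cohort(cfg, rng=np.random.default_rng(21))
        frac_censored = 1.0 - cohort.table["event"].mean()
        assert frac_censored == pytest.approx(0.3, abs=0.07)

    def test_small_cohort_rejected(self):
        cfg = SimulationConfig(n_genes=5, n_signature_genes=2, external_n=265, rng_seed=22)
        cfg.external_n = 10
        with pytest.raises(ValueError, match="external_n"):
            simulate_external_cohort(cfg, rng=np.random.default_rng(22))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"biopsies_per_patient_range": (1, 7)},
            {"biopsies_per_patient_range": (2, 9)},
            {"censoring_rate": 1.0},
            {"n_signature_genes": 999999},
            {"habitat_stiffness_factors": {"CE": -0.5}},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)
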