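"""Synthetic cohort generator with known ground truth.

Emulates the statistical structure of an MRE-plus-biopsy-transcriptomics
glioblastoma study so the whole pipeline is testable without external
downloads: per-patient stiffness/phase volumes with a nested-habitat
segmentation, image-localized biopsies, negative-binomially distributed
counts with patient effects and a planted stiffness-associated gene
program, toy gene-set collections, and an external expression cohort with
proportional-hazards survival times.

Study conditions encoded in the defaults: 13 patients with 2-7 biopsies
each; contrast-enhancing tumor 20% and necrosis 30% softer than
normal-appearing white matter; phase angle reduced by 10% / 8% / 15% in
CE / necrosis / FLAIR habitats; a cohort median max/min biopsy stiffness
ratio near 1.6; an external cohort of 265 subjects of whom ~24% carry the
expression signal, with a true hazard ratio of 1.45 for carriers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from . import mre
from .de import CountMatrix
from .mre import BiopsySample, StiffnessVolume, BIOPSY_HABITATS, SOFT, STIFF


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort, with study-condition defaults."""

    n_patients: int = 13
    biopsies_per_patient_range: tuple[int, int] = (2, 7)
    grid_shape: tuple[int, int, int] = (48, 48, 20)
    voxel_size_mm: tuple[float, float, float] = (3.1, 3.1, 3.1)
    nawm_stiffness_kpa: tuple[float, float] = (2.7, 0.35)  # mean, voxel sd
    nawm_phase_rad: tuple[float, float] = (0.85, 0.08)
    habitat_stiffness_factors: Mapping[str, float] = field(
        default_factory=lambda: {"NAWM-GM": 0.9, "FLAIR": 1.0, "CE": 0.8, "necrosis": 0.7}
    )
    habitat_phase_factors: Mapping[str, float] = field(
        default_factory=lambda: {"NAWM-GM": 1.0, "FLAIR": 0.85, "CE": 0.9, "necrosis": 0.92}
    )
    #: log-scale sd of the smooth multiplicative within-habitat stiffness
    #: field (sets the spread of biopsy values, hence the max/min ratio)
    intra_habitat_sd: float = 0.28
    #: Gaussian smoothing (voxels) of noise and heterogeneity fields; the
    #: spatial autocorrelation of stiffness within habitats is a free knob
    smoothness_sigma: float = 1.0
    #: correlation knob between surgeon grade and |G*|_norm (0 = none)
    surgeon_grade_correlation: float = 0.0

    n_genes: int = 2000
    n_signature_genes: int = 100
    signature_log2fc: float = 2.0
    signature_stiff_fraction: float = 0.8  # fraction of planted genes up in stiff
    baseline_log_mean: tuple[float, float] = (4.0, 1.5)  # natural-log mean, sd
    nb_dispersion_shape: float = 4.0
    dispersion_trend: tuple[float, float] = (0.05, 1.0)  # a0 + a1/mu
    patient_effect_sd: float = 0.3
    library_size_sd: float = 0.25

    external_n: int = 265
    carrier_fraction: float = 63.0 / 265.0
    true_log_hr: float = math.log(1.45)
    baseline_median_days: float = 460.0
    censoring_rate: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.biopsies_per_patient_range
        if self.n_patients < 1 or self.n_genes < 1:
            raise ValueError("counts must be >= 1")
        if not (2 <= lo <= hi <= 7):
            raise ValueError("biopsies_per_patient_range must lie within [2, 7]")
        if any(f <= 0 for f in self.habitat_stiffness_factors.values()):
            raise ValueError("habitat multipliers must be positive")
        if any(f <= 0 for f in self.habitat_phase_factors.values()):
            raise ValueError("habitat multipliers must be positive")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        if not (0 <= self.n_signature_genes <= self.n_genes):
            raise ValueError("n_signature_genes must be in [0, n_genes]")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort."""

    signature_gene_ids: list[str]
    per_gene_log2fc: dict[str, float]
    biopsy_true_labels: dict[str, str] = field(default_factory=dict)
    external_true_classes: dict[str, str] = field(default_factory=dict)
    true_log_hr: float | None = None
    seeds_used: list[int] = field(default_factory=list)


# --------------------------------------------------------------------------
# geometry / volumes

def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def _habitat_geometry(shape: Sequence[int]) -> np.ndarray:
    """Nested axis-aligned ellipsoid habitats in one hemisphere.

    Brain = large ellipsoid; its outer shell is gray matter, the interior
    white matter.  The tumor (FLAIR > CE > necrosis, nested) sits in the
    +i hemisphere, leaving the mirror hemisphere as contralateral NAWM.
    """
    shape = tuple(int(s) for s in shape)
    seg = np.zeros(shape, dtype=np.int16)
    center = tuple((s - 1) / 2.0 for s in shape)
    brain_r = tuple(0.46 * s for s in shape)
    inner_r = tuple(0.85 * r for r in brain_r)
    brain = _ellipsoid(shape, center, brain_r)
    inner = _ellipsoid(shape, center, inner_r)
    seg[brain] = mre.NAWM_GM
    seg[inner] = mre.NAWM_WM

    tcenter = (center[0] + 0.45 * inner_r[0], center[1], center[2])
    flair_r = tuple(0.48 * r for r in inner_r)
    ce_r = tuple(0.7 * r for r in flair_r)
    nec_r = tuple(0.55 * r for r in ce_r)
    for mask_r, label in ((flair_r, mre.FLAIR), (ce_r, mre.CE), (nec_r, mre.NECROSIS)):
        m = _ellipsoid(shape, tcenter, mask_r) & inner
        if not m.any():
            raise ValueError(
                f"grid {shape} too small to embed nested habitats (radii {mask_r})"
            )
        seg[m] = label
    for label in (mre.FLAIR, mre.CE, mre.NECROSIS):
        if not (seg == label).any():
            raise ValueError(f"grid {shape} too small: habitat {label} empty")
    return seg


def _heterogeneity_field(shape, sd_log, sigma, rng) -> np.ndarray:
    """Smooth multiplicative lognormal field with unit scale."""
    if sd_log <= 0:
        return np.ones(shape)
    raw = rng.standard_normal(shape)
    if sigma > 0:
        raw = gaussian_filter(raw, sigma=sigma)
    sdr = raw.std()
    if sdr > 0:
        raw = raw / sdr * sd_log
    return np.exp(raw)


def simulate_stiffness_volume(
    config: SimulationConfig, patient_index: int, rng: np.random.Generator
) -> StiffnessVolume:
    """One patient's |G*| / phi / segmentation grids.

    Habitat means of |G*| and phi equal the NAWM mean times the configured
    multiplier (the within-habitat heterogeneity field is re-centered per
    habitat, so habitat means are preserved exactly in expectation).
    """
    seg = _habitat_geometry(config.grid_shape)
    g_mean, g_sd = config.nawm_stiffness_kpa
    p_mean, p_sd = config.nawm_phase_rad

    gfac = {mre.NAWM_WM: 1.0}
    pfac = {mre.NAWM_WM: 1.0}
    for lab, name in mre.HABITAT_NAMES.items():
        if name in config.habitat_stiffness_factors:
            gfac[lab] = float(config.habitat_stiffness_factors[name])
        if name in config.habitat_phase_factors:
            pfac[lab] = float(config.habitat_phase_factors[name])

    gstar = np.full(seg.shape, g_mean, dtype=float)
    phi = np.full(seg.shape, p_mean, dtype=float)
    het = _heterogeneity_field(seg.shape, config.intra_habitat_sd, config.smoothness_sigma, rng)
    for lab in mre.HABITAT_NAMES:
        mask = seg == lab
        if not mask.any():
            continue
        mult = np.ones(mask.sum())
        if lab in (mre.FLAIR, mre.CE, mre.NECROSIS):
            mult = het[mask] / het[mask].mean()  # re-centered per habitat
        gstar[mask] = g_mean * gfac.get(lab, 1.0) * mult
        phi[mask] = p_mean * pfac.get(lab, 1.0)

    noise_g = rng.standard_normal(seg.shape)
    noise_p = rng.standard_normal(seg.shape)
    if config.smoothness_sigma > 0 and g_sd > 0:
        for noise in (noise_g, noise_p):
            sm = gaussian_filter(noise, sigma=config.smoothness_sigma)
            sdr = sm.std()
            noise[...] = sm / sdr if sdr > 0 else sm
    gstar = gstar + g_sd * noise_g
    phi = phi + p_sd * noise_p

    fg = seg != mre.BACKGROUND
    gstar[fg] = np.clip(gstar[fg], 0.05, None)
    phi[fg] = np.clip(phi[fg], 0.02, np.pi / 2 - 0.02)
    gstar[~fg] = 0.0
    phi[~fg] = 0.01

    return StiffnessVolume(
        gstar=gstar,
        phi=phi,
        segmentation=seg,
        voxel_size_mm=config.voxel_size_mm,
        patient_id=f"P{patient_index + 1:02d}",
    )


def place_biopsies(
    volume: StiffnessVolume, n_biopsies: int, rng: np.random.Generator
) -> list[BiopsySample]:
    """Sample distinct biopsy seed voxels inside the tumor habitats.

    Seeds are drawn from CE, necrosis and FLAIR voxels whose 3x3 in-plane
    ROI stays inside the grid; each sample records its radiological class
    from the segmentation label at the seed.
    """
    seg = volume.segmentation
    eligible = np.argwhere(np.isin(seg, list(BIOPSY_HABITATS)))
    # keep seeds whose ROI neighborhood is interior
    shape = seg.shape
    ok = (
        (eligible[:, 0] >= 1) & (eligible[:, 0] < shape[0] - 1)
        & (eligible[:, 1] >= 1) & (eligible[:, 1] < shape[1] - 1)
    )
    eligible = eligible[ok]
    if n_biopsies > len(eligible):
        raise ValueError(
            f"requested {n_biopsies} biopsies but only {len(eligible)} eligible voxels"
        )
    pick = rng.choice(len(eligible), size=n_biopsies, replace=False)
    samples = []
    for b, row in enumerate(eligible[pick]):
        seed = tuple(int(v) for v in row)
        samples.append(
            BiopsySample(
                patient_id=volume.patient_id,
                sample_id=f"{volume.patient_id}_s{b + 1}",
                seed_voxel=seed,
                radiological_class=BIOPSY_HABITATS[int(seg[seed])],
                surgeon_grade=int(rng.integers(1, 4)),
            )
        )
    return samples


# --------------------------------------------------------------------------
# expression

def _gene_params(config: SimulationConfig):
    """Per-gene baselines, dispersions and the planted signature.

    Derived from ``config.rng_seed`` alone so the biopsy cohort and the
    external cohort share one gene universe.
    """
    rng = np.random.default_rng([config.rng_seed, 7_919])
    gene_ids = [f"g{i + 1:05d}" for i in range(config.n_genes)]
    log_mu = rng.normal(config.baseline_log_mean[0], config.baseline_log_mean[1], config.n_genes)
    mu = np.exp(log_mu)
    a0, a1 = config.dispersion_trend
    shape = config.nb_dispersion_shape
    alpha = (a0 + a1 / mu) * rng.gamma(shape, 1.0 / shape, config.n_genes)
    sig_idx = rng.choice(config.n_genes, size=config.n_signature_genes, replace=False)
    n_up = int(round(config.signature_stiff_fraction * config.n_signature_genes))
    signs = np.array([1.0] * n_up + [-1.0] * (config.n_signature_genes - n_up))
    log2fc = np.zeros(config.n_genes)
    log2fc[sig_idx] = config.signature_log2fc * signs
    return gene_ids, mu, alpha, sig_idx, log2fc


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw of NB counts; alpha -> 0 degenerates to Poisson."""
    alpha = np.broadcast_to(alpha, mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    tiny = alpha < 1e-9
    if tiny.any():
        out[tiny] = rng.poisson(mean[tiny])
    if (~tiny).any():
        lam = rng.gamma(1.0 / alpha[~tiny], alpha[~tiny] * mean[~tiny])
        out[~tiny] = rng.poisson(lam)
    return out


def simulate_counts(
    biopsy_labels: Mapping[str, tuple[str, str]] | pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[CountMatrix, SyntheticTruth]:
    """NB counts for labeled biopsies with a planted stiffness program.

    ``biopsy_labels`` maps sample id -> (patient id, "stiff"/"soft"), or is
    a DataFrame indexed by sample id with columns patient_id / mre_label.
    Per gene, log mean = baseline + patient effect + label effect (planted
    signature genes only), plus a per-sample library-size factor.
    """
    if isinstance(biopsy_labels, pd.DataFrame):
        meta = biopsy_labels[["patient_id", "mre_label"]].copy()
    else:
        meta = pd.DataFrame(
            {
                "patient_id": {k: v[0] for k, v in biopsy_labels.items()},
                "mre_label": {k: v[1] for k, v in biopsy_labels.items()},
            }
        )
    patients = list(dict.fromkeys(meta["patient_id"]))
    if len(patients) < 2:
        raise ValueError("simulate_counts needs >= 2 patients")
    per_pat = meta.groupby("patient_id")["mre_label"].agg(set)
    if any(v != {STIFF, SOFT} for v in per_pat):
        raise ValueError("every patient needs at least one stiff and one soft biopsy")

    gene_ids, mu, alpha, sig_idx, log2fc = _gene_params(config)
    G, S = config.n_genes, len(meta)
    pat_eff = {
        p: rng.normal(0.0, config.patient_effect_sd, G) for p in patients
    }
    lib = np.exp(rng.normal(0.0, config.library_size_sd, S))
    is_stiff = (meta["mre_label"] == STIFF).to_numpy()

    counts = np.empty((G, S), dtype=np.int64)
    ln2 = math.log(2.0)
    for j, sid in enumerate(meta.index):
        logm = (
            np.log(mu)
            + pat_eff[meta["patient_id"].iloc[j]]
            + (log2fc * ln2 if is_stiff[j] else 0.0)
            + math.log(lib[j])
        )
        counts[:, j] = _nb_draw(rng, np.exp(logm), alpha)

    cm = CountMatrix(
        pd.DataFrame(counts, index=gene_ids, columns=list(meta.index)), meta
    )
    truth = SyntheticTruth(
        signature_gene_ids=[gene_ids[i] for i in sorted(sig_idx)],
        per_gene_log2fc={gene_ids[i]: float(log2fc[i]) for i in sorted(sig_idx)},
        biopsy_true_labels=dict(zip(meta.index, meta["mre_label"])),
        seeds_used=[config.rng_seed],
    )
    return cm, truth


def simulate_external_cohort(
    config: SimulationConfig,
    signature_genes: Mapping[str, float] | None = None,
    rng: np.random.Generator | None = None,
):
    """External expression cohort with proportional-hazards survival times.

    A configured fraction of subjects carry the expression signal (the
    planted signature genes shifted in their trained direction); survival
    times are exponential with hazard multiplied by exp(true_log_hr) for
    carriers, with independent exponential censoring calibrated to the
    configured censoring fraction.  Returns (CountMatrix, survival table,
    truth).
    """
    from .survival import SurvivalCohort

    if rng is None:
        rng = config.rng()
    if config.external_n < 20:
        raise ValueError("external_n must be >= 20")
    gene_ids, mu, alpha, sig_idx, log2fc = _gene_params(config)
    if signature_genes is None:
        signature_genes = {gene_ids[i]: float(log2fc[i]) for i in sig_idx}
    shift = np.zeros(config.n_genes)
    gpos = {g: i for i, g in enumerate(gene_ids)}
    for g, fc in signature_genes.items():
        if g in gpos:
            shift[gpos[g]] = fc

    n = config.external_n
    subj = [f"X{i + 1:04d}" for i in range(n)]
    carrier = rng.random(n) < config.carrier_fraction
    lib = np.exp(rng.normal(0.0, config.library_size_sd, n))
    subj_eff = rng.normal(0.0, config.patient_effect_sd, (config.n_genes, n))
    ln2 = math.log(2.0)
    logm = (
        np.log(mu)[:, None]
        + subj_eff
        + shift[:, None] * ln2 * carrier[None, :]
        + np.log(lib)[None, :]
    )
    counts = _nb_draw(rng, np.exp(logm), alpha[:, None])

    lam0 = math.log(2.0) / config.baseline_median_days
    lam = lam0 * np.exp(config.true_log_hr * carrier)
    t_event = rng.exponential(1.0 / lam)
    if config.censoring_rate > 0:
        # exponential censoring with P(censor) ~= censoring_rate marginally
        lam_bar = lam.mean()
        lam_c = lam_bar * config.censoring_rate / (1.0 - config.censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, n)
        event = (t_event <= t_cens).astype(int)
        time = np.minimum(t_event, t_cens)
    else:
        event = np.ones(n, dtype=int)
        time = t_event
    time = np.maximum(time, 0.5)

    meta = pd.DataFrame(
        {
            "patient_id": subj,
            "mre_label": np.where(carrier, STIFF, SOFT),  # placeholder labels
        },
        index=subj,
    )
    cm = CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=subj), meta)
    table = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "signature_class": np.where(carrier, "signal", "no-signal"),
            "age": np.round(rng.normal(60.0, 10.0, n), 1),
            "sex": rng.choice(["F", "M"], size=n, p=[0.4, 0.6]),
            "treatment": rng.choice(
                ["RT+TMZ", "RT", "other"], size=n, p=[0.6, 0.25, 0.15]
            ),
        },
        index=pd.Index(subj, name="subject_id"),
    )
    cohort = SurvivalCohort(table)
    truth = SyntheticTruth(
        signature_gene_ids=[gene_ids[i] for i in sorted(sig_idx)],
        per_gene_log2fc={g: float(f) for g, f in signature_genes.items()},
        external_true_classes={
            s: ("signal" if c else "no-signal") for s, c in zip(subj, carrier)
        },
        true_log_hr=config.true_log_hr,
        seeds_used=[config.rng_seed],
    )
    return cm, cohort, truth


def simulate_gene_sets(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_random_sets: int = 19,
    set_size: int = 30,
) -> dict[str, list[str]]:
    """Toy gene-set collection with one planted stiffness-program set."""
    gene_ids, _, _, sig_idx, log2fc = _gene_params(config)
    sets: dict[str, list[str]] = {}
    planted = [gene_ids[i] for i in sig_idx if log2fc[i] > 0]
    if planted:
        sets["planted_stiffness_program"] = sorted(planted)
    for k in range(n_random_sets):
        pick = rng.choice(config.n_genes, size=set_size, replace=False)
        sets[f"random_set_{k + 1:02d}"] = sorted(gene_ids[i] for i in pick)
    return sets


def simulate_patient(
    config: SimulationConfig, patient_index: int, rng: np.random.Generator
) -> tuple[StiffnessVolume, list[BiopsySample]]:
    """Volume plus quantified, labeled biopsies for one patient."""
    volume = simulate_stiffness_volume(config, patient_index, rng)
    lo, hi = config.biopsies_per_patient_range
    n_b = int(rng.integers(lo, hi + 1))
    samples = place_biopsies(volume, n_b, rng)
    samples = [mre.quantify_biopsy(volume, s) for s in samples]
    samples = mre.label_biopsies(samples)
    if config.surgeon_grade_correlation > 0:
        # optional: tilt the ordinal grade toward the measured stiffness
        for i, s in enumerate(samples):
            if rng.random() < config.surgeon_grade_correlation:
                samples[i].surgeon_grade = 3 if s.gstar_norm > 1 else 1
    return volume, samples


def simulate_cohort(config: SimulationConfig, rng: np.random.Generator | None = None):
    """All patients' volumes and labeled biopsies."""
    if rng is None:
        rng = config.rng()
    volumes, samples = [], []
    for i in range(config.n_patients):
        vol, ss = simulate_patient(config, i, rng)
        volumes.append(vol)
        samples.extend(ss)
    return volumes, samples
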