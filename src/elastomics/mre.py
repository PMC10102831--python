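"""Biopsy-level stiffness quantification from MR elastography volumes.

MR elastography (MRE) produces voxel maps of the shear-modulus magnitude
|G*| (kPa, "tissue stiffness") and the shear phase angle phi (rad, related
to viscous dissipation).  This module turns such volumes plus biopsy seed
voxels into normalized biopsy stiffness values (|G*|_norm, the ROI value
divided by the mean of the patient's contralateral normal-appearing white
matter), relative "stiff"/"soft" labels within each tumor, and region-level
summary statistics, together with the two nonparametric tests used to
compare them (Wilcoxon signed-rank, Spearman rank correlation).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

# Habitat segmentation label convention (integer labels in the segmentation
# volume).  "Habitat" = tumor subregion or normal-tissue class.
BACKGROUND = 0
NAWM_WM = 1
NAWM_GM = 2
FLAIR = 3
CE = 4
NECROSIS = 5

HABITAT_NAMES: dict[int, str] = {
    NAWM_WM: "NAWM-WM",
    NAWM_GM: "NAWM-GM",
    FLAIR: "FLAIR",
    CE: "CE",
    NECROSIS: "necrosis",
}

#: segmentation labels a biopsy may be seeded in, and the radiological class
#: recorded for each
BIOPSY_HABITATS: dict[int, str] = {CE: "CE", NECROSIS: "necrosis", FLAIR: "FLAIR"}

STIFF = "stiff"
SOFT = "soft"


class BoundaryError(ValueError):
    """ROI neighborhood exits the image grid; no silent padding is done."""


@dataclass
class StiffnessVolume:
    """Co-registered |G*|, phi and habitat segmentation grids for one patient.

    All grids share one shape and one voxel size; seeds are 0-based voxel
    indices in this grid (synthetic data share a single space, so no
    world-coordinate transform is applied).
    """

    gstar: np.ndarray
    phi: np.ndarray
    segmentation: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    patient_id: str

    def __post_init__(self) -> None:
        self.gstar = np.asarray(self.gstar, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.segmentation = np.asarray(self.segmentation)
        if not (self.gstar.shape == self.phi.shape == self.segmentation.shape):
            raise ValueError(
                f"grid shapes differ: gstar {self.gstar.shape}, "
                f"phi {self.phi.shape}, segmentation {self.segmentation.shape}"
            )
        if self.gstar.ndim != 3:
            raise ValueError("volumes must be 3D")
        fg = self.segmentation != BACKGROUND
        if np.any(self.gstar[fg] <= 0):
            raise ValueError("|G*| must be positive inside the brain mask")
        if np.any((self.phi[fg] <= 0) | (self.phi[fg] >= np.pi / 2)):
            raise ValueError("phi must lie in (0, pi/2) inside the brain mask")

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.voxel_size_mm)) / 1000.0


@dataclass
class BiopsySample:
    """One image-localized biopsy with its stiffness quantification.

    ``surgeon_grade`` is the intraoperative consistency evaluation on the
    ordinal scale 1 = softer than normal brain, 2 = similar, 3 = firmer.
    ``mre_label`` is set only by :func:`label_biopsies` (relative rule
    within each tumor).
    """

    patient_id: str
    sample_id: str
    seed_voxel: tuple[int, int, int] | None = None
    radiological_class: str | None = None
    surgeon_grade: int | None = None
    gstar_roi_kpa: float | None = None
    gstar_norm: float | None = None
    phi_norm: float | None = None
    mre_label: str | None = None


@dataclass
class RegionSummary:
    """Per-habitat stiffness statistics for one patient volume.

    Habitats absent from the segmentation are recorded as None (flagged
    absent, never silently zero).
    """

    patient_id: str
    mean_gstar_kpa: dict[str, float | None]
    mean_phi_rad: dict[str, float | None]
    mean_gstar_norm: dict[str, float | None]
    mean_phi_norm: dict[str, float | None]
    pct_diff_gstar_vs_nawm: dict[str, float | None]
    pct_diff_phi_vs_nawm: dict[str, float | None]
    tumor_volume_cm3: float
    flair_volume_cm3: float


def _in_plane_neighborhood(seed: Sequence[int], shape: Sequence[int], plane_axes=(0, 1)):
    """Indices of the 3x3 in-plane neighborhood centered on ``seed``."""
    i, j, k = (int(v) for v in seed)
    offsets = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1)]
    out = []
    for di, dj in offsets:
        idx = [i, j, k]
        idx[plane_axes[0]] += di
        idx[plane_axes[1]] += dj
        if not all(0 <= idx[a] < shape[a] for a in range(3)):
            raise BoundaryError(
                f"3x3 ROI neighborhood around seed {tuple(seed)} exits the grid {tuple(shape)}"
            )
        out.append(tuple(idx))
    return out


def _nearest_3d_neighborhood(seed, shape, voxel_size_mm):
    """Seed voxel plus its 8 physically nearest neighbors in 3D.

    Candidates are the 26-connected neighbors ranked by physical distance
    (voxel size breaks ties between in-plane and through-plane neighbors);
    remaining ties break lexicographically for determinism.
    """
    i, j, k = (int(v) for v in seed)
    cands = []
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            for dk in (-1, 0, 1):
                d = math.sqrt(
                    (di * voxel_size_mm[0]) ** 2
                    + (dj * voxel_size_mm[1]) ** 2
                    + (dk * voxel_size_mm[2]) ** 2
                )
                cands.append((d, (di, dj, dk)))
    cands.sort(key=lambda t: (t[0], t[1]))
    out = []
    for _, (di, dj, dk) in cands[:9]:
        idx = (i + di, j + dj, k + dk)
        if not all(0 <= idx[a] < shape[a] for a in range(3)):
            raise BoundaryError(
                f"3D ROI neighborhood around seed {tuple(seed)} exits the grid {tuple(shape)}"
            )
        out.append(idx)
    return out


def extract_roi_value(
    volume: StiffnessVolume,
    seed_voxel: Sequence[int],
    quantity: str = "gstar",
    neighborhood: str = "in-plane",
) -> float:
    """Trimmed mean of the 9-voxel ROI centered on a biopsy seed.

    The single highest and single lowest of the nine values are removed and
    the remaining seven averaged, making the biopsy value robust to brain
    shift and coregistration error.  ``neighborhood`` selects the 3x3
    in-plane patch on the seed's slice (default) or the 9 physically
    nearest voxels in 3D.
    """
    grid = getattr(volume, quantity)
    if neighborhood == "in-plane":
        idx = _in_plane_neighborhood(seed_voxel, grid.shape)
    elif neighborhood == "9-nearest-3d":
        idx = _nearest_3d_neighborhood(seed_voxel, grid.shape, volume.voxel_size_mm)
    else:
        raise ValueError(f"unknown neighborhood {neighborhood!r}")
    vals = np.sort(np.array([grid[t] for t in idx], dtype=float))
    return float(vals[1:-1].mean())


def tumor_centroid(volume: StiffnessVolume) -> np.ndarray:
    """Voxel-space centroid of the tumor (CE + necrosis, else FLAIR)."""
    mask = np.isin(volume.segmentation, (CE, NECROSIS))
    if not mask.any():
        mask = volume.segmentation == FLAIR
    if not mask.any():
        raise ValueError(f"patient {volume.patient_id}: no tumor habitat in segmentation")
    return np.mean(np.argwhere(mask), axis=0)


def contralateral_nawm_mask(volume: StiffnessVolume, lr_axis: int = 0) -> np.ndarray:
    """NAWM white-matter voxels in the hemisphere opposite the tumor centroid.

    The left-right axis is the first grid axis by convention; the midplane
    is the grid center along that axis.
    """
    centroid = tumor_centroid(volume)
    mid = (volume.segmentation.shape[lr_axis] - 1) / 2.0
    coords = np.arange(volume.segmentation.shape[lr_axis])
    if centroid[lr_axis] >= mid:
        side = coords < mid
    else:
        side = coords > mid
    shape = [1, 1, 1]
    shape[lr_axis] = -1
    hemi = np.broadcast_to(side.reshape(shape), volume.segmentation.shape)
    mask = (volume.segmentation == NAWM_WM) & hemi
    if not mask.any():
        raise ValueError(
            f"patient {volume.patient_id}: contralateral NAWM-WM mask is empty"
        )
    return mask


def nawm_reference_mean(volume: StiffnessVolume, quantity: str = "gstar") -> float:
    """Mean |G*| (or phi) over the contralateral NAWM-WM reference region."""
    mask = contralateral_nawm_mask(volume)
    return float(getattr(volume, quantity)[mask].mean())


def normalize_to_nawm(
    roi_value: float, volume: StiffnessVolume, quantity: str = "gstar"
) -> float:
    """Dimensionless ratio of an ROI value to the contralateral NAWM mean."""
    ref = nawm_reference_mean(volume, quantity)
    if ref <= 0:
        raise ValueError("non-positive NAWM reference mean")
    return float(roi_value) / ref


def quantify_biopsy(
    volume: StiffnessVolume, sample: BiopsySample, neighborhood: str = "in-plane"
) -> BiopsySample:
    """Fill gstar_roi_kpa, gstar_norm and phi_norm for one biopsy."""
    if sample.seed_voxel is None:
        raise ValueError(f"sample {sample.sample_id}: no seed voxel")
    roi_g = extract_roi_value(volume, sample.seed_voxel, "gstar", neighborhood)
    roi_p = extract_roi_value(volume, sample.seed_voxel, "phi", neighborhood)
    return replace(
        sample,
        gstar_roi_kpa=roi_g,
        gstar_norm=normalize_to_nawm(roi_g, volume, "gstar"),
        phi_norm=normalize_to_nawm(roi_p, volume, "phi"),
    )


def label_biopsies(samples: Sequence[BiopsySample]) -> list[BiopsySample]:
    """Assign relative "stiff"/"soft" labels within one patient's tumor.

    A biopsy is "stiff" iff its |G*|_norm is strictly greater than the mean
    |G*|_norm over that patient's biopsies, else "soft" (ties go to soft).
    With at least two non-tied biopsies this guarantees each patient at
    least one stiff and one soft biopsy.
    """
    if len(samples) < 2:
        raise ValueError("relative stiff/soft rule needs >= 2 biopsies per patient")
    if len({s.patient_id for s in samples}) != 1:
        raise ValueError("label_biopsies operates on one patient at a time")
    values = [s.gstar_norm for s in samples]
    if any(v is None for v in values):
        raise ValueError("all biopsies must have gstar_norm set before labeling")
    mean = float(np.mean([float(v) for v in values]))
    return [
        replace(s, mre_label=STIFF if float(s.gstar_norm) > mean else SOFT)
        for s in samples
    ]


def region_summary(volume: StiffnessVolume) -> RegionSummary:
    """Per-habitat mean |G*| and phi, normalized means, percent differences
    versus contralateral NAWM-WM, and tumor / FLAIR volumes in cm^3."""
    seg = volume.segmentation
    if not (seg == NAWM_WM).any():
        raise ValueError("segmentation contains no NAWM-WM")
    ref_g = nawm_reference_mean(volume, "gstar")
    ref_p = nawm_reference_mean(volume, "phi")

    mg: dict[str, float | None] = {}
    mp: dict[str, float | None] = {}
    ng: dict[str, float | None] = {}
    npn: dict[str, float | None] = {}
    dg: dict[str, float | None] = {}
    dp: dict[str, float | None] = {}
    for lab, name in HABITAT_NAMES.items():
        mask = seg == lab
        if not mask.any():
            mg[name] = mp[name] = ng[name] = npn[name] = dg[name] = dp[name] = None
            continue
        g = float(volume.gstar[mask].mean())
        p = float(volume.phi[mask].mean())
        mg[name], mp[name] = g, p
        ng[name], npn[name] = g / ref_g, p / ref_p
        dg[name] = 100.0 * (g / ref_g - 1.0)
        dp[name] = 100.0 * (p / ref_p - 1.0)

    vox = volume.voxel_volume_cm3
    return RegionSummary(
        patient_id=volume.patient_id,
        mean_gstar_kpa=mg,
        mean_phi_rad=mp,
        mean_gstar_norm=ng,
        mean_phi_norm=npn,
        pct_diff_gstar_vs_nawm=dg,
        pct_diff_phi_vs_nawm=dp,
        tumor_volume_cm3=float(np.isin(seg, (CE, NECROSIS)).sum()) * vox,
        flair_volume_cm3=float((seg == FLAIR).sum()) * vox,
    )


class HeterogeneityResult(NamedTuple):
    per_patient: dict[str, float]
    cohort_median: float


def heterogeneity_ratio(
    samples_by_patient: Mapping[str, Sequence[BiopsySample]] | Iterable[BiopsySample],
) -> HeterogeneityResult:
    """Per-patient max/min |G*|_norm biopsy ratio and the cohort median.

    Quantifies intratumoral stiffness heterogeneity: the ratio between the
    stiffest and softest biopsy of each tumor.
    """
    if not isinstance(samples_by_patient, Mapping):
        grouped: dict[str, list[BiopsySample]] = {}
        for s in samples_by_patient:
            grouped.setdefault(s.patient_id, []).append(s)
        samples_by_patient = grouped
    ratios: dict[str, float] = {}
    for pid, samples in samples_by_patient.items():
        vals = np.array([float(s.gstar_norm) for s in samples], dtype=float)
        if len(vals) < 2:
            raise ValueError(f"patient {pid}: ratio needs >= 2 biopsies")
        if np.any(vals <= 0):
            raise ValueError(f"patient {pid}: non-positive |G*|_norm")
        ratios[pid] = float(vals.max() / vals.min())
    return HeterogeneityResult(ratios, float(np.median(list(ratios.values()))))


class TestResult(NamedTuple):
    statistic: float
    pvalue: float
    degenerate: bool = False


def wilcoxon_signed_rank(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Exact enumeration for n <= 12 without ties or zero differences, normal
    approximation (with tie/zero handling) otherwise.  All-zero differences
    make the test degenerate: reported as p = 1 with the flag set.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = a - b
    if np.all(d == 0):
        return TestResult(0.0, 1.0, degenerate=True)
    nz = d[d != 0]
    exact_ok = (
        len(nz) <= 12
        and len(nz) == len(d)
        and len(np.unique(np.abs(nz))) == len(nz)
    )
    method = "exact" if exact_ok else "approx"
    res = stats.wilcoxon(a, b, alternative="two-sided", method=method,
                         zero_method="wilcox", correction=(method == "approx"))
    return TestResult(float(res.statistic), float(res.pvalue), degenerate=False)


def spearman_rank(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation with an exact permutation p for n <= 8.

    rho is the Pearson correlation of mid-ranks.  For n <= 8 the two-sided
    p-value enumerates all n! pairings of the rank vectors; for larger n
    the usual t-distribution approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    n = len(x)
    if n < 4:
        raise ValueError("spearman_rank needs n >= 4")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman correlation undefined")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        null = np.empty(math.factorial(n))
        rxc = rx - rx.mean()
        denom_x = math.sqrt(float(rxc @ rxc))
        ryc = ry - ry.mean()
        denom_y = math.sqrt(float(ryc @ ryc))
        for i, perm in enumerate(itertools.permutations(range(n))):
            null[i] = float(rxc @ ryc[list(perm)]) / (denom_x * denom_y)
        p = float(np.mean(np.abs(null) >= abs(rho) - 1e-12))
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1.0 - rho * rho))
        p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return TestResult(rho, min(1.0, p))
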