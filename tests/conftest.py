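import numpy as np
import pandas as pd
import pytest

from elastomics import io
from elastomics.de import CountMatrix
from elastomics.mre import StiffnessVolume
from elastomics.simulate import SimulationConfig, simulate_counts


@pytest.fixture(scope="session")
def reference_biopsies():
    return io.load_reference_biopsies()


@pytest.fixture(scope="session")
def reference_by_patient(reference_biopsies):
    out = {}
    for s in reference_biopsies:
        out.setdefault(s.patient_id, []).append(s)
    return out


def blocked_labels(n_patients=8, n_biopsies=3):
    """patient/label design: first biopsy stiff, the rest soft."""
    return {
        f"P{p}_s{b}": (f"P{p}", "stiff" if b == 0 else "soft")
        for p in range(n_patients)
        for b in range(n_biopsies)
    }


@pytest.fixture(scope="session")
def planted_counts():
    """8 patients x 3 biopsies, 100 planted genes at log2FC = 2."""
    cfg = SimulationConfig(
        n_genes=1000, n_signature_genes=100, signature_log2fc=2.0, rng_seed=11
    )
    cm, truth = simulate_counts(blocked_labels(), cfg, np.random.default_rng(11))
    return cm, truth


@pytest.fixture
def toy_volume():
    """Small uniform volume: NAWM everywhere except a CE blob off-center."""
    shape = (16, 12, 8)
    seg = np.ones(shape, dtype=np.int16)
    seg[10:14, 4:8, 2:6] = 4  # CE tumor in the +i hemisphere
    gstar = np.full(shape, 2.0)
    gstar[seg == 4] = 1.6
    phi = np.full(shape, 0.8)
    phi[seg == 4] = 0.72
    return StiffnessVolume(
        gstar=gstar, phi=phi, segmentation=seg,
        voxel_size_mm=(3.1, 3.1, 3.1), patient_id="T01",
    )


def make_count_matrix(counts, patients, labels, gene_ids=None):
    counts = np.asarray(counts)
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(counts.shape[0])]
    sample_ids = [f"s{j}" for j in range(counts.shape[1])]
    meta = pd.DataFrame(
        {"patient_id": patients, "mre_label": labels}, index=sample_ids
    )
    return CountMatrix(pd.DataFrame(counts, index=gene_ids, columns=sample_ids), meta)
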