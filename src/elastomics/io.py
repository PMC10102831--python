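"""Readers and writers for the pipeline's on-disk formats.

TSV (tab-separated, UTF-8, '.' decimal) is the canonical table dialect;
volumes are NIfTI (|G*| and phi as float images, the habitat segmentation
as integer labels 0=background, 1=NAWM-WM, 2=NAWM-GM, 3=FLAIR, 4=CE,
5=necrosis); gene sets are GMT; models, truth and reports are JSON.  All
readers validate schemas and report malformed rows with their location.
Also exposes the packaged reference tables: the published 22-biopsy cohort
with printed |G*|_norm values and the 43-gene stable signature list.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .de import CountMatrix
from .enrich import GeneSetCollection
from .mre import BiopsySample, StiffnessVolume
from .simulate import SyntheticTruth
from .survival import SurvivalCohort

_SURGEON_GRADE = {"Soft": 1, "Similar": 2, "Stiff": 3}


# --------------------------------------------------------------------------
# packaged reference tables

def load_reference_biopsies() -> list[BiopsySample]:
    """The published 22-biopsy reference cohort (8 patients).

    Carries each biopsy's radiological class, the surgeon's ordinal
    consistency evaluation, the printed |G*|_norm value and the published
    MRE stiff/soft label.
    """
    ref = importlib.resources.files("elastomics.data") / "biopsy_cohort.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype=str)
    samples = []
    for _, row in df.iterrows():
        samples.append(
            BiopsySample(
                patient_id=str(row["patient_id"]),
                sample_id=f"{row['patient_id']}_{row['sample_id']}",
                radiological_class=row["radiological_class"],
                surgeon_grade=_SURGEON_GRADE[row["surgeon_eval"]],
                gstar_norm=float(row["gstar_norm"]),
                mre_label=row["mre_label"].lower(),
            )
        )
    return samples


def load_reference_stable_genes() -> pd.DataFrame:
    """The published 43-gene stable signature table (35 stiff / 8 soft)."""
    ref = importlib.resources.files("elastomics.data") / "stable_genes.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", dtype={"entrez_id": str})


# --------------------------------------------------------------------------
# NIfTI volumes

def write_nifti(volume: StiffnessVolume, directory: str | Path) -> dict[str, Path]:
    """Write |G*|, phi and segmentation as .nii.gz; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(volume.voxel_size_mm) + [1.0])
    out = {}
    for name, arr, dtype in (
        ("gstar", volume.gstar, np.float32),
        ("phi", volume.phi, np.float32),
        ("segmentation", volume.segmentation, np.int16),
    ):
        path = directory / f"{volume.patient_id}_{name}.nii.gz"
        nib.save(nib.Nifti1Image(arr.astype(dtype), affine), str(path))
        out[name] = path
    return out


def read_nifti(directory: str | Path, patient_id: str) -> StiffnessVolume:
    """Read one patient's volume triplet written by :func:`write_nifti`."""
    directory = Path(directory)
    imgs = {}
    for name in ("gstar", "phi", "segmentation"):
        path = directory / f"{patient_id}_{name}.nii.gz"
        if not path.exists():
            raise FileNotFoundError(path)
        imgs[name] = nib.load(str(path))
    voxel = tuple(float(z) for z in imgs["gstar"].header.get_zooms()[:3])
    return StiffnessVolume(
        gstar=np.asarray(imgs["gstar"].dataobj, dtype=float),
        phi=np.asarray(imgs["phi"].dataobj, dtype=float),
        segmentation=np.asarray(imgs["segmentation"].dataobj).astype(np.int16),
        voxel_size_mm=voxel,
        patient_id=patient_id,
    )


# --------------------------------------------------------------------------
# biopsy tables

_BIOPSY_COLUMNS = [
    "patient_id", "sample_id", "seed_i", "seed_j", "seed_k",
    "radiological_class", "surgeon_grade", "gstar_roi_kpa",
    "gstar_norm", "phi_norm", "mre_label",
]


def write_biopsy_table(samples: list[BiopsySample], path: str | Path) -> None:
    rows = []
    for s in samples:
        seed = s.seed_voxel or (None, None, None)
        rows.append(
            {
                "patient_id": s.patient_id,
                "sample_id": s.sample_id,
                "seed_i": seed[0],
                "seed_j": seed[1],
                "seed_k": seed[2],
                "radiological_class": s.radiological_class,
                "surgeon_grade": s.surgeon_grade,
                "gstar_roi_kpa": s.gstar_roi_kpa,
                "gstar_norm": s.gstar_norm,
                "phi_norm": s.phi_norm,
                "mre_label": s.mre_label,
            }
        )
    pd.DataFrame(rows, columns=_BIOPSY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_biopsy_table(path: str | Path) -> list[BiopsySample]:
    """Read a biopsy TSV; malformed rows are reported with line numbers."""
    df = pd.read_csv(path, sep="\t")
    missing = {"patient_id", "sample_id"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    samples = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            seed = None
            if pd.notna(row.get("seed_i")):
                seed = (int(row["seed_i"]), int(row["seed_j"]), int(row["seed_k"]))
            grade = int(row["surgeon_grade"]) if pd.notna(row.get("surgeon_grade")) else None
            if grade is not None and grade not in (1, 2, 3):
                raise ValueError(f"surgeon_grade must be 1/2/3, got {grade}")
            label = row.get("mre_label")
            label = str(label).lower() if pd.notna(label) else None
            if label is not None and label not in ("stiff", "soft"):
                raise ValueError(f"mre_label must be stiff/soft, got {label!r}")
            samples.append(
                BiopsySample(
                    patient_id=str(row["patient_id"]),
                    sample_id=str(row["sample_id"]),
                    seed_voxel=seed,
                    radiological_class=(
                        str(row["radiological_class"])
                        if pd.notna(row.get("radiological_class"))
                        else None
                    ),
                    surgeon_grade=grade,
                    gstar_roi_kpa=(
                        float(row["gstar_roi_kpa"]) if pd.notna(row.get("gstar_roi_kpa")) else None
                    ),
                    gstar_norm=(
                        float(row["gstar_norm"]) if pd.notna(row.get("gstar_norm")) else None
                    ),
                    phi_norm=(
                        float(row["phi_norm"]) if pd.notna(row.get("phi_norm")) else None
                    ),
                    mre_label=label,
                )
            )
        except (TypeError, ValueError) as err:
            raise ValueError(f"{path}: malformed row at line {line}: {err}") from err
    return samples


# --------------------------------------------------------------------------
# counts + metadata

def write_counts(cm: CountMatrix, counts_path: str | Path, metadata_path: str | Path) -> None:
    cm.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    cm.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


def read_counts(counts_path: str | Path, metadata_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus its sample metadata TSV.

    Counts must be non-negative integers; offending entries are reported
    with their gene row and sample column.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    for col in counts.columns:
        vals = counts[col]
        nonint = vals[(vals != np.floor(vals)) | vals.isna()]
        if len(nonint):
            raise ValueError(
                f"{counts_path}: non-integer count for gene {nonint.index[0]!r}, "
                f"sample {col!r}: {nonint.iloc[0]}"
            )
        neg = vals[vals < 0]
        if len(neg):
            raise ValueError(
                f"{counts_path}: negative count for gene {neg.index[0]!r}, "
                f"sample {col!r}: {neg.iloc[0]}"
            )
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype={"patient_id": str})
    return CountMatrix(counts.astype(np.int64), meta)


# --------------------------------------------------------------------------
# GMT gene sets

def write_gmt(collection: GeneSetCollection | dict, path: str | Path, source: str = "") -> None:
    sets = collection.sets if isinstance(collection, GeneSetCollection) else collection
    src = collection.source if isinstance(collection, GeneSetCollection) else source
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, src or "na", *members]) + "\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> member genes...)."""
    sets: dict[str, list[str]] = {}
    source = ""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: GMT rows need name, description and >= 1 gene"
                )
            name, desc, *genes = parts
            if name in sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            sets[name] = [g for g in genes if g]
            source = source or desc
    if not sets:
        warnings.warn(f"{path}: empty GMT file, empty collection returned")
    return GeneSetCollection(sets, source=source)


# --------------------------------------------------------------------------
# JSON helpers

def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(dataclasses.asdict(truth), fh, indent=1)


def read_truth(path: str | Path) -> SyntheticTruth:
    with open(path, encoding="utf-8") as fh:
        return SyntheticTruth(**json.load(fh))


def write_survival_table(cohort: SurvivalCohort, path: str | Path) -> None:
    cohort.table.rename_axis("subject_id").to_csv(path, sep="\t")


def read_survival_table(path: str | Path) -> SurvivalCohort:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SurvivalCohort(df)
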