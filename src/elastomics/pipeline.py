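"""End-to-end orchestration: simulate → quantify → label → DE → stability →
enrichment → signature → external classification → survival.

One :class:`PipelineConfig` (YAML-serializable) drives every stage; all
randomness flows from its single seed, so a rerun with the same config is
byte-identical.  Each stage writes its TSV/JSON outputs into the run
directory and contributes a section to the summary report, which embeds
the config hash and the seeds used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import de, enrich, io, mre, signature, simulate, survival

log = logging.getLogger("elastomics")


@dataclass
class PipelineConfig:
    """Everything one run needs; unset paths mean "simulate instead"."""

    output_dir: str = "elastomics_run"
    rng_seed: int = 0
    alpha: float = 0.05
    run_loo: bool = True
    run_enrichment: bool = True
    run_signature: bool = True
    run_survival: bool = True
    write_volumes: bool = False
    write_plots: bool = False
    keep_x_grid: tuple[int, ...] = (5, 10, 25, 50)
    n_components_grid: tuple[int, ...] = (1, 2)
    cv_folds: int = 5
    cv_repeats: int = 100
    tune_signature: bool = False
    survival_covariates: tuple[str, ...] = ("age", "sex", "treatment")
    simulate: simulate.SimulationConfig = field(default_factory=simulate.SimulationConfig)
    # optional pre-existing inputs (override simulation of that stage)
    biopsy_table: str | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        self.simulate.rng_seed = self.rng_seed  # one seed drives everything
        for p in (self.biopsy_table, self.counts_path, self.metadata_path, self.gmt_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulate", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if sim:
            cfg.simulate = simulate.SimulationConfig(
                **{k: tuple(v) if isinstance(v, list) else v for k, v in sim.items()}
            )
        cfg.simulate.rng_seed = cfg.rng_seed
        return cfg

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["simulate"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(self.simulate).items()
        }
        d["simulate"].pop("habitat_stiffness_factors", None)
        d["simulate"]["habitat_stiffness_factors"] = dict(self.simulate.habitat_stiffness_factors)
        d["simulate"]["habitat_phase_factors"] = dict(self.simulate.habitat_phase_factors)
        return yaml.safe_dump(
            {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()},
            sort_keys=True,
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def _stage(report: dict, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                log.error("stage %s: FAILED after %.2fs", name, dt)
                raise RuntimeError(f"pipeline stage {name!r} failed") from exc
            report.setdefault("timings_s", {})[name] = round(dt, 3)
            log.info("stage %s: done in %.2fs", name, dt)

    return _Timer()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns the report dict (also written
    as report.json in the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.simulate.rng_seed = config.rng_seed
    rng = np.random.default_rng(config.rng_seed)
    report: dict = {
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
    }
    (out / "config.yaml").write_text(config.to_yaml(), encoding="utf-8")

    # ---- stiffness volumes + biopsies -------------------------------------
    samples: list[mre.BiopsySample]
    with _stage(report, "quantify"):
        if config.biopsy_table:
            samples = io.read_biopsy_table(config.biopsy_table)
            volumes = []
        else:
            volumes, samples = simulate.simulate_cohort(config.simulate, rng)
            if config.write_volumes:
                for vol in volumes:
                    io.write_nifti(vol, out / "volumes")
        by_patient: dict[str, list[mre.BiopsySample]] = {}
        for s in samples:
            by_patient.setdefault(s.patient_id, []).append(s)
        het = mre.heterogeneity_ratio(by_patient)
        io.write_biopsy_table(samples, out / "biopsies.tsv")
        if volumes:
            summaries = [mre.region_summary(v) for v in volumes]
            pd.DataFrame(
                [
                    {
                        "patient_id": rs.patient_id,
                        "tumor_volume_cm3": rs.tumor_volume_cm3,
                        "flair_volume_cm3": rs.flair_volume_cm3,
                        **{
                            f"pct_diff_gstar[{h}]": v
                            for h, v in rs.pct_diff_gstar_vs_nawm.items()
                        },
                    }
                    for rs in summaries
                ]
            ).to_csv(out / "region_summary.tsv", sep="\t", index=False)
        report["quantify"] = {
            "n_patients": len(by_patient),
            "n_biopsies": len(samples),
            "n_stiff": sum(s.mre_label == mre.STIFF for s in samples),
            "n_soft": sum(s.mre_label == mre.SOFT for s in samples),
            "median_max_min_ratio": round(het.cohort_median, 3),
        }

    # ---- counts -----------------------------------------------------------
    with _stage(report, "counts"):
        if config.counts_path and config.metadata_path:
            cm = io.read_counts(config.counts_path, config.metadata_path)
            truth = None
        else:
            meta = pd.DataFrame(
                {
                    "patient_id": [s.patient_id for s in samples],
                    "mre_label": [s.mre_label for s in samples],
                },
                index=[s.sample_id for s in samples],
            )
            cm, truth = simulate.simulate_counts(meta, config.simulate, rng)
            io.write_counts(cm, out / "counts.tsv", out / "sample_metadata.tsv")
            io.write_truth(truth, out / "truth.json")

    # ---- differential expression ------------------------------------------
    with _stage(report, "de"):
        de_res = de.run_de(cm, alpha=config.alpha)
        de_res.rename_axis("gene_id").to_csv(out / "de_results.tsv", sep="\t")
        report["de"] = {
            "n_genes": len(de_res),
            "n_significant": de_res.attrs["n_significant"],
            "n_up_stiff": de_res.attrs["n_up_stiff"],
            "n_up_soft": de_res.attrs["n_up_soft"],
            "n_untested": de_res.attrs["n_untested"],
        }

    if config.run_loo:
        with _stage(report, "loo_stability"):
            stable = de.loo_stable_genes(cm, alpha=config.alpha)
            pd.DataFrame(
                {
                    "gene_id": stable.genes,
                    "association": ["stiff"] * len(stable.stiff_associated)
                    + ["soft"] * len(stable.soft_associated),
                }
            ).to_csv(out / "stable_genes.tsv", sep="\t", index=False)
            report["loo_stability"] = {
                "n_stable": len(stable.genes),
                "n_stiff_associated": len(stable.stiff_associated),
                "n_soft_associated": len(stable.soft_associated),
                "skipped_iterations": stable.skipped_patients,
            }

    # ---- enrichment -------------------------------------------------------
    if config.run_enrichment:
        with _stage(report, "enrichment"):
            if config.gmt_path:
                gsc = io.read_gmt(config.gmt_path)
            else:
                gsc = enrich.GeneSetCollection(
                    simulate.simulate_gene_sets(config.simulate, rng), source="synthetic"
                )
            sig_genes = list(de_res.index[de_res["padj"] < config.alpha])
            if sig_genes and len(gsc):
                ora = enrich.ora_hypergeometric(sig_genes, list(de_res.index), gsc)
                ora.to_csv(out / "ora_results.tsv", sep="\t")
            ranked = de_res.loc[de_res["tested"], "stat"]
            gsea = enrich.gsea_preranked(ranked, gsc, n_perm=500, rng=rng)
            if len(gsea):
                gsea.to_csv(out / "gsea_results.tsv", sep="\t")
            report["enrichment"] = {
                "n_sets": len(gsc),
                "n_gsea_tested": int(len(gsea)),
                "n_gsea_significant": int((gsea["padj"] < config.alpha).sum())
                if len(gsea)
                else 0,
            }

    # ---- signature + external survival ------------------------------------
    if config.run_signature:
        with _stage(report, "signature"):
            sf = de.size_factors(cm)
            X = de.transform_counts(cm, sf).T  # samples x genes
            y = cm.metadata["mre_label"]
            if config.tune_signature:
                choice = signature.tune_splsda(
                    X,
                    y,
                    keep_x_grid=config.keep_x_grid,
                    n_components_grid=config.n_components_grid,
                    folds=config.cv_folds,
                    repeats=config.cv_repeats,
                    rng=rng,
                )
                n_comp, keep_x = choice["n_components"], choice["keep_x"]
            else:
                n_comp, keep_x = 1, min(22, X.shape[1])
            model = signature.fit_splsda(X, y, n_components=n_comp, keep_x=keep_x)
            (out / "signature_model.json").write_text(model.to_json(), encoding="utf-8")
            report["signature"] = {
                "n_components": n_comp,
                "keep_x": keep_x,
                "n_signature_genes": len(model.signature_genes),
            }

        if config.run_survival:
            with _stage(report, "survival"):
                ext_cm, ext_cohort, ext_truth = simulate.simulate_external_cohort(
                    config.simulate, rng=rng
                )
                ext_sf = de.size_factors(ext_cm)
                ext_X = de.transform_counts(ext_cm, ext_sf).T
                pred = signature.predict_class(model, ext_X)
                tab = ext_cohort.table.copy()
                tab["signature_class"] = np.where(
                    pred["predicted_class"].to_numpy() == "stiff",
                    survival.SIGNAL,
                    survival.NO_SIGNAL,
                )
                classified = survival.SurvivalCohort(tab)
                io.write_survival_table(classified, out / "external_survival.tsv")
                comp = survival.compare_groups(
                    classified, covariates=config.survival_covariates
                )
                cox = comp["cox"]
                if config.write_plots:
                    from . import plots

                    plots.km_plot(classified, out / "km_curves.png")
                    plots.volcano_plot(de_res, config.alpha, out / "volcano.png")
                report["survival"] = {
                    "n_subjects": len(tab),
                    "n_signal": int((tab["signature_class"] == survival.SIGNAL).sum()),
                    "n_no_signal": int(
                        (tab["signature_class"] == survival.NO_SIGNAL).sum()
                    ),
                    "median_signal_days": comp["median_signal"],
                    "median_no_signal_days": comp["median_no_signal"],
                    "logrank_p": None
                    if comp["logrank"] is None
                    else float(comp["logrank"].pvalue),
                    "hr_signature": float(cox.loc["signature[signal]", "hr"]),
                    "hr_ci": [
                        float(cox.loc["signature[signal]", "ci_low"]),
                        float(cox.loc["signature[signal]", "ci_high"]),
                    ],
                    "cox_p": float(cox.loc["signature[signal]", "pvalue"]),
                }

    (out / "report.json").write_text(json.dumps(report, indent=1), encoding="utf-8")
    return report
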