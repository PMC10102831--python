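"""Static summary figures: Kaplan-Meier curves and a volcano plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .survival import NO_SIGNAL, SIGNAL, SurvivalCohort, km_estimate


def km_plot(cohort: SurvivalCohort, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls, color in ((SIGNAL, "black"), (NO_SIGNAL, "gray")):
        sub = cohort.table[cohort.table["signature_class"] == cls]
        if not len(sub):
            continue
        km = km_estimate(sub["time"], sub["event"])
        ax.step(km.times, km.survival, where="post", color=color,
                label=f"{cls} (n={len(sub)})")
    ax.set_xlabel("time (days)")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def volcano_plot(de_res, alpha: float, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    x = de_res["log2FoldChange"].to_numpy()
    y = -np.log10(np.clip(de_res["pvalue"].to_numpy(), 1e-300, None))
    sig = de_res["padj"].to_numpy() < alpha
    ax.scatter(x[~sig], y[~sig], s=4, c="lightgray")
    up = sig & (x > 0)
    dn = sig & (x < 0)
    ax.scatter(x[up], y[up], s=5, c="firebrick", label="up in stiff")
    ax.scatter(x[dn], y[dn], s=5, c="steelblue", label="up in soft")
    ax.set_xlabel("log2 fold change (stiff vs soft)")
    ax.set_ylabel("-log10 p")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
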