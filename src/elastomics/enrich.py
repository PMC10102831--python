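"""Over-representation analysis and preranked gene-set enrichment.

ORA asks whether a discrete query list (e.g. the significant DE genes)
overlaps a gene set more than hypergeometric chance; preranked GSEA walks a
ranked gene list (here ranked by the signed Wald statistic, so positive =
up in stiff biopsies) and scores each set with the weighted
Kolmogorov-Smirnov running-sum enrichment statistic against a gene-label
permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust


@dataclass
class GeneSetCollection:
    """Named, nonempty gene sets (GMT-style) with a source tag."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
        self.sets = {name: list(dict.fromkeys(m)) for name, m in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe: Sequence[str]) -> dict[str, list[str]]:
        uni = set(universe)
        return {n: [g for g in m if g in uni] for n, m in self.sets.items()}


def ora_hypergeometric(
    query_genes: Sequence[str],
    universe: Sequence[str],
    gene_sets: GeneSetCollection | Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per gene set.

    The query must be drawn from the universe; sets are intersected with
    the universe before testing.  Terms whose restricted set exhausts the
    whole universe carry no enrichment signal and are flagged degenerate.
    """
    query = list(dict.fromkeys(query_genes))
    uni = list(dict.fromkeys(universe))
    if not query or not uni:
        raise ValueError("query and universe must be nonempty")
    uni_set = set(uni)
    stray = [g for g in query if g not in uni_set]
    if stray:
        raise ValueError(f"query genes outside the universe: {stray[:5]}")
    if not isinstance(gene_sets, GeneSetCollection):
        gene_sets = GeneSetCollection(dict(gene_sets))
    restricted = gene_sets.restricted_to(uni)

    N = len(uni)
    n = len(query)
    qset = set(query)
    rows = []
    for name, members in restricted.items():
        K = len(members)
        k = len(qset & set(members))
        if K == 0:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        # odds ratio of the 2x2 overlap table (Haldane 0.5 correction)
        a, b = k, n - k
        c, d = K - k, N - K - (n - k)
        orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        rows.append(
            {
                "term": name,
                "set_size": K,
                "overlap": k,
                "odds_ratio": orat,
                "pvalue": p,
                "degenerate": K == N,
                "genes": ";".join(sorted(qset & set(members))),
            }
        )
    res = pd.DataFrame(rows).set_index("term")
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res


def _enrichment_score(in_set: np.ndarray, weights: np.ndarray) -> float:
    """Signed max deviation of the weighted KS running sum.

    ``in_set`` marks set membership along the ranked list (descending
    statistic); ``weights`` are |stat| ** w at each position.
    """
    hit_w = np.where(in_set, weights, 0.0)
    denom = hit_w.sum()
    n_miss = (~in_set).sum()
    if denom <= 0 or n_miss == 0:
        return 0.0
    p_hit = np.cumsum(hit_w) / denom
    p_miss = np.cumsum(~in_set) / n_miss
    run = p_hit - p_miss
    i = int(np.argmax(np.abs(run)))
    return float(run[i])


def gsea_preranked(
    ranked_stats: pd.Series,
    gene_sets: GeneSetCollection | Mapping[str, Sequence[str]],
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
    weight: float = 1.0,
    min_size: int = 5,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    Genes are ranked by the signed statistic (descending); ES is the
    weighted KS running-sum extremum with weight |stat| ** ``weight``; the
    null redraws each set's positions uniformly from the ranked list.
    NES = ES / mean(|null ES|) among same-sign null draws; p is the
    one-sided empirical tail with add-one smoothing, BH-adjusted across
    terms.  Sets smaller than ``min_size`` after restriction are skipped.
    """
    if rng is None:
        rng = np.random.default_rng()
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    stats_ = ranked_stats.astype(float)
    if not np.isfinite(stats_.to_numpy()).all():
        raise ValueError("ranking statistic must be finite for all genes")
    order = stats_.sort_values(ascending=False, kind="mergesort")
    genes = np.array(order.index)
    weights = np.abs(order.to_numpy()) ** weight
    pos = {g: i for i, g in enumerate(genes)}
    N = len(genes)

    if not isinstance(gene_sets, GeneSetCollection):
        gene_sets = GeneSetCollection(dict(gene_sets))
    rows = []
    for name, members in gene_sets.restricted_to(list(genes)).items():
        K = len(members)
        if K < min_size or K >= N:
            warnings.warn(f"gene set {name!r} skipped (size {K} after restriction)")
            continue
        in_set = np.zeros(N, dtype=bool)
        in_set[[pos[g] for g in members]] = True
        es = _enrichment_score(in_set, weights)

        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(N, dtype=bool)
            perm[rng.choice(N, size=K, replace=False)] = True
            null[b] = _enrichment_score(perm, weights)
        same = null[np.sign(null) == np.sign(es)] if es != 0 else null
        if len(same) == 0:
            nes, p = np.nan, 1.0
        else:
            nes = es / np.abs(same).mean()
            p = (1.0 + float((np.abs(same) >= abs(es)).sum())) / (1.0 + len(same))

        # leading edge: set members at or before the running-sum extremum
        hit_w = np.where(in_set, weights, 0.0)
        run = np.cumsum(hit_w) / max(hit_w.sum(), 1e-300) - np.cumsum(~in_set) / max(
            (~in_set).sum(), 1
        )
        i_ext = int(np.argmax(np.abs(run)))
        if es >= 0:
            lead = [g for g in genes[: i_ext + 1] if g in set(members)]
        else:
            lead = [g for g in genes[i_ext:] if g in set(members)]
        rows.append(
            {
                "term": name,
                "set_size": K,
                "es": es,
                "nes": nes,
                "pvalue": p,
                "leading_edge": ";".join(lead),
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res = res.set_index("term")
        res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res
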