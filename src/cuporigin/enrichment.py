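"""Gene-set enrichment: overlap tests, permutation GSEA, instability score.

Three complementary views of a gene list or expression contrast:

* :func:`overlap_test` — the hypergeometric ("compute overlaps") test
  of a query gene list against each set of a collection, with BH FDR
  across sets.
* :func:`gsea` — the weighted Kolmogorov-Smirnov running-sum
  enrichment score on a signal-to-noise ranking, with a permutation
  null (group labels when groups are large enough, random gene sets
  otherwise) giving p and the normalized enrichment score (NES).
* :func:`instability_score` — a per-sample chromosomal-instability
  index: the mean of the standardized expression of a CIN signature's
  probes after keeping only the most variable half (redundant,
  non-responsive probes dilute the signal).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr

from .differential import bh_fdr
from .genesets import GeneSet, GeneSetCollection
from .preprocess import standardize_probes

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# hypergeometric overlap
# ---------------------------------------------------------------------------

def overlap_test(
    query: list[str],
    sets: GeneSetCollection,
    universe: list[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric overlap of a query list with each set.

    Every set is intersected with the universe before testing; p is
    P(X >= k) drawing |query| genes from a universe containing K set
    members.  Returns one row per set (K, k, k/K, p, BH q), sorted by p.
    """
    universe_set = set(universe)
    query_set = set(query)
    stray = query_set - universe_set
    if stray:
        raise ValueError(f"query genes outside the universe, e.g. {sorted(stray)[:5]}")
    n_universe, n_query = len(universe_set), len(query_set)
    records = []
    for gene_set in sets.values():
        members = set(gene_set.genes) & universe_set
        big_k = len(members)
        k = len(members & query_set)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_query)) if big_k else 1.0
        records.append(
            {
                "set": gene_set.name,
                "K": big_k,
                "k": k,
                "k_over_K": k / big_k if big_k else 0.0,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(records).set_index("set")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out.sort_values(["p", "K"], kind="mergesort")


# ---------------------------------------------------------------------------
# GSEA
# ---------------------------------------------------------------------------

def signal_to_noise(
    matrix: pd.DataFrame, in_group_a: np.ndarray, sd_floor_fraction: float = 0.2
) -> np.ndarray:
    """GSEA-style signal-to-noise: (mA - mB) / (sA + sB) per row, with
    each sd floored at ``sd_floor_fraction * |mean|`` (or that fraction
    absolutely when the mean is 0)."""
    a = matrix.to_numpy(dtype=float)[:, in_group_a]
    b = matrix.to_numpy(dtype=float)[:, ~in_group_a]
    stats = []
    for g in (a, b):
        m = g.mean(axis=1)
        s = g.std(axis=1, ddof=1)
        floor = np.where(m != 0, sd_floor_fraction * np.abs(m), sd_floor_fraction)
        stats.append((m, np.maximum(s, floor)))
    (ma, sa), (mb, sb) = stats
    return (ma - mb) / (sa + sb)


def enrichment_score(
    ranked_stats: np.ndarray, in_set: np.ndarray, weight: float = 1.0
) -> float:
    """Weighted KS running-sum enrichment score.

    ``ranked_stats`` must already be sorted descending; ``in_set``
    flags the set members at each rank.  Hits advance the sum by
    |stat|^weight (normalized), misses retreat by 1/(N - Nh); ES is the
    deviation of largest magnitude, signed.
    """
    n = len(ranked_stats)
    n_hit = int(in_set.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("gene set must hit a strict subset of the ranking")
    hit_w = np.where(in_set, np.abs(ranked_stats) ** weight, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit stats are exactly 0: fall back to unweighted
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    running = np.cumsum(hit_w / total - (~in_set) / (n - n_hit))
    return float(running[np.argmax(np.abs(running))])


@dataclass(frozen=True)
class GseaResult:
    """Enrichment score, NES, and permutation p for one gene set."""

    set_name: str
    es: float
    nes: float
    p: float
    n_permutations: int
    permutation_type: str  # "labels" | "gene_sets"
    n_genes_in_set: int


def _collapse_to_genes(matrix: pd.DataFrame, annotation: pd.Series) -> pd.DataFrame:
    """Average probes of the same gene into one row per gene symbol."""
    symbols = annotation.reindex(matrix.index).dropna()
    collapsed = matrix.loc[symbols.index].groupby(symbols).mean()
    collapsed.index.name = "gene_symbol"
    return collapsed


def gsea(
    matrix: pd.DataFrame,
    groups: pd.Series,
    gene_set: GeneSet,
    annotation: pd.Series,
    n_permutations: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_group_for_label_permutation: int = 7,
) -> GseaResult:
    """Permutation GSEA of one gene set on a two-group contrast.

    Genes (probes collapsed by mean) are ranked by signal-to-noise
    between the two groups; the weighted KS running sum gives ES.  The
    null permutes group labels when both groups have at least
    ``min_group_for_label_permutation`` samples, otherwise it draws
    random gene sets of the same size (logged).  p is the fraction of
    same-sign permuted ES at least as extreme as the observed one, and
    NES = ES / mean |same-sign permuted ES|.
    """
    groups = pd.Series(groups, index=matrix.columns).dropna()
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels}")
    counts = groups.value_counts()
    if counts.min() < 3:
        raise ValueError("both groups need at least 3 samples")
    expr = _collapse_to_genes(matrix.loc[:, groups.index], annotation)
    in_set_genes = expr.index.isin(gene_set.genes)
    if not in_set_genes.any():
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the matrix")
    if in_set_genes.all():
        raise ValueError(f"gene set {gene_set.name!r} covers every ranked gene")
    in_a = (groups == labels[0]).to_numpy()

    stats = signal_to_noise(expr, in_a)
    order = np.argsort(-stats, kind="mergesort")
    es = enrichment_score(stats[order], in_set_genes[order], weight)

    rng = np.random.default_rng(seed)
    use_labels = counts.min() >= min_group_for_label_permutation
    perm_es = np.empty(n_permutations)
    if use_labels:
        perm_type = "labels"
        n_a = int(in_a.sum())
        for i in range(n_permutations):
            perm = np.zeros(len(groups), dtype=bool)
            perm[rng.choice(len(groups), size=n_a, replace=False)] = True
            p_stats = signal_to_noise(expr, perm)
            p_order = np.argsort(-p_stats, kind="mergesort")
            perm_es[i] = enrichment_score(p_stats[p_order], in_set_genes[p_order], weight)
    else:
        perm_type = "gene_sets"
        log.info("groups below %d samples; permuting gene sets instead of labels",
                 min_group_for_label_permutation)
        n_hit = int(in_set_genes.sum())
        ranked = stats[order]
        for i in range(n_permutations):
            mask = np.zeros(len(ranked), dtype=bool)
            mask[rng.choice(len(ranked), size=n_hit, replace=False)] = True
            perm_es[i] = enrichment_score(ranked, mask, weight)

    same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
    n_same = int(same_sign.sum())
    if n_same == 0:
        p_val, nes = 1.0, math.nan
    else:
        p_val = float((np.abs(perm_es[same_sign]) >= abs(es)).sum() / n_same)
        denom = float(np.abs(perm_es[same_sign]).mean())
        nes = es / denom if denom > 0 else math.nan
    return GseaResult(
        set_name=gene_set.name,
        es=es,
        nes=nes,
        p=p_val,
        n_permutations=n_permutations,
        permutation_type=perm_type,
        n_genes_in_set=int(in_set_genes.sum()),
    )


# ---------------------------------------------------------------------------
# instability score
# ---------------------------------------------------------------------------

def instability_score(
    matrix: pd.DataFrame,
    signature: GeneSet,
    annotation: pd.Series,
    variance_keep_fraction: float = 0.5,
    samples: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample mean of the standardized signature probes.

    Signature gene symbols are translated to probes; only the top
    ``variance_keep_fraction`` of those probes by across-sample
    variance is kept (0.5 by default — the rest are treated as
    redundant, non-responsive probes); retained probes are standardized
    to mean 0 / variance 1 and averaged per sample.
    """
    if not 0 < variance_keep_fraction <= 1:
        raise ValueError("variance_keep_fraction must lie in (0, 1]")
    members = annotation.reindex(matrix.index).isin(signature.genes)
    probes = matrix.index[members]
    if len(probes) == 0:
        raise ValueError(f"no probes map to signature {signature.name!r}")
    sub = matrix.loc[probes]
    variances = sub.var(axis=1, ddof=1)
    n_keep = max(1, math.ceil(variance_keep_fraction * len(probes)))
    kept = variances.sort_values(ascending=False, kind="mergesort").index[:n_keep]
    if (sub.loc[kept].std(axis=1, ddof=1) == 0).any():
        # constant probes can only be retained when everything is constant
        scores = pd.Series(0.0, index=matrix.columns)
    else:
        scores = standardize_probes(sub.loc[kept]).mean(axis=0)
    out = pd.DataFrame({"score": scores})
    out.index.name = "sample_id"
    out["group"] = samples["group"].reindex(out.index) if samples is not None else "unknown"
    return out


def correlate_outlier_instability(
    outliers: pd.DataFrame, instability: pd.DataFrame
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between outlier score and
    instability score on the shared samples."""
    shared = outliers.index.intersection(instability.index)
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared samples; need at least 3")
    r, p = pearsonr(
        outliers.loc[shared, "os"].to_numpy(dtype=float),
        instability.loc[shared, "score"].to_numpy(dtype=float),
    )
    return float(r), float(p)
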