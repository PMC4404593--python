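"""Paired differential expression between CUP and metastases of known origin.

Because CUPs and their comparison metastases (MOKO) sit in different
predicted tumor classes, a naive two-group test would be dominated by
class differences.  The paired test therefore fits, per probe, an
additive two-factor fixed-effects model

    expression = class effect + group effect + residual

and reports the two-sided t test of the group effect with residual
degrees of freedom n - (#classes) - 1.  Any per-class constant offset
is absorbed by the class factor, so only the CUP-vs-MOKO contrast
survives.  Classes lacking either group are excluded (with a log
notice) — the contrast is not estimable there.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .genesets import GeneSet, GeneSetCollection

log = logging.getLogger(__name__)

CUP_GROUP = "CUP"
MOKO_GROUP = "MOKO"


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValueError("pvalues must be a non-empty 1-D sequence")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_class_test(
    matrix: pd.DataFrame,
    groups: pd.Series,
    classes: pd.Series,
) -> pd.DataFrame:
    """Class-eliminating linear model test of CUP vs MOKO, per probe.

    ``groups`` holds "CUP" / "MOKO" per sample; ``classes`` the
    (typically classifier-predicted) tumor class used for pairing.
    Returns a table indexed by probe with columns ``effect`` (mean
    CUP - MOKO difference after class elimination, log2 units), ``t``,
    ``p``, ``q`` (BH) and ``direction``.
    """
    groups = pd.Series(groups, index=matrix.columns)
    classes = pd.Series(classes, index=matrix.columns)
    bad = set(groups.dropna()) - {CUP_GROUP, MOKO_GROUP}
    if bad:
        raise ValueError(f"groups must be {CUP_GROUP!r}/{MOKO_GROUP!r}; got {sorted(bad)}")

    keep_classes = []
    for cls, sub in groups.groupby(classes):
        present = set(sub)
        if present >= {CUP_GROUP, MOKO_GROUP}:
            keep_classes.append(cls)
        else:
            log.info("class %r lacks %s samples; excluded from the paired test",
                     cls, (present ^ {CUP_GROUP, MOKO_GROUP}))
    if not keep_classes:
        raise ValueError("no class contains both CUP and MOKO samples")
    keep = classes.isin(keep_classes) & groups.notna()
    cols = matrix.columns[keep.to_numpy()]
    sub_classes = classes.loc[cols]
    sub_groups = groups.loc[cols]

    n = len(cols)
    k = len(keep_classes)
    df = n - k - 1
    if df < 1:
        raise ValueError(f"only {n} samples across {k} classes: no residual degrees of freedom")

    # design: intercept + (k-1) class dummies + CUP indicator
    design = np.ones((n, k + 1))
    for j, cls in enumerate(keep_classes[1:], start=1):
        design[:, j] = (sub_classes == cls).to_numpy(dtype=float)
    design[:, k] = (sub_groups == CUP_GROUP).to_numpy(dtype=float)

    y = matrix.loc[:, cols].to_numpy(dtype=float).T  # n x probes
    q_mat, r_mat = np.linalg.qr(design)
    beta = np.linalg.solve(r_mat, q_mat.T @ y)  # (k+1) x probes
    resid = y - design @ beta
    rss = (resid**2).sum(axis=0)
    sigma2 = rss / df
    xtx_inv = np.linalg.inv(r_mat.T @ r_mat)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[k, k], 0.0))
    effect = beta[k]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, effect / se, 0.0)
    p = 2.0 * t_dist.sf(np.abs(t_stat), df)
    out = pd.DataFrame(
        {
            "effect": effect,
            "t": t_stat,
            "p": p,
            "q": bh_fdr(p),
            "direction": np.where(effect >= 0, "up", "down"),
        },
        index=matrix.index,
    )
    out.index.name = "probe_id"
    return out


@dataclass(frozen=True)
class CoreSet:
    """Probes (and their deduplicated genes) most differential in CUP."""

    up_probes: tuple[str, ...]
    down_probes: tuple[str, ...]
    up_genes: tuple[str, ...]
    down_genes: tuple[str, ...]
    p_cutoff: float

    def to_gene_sets(self) -> GeneSetCollection:
        """Expose the up/down gene lists as a GMT-serializable collection."""
        collection = GeneSetCollection()
        if self.up_genes:
            collection.add(
                GeneSet("cup_core_up", f"genes up in CUP at p<{self.p_cutoff:g}", self.up_genes)
            )
        if self.down_genes:
            collection.add(
                GeneSet("cup_core_down", f"genes down in CUP at p<{self.p_cutoff:g}", self.down_genes)
            )
        return collection


def extract_core_set(
    de: pd.DataFrame,
    annotation: pd.Series,
    p_cutoff: float = 1e-8,
) -> CoreSet:
    """Split probes passing the cutoff by direction and translate to genes.

    Unannotated probes are dropped from the gene lists; repeated
    symbols (several probes per gene) are deduplicated preserving
    probe order.  1e-8 is the conventional cutoff for a large cohort;
    smaller studies need a laxer one.
    """
    if not 0 < p_cutoff < 1:
        raise ValueError(f"p_cutoff must lie in (0, 1), got {p_cutoff}")
    hits = de[de["p"] < p_cutoff]
    up = hits.index[hits["effect"] > 0]
    down = hits.index[hits["effect"] < 0]

    def genes(probes) -> tuple[str, ...]:
        symbols = annotation.reindex(probes).dropna()
        return tuple(dict.fromkeys(symbols))

    return CoreSet(
        up_probes=tuple(up),
        down_probes=tuple(down),
        up_genes=genes(up),
        down_genes=genes(down),
        p_cutoff=p_cutoff,
    )
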