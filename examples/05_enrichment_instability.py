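"""Characterize the CUP core set: overlap enrichment, GSEA, and the
chromosomal-instability score with its outlier-score correlation.
"""

import numpy as np
import pandas as pd

from cuporigin import (
    CohortConfig,
    correlate_outlier_instability,
    extract_core_set,
    generate_cohort,
    generate_gene_sets,
    gsea,
    instability_score,
    iqr_filter,
    loocv_outlier_scores,
    overlap_test,
    paired_class_test,
)

matrix, samples, truth = generate_cohort(CohortConfig(seed=42))
filtered = iqr_filter(matrix, 0.8)
gene_sets = generate_gene_sets(truth, n_decoys=20, decoy_size=100, seed=7)

tumors = samples["group"].isin(["CUP", "metastasis"])
groups = pd.Series(
    np.where(samples.loc[tumors, "group"] == "CUP", "CUP", "MOKO"),
    index=samples.index[tumors],
)
classes = truth.samples.loc[groups.index, "true_class"]
de = paired_class_test(filtered.loc[:, groups.index], groups, classes)
core = extract_core_set(de, truth.annotation, p_cutoff=1e-6)

universe = list(dict.fromkeys(truth.annotation.reindex(filtered.index).dropna()))
overlaps = overlap_test(list(core.up_genes), gene_sets, universe)
print("top overlap hits for the up-regulated core set (k/K of Table-style output):")
print(overlaps.head(3)[["K", "k", "k_over_K", "p", "q"]].to_string())

cin_set = gene_sets["instability_signature"]
result = gsea(
    filtered.loc[:, groups.index], groups, cin_set, truth.annotation,
    n_permutations=200, seed=3,
)
print(f"\nGSEA of the instability signature: ES={result.es:.3f} "
      f"NES={result.nes:.2f} p={result.p:.3g} ({result.permutation_type} permutation)")

cin = instability_score(filtered, cin_set, truth.annotation, samples=samples)
print("\nmean instability score by group (normal < primary < MOKO < CUP expected):")
print(cin.groupby("group")["score"].mean().round(3).to_string())

outliers = loocv_outlier_scores(filtered, samples)
tumor = outliers[outliers["group"] != "normal"]
r, p = correlate_outlier_instability(tumor, cin)
print(f"\noutlier score vs instability score: Pearson r={r:.3f} (p={p:.2g})")
print("a positive r: the least class-like samples are also the most unstable")
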