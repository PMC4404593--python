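"""Generate a synthetic tumor cohort and inspect its structure.

The generator plants a per-class expression signature, an extra shift
in metastases, and gives CUP samples doubled dispersion plus an
up-shifted chromosomal-instability signature.
"""

from cuporigin import CohortConfig, generate_cohort

config = CohortConfig(seed=42)
matrix, samples, truth = generate_cohort(config)

print(f"matrix: {matrix.shape[0]} probes x {matrix.shape[1]} samples (log2 scale)")
print("samples per group:", samples["group"].value_counts().to_dict())
print("probe strata:", truth.probes["stratum"].value_counts().head(3).to_dict(), "...")
print()
print("CUP samples carry class label 'unknown' in the analyst-facing table;")
print("their generating class lives in the truth table:")
cups = samples.index[samples["group"] == "CUP"][:3]
for s in cups:
    print(f"  {s}: visible={samples.loc[s, 'class_label']!r}, "
          f"truth={truth.samples.loc[s, 'true_class']!r}")
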