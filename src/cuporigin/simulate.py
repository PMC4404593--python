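"""Synthetic expression cohorts with a known tumor-class structure.

The generator emulates the statistical shape of a multi-class bulk
expression study on the log2 scale: each tumor class elevates its own
block of signature probes, metastases carry an additional shift on
those probes, CUP samples are drawn *from* a known class (the truth a
classifier should recover) but with inflated within-class dispersion
and an up-shifted chromosomal-instability signature, and normal tissue
expresses baseline everywhere.  Every generated probe and sample is
recorded in a truth table so downstream stages can be scored against
ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genesets import GeneSet, GeneSetCollection

log = logging.getLogger(__name__)

NULL_STRATUM = "null"
INSTABILITY_STRATUM = "instability"
UNKNOWN_CLASS = "unknown"
NORMAL_CLASS = "normal"


class ConfigurationError(ValueError):
    """Raised when a cohort configuration violates an invariant."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic cohort.

    Effects are on the log2 scale.  Defaults describe a five-class
    cohort with 40 primaries and 40 metastases per class, a clearly
    separable class signature (2 log2 units against unit noise), CUPs
    with doubled within-class dispersion and a one-unit instability
    up-shift, and metastases with a smaller (0.3 unit) instability
    shift — primaries < metastases < CUP on the instability axis.
    """

    n_classes: int = 5
    n_probes: int = 2000
    probes_per_class_signature: int = 30
    n_primary_per_class: int = 40
    n_metastasis_per_class: int = 40
    n_cup: int = 40
    n_normal: int = 20
    class_effect: float = 2.0
    metastasis_effect: float = 0.5
    cup_dispersion_factor: float = 2.0
    instability_signature_size: int = 180
    instability_effect: float = 1.0
    instability_effect_metastasis: float = 0.3
    noise_sd: float = 1.0
    baseline: float = 7.0
    sex_fraction_female: float = 0.5
    sex_specific_classes: dict = field(default_factory=dict)  # class -> "M" | "F"
    two_probe_gene_fraction: float = 0.3
    seed: int = 0

    def validate(self) -> "CohortConfig":
        positive = (
            "n_classes",
            "n_probes",
            "probes_per_class_signature",
            "n_primary_per_class",
            "n_metastasis_per_class",
        )
        for name in positive:
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1 (got {getattr(self, name)})")
        for name in ("n_cup", "n_normal", "instability_signature_size"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0 (got {getattr(self, name)})")
        if self.cup_dispersion_factor < 1:
            raise ConfigurationError(
                f"cup_dispersion_factor must be >= 1 (got {self.cup_dispersion_factor})"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0 (got {self.noise_sd})")
        needed = (
            self.probes_per_class_signature * self.n_classes
            + self.instability_signature_size
        )
        if needed > self.n_probes:
            raise ConfigurationError(
                "signature probes exceed n_probes: "
                f"{self.probes_per_class_signature} x {self.n_classes} + "
                f"{self.instability_signature_size} > {self.n_probes}"
            )
        if not 0 <= self.sex_fraction_female <= 1:
            raise ConfigurationError("sex_fraction_female must lie in [0, 1]")
        if not 0 <= self.two_probe_gene_fraction <= 1:
            raise ConfigurationError("two_probe_gene_fraction must lie in [0, 1]")
        bad = set(self.sex_specific_classes.values()) - {"M", "F"}
        if bad:
            raise ConfigurationError(f"sex_specific_classes values must be M or F, got {bad}")
        unknown = set(self.sex_specific_classes) - set(self.class_names())
        if unknown:
            raise ConfigurationError(
                f"sex_specific_classes names unknown classes: {sorted(unknown)}"
            )
        return self

    def class_names(self) -> list[str]:
        return [f"class{i + 1:02d}" for i in range(self.n_classes)]


@dataclass(frozen=True)
class TruthTable:
    """Ground truth of a generated cohort.

    ``samples`` carries the true class, group and sex of every sample
    (including CUPs, whose class the sample table hides); ``probes``
    carries each probe's gene symbol and stratum — a class signature,
    the instability signature, or null.
    """

    samples: pd.DataFrame
    probes: pd.DataFrame

    @property
    def annotation(self) -> pd.Series:
        """Probe -> gene symbol mapping."""
        return self.probes["gene_symbol"]

    def probes_in_stratum(self, stratum: str) -> pd.Index:
        return self.probes.index[self.probes["stratum"] == stratum]

    def genes_in_stratum(self, stratum: str) -> list[str]:
        genes = self.probes.loc[self.probes["stratum"] == stratum, "gene_symbol"]
        return list(dict.fromkeys(genes))


def _assign_genes(config: CohortConfig, strata: pd.Series, rng: np.random.Generator) -> pd.Series:
    """Assign gene symbols probe-wise, 1-2 probes per gene within a stratum."""
    symbols = np.empty(len(strata), dtype=object)
    gene_counter = 0
    for stratum in dict.fromkeys(strata):
        idx = np.flatnonzero(strata.to_numpy() == stratum)
        pos = 0
        while pos < len(idx):
            gene_counter += 1
            symbol = f"G{gene_counter:05d}"
            take = 1
            if pos + 1 < len(idx) and rng.random() < config.two_probe_gene_fraction:
                take = 2
            for j in range(take):
                symbols[idx[pos + j]] = symbol
            pos += take
    return pd.Series(symbols, index=strata.index, name="gene_symbol")


def _draw_sex(config: CohortConfig, true_class: str, rng: np.random.Generator) -> str:
    forced = config.sex_specific_classes.get(true_class)
    if forced is not None:
        return forced
    return "F" if rng.random() < config.sex_fraction_female else "M"


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Generate (expression matrix, sample table, truth table).

    The matrix is probes x samples on the log2 scale.  The sample table
    is what an analyst would see: CUP samples carry class label
    ``unknown``; the truth table retains their generating class.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    classes = config.class_names()

    # --- probe strata ---------------------------------------------------
    probe_ids = pd.Index([f"P{i + 1:05d}" for i in range(config.n_probes)], name="probe_id")
    strata = np.full(config.n_probes, NULL_STRATUM, dtype=object)
    pos = 0
    sig_slices: dict[str, slice] = {}
    for cls in classes:
        sig_slices[cls] = slice(pos, pos + config.probes_per_class_signature)
        strata[sig_slices[cls]] = f"class_signature:{cls}"
        pos += config.probes_per_class_signature
    instability_slice = slice(pos, pos + config.instability_signature_size)
    strata[instability_slice] = INSTABILITY_STRATUM
    strata = pd.Series(strata, index=probe_ids, name="stratum")
    genes = _assign_genes(config, strata, rng)
    probe_truth = pd.DataFrame({"gene_symbol": genes, "stratum": strata})

    # --- samples --------------------------------------------------------
    records = []  # (sample_id, true_class, group, sex)
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"S{counter:04d}"

    for cls in classes:
        for _ in range(config.n_primary_per_class):
            records.append((new_id(), cls, "primary", _draw_sex(config, cls, rng)))
        for _ in range(config.n_metastasis_per_class):
            records.append((new_id(), cls, "metastasis", _draw_sex(config, cls, rng)))
    for _ in range(config.n_cup):
        cls = classes[rng.integers(config.n_classes)]
        records.append((new_id(), cls, "CUP", _draw_sex(config, cls, rng)))
    for _ in range(config.n_normal):
        records.append((new_id(), NORMAL_CLASS, "normal", _draw_sex(config, NORMAL_CLASS, rng)))

    sample_truth = pd.DataFrame(
        records, columns=["sample_id", "true_class", "group", "sex"]
    ).set_index("sample_id")

    # --- expression values ----------------------------------------------
    n_samples = len(sample_truth)
    means = np.full((config.n_probes, n_samples), config.baseline, dtype=float)
    sds = np.full(n_samples, config.noise_sd, dtype=float)
    for j, (_, row) in enumerate(sample_truth.iterrows()):
        cls, group = row["true_class"], row["group"]
        if cls in sig_slices:
            means[sig_slices[cls], j] += config.class_effect
            if group in ("metastasis", "CUP"):
                means[sig_slices[cls], j] += config.metastasis_effect
        if group == "CUP":
            means[instability_slice, j] += config.instability_effect
            sds[j] *= config.cup_dispersion_factor
        elif group == "metastasis":
            means[instability_slice, j] += config.instability_effect_metastasis

    values = means + rng.normal(size=(config.n_probes, n_samples)) * sds[None, :]
    matrix = pd.DataFrame(values, index=probe_ids, columns=sample_truth.index)

    samples = sample_truth.rename(columns={"true_class": "class_label"}).copy()
    samples.loc[samples["group"] == "CUP", "class_label"] = UNKNOWN_CLASS

    return matrix, samples, TruthTable(samples=sample_truth, probes=probe_truth)


def generate_gene_sets(
    truth: TruthTable,
    n_decoys: int = 0,
    decoy_size: int = 50,
    seed: int = 0,
) -> GeneSetCollection:
    """Matched gene sets: one per class signature, one instability set,
    plus ``n_decoys`` random sets drawn uniformly from all genes."""
    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    strata = truth.probes["stratum"]
    for stratum in dict.fromkeys(strata):
        if stratum.startswith("class_signature:"):
            cls = stratum.split(":", 1)[1]
            collection.add(
                GeneSet(
                    name=f"{cls}_signature",
                    description=f"planted signature genes of {cls}",
                    genes=tuple(truth.genes_in_stratum(stratum)),
                )
            )
    if (strata == INSTABILITY_STRATUM).any():
        collection.add(
            GeneSet(
                name="instability_signature",
                description="planted chromosomal-instability signature genes",
                genes=tuple(truth.genes_in_stratum(INSTABILITY_STRATUM)),
            )
        )
    all_genes = list(dict.fromkeys(truth.probes["gene_symbol"]))
    if n_decoys > 0:
        if decoy_size > len(all_genes):
            raise ConfigurationError(
                f"decoy_size {decoy_size} exceeds the {len(all_genes)} annotated genes"
            )
        # decoys are simple random draws from the whole gene universe, so
        # their overlap with any fixed query is exactly hypergeometric
        for d in range(n_decoys):
            members = rng.choice(all_genes, size=decoy_size, replace=False)
            collection.add(
                GeneSet(
                    name=f"decoy_{d + 1:03d}",
                    description="random genes from the cohort universe",
                    genes=tuple(sorted(members)),
                )
            )
    return collection


def zero_effect_config(base: CohortConfig | None = None, **overrides) -> CohortConfig:
    """A no-signal variant of a configuration (all effects zero,
    dispersion 1); downstream classification should be at chance."""
    base = base or CohortConfig()
    return replace(
        base,
        class_effect=0.0,
        metastasis_effect=0.0,
        cup_dispersion_factor=1.0,
        instability_effect=0.0,
        instability_effect_metastasis=0.0,
        **overrides,
    )
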