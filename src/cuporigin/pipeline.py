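"""End-to-end orchestration: classify, score outliers, paired DE,
enrichment and instability, from one configuration.

The configuration is a plain YAML document with three top-level keys:
``inputs`` (paths; when no matrix is given a synthetic cohort is
generated), ``parameters`` (stage settings) and ``seed``.  Unknown
keys are rejected.  Every run writes its result tables plus a
``manifest.json`` recording resolved parameters, package version and
input checksums, which suffices to re-run identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, differential, enrichment, io, outlier, preprocess
from .genesets import read_gmt, write_gmt
from .simulate import CohortConfig, TruthTable, generate_cohort, generate_gene_sets

log = logging.getLogger(__name__)

_DEFAULT_PARAMETERS = {
    "iqr_threshold": 0.8,
    "cutoff_grid": list(classify.DEFAULT_CUTOFF_GRID),
    "var_floor": 1e-6,
    "sex_specific_map": dict(classify.DEFAULT_SEX_MAP),
    "n_bins": 10,
    "curve_degree": 2,
    "de_p_cutoff": 1e-8,
    "variance_keep_fraction": 0.5,
    "n_permutations": 1000,
    "instability_set": "instability_signature",
    "n_decoys": 50,
    "decoy_size": 150,
}


class PipelineConfigError(ValueError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline configuration."""

    inputs: dict
    parameters: dict
    simulate: dict
    seed: int

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - {"inputs", "parameters", "simulate", "seed"}
        if unknown:
            raise PipelineConfigError(f"unknown configuration key(s): {sorted(unknown)}")
        inputs = dict(raw.get("inputs") or {})
        bad = set(inputs) - {"matrix", "samples", "annotation", "gene_sets"}
        if bad:
            raise PipelineConfigError(f"unknown input key(s): {sorted(bad)}")
        for name, path in inputs.items():
            if path is not None and not Path(path).exists():
                raise PipelineConfigError(f"input {name!r}: no such file {path}")
        params = dict(_DEFAULT_PARAMETERS)
        extra = set(raw.get("parameters") or {}) - set(_DEFAULT_PARAMETERS)
        if extra:
            raise PipelineConfigError(f"unknown parameter(s): {sorted(extra)}")
        params.update(raw.get("parameters") or {})
        simulate = dict(raw.get("simulate") or {})
        allowed = {f.name for f in dataclasses.fields(CohortConfig)}
        bad = set(simulate) - allowed
        if bad:
            raise PipelineConfigError(f"unknown simulate key(s): {sorted(bad)}")
        return cls(
            inputs=inputs,
            parameters=params,
            simulate=simulate,
            seed=int(raw.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage; returns the manifest dictionary.

    On stage failure the exception propagates with the stage name in
    the log; tables written by earlier stages are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = config.parameters
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": params,
        "inputs": {},
        "stages": {},
    }

    stage = "load"
    try:
        gene_sets = None
        truth: TruthTable | None = None
        if config.inputs.get("matrix"):
            matrix = io.read_matrix(config.inputs["matrix"])
            samples = io.align(matrix, io.read_samples(config.inputs["samples"]))
            annotation = io.read_annotation(config.inputs["annotation"])
            for name, path in config.inputs.items():
                if path:
                    manifest["inputs"][name] = {"path": str(path), "sha256": _sha256(Path(path))}
            if config.inputs.get("gene_sets"):
                gene_sets = read_gmt(config.inputs["gene_sets"])
        else:
            cohort_config = CohortConfig(**{**config.simulate, "seed": config.seed})
            matrix, samples, truth = generate_cohort(cohort_config)
            annotation = truth.annotation
            gene_sets = generate_gene_sets(
                truth,
                n_decoys=int(params["n_decoys"]),
                decoy_size=int(params["decoy_size"]),
                seed=config.seed + 1,
            )
            io.write_matrix(matrix, out / "matrix.tsv")
            io.write_samples(samples, out / "samples.tsv")
            io.write_samples(truth.samples, out / "truth_samples.tsv")
            truth.probes.to_csv(out / "truth_probes.tsv", sep="\t")
            write_gmt(gene_sets, out / "gene_sets.gmt")
            manifest["inputs"]["simulated"] = dataclasses.asdict(cohort_config)
        log.info("stage %s: %d probes x %d samples", stage, *matrix.shape)

        stage = "filter"
        filtered = preprocess.iqr_filter(matrix, params["iqr_threshold"])
        manifest["stages"][stage] = {"probes_kept": int(filtered.shape[0])}
        log.info("stage %s: %d probes retained", stage, filtered.shape[0])

        stage = "train"
        known = samples["class_label"] != "unknown"
        train_matrix = filtered.loc[:, known.to_numpy()]
        train_classes = samples.loc[known, "class_label"]
        grid = classify.loocv_grid_search(
            train_matrix,
            train_classes,
            cutoff_grid=tuple(params["cutoff_grid"]),
            var_floor=params["var_floor"],
        )
        grid.accuracies.rename("loocv_accuracy").to_csv(out / "grid_search.tsv", sep="\t")
        stats = classify.f_statistics(train_matrix, train_classes)
        selected = classify.select_probes(stats, grid.best_cutoff)
        if len(selected) == 0:
            selected = stats.sort_values("p").index[:1]
        model = classify.fit_lda(
            train_matrix.loc[selected], train_classes, var_floor=params["var_floor"]
        )
        model.to_json(out / "model.json")
        predictions = classify.predict_matrix(
            model,
            filtered.loc[selected],
            samples,
            sex_specific_map=params["sex_specific_map"],
        )
        predictions.to_csv(out / "predictions.tsv", sep="\t")
        manifest["stages"][stage] = {
            "best_cutoff": grid.best_cutoff,
            "loocv_accuracy": grid.best_accuracy,
            "n_selected_probes": int(len(selected)),
        }
        log.info("stage %s: cutoff %.1e, LOOCV accuracy %.3f, %d probes",
                 stage, grid.best_cutoff, grid.best_accuracy, len(selected))

        stage = "outlier"
        outliers = outlier.loocv_outlier_scores(
            filtered.loc[selected], samples, var_floor=params["var_floor"]
        )
        outliers.to_csv(out / "outliers.tsv", sep="\t")
        bins = outlier.bin_error_rates(outliers, n_bins=int(params["n_bins"]))
        bins.to_csv(out / "error_bins.tsv", sep="\t")
        curve = outlier.fit_error_curve(bins, degree=int(params["curve_degree"]))
        manifest["stages"][stage] = {
            "curve_coefficients": curve.coefficients.tolist(),
            "median_os_by_group": outliers.groupby("group")["os"].median().to_dict(),
        }

        stage = "differential"
        pred_class = predictions["predicted_class"]
        is_cup = samples["group"] == "CUP"
        is_moko = samples["group"] == "metastasis"
        usable = (is_cup & (pred_class != "normal")) | is_moko
        de_groups = pd.Series(
            np.where(is_cup[usable], differential.CUP_GROUP, differential.MOKO_GROUP),
            index=samples.index[usable],
        )
        de = differential.paired_class_test(
            filtered.loc[:, usable.to_numpy()], de_groups, pred_class[usable]
        )
        de.to_csv(out / "differential.tsv", sep="\t")
        core = differential.extract_core_set(de, annotation, p_cutoff=params["de_p_cutoff"])
        if core.up_genes or core.down_genes:
            write_gmt(core.to_gene_sets(), out / "cup_core.gmt")
        manifest["stages"][stage] = {
            "n_up_probes": len(core.up_probes),
            "n_down_probes": len(core.down_probes),
            "n_up_genes": len(core.up_genes),
            "n_down_genes": len(core.down_genes),
        }
        log.info("stage %s: %d up / %d down probes at p<%g",
                 stage, len(core.up_probes), len(core.down_probes), params["de_p_cutoff"])

        stage = "enrichment"
        enrichment_summary: dict = {}
        if gene_sets is not None:
            universe = list(dict.fromkeys(annotation.reindex(filtered.index).dropna()))
            for direction, genes in (("up", core.up_genes), ("down", core.down_genes)):
                if genes:
                    table = enrichment.overlap_test(list(genes), gene_sets, universe)
                    table.to_csv(out / f"overlap_{direction}.tsv", sep="\t")
                    enrichment_summary[f"top_overlap_{direction}"] = str(table.index[0])
            set_name = params["instability_set"]
            if set_name in gene_sets:
                centered = preprocess.center_within_groups(
                    filtered.loc[:, usable.to_numpy()], pred_class[usable]
                )
                result = enrichment.gsea(
                    centered,
                    de_groups,
                    gene_sets[set_name],
                    annotation,
                    n_permutations=int(params["n_permutations"]),
                    seed=config.seed + 2,
                )
                enrichment_summary["gsea"] = dataclasses.asdict(result)
        manifest["stages"][stage] = enrichment_summary

        stage = "instability"
        instability_summary: dict = {}
        if gene_sets is not None and params["instability_set"] in gene_sets:
            cin = enrichment.instability_score(
                filtered,
                gene_sets[params["instability_set"]],
                annotation,
                variance_keep_fraction=params["variance_keep_fraction"],
                samples=samples,
            )
            cin.to_csv(out / "instability.tsv", sep="\t")
            tumor = outliers[outliers["group"] != "normal"]
            r, p = enrichment.correlate_outlier_instability(tumor, cin)
            instability_summary = {
                "mean_score_by_group": cin.groupby("group")["score"].mean().to_dict(),
                "outlier_correlation_r": r,
                "outlier_correlation_p": p,
            }
            log.info("stage %s: outlier-instability r=%.3f (p=%.2e)", stage, r, p)
        manifest["stages"][stage] = instability_summary
    except Exception:
        log.exception("pipeline failed in stage %r", stage)
        raise

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
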