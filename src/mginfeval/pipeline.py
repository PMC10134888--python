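"""End-to-end pipeline: simulate → cluster → restrict → evaluate → report.

Every stage writes its outputs before the next begins, a run manifest records
every resolved parameter, and two runs with equal manifests produce identical
files.  The report stage condenses the per-record outputs into one table per
headline analysis: abundance concordance by cluster and by category, Pt
concordance, permutation-null quantiles, and the composition → category
coupling grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .community import (
    cut_clusters,
    jsd_distance_matrix,
    validate_clustering,
    ward_hierarchical_clustering,
)
from .concordance import (
    PermutationPlan,
    feature_concordance,
    permutation_robustness,
    restrict_to_shared_features,
    summarize_concordance,
)
from .differential import pvalue_concordance, summarize_pconcordance
from .regression import RATIO_PREDICTOR, taxon_category_coupling
from .simulate import GeneratorConfig, generate_paired_dataset
from .tables import (
    AbundanceTable,
    FeatureAnnotation,
    SampleFrame,
    align_samples,
    read_abundance_table,
    read_feature_annotation,
    read_sample_frame,
)

__all__ = ["RunConfig", "run_pipeline", "build_report", "PipelineError"]

logger = logging.getLogger("mginfeval")

REPORT_SECTIONS = (
    "concordance_by_cluster",
    "concordance_by_category",
    "pt_concordance",
    "permutation_null",
    "coupling",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible run needs.

    Either ``generator`` (synthetic data is produced in-run) or the four input
    paths must be supplied.  ``predicted_paths`` maps a method label to its
    KO-table path.
    """

    out_dir: str | Path = "mginfeval_run"
    seed: int = 0
    generator: GeneratorConfig | None = None
    taxon_path: str | Path | None = None
    observed_path: str | Path | None = None
    predicted_paths: Mapping[str, str | Path] = field(default_factory=dict)
    metadata_path: str | Path | None = None
    annotation_path: str | Path | None = None
    k: int = 3
    validate_k: Sequence[int] = (2, 3, 4, 5, 6)
    strata: Sequence[str] = ("overall", "cluster")
    n_permutations: int = 0
    predictors: Sequence[str] = ("L_crispatus", "L_iners", RATIO_PREDICTOR)

    def manifest(self) -> dict:
        gen = None
        if self.generator is not None:
            gen = {
                "seed": self.generator.seed,
                "n_samples_per_cluster": dict(self.generator.n_samples_per_cluster),
                "n_cases_per_cluster": dict(self.generator.n_cases_per_cluster),
                "dominance_mean": dict(self.generator.dominance_mean),
                "dirichlet_concentration": dict(
                    self.generator.dirichlet_concentration
                ),
                "n_taxa": self.generator.n_taxa,
                "n_kos": self.generator.n_kos,
                "noise_sd": self.generator.noise_sd,
                "reference_modes": {
                    label: ref.mode for label, ref in self.generator.reference.items()
                },
            }
        return {
            "package_version": __version__,
            "seed": self.seed,
            "generator": gen,
            "taxon_path": str(self.taxon_path) if self.taxon_path else None,
            "observed_path": str(self.observed_path) if self.observed_path else None,
            "predicted_paths": {k: str(v) for k, v in self.predicted_paths.items()},
            "metadata_path": str(self.metadata_path) if self.metadata_path else None,
            "annotation_path": str(self.annotation_path)
            if self.annotation_path
            else None,
            "k": self.k,
            "validate_k": list(self.validate_k),
            "strata": list(self.strata),
            "n_permutations": self.n_permutations,
            "predictors": list(self.predictors),
        }


def _load_inputs(config: RunConfig):
    if config.generator is not None:
        ds = generate_paired_dataset(config.generator)
        return ds.taxon_table, ds.observed_ko, dict(ds.predicted_ko), ds.frame, ds.annotation
    for name in ("taxon_path", "observed_path", "metadata_path", "annotation_path"):
        value = getattr(config, name)
        if value is None:
            raise PipelineError(f"stage load: missing required input {name}")
        if not Path(value).exists():
            raise PipelineError(f"stage load: input file not found: {value}")
    if not config.predicted_paths:
        raise PipelineError("stage load: at least one predicted table is required")
    taxon = read_abundance_table(config.taxon_path, scale_hint="relative")
    observed = read_abundance_table(config.observed_path, scale_hint="relative")
    predicted = {
        label: read_abundance_table(path, scale_hint="relative")
        for label, path in config.predicted_paths.items()
    }
    frame = read_sample_frame(config.metadata_path)
    annotation = read_feature_annotation(config.annotation_path)
    tables, frame = align_samples([taxon, observed, *predicted.values()], frame)
    taxon, observed = tables[0], tables[1]
    predicted = dict(zip(predicted.keys(), tables[2:]))
    return taxon, observed, predicted, frame, annotation


def run_pipeline(config: RunConfig) -> Path:
    """Execute every stage; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(config.manifest(), fh, sort_keys=True)

    def _stage(name):
        logger.info("stage %s", name)

    try:
        _stage("load")
        taxon, observed, predicted, frame, annotation = _load_inputs(config)
        if config.generator is not None:
            generate_paired_dataset(config.generator, out / "simulated")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage load: {exc}") from exc

    try:
        _stage("cluster")
        distances = jsd_distance_matrix(taxon)
        dendrogram = ward_hierarchical_clustering(distances)
        labels = cut_clusters(dendrogram, config.k)
        valid_k = [k for k in config.validate_k if 1 < k <= distances.n]
        validation = validate_clustering(
            distances, dendrogram, valid_k,
            neighbors=min(10, distances.n - 1),
        )
        frame = frame.with_cluster(labels.map(lambda v: f"cluster_{v}"))
        labels.rename("cluster").to_frame().assign(
            cluster=frame.cluster
        ).to_csv(out / "clusters.tsv", sep="\t")
        pd.DataFrame([vars(v) for v in validation]).to_csv(
            out / "cluster_validation.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage cluster: {exc}") from exc

    try:
        _stage("restrict")
        obs_cut, pred_cut, shared = restrict_to_shared_features(observed, predicted)
        pd.DataFrame(
            {"source": list(shared.source_counts), "n_positive": list(shared.source_counts.values())}
        ).assign(n_shared=shared.n_shared).to_csv(
            out / "shared_features.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage restrict: {exc}") from exc

    try:
        _stage("evaluate-abundance")
        records = feature_concordance(
            obs_cut, pred_cut, frame, config.strata, annotation
        )
        records.to_csv(out / "concordance_records.tsv", sep="\t", index=False)
        summarize_concordance(records).to_csv(
            out / "concordance_summary.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage evaluate-abundance: {exc}") from exc

    try:
        _stage("evaluate-pvalue")
        pt_records, pconc = pvalue_concordance(
            obs_cut, pred_cut, frame, config.strata, annotation
        )
        pt_records.to_csv(out / "pt_records.tsv", sep="\t", index=False)
        summarize_pconcordance(pconc).to_csv(
            out / "pt_concordance.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage evaluate-pvalue: {exc}") from exc

    if config.n_permutations > 0:
        try:
            _stage("permutation-null")
            plan = PermutationPlan(config.n_permutations, config.seed)
            _, grand_abund = permutation_robustness(
                obs_cut, pred_cut, plan,
                evaluator=lambda o, p: feature_concordance(o, p, frame, ("overall",)),
                summarizer=summarize_concordance,
            )
            grand_abund.to_csv(
                out / "permutation_null_abundance.tsv", sep="\t", index=False
            )
            _, grand_pt = permutation_robustness(
                obs_cut, pred_cut, plan,
                evaluator=lambda o, p: pvalue_concordance(o, p, frame, ("overall",))[1],
                summarizer=summarize_pconcordance,
            )
            grand_pt.to_csv(
                out / "permutation_null_pvalue.tsv", sep="\t", index=False
            )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"stage permutation-null: {exc}") from exc

    try:
        _stage("coupling")
        predictors = [
            p for p in config.predictors
            if p == RATIO_PREDICTOR or p in taxon.data.columns
        ]
        results = taxon_category_coupling(taxon, observed, annotation, predictors)
        pd.DataFrame([vars(r) for r in results]).to_csv(
            out / "coupling.tsv", sep="\t", index=False
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage coupling: {exc}") from exc

    _stage("report")
    build_report(out)
    return out


def build_report(outputs_dir: str | Path) -> Path:
    """Condense stage outputs into one table per headline analysis.

    Missing upstream outputs are noted in the report manifest rather than
    failing the whole report.
    """
    src = Path(outputs_dir)
    if not src.exists() or not any(src.iterdir()):
        raise PipelineError(f"stage report: no outputs found in {src}")
    dest = src / "report"
    dest.mkdir(exist_ok=True)
    status: dict[str, str] = {}

    conc_path = src / "concordance_summary.tsv"
    if conc_path.exists():
        summary = pd.read_csv(conc_path, sep="\t")
        by_cluster = summary[summary["stratum_type"].isin(["overall", "cluster"])]
        by_cluster.to_csv(dest / "concordance_by_cluster.tsv", sep="\t", index=False)
        status["concordance_by_cluster"] = "ok"
        by_cat = summary[summary["stratum_type"] == "category"]
        by_cat.to_csv(dest / "concordance_by_category.tsv", sep="\t", index=False)
        status["concordance_by_category"] = "ok"
    else:
        status["concordance_by_cluster"] = "missing"
        status["concordance_by_category"] = "missing"

    pt_path = src / "pt_concordance.tsv"
    if pt_path.exists():
        pd.read_csv(pt_path, sep="\t").to_csv(
            dest / "pt_concordance.tsv", sep="\t", index=False
        )
        status["pt_concordance"] = "ok"
    else:
        status["pt_concordance"] = "missing"

    null_parts = []
    for name, label in (
        ("permutation_null_abundance.tsv", "abundance"),
        ("permutation_null_pvalue.tsv", "pt"),
    ):
        p = src / name
        if p.exists():
            part = pd.read_csv(p, sep="\t")
            part.insert(0, "evaluation", label)
            null_parts.append(part)
    if null_parts:
        pd.concat(null_parts, ignore_index=True).to_csv(
            dest / "permutation_null.tsv", sep="\t", index=False
        )
        status["permutation_null"] = "ok"
    else:
        status["permutation_null"] = "absent (run with --permutations > 0)"

    coup_path = src / "coupling.tsv"
    if coup_path.exists():
        pd.read_csv(coup_path, sep="\t").to_csv(
            dest / "coupling.tsv", sep="\t", index=False
        )
        status["coupling"] = "ok"
    else:
        status["coupling"] = "missing"

    with open(dest / "report_manifest.yaml", "w") as fh:
        yaml.safe_dump({"sections": status}, fh, sort_keys=True)
    return dest
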