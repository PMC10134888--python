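"""Synthetic paired taxon / KO data with vaginal community structure.

The generator emulates the statistical structure under which differential
metagenome-inference error arises in vaginal microbiome data:

* three community clusters — *L. crispatus*-dominated, *L. iners*-dominated,
  and mixed — with configurable sizes and case/control counts (defaults
  17/31/24 samples, 11/13/11 early-preterm cases);
* within-cluster compositions drawn from a Dirichlet centred on a cluster
  template whose dominant taxon sits at the configured dominance mean
  (defaults 0.87 for the crispatus-like and 0.86 for the iners-like taxon);
* per-taxon genome content coupling taxa to KO functional categories, with
  the iners-like taxon enriched for genetic-information-processing genes and
  depleted for uncharacterized genes relative to the crispatus-like taxon;
* an "observed" KO table computed as composition × genome content with
  multiplicative log-normal noise, standing in for shotgun sequencing;
* "predicted" KO tables degraded by a per-taxon reference-fidelity model with
  two failure modes: ``retain_blend`` (genome rows blended toward a perturbed
  row as reference similarity falls — a PICRUSt2-like mechanism) and
  ``discard_renormalize`` (taxa below an average-nucleotide-identity
  threshold dropped before inference — a Tax4Fun2-like mechanism).

Every stochastic step draws from a named child stream of the single config
seed, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from ._rng import child_rng
from .tables import (
    AbundanceTable,
    FeatureAnnotation,
    SampleFrame,
    TableError,
    write_abundance_table,
    write_feature_annotation,
    write_sample_frame,
)

__all__ = [
    "GeneratorConfig",
    "GenomeContent",
    "ReferenceModel",
    "PairedDataset",
    "build_genome_content",
    "sample_taxon_table",
    "compute_observed_ko",
    "compute_predicted_ko",
    "generate_paired_dataset",
    "CATEGORIES",
    "TAXON_CRISPATUS",
    "TAXON_INERS",
    "CAT_GIP",
    "CAT_UNCHAR",
]

TAXON_CRISPATUS = "L_crispatus"
TAXON_INERS = "L_iners"

_BASE_TAXA = (
    TAXON_CRISPATUS,
    TAXON_INERS,
    "Gardnerella",
    "Atopobium",
    "Prevotella",
    "Sneathia",
    "Megasphaera",
    "L_jensenii",
)

CAT_GIP = "genetic_information_processing"
CAT_UNCHAR = "uncharacterized"

CATEGORIES = (
    "metabolism",
    CAT_GIP,
    "environmental_information_processing",
    "cellular_processes",
    "brite_hierarchies",
    CAT_UNCHAR,
)

# fraction of the KO catalogue assigned to each level-1 category
_CATEGORY_PROPORTIONS = {
    "metabolism": 0.40,
    CAT_GIP: 0.15,
    "environmental_information_processing": 0.10,
    "cellular_processes": 0.10,
    "brite_hierarchies": 0.15,
    CAT_UNCHAR: 0.10,
}

# per-taxon genome mass over level-1 categories; the crispatus/iners contrast
# in genetic information processing vs uncharacterized genes carries the
# taxon→function coupling the downstream regressions measure
_DEFAULT_CATEGORY_WEIGHTS: dict[str, dict[str, float]] = {
    TAXON_CRISPATUS: {
        "metabolism": 0.46,
        CAT_GIP: 0.10,
        "environmental_information_processing": 0.10,
        "cellular_processes": 0.09,
        "brite_hierarchies": 0.05,
        CAT_UNCHAR: 0.20,
    },
    TAXON_INERS: {
        "metabolism": 0.33,
        CAT_GIP: 0.32,
        "environmental_information_processing": 0.10,
        "cellular_processes": 0.10,
        "brite_hierarchies": 0.10,
        CAT_UNCHAR: 0.05,
    },
    "_other": {
        "metabolism": 0.40,
        CAT_GIP: 0.18,
        "environmental_information_processing": 0.11,
        "cellular_processes": 0.10,
        "brite_hierarchies": 0.11,
        CAT_UNCHAR: 0.10,
    },
}

# minor-taxon profiles (unnormalized) completing each dominated-cluster
# template, and the full mixed-cluster template
_CRISP_MINOR = {
    TAXON_INERS: 4.0,
    "Gardnerella": 2.0,
    "Atopobium": 1.5,
    "Prevotella": 1.5,
    "Sneathia": 1.0,
    "Megasphaera": 1.0,
    "L_jensenii": 2.0,
}
_INERS_MINOR = {
    TAXON_CRISPATUS: 4.0,
    "Gardnerella": 3.0,
    "Atopobium": 2.0,
    "Prevotella": 2.0,
    "Sneathia": 1.0,
    "Megasphaera": 1.0,
    "L_jensenii": 1.0,
}
_MIXED_TEMPLATE = {
    "Gardnerella": 0.30,
    "Atopobium": 0.15,
    "Prevotella": 0.15,
    "Sneathia": 0.10,
    "Megasphaera": 0.10,
    TAXON_INERS: 0.10,
    TAXON_CRISPATUS: 0.05,
    "L_jensenii": 0.05,
}

_DEFAULT_ANI = {
    TAXON_CRISPATUS: 0.995,
    TAXON_INERS: 0.92,
    "Gardnerella": 0.96,
    "Atopobium": 0.95,
    "Prevotella": 0.97,
    "Sneathia": 0.94,
    "Megasphaera": 0.96,
    "L_jensenii": 0.98,
}

CLUSTER_CRISPATUS = "crispatus"
CLUSTER_INERS = "iners"
CLUSTER_MIXED = "mixed"


@dataclass(frozen=True)
class ReferenceModel:
    """Per-taxon reference-database fidelity and how it degrades predictions.

    ``ani`` maps each taxon to the average nucleotide identity of its nearest
    reference neighbor, in [0, 1].  ``discard_renormalize`` drops taxa with
    ani below ``ani_discard_threshold`` (default 0.97) and renormalizes the
    remainder; ``retain_blend`` keeps every taxon but replaces its genome row
    with a blend of the true row (weight ani**blend_exponent) and a fixed
    seeded log-normal perturbation of it (sd ``perturbation_sd``).
    """

    ani: Mapping[str, float]
    mode: str = "retain_blend"
    ani_discard_threshold: float = 0.97
    blend_exponent: float = 25.0
    perturbation_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("retain_blend", "discard_renormalize"):
            raise ValueError(f"unknown reference mode {self.mode!r}")
        for taxon, a in self.ani.items():
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"ani for {taxon!r} outside [0, 1]: {a}")
        if not 0.0 < self.ani_discard_threshold < 1.0:
            raise ValueError("ani_discard_threshold must lie in (0, 1)")
        if self.blend_exponent <= 0:
            raise ValueError("blend_exponent must be positive")
        if self.perturbation_sd < 0:
            raise ValueError("perturbation_sd must be non-negative")


def _default_reference() -> dict[str, ReferenceModel]:
    return {
        "blend": ReferenceModel(ani=dict(_DEFAULT_ANI), mode="retain_blend"),
        "discard": ReferenceModel(ani=dict(_DEFAULT_ANI), mode="discard_renormalize"),
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-design parameters for one synthetic paired dataset.

    Defaults reproduce the reference study design: 72 pregnant participants in
    three community clusters (17 crispatus-dominated with 11 early-preterm
    cases, 31 iners-dominated with 13 cases, 24 mixed with 11 cases), within-
    cluster dominant-taxon means of 0.87/0.86, and 500 KOs across six level-1
    functional categories.  The default case/control signal is taxonomic —
    cases' *L. crispatus* abundance is scaled by 0.3 before renormalization,
    encoding the protective crispatus–term-birth association — so predictions
    can recover it through the taxon table.  ``effect_kos`` shifts instead go
    only into the observed table (functional signal invisible to taxonomy).
    """

    n_samples_per_cluster: Mapping[str, int] = field(
        default_factory=lambda: {
            CLUSTER_CRISPATUS: 17,
            CLUSTER_INERS: 31,
            CLUSTER_MIXED: 24,
        }
    )
    n_cases_per_cluster: Mapping[str, int] = field(
        default_factory=lambda: {
            CLUSTER_CRISPATUS: 11,
            CLUSTER_INERS: 13,
            CLUSTER_MIXED: 11,
        }
    )
    dominance_mean: Mapping[str, float] = field(
        default_factory=lambda: {CLUSTER_CRISPATUS: 0.87, CLUSTER_INERS: 0.86}
    )
    dirichlet_concentration: Mapping[str, float] = field(
        default_factory=lambda: {
            CLUSTER_CRISPATUS: 15.0,
            CLUSTER_INERS: 15.0,
            CLUSTER_MIXED: 40.0,
        }
    )
    minor_profile_concentration: float = 150.0
    n_taxa: int = 8
    n_kos: int = 500
    category_weights: Mapping[str, Mapping[str, float]] | None = None
    noise_sd: float = 0.2
    effect_kos: Mapping[str, float] | None = None
    effect_taxa: Mapping[str, float] | None = field(
        default_factory=lambda: {TAXON_CRISPATUS: 0.3}
    )
    reference: Mapping[str, ReferenceModel] = field(default_factory=_default_reference)
    seed: int = 7

    def __post_init__(self) -> None:
        for c, n in self.n_samples_per_cluster.items():
            if n <= 0:
                raise ValueError(f"cluster {c!r} sample count must be positive")
            k = self.n_cases_per_cluster.get(c, 0)
            if not 0 <= k <= n:
                raise ValueError(f"cluster {c!r}: cases {k} exceed samples {n}")
        for c, m in self.dominance_mean.items():
            if not 0.0 < m < 1.0:
                raise ValueError(f"dominance_mean for {c!r} outside (0, 1): {m}")
        for c, a in self.dirichlet_concentration.items():
            if a <= 0:
                raise ValueError(f"concentration for {c!r} must be positive")
        if self.minor_profile_concentration <= 0:
            raise ValueError("minor_profile_concentration must be positive")
        if self.n_taxa < len(_BASE_TAXA):
            raise ValueError(f"n_taxa must be at least {len(_BASE_TAXA)}")
        if self.n_kos < len(CATEGORIES):
            raise ValueError("n_kos must cover every category")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def taxon_ids(self) -> tuple[str, ...]:
        extra = tuple(
            f"background_{i + 1}" for i in range(self.n_taxa - len(_BASE_TAXA))
        )
        return _BASE_TAXA + extra

    def resolved_category_weights(self) -> dict[str, dict[str, float]]:
        weights = {}
        for taxon in self.taxon_ids:
            if self.category_weights is not None and taxon in self.category_weights:
                w = dict(self.category_weights[taxon])
            else:
                w = dict(
                    _DEFAULT_CATEGORY_WEIGHTS.get(
                        taxon, _DEFAULT_CATEGORY_WEIGHTS["_other"]
                    )
                )
            total = sum(w.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"category weights for {taxon!r} sum to {total}, not 1"
                )
            weights[taxon] = w
        return weights


@dataclass(frozen=True)
class GenomeContent:
    """Row-stochastic taxon × KO weight matrix (per-taxon gene content)."""

    weights: pd.DataFrame  # index: taxon_ids; columns: feature_ids

    def __post_init__(self) -> None:
        v = self.weights.to_numpy()
        if (v < 0).any():
            raise ValueError("genome weights must be non-negative")
        sums = v.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-9:
            raise ValueError("genome rows must sum to 1 within 1e-9")

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.weights.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.weights.columns)


@dataclass(frozen=True)
class PairedDataset:
    """One synthetic study: taxa, observed KOs, predicted KOs, metadata, truth."""

    taxon_table: AbundanceTable
    observed_ko: AbundanceTable
    predicted_ko: dict[str, AbundanceTable]
    frame: SampleFrame
    annotation: FeatureAnnotation
    genome: GenomeContent
    config: GeneratorConfig
    discard_fraction: dict[str, pd.Series]

    def write(self, out_dir: str | Path) -> None:
        """Emit taxon.tsv, observed_ko.tsv, predicted_<label>.tsv, metadata.tsv,
        annotation.tsv and truth.yaml under ``out_dir``."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_abundance_table(self.taxon_table, out / "taxon.tsv")
        write_abundance_table(self.observed_ko, out / "observed_ko.tsv")
        for label, table in self.predicted_ko.items():
            write_abundance_table(table, out / f"predicted_{label}.tsv")
        write_sample_frame(self.frame, out / "metadata.tsv")
        write_feature_annotation(self.annotation, out / "annotation.tsv")
        truth = {
            "seed": self.config.seed,
            "n_samples_per_cluster": dict(self.config.n_samples_per_cluster),
            "n_cases_per_cluster": dict(self.config.n_cases_per_cluster),
            "dominance_mean": dict(self.config.dominance_mean),
            "dirichlet_concentration": dict(self.config.dirichlet_concentration),
            "minor_profile_concentration": self.config.minor_profile_concentration,
            "n_taxa": self.config.n_taxa,
            "n_kos": self.config.n_kos,
            "noise_sd": self.config.noise_sd,
            "effect_kos": dict(self.config.effect_kos or {}),
            "effect_taxa": dict(self.config.effect_taxa or {}),
            "reference": {
                label: {
                    "mode": ref.mode,
                    "ani": dict(ref.ani),
                    "ani_discard_threshold": ref.ani_discard_threshold,
                    "blend_exponent": ref.blend_exponent,
                    "perturbation_sd": ref.perturbation_sd,
                }
                for label, ref in self.config.reference.items()
            },
            "discard_fraction": {
                label: {k: float(v) for k, v in s.items()}
                for label, s in self.discard_fraction.items()
            },
        }
        with open(out / "truth.yaml", "w") as fh:
            yaml.safe_dump(truth, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# components
# ---------------------------------------------------------------------------

def _ko_ids(n_kos: int) -> list[str]:
    return [f"K{i + 1:05d}" for i in range(n_kos)]


def partition_kos(n_kos: int) -> FeatureAnnotation:
    """Assign the KO catalogue to level-1 categories at fixed proportions."""
    ids = _ko_ids(n_kos)
    counts = {c: int(round(_CATEGORY_PROPORTIONS[c] * n_kos)) for c in CATEGORIES}
    drift = n_kos - sum(counts.values())
    counts["metabolism"] += drift  # absorb rounding in the largest category
    labels: list[str] = []
    for c in CATEGORIES:
        labels.extend([c] * counts[c])
    df = pd.DataFrame({"category_l1": labels}, index=pd.Index(ids, name="feature_id"))
    return FeatureAnnotation(df)


def build_genome_content(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[GenomeContent, FeatureAnnotation]:
    """Draw per-taxon KO weights whose category masses match category_weights.

    Within each category each taxon's mass is spread over the category's KOs
    by a flat Dirichlet, so taxa differ both in category totals and in which
    individual KOs they favor.
    """
    annotation = partition_kos(config.n_kos)
    cat_members = {
        c: annotation.data.index[annotation.category_l1 == c] for c in CATEGORIES
    }
    weights = config.resolved_category_weights()
    rows = {}
    for taxon in config.taxon_ids:
        row = pd.Series(0.0, index=annotation.data.index)
        for cat, w in weights[taxon].items():
            members = cat_members.get(cat, [])
            if w > 0 and len(members) == 0:
                raise ValueError(
                    f"category {cat!r} has positive weight for {taxon!r} but no KOs"
                )
            if len(members) and w > 0:
                row[members] = rng.dirichlet(np.ones(len(members))) * w
        rows[taxon] = row / row.sum()
    df = pd.DataFrame(rows).T.loc[list(config.taxon_ids)]
    return GenomeContent(df), annotation


def _cluster_template(config: GeneratorConfig, cluster: str) -> pd.Series:
    taxa = list(config.taxon_ids)
    template = pd.Series(0.0, index=taxa)
    if cluster == CLUSTER_CRISPATUS:
        dm = config.dominance_mean[CLUSTER_CRISPATUS]
        template[TAXON_CRISPATUS] = dm
        minor = pd.Series(_CRISP_MINOR)
        template[minor.index] = minor / minor.sum() * (1.0 - dm)
    elif cluster == CLUSTER_INERS:
        dm = config.dominance_mean[CLUSTER_INERS]
        template[TAXON_INERS] = dm
        minor = pd.Series(_INERS_MINOR)
        template[minor.index] = minor / minor.sum() * (1.0 - dm)
    elif cluster == CLUSTER_MIXED:
        mixed = pd.Series(_MIXED_TEMPLATE)
        template[mixed.index] = mixed
    else:
        raise ValueError(f"unknown cluster {cluster!r}")
    extra = [t for t in taxa if t.startswith("background_")]
    if extra:
        # carve a small slice for background taxa, proportional shrink of the rest
        share = 0.10 if cluster == CLUSTER_MIXED else 0.01
        template *= 1.0 - share
        template[extra] = share / len(extra)
    return template / template.sum()


def sample_taxon_table(
    config: GeneratorConfig, rng: np.random.Generator
) -> tuple[AbundanceTable, SampleFrame]:
    """Draw per-sample compositions and case/control labels, cluster by cluster.

    Dominated clusters use a two-level composition model: the dominant-taxon
    fraction is Beta(c·m, c·(1−m)) with c the cluster's concentration and m
    its dominance mean — so the fraction itself varies realistically across
    samples — while the remaining mass is spread over the minor taxa by a
    Dirichlet centred on the cluster's minor profile at the (higher)
    ``minor_profile_concentration``, keeping the minor profile comparatively
    stable.  The mixed cluster is a plain Dirichlet(c × template).  Cluster
    means equal the templates exactly; infinite concentration collapses every
    sample onto its template.
    """
    taxa = list(config.taxon_ids)
    comp_rows, meta_rows, sample_ids = [], [], []
    counter = 0
    dominant = {CLUSTER_CRISPATUS: TAXON_CRISPATUS, CLUSTER_INERS: TAXON_INERS}
    for cluster in (CLUSTER_CRISPATUS, CLUSTER_INERS, CLUSTER_MIXED):
        n = config.n_samples_per_cluster.get(cluster, 0)
        if n == 0:
            continue
        template_s = _cluster_template(config, cluster)
        template = template_s.to_numpy()
        conc = config.dirichlet_concentration[cluster]
        if np.isinf(conc):
            comps = np.tile(template, (n, 1))
        elif cluster in dominant:
            dom = dominant[cluster]
            dom_idx = taxa.index(dom)
            dm = float(template_s[dom])
            dom_frac = rng.beta(conc * dm, conc * (1.0 - dm), size=n)
            minor = template_s.drop(dom)
            minor_profile = (minor / minor.sum()).to_numpy()
            mc = config.minor_profile_concentration
            minor_draws = rng.dirichlet(mc * minor_profile, size=n)
            comps = np.empty((n, len(taxa)))
            minor_idx = [taxa.index(t) for t in minor.index]
            comps[:, dom_idx] = dom_frac
            comps[:, minor_idx] = (1.0 - dom_frac)[:, None] * minor_draws
        else:
            comps = rng.dirichlet(conc * template, size=n)
        n_cases = config.n_cases_per_cluster.get(cluster, 0)
        outcomes = np.array(["case"] * n_cases + ["control"] * (n - n_cases))
        outcomes = rng.permutation(outcomes)
        for i in range(n):
            counter += 1
            sample_ids.append(f"S{counter:03d}")
            comp_rows.append(comps[i])
            meta_rows.append({"outcome": outcomes[i], "cluster": cluster})
    comp = pd.DataFrame(comp_rows, index=sample_ids, columns=taxa)
    comp = comp.div(comp.sum(axis=1), axis=0)
    table = AbundanceTable(comp, "relative")
    frame = SampleFrame(pd.DataFrame(meta_rows, index=sample_ids))
    return table, frame


def _renormalize(df: pd.DataFrame) -> pd.DataFrame:
    return df.div(df.sum(axis=1), axis=0)


def compute_observed_ko(
    taxon_table: AbundanceTable,
    genome: GenomeContent,
    noise_sd: float,
    rng: np.random.Generator,
    case_effects: Mapping[str, float] | None = None,
    case_ids: list[str] | None = None,
) -> AbundanceTable:
    """Observed (shotgun-like) KO table: composition × genome content + noise.

    ``case_effects`` optionally multiplies specific KO columns in case samples
    before the final renormalization, injecting a case/control signal that
    exists only at the functional level (invisible to taxonomy).
    """
    if taxon_table.scale != "relative":
        raise TableError("taxon table must be relative")
    comp = taxon_table.data[genome.taxon_ids]
    ko = comp.to_numpy() @ genome.weights.to_numpy()
    df = pd.DataFrame(ko, index=taxon_table.sample_ids, columns=genome.feature_ids)
    if case_effects:
        if case_ids is None:
            raise ValueError("case_effects given without case_ids")
        for ko_id, fold in case_effects.items():
            df.loc[case_ids, ko_id] *= fold
    if noise_sd > 0:
        df = df * rng.lognormal(mean=0.0, sigma=noise_sd, size=df.shape)
    return AbundanceTable(_renormalize(df), "relative")


def compute_predicted_ko(
    taxon_table: AbundanceTable,
    genome: GenomeContent,
    ref: ReferenceModel,
    rng: np.random.Generator,
) -> tuple[AbundanceTable, pd.Series]:
    """Predicted KO table degraded by the reference-fidelity model.

    Returns the table plus the per-sample discarded-abundance fraction (zero
    everywhere in ``retain_blend`` mode, which discards nothing).  A sample
    whose entire composition falls below the discard threshold is an error.
    """
    if taxon_table.scale != "relative":
        raise TableError("taxon table must be relative")
    comp = taxon_table.data[genome.taxon_ids].copy()
    ani = pd.Series({t: ref.ani.get(t, 1.0) for t in genome.taxon_ids})
    if ref.mode == "discard_renormalize":
        discarded = ani < ref.ani_discard_threshold
        frac = comp.loc[:, discarded[discarded].index].sum(axis=1)
        kept = comp.loc[:, discarded[~discarded].index]
        sums = kept.sum(axis=1)
        empty = sums <= 0
        if empty.any():
            raise TableError(
                f"entire composition discarded for sample(s) "
                f"{kept.index[empty].tolist()[:5]}"
            )
        kept = kept.div(sums, axis=0)
        ko = kept.to_numpy() @ genome.weights.loc[kept.columns].to_numpy()
    else:  # retain_blend
        frac = pd.Series(0.0, index=comp.index)
        true_w = genome.weights.to_numpy()
        perturbed = true_w * rng.lognormal(
            mean=0.0, sigma=ref.perturbation_sd, size=true_w.shape
        )
        perturbed /= perturbed.sum(axis=1, keepdims=True)
        blend_w = (ani.loc[genome.taxon_ids].to_numpy() ** ref.blend_exponent)[:, None]
        effective = blend_w * true_w + (1.0 - blend_w) * perturbed
        ko = comp.to_numpy() @ effective
    df = pd.DataFrame(ko, index=taxon_table.sample_ids, columns=genome.feature_ids)
    frac.name = "discarded_fraction"
    return AbundanceTable(_renormalize(df), "relative"), frac


def generate_paired_dataset(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> PairedDataset:
    """Run the full generator: taxa → genome → observed → predictions.

    Deterministic under ``config.seed``; writes the TSV/YAML bundle when
    ``out_dir`` is given.
    """
    seed = config.seed
    genome, annotation = build_genome_content(config, child_rng(seed, "genome"))
    taxon_table, frame = sample_taxon_table(config, child_rng(seed, "taxa"))
    if config.effect_taxa:
        df = taxon_table.data.copy()
        cases = frame.case_ids()
        for taxon, fold in config.effect_taxa.items():
            df.loc[cases, taxon] *= fold
        taxon_table = AbundanceTable(_renormalize(df), "relative")
    observed = compute_observed_ko(
        taxon_table,
        genome,
        config.noise_sd,
        child_rng(seed, "noise"),
        case_effects=config.effect_kos,
        case_ids=frame.case_ids(),
    )
    predicted: dict[str, AbundanceTable] = {}
    discard: dict[str, pd.Series] = {}
    for label, ref in config.reference.items():
        table, frac = compute_predicted_ko(
            taxon_table, genome, ref, child_rng(seed, "predict", label)
        )
        predicted[label] = table
        discard[label] = frac
    dataset = PairedDataset(
        taxon_table=taxon_table,
        observed_ko=observed,
        predicted_ko=predicted,
        frame=frame,
        annotation=annotation,
        genome=genome,
        config=config,
        discard_fraction=discard,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
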