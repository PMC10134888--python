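import numpy as np
import pandas as pd
import pytest

from mginfeval import (
    GeneratorConfig,
    ReferenceModel,
    TableError,
    build_genome_content,
    compute_observed_ko,
    compute_predicted_ko,
    generate_paired_dataset,
    sample_taxon_table,
)
from mginfeval._rng import child_rng
from mginfeval.simulate import (
    CAT_GIP,
    TAXON_CRISPATUS,
    TAXON_INERS,
    _DEFAULT_ANI,
    partition_kos,
)

from conftest import perfect_reference_config


class TestGenomeContent:
    def test_rows_are_stochastic_and_category_mass_matches_weights(self):
        config = GeneratorConfig(seed=1)
        genome, annotation = build_genome_content(config, child_rng(1, "genome"))
        sums = genome.weights.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
        weights = config.resolved_category_weights()
        for taxon in (TAXON_CRISPATUS, TAXON_INERS):
            for cat, w in weights[taxon].items():
                members = annotation.data.index[annotation.category_l1 == cat]
                np.testing.assert_allclose(
                    genome.weights.loc[taxon, members].sum(), w, atol=1e-9
                )

    def test_iners_exceeds_crispatus_on_genetic_information_processing(self):
        config = GeneratorConfig(seed=2)
        genome, annotation = build_genome_content(config, child_rng(2, "genome"))
        gip = annotation.data.index[annotation.category_l1 == CAT_GIP]
        assert (
            genome.weights.loc[TAXON_CRISPATUS, gip].sum()
            < genome.weights.loc[TAXON_INERS, gip].sum()
        )

    def test_degenerate_weights_put_all_mass_in_one_category(self):
        config = GeneratorConfig(
            seed=3,
            category_weights={
                t: {"metabolism": 1.0} for t in GeneratorConfig().taxon_ids
            },
        )
        genome, annotation = build_genome_content(config, child_rng(3, "genome"))
        metab = annotation.data.index[annotation.category_l1 == "metabolism"]
        np.testing.assert_allclose(
            genome.weights.loc[:, metab].sum(axis=1), 1.0, atol=1e-9
        )

    def test_same_seed_gives_identical_grids(self):
        config = GeneratorConfig(seed=4)
        g1, _ = build_genome_content(config, child_rng(4, "genome"))
        g2, _ = build_genome_content(config, child_rng(4, "genome"))
        pd.testing.assert_frame_equal(g1.weights, g2.weights)


class TestTaxonTable:
    def test_default_design_counts(self):
        table, frame = sample_taxon_table(GeneratorConfig(seed=5), child_rng(5, "taxa"))
        assert table.n_samples == 72
        assert frame.cluster.value_counts().to_dict() == {
            "iners": 31, "mixed": 24, "crispatus": 17,
        }
        by = frame.data.groupby("cluster")["outcome"].apply(
            lambda s: (s == "case").sum()
        )
        assert by.to_dict() == {"crispatus": 11, "iners": 13, "mixed": 11}

    def test_dominance_calibration_over_1000_samples(self):
        config = GeneratorConfig(
            seed=6,
            n_samples_per_cluster={"crispatus": 1000, "iners": 1000, "mixed": 10},
            n_cases_per_cluster={"crispatus": 500, "iners": 500, "mixed": 5},
        )
        table, frame = sample_taxon_table(config, child_rng(6, "taxa"))
        crisp = table.data.loc[frame.cluster == "crispatus", TAXON_CRISPATUS].mean()
        iners = table.data.loc[frame.cluster == "iners", TAXON_INERS].mean()
        assert abs(crisp - 0.87) < 0.03
        assert abs(iners - 0.86) < 0.03

    def test_infinite_concentration_collapses_to_template(self):
        config = GeneratorConfig(
            seed=7,
            dirichlet_concentration={
                "crispatus": np.inf, "iners": np.inf, "mixed": np.inf,
            },
        )
        table, frame = sample_taxon_table(config, child_rng(7, "taxa"))
        crisp_rows = table.data.loc[frame.cluster == "crispatus"]
        assert (crisp_rows.nunique() == 1).all()
        np.testing.assert_allclose(crisp_rows[TAXON_CRISPATUS], 0.87, atol=1e-12)


class TestObservedKo:
    def test_single_taxon_sample_reproduces_genome_row(self):
        config = GeneratorConfig(seed=8)
        genome, _ = build_genome_content(config, child_rng(8, "genome"))
        taxa = genome.taxon_ids
        comp = pd.DataFrame(
            [np.eye(len(taxa))[0]], index=["s"], columns=taxa
        )
        from mginfeval import AbundanceTable

        table = AbundanceTable(comp, "relative")
        observed = compute_observed_ko(table, genome, 0.0, child_rng(8, "noise"))
        np.testing.assert_allclose(
            observed.values[0], genome.weights.iloc[0].to_numpy(), atol=1e-12
        )

    def test_even_mixture_is_mean_of_genome_rows(self):
        config = GeneratorConfig(seed=9)
        genome, _ = build_genome_content(config, child_rng(9, "genome"))
        taxa = genome.taxon_ids
        row = np.zeros(len(taxa))
        row[:2] = 0.5
        from mginfeval import AbundanceTable

        table = AbundanceTable(
            pd.DataFrame([row], index=["s"], columns=taxa), "relative"
        )
        observed = compute_observed_ko(table, genome, 0.0, child_rng(9, "noise"))
        expected = genome.weights.iloc[:2].mean(axis=0).to_numpy()
        np.testing.assert_allclose(observed.values[0], expected, atol=1e-12)

    def test_noisy_rows_still_sum_to_one(self, small_dataset):
        sums = small_dataset.observed_ko.values.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestPredictedKo:
    def test_perfect_reference_reproduces_noise_free_observed(self):
        ds = generate_paired_dataset(perfect_reference_config())
        for label, pred in ds.predicted_ko.items():
            np.testing.assert_allclose(
                pred.values, ds.observed_ko.values, atol=1e-12, err_msg=label
            )

    def test_discard_fraction_equals_discarded_abundance(self):
        config = GeneratorConfig(seed=10)
        genome, _ = build_genome_content(config, child_rng(10, "genome"))
        taxa = genome.taxon_ids
        iners_idx = taxa.index(TAXON_INERS)
        row = np.full(len(taxa), 0.03 / (len(taxa) - 1))
        row[iners_idx] = 0.97
        from mginfeval import AbundanceTable

        table = AbundanceTable(
            pd.DataFrame([row], index=["s"], columns=taxa), "relative"
        )
        ani = {t: 1.0 for t in taxa}
        ani[TAXON_INERS] = 0.90
        ref = ReferenceModel(ani=ani, mode="discard_renormalize")
        _, frac = compute_predicted_ko(table, genome, ref, child_rng(10, "p"))
        np.testing.assert_allclose(frac["s"], 0.97, atol=1e-12)

    def test_all_discarded_sample_is_an_error_naming_it(self):
        config = GeneratorConfig(seed=11)
        genome, _ = build_genome_content(config, child_rng(11, "genome"))
        taxa = genome.taxon_ids
        row = np.zeros(len(taxa))
        row[0] = 1.0
        from mginfeval import AbundanceTable

        table = AbundanceTable(
            pd.DataFrame([row], index=["lonely"], columns=taxa), "relative"
        )
        ani = {t: 1.0 for t in taxa}
        ani[taxa[0]] = 0.5
        ref = ReferenceModel(ani=ani, mode="discard_renormalize")
        with pytest.raises(TableError, match="lonely"):
            compute_predicted_ko(table, genome, ref, child_rng(11, "p"))

    def test_zero_ani_blend_uses_only_the_perturbed_row(self):
        config = GeneratorConfig(seed=12)
        genome, _ = build_genome_content(config, child_rng(12, "genome"))
        taxa = genome.taxon_ids
        row = np.zeros(len(taxa))
        row[0] = 1.0
        from mginfeval import AbundanceTable

        table = AbundanceTable(
            pd.DataFrame([row], index=["s"], columns=taxa), "relative"
        )
        ani = {t: 1.0 for t in taxa}
        ani[taxa[0]] = 0.0
        ref = ReferenceModel(ani=ani, mode="retain_blend", perturbation_sd=1.0)
        pred, _ = compute_predicted_ko(table, genome, ref, child_rng(12, "p"))
        # the perturbed row differs from the true row almost surely
        assert not np.allclose(pred.values[0], genome.weights.iloc[0].to_numpy())
        np.testing.assert_allclose(pred.values.sum(), 1.0, atol=1e-9)


class TestPairedDataset:
    def test_same_seed_gives_byte_identical_written_outputs(self, tmp_path):
        config = GeneratorConfig(
            seed=13,
            n_samples_per_cluster={"crispatus": 4, "iners": 4, "mixed": 4},
            n_cases_per_cluster={"crispatus": 2, "iners": 2, "mixed": 2},
            n_kos=30,
        )
        generate_paired_dataset(config, tmp_path / "a")
        generate_paired_dataset(config, tmp_path / "b")
        for name in sorted(p.name for p in (tmp_path / "a").iterdir()):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name

    def test_null_config_keeps_case_control_exchangeable(self):
        # no KO effects and no taxon effects: within a cluster the observed
        # KO distributions of cases and controls are identically generated
        config = GeneratorConfig(seed=14, effect_kos=None, effect_taxa=None)
        ds = generate_paired_dataset(config)
        cluster = ds.frame.cluster == "iners"
        cases = ds.frame.data.index[cluster & (ds.frame.outcome == "case")]
        controls = ds.frame.data.index[cluster & (ds.frame.outcome == "control")]
        case_means = ds.observed_ko.data.loc[cases].mean()
        control_means = ds.observed_ko.data.loc[controls].mean()
        # per-KO group means should be statistically indistinguishable: the
        # median absolute relative difference stays small
        rel = ((case_means - control_means).abs() / control_means).median()
        assert rel < 0.25

    def test_effect_kos_shift_only_the_observed_table(self):
        base = GeneratorConfig(seed=15, effect_taxa=None)
        ko = "K00010"
        shifted = GeneratorConfig(
            seed=15, effect_taxa=None, effect_kos={ko: 4.0}
        )
        ds0 = generate_paired_dataset(base)
        ds1 = generate_paired_dataset(shifted)
        cases = ds1.frame.case_ids()
        controls = ds1.frame.control_ids()
        ratio1 = (
            ds1.observed_ko.data.loc[cases, ko].mean()
            / ds1.observed_ko.data.loc[controls, ko].mean()
        )
        ratio0 = (
            ds0.observed_ko.data.loc[cases, ko].mean()
            / ds0.observed_ko.data.loc[controls, ko].mean()
        )
        assert ratio1 > 2.0 * ratio0
        for label in ds1.predicted_ko:
            pd.testing.assert_frame_equal(
                ds1.predicted_ko[label].data, ds0.predicted_ko[label].data
            )

    def test_truth_metadata_written(self, tmp_path):
        config = GeneratorConfig(
            seed=16,
            n_samples_per_cluster={"crispatus": 3, "iners": 3, "mixed": 3},
            n_cases_per_cluster={"crispatus": 1, "iners": 1, "mixed": 1},
            n_kos=24,
        )
        generate_paired_dataset(config, tmp_path)
        import yaml

        truth = yaml.safe_load((tmp_path / "truth.yaml").read_text())
        assert truth["seed"] == 16
        assert truth["n_kos"] == 24
        assert set(truth["reference"]) == {"blend", "discard"}


class TestAnnotationPartition:
    def test_every_ko_gets_exactly_one_category(self):
        annotation = partition_kos(500)
        assert len(annotation.feature_ids) == 500
        assert annotation.category_l1.notna().all()

    def test_category_proportions_roughly_respected(self):
        annotation = partition_kos(500)
        counts = annotation.category_l1.value_counts()
        assert counts["metabolism"] == 200
        assert counts[CAT_GIP] == 75


class TestConfigValidation:
    def test_cases_cannot_exceed_samples(self):
        with pytest.raises(ValueError, match="exceed"):
            GeneratorConfig(
                n_samples_per_cluster={"crispatus": 5, "iners": 5, "mixed": 5},
                n_cases_per_cluster={"crispatus": 6, "iners": 1, "mixed": 1},
            )

    def test_dominance_mean_must_be_probability(self):
        with pytest.raises(ValueError, match="dominance"):
            GeneratorConfig(dominance_mean={"crispatus": 1.2, "iners": 0.86})

    def test_ani_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="ani"):
            ReferenceModel(ani={"t": 1.5})
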