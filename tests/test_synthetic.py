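import numpy as np
import pandas as pd
import pytest

from phytoquant.synthetic import (
    ClassSpec,
    GeneratorConfig,
    generate_dataset,
    generate_truth,
    sample_ids,
    simulate_microscopy,
    simulate_reads,
    unbiased_config,
)


def flat_config(classes, **overrides):
    """Config with every random effect silenced except what the test sets."""
    defaults = dict(
        classes=classes, n_stations=2, n_years=2, read_depth=10_000,
        frac_one_to_one=1.0, frac_merged=0.0, frac_meta_only=0.0,
        heterotroph_asv_count=0, heterotroph_read_fraction=0.0,
        year_effect_sd=0.0, community_year_sd=0.0, species_year_sd=0.0,
        residual_sd=0.0, seed=5,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


def one_species(log_a=np.log(1000), log_v=np.log(500)):
    return ClassSpec("Chrysophyceae", 1, log_a, 0.0, log_v, 0.0, 1.0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "overrides, field",
        [
            ({"n_stations": 0}, "n_stations"),
            ({"read_depth": 50}, "read_depth"),
            ({"microscopy_count_volume": 0.0}, "microscopy_count_volume"),
            ({"frac_one_to_one": 0.5}, "mapping fractions"),
            ({"heterotroph_read_fraction": 1.0}, "heterotroph_read_fraction"),
            ({"year_effect_sd": -1.0}, "year_effect_sd"),
        ],
    )
    def test_invalid_config_names_field(self, overrides, field):
        with pytest.raises(ValueError, match=field):
            flat_config((one_species(),), **overrides)

    def test_nonpositive_primer_efficiency_rejected(self):
        bad = ClassSpec("X", 1, 0.0, 0.0, 0.0, 0.0, primer_efficiency=0.0)
        with pytest.raises(ValueError, match="primer_efficiency"):
            flat_config((bad,))

    def test_roundtrips_through_dict(self):
        cfg = unbiased_config(seed=3)
        assert GeneratorConfig.from_dict(cfg.to_dict()) == cfg


class TestGenerateTruth:
    def test_degenerate_variance_gives_constant_abundance(self):
        truth = generate_truth(flat_config((one_species(),)))
        values = truth.abundance.values
        assert np.allclose(values, values[0, 0])
        assert values[0, 0] == pytest.approx(1000.0)

    def test_deterministic_given_seed(self):
        cfg = unbiased_config(seed=42)
        t1, t2 = generate_truth(cfg), generate_truth(cfg)
        pd.testing.assert_frame_equal(t1.abundance, t2.abundance)
        pd.testing.assert_series_equal(t1.cell_volume, t2.cell_volume)
        pd.testing.assert_series_equal(t1.asv_of, t2.asv_of)

    def test_copy_number_power_law(self):
        classes = (
            ClassSpec("Chrysophyceae", 1, 0.0, 0.0, np.log(10), 0.0, 1.0),
            ClassSpec("Cryptophyceae", 1, 0.0, 0.0, np.log(100), 0.0, 1.0),
        )
        truth = generate_truth(flat_config(classes, copy_number_exponent=1.0))
        ratio = truth.copy_number.max() / truth.copy_number.min()
        assert ratio == pytest.approx(10.0)

    def test_sample_grid_and_id_convention(self):
        cfg = flat_config((one_species(),), n_stations=3, n_years=2)
        truth = generate_truth(cfg)
        assert list(truth.abundance.index) == sample_ids(cfg)
        assert truth.abundance.shape[0] == 6
        assert "1_20" in truth.abundance.index and "3_21" in truth.abundance.index

    def test_samples_correlated_within_year(self):
        # the shared year effect must make within-year samples more alike
        cfg = GeneratorConfig(n_stations=9, n_years=3, seed=2)
        truth = generate_truth(cfg)
        logs = np.log(truth.abundance)
        year = [s.split("_")[1] for s in logs.index]
        corr = np.corrcoef(logs.values)
        same = [corr[i, j] for i in range(27) for j in range(i + 1, 27)
                if year[i] == year[j]]
        diff = [corr[i, j] for i in range(27) for j in range(i + 1, 27)
                if year[i] != year[j]]
        assert np.mean(same) > np.mean(diff)


class TestSimulateMicroscopy:
    def test_zero_abundance_never_observed(self):
        cfg = flat_config((one_species(),))
        truth = generate_truth(cfg)
        truth.abundance.iloc[:, 0] = 0.0
        assert simulate_microscopy(truth, cfg).empty

    def test_large_count_volume_recovers_truth(self):
        cfg = flat_config((one_species(np.log(5000)),),
                          microscopy_count_volume=100.0)
        truth = generate_truth(cfg)
        table = simulate_microscopy(truth, cfg)
        np.testing.assert_allclose(table["abundance"], 5000.0, rtol=2e-2)

    def test_total_within_poisson_error(self):
        cfg = GeneratorConfig(seed=4)
        truth = generate_truth(cfg)
        table = simulate_microscopy(truth, cfg)
        V = cfg.microscopy_count_volume
        visible = truth.microscopy_visible
        expected = (truth.abundance.loc[:, visible].sum(axis=1) * V).sum()
        observed = table["abundance"].sum() * V
        assert abs(observed - expected) < 3 * np.sqrt(expected)

    def test_biomass_is_abundance_times_volume(self):
        cfg = flat_config((one_species(np.log(2000), np.log(500)),))
        truth = generate_truth(cfg)
        table = simulate_microscopy(truth, cfg)
        np.testing.assert_allclose(
            table["biomass"], table["abundance"] * 500.0 * 1e-9, rtol=1e-12)


class TestSimulateReads:
    def test_reads_sum_to_depth(self, small_config):
        truth = generate_truth(small_config)
        reads = simulate_reads(truth, small_config)
        assert (reads.counts.sum(axis=1) == small_config.read_depth).all()

    def test_unbiased_proportions_converge(self):
        classes = (
            ClassSpec("Chrysophyceae", 5, np.log(5000), 1.0, np.log(500), 0.5, 1.0),
            ClassSpec("Cryptophyceae", 5, np.log(2000), 1.0, np.log(800), 0.5, 1.0),
        )
        cfg = flat_config(classes, n_stations=1, n_years=1,
                          read_depth=1_000_000, residual_sd=0.5,
                          copy_number_exponent=0.0)
        truth = generate_truth(cfg)
        reads = simulate_reads(truth, cfg)
        p_true = truth.abundance.iloc[0] / truth.abundance.iloc[0].sum()
        by_asv = p_true.groupby(truth.asv_of).sum()
        p_obs = reads.counts.iloc[0] / cfg.read_depth
        assert (p_obs - by_asv.reindex(p_obs.index)).abs().max() < 0.01

    def test_copy_number_bias_shifts_read_ratio(self):
        classes = (
            ClassSpec("Chrysophyceae", 1, np.log(1000), 0.0, np.log(10), 0.0, 1.0),
            ClassSpec("Cryptophyceae", 1, np.log(1000), 0.0, np.log(100), 0.0, 1.0),
        )
        cfg = flat_config(classes, n_stations=1, n_years=1,
                          copy_number_exponent=1.0, read_depth=1_000_000)
        truth = generate_truth(cfg)
        reads = simulate_reads(truth, cfg).counts.iloc[0]
        big = reads[truth.asv_of[truth.cell_volume.idxmax()]]
        small = reads[truth.asv_of[truth.cell_volume.idxmin()]]
        # equal abundance, copy number 1:10 -> expected read ratio 1:10
        assert big / small == pytest.approx(10.0, rel=0.05)

    def test_merged_species_share_one_asv(self):
        classes = (ClassSpec("Chrysophyceae", 2, np.log(1000), 0.0,
                             np.log(100), 0.0, 1.0),)
        cfg = flat_config(classes, frac_one_to_one=0.0, frac_merged=1.0,
                          n_stations=1, n_years=1, read_depth=10_000)
        truth = generate_truth(cfg)
        assert truth.asv_of.nunique() == 1
        reads = simulate_reads(truth, cfg)
        # the shared ASV absorbs both species' weight: all reads land on it
        assert reads.counts.iloc[0].sum() == 10_000
        assert reads.counts.shape[1] == 1

    def test_within_class_shares_unbiased_under_class_bias(self):
        # class-level bias must cancel inside a class: the premise that
        # makes class-specific anchoring the more accurate scheme
        classes = (
            ClassSpec("Chrysophyceae", 4, np.log(5000), 1.0, np.log(500), 0.0, 3.0),
            ClassSpec("Cryptophyceae", 4, np.log(5000), 1.0, np.log(800), 0.0, 0.5),
        )
        cfg = flat_config(classes, n_stations=1, n_years=1,
                          read_depth=1_000_000, residual_sd=0.3)
        truth = generate_truth(cfg)
        reads = simulate_reads(truth, cfg)
        for cls in ("Chrysophyceae", "Cryptophyceae"):
            members = truth.class_of.index[truth.class_of == cls]
            asvs = truth.asv_of[members]
            true_share = (truth.abundance.iloc[0][members]
                          / truth.abundance.iloc[0][members].sum())
            cnt = reads.counts.iloc[0][asvs.values]
            read_share = cnt / cnt.sum()
            np.testing.assert_allclose(
                read_share.values, true_share.values, atol=0.01)

    def test_heterotrophs_absent_when_disabled(self, small_config):
        truth = generate_truth(small_config)
        reads = simulate_reads(truth, small_config)
        het = reads.taxonomy["trophic"] == "heterotroph"
        assert het.sum() == small_config.heterotroph_asv_count
        cfg0 = GeneratorConfig(
            **{**small_config.to_dict(), "classes": small_config.classes,
               "heterotroph_asv_count": 0, "heterotroph_read_fraction": 0.0})
        reads0 = simulate_reads(generate_truth(cfg0), cfg0)
        assert (reads0.taxonomy["trophic"] == "phytoplankton").all()


class TestGenerateDataset:
    def test_tables_share_sample_ids(self, small_config):
        species, reads, truth = generate_dataset(small_config)
        assert set(species["sample_id"]) <= set(reads.counts.index)
        assert list(reads.counts.index) == list(truth.abundance.index)

    def test_fixed_seed_reproduces_serialized_output(self, small_config, tmp_path):
        out = []
        for run in range(2):
            species, reads, _ = generate_dataset(small_config)
            p = tmp_path / f"run{run}.tsv"
            species.to_csv(p, sep="\t", index=False)
            out.append(p.read_bytes() + reads.counts.to_csv().encode())
        assert out[0] == out[1]

    def test_meta_only_taxa_hidden_from_microscopy(self):
        classes = (ClassSpec("Chrysophyceae", 4, np.log(5000), 0.5,
                             np.log(500), 0.5, 1.0),)
        cfg = flat_config(classes, frac_one_to_one=0.5, frac_merged=0.0,
                          frac_meta_only=0.5)
        species, reads, truth = generate_dataset(cfg)
        hidden = truth.microscopy_visible.index[~truth.microscopy_visible]
        assert len(hidden) == 2
        assert not set(species["species"]) & set(hidden)
        # but their ASVs do receive reads
        hidden_asvs = truth.asv_of[hidden]
        assert reads.counts[hidden_asvs.values].sum().sum() > 0
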