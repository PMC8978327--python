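"""Generator contracts: reproducibility, invariants, planted recoverability."""

import numpy as np
import pytest

from bcellcerna.matrix import STAGES
from bcellcerna.synthetic_data import (
    ConfigurationError,
    GroundTruth,
    SimulationConfig,
    generate_dataset,
    generate_sequences,
)
from bcellcerna.target_prediction import find_seed_matches, seed_site_strings

from conftest import SMALL_KWARGS


class TestSimulationConfig:
    def test_triplets_exceeding_layer_size_rejected(self):
        with pytest.raises(ConfigurationError, match="n_planted_triplets"):
            SimulationConfig(n_circ=5, n_mirna=100, n_mrna=100,
                             n_planted_triplets=10)

    def test_fraction_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError, match="frac_stage_specific_circ"):
            SimulationConfig(frac_stage_specific_circ=1.2)

    def test_planted_roles_exceeding_layer_rejected(self):
        with pytest.raises(ConfigurationError, match="exceed"):
            generate_dataset(SimulationConfig(
                n_circ=50, n_mirna=100, n_mrna=100, n_planted_de=30))

    def test_unknown_noise_model_rejected(self):
        with pytest.raises(ConfigurationError, match="noise_model"):
            SimulationConfig(noise_model="gaussian")


class TestGenerateDataset:
    def test_empty_config_gives_empty_outputs(self):
        cfg = SimulationConfig(n_circ=0, n_mirna=0, n_mrna=0,
                               n_planted_triplets=0, n_planted_de=0,
                               n_planted_patterns=0)
        dataset, truth = generate_dataset(cfg)
        assert dataset.circ_matrix.n_transcripts == 0
        assert dataset.mrna_counts.n_transcripts == 0
        assert truth.planted_triplets == [] and truth.de_truth == {}
        assert dataset.sequences == {}

    def test_same_seed_bitwise_reproducible(self):
        cfg = SimulationConfig(rng_seed=33, **SMALL_KWARGS)
        d1, t1 = generate_dataset(cfg)
        d2, t2 = generate_dataset(SimulationConfig(rng_seed=33, **SMALL_KWARGS))
        for layer in ("circ", "mirna", "mrna"):
            assert getattr(d1, f"{layer}_matrix").data.equals(
                getattr(d2, f"{layer}_matrix").data)
            assert getattr(d1, f"{layer}_counts").data.equals(
                getattr(d2, f"{layer}_counts").data)
        assert d1.sequences == d2.sequences
        assert t1.to_json() == t2.to_json()

    def test_different_seed_differs(self):
        d1, _ = generate_dataset(SimulationConfig(rng_seed=1, **SMALL_KWARGS))
        d2, _ = generate_dataset(SimulationConfig(rng_seed=2, **SMALL_KWARGS))
        assert not d1.circ_matrix.data.equals(d2.circ_matrix.data)

    def test_normalization_identity_counts_vs_rpm(self, noisy_dataset):
        # RPM = count / library_size * 1e6 for the circRNA layer
        dataset, _ = noisy_dataset
        libs = dataset.library_sizes["circ"]
        for stage in STAGES:
            np.testing.assert_allclose(
                dataset.circ_matrix.data[stage].to_numpy(),
                dataset.circ_counts.data[stage].to_numpy() / libs[stage] * 1e6)

    def test_ground_truth_invariants_validated(self, hard_dataset):
        _, truth = hard_dataset
        truth.validate()  # direction consistency + planted sites
        assert len(truth.planted_triplets) == 3 * SMALL_KWARGS["n_planted_triplets"]

    def test_hard_planted_specificity_exact(self, hard_dataset):
        dataset, truth = hard_dataset
        values = dataset.mirna_matrix.data
        for transcript, stages in truth.specificity_labels.items():
            if not transcript.startswith("miR"):
                continue
            row = values.loc[transcript]
            assert tuple(s for s in STAGES if row[s] > 0) == tuple(stages)

    def test_planted_sites_recorded_and_present(self, hard_dataset):
        dataset, truth = hard_dataset
        for (mirna, target), sites in truth.planted_sites.items():
            for start, end, site_type in sites:
                assert site_type == "8mer"
                site = seed_site_strings(dataset.sequences[mirna])["8mer"]
                assert dataset.sequences[target][start:end] == site

    def test_ground_truth_json_round_trip(self, hard_dataset):
        _, truth = hard_dataset
        back = GroundTruth.from_json(truth.to_json())
        assert back.to_json() == truth.to_json()
        assert back.de_truth == truth.de_truth
        assert back.planted_triplets == truth.planted_triplets

    def test_negative_binomial_noise_runs_and_overdisperses(self):
        cfg_p = SimulationConfig(rng_seed=5, **SMALL_KWARGS)
        cfg_nb = SimulationConfig(rng_seed=5, noise_model="negative_binomial",
                                  dispersion=0.5, **SMALL_KWARGS)
        _, _ = generate_dataset(cfg_nb)  # runs
        dp, _ = generate_dataset(cfg_p)
        dnb, _ = generate_dataset(cfg_nb)
        # NB counts vary more around the same means than Poisson counts
        assert dnb.circ_counts.data.to_numpy().var() > \
            dp.circ_counts.data.to_numpy().var()

    def test_dataset_write_round_trip(self, tmp_path, hard_dataset):
        from bcellcerna import io_formats
        dataset, _ = hard_dataset
        dataset.write(tmp_path)
        back = io_formats.read_expression_tsv(tmp_path / "circ_expression.tsv", "RPM")
        assert np.allclose(back.data.to_numpy(),
                           dataset.circ_matrix.data.to_numpy(), rtol=1e-9)
        seqs = io_formats.read_fasta(tmp_path / "sequences.fa")
        assert seqs == dataset.sequences

    def test_stage_specific_fraction_band_over_seeds(self):
        # planted per-stage specific fraction 0.6 stays inside [0.5, 0.7]
        # under Poisson sampling, across 20 seeds
        from bcellcerna.expression_profiles import (
            call_expressed, classify_specificity, specificity_fraction)
        for seed in range(20):
            cfg = SimulationConfig(rng_seed=seed, n_circ=400, n_mirna=30,
                                   n_mrna=30, n_planted_triplets=2,
                                   n_planted_de=2, n_planted_patterns=1)
            dataset, _ = generate_dataset(cfg)
            calls = classify_specificity(call_expressed(dataset.circ_matrix))
            for stage in STAGES:
                assert 0.5 <= specificity_fraction(calls, stage) <= 0.7


class TestGenerateSequences:
    def test_no_planted_interactions_gives_clean_sequences(self):
        sequences, sites = generate_sequences(
            ["m1", "m2"], ["t1", "t2"], [], rng_seed=7)
        assert sites == {}
        for m in ("m1", "m2"):
            for t in ("t1", "t2"):
                assert find_seed_matches(sequences[m], sequences[t]) == []

    def test_planted_pair_has_8mer_at_recorded_offset(self):
        sequences, sites = generate_sequences(["m1"], ["t1"], [("m1", "t1")],
                                              rng_seed=8)
        ((start, end, site_type),) = sites[("m1", "t1")]
        assert site_type == "8mer"
        expected = seed_site_strings(sequences["m1"])["8mer"]
        assert sequences["t1"][start:end] == expected

    def test_non_planted_pairs_have_no_site_at_scale(self):
        mirnas = [f"m{i}" for i in range(5)]
        targets = [f"t{i}" for i in range(20)]
        planted = [(f"m{i % 5}", f"t{i}") for i in range(20)]
        sequences, _ = generate_sequences(mirnas, targets, planted, rng_seed=9)
        for m in mirnas:
            for t in targets:
                matches = find_seed_matches(sequences[m], sequences[t])
                if (m, t) in planted:
                    assert any(x.site_type == "8mer" for x in matches)
                else:
                    assert matches == []

    def test_unknown_ids_rejected(self):
        with pytest.raises(ValueError, match="unknown ids"):
            generate_sequences(["m1"], ["t1"], [("mX", "t1")], rng_seed=1)

    def test_empty_supplied_mirna_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty miRNA sequence"):
            generate_sequences(["m1"], ["t1"], [("m1", "t1")], rng_seed=1,
                               mirna_seqs={"m1": ""})
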