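"""Generator behaviour: determinism, digestion, intensity model, evidence tables."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pyteomics import parser as pt_parser

from mitoproteome import (
    SimulationConfig,
    digest_tryptic,
    generate_proteome,
    simulate_decoy_scores,
    simulate_observations,
    simulate_ortholog_tables,
    simulate_targeting_tables,
)
from mitoproteome.synthetic import (
    AMINO_ACIDS,
    TRUE_MITO,
    ConfigurationError,
    SequenceError,
)

sequences = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=120)


class TestConfig:
    def test_invalid_proportions_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(localization_proportions={"mito": 0.5, "cytosol": 0.4})

    def test_unknown_localization_rejected(self):
        with pytest.raises(ConfigurationError):
            SimulationConfig(localization_proportions={"nucleus": 1.0})

    @pytest.mark.parametrize(
        "field,value",
        [
            ("missing_rate", 1.5),
            ("detectability", -0.1),
            ("enrichment_fold", 0.0),
            ("n_replicates_per_fraction", 0),
            ("missed_cleavages", 3),
        ],
    )
    def test_out_of_range_fields_rejected(self, field, value):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**{field: value})


class TestGenerateProteome:
    def test_degenerate_all_mito(self):
        cfg = SimulationConfig(
            n_proteins=100, localization_proportions={"mito": 1.0}, seed=1
        )
        truth = generate_proteome(cfg)
        assert len(truth) == 100
        assert (truth["localization"] == "mito").all()
        assert truth["has_targeting_signal"].all()

    def test_empty_proteome(self):
        truth = generate_proteome(SimulationConfig(n_proteins=0))
        assert truth.empty

    def test_localization_counts_match_proportions_to_rounding(self, small_truth):
        counts = small_truth["localization"].value_counts()
        cfg = SimulationConfig(n_proteins=200, seed=7)
        for loc, prop in cfg.proportions.items():
            if prop > 0:
                assert abs(counts.get(loc, 0) - 200 * prop) < 1

    def test_identifiers_unique_and_sequences_valid(self, small_truth):
        assert small_truth["protein_id"].is_unique
        assert (
            small_truth["sequence"].map(lambda s: set(s) <= set(AMINO_ACIDS)).all()
        )
        assert (small_truth["sequence"].str.len() > 0).all()

    def test_seed_determinism_byte_identical(self, small_config, small_truth):
        again = generate_proteome(small_config)
        assert small_truth.to_csv() == again.to_csv()
        obs1 = simulate_observations(small_truth, small_config)
        obs2 = simulate_observations(again, small_config)
        assert obs1.to_csv() == obs2.to_csv()
        t1 = simulate_targeting_tables(small_truth, small_config)
        t2 = simulate_targeting_tables(small_truth, small_config)
        assert all(t1[v].to_csv() == t2[v].to_csv() for v in t1)
        o1 = simulate_ortholog_tables(small_truth, small_config)
        o2 = simulate_ortholog_tables(small_truth, small_config)
        assert o1.to_csv() == o2.to_csv()


class TestDigest:
    def test_cleaves_after_k_and_r(self):
        assert digest_tryptic("AAAAAKDDDDDD", 6) == ["AAAAAK", "DDDDDD"]

    def test_proline_suppresses_cleavage(self):
        assert digest_tryptic("AAAKPAAA", 1) == ["AAAKPAAA"]

    def test_all_below_min_length(self):
        assert digest_tryptic("KKK", 6) == []

    def test_invalid_residue_raises(self):
        with pytest.raises(SequenceError):
            digest_tryptic("AAAXAA")

    @settings(max_examples=300, deadline=None)
    @given(sequences)
    def test_concatenation_recovers_sequence(self, seq):
        peptides = digest_tryptic(seq, min_length=1)
        assert "".join(peptides) == seq

    @settings(max_examples=100, deadline=None)
    @given(sequences)
    def test_matches_pyteomics_cleavage_oracle(self, seq):
        # plain tryptic rule (cleave after K/R unless before P), evaluated by
        # pyteomics' regex-based cleaver as an independent implementation
        ours = set(digest_tryptic(seq, min_length=1))
        oracle = pt_parser.cleave(seq, r"[KR](?=[^P])", missed_cleavages=0, min_length=1)
        assert ours == set(oracle)

    def test_missed_cleavages_superset(self):
        seq = "AAAAAKDDDDDDKEEEEEE"
        zero = set(digest_tryptic(seq, 6, missed_cleavages=0))
        one = set(digest_tryptic(seq, 6, missed_cleavages=1))
        assert zero <= one
        assert "AAAAAKDDDDDDK" in one


class TestObservations:
    def test_zero_noise_ratio_equals_fold(self, noiseless_config):
        truth = generate_proteome(noiseless_config)
        obs = simulate_observations(truth, noiseless_config)
        mito_ids = set(
            truth.loc[
                (truth["localization"] == "mito")
                & ~truth["is_contaminant_annotation"],
                "protein_id",
            ]
        )
        pid = sorted(mito_ids)[0]
        sub = obs[obs["protein_ids"] == pid]
        mt = sub[(sub["fraction"] == "mt") & (sub["replicate"] == 1)]["intensity"]
        cp = sub[(sub["fraction"] == "cp") & (sub["replicate"] == 1)]["intensity"]
        assert len(mt) and len(cp)
        ratios = mt.to_numpy() / cp.to_numpy()
        assert np.allclose(ratios, noiseless_config.enrichment_fold)

    def test_missing_rate_one_gives_empty_table(self, small_truth):
        cfg = SimulationConfig(n_proteins=200, seed=7, missing_rate=1.0)
        obs = simulate_observations(small_truth, cfg)
        assert obs.empty
        assert list(obs.columns) == [
            "peptide",
            "protein_ids",
            "fraction",
            "replicate",
            "intensity",
        ]

    def test_mean_log_ratio_recovers_fold(self):
        # Monte-Carlo: over many mitochondrial proteins the mean log10 Mt/Cp
        # equals log10(enrichment_fold) within 3 standard errors.
        cfg = SimulationConfig(
            n_proteins=1000,
            localization_proportions={"mito": 1.0},
            contaminant_rate=0.0,
            missing_rate=0.0,
            detectability=0.2,
            seed=11,
        )
        truth = generate_proteome(cfg)
        obs = simulate_observations(truth, cfg)
        per = obs.pivot_table(
            index="protein_ids", columns="fraction", values="intensity", aggfunc="mean"
        )
        logr = np.log10(per["mt"] / per["cp"]).to_numpy()
        se = logr.std(ddof=1) / math.sqrt(len(logr))
        assert abs(logr.mean() - math.log10(cfg.enrichment_fold)) < 3 * se


class TestTargetingTables:
    def test_no_truncation_all_mito_predicted(self, small_truth):
        cfg = SimulationConfig(n_proteins=200, seed=7, truncation_prob=0.0)
        tables = simulate_targeting_tables(small_truth, cfg)
        signal = small_truth[small_truth["has_targeting_signal"]]["protein_id"]
        for table in tables.values():
            sub = table.set_index("name").loc[signal]
            assert (sub["loc"] == "M").all()
            assert sub["start_met"].all()

    def test_full_truncation_no_mito_prediction(self, small_truth):
        cfg = SimulationConfig(n_proteins=200, seed=7, truncation_prob=1.0)
        tables = simulate_targeting_tables(small_truth, cfg)
        for table in tables.values():
            assert not (table["loc"] == "M").any()
            assert not table["start_met"].any()

    def test_majority_rate_matches_binomial_closed_form(self):
        cfg = SimulationConfig(
            n_proteins=2000,
            localization_proportions={"mito": 1.0},
            truncation_prob=0.3,
            seed=13,
        )
        truth = generate_proteome(cfg)
        tables = simulate_targeting_tables(truth, cfg)
        votes = sum(
            ((t["loc"] == "M") & t["start_met"]).to_numpy(dtype=int)
            for t in tables.values()
        )
        passed = (votes >= 2).mean()
        p = 1.0 - cfg.truncation_prob
        expected = 3 * p**2 * (1 - p) + p**3
        se = math.sqrt(expected * (1 - expected) / len(truth))
        assert abs(passed - expected) < 3 * se


class TestOrthologsAndDecoys:
    def test_full_coverage_links_every_mito_protein(self, small_truth):
        cfg = SimulationConfig(n_proteins=200, seed=7, reference_coverage=1.0)
        table = simulate_ortholog_tables(small_truth, cfg)
        mito = small_truth[small_truth["localization"].isin(TRUE_MITO)]
        counts = table.groupby("protein_id").size()
        assert set(counts.index) == set(mito["protein_id"])
        assert (counts == cfg.n_reference_proteomes).all()

    def test_zero_coverage_empty_table(self, small_truth):
        cfg = SimulationConfig(n_proteins=200, seed=7, reference_coverage=0.0)
        assert simulate_ortholog_tables(small_truth, cfg).empty

    def test_large_separation_admits_all_targets_no_decoys(self):
        from mitoproteome import decoy_fdr_threshold

        df = simulate_decoy_scores(500, 500, 100.0, seed=1, false_target_fraction=0.0)
        res = decoy_fdr_threshold(list(zip(df["score"], df["is_decoy"])), 0.01)
        assert res.n_targets == 500
        assert res.n_decoys == 0
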