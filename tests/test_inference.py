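"""Identification layer: canonicalisation, grouping, unique counts, FDR."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoproteome import (
    PeptideMatch,
    build_matches,
    collapse_and_filter,
    count_unique_peptides,
    decoy_fdr_threshold,
    group_proteins,
)
from mitoproteome.inference import (
    read_peptides_table,
    write_peptides_table,
)
from mitoproteome.synthetic import SequenceError


def match(pep, *prots):
    return PeptideMatch(pep, frozenset(prots))


class TestCollapseAndFilter:
    def test_isoleucine_collapses_to_leucine(self):
        assert collapse_and_filter(["PEPTIDE"]) == ["PEPTLDE"]

    def test_short_peptides_dropped(self):
        assert collapse_and_filter(["AAAAA"]) == []

    def test_invalid_residue_rejected(self):
        with pytest.raises(SequenceError):
            collapse_and_filter(["PEPT1DE"])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", max_size=20), max_size=20))
    def test_idempotent(self, peptides):
        once = collapse_and_filter(peptides)
        assert collapse_and_filter(once) == once


def brute_force_groups(peptide_sets: dict[str, frozenset]) -> set[frozenset]:
    """Independent oracle: each protein joins the protein with the largest
    superset of its peptide set (ties by lexicographically smallest id)."""
    def leader(p):
        candidates = [
            q for q in peptide_sets if peptide_sets[p] <= peptide_sets[q]
        ]
        return min(candidates, key=lambda q: (-len(peptide_sets[q]), q))

    by_leader: dict[str, set] = {}
    for p in peptide_sets:
        by_leader.setdefault(leader(p), set()).add(p)
    return {frozenset(members) for members in by_leader.values()}


class TestGrouping:
    def test_subset_joins_superset(self):
        ms = [
            match("PEPAAA", "A"),
            match("PEPBBB", "A", "B"),
            match("PEPCCC", "A"),
            match("PEPDDD", "C"),
        ]
        groups = group_proteins(ms)
        assert {g.members for g in groups} == {("A", "B"), ("C",)}
        assert [g.leader for g in groups] == ["A", "C"]

    def test_identical_sets_share_group_lexicographic_leader(self):
        groups = group_proteins([match("PEPAAA", "A", "B")])
        assert len(groups) == 1
        assert groups[0].leader == "A"
        assert groups[0].members == ("A", "B")

    def test_overlap_without_subsumption_stays_separate(self):
        ms = [match("PEPAAA", "A"), match("PEPBBB", "A", "B"), match("PEPCCC", "B")]
        groups = group_proteins(ms)
        assert {g.members for g in groups} == {("A",), ("B",)}

    def test_chain_subsumption_through_leader(self):
        # B and C both subsets of A but incomparable with each other
        ms = [
            match("PEPAAA", "A", "B"),
            match("PEPBBB", "A", "C"),
            match("PEPCCC", "A"),
        ]
        groups = group_proteins(ms)
        assert {g.members for g in groups} == {("A", "B", "C")}

    def test_empty_input(self):
        assert group_proteins([]) == []

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_prot = rng.integers(2, 20)
        n_pep = rng.integers(1, 50)
        peptides = [f"PEPTIDE{i:03d}" for i in range(n_pep)]
        matches = []
        for pep in peptides:
            prots = rng.choice(
                n_prot, size=rng.integers(1, min(4, n_prot + 1)), replace=False
            )
            matches.append(match(pep, *(f"P{p:02d}" for p in prots)))
        sets: dict[str, set] = {}
        for m in matches:
            for p in m.proteins:
                sets.setdefault(p, set()).add(m.peptide)
        expected = brute_force_groups({p: frozenset(s) for p, s in sets.items()})
        got = {frozenset(g.members) for g in group_proteins(matches)}
        assert got == expected

    def test_order_invariant(self):
        rng = np.random.default_rng(0)
        matches = [
            match(f"PEPTIDE{i:02d}", *(f"P{j}" for j in rng.choice(6, 2, replace=False)))
            for i in range(12)
        ]
        reference = {frozenset(g.members) for g in group_proteins(matches)}
        for perm in itertools.islice(itertools.permutations(matches), 0, 24, 5):
            assert {frozenset(g.members) for g in group_proteins(list(perm))} == reference


class TestUniqueCounts:
    def test_peptides_within_single_group_are_unique(self):
        ms = [match("PEPAAA", "A"), match("PEPBBB", "A", "B")]
        groups = group_proteins(ms)
        counts, partition = count_unique_peptides(groups, ms)
        assert counts == {"A": 2}
        assert partition == {">1": 1, "1": 0, "0": 0}

    def test_razor_peptide_counts_for_no_group(self):
        ms = [
            match("PEPAAA", "A"),
            match("PEPBBB", "B"),
            match("PEPRAZ", "A", "B"),  # shared across the two groups
        ]
        groups = group_proteins(ms)
        counts, partition = count_unique_peptides(groups, ms)
        assert counts == {"A": 1, "B": 1}
        assert partition == {">1": 0, "1": 2, "0": 0}
        assert all(g.razor_peptides == 1 for g in groups)

    @pytest.mark.parametrize("seed", range(5))
    def test_unique_counts_bounded_by_total_peptides(self, seed):
        rng = np.random.default_rng(seed)
        matches = [
            match(f"PEPTIDE{i:03d}", *(f"P{j}" for j in rng.choice(8, rng.integers(1, 3), replace=False)))
            for i in range(30)
        ]
        groups = group_proteins(matches)
        counts, _ = count_unique_peptides(groups, matches)
        assert sum(counts.values()) <= len(matches)


class TestDecoyFdr:
    def test_clean_separation_accepts_all_targets(self):
        scored = [(10, False), (9, False), (8, False), (7, False), (6, True)]
        res = decoy_fdr_threshold(scored, 0.01)
        assert (res.threshold, res.n_targets, res.n_decoys, res.fdr) == (7, 4, 0, 0.0)

    def test_decoy_above_single_target_empties_acceptance(self):
        res = decoy_fdr_threshold([(10, False), (11, True)], 0.01)
        assert res.n_targets == 0
        assert res.n_decoys == 0
        assert res.fdr == 0.0
        assert math.isinf(res.threshold)

    def test_all_decoys_empty_acceptance(self):
        res = decoy_fdr_threshold([(5, True), (4, True)], 0.01)
        assert res.n_targets == 0 and res.fdr == 0.0

    def test_estimated_fdr_never_exceeds_level(self):
        rng = np.random.default_rng(2)
        scored = [(float(s), bool(d)) for s, d in zip(rng.normal(1, 2, 500), rng.random(500) < 0.5)]
        for level in (0.01, 0.05, 0.2):
            res = decoy_fdr_threshold(scored, level)
            assert res.fdr <= level

    def test_monotone_in_level(self):
        rng = np.random.default_rng(3)
        scored = [
            (float(s), bool(d))
            for s, d in zip(rng.normal(1, 2, 1000), rng.random(1000) < 0.5)
        ]
        sizes = [
            decoy_fdr_threshold(scored, level).n_targets
            for level in (0.001, 0.01, 0.05, 0.2)
        ]
        assert sizes == sorted(sizes)


class TestTables:
    def test_peptides_table_round_trip(self, tmp_path):
        ms = [
            PeptideMatch("PEPTLDEK", frozenset({"A", "B"}), {"mt_1": 100.0, "cp_2": 5.0}),
            PeptideMatch("AAAAAAR", frozenset({"C"}), {"wc_3": 7.5}),
        ]
        path = tmp_path / "peptides.tsv"
        write_peptides_table(ms, path)
        back = read_peptides_table(path)
        assert {m.peptide for m in back} == {m.peptide for m in ms}
        by_pep = {m.peptide: m for m in back}
        for m in ms:
            assert by_pep[m.peptide].proteins == m.proteins
            assert by_pep[m.peptide].intensities == m.intensities

    def test_build_matches_sums_and_collapses(self, small_observations):
        matches = build_matches(small_observations)
        assert matches == sorted(matches, key=lambda m: m.peptide)
        assert all("I" not in m.peptide for m in matches)
        assert all(len(m.peptide) >= 6 for m in matches)
        assert all(v > 0 for m in matches for v in m.intensities.values())
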