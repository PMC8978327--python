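"""Exclusive-group assignment and triplet assembly vs exhaustive oracles."""

from itertools import product

import numpy as np
import pytest

from bcellcerna.cerna_assembly import (
    GROUP_OF_COMPARISON,
    GROUPS,
    ExclusiveGroup,
    assign_exclusive_groups,
    build_triplets,
    network_summary,
)
from bcellcerna.differential_expression import COMPARISONS, DERecord
from bcellcerna.target_prediction import Interaction, InteractionTable


def de_record(transcript, comparison, direction):
    is_de = direction != "none"
    lfc = {"up": 2.0, "down": -2.0, "none": 0.0}[direction]
    p = 0.001 if is_de else 0.9
    return DERecord(transcript, comparison, lfc, p, p, direction, is_de)


def records_for(transcript, directions):
    """One DERecord per comparison from a 3-word direction spec."""
    return [de_record(transcript, comp, d)
            for comp, d in zip(COMPARISONS, directions)]


def table_from(edges):
    table = InteractionTable()
    for mirna, target, kind in edges:
        table.add(Interaction(mirna, target, kind))
    return table


class TestAssignExclusiveGroups:
    def test_single_comparison_de_gets_its_group(self):
        (group,) = assign_exclusive_groups(records_for("t", ["up", "none", "none"]))
        assert group == ExclusiveGroup("t", "PrePro_only", "up")

    def test_multi_comparison_de_gets_none(self):
        (group,) = assign_exclusive_groups(records_for("t", ["up", "none", "down"]))
        assert group.group == "none"

    def test_no_de_gets_none(self):
        (group,) = assign_exclusive_groups(records_for("t", ["none"] * 3))
        assert group.group == "none"

    def test_missing_comparison_rejected(self):
        with pytest.raises(ValueError, match="lacks DE records"):
            assign_exclusive_groups([de_record("t", "PreVsPro", "up")])

    def test_matches_truth_table_brute_force(self):
        rng = np.random.default_rng(14)
        choices = ["up", "down", "none"]
        records, expected = [], {}
        for i in range(100):
            directions = [choices[k] for k in rng.integers(0, 3, 3)]
            records += records_for(f"t{i:03d}", directions)
            de_in = [c for c, d in zip(COMPARISONS, directions) if d != "none"]
            if len(de_in) == 1:
                expected[f"t{i:03d}"] = (GROUP_OF_COMPARISON[de_in[0]],
                                         directions[list(COMPARISONS).index(de_in[0])])
            else:
                expected[f"t{i:03d}"] = ("none", "none")
        for g in assign_exclusive_groups(records):
            assert (g.group, g.direction) == expected[g.transcript]


def oracle_triplets(circ_groups, mirna_groups, mrna_groups, interactions, group_label):
    """Exhaustive enumeration over all trios, filtered by the invariants."""
    out = set()
    for c, m, g in product(circ_groups, mirna_groups, mrna_groups):
        if not (c.group == m.group == g.group == group_label):
            continue
        if c.direction == "none" or c.direction != g.direction:
            continue
        if m.direction == c.direction or m.direction == "none":
            continue
        if (m.transcript, c.transcript, "circRNA") not in interactions.rows:
            continue
        if (m.transcript, g.transcript, "mRNA") not in interactions.rows:
            continue
        out.add((c.transcript, m.transcript, g.transcript))
    return out


class TestBuildTriplets:
    def _groups(self, spec):
        return [ExclusiveGroup(t, g, d) for t, g, d in spec]

    def test_single_consistent_triplet(self):
        circ = self._groups([("C1", "PrePro_only", "down")])
        mir = self._groups([("M1", "PrePro_only", "up")])
        mrna = self._groups([("G1", "PrePro_only", "down")])
        table = table_from([("M1", "C1", "circRNA"), ("M1", "G1", "mRNA")])
        (t,) = build_triplets(circ, mir, mrna, table, "PrePro_only")
        assert (t.circ_id, t.mirna_id, t.mrna_id) == ("C1", "M1", "G1")
        assert t.scheme == "circ_down_mir_up_mrna_down"

    def test_direction_scheme_violation_gives_empty(self):
        circ = self._groups([("C1", "PrePro_only", "down")])
        mir = self._groups([("M1", "PrePro_only", "up")])
        mrna = self._groups([("G1", "PrePro_only", "up")])  # same as miRNA: invalid
        table = table_from([("M1", "C1", "circRNA"), ("M1", "G1", "mRNA")])
        assert build_triplets(circ, mir, mrna, table, "PrePro_only") == []

    def test_hub_sponge_with_four_mirnas(self):
        # one upregulated circRNA sponging four downregulated miRNAs that all
        # target one upregulated mRNA, in the mature-vs-immature transition:
        # the Cr2 hub topology
        mirnas = ["mmu-miR-130b-5p", "mmu-miR-148a-5p", "mmu-miR-18b-3p",
                  "mmu-miR-467e-5p"]
        circ = self._groups([("novel_circ_000150", "MatureImmature_only", "up")])
        mir = self._groups([(m, "MatureImmature_only", "down") for m in mirnas])
        mrna = self._groups([("Cr2", "MatureImmature_only", "up")])
        table = table_from(
            [(m, "novel_circ_000150", "circRNA") for m in mirnas]
            + [(m, "Cr2", "mRNA") for m in mirnas])
        triplets = build_triplets(circ, mir, mrna, table, "MatureImmature_only")
        assert len(triplets) == 4
        assert all(t.circ_id == "novel_circ_000150" and t.mrna_id == "Cr2"
                   and t.scheme == "circ_up_mir_down_mrna_up" for t in triplets)
        assert sorted(t.mirna_id for t in triplets) == sorted(mirnas)
        assert network_summary(triplets) == {
            "n_circ": 1, "n_mirna": 4, "n_mrna": 1, "n_edges": 8}

    def test_members_outside_group_excluded(self):
        circ = self._groups([("C1", "ImmaturePre_only", "down")])
        mir = self._groups([("M1", "PrePro_only", "up")])
        mrna = self._groups([("G1", "PrePro_only", "down")])
        table = table_from([("M1", "C1", "circRNA"), ("M1", "G1", "mRNA")])
        assert build_triplets(circ, mir, mrna, table, "PrePro_only") == []

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError):
            build_triplets([], [], [], InteractionTable(), "FancyGroup")

    def test_matches_exhaustive_enumeration_on_random_instances(self):
        rng = np.random.default_rng(15)
        groups_plus_none = list(GROUPS) + ["none"]
        directions = ["up", "down"]
        for _ in range(50):
            def random_groups(prefix, n):
                out = []
                for i in range(n):
                    g = groups_plus_none[rng.integers(len(groups_plus_none))]
                    d = directions[rng.integers(2)] if g != "none" else "none"
                    out.append(ExclusiveGroup(f"{prefix}{i}", g, d))
                return out

            circ = random_groups("C", int(rng.integers(1, 21)))
            mir = random_groups("M", int(rng.integers(1, 21)))
            mrna = random_groups("G", int(rng.integers(1, 21)))
            table = InteractionTable()
            for m in mir:
                for c in circ:
                    if rng.random() < 0.3:
                        table.add(Interaction(m.transcript, c.transcript, "circRNA"))
                for g in mrna:
                    if rng.random() < 0.3:
                        table.add(Interaction(m.transcript, g.transcript, "mRNA"))
            group_label = GROUPS[rng.integers(3)]
            got = build_triplets(circ, mir, mrna, table, group_label)
            got_keys = {(t.circ_id, t.mirna_id, t.mrna_id) for t in got}
            assert got_keys == oracle_triplets(circ, mir, mrna, table, group_label)
            assert len(got_keys) == len(got)  # no duplicates
            # emitted triplets are each direction-consistent
            for t in got:
                assert t.group == group_label


class TestNetworkSummary:
    def test_empty_network_all_zero(self):
        assert network_summary([]) == {"n_circ": 0, "n_mirna": 0,
                                       "n_mrna": 0, "n_edges": 0}

    def test_counts_equal_brute_force_set_cardinalities(self):
        rng = np.random.default_rng(16)
        from bcellcerna.cerna_assembly import CeRNATriplet
        for _ in range(20):
            triplets = [
                CeRNATriplet(f"C{rng.integers(5)}", f"M{rng.integers(5)}",
                             f"G{rng.integers(5)}", "PrePro_only",
                             "circ_down_mir_up_mrna_down")
                for _ in range(int(rng.integers(0, 30)))
            ]
            summary = network_summary(triplets)
            assert summary["n_circ"] == len({t.circ_id for t in triplets})
            assert summary["n_mirna"] == len({t.mirna_id for t in triplets})
            assert summary["n_mrna"] == len({t.mrna_id for t in triplets})
            edges = {(t.circ_id, t.mirna_id) for t in triplets} | \
                    {("x", t.mirna_id, t.mrna_id) for t in triplets}
            assert summary["n_edges"] == len(edges)
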