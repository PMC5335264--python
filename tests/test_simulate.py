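"""Simulator determinism, truth bookkeeping, and emitted-format fidelity."""

import numpy as np
import pytest

from retroscreen.axt import parse_axt
from retroscreen.repeatmasker import parse_repeatmasker_out
from retroscreen.simulate import (
    DEFAULT_TREE,
    FAMILY_LIBRARY,
    emit_axt,
    emit_repeatmasker,
    simulate,
    truth_markers,
)


class TestSimulate:
    def test_same_seed_is_bit_identical(self):
        a = simulate(seed=9, genome_length=20_000, insertion_rate=3.0)
        b = simulate(seed=9, genome_length=20_000, insertion_rate=3.0)
        assert a.genomes == b.genomes
        assert a.events == b.events
        for taxon in a.taxa:
            assert emit_axt(a, "beaver", taxon) == emit_axt(b, "beaver", taxon) \
                if taxon != "beaver" else True
            assert emit_repeatmasker(a, taxon) == emit_repeatmasker(b, taxon)

    def test_zero_insertion_rate(self):
        ds = simulate(seed=2, insertion_rate=0.0, genome_length=20_000)
        assert ds.events == []
        assert all(len(g) == 20_000 for g in ds.genomes.values())

    def test_no_noise_carriers_are_full_descendant_sets(self):
        ds = simulate(seed=3, subst_rate=0.0, ils_prob=0.0, insertion_rate=3.0,
                      genome_length=50_000)
        assert ds.events
        for ev in ds.events:
            assert ev.carriers == frozenset(ev.branch)

    def test_no_noise_genomes_differ_only_by_events(self):
        ds = simulate(seed=3, subst_rate=0.0, ils_prob=0.0, insertion_rate=2.0,
                      genome_length=30_000)
        # removing all event sites leaves every taxon with the root sequence
        stripped = set()
        for taxon in ds.taxa:
            ids = ds.site_ids[taxon]
            keep = ids < ds.genome_length
            stripped.add("".join(c for c, k in zip(ds.genomes[taxon], keep) if k))
        assert len(stripped) == 1

    def test_rates_validated(self):
        with pytest.raises(ValueError):
            simulate(insertion_rate=-1)
        with pytest.raises(ValueError):
            simulate(ils_prob=1.5)
        with pytest.raises(ValueError):
            simulate(genome_length=100)


class TestEmitRepeatmasker:
    def test_no_insertions_gives_header_only(self):
        ds = simulate(seed=4, insertion_rate=0.0, genome_length=20_000)
        text = emit_repeatmasker(ds, "mouse")
        assert parse_repeatmasker_out(text.splitlines()) == []

    def test_row_count_matches_truth(self):
        ds = simulate(seed=5, insertion_rate=3.0, genome_length=50_000)
        for taxon in ds.taxa:
            records = parse_repeatmasker_out(emit_repeatmasker(ds, taxon).splitlines())
            expected = sum(1 for ev in ds.events if taxon in ev.carriers)
            assert len(records) == expected

    def test_coordinates_match_truth_and_sequence(self):
        ds = simulate(seed=6, subst_rate=0.0, insertion_rate=3.0, genome_length=50_000)
        for taxon in ds.taxa:
            records = parse_repeatmasker_out(emit_repeatmasker(ds, taxon).splitlines())
            by_id = {r.element_id: r for r in records}
            for ev, start, end in ds.elements[taxon]:
                record = by_id[ev.event_id]
                assert record.interval() == (start, end)
                assert ds.genomes[taxon][start:end] == FAMILY_LIBRARY[ev.family][1]


class TestEmitAxt:
    def test_identical_genomes_single_gap_free_block(self):
        ds = simulate(seed=7, insertion_rate=0.0, subst_rate=0.0, genome_length=20_000)
        blocks = parse_axt(emit_axt(ds, "mouse", "beaver").splitlines())
        assert len(blocks) == 1
        b = blocks[0]
        assert "-" not in b.ref_aln and "-" not in b.query_aln
        assert (b.ref_start, b.ref_end) == (0, 20_000)

    def test_ref_only_insertion_yields_matching_gap_columns(self):
        ds = simulate(seed=8, subst_rate=0.0, ils_prob=0.0,
                      insertions={("beaver",): 1}, genome_length=20_000)
        (ev,) = ds.events
        blocks = parse_axt(emit_axt(ds, "beaver", "mouse").splitlines())
        total_query_gaps = sum(b.query_aln.count("-") for b in blocks)
        assert total_query_gaps == ev.length

    def test_round_trip_preserves_coordinates(self):
        ds = simulate(seed=9, insertion_rate=2.0, subst_rate=0.01, genome_length=30_000)
        text = emit_axt(ds, "mouse", "kangaroo_rat")
        blocks = parse_axt(text.splitlines())
        from retroscreen.axt import write_axt

        assert parse_axt(write_axt(blocks).splitlines()) == blocks

    def test_block_sequences_match_genomes(self):
        ds = simulate(seed=10, insertion_rate=2.0, subst_rate=0.02, genome_length=30_000)
        for b in parse_axt(emit_axt(ds, "beaver", "guinea_pig").splitlines()):
            assert b.ref_aln.replace("-", "") == ds.genomes["beaver"][b.ref_start:b.ref_end]
            assert (b.query_aln.replace("-", "")
                    == ds.genomes["guinea_pig"][b.query_start:b.query_end])

    def test_block_length_splitting(self):
        ds = simulate(seed=11, insertion_rate=0.0, subst_rate=0.0, genome_length=20_000)
        blocks = parse_axt(
            emit_axt(ds, "mouse", "beaver", block_length=5000).splitlines())
        assert len(blocks) == 4
        assert [b.ref_start for b in blocks] == [0, 5000, 10000, 15000]


class TestTruthMarkers:
    def test_leaf_clade_gives_private_insertions(self):
        ds = simulate(seed=12, insertion_rate=3.0, ils_prob=0.0, genome_length=50_000)
        private = truth_markers(ds, ["mouse"])
        assert all(ev.carriers == frozenset({"mouse"}) for ev in private)
        assert len(private) == sum(1 for ev in ds.events if ev.branch == ("mouse",))

    def test_clades_partition_events_without_ils(self):
        ds = simulate(seed=13, insertion_rate=3.0, ils_prob=0.0, genome_length=50_000)
        import dendropy

        tree = dendropy.Tree.get(data=DEFAULT_TREE, schema="newick",
                                 preserve_underscores=True)
        clades = []
        for node in tree.preorder_node_iter():
            if node is not tree.seed_node:
                clades.append(tuple(sorted(l.taxon.label for l in node.leaf_iter())))
        recovered = [ev for clade in clades for ev in truth_markers(ds, clade)]
        assert sorted(ev.event_id for ev in recovered) == [ev.event_id for ev in ds.events]

    def test_hand_built_three_event_scenario(self):
        ds = simulate(
            seed=14, subst_rate=0.0, ils_prob=0.0,
            insertions={("beaver", "kangaroo_rat"): 1, ("mouse",): 1,
                        ("ground_squirrel",): 1},
        )
        (marker,) = truth_markers(ds, ["beaver", "kangaroo_rat"])
        assert marker.branch == ("beaver", "kangaroo_rat")
        assert len(ds.events) == 3


class TestEndToEnd:
    def test_recall_degrades_with_substitution_rate(self):
        from conftest import CASTORIMORPHA_PATTERNS, screen_from_dataset

        recalls = []
        for subst in (0.0, 0.25, 0.6):
            found = 0
            for rep in range(3):
                ds = simulate(seed=500 + rep, subst_rate=subst, ils_prob=0.0,
                              insertions={("beaver", "kangaroo_rat"): 6},
                              genome_length=60_000)
                result = screen_from_dataset(ds, CASTORIMORPHA_PATTERNS)
                found += result.pattern_counts["castorimorpha"]
            recalls.append(found / 18)
        assert recalls[0] == 1.0
        assert recalls == sorted(recalls, reverse=True)
        assert recalls[-1] < 1.0
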