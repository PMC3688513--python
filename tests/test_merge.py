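"""Merging redundant transcripts, proximity grouping, naming, strand calls."""

import numpy as np
import pytest
from oracles import merge_components_oracle

from linccat.intervals import TranscriptModel, interval_gap_distance
from linccat.merge import (
    assign_names,
    build_catalog,
    group_by_proximity,
    infer_strand,
    merge_closure,
    should_merge,
)


def _tx(tid, exons, strand=".", chrom="chr1"):
    return TranscriptModel(tid, chrom, strand, exons)


class TestShouldMerge:
    def test_fifty_percent_boundary(self):
        assert should_merge(_tx("a", [(0, 1000)]), _tx("b", [(500, 1500)]))  # 50%
        assert not should_merge(_tx("a", [(0, 1000)]), _tx("b", [(600, 1600)]))  # 40%

    def test_one_directional_small_exon_contained(self):
        assert should_merge(_tx("a", [(0, 100)]), _tx("b", [(0, 10_000)]))

    def test_opposite_definite_strands_never_merge(self):
        assert not should_merge(
            _tx("a", [(0, 1000)], "+"), _tx("b", [(0, 1000)], "-")
        )
        assert should_merge(_tx("a", [(0, 1000)], "+"), _tx("b", [(0, 1000)], "."))

    def test_cross_chromosome_false(self):
        assert not should_merge(
            _tx("a", [(0, 1000)]), _tx("b", [(0, 1000)], chrom="chr2")
        )

    def test_exon_level_not_span_level(self):
        # spans overlap heavily but no exon pair reaches 50%
        a = _tx("a", [(0, 200), (5000, 5200)])
        b = _tx("b", [(2000, 2200), (9000, 9200)])
        assert not should_merge(a, b)


def _random_transcripts(rng, n, span=50_000):
    txs = []
    for i in range(n):
        start = int(rng.integers(0, span))
        n_ex = int(rng.integers(1, 4))
        exons = []
        pos = start
        for _ in range(n_ex):
            ln = int(rng.integers(100, 600))
            exons.append((pos, pos + ln))
            pos += ln + int(rng.integers(100, 800))
        txs.append(
            _tx(f"t{i}", exons, strand=["+", "-", "."][int(rng.integers(3))],
                chrom=f"chr{int(rng.integers(1, 3))}")
        )
    return txs


class TestMergeClosure:
    def test_chain_forms_one_component(self):
        a = _tx("a", [(0, 1000)])
        b = _tx("b", [(500, 1500)])
        c = _tx("c", [(1000, 2000)])
        assert not should_merge(a, c)
        merged = merge_closure([a, b, c])
        assert len(merged) == 1
        assert merged[0].member_ids == ["a", "b", "c"]
        assert merged[0].model.exons == [(0, 2000)]

    def test_pairwise_non_mergeable_identity(self):
        txs = [_tx(f"t{i}", [(i * 5000, i * 5000 + 500)]) for i in range(5)]
        assert len(merge_closure(txs)) == 5

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            txs = _random_transcripts(rng, int(rng.integers(20, 80)))
            merged = merge_closure(txs)
            got = {frozenset(m.member_ids) for m in merged}
            expected = merge_components_oracle(txs, should_merge)
            assert got == expected

    def test_output_is_fixed_point(self):
        rng = np.random.default_rng(2)
        txs = _random_transcripts(rng, 60)
        merged = merge_closure(txs)
        models = [m.model for m in merged]
        for i, a in enumerate(models):
            for b in models[i + 1 :]:
                assert not should_merge(a, b)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(3)
        txs = _random_transcripts(rng, 50)
        m1 = merge_closure(txs)
        perm = list(txs)
        rng.shuffle(perm)
        m2 = merge_closure(perm)
        assert [m.member_ids for m in m1] == [m.member_ids for m in m2]
        assert [m.model.exons for m in m1] == [m.model.exons for m in m2]


class TestGrouping:
    def _merged(self, spans, chrom="chr1"):
        txs = [_tx(f"t{i}", [span], chrom=chrom) for i, span in enumerate(spans)]
        return merge_closure(txs)

    def test_1kb_boundary(self):
        groups = group_by_proximity(self._merged([(0, 100), (1099, 1200)]))
        assert groups[0].group_id == groups[1].group_id  # 999 bp apart
        groups = group_by_proximity(self._merged([(0, 100), (1101, 1200)]))
        assert groups[0].group_id != groups[1].group_id  # 1001 bp apart

    def test_chain_is_transitive(self):
        groups = group_by_proximity(
            self._merged([(0, 100), (1000, 1100), (2000, 2100)])
        )
        assert len({m.group_id for m in groups}) == 1

    def test_matches_gap_graph_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            txs = _random_transcripts(rng, 60)
            merged = group_by_proximity(merge_closure(txs))

            class _Node:
                def __init__(self, m):
                    self.id = m.model.id
                    self.m = m

            nodes = [_Node(m) for m in merged]
            comp = merge_components_oracle(
                nodes,
                lambda a, b: interval_gap_distance(
                    (a.m.model.chrom, a.m.model.start, a.m.model.end),
                    (b.m.model.chrom, b.m.model.start, b.m.model.end),
                )
                <= 1000,
            )
            got = {}
            for m in merged:
                got.setdefault(m.group_id, set()).add(m.model.id)
            assert {frozenset(v) for v in got.values()} == comp


class TestNaming:
    def test_template_and_numbering(self):
        merged = group_by_proximity(
            merge_closure(
                [_tx("a", [(0, 500)]), _tx("b", [(900, 1400)]), _tx("c", [(9000, 9500)])]
            )
        )
        named = assign_names(merged, tier=1)
        assert [m.name for m in named] == [
            "FPKM1_group_1_transcript_1",
            "FPKM1_group_1_transcript_2",
            "FPKM1_group_2_transcript_1",
        ]

    def test_deterministic(self):
        txs = [_tx("a", [(0, 500)]), _tx("b", [(2000, 2500)])]
        n1 = [m.name for m in assign_names(group_by_proximity(merge_closure(txs)), 10)]
        n2 = [m.name for m in assign_names(group_by_proximity(merge_closure(txs)), 10)]
        assert n1 == n2 == ["FPKM10_group_1_transcript_1", "FPKM10_group_2_transcript_1"]


class TestInferStrand:
    def _merged_tx(self, exons):
        m = merge_closure([_tx("a", exons)])
        return m[0]

    def test_gt_ag_introns_give_plus(self):
        seq = "A" * 100 + "GT" + "A" * 96 + "AG" + "A" * 100
        m = self._merged_tx([(0, 100), (200, 300)])
        assert infer_strand(m, sequences={"chr1": seq}) == "+"

    def test_ct_ac_introns_give_minus(self):
        seq = "A" * 100 + "CT" + "A" * 96 + "AC" + "A" * 100
        m = self._merged_tx([(0, 100), (200, 300)])
        assert infer_strand(m, sequences={"chr1": seq}) == "-"

    def test_single_exon_ambiguous(self):
        assert infer_strand(self._merged_tx([(0, 300)]), sequences={"chr1": "A" * 300}) == "."

    def test_conflicting_junctions_ambiguous(self):
        assert infer_strand(self._merged_tx([(0, 100)]), junction_orientations=["+", "-"]) == "."


class TestMergedExpression:
    def test_merged_count_never_below_member_count(self):
        """The merged exon union is a superset of each member's exons, so
        any read counted for a member is counted for the merged model."""
        from linccat.expression import count_reads_full_assignment
        from linccat.intervals import ReadAlignment

        rng = np.random.default_rng(5)
        txs = _random_transcripts(rng, 40, span=20_000)
        reads = [
            ReadAlignment(
                chrom=f"chr{int(rng.integers(1, 3))}",
                blocks=[(int(s), int(s) + 75)],
            )
            for s in rng.integers(0, 25_000, size=2000)
        ]
        member_counts = count_reads_full_assignment(reads, txs)
        merged = merge_closure(txs)
        merged_counts = count_reads_full_assignment(reads, [m.model for m in merged])
        for m in merged:
            assert merged_counts[m.model.id] >= max(
                member_counts[mid] for mid in m.member_ids
            )

    def test_build_catalog_runs_all_steps(self):
        txs = [_tx("a", [(0, 500)]), _tx("b", [(250, 750)]), _tx("c", [(5000, 5500)])]
        catalog = build_catalog(txs, tier=1)
        assert len(catalog) == 2
        assert all(m.name.startswith("FPKM1_group_") for m in catalog)
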