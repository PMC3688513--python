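"""Collapse redundant surviving transcripts into lincRNA "genes", group by
proximity, and assign catalog names.

Two transcripts are merged when at least 50% of an exon of either one is
covered by an exon of the other (one-directional suffices); merging is
taken to transitive closure so each merged model is the exon union of a
connected component. Merged models within 1 kb of each other share a group
id but keep distinct transcript numbers; names follow the pattern
``FPKM{tier}_group_{g}_transcript_{t}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .intervals import (
    AMBIGUOUS,
    TranscriptModel,
    exon_overlap_bp,
    merge_intervals,
)

MERGE_FRACTION = 0.5
GROUP_BP = 1000


def _strand_compatible(a: str, b: str) -> bool:
    # opposite definite strands never merge; ambiguous matches both
    return a == AMBIGUOUS or b == AMBIGUOUS or a == b


def should_merge(a: TranscriptModel, b: TranscriptModel,
                 fraction: float = MERGE_FRACTION) -> bool:
    """True iff some exon pair overlaps by >= 50% of either exon's length."""
    if a.chrom != b.chrom:
        return False
    if not _strand_compatible(a.strand, b.strand):
        return False
    for ea in a.exons:
        la = ea[1] - ea[0]
        for eb in b.exons:
            ov = exon_overlap_bp(ea, eb)
            if ov == 0:
                continue
            lb = eb[1] - eb[0]
            if ov >= fraction * la or ov >= fraction * lb:
                return True
    return False


@dataclass
class MergedTranscript:
    """Union exon structure of a merge component plus its member ids."""

    model: TranscriptModel
    member_ids: list[str]
    group_id: int = -1
    name: str = ""


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _component_strand(strands: Iterable[str]) -> str:
    definite = {s for s in strands if s != AMBIGUOUS}
    if len(definite) == 1:
        return definite.pop()
    return AMBIGUOUS


def merge_closure(transcripts: Sequence[TranscriptModel]) -> list[MergedTranscript]:
    """Connected components under ``should_merge``, each collapsed to its
    per-chromosome exon union.

    Candidate pairs are found with an interval index over transcript spans
    (only span-overlapping pairs can satisfy the exon test), then closed
    with union-find. Output is sorted by (chrom, start) and is a fixed
    point: no two outputs satisfy the merge predicate.
    """
    ordered = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.end, t.id))
    dsu = _DisjointSet(len(ordered))
    trees: dict[str, IntervalTree] = {}
    for i, t in enumerate(ordered):
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end, i)
    for i, t in enumerate(ordered):
        for iv in trees[t.chrom].overlap(t.start, t.end):
            j = iv.data
            if j <= i:
                continue
            if should_merge(t, ordered[j]):
                dsu.union(i, j)
    components: dict[int, list[int]] = {}
    for i in range(len(ordered)):
        components.setdefault(dsu.find(i), []).append(i)
    merged = []
    for members in components.values():
        ts = [ordered[i] for i in members]
        exons = merge_intervals([ex for t in ts for ex in t.exons])
        model = TranscriptModel(
            id="+".join(sorted(t.id for t in ts)),
            chrom=ts[0].chrom,
            strand=_component_strand(t.strand for t in ts),
            exons=exons,
            source_tag="merged",
        )
        merged.append(
            MergedTranscript(model=model, member_ids=sorted(t.id for t in ts))
        )
    merged.sort(key=lambda m: (m.model.chrom, m.model.start, m.model.end))
    return merged


def group_by_proximity(
    merged: Sequence[MergedTranscript], group_bp: int = GROUP_BP
) -> list[MergedTranscript]:
    """Assign dense group ids: merged spans within 1 kb (inclusive,
    transitively) share a group. Ids are ordered by leftmost coordinate."""
    ordered = sorted(merged, key=lambda m: (m.model.chrom, m.model.start, m.model.end))
    gid = -1
    prev = None
    for m in ordered:
        if (
            prev is None
            or m.model.chrom != prev.model.chrom
            or m.model.start - prev_end > group_bp
        ):
            gid += 1
            prev_end = m.model.end
        else:
            prev_end = max(prev_end, m.model.end)
        m.group_id = gid
        prev = m
    return ordered


def assign_names(merged: Sequence[MergedTranscript], tier: int) -> list[MergedTranscript]:
    """Name merged transcripts ``FPKM{tier}_group_{g}_transcript_{t}`` with
    transcripts numbered from 1 within each group by leftmost coordinate."""
    ordered = sorted(merged, key=lambda m: (m.group_id, m.model.chrom, m.model.start))
    counters: dict[int, int] = {}
    for m in ordered:
        counters[m.group_id] = counters.get(m.group_id, 0) + 1
        m.name = f"FPKM{tier}_group_{m.group_id + 1}_transcript_{counters[m.group_id]}"
        m.model.id = m.name
    return ordered


def infer_strand(
    merged: MergedTranscript, sequences: Mapping[str, str] | None = None,
    junction_orientations: Sequence[str] | None = None,
) -> str:
    """Infer strand from splice-junction orientation (GT..AG introns).

    Junction orientations may be supplied directly (``"+"``/``"-"`` per
    intron) or derived from chromosome sequence. Returns a definite strand
    only when all junctions agree; single-exon transcripts and conflicting
    evidence yield ambiguous.
    """
    model = merged.model
    if junction_orientations is None:
        if sequences is None or model.n_exons < 2:
            return AMBIGUOUS
        seq = sequences[model.chrom]
        junction_orientations = []
        for s, e in model.introns:
            donor = seq[s : s + 2].upper()
            acceptor = seq[e - 2 : e].upper()
            if donor == "GT" and acceptor == "AG":
                junction_orientations.append("+")
            elif donor == "CT" and acceptor == "AC":
                junction_orientations.append("-")
            else:
                junction_orientations.append(AMBIGUOUS)
    calls = set(junction_orientations)
    if calls == {"+"}:
        return "+"
    if calls == {"-"}:
        return "-"
    return AMBIGUOUS


def build_catalog(
    transcripts: Sequence[TranscriptModel],
    tier: int,
    sequences: Mapping[str, str] | None = None,
) -> list[MergedTranscript]:
    """merge -> group -> name -> strand inference, in one call."""
    merged = group_by_proximity(merge_closure(transcripts))
    merged = assign_names(merged, tier)
    for m in merged:
        m.model.strand = infer_strand(m, sequences=sequences)
    return merged


def write_membership_tsv(path, merged: Sequence[MergedTranscript]) -> None:
    with open(path, "w") as fh:
        fh.write("name\tgroup_id\tmember_ids\n")
        for m in merged:
            fh.write(f"{m.name}\t{m.group_id + 1}\t{','.join(m.member_ids)}\n")
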