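"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive — per-base arrays, all-pairs loops,
exhaustive enumeration — and shares no code path with the package.
"""

from __future__ import annotations

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[c] for c in reversed(seq))


def orf_calls_oracle(seq: str) -> set[tuple[int, str, int, int]]:
    """All large-ORF calls as (frame, kind, start_offset, aa_length).

    Complete: ATG -> stop, > 100 aa, using the first ATG after the previous
    stop. Stop-truncated: the first ATG with no downstream in-frame stop and
    > 300 nt after the start codon. Start-truncated: the first in-frame stop
    with no prior in-frame ATG/stop and > 300 nt upstream of it.
    """
    seq = seq.upper()
    calls: set[tuple[int, str, int, int]] = set()
    for strand_idx, s in enumerate((seq, revcomp(seq))):
        n = len(s)
        for f in range(3):
            frame = 3 * strand_idx + f
            positions = list(range(f, n - 2, 3))
            stops = [p for p in positions if s[p : p + 3] in STOPS]
            atgs = [p for p in positions if s[p : p + 3] == "ATG"]
            for sp in stops:
                priors = [
                    a for a in atgs
                    if a < sp and not any(a < st < sp for st in stops)
                ]
                if priors:
                    a = min(priors)
                    aa = (sp - a) // 3
                    if aa > 100:
                        calls.add((frame, "complete", a, aa))
            tail = [a for a in atgs if not any(st > a for st in stops)]
            if tail:
                a = min(tail)
                if n - (a + 3) > 300:
                    calls.add((frame, "stop_truncated", a, (n - a) // 3))
            if stops:
                fs = min(stops)
                if not any(a < fs for a in atgs) and fs > 300:
                    calls.add((frame, "start_truncated", f, (fs - f) // 3))
    return calls


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ACGT"[i] for i in rng.choice(4, size=n, p=p))


def depth_oracle(reads, chrom_size: int, chrom: str, include_inferred: bool) -> np.ndarray:
    """Naive per-base depth array for one chromosome."""
    depth = np.zeros(chrom_size, dtype=int)
    for r in reads:
        if r.chrom != chrom:
            continue
        if include_inferred:
            for pos in range(r.start, r.end):
                depth[pos] += 1
        else:
            for s, e in r.blocks:
                for pos in range(s, e):
                    depth[pos] += 1
    return depth


def merge_components_oracle(transcripts, predicate) -> set[frozenset]:
    """All-pairs connected components via networkx."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(t.id for t in transcripts)
    for i, a in enumerate(transcripts):
        for b in transcripts[i + 1 :]:
            if predicate(a, b):
                g.add_edge(a.id, b.id)
    return {frozenset(c) for c in nx.connected_components(g)}


def tx_to_genome_map(t) -> list[int]:
    return [pos for s, e in t.exons for pos in range(s, e)]


def window_ratio_oracle(t, ribo_reads, rna_reads, window: int = 30):
    """Exhaustive per-window read-overlap ratio maximum."""
    gmap = tx_to_genome_map(t)
    L = len(gmap)
    if L < window:
        return None
    ribo_bases = [
        {p for s, e in r.blocks for p in range(s, e)}
        for r in ribo_reads if r.chrom == t.chrom
    ]
    rna_bases = [
        {p for s, e in r.blocks for p in range(s, e)}
        for r in rna_reads if r.chrom == t.chrom
    ]
    best = None
    for w in range(L - window + 1):
        wpos = set(gmap[w : w + window])
        rna = sum(1 for b in rna_bases if b & wpos)
        if rna == 0:
            continue
        ratio = sum(1 for b in ribo_bases if b & wpos) / rna
        best = ratio if best is None else max(best, ratio)
    return best


def conserved_window_oracle(t, scores_by_chrom, window: int = 50):
    """Exhaustive max mean over fully-scored exonic windows."""
    gmap = tx_to_genome_map(t)
    vals = [scores_by_chrom[t.chrom][p] for p in gmap]
    best = None
    for w in range(len(vals) - window + 1):
        chunk = vals[w : w + window]
        if any(np.isnan(v) for v in chunk):
            continue
        m = float(np.mean(chunk))
        best = m if best is None else max(best, m)
    return best


def fisher_oracle(table) -> float:
    """Two-sided Fisher p by hypergeometric enumeration."""
    from scipy.stats import hypergeom

    (a, b), (c, d) = table
    n1 = a + b
    n2 = c + d
    k = a + c
    lo = max(0, k - n2)
    hi = min(k, n1)
    pmf_obs = hypergeom.pmf(a, n1 + n2, k, n1)
    p = 0.0
    for x in range(lo, hi + 1):
        px = hypergeom.pmf(x, n1 + n2, k, n1)
        if px <= pmf_obs * (1 + 1e-9):
            p += px
    return min(1.0, float(p))
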