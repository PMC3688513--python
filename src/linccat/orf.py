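"""Open-reading-frame scanning for coding-potential filtering.

A transcript is flagged as potentially coding if any of its six reading
frames (three per strand) contains:

* a complete ORF — ATG ... in-frame stop — longer than 100 amino acids
  (the stop codon is excluded from the amino-acid count, so 101 aa is the
  smallest "large" ORF), or
* a start codon followed by more than 300 nt of in-frame stop-free sequence
  running off the end of the transcript (stop-truncated ORF), or
* an in-frame stop codon more than 300 nt from the start of the transcript
  with no in-frame ATG or stop before it (start-truncated ORF).

The truncation rules account for transcript models whose annotated region
clips the true start or stop codon. Codons containing ``N`` never match a
start or stop codon.
"""

from __future__ import annotations

from dataclasses import dataclass

STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))
START_CODON = "ATG"
LARGE_ORF_AA = 100       # strict: aa_length > 100
TRUNCATION_NT = 300      # strict: > 300 nt of frame-clipped coding potential

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_NT = frozenset("ACGTN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class OrfCall:
    """One putative large ORF in one reading frame of a transcript sequence.

    Offsets are nucleotide positions within the scanned (forward or
    reverse-complemented) sequence; ``frame`` 0-2 are forward, 3-5 reverse.
    """

    frame: int
    start_offset: int
    end_offset: int
    aa_length: int
    kind: str  # complete | start_truncated | stop_truncated


def _scan_frame(seq: str, offset: int, frame_index: int) -> list[OrfCall]:
    n = len(seq)
    calls: list[OrfCall] = []
    # in-frame codon start positions
    codon_starts = range(offset, n - 2, 3)
    atg_positions = []
    stop_positions = []
    for p in codon_starts:
        codon = seq[p : p + 3]
        if codon == START_CODON:
            atg_positions.append(p)
        elif codon in STOP_CODONS:
            stop_positions.append(p)

    # Complete ORFs: for each stop, the ORF from the first ATG after the
    # previous stop (the longest ATG->stop ORF ending at that stop).
    ai = 0
    prev_stop_end = offset - 1
    for sp in stop_positions:
        while ai < len(atg_positions) and atg_positions[ai] <= prev_stop_end:
            ai += 1
        if ai < len(atg_positions) and atg_positions[ai] < sp:
            atg = atg_positions[ai]
            aa = (sp - atg) // 3
            if aa > LARGE_ORF_AA:
                calls.append(
                    OrfCall(frame_index, atg, sp + 3, aa, "complete")
                )
        prev_stop_end = sp

    # Stop-truncated: first ATG after the last stop, with >300 stop-free nt
    # downstream of the start codon to the end of the sequence.
    last_stop = stop_positions[-1] if stop_positions else offset - 1
    tail_atgs = [p for p in atg_positions if p > last_stop]
    if tail_atgs:
        atg = tail_atgs[0]
        downstream = n - (atg + 3)
        if downstream > TRUNCATION_NT:
            calls.append(
                OrfCall(frame_index, atg, n, (n - atg) // 3, "stop_truncated")
            )

    # Start-truncated: first stop in the frame, >300 nt upstream of its first
    # base, with no in-frame ATG (or stop) before it.
    if stop_positions:
        first_stop = stop_positions[0]
        no_prior_atg = not atg_positions or atg_positions[0] > first_stop
        if no_prior_atg and first_stop > TRUNCATION_NT:
            calls.append(
                OrfCall(
                    frame_index,
                    offset,
                    first_stop + 3,
                    (first_stop - offset) // 3,
                    "start_truncated",
                )
            )
    return calls


def find_large_orfs(sequence: str, strandedness: str = "both") -> list[OrfCall]:
    """Scan all six reading frames for putative large ORFs.

    Returns only qualifying ("large") calls; an empty list means the
    sequence shows no coding potential under the filter's rules. Transcripts
    are scanned on both strands regardless of annotated strand, matching the
    mostly strand-ambiguous nature of assembled intergenic transcripts.
    """
    seq = sequence.upper()
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    bad = set(seq) - VALID_NT
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    calls: list[OrfCall] = []
    for f in range(3):
        calls.extend(_scan_frame(seq, f, f))
    if strandedness == "both":
        rc = reverse_complement(seq)
        for f in range(3):
            calls.extend(_scan_frame(rc, f, 3 + f))
    return calls


def has_large_orf(sequence: str) -> bool:
    return bool(find_large_orfs(sequence))
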