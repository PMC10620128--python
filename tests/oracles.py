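"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorised code paths: interval
arithmetic is checked against per-base boolean sets, guide enumeration
against exhaustive placement loops over plain strings, and off-target
search against a sliding-window Hamming scan.
"""

from __future__ import annotations

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def base_set(intervals) -> set[tuple[str, int]]:
    """Every (chrom, position) covered by the intervals."""
    covered = set()
    for iv in intervals:
        for pos in range(iv.start, iv.end):
            covered.add((iv.chrom, pos))
    return covered


def placement_guides(seq: str, ebox_start: int, ebox_end: int) -> set[tuple[str, str, int]]:
    """All (protospacer, strand, start) whose cut bond is inside the E-box.

    Exhaustive loop over every protospacer placement on both strands of a
    plain sequence string; the blunt cut sits 3 nt 5' of the NGG PAM.
    """
    out = set()
    L = len(seq)
    internal = set(range(ebox_start + 1, ebox_end))
    for p in range(L - 22):
        if seq[p + 21 : p + 23] == "GG" and (p + 17) in internal:
            window = seq[p : p + 23]
            if "N" not in window:
                out.add((seq[p : p + 20], "+", p))
    for q in range(3, L - 19):
        if seq[q - 3 : q - 1] == "CC" and (q + 3) in internal:
            window = seq[q - 3 : q + 20]
            if "N" not in window:
                out.add((revcomp(seq[q : q + 20]), "-", q))
    return out


def sliding_offtargets(genome_sequences: dict[str, str], protospacer: str,
                       max_mm: int) -> set[tuple[str, int, str, frozenset[int]]]:
    """Every NGG-adjacent locus within max_mm mismatches of the guide.

    Returns (chrom, protospacer_start, strand, mismatch_positions) with
    positions in 1-20 protospacer coordinates (1 = PAM-distal).
    """
    rc = revcomp(protospacer)
    hits = set()
    for chrom, seq in genome_sequences.items():
        L = len(seq)
        for p in range(L - 22):
            if seq[p + 21 : p + 23] == "GG":
                w = seq[p : p + 20]
                mm = [i + 1 for i in range(20) if w[i] != protospacer[i]]
                if len(mm) <= max_mm:
                    hits.add((chrom, p, "+", frozenset(mm)))
        for q in range(3, L - 19):
            if seq[q - 3 : q - 1] == "CC":
                w = seq[q : q + 20]
                mm = [20 - i for i in range(20) if w[i] != rc[i]]
                if len(mm) <= max_mm:
                    hits.add((chrom, q, "-", frozenset(mm)))
    return hits


def retention_rule(sites: set[tuple[str, int, str, frozenset[int]]],
                   on_target: set[tuple[str, int, str]]) -> bool:
    """Literal application of the mismatch retention rule."""
    for chrom, start, strand, mm in sites:
        if (chrom, start, strand) in on_target:
            continue
        if len(mm) >= 3:
            continue
        if len(mm) >= 2 and any(9 <= p <= 20 for p in mm):
            continue
        return False
    return True
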