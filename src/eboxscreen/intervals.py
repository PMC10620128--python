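"""Genomic intervals, binding sites and sequence access.

Coordinates are 0-based half-open (BED-native) throughout; 1-based
coordinates appear only in human-facing reports. Chromosome sequences are
held in memory as uppercase strings over the {A, C, G, T, N} alphabet,
which is comfortable for the peak-scale inputs this package works with.
"""

from __future__ import annotations

import textwrap
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GenomicInterval",
    "BindingSite",
    "Genome",
    "merge_intervals",
    "assign_binding_sites",
    "overlaps",
    "fetch_sequence",
    "reverse_complement",
    "read_bed",
    "write_bed",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_DNA_ALPHABET = frozenset("ACGTN")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``.

    ``strand`` is optional and ignored by interval arithmetic; it matters
    only for features that have an orientation (guides, TSSs).
    """

    chrom: str
    start: int
    end: int
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("interval chromosome name must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class BindingSite:
    """A merged ChIP-peak region with a per-chromosome ordinal identity.

    Sites are labelled ``{chrom}_BS{ordinal}`` with ordinals assigned in
    ascending start order and restarting at 1 on every chromosome.
    ``sources`` records which cell lines contributed peaks to the merged
    region (the union of labels survives merging).
    """

    interval: GenomicInterval
    ordinal: int
    sources: frozenset[str] = frozenset()

    @property
    def id(self) -> str:
        return f"{self.interval.chrom}_BS{self.ordinal}"


class Genome:
    """In-memory reference genome: chromosome name -> uppercase DNA string."""

    def __init__(self, sequences: Mapping[str, str]):
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            bad = set(seq) - _DNA_ALPHABET
            if bad:
                raise ValueError(f"chromosome {name!r} contains non-DNA characters {sorted(bad)}")
            self.sequences[name] = seq

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, interval: GenomicInterval) -> str:
        return fetch_sequence(self, interval)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.sequences):
                fh.write(f">{name}\n")
                fh.write(textwrap.fill(self.sequences[name], width) + "\n")


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and bookended intervals into disjoint regions.

    The result is sorted by (chrom, start); bookended inputs (``end ==
    start``) coalesce, so consecutive output intervals are separated by at
    least one uncovered base.
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in by_pos:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


def assign_binding_sites(
    merged: Sequence[GenomicInterval],
    sources: Sequence[Iterable[str]] | None = None,
) -> list[BindingSite]:
    """Label merged intervals with per-chromosome ``BS`` ordinals.

    Ordinals restart at 1 per chromosome and follow ascending start order.
    Raises if the input still contains overlapping or bookended intervals
    on one chromosome (i.e. was not produced by :func:`merge_intervals`).
    """
    if sources is not None and len(sources) != len(merged):
        raise ValueError("sources must align with the merged interval list")
    order = sorted(range(len(merged)), key=lambda i: (merged[i].chrom, merged[i].start))
    sites: list[BindingSite] = []
    counter: dict[str, int] = {}
    prev_end: dict[str, int] = {}
    for i in order:
        iv = merged[i]
        if iv.chrom in prev_end and iv.start <= prev_end[iv.chrom]:
            raise ValueError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} overlaps or touches its "
                "predecessor; run merge_intervals first"
            )
        prev_end[iv.chrom] = iv.end
        counter[iv.chrom] = counter.get(iv.chrom, 0) + 1
        labels = frozenset(sources[i]) if sources is not None else frozenset()
        sites.append(BindingSite(iv, counter[iv.chrom], labels))
    return sites


def overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """Half-open overlap test: bookended intervals do not overlap."""
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def fetch_sequence(genome: Genome, interval: GenomicInterval) -> str:
    """Plus-strand sequence of ``interval``; errors outside chromosome bounds."""
    if interval.chrom not in genome:
        raise KeyError(f"unknown chromosome {interval.chrom!r}")
    seq = genome[interval.chrom]
    if interval.end > len(seq):
        raise IndexError(
            f"interval {interval.chrom}:{interval.start}-{interval.end} exceeds "
            f"chromosome length {len(seq)}"
        )
    return seq[interval.start : interval.end]


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A, C, G, T, N}; an involution."""
    seq = seq.upper()
    bad = set(seq) - _DNA_ALPHABET
    if bad:
        raise ValueError(f"cannot reverse-complement characters {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 (tab-separated, 0-based half-open)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected at least 3 BED columns")
            strand = parts[5] if len(parts) >= 6 and parts[5] in ("+", "-") else None
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(
    path: str | Path,
    intervals: Sequence[GenomicInterval],
    names: Sequence[str] | None = None,
) -> None:
    """Write BED3 (or BED6 when names are given) in (chrom, start) order."""
    rows = list(zip(intervals, names if names is not None else [None] * len(intervals)))
    rows.sort(key=lambda r: (r[0].chrom, r[0].start, r[0].end))
    with open(path, "w") as fh:
        for iv, name in rows:
            if name is None:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand or '+'}\n")
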