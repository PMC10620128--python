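"""Pooled-screen read counting and screen-planning quantities.

Amplicon reads carry a variable 9-18 nt stagger, an 8-nt sample barcode
(on the reverse primer, so not inside the read used here), and the
constant vector sequence ending ``GAAACACCG`` immediately 5' of the 20-nt
protospacer.  Protospacers are therefore recovered by locating that
anchor string, not by positional trimming, and counted only on an exact
20-nt match to the library — mismatched reads are never assigned.
"""

from __future__ import annotations

import gzip
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .design import LibraryEntry

__all__ = [
    "DEFAULT_ANCHOR",
    "AmpliconLayout",
    "CountMatrix",
    "extract_protospacer",
    "count_exact",
    "count_fastq",
    "skew_ratio",
    "fold_coverage",
    "single_infection_fraction",
    "read_fastq",
    "sample_qc",
]

#: Tail of the left oligo arm; the last vector bases before the protospacer.
DEFAULT_ANCHOR = "GAAACACCG"


@dataclass(frozen=True)
class AmpliconLayout:
    """Structure of a screen amplicon read."""

    anchor: str = DEFAULT_ANCHOR
    stagger_min: int = 9
    stagger_max: int = 18
    barcode_length: int = 8

    def __post_init__(self) -> None:
        if not self.anchor:
            raise ValueError("anchor must be non-empty")
        if not 0 < self.stagger_min <= self.stagger_max:
            raise ValueError("stagger range must satisfy 0 < min <= max")


class CountMatrix:
    """Integer construct x sample count table (thin pandas wrapper).

    Rows are library-entry (or target) names, columns are sample labels
    such as ``K562_EBOX_R1_T0``.
    """

    def __init__(self, counts: pd.DataFrame):
        if counts.index.has_duplicates:
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row names: {dups[:5]}")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.counts = counts.astype(np.int64)

    @property
    def entries(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def column(self, sample: str) -> pd.Series:
        return self.counts[sample]

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="name")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)


def extract_protospacer(read: str, layout: AmpliconLayout | None = None) -> str | None:
    """The 20 nt after the first anchor occurrence, or None if unparseable."""
    layout = layout or AmpliconLayout()
    idx = read.find(layout.anchor)
    if idx < 0:
        return None
    start = idx + len(layout.anchor)
    if len(read) - start < 20:
        return None
    return read[start : start + 20]


def count_exact(
    protospacers: Iterable[str | None],
    library: Sequence[LibraryEntry] | Sequence[str],
) -> tuple[pd.Series, int]:
    """Exact-match counting of extracted protospacers against the library.

    Returns (per-entry counts, number of unmatched extractions).  ``None``
    items (unparseable reads) count as unmatched.  Order-invariant.
    """
    if library and isinstance(library[0], LibraryEntry):
        names = [e.name for e in library]
        seq_to_name = {e.protospacer: e.name for e in library}
    else:
        names = list(library)
        seq_to_name = {s: s for s in library}
    if len(seq_to_name) != len(names):
        raise ValueError("library protospacer sequences must be unique")
    tally = dict.fromkeys(names, 0)
    unmatched = 0
    for proto in protospacers:
        name = seq_to_name.get(proto) if proto is not None else None
        if name is None:
            unmatched += 1
        else:
            tally[name] += 1
    return pd.Series(tally, name="count"), unmatched


def read_fastq(path: str | Path) -> Iterator[str]:
    """Yield read sequences from a plain or gzipped FASTQ file."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for _title, seq, _qual in FastqGeneralIterator(fh):
            yield seq.upper()


def count_fastq(
    sample_fastqs: Mapping[str, str | Path],
    library: Sequence[LibraryEntry],
    layout: AmpliconLayout | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Count one FASTQ per (already demultiplexed) sample.

    Returns the count matrix and a per-sample QC frame with total,
    anchor-assigned, matched and unmatched read numbers and the skew
    ratio of the matched counts.
    """
    layout = layout or AmpliconLayout()
    columns: dict[str, pd.Series] = {}
    qc_rows = []
    for sample, path in sample_fastqs.items():
        total = assigned = 0

        def extracted() -> Iterator[str | None]:
            nonlocal total, assigned
            for read in read_fastq(path):
                total += 1
                proto = extract_protospacer(read, layout)
                if proto is not None:
                    assigned += 1
                yield proto

        counts, unmatched = count_exact(extracted(), library)
        columns[sample] = counts
        qc_rows.append({"sample": sample, "total_reads": total, "assigned": assigned,
                        "matched": int(counts.sum()), "unmatched": unmatched,
                        "skew_ratio": skew_ratio(counts) if (counts > 0).sum() >= 10
                        else np.nan})
    return CountMatrix(pd.DataFrame(columns)), pd.DataFrame(qc_rows).set_index("sample")


def sample_qc(counts: pd.Series) -> dict[str, float]:
    return {"total": float(counts.sum()), "detected": float((counts > 0).sum()),
            "skew_ratio": skew_ratio(counts)}


def skew_ratio(counts: pd.Series | np.ndarray) -> float:
    """90th / 10th percentile of construct counts (linear interpolation).

    A uniformity QC metric: 1.0 for a perfectly even library, larger for
    skewed representation.  Infinite (with a warning) when the 10th
    percentile is zero.
    """
    values = np.asarray(counts, dtype=float)
    if (values > 0).sum() < 10:
        raise ValueError("skew ratio needs at least 10 entries with positive counts")
    p10, p90 = np.percentile(values, [10, 90])
    if p10 == 0:
        warnings.warn("10th percentile is zero; skew ratio is infinite")
        return math.inf
    return float(p90 / p10)


def fold_coverage(n_cells: float, transduction_fraction: float, library_size: int) -> float:
    """Screen coverage: transduced cells per library construct."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return n_cells * transduction_fraction / library_size


def single_infection_fraction(transduced_fraction: float) -> float:
    """P(single integration | transduced) under a Poisson MOI model.

    With transduced fraction ``f``, the Poisson rate is ``lambda =
    -ln(1 - f)`` and the returned probability is ``lambda * exp(-lambda) /
    f``, which approaches 1 as ``f -> 0``.
    """
    f = transduced_fraction
    if not 0.0 < f < 1.0:
        raise ValueError("transduced fraction must lie strictly between 0 and 1")
    lam = -math.log1p(-f)
    return lam * math.exp(-lam) / f
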