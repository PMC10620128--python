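"""Flanking-sequence grammar of E-boxes.

E-boxes are (quasi)palindromic and can be read on either strand, so the
base at flank position +k on one reading is the complement of the base
at -k on the other.  Flank counts therefore pool both orientation
readings of every E-box, which makes the profile strand-symmetric by
construction: ``count(+k, b) == count(-k, complement(b))`` exactly on
N-free input.  Essential-vs-background composition differences are
scored per position with chi-squared goodness-of-fit tests, treating the
(much larger) background profile as fixed expected proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .design import EBox
from .intervals import Genome, GenomicInterval, reverse_complement

__all__ = ["FlankProfile", "GofResult", "pooled_flank_counts", "flank_gof_test",
           "logo_matrix", "significance_stars"]

_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class GofResult:
    position: int
    nucleotide: str  # base or "all"
    chi2: float
    df: int
    p: float
    low_expected: bool = False


class FlankProfile:
    """Position x nucleotide counts around a set of E-boxes.

    Positions run -K..-1, +1..+K relative to the hexamer (0 is never
    used).  With both orientation readings pooled and no N bases, every
    position's counts sum to ``2 * n_eboxes``.
    """

    def __init__(self, counts: pd.DataFrame, n_eboxes: int):
        if list(counts.columns) != list(_BASES):
            raise ValueError("profile columns must be A, C, G, T")
        if (counts.to_numpy() < 0).any():
            raise ValueError("profile counts must be non-negative")
        self.counts = counts
        self.n_eboxes = n_eboxes

    @property
    def K(self) -> int:
        return int(max(self.counts.index))

    @property
    def positions(self) -> list[int]:
        return list(self.counts.index)

    def is_symmetric(self) -> bool:
        for k in range(1, self.K + 1):
            for b in _BASES:
                if self.counts.at[k, b] != self.counts.at[-k, _COMP[b]]:
                    return False
        return True

    def proportions(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0)

    def to_tsv(self, path: str | Path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="position")

    @classmethod
    def from_tsv(cls, path: str | Path, n_eboxes: int) -> "FlankProfile":
        return cls(pd.read_csv(path, sep="\t", index_col=0), n_eboxes)


def _positions(K: int) -> list[int]:
    return list(range(-K, 0)) + list(range(1, K + 1))


def pooled_flank_counts(eboxes: Sequence[EBox], genome: Genome, K: int = 10) -> FlankProfile:
    """Tally flank bases over both orientation readings of every E-box.

    E-boxes with fewer than K bases of context on either side are dropped
    (with a warning); N bases are excluded from the tallies, so column
    sums can fall below ``2 * n_eboxes`` only on N-containing input.
    """
    if K <= 0:
        raise ValueError("flank width K must be positive")
    pos = _positions(K)
    windows: list[str] = []
    n_dropped = 0
    for eb in eboxes:
        start = eb.interval.start - K
        end = eb.interval.end + K
        if start < 0 or end > genome.chrom_length(eb.interval.chrom):
            n_dropped += 1
            continue
        window = genome.fetch(GenomicInterval(eb.interval.chrom, start, end))
        windows.append(window)
        windows.append(reverse_complement(window))
    n_used = len(windows) // 2
    counts = pd.DataFrame(0, index=pos, columns=list(_BASES))
    if windows:
        table = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
        mat = np.frombuffer("".join(windows).encode().translate(table),
                            dtype=np.uint8).reshape(len(windows), 2 * K + 6)
        for i, k in enumerate(pos):
            col = mat[:, i] if k < 0 else mat[:, i + 6]
            tallies = np.bincount(col, minlength=5)[:4]  # N (code 4) excluded
            counts.loc[k] += tallies
    if n_dropped:
        import warnings

        warnings.warn(f"dropped {n_dropped} E-boxes with < {K} bases of context")
    return FlankProfile(counts, n_used)


def flank_gof_test(essential: FlankProfile, background: FlankProfile) -> list[GofResult]:
    """Per-position chi-squared goodness-of-fit of essential vs background.

    For each position +1..+K (the negative side is the mirror image under
    the pooled-orientation symmetry): a 4-category test of the essential
    counts against expected proportions from the background (df = 3), and
    a 1-vs-rest 2-category test per nucleotide (df = 1).  Expected cells
    below 5 are flagged; zero-probability background categories observed
    in the essential profile get a continuity guard and a flag.
    """
    if essential.K != background.K:
        raise ValueError("profiles must share the flank width K")
    results: list[GofResult] = []
    for k in range(1, essential.K + 1):
        obs = essential.counts.loc[k].to_numpy(dtype=float)
        bg = background.counts.loc[k].to_numpy(dtype=float)
        n = obs.sum()
        if n == 0 or bg.sum() == 0:
            continue
        probs = bg / bg.sum()
        guarded = False
        if np.any((probs == 0) & (obs > 0)):
            probs = (bg + 0.5) / (bg + 0.5).sum()
            guarded = True
        exp = n * probs
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
        stat = float(terms.sum())
        results.append(GofResult(k, "all", stat, 3, float(chi2_dist.sf(stat, 3)),
                                 low_expected=bool((exp < 5).any() or guarded)))
        for b_idx, base in enumerate(_BASES):
            p1 = probs[b_idx]
            o = np.array([obs[b_idx], n - obs[b_idx]])
            e = np.array([n * p1, n * (1 - p1)])
            if (e == 0).any():
                e = np.maximum(e, 0.5)
                guarded_b = True
            else:
                guarded_b = False
            stat_b = float((((o - e) ** 2) / e).sum())
            results.append(GofResult(k, base, stat_b, 1, float(chi2_dist.sf(stat_b, 1)),
                                     low_expected=bool((e < 5).any() or guarded_b)))
    return results


def significance_stars(p: float) -> str:
    """Star annotation used in flank-bias plots."""
    for thr, stars in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thr:
            return stars
    return ""


def logo_matrix(profile: FlankProfile) -> pd.DataFrame:
    """Row-normalised position frequencies for sequence-logo rendering."""
    if profile.counts.to_numpy().sum() == 0:
        raise ValueError("cannot normalise an empty profile")
    return profile.proportions()


def gof_results_to_frame(results: Sequence[GofResult]) -> pd.DataFrame:
    from statsmodels.stats.multitest import multipletests

    df = pd.DataFrame([r.__dict__ for r in results])
    if not df.empty:
        df["padj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["stars"] = df["p"].map(significance_stars)
    return df
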