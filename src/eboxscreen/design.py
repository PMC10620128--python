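"""E-box sgRNA library design.

The design pipeline locates E-box hexamers inside transcription-factor
binding sites, drops motifs overlapping coding exons, enumerates every
SpCas9 guide whose blunt-cut bond falls strictly inside a motif, filters
guides by a mismatch-based off-target retention rule, scores specificity,
and assembles synthesis-ready 104-nt oligos.

Conventions
-----------
* Protospacer positions are numbered 1-20 from the 5' (PAM-distal) end;
  the seed region is positions 9-20 (the 12 PAM-proximal nucleotides).
* Cas9 cuts bluntly 3 nt 5' of the PAM, i.e. between protospacer
  positions 17 and 18.  A guide "targets" an E-box when that cut bond is
  one of the hexamer's five internal phosphodiester bonds.
* A cut bond is stored as a between-base genomic index: bond ``b`` sits
  between plus-strand positions ``b - 1`` and ``b``.
* Off-target PAM space is NGG only (configurable via ``pam_pattern`` is a
  non-goal here; NAG sites are not searched).

The per-mismatch activity table used by :func:`cfd_specificity` is a
synthetic stand-in bundled as ``data/synthetic_cfd_matrix.tsv``: it has
the qualitative structure of published cutting-frequency-determination
measurements (PAM-proximal mismatches penalised most, wobble-like
pairings tolerated best) but the numbers are constructed, not measured.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import (
    BindingSite,
    Genome,
    GenomicInterval,
    merge_intervals,
    overlaps,
    reverse_complement,
)

__all__ = [
    "DEFAULT_MOTIFS",
    "LEFT_FLANK",
    "RIGHT_FLANK",
    "SEED_REGION",
    "MotifSet",
    "EBox",
    "GuideRNA",
    "OffTargetSite",
    "LibraryEntry",
    "scan_eboxes",
    "flag_exonic",
    "enumerate_guides",
    "find_offtarget_sites",
    "passes_offtarget_rule",
    "load_cfd_matrix",
    "cfd_specificity",
    "assemble_library",
    "design_summary",
    "write_library_tsv",
]

#: Canonical E-box plus the two most common non-canonical variants, each
#: with its reverse complement so plus-strand scanning covers both strands.
DEFAULT_MOTIFS = ("CACGTG", "CACATG", "CATGTG", "CACGCG", "CGCGTG")

#: Constant oligo arms from the lentiCRISPRv2 cloning design (41 + 43 nt);
#: the left arm ends in the vector anchor GAAACACCG that amplicon reads share.
LEFT_FLANK = "TTTCTTGGCTTTATATATCTTGTGGAAAGGACGAAACACCG"
RIGHT_FLANK = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGT"

SEED_REGION = range(9, 21)  # protospacer positions 9..20, PAM-proximal

_CUT_OFFSET = 17  # blunt cut between protospacer nt 17 and 18


@dataclass(frozen=True)
class MotifSet:
    """An ordered, reverse-complement-closed set of 6-mers."""

    hexamers: tuple[str, ...] = DEFAULT_MOTIFS

    def __post_init__(self) -> None:
        seen = set(self.hexamers)
        for h in self.hexamers:
            if len(h) != 6:
                raise ValueError(f"motif {h!r} is not a hexamer")
            if reverse_complement(h) not in seen:
                raise ValueError(
                    f"motif set is not closed under reverse complement: {h} lacks "
                    f"{reverse_complement(h)}"
                )

    def __contains__(self, hexamer: str) -> bool:
        return hexamer in self.hexamers

    def __iter__(self):
        return iter(self.hexamers)


@dataclass(frozen=True)
class EBox:
    """A 6-bp motif occurrence inside a binding site.

    ``hexamer`` is always the plus-strand reading; the id is rendered as
    ``{binding_site.id}_{hexamer}``.
    """

    interval: GenomicInterval
    hexamer: str
    binding_site: BindingSite
    exonic: bool = False

    def __post_init__(self) -> None:
        if len(self.interval) != 6:
            raise ValueError("an E-box interval must span exactly 6 bases")
        if len(self.hexamer) != 6:
            raise ValueError("E-box hexamer must have length 6")

    @property
    def id(self) -> str:
        return f"{self.binding_site.id}_{self.hexamer}"

    def internal_bonds(self) -> range:
        """The five between-base bond indices strictly inside the hexamer."""
        return range(self.interval.start + 1, self.interval.end)


@dataclass(frozen=True)
class GuideRNA:
    protospacer: str
    pam: str
    strand: str
    protospacer_interval: GenomicInterval
    cut_bond: int
    targets: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if len(self.protospacer) != 20:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != 3 or not self.pam.endswith("GG"):
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if self.strand not in ("+", "-"):
            raise ValueError("guide strand must be + or -")

    def cut_annotation(self, ebox: EBox) -> str:
        """Render the cut position inside an E-box, e.g. ``CACAT*G``."""
        k = self.cut_bond - ebox.interval.start
        if not 1 <= k <= 5:
            raise ValueError("cut bond is not inside this E-box")
        return ebox.hexamer[:k] + "*" + ebox.hexamer[k:]


@dataclass(frozen=True)
class OffTargetSite:
    locus: GenomicInterval
    strand: str
    pam: str
    n_mismatches: int
    mismatch_positions: frozenset[int]

    def __post_init__(self) -> None:
        if len(self.mismatch_positions) != self.n_mismatches:
            raise ValueError("mismatch_positions must have n_mismatches members")
        if any(not 1 <= p <= 20 for p in self.mismatch_positions):
            raise ValueError("mismatch positions are 1-20 protospacer coordinates")


@dataclass(frozen=True)
class LibraryEntry:
    name: str
    protospacer: str
    category: str  # targeting | non_targeting | positive_control
    targets: tuple[str, ...] = ()
    guide: GuideRNA | None = None
    cfd: float | None = None
    n_offtargets_le2mm: int | None = None

    @property
    def oligo(self) -> str:
        return LEFT_FLANK + self.protospacer + RIGHT_FLANK


def scan_eboxes(
    genome: Genome,
    sites: Sequence[BindingSite],
    motifs: MotifSet | None = None,
) -> list[EBox]:
    """Report every plus-strand motif occurrence inside the binding sites.

    Because the motif set is reverse-complement-closed, plus-strand
    scanning sees occurrences on either strand exactly once, labelled by
    the plus-strand hexamer.  Windows containing N are skipped.  Output is
    sorted by (chrom, start).
    """
    motifs = motifs or MotifSet()
    out: list[EBox] = []
    for site in sites:
        seq = genome.fetch(site.interval)
        for off in range(len(seq) - 5):
            hexamer = seq[off : off + 6]
            if "N" in hexamer or hexamer not in motifs:
                continue
            iv = GenomicInterval(site.interval.chrom, site.interval.start + off,
                                 site.interval.start + off + 6)
            out.append(EBox(iv, hexamer, site))
    out.sort(key=lambda e: (e.interval.chrom, e.interval.start))
    return out


def flag_exonic(eboxes: Sequence[EBox], coding_exons: Sequence[GenomicInterval]) -> list[EBox]:
    """Mark E-boxes overlapping >= 1 coding-exon base (half-open semantics).

    Exonic E-boxes stay in the list (they are reported) but downstream
    guide design skips them.
    """
    exons = merge_intervals(coding_exons)
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for ex in exons:
        by_chrom.setdefault(ex.chrom, []).append(ex)
    flagged = []
    for eb in eboxes:
        hit = any(overlaps(eb.interval, ex) for ex in by_chrom.get(eb.interval.chrom, ()))
        flagged.append(replace(eb, exonic=hit))
    return flagged


def enumerate_guides(genome: Genome, ebox: EBox) -> list[GuideRNA]:
    """All NGG guides (either strand) whose cut bond falls inside the E-box.

    Five candidate bonds exist per strand.  Guides running past a contig
    edge, or containing N, are silently dropped; an E-box too close to the
    edge simply yields an empty list.
    """
    chrom = ebox.interval.chrom
    seq = genome[chrom]
    L = len(seq)
    guides: list[GuideRNA] = []
    seen: set[tuple[str, int, str]] = set()
    for bond in ebox.internal_bonds():
        # plus strand: protospacer [p, p+20), PAM [p+20, p+23); cut at p+17
        p = bond - _CUT_OFFSET
        if p >= 0 and p + 23 <= L and seq[p + 21 : p + 23] == "GG":
            proto, pam = seq[p : p + 20], seq[p + 20 : p + 23]
            if "N" not in proto + pam and (proto, p, "+") not in seen:
                seen.add((proto, p, "+"))
                guides.append(GuideRNA(proto, pam, "+",
                                       GenomicInterval(chrom, p, p + 20, "+"),
                                       bond, frozenset({ebox.id})))
        # minus strand: protospacer [q, q+20) read 3'->5' on plus; PAM is
        # CCN at [q-3, q) on the plus strand; cut bond at q+3
        q = bond - 3
        if q - 3 >= 0 and q + 20 <= L and seq[q - 3 : q - 1] == "CC":
            window, pam_plus = seq[q : q + 20], seq[q - 3 : q]
            if "N" not in window + pam_plus:
                proto = reverse_complement(window)
                if (proto, q, "-") not in seen:
                    seen.add((proto, q, "-"))
                    guides.append(GuideRNA(proto, reverse_complement(pam_plus), "-",
                                           GenomicInterval(chrom, q, q + 20, "-"),
                                           bond, frozenset({ebox.id})))
    guides.sort(key=lambda g: (g.protospacer_interval.start, g.strand))
    return guides


_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
                         dtype=np.uint8)


def find_offtarget_sites(
    guide: GuideRNA,
    genome: Genome,
    max_mismatches: int = 3,
) -> list[OffTargetSite]:
    """Exhaustive genome scan for NGG-adjacent near-matches of the guide.

    Every locus on either strand whose protospacer-aligned 20-mer is within
    ``max_mismatches`` Hamming distance is returned, including the
    on-target 0-mismatch hit.  Mismatch positions use 1-20 protospacer
    coordinates (1 = PAM-distal).  N bases never match.
    """
    if max_mismatches < 2:
        raise ValueError("the retention rule needs all sites with <= 2 mismatches")
    g_plus = _encode(guide.protospacer)
    g_minus = _encode(reverse_complement(guide.protospacer))
    sites: list[OffTargetSite] = []
    for chrom, seq in genome.sequences.items():
        codes = _encode(seq)
        if codes.size < 23:
            continue
        win = np.lib.stride_tricks.sliding_window_view(codes, 20)
        # plus strand: PAM GG at [p+21, p+23)
        pam_ok = np.zeros(win.shape[0], dtype=bool)
        gg = (codes[:-1] == 2) & (codes[1:] == 2)
        pam_ok[: codes.size - 22] = gg[21 : codes.size - 1]
        for g_codes, strand in ((g_plus, "+"), (g_minus, "-")):
            if strand == "+":
                cand = np.flatnonzero(pam_ok)
            else:
                cc = (codes[:-1] == 1) & (codes[1:] == 1)
                ok = np.zeros(win.shape[0], dtype=bool)
                ok[3 : codes.size - 19] = cc[0 : codes.size - 22]
                cand = np.flatnonzero(ok)
            if cand.size == 0:
                continue
            mm = (win[cand] != g_codes) | (win[cand] == 4)
            nmm = mm.sum(axis=1)
            for idx in np.flatnonzero(nmm <= max_mismatches):
                p = int(cand[idx])
                row = mm[idx]
                if strand == "+":
                    positions = frozenset(int(j) + 1 for j in np.flatnonzero(row))
                    pam = seq[p + 20 : p + 23]
                else:
                    # window index j corresponds to protospacer position 20 - j
                    positions = frozenset(20 - int(j) for j in np.flatnonzero(row))
                    pam = reverse_complement(seq[p - 3 : p])
                sites.append(OffTargetSite(GenomicInterval(chrom, p, p + 20, strand),
                                           strand, pam, int(nmm[idx]), positions))
    sites.sort(key=lambda s: (s.locus.chrom, s.locus.start, s.strand))
    return sites


def passes_offtarget_rule(
    sites: Iterable[OffTargetSite],
    on_target_loci: set[tuple[str, int, str]],
) -> bool:
    """Mismatch-count retention rule for a guide's off-target site list.

    A guide is retained iff every site that is not an intended on-target
    has at least three mismatches, or at least two mismatches of which at
    least one lies in the seed region (protospacer nt 9-20).  Perfect or
    single-mismatch off-targets, and double mismatches confined to the
    PAM-distal nt 1-8, reject the guide.
    """
    for site in sites:
        key = (site.locus.chrom, site.locus.start, site.strand)
        if key in on_target_loci:
            continue
        if site.n_mismatches >= 3:
            continue
        if site.n_mismatches >= 2 and any(p in SEED_REGION for p in site.mismatch_positions):
            continue
        return False
    return True


def load_cfd_matrix() -> dict[tuple[int, str, str], float]:
    """Load the bundled synthetic per-position mismatch-activity table.

    Keys are ``(position, rna_base, dna_base)`` with position 1-20
    (PAM-distal = 1), the guide base given as RNA (U for T) and the
    off-target base as DNA on the protospacer-aligned strand.
    """
    table: dict[tuple[int, str, str], float] = {}
    text = resources.files("eboxscreen.data").joinpath("synthetic_cfd_matrix.tsv").read_text()
    for line in text.splitlines()[1:]:
        pos, rna, dna, act = line.split("\t")
        table[(int(pos), rna, dna)] = float(act)
    return table


def site_cfd(
    guide: GuideRNA,
    site: OffTargetSite,
    genome: Genome,
    matrix: Mapping[tuple[int, str, str], float],
) -> float:
    """Per-site cutting likelihood: product of per-mismatch activities."""
    if site.n_mismatches == 0:
        return 1.0
    window = genome.fetch(GenomicInterval(site.locus.chrom, site.locus.start, site.locus.end))
    if site.strand == "-":
        window = reverse_complement(window)
    score = 1.0
    for pos in sorted(site.mismatch_positions):
        rna = guide.protospacer[pos - 1].replace("T", "U")
        dna = window[pos - 1]
        try:
            score *= matrix[(pos, rna, dna)]
        except KeyError as exc:
            raise KeyError(f"activity matrix has no entry for position {pos}, "
                           f"r{rna}:d{dna}") from exc
    return score


def cfd_specificity(
    guide: GuideRNA,
    offtargets: Sequence[OffTargetSite],
    genome: Genome,
    matrix: Mapping[tuple[int, str, str], float] | None = None,
) -> float:
    """Aggregate specificity on a 0-100 scale: ``100 / (1 + sum site CFD)``.

    ``offtargets`` should exclude intended on-target loci; a guide with no
    off-target sites scores 100, and the score is non-increasing as sites
    are added.
    """
    matrix = matrix if matrix is not None else load_cfd_matrix()
    total = sum(site_cfd(guide, s, genome, matrix) for s in offtargets)
    return 100.0 / (1.0 + total)


def _dedupe_guides(guides: Sequence[GuideRNA]) -> list[GuideRNA]:
    by_seq: dict[str, GuideRNA] = {}
    for g in guides:
        if g.protospacer in by_seq:
            prev = by_seq[g.protospacer]
            by_seq[g.protospacer] = replace(prev, targets=prev.targets | g.targets)
        else:
            by_seq[g.protospacer] = g
    return list(by_seq.values())


def assemble_library(
    guides: Sequence[GuideRNA],
    non_targeting: Sequence[str] = (),
    positive_controls: Sequence[tuple[str, str]] = (),
    cfd_scores: Mapping[str, float] | None = None,
    offtarget_counts: Mapping[str, int] | None = None,
) -> list[LibraryEntry]:
    """Build the final oligo manifest: targeting guides plus controls.

    Guides are deduplicated library-wide by protospacer sequence (a guide
    hitting several E-boxes appears once, carrying all target ids).
    Targeting names are ``{ebox_id}_sg{i}`` with ``i`` assigned in genomic
    order within each E-box; control names are ``NT_{i}`` and the given
    positive-control names.  A sequence shared across categories is an
    error.
    """
    unique = _dedupe_guides(guides)
    unique.sort(key=lambda g: (g.protospacer_interval.chrom,
                               g.protospacer_interval.start, g.strand))
    per_ebox_counter: dict[str, int] = {}
    entries: list[LibraryEntry] = []
    targeting_seqs = set()
    for g in unique:
        primary = sorted(g.targets)[0]
        per_ebox_counter[primary] = per_ebox_counter.get(primary, 0) + 1
        name = f"{primary}_sg{per_ebox_counter[primary]}"
        entries.append(LibraryEntry(
            name, g.protospacer, "targeting", tuple(sorted(g.targets)), g,
            cfd=None if cfd_scores is None else cfd_scores.get(g.protospacer),
            n_offtargets_le2mm=None if offtarget_counts is None
            else offtarget_counts.get(g.protospacer)))
        targeting_seqs.add(g.protospacer)
    control_seqs = set()
    for i, seq in enumerate(non_targeting, 1):
        _check_control(seq, targeting_seqs, control_seqs)
        entries.append(LibraryEntry(f"NT_{i}", seq, "non_targeting"))
    for name, seq in positive_controls:
        _check_control(seq, targeting_seqs, control_seqs)
        entries.append(LibraryEntry(name, seq, "positive_control"))
    return entries


def _check_control(seq: str, targeting: set[str], controls: set[str]) -> None:
    if len(seq) != 20:
        raise ValueError(f"control protospacer {seq!r} is not 20 nt")
    if seq in targeting or seq in controls:
        raise ValueError(f"protospacer {seq} duplicated across library categories")
    controls.add(seq)


def design_summary(
    n_binding_sites: int,
    eboxes: Sequence[EBox],
    n_candidate_guides: int,
    entries: Sequence[LibraryEntry],
) -> dict[str, int]:
    """Counts at each design stage, mirroring a library-design report."""
    targeting = [e for e in entries if e.category == "targeting"]
    targeted = set()
    for e in targeting:
        targeted.update(e.targets)
    return {
        "binding_sites": n_binding_sites,
        "eboxes_found": len(eboxes),
        "eboxes_exonic_excluded": sum(e.exonic for e in eboxes),
        "candidate_guides": n_candidate_guides,
        "retained_guides": len(targeting),
        "targeted_eboxes": len(targeted),
        "non_targeting_controls": sum(e.category == "non_targeting" for e in entries),
        "positive_controls": sum(e.category == "positive_control" for e in entries),
        "library_size": len(entries),
    }


def read_library_tsv(path) -> list[LibraryEntry]:
    """Read a library manifest written by :func:`write_library_tsv`.

    Guide geometry columns are not reconstructed into GuideRNA objects;
    names, protospacers, categories and target ids are, which is all that
    counting and target aggregation need.
    """
    entries: list[LibraryEntry] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {c: i for i, c in enumerate(header)}
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            targets = tuple(t for t in parts[col["ebox_id"]].split(",") if t)
            cfd = parts[col["cfd_specificity"]]
            noff = parts[col["n_offtargets_le2mm"]]
            entries.append(LibraryEntry(
                parts[col["name"]], parts[col["protospacer"]], parts[col["category"]],
                targets, None, float(cfd) if cfd else None, int(noff) if noff else None))
    return entries


def write_library_tsv(path, entries: Sequence[LibraryEntry],
                      eboxes: Mapping[str, EBox] | None = None) -> None:
    cols = ["name", "ebox_id", "chrom", "ebox_start", "ebox_end", "hexamer",
            "protospacer", "pam", "strand", "cut_bond", "n_offtargets_le2mm",
            "cfd_specificity", "category", "oligo"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for e in entries:
            ebox_id = chrom = estart = eend = hexamer = pam = strand = cut = ""
            if e.guide is not None:
                ebox_id = ",".join(e.targets)
                iv = e.guide.protospacer_interval
                chrom, pam, strand = iv.chrom, e.guide.pam, e.guide.strand
                cut = str(e.guide.cut_bond)
                if eboxes and e.targets and e.targets[0] in eboxes:
                    eb = eboxes[e.targets[0]]
                    estart, eend = str(eb.interval.start), str(eb.interval.end)
                    hexamer = eb.hexamer
            fh.write("\t".join([
                e.name, ebox_id, chrom, estart, eend, hexamer, e.protospacer,
                pam, strand, cut,
                "" if e.n_offtargets_le2mm is None else str(e.n_offtargets_le2mm),
                "" if e.cfd is None else f"{e.cfd:.2f}", e.category, e.oligo]) + "\n")
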