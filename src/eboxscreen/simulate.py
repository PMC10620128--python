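"""Synthetic data generators for the design and screen-analysis pipeline.

Three generators make the whole package testable without downloads:

* :func:`make_genome` builds a small multi-chromosome genome with planted
  E-box hexamers (some inside planted "coding exons"), near-duplicate
  off-target decoy loci with chosen mismatch positions, and a truth
  manifest.
* :func:`simulate_screen_counts` draws T0/T1 replicate count matrices
  from the same negative-binomial model the depletion test assumes
  (variance mu + alpha * mu^2), with log-normal guide abundances and
  spiked true fold changes.
* :func:`simulate_fastq` turns a count column into amplicon reads
  (stagger + barcode + anchor + protospacer) with an optional per-base
  error rate.

All generators take an explicit seed and are bit-reproducible; there is
no hidden global RNG state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .counting import AmpliconLayout, CountMatrix
from .design import EBox, GuideRNA, LibraryEntry, MotifSet, enumerate_guides, flag_exonic, scan_eboxes
from .intervals import (
    BindingSite,
    Genome,
    GenomicInterval,
    assign_binding_sites,
    merge_intervals,
    reverse_complement,
)

__all__ = [
    "GenomeFixtureSpec",
    "ScreenSimSpec",
    "GenomeFixture",
    "make_genome",
    "simulate_screen_counts",
    "simulate_fastq",
    "make_flank_eboxes",
    "random_protospacers",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class GenomeFixtureSpec:
    """Recipe for a planted-feature toy genome.

    ``n_eboxes_per_motif`` E-boxes are planted for every motif in the
    default set; ``fraction_exonic`` of all planted E-boxes get an
    overlapping coding exon; ``n_offtarget_decoys`` near-duplicate copies
    of designed guide loci are planted away from the binding sites,
    cycling through ``decoy_mismatch_patterns`` (protospacer coordinates,
    () = perfect copy).
    """

    seed: int
    n_chromosomes: int = 2
    chrom_length: int = 50_000
    n_eboxes_per_motif: int = 6
    fraction_exonic: float = 0.1
    n_offtarget_decoys: int = 0
    decoy_mismatch_patterns: tuple[tuple[int, ...], ...] = (
        (), (5,), (3, 7), (3, 15), (2, 9, 17))
    gc_content: float = 0.41
    site_flank: int = 30

    def __post_init__(self) -> None:
        if self.n_chromosomes < 1 or self.chrom_length < 200:
            raise ValueError("need >= 1 chromosome of >= 200 bp")
        if not 0 <= self.fraction_exonic <= 1:
            raise ValueError("fraction_exonic must lie in [0, 1]")
        if min(self.n_eboxes_per_motif, self.n_offtarget_decoys) < 0:
            raise ValueError("feature counts must be non-negative")


@dataclass
class GenomeFixture:
    """A toy genome plus its truth manifest."""

    genome: Genome
    sites: list[BindingSite]
    eboxes: list[EBox]
    exons: list[GenomicInterval]
    decoys: pd.DataFrame  # protospacer, chrom, start, strand, mismatch_positions

    def write(self, outdir: str | Path) -> None:
        from .intervals import write_bed

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.genome.to_fasta(outdir / "genome.fa")
        write_bed(outdir / "eboxes.bed", [e.interval for e in self.eboxes],
                  [e.id for e in self.eboxes])
        if self.exons:
            write_bed(outdir / "exons.bed", self.exons)
        self.decoys.to_csv(outdir / "decoys.tsv", sep="\t", index=False)


def _random_dna(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.arange(4), size=n, p=p)


def _scrub_accidental_motifs(chars: list[str], lo: int, hi: int,
                             planted: set[int], motifs: MotifSet,
                             rng: np.random.Generator) -> None:
    """Mutate accidental motif hits in [lo, hi) that are not planted E-boxes.

    ``planted`` holds the start coordinates of intended E-boxes on this
    chromosome; bases inside them are never touched.
    """
    protected = set()
    for s in planted:
        protected.update(range(s, s + 6))
    for _ in range(10):  # a mutation can create a new hit; iterate to fixpoint
        dirty = False
        for off in range(max(lo, 0), hi - 5):
            hexamer = "".join(chars[off : off + 6])
            if hexamer in motifs and off not in planted:
                editable = [j for j in range(off, off + 6) if j not in protected]
                if not editable:
                    continue
                j = editable[len(editable) // 2]
                current = chars[j]
                chars[j] = rng.permuted([b for b in "ACGT" if b != current])[0]
                dirty = True
        if not dirty:
            return


def make_genome(spec: GenomeFixtureSpec) -> GenomeFixture:
    """Build a toy genome with planted E-boxes, exons and off-target decoys.

    Every planted E-box is recoverable by :func:`scan_eboxes` over the
    returned binding sites (accidental motif hits inside site windows are
    scrubbed); decoys are exact guide-locus copies mutated at the
    specified protospacer positions, planted outside the sites.
    """
    rng = np.random.default_rng(spec.seed)
    motifs = MotifSet()
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    chars: dict[str, list[str]] = {
        c: list(_BASES[_random_dna(rng, spec.chrom_length, spec.gc_content)])
        for c in chroms
    }

    # choose non-overlapping plant slots, round-robin over chromosomes
    n_plant = spec.n_eboxes_per_motif * len(motifs.hexamers)
    margin = spec.site_flank + 40
    slot_gap = 2 * spec.site_flank + 80  # keep site windows from merging
    usable = spec.chrom_length - 2 * margin
    per_chrom = -(-n_plant // spec.n_chromosomes)
    if per_chrom * slot_gap > usable:
        raise ValueError("overcrowded fixture spec: features do not fit")
    planted: dict[str, list[tuple[int, str]]] = {c: [] for c in chroms}
    hexamer_cycle = itertools.cycle(motifs.hexamers)
    chrom_cycle = itertools.cycle(chroms)
    for _ in range(n_plant):
        chrom = next(chrom_cycle)
        k = len(planted[chrom])
        jitter = int(rng.integers(0, max(slot_gap - 60, 1)))
        start = margin + k * slot_gap + jitter
        hexamer = next(hexamer_cycle)
        chars[chrom][start : start + 6] = list(hexamer)
        planted[chrom].append((start, hexamer))

    site_ivs: list[GenomicInterval] = []
    for chrom in chroms:
        starts = {s for s, _ in planted[chrom]}
        for s, _ in planted[chrom]:
            site_ivs.append(GenomicInterval(chrom, s - spec.site_flank, s + 6 + spec.site_flank))
        for s, _ in planted[chrom]:
            _scrub_accidental_motifs(chars[chrom], s - spec.site_flank - 5,
                                     s + 6 + spec.site_flank + 5, starts, motifs, rng)

    merged = merge_intervals(site_ivs)
    sites = assign_binding_sites(merged)
    genome = Genome({c: "".join(chars[c]) for c in chroms})
    eboxes = scan_eboxes(genome, sites, motifs)
    if len(eboxes) != n_plant:
        raise AssertionError("fixture self-check failed: planted E-box count mismatch")

    # exons overlap a deterministic subset of planted E-boxes
    n_exonic = int(round(spec.fraction_exonic * len(eboxes)))
    exon_idx = sorted(rng.choice(len(eboxes), size=n_exonic, replace=False)) if n_exonic else []
    exons = []
    for i in exon_idx:
        iv = eboxes[i].interval
        exons.append(GenomicInterval(iv.chrom, iv.start + 3, iv.start + 3 + 60))
    eboxes = flag_exonic(eboxes, exons)

    # decoys: copies of real guide loci, mutated at chosen protospacer positions
    decoy_rows = []
    nonexonic = [e for e in eboxes if not e.exonic]
    if spec.n_offtarget_decoys:
        pattern_cycle = itertools.cycle(spec.decoy_mismatch_patterns)
        ebox_cycle = itertools.cycle(nonexonic)
        # decoys go into the free tail beyond the last site window
        tail_start = margin + per_chrom * slot_gap + 60
        per_chrom_decoys = -(-spec.n_offtarget_decoys // spec.n_chromosomes)
        if tail_start + 31 * per_chrom_decoys > spec.chrom_length - 5:
            raise ValueError("overcrowded fixture spec: no room for decoys")
        free_cursor: dict[str, int] = {c: tail_start for c in chroms}
        placed = 0
        attempts = 0
        while placed < spec.n_offtarget_decoys and attempts < 10 * spec.n_offtarget_decoys:
            attempts += 1
            eb = next(ebox_cycle)
            guides = enumerate_guides(genome, eb)
            if not guides:
                continue
            g = guides[placed % len(guides)]
            pattern = next(pattern_cycle)
            iv = g.protospacer_interval
            if g.strand == "+":
                context = genome[iv.chrom][iv.start : iv.end + 3]
            else:
                context = genome[iv.chrom][iv.start - 3 : iv.end]
            ctx = list(context)
            # mutate protospacer positions (1-20, PAM-distal = 1) in context
            for pos in pattern:
                if g.strand == "+":
                    j = pos - 1
                else:
                    j = 3 + (20 - pos)
                current = ctx[j]
                ctx[j] = rng.permuted([b for b in "ACGT" if b != current])[0]
            target_chrom = chroms[placed % len(chroms)]
            start = free_cursor[target_chrom]
            if start + len(ctx) > spec.chrom_length - 5:
                break
            free_cursor[target_chrom] += len(ctx) + 8
            chars_t = list(genome[target_chrom])
            chars_t[start : start + len(ctx)] = ctx
            genome.sequences[target_chrom] = "".join(chars_t)
            proto_start = start if g.strand == "+" else start + 3
            decoy_rows.append({
                "protospacer": g.protospacer, "source_ebox": sorted(g.targets)[0],
                "chrom": target_chrom, "start": proto_start, "strand": g.strand,
                "mismatch_positions": ",".join(map(str, pattern))})
            placed += 1

    decoys = pd.DataFrame(decoy_rows, columns=[
        "protospacer", "source_ebox", "chrom", "start", "strand", "mismatch_positions"])
    return GenomeFixture(genome, sites, eboxes, exons, decoys)


@dataclass(frozen=True)
class ScreenSimSpec:
    """Recipe for a simulated pooled screen.

    Counts follow NB(mean = s_j * q_i * 2^(x_j * beta_i), variance =
    mu + dispersion * mu^2) with x_j = 1 for T1 samples; guide abundances
    q_i are log-normal around ``depth`` reads/guide (the screen-coverage
    scale), and ``n_spiked`` targets carry a true log2 fold change
    ``spike_log2fc``.
    """

    seed: int
    n_targets: int = 2000
    guides_per_target: int = 1
    depth: float = 500.0
    dispersion: float = 0.05
    n_spiked: int = 0
    spike_log2fc: float = -2.0
    n_replicates: int = 2
    abundance_sigma: float = 0.25
    depth_factor_sigma: float = 0.1
    cell_line: str = "SIM"
    library_label: str = "EBOX"

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.dispersion <= 0:
            raise ValueError("depth and dispersion must be positive")
        if self.n_spiked > self.n_targets:
            raise ValueError("cannot spike more targets than exist")


def simulate_screen_counts(
    spec: ScreenSimSpec,
    library: Sequence[LibraryEntry] | None = None,
) -> tuple[CountMatrix, pd.DataFrame, pd.DataFrame]:
    """Draw a T0/T1 replicate count matrix with known spiked effects.

    When ``library`` is given its targeting entries define the guides and
    targets (spec.n_targets/guides_per_target are ignored); otherwise
    synthetic names ``T{i}_sg{j}`` / ``T{i}`` are used.  Returns (counts,
    truth, design): truth has one row per target with its true log2 fold
    change, design maps samples to condition and replicate.
    """
    rng = np.random.default_rng(spec.seed)
    if library is not None:
        guides = [(e.name, e.targets[0] if e.targets else f"_ctrl_{e.category}")
                  for e in library]
    else:
        guides = [(f"T{i}_sg{j}", f"T{i}")
                  for i in range(spec.n_targets)
                  for j in range(1, spec.guides_per_target + 1)]
    guide_names = [g for g, _ in guides]
    targets = sorted({t for _, t in guides})
    spikable = [i for i, t in enumerate(targets) if not t.startswith("_ctrl_")]
    spiked = set(rng.choice(spikable, size=spec.n_spiked, replace=False)) \
        if spec.n_spiked else set()
    beta = {t: (spec.spike_log2fc if i in spiked else 0.0)
            for i, t in enumerate(targets)}

    q = spec.depth * np.exp(rng.normal(0.0, spec.abundance_sigma, size=len(guides)))
    samples, conditions, reps = [], [], []
    for rep in range(1, spec.n_replicates + 1):
        for cond in ("T0", "T1"):
            samples.append(f"{spec.cell_line}_{spec.library_label}_R{rep}_{cond}")
            conditions.append(cond)
            reps.append(rep)
    s = np.exp(rng.normal(0.0, spec.depth_factor_sigma, size=len(samples)))
    x = np.array([1.0 if c == "T1" else 0.0 for c in conditions])

    beta_g = np.array([beta[t] for _, t in guides])
    mu = s[None, :] * q[:, None] * np.power(2.0, x[None, :] * beta_g[:, None])
    shape = 1.0 / spec.dispersion
    lam = rng.gamma(shape, mu / shape)
    counts = rng.poisson(lam)
    cm = CountMatrix(pd.DataFrame(counts, index=guide_names, columns=samples))
    truth = pd.DataFrame({"target": targets,
                          "log2fc": [beta[t] for t in targets]}).set_index("target")
    design = pd.DataFrame({"sample": samples, "condition": conditions,
                           "replicate": reps})
    return cm, truth, design


def simulate_fastq(
    column: pd.Series,
    protospacers: Mapping[str, str],
    layout: AmpliconLayout | None = None,
    seed: int = 0,
    error_rate: float = 0.0,
    barcode: str = "ACGTACGT",
    read_length: int = 76,
    path: str | Path | None = None,
) -> list[str] | Path:
    """Emit one amplicon read per count unit for a sample column.

    Read structure: random 9-18 nt stagger + sample barcode + anchor +
    protospacer + random filler up to ``read_length``; each base is then
    corrupted independently with probability ``error_rate``.  With error
    rate 0 the counts round-trip exactly through anchor extraction and
    exact matching.  Returns FASTQ lines, or the path when one is given.
    """
    layout = layout or AmpliconLayout()
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    read_no = 0
    for name, n in column.items():
        proto = protospacers[name]
        for _ in range(int(n)):
            read_no += 1
            # redraw if a random stagger/filler happens to contain the anchor
            # earlier than the intended copy, which would break extraction
            for _attempt in range(100):
                stagger_len = int(rng.integers(layout.stagger_min, layout.stagger_max + 1))
                stagger = "".join(_BASES[rng.integers(0, 4, size=stagger_len)])
                seq = stagger + barcode + layout.anchor + proto
                if len(seq) < read_length:
                    seq += "".join(_BASES[rng.integers(0, 4, size=read_length - len(seq))])
                if seq.find(layout.anchor) == stagger_len + len(barcode):
                    break
            if error_rate > 0:
                arr = np.array(list(seq))
                hit = rng.random(len(arr)) < error_rate
                for j in np.flatnonzero(hit):
                    arr[j] = rng.permuted([b for b in "ACGT" if b != arr[j]])[0]
                seq = "".join(arr)
            lines += [f"@read{read_no} {name}", seq, "+", "I" * len(seq)]
    if path is not None:
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
        return Path(path)
    return lines


def make_flank_eboxes(
    n_eboxes: int,
    seed: int,
    K: int = 10,
    hexamer: str = "CACGTG",
    base_probs: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    plus_side_probs: Mapping[int, Sequence[float]] | None = None,
) -> tuple[Genome, list[EBox]]:
    """Toy single-chromosome genome of E-boxes with controlled flank bias.

    Flank bases are iid from ``base_probs`` (A, C, G, T order) except at
    positions named in ``plus_side_probs`` (+1..+K), whose distribution is
    also mirrored to the matching negative position with complemented
    bases, so the planted bias respects the palindromic reading symmetry
    the profile construction assumes.
    """
    rng = np.random.default_rng(seed)
    probs = {k: np.asarray(base_probs, dtype=float) for k in range(1, K + 1)}
    if plus_side_probs:
        for k, p in plus_side_probs.items():
            if not 1 <= k <= K:
                raise ValueError("plus_side_probs keys must lie in 1..K")
            probs[k] = np.asarray(p, dtype=float)
    neg = {-k: probs[k][::-1] for k in probs}  # complement = reversed ACGT order

    spacer = 12
    pieces: list[str] = []
    eboxes_pos: list[int] = []
    cursor = 0
    for _ in range(n_eboxes):
        pieces.append("".join(_BASES[rng.integers(0, 4, size=spacer)]))
        cursor += spacer
        left = "".join(rng.choice(_BASES, p=neg[-k] / neg[-k].sum())
                       for k in range(K, 0, -1))
        right = "".join(rng.choice(_BASES, p=probs[k] / probs[k].sum())
                        for k in range(1, K + 1))
        pieces.append(left + hexamer + right)
        eboxes_pos.append(cursor + K)
        cursor += 2 * K + 6
    pieces.append("".join(_BASES[rng.integers(0, 4, size=spacer)]))
    genome = Genome({"chrF": "".join(pieces)})
    sites = assign_binding_sites(merge_intervals(
        [GenomicInterval("chrF", max(p - K, 0), p + 6 + K) for p in eboxes_pos]))
    site_lookup = sorted(sites, key=lambda s: s.interval.start)
    eboxes = []
    for p in eboxes_pos:
        site = next(s for s in site_lookup
                    if s.interval.start <= p and p + 6 <= s.interval.end)
        eboxes.append(EBox(GenomicInterval("chrF", p, p + 6), hexamer, site))
    return genome, eboxes


def random_protospacers(n: int, seed: int, exclude: set[str] | None = None) -> list[str]:
    """Random distinct 20-mers (e.g. non-targeting controls)."""
    rng = np.random.default_rng(seed)
    exclude = exclude or set()
    out: list[str] = []
    seen = set(exclude)
    while len(out) < n:
        seq = "".join(_BASES[rng.integers(0, 4, size=20)])
        if seq not in seen:
            seen.add(seq)
            out.append(seq)
    return out
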