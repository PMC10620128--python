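"""End-to-end library design: peaks -> E-boxes -> filtered guide library."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .design import (
    EBox,
    GuideRNA,
    LibraryEntry,
    MotifSet,
    assemble_library,
    design_summary,
    enumerate_guides,
    find_offtarget_sites,
    flag_exonic,
    passes_offtarget_rule,
    scan_eboxes,
)
from .intervals import BindingSite, Genome, GenomicInterval, assign_binding_sites, merge_intervals

__all__ = ["DesignResult", "design_library"]


@dataclass
class DesignResult:
    sites: list[BindingSite]
    eboxes: list[EBox]
    candidate_guides: list[GuideRNA]
    retained_guides: list[GuideRNA]
    entries: list[LibraryEntry]
    summary: dict[str, int]

    @property
    def ebox_index(self) -> dict[str, EBox]:
        return {e.id: e for e in self.eboxes}


def design_library(
    genome: Genome,
    peaks: Sequence[GenomicInterval],
    coding_exons: Sequence[GenomicInterval] = (),
    motifs: MotifSet | None = None,
    non_targeting: Sequence[str] = (),
    positive_controls: Sequence[tuple[str, str]] = (),
    max_mismatches: int = 2,
    peak_sources: Sequence[set] | None = None,
) -> DesignResult:
    """Run the full design pipeline and return every intermediate stage.

    Peaks are merged and labelled with per-chromosome BS ordinals, E-boxes
    scanned and exon-flagged, guides enumerated for every non-exonic
    E-box, and each candidate kept only if its genome-wide off-target
    sites (up to ``max_mismatches`` mismatches) pass the retention rule.
    On-target loci are the perfect-match sites whose cut bond lies inside
    any library E-box.
    """
    motifs = motifs or MotifSet()
    merged = merge_intervals(peaks)
    if peak_sources is not None:
        # union of source labels over the peaks swallowed by each merged region
        src: list[set] = [set() for _ in merged]
        idx = {(iv.chrom, iv.start, iv.end): i for i, iv in enumerate(merged)}
        for peak, labels in zip(peaks, peak_sources):
            for i, m in enumerate(merged):
                if m.chrom == peak.chrom and m.start <= peak.start and peak.end <= m.end:
                    src[i] |= set(labels)
                    break
        sites = assign_binding_sites(merged, src)
    else:
        sites = assign_binding_sites(merged)
    eboxes = flag_exonic(scan_eboxes(genome, sites, motifs), list(coding_exons))

    candidates: list[GuideRNA] = []
    for eb in eboxes:
        if not eb.exonic:
            candidates.extend(enumerate_guides(genome, eb))

    # a perfect-match locus is "intended" iff its cut bond sits inside a
    # designable library E-box
    ebox_bonds: dict[str, set[int]] = {}
    for eb in eboxes:
        if not eb.exonic:
            ebox_bonds.setdefault(eb.interval.chrom, set()).update(eb.internal_bonds())

    retained: list[GuideRNA] = []
    offtarget_counts: dict[str, int] = {}
    for g in candidates:
        sites_found = find_offtarget_sites(g, genome, max_mismatches=max_mismatches)
        on_target = set()
        n_off = 0
        for s in sites_found:
            if s.n_mismatches == 0:
                bond = s.locus.start + 17 if s.strand == "+" else s.locus.start + 3
                if bond in ebox_bonds.get(s.locus.chrom, ()):
                    on_target.add((s.locus.chrom, s.locus.start, s.strand))
                    continue
            n_off += 1
        offtarget_counts[g.protospacer] = n_off
        if passes_offtarget_rule(sites_found, on_target):
            retained.append(g)

    entries = assemble_library(retained, non_targeting, positive_controls,
                               offtarget_counts=offtarget_counts)
    summary = design_summary(len(sites), eboxes, len(candidates), entries)
    return DesignResult(sites, eboxes, candidates, retained, entries, summary)
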