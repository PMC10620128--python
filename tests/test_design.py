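import numpy as np
import pytest

from eboxscreen.design import (
    LEFT_FLANK,
    RIGHT_FLANK,
    EBox,
    GuideRNA,
    MotifSet,
    OffTargetSite,
    assemble_library,
    cfd_specificity,
    enumerate_guides,
    find_offtarget_sites,
    flag_exonic,
    load_cfd_matrix,
    passes_offtarget_rule,
    scan_eboxes,
    site_cfd,
    write_library_tsv,
)
from eboxscreen.intervals import (
    BindingSite,
    Genome,
    GenomicInterval,
    assign_binding_sites,
    merge_intervals,
    reverse_complement,
)
from oracles import base_set, placement_guides, sliding_offtargets

RNG = np.random.default_rng(42)
BASES = np.array(list("ACGT"))


def _random_seq(n, rng=RNG):
    return "".join(BASES[rng.integers(0, 4, size=n)])


def _site(chrom, start, end, ordinal=1):
    return BindingSite(GenomicInterval(chrom, start, end), ordinal)


def _ebox_in(seq, chrom="chrT", offset=None, hexamer=None):
    """Wrap a sequence containing one planted E-box into Genome + EBox."""
    genome = Genome({chrom: seq})
    site = _site(chrom, 0, len(seq))
    if offset is None:
        (eb,) = scan_eboxes(genome, [site])
        return genome, eb
    return genome, EBox(GenomicInterval(chrom, offset, offset + 6), hexamer, site)


class TestScanEboxes:
    def test_single_canonical_occurrence(self):
        genome = Genome({"chr1": "TTCACGTGAA"})
        out = scan_eboxes(genome, [_site("chr1", 0, 10)])
        assert len(out) == 1
        eb = out[0]
        assert eb.hexamer == "CACGTG" and eb.interval.start == 2
        assert eb.id == "chr1_BS1_CACGTG"

    def test_plus_strand_label_without_double_count(self):
        # CATGTG on the plus strand is CACATG on the minus strand: one E-box,
        # labelled by its plus-strand reading, same as a both-strand scan
        # deduplicated by coordinate.
        genome = Genome({"chr1": "AACATGTGAA"})
        out = scan_eboxes(genome, [_site("chr1", 0, 10)])
        assert [(e.hexamer, e.interval.start) for e in out] == [("CATGTG", 2)]
        both_strand_starts = {m.start() for hexamer in MotifSet()
                              for m in _find_all(genome["chr1"], hexamer)}
        assert both_strand_starts == {2}

    def test_revcomp_closure_on_mirrored_genome(self, toy_fixture):
        genome, sites = toy_fixture.genome, toy_fixture.sites
        n_forward = len(scan_eboxes(genome, sites))
        mirrored = Genome({c: reverse_complement(s) for c, s in genome.sequences.items()})
        mirrored_sites = assign_binding_sites(merge_intervals([
            GenomicInterval(s.interval.chrom,
                            genome.chrom_length(s.interval.chrom) - s.interval.end,
                            genome.chrom_length(s.interval.chrom) - s.interval.start)
            for s in sites]))
        assert len(scan_eboxes(mirrored, mirrored_sites)) == n_forward

    def test_window_with_n_skipped(self):
        genome = Genome({"chr1": "TTCACGNGAA"})
        assert scan_eboxes(genome, [_site("chr1", 0, 10)]) == []

    def test_non_closed_motif_set_rejected(self):
        with pytest.raises(ValueError, match="reverse complement"):
            MotifSet(("CACGTG", "CACATG"))


def _find_all(seq, sub):
    import re

    return [m for m in re.finditer(f"(?={sub})", seq)]


class TestFlagExonic:
    def test_one_bp_overlap_is_exonic(self):
        genome = Genome({"c": "A" * 300})
        eb = EBox(GenomicInterval("c", 100, 106), "CACGTG", _site("c", 90, 120))
        (flagged,) = flag_exonic([eb], [GenomicInterval("c", 105, 200)])
        assert flagged.exonic

    def test_bookended_exon_is_not_exonic(self):
        eb = EBox(GenomicInterval("c", 100, 106), "CACGTG", _site("c", 90, 120))
        (flagged,) = flag_exonic([eb], [GenomicInterval("c", 106, 200)])
        assert not flagged.exonic

    def test_agrees_with_base_set_intersection(self):
        rng = np.random.default_rng(7)
        exons = [GenomicInterval("c", int(s), int(s) + int(l))
                 for s, l in zip(rng.integers(0, 900, 30), rng.integers(1, 50, 30))]
        for start in rng.integers(0, 950, 100):
            eb = EBox(GenomicInterval("c", int(start), int(start) + 6), "CACGTG",
                      _site("c", 0, 1000))
            (flagged,) = flag_exonic([eb], exons)
            assert flagged.exonic == bool(base_set([eb.interval]) & base_set(exons))


class TestEnumerateGuides:
    def test_matches_placement_oracle_on_random_contexts(self):
        rng = np.random.default_rng(1)
        checked = 0
        for _ in range(60):
            seq = _random_seq(60, rng)
            off = 27
            seq = seq[:off] + "CACGTG" + seq[off + 6 :]
            genome, eb = _ebox_in(seq, offset=off, hexamer="CACGTG")
            got = {(g.protospacer, g.strand, g.protospacer_interval.start)
                   for g in enumerate_guides(genome, eb)}
            assert got == placement_guides(seq, off, off + 6)
            checked += len(got)
        assert checked > 0  # contexts actually produced guides

    def test_cut_bond_always_inside_motif(self):
        rng = np.random.default_rng(2)
        for _ in range(40):
            seq = _random_seq(60, rng)
            seq = seq[:27] + "CATGTG" + seq[33:]
            genome, eb = _ebox_in(seq, offset=27, hexamer="CATGTG")
            for g in enumerate_guides(genome, eb):
                assert g.cut_bond in eb.internal_bonds()
                # re-validate sequence and PAM against the genome
                iv = g.protospacer_interval
                window = genome.fetch(iv)
                if g.strand == "+":
                    assert window == g.protospacer
                    assert genome["chrT"][iv.end + 1 : iv.end + 3] == "GG"
                else:
                    assert reverse_complement(window) == g.protospacer
                    assert genome["chrT"][iv.start - 3 : iv.start - 1] == "CC"

    def test_no_pam_no_guides(self):
        seq = ("ATATATATATATATATATATATCACGTGATATATATATATATATATATAT"
               "ATATATATAT")
        genome, eb = _ebox_in(seq, offset=22, hexamer="CACGTG")
        assert enumerate_guides(genome, eb) == []

    def test_single_engineered_pam_gives_one_guide(self):
        # A/T background, one E-box, one NGG PAM placed so the cut bond
        # (3 nt 5' of the PAM) lands inside the motif.
        seq = list("AT" * 30)
        seq[27:33] = "CACATG"
        seq[35:37] = "GG"  # PAM = [34, 37): protospacer p = 14, cut bond 31
        seq = "".join(seq)
        genome, eb = _ebox_in(seq, offset=27, hexamer="CACATG")
        guides = enumerate_guides(genome, eb)
        oracle = placement_guides(seq, 27, 33)
        assert {(g.protospacer, g.strand, g.protospacer_interval.start)
                for g in guides} == oracle
        assert len(guides) == 1
        assert guides[0].cut_bond in eb.internal_bonds()

    def test_cut_annotation_before_last_base(self):
        # guide cutting between motif positions 5 and 6 renders CACAT*G
        seq = list(_random_seq(60, np.random.default_rng(3)))
        seq[27:33] = "CACATG"
        seq[36:38] = "GG"  # PAM = [35, 38): protospacer p = 15, cut bond 32 = start+5
        seq = "".join(seq)
        genome, eb = _ebox_in(seq, offset=27, hexamer="CACATG")
        guides = [g for g in enumerate_guides(genome, eb) if g.cut_bond == 32]
        assert guides and guides[0].cut_annotation(eb) == "CACAT*G"

    def test_ebox_at_contig_edge_yields_empty_list(self):
        genome, eb = _ebox_in("CACGTGAAGG", offset=0, hexamer="CACGTG")
        assert enumerate_guides(genome, eb) == []


class TestOffTargetSearch:
    def _plant(self, rng, copies):
        """Random genome with a guide locus and extra (mutated) copies."""
        seq = list(_random_seq(3000, rng))
        proto = _random_seq(20, rng)
        locus = proto + "TGG"
        seq[100:123] = locus
        starts = []
        for i, positions in enumerate(copies):
            mutated = list(locus)
            for pos in positions:
                mutated[pos - 1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[pos - 1]]
            start = 400 + 60 * i
            seq[start : start + 23] = mutated
            starts.append(start)
        genome = Genome({"chrO": "".join(seq)})
        guide = GuideRNA(proto, "TGG", "+", GenomicInterval("chrO", 100, 120, "+"), 117)
        return genome, guide, starts

    def test_self_hit_reported_with_zero_mismatches(self):
        genome, guide, _ = self._plant(np.random.default_rng(10), [])
        sites = find_offtarget_sites(guide, genome, max_mismatches=2)
        self_hits = [s for s in sites if s.locus.start == 100 and s.strand == "+"]
        assert self_hits and self_hits[0].n_mismatches == 0

    def test_planted_single_mismatch_copy(self):
        genome, guide, (start,) = self._plant(np.random.default_rng(11), [(5,)])
        sites = find_offtarget_sites(guide, genome, max_mismatches=2)
        hit = [s for s in sites if s.locus.start == start]
        assert hit and hit[0].mismatch_positions == frozenset({5})

    def test_agreement_with_sliding_window_oracle(self):
        rng = np.random.default_rng(12)
        genome = Genome({"chrA": _random_seq(4000, rng), "chrB": _random_seq(3000, rng)})
        for _ in range(15):
            proto = _random_seq(20, rng)
            guide = GuideRNA(proto, "AGG", "+", GenomicInterval("chrA", 0, 20, "+"), 17)
            got = {(s.locus.chrom, s.locus.start, s.strand, s.mismatch_positions)
                   for s in find_offtarget_sites(guide, genome, max_mismatches=3)}
            assert got == sliding_offtargets(genome.sequences, proto, 3)

    def test_requires_complete_two_mismatch_search(self):
        genome, guide, _ = self._plant(np.random.default_rng(13), [])
        with pytest.raises(ValueError):
            find_offtarget_sites(guide, genome, max_mismatches=1)


def _ot(n, positions, start=0):
    return OffTargetSite(GenomicInterval("c", 1000 + start, 1020 + start, "+"),
                         "+", "AGG", n, frozenset(positions))


class TestRetentionRule:
    @pytest.mark.parametrize("site,expected", [
        (_ot(1, {4}), False),        # single mismatch: reject
        (_ot(2, {3, 7}), False),     # two mismatches, both PAM-distal: reject
        (_ot(2, {3, 15}), True),     # two mismatches, one in seed: keep
        (_ot(3, {1, 2, 3}), True),   # three mismatches anywhere: keep
        (_ot(0, set()), False),      # perfect unintended match: reject
    ])
    def test_single_site_cases(self, site, expected):
        assert passes_offtarget_rule([site], set()) is expected

    def test_on_target_locus_is_ignored(self):
        site = _ot(0, set())
        assert passes_offtarget_rule([site], {("c", 1000, "+")})

    def test_exhaustive_truth_table(self):
        from itertools import combinations

        for n in range(4):
            for positions in combinations(range(1, 21), n):
                expected = n >= 3 or (n >= 2 and any(p >= 9 for p in positions))
                assert passes_offtarget_rule([_ot(n, set(positions))], set()) is expected


class TestCfd:
    def test_no_offtargets_scores_100(self):
        genome = Genome({"c": "A" * 100})
        guide = GuideRNA("A" * 20, "AGG", "+", GenomicInterval("c", 0, 20, "+"), 17)
        assert cfd_specificity(guide, [], genome) == 100.0

    def test_perfect_site_has_unit_cfd(self):
        genome = Genome({"c": "A" * 100})
        guide = GuideRNA("A" * 20, "AGG", "+", GenomicInterval("c", 0, 20, "+"), 17)
        site = OffTargetSite(GenomicInterval("c", 30, 50, "+"), "+", "AGG", 0, frozenset())
        assert site_cfd(guide, site, genome, load_cfd_matrix()) == 1.0

    def test_single_mismatch_site_equals_matrix_entry(self):
        matrix = load_cfd_matrix()
        seq = "A" * 100
        seq = seq[:30] + "A" * 4 + "G" + "A" * 15 + seq[50:]  # G at protospacer pos 5
        genome = Genome({"c": seq})
        guide = GuideRNA("A" * 20, "AGG", "+", GenomicInterval("c", 0, 20, "+"), 17)
        site = OffTargetSite(GenomicInterval("c", 30, 50, "+"), "+", "AGG", 1, frozenset({5}))
        assert site_cfd(guide, site, genome, matrix) == matrix[(5, "A", "G")]

    def test_score_non_increasing_in_offtargets(self):
        genome = Genome({"c": "A" * 200})
        guide = GuideRNA("A" * 20, "AGG", "+", GenomicInterval("c", 0, 20, "+"), 17)
        sites = [OffTargetSite(GenomicInterval("c", 30 + 25 * i, 50 + 25 * i, "+"),
                               "+", "AGG", 0, frozenset()) for i in range(4)]
        scores = [cfd_specificity(guide, sites[:k], genome) for k in range(5)]
        assert scores[0] == 100.0
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestAssembleLibrary:
    def _guides(self, n, seed=21):
        rng = np.random.default_rng(seed)
        guides = []
        for i in range(n):
            site = _site("chr1", 100 * i, 100 * i + 40, ordinal=i + 1)
            guides.append(GuideRNA(_random_seq(20, rng), "AGG", "+",
                                   GenomicInterval("chr1", 100 * i, 100 * i + 20, "+"),
                                   100 * i + 17,
                                   frozenset({f"{site.id}_CACGTG"})))
        return guides

    def test_counts_and_oligo_structure(self):
        entries = assemble_library(self._guides(2),
                                   non_targeting=["T" * 20, "G" * 20, "C" * 20],
                                   positive_controls=[("POS_MYC_1", "A" * 20)])
        assert len(entries) == 6
        for e in entries:
            assert len(e.oligo) == 104
            assert e.oligo == LEFT_FLANK + e.protospacer + RIGHT_FLANK
            assert e.oligo[32:41 + 20] == "GAAACACCG" + e.protospacer

    def test_flank_constants_verbatim(self):
        assert LEFT_FLANK == "TTTCTTGGCTTTATATATCTTGTGGAAAGGACGAAACACCG"
        assert RIGHT_FLANK == "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGT"
        assert (len(LEFT_FLANK), len(RIGHT_FLANK)) == (41, 43)

    def test_empty_guides_gives_controls_only(self):
        entries = assemble_library([], non_targeting=["T" * 20])
        assert [e.category for e in entries] == ["non_targeting"]

    def test_duplicate_sequence_across_categories_rejected(self):
        guides = self._guides(1)
        with pytest.raises(ValueError, match="duplicated"):
            assemble_library(guides, non_targeting=[guides[0].protospacer])

    def test_shared_protospacer_merges_targets(self):
        g = self._guides(1)[0]
        twin = GuideRNA(g.protospacer, "AGG", "+", g.protospacer_interval,
                        g.cut_bond, frozenset({"chr1_BS9_CACGTG"}))
        entries = assemble_library([g, twin])
        assert len(entries) == 1
        assert set(entries[0].targets) == set(g.targets) | {"chr1_BS9_CACGTG"}

    def test_names_follow_genomic_order(self):
        guides = self._guides(3)
        names = [e.name for e in assemble_library(guides)]
        assert names == sorted(names, key=lambda n: int(n.split("_BS")[1].split("_")[0]))


def test_design_outputs_are_deterministic(tmp_path, toy_fixture):
    from eboxscreen import pipeline

    paths = []
    for run in (1, 2):
        res = pipeline.design_library(
            toy_fixture.genome, [s.interval for s in toy_fixture.sites], toy_fixture.exons)
        p = tmp_path / f"library{run}.tsv"
        write_library_tsv(p, res.entries, res.ebox_index)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]
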