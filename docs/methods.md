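# Methods

This note documents the models, conventions and numerical choices behind
`eboxscreen`, and what the synthetic fixtures do and do not emulate.

## Coordinates and sequence conventions

All intervals are 0-based half-open (BED-native); 1-based coordinates
appear only in rendered reports. Overlap is strict half-open overlap, so
bookended intervals do not overlap — but bookended intervals *do* merge,
since a screen treats back-to-back peak fragments as one region; there
is no gap-tolerant merging beyond touching. Binding sites are labelled
`{chrom}_BS{ordinal}` with ordinals assigned per chromosome in ascending
start order, starting at 1. This numbering is deterministic and
documented, but it is our convention: datasets using other orderings
will produce different labels for the same regions.

Motif scanning uses a reverse-complement-closed hexamer set (default
CACGTG, CACATG/CATGTG, CACGCG/CGCGTG), so one plus-strand pass sees
every occurrence on either strand exactly once, labelled by its
plus-strand reading. Windows containing N are skipped.

## Guide geometry

SpCas9 cuts bluntly 3 nt 5′ of the NGG PAM, between protospacer
positions 17 and 18 (numbering 1–20 from the PAM-distal 5′ end). We
define "targeting an E-box" as: that cut bond is one of the hexamer's
five internal phosphodiester bonds. This is the geometric condition
under which the repair indel must disrupt the motif itself; guides whose
cut falls outside the hexamer mostly leave it intact. Enumeration
considers both strands (an NGG PAM on the minus strand appears as CCN on
the plus strand), giving at most five candidate cut bonds per strand per
E-box. Cut positions can be rendered against the motif
(e.g. `CACAT*G` for a cut directly before the final G).

## Off-target retention rule and specificity score

Candidate guides are screened against every genomic locus (both strands)
with an NGG PAM whose aligned 20-mer is within 2 mismatches. A perfect
match whose cut bond lies inside any designable library E-box is an
intended on-target; every other site must have ≥ 3 mismatches, or ≥ 2
mismatches with at least one in the seed region (nt 9–20), else the
guide is discarded. The search is an exhaustive vectorised
sliding-window scan — appropriate for the genome sizes the fixtures use
and independently verified against a plain-string oracle; NAG PAMs are
not searched.

A CFD-style aggregate specificity score is also provided:
per-site cutting likelihood is the product of per-position
mismatch-activity penalties, and the guide score is
100 / (1 + Σ per-site likelihood over off-target sites), i.e. 100 for a
guide with no off-targets and monotonically decreasing as sites
accumulate. The bundled activity table
(`data/synthetic_cfd_matrix.tsv`) is **synthetic**: it reproduces the
qualitative structure of published cutting-frequency-determination
measurements (penalties grow toward the PAM, wobble-like pairings are
most tolerated) but its numbers are constructed, so scores should be
used for ranking within this package, not compared against published
CFD values. The score does not gate library membership; the mismatch
rule above does.

## Oligo format

Library entries are 104-nt synthesis oligos:
41-nt left arm `TTTCTTGGCTTTATATATCTTGTGGAAAGGACGAAACACCG` + protospacer
+ 43-nt right arm `GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGT` (the
lentiCRISPRv2 cloning arms). Guides are deduplicated library-wide by
protospacer; a sequence cutting several E-boxes appears once and carries
all target ids. Controls are non-targeting sequences plus named
positive controls; any sequence shared across categories is an error.

## Read counting

Amplicon reads carry a 9–18-nt stagger before the constant vector
sequence, so extraction anchors on the invariant `GAAACACCG`
immediately 5′ of the protospacer: the 20 nt after the first anchor
occurrence are matched *exactly* against the library; anything else is
tallied as unmatched. No fuzzy matching is attempted — with exact
matching a single sequencing error silently drops a read rather than
reassigning it. Demultiplexing is exact 8-nt barcode matching, outside
the scope of the counter itself (one FASTQ per sample is expected).

QC quantities: the skew ratio is the 90th/10th percentile of construct
counts under linear-interpolation quantiles (infinite, with a warning,
when the 10th percentile is zero); fold coverage is
cells × transduction fraction / library size; the single-infection
fraction uses a Poisson MOI model, λ = −ln(1 − f),
P(X = 1 | X ≥ 1) = λe^(−λ)/f — at f = 0.30 this gives 0.832, the basis
of the usual "~85 % of transduced cells carry one integration" planning
figure.

## Depletion model

Counts are aggregated to targets by summation (a multi-target guide
contributes to each of its targets), then modelled as negative binomial
with mean μ_ij = s_j · q_i · 2^(x_j β_i) (x_j = 1 for T1) and variance
μ + α μ². The fitting pipeline follows the DESeq2 framework without
claiming numerical parity:

1. **Size factors** — median-of-ratios over rows with all-positive
   counts; a pseudo-reference fallback (`counts + 1`) exists for
   zero-heavy matrices.
2. **Per-target dispersion** — method-of-moments from the pooled
   within-condition variance of normalised counts, with the shot-noise
   term μ̄ · mean(1/s) removed; clipped to [10⁻⁸, 10].
3. **Dispersion trend** — α(μ) = a₁/μ + a₀ fitted by gamma-weighted
   iteratively reweighted least squares with outlier trimming
   (points > 15× or < 10⁻⁴× the fitted value are dropped per
   iteration).
4. **Shrinkage** — per-target dispersions maximise a Cox–Reid-adjusted
   NB likelihood plus a log-normal prior centred on the trend, on a
   48-point log-α grid with quadratic interpolation at the optimum.
   The prior width is the MAD² of MLE log-residuals minus the
   theoretical sampling variance of a log dispersion
   (trigamma((m − p)/2)), floored at 0.25².
5. **Wald test** — β and its standard error come from a vectorised
   two-column IRLS fit (coefficients clipped to |β| ≤ 30 on the natural
   log scale to contain all-zero groups); z = β̂/se is compared to a
   standard normal, two-sided, and BH-adjusted over all targets with
   nonzero totals (zero-total targets are excluded and reported).
   No independent filtering and no fold-change shrinkage are applied:
   calls are padj < 0.001 (default) split by the sign of the estimate.

T0 is the reference condition; depletion means a negative log2FC at T1.
The test suite cross-checks estimates against pydeseq2 on a simulated
matrix (correlation and call agreement, not exact equality).

The guide-level replicate-consistency filter calls a guide depleted when
its normalised T1/T0 ratio is ≤ 1/2 in *both* replicates (enrichment
symmetric), with a 0.5 pseudocount on normalised counts since zero
handling is otherwise undefined.

Nearest-TSS annotation measures distance from the E-box midpoint,
returns at most one gene on each side, and uses an inclusive 50-kb
window; ties go to the lexicographically smaller gene name. Midpoint
distance and boundary inclusivity are our choices — the quantity is
insensitive to them except exactly at the window edge.

## Flank grammar

Because E-boxes are (quasi)palindromic, both orientation readings of
every E-box window are pooled into the profile, which makes
count(+k, b) = count(−k, complement(b)) hold exactly on N-free input
(each position's counts sum to 2 × n E-boxes). An option to orient
non-palindromic motifs to a canonical strand instead is deliberately not
the default: pooling realises the palindromic identity exactly and
avoids an arbitrary orientation rule.

Composition differences are tested per flank position with chi-squared
goodness-of-fit against expected proportions taken from the background
profile treated as fixed (df = 3 for the 4-category test, df = 1 for
each 1-vs-rest nucleotide test). Only positions +1..+K are reported —
the negative side is the mirror image by construction. Expected cells
below 5 are flagged; a zero-probability background category observed in
the essential profile triggers a 0.5 continuity guard and a flag.
Star annotations follow the usual 0.05/0.01/0.001/0.0001 ladder; BH-
adjusted p-values are emitted alongside, since many positions are
tested. Pearson's statistic scales with n, so profiles of different
sizes are compared through their proportions, never their raw χ².
Default flank widths: K = 20 for logo export, K = 10 for tests.

## Synthetic fixtures

`make_genome` plants E-box hexamers in random-background chromosomes
(41 % GC by default, the human-like value), wraps each in a ±30-bp
"binding site", scrubs accidental motif hits inside site windows so the
planted set is exactly recoverable, overlaps a chosen fraction of
E-boxes with 60-bp "coding exons", and plants near-duplicate copies of
real guide loci (chosen mismatch patterns, including perfect copies and
seed/non-seed doubles) away from the sites as off-target decoys.

`simulate_screen_counts` draws gamma-Poisson (negative-binomial) counts
under exactly the model the test assumes, with log-normal guide
abundances (σ = 0.25) around a 500 reads/guide depth — the coverage
scale of a duplicate screen at ~500× — dispersion 0.05, log-normal
sample-depth factors (σ = 0.1), and a configurable set of spiked
targets. `simulate_fastq` emits stagger + barcode + anchor + protospacer
reads with an optional independent per-base error rate, redrawing the
rare read whose random stagger would contain a spurious anchor copy.

What the fixtures do **not** emulate: real ChIP peak-length and motif
clustering, chromatin context, PCR jackpotting and amplification bias,
guide-efficiency heterogeneity, and genome-scale off-target landscapes.
Passing tests therefore demonstrate the correctness of the algorithms
under their stated model, not screen performance on real genomes.

## Problem sizes and determinism

The bundled analyses run at desk scale by choice: 100-kb two-chromosome
decoy genomes (~30 planted E-boxes, 50 decoys), 2,000-target screen
simulations at 2 + 2 samples, 10⁵-read counting round trips, and
200-replicate power runs for the grammar test. Every stochastic
component takes an explicit seed (numpy `default_rng`; no global state),
and all generators are bit-reproducible given (spec, seed). The
acceptance script derives independent sub-seeds from its single `--seed`
argument.

## Known limitations

* Exact reproduction of any published library requires the original
  peak sets, annotation and genome build; BS ordinals and guide names
  are deterministic but convention-dependent.
* The Wald test with 2 + 2 samples leans on the dispersion prior;
  strongly non-NB noise (jackpots) would mis-calibrate it.
* Off-target search is exhaustive-scan only — fine up to tens of
  megabases, not tuned for a full human genome.
* The specificity score ranks guides with a synthetic activity table;
  it is not comparable to published CFD values.
* No on-target efficiency model (Rule Set 2 and kin) and no alternative
  PAM chemistries.
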