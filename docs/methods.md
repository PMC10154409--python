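# Methods

## Coordinate frame

All internal coordinates are 0-based half-open (BED convention); VCF
positions are converted on ingest.  Distance from a position to a chromosome
end is `min(p, L-1-p)`, treating both ends identically — the organisms these
analyses target have acrocentric chromosomes and no end-specific logic is
needed.  "Within *t* of the telomere" is strict (`distance < t`), and an
interval's subtelomere membership is decided by its 5′-most coordinate
(start): the reference point is stable across feature lengths, whereas
midpoints shift with annotation trimming.  Arm assignment sends the exact
midpoint left.  All three conventions are configurable where they surface.

## Genomic-category classifier

Categories partition every position: promoter (within 2 kb of any TSS, both
sides, strand-agnostic, matching the "2 kb around the TSS" convention) takes
precedence over exon, then intron, then strand-aware flank windows of the
nearest gene (2–10 kb upstream → 5′ proximal, 10–100 kb upstream → 5′
distal, 0–10 kb downstream → 3′ proximal, 10–100 kb downstream → 3′ distal),
then gene desert (strictly > 100 kb from every gene).  Nearest-gene ties
break by TSS distance, then gene id, so the map is deterministic.  Intergenic
positions within 100 kb of a gene that fall in no named window get an
explicit `intergenic_other` bin rather than being silently dropped.  The
production classifier is interval-indexed (interval trees for bodies/exons,
sorted TSS arrays); the test suite checks it position-by-position against an
independent linear-scan implementation.

## Subtelomeric TE enrichment

DE filters follow the field convention: fold change strictly > 1.5 (both
this default and the stricter 2.0 sometimes used for per-locus displays are
exposed as parameters), *p* strictly < 0.05, and instances covered by fewer
than 5 uniquely mapped reads removed — from the DE set *and* from the
background universe, since coverage failure makes an instance invisible to
both.  The default background is therefore the superfamily's *expressed*
instances; a flag switches to the full annotation.  The expected subtelomeric
count is the DE count times the background subtelomeric fraction.

The two-sided Fisher *p* is the probability-mass form: the sum of
fixed-margin hypergeometric probabilities no larger than the observed
table's.  For tables up to N = 2000 this is computed in exact integer
arithmetic (bit-identical to full enumeration); larger tables use a
log-gamma evaluation with a 1e-12 relative tie tolerance, since big-integer
enumeration at N ≈ 5000 costs ~50 ms per table.  Multiple testing is
Benjamini–Hochberg across all tests of one scan.

Calibration: the null study (no positional bias, enrichment factor 1) uses
genome-scale tables — 300 DE instances over a background of 3000 with a 10 %
subtelomeric fraction — where the rejection rate at nominal 0.05 is ~0.05.
At small counts (e.g. 50 DE instances) the exact test is intrinsically
conservative (observed type-I ≈ 0.02); this is a property of discrete exact
tests, not of the implementation, and small-count scans should be read
accordingly.  The power study keeps the small-count design: a 5× planted
factor on 50 DE instances is detected (p < 0.05) in ≥ 97 % of replicates.

## Variant spectra

Baseline subtraction matches on exact (chrom, pos, ref, alt); a
position-only mode tolerates indel representation drift between callers (no
left-alignment is attempted — inputs are assumed normalised).  Indels are
classified at their leftmost reference base.  The CNV depth filter is
strictly `depth > 10` as printed in the convention it follows.  SBS classes
are directional by default; the collapsed form maps purine-reference classes
to their reverse complement (exactly two directional classes per collapsed
class).

## Retrotransposition

Insertion sequences are scored against each consensus as the fraction of the
insertion's *k*-mers present in the consensus *k*-mer set, on the better of
the two strands; ties between families break toward the longer consensus,
then lexicographic name.  *k* = 15 balances specificity (chance 15-mer hits
against a ~30 kb library are ~1 in 3×10⁴ per *k*-mer) against divergence
tolerance.  The identity threshold (default 0.05) was placed by a separation
analysis: expected *k*-mer survival under per-base divergence *d* is
(1−*d*)^*k* ≈ 0.46 at *d* = 0.05, with a 0.1 % quantile of 0.124 for 200 bp
insertions, while the maximum chance identity of random sequence over 3000
draws is 0.016 (mean 7×10⁻⁵) — so 0.05 keeps ≥ 3× margin to both
distributions.  Thresholds in the 0.3–0.5 range, though intuitively
"stringent", would reject 6–60 % of genuine 5 %-divergent copies, because
survival concentrates near 0.46, far below naive sequence-identity
intuition.  The best-scoring family is empirically always the true one on
planted data; the threshold only arbitrates assigned-vs-unclassified.  An
edlib infix-alignment scorer is available (`method="alignment"`) as a slower
validation route.

Baseline insertion subtraction uses a ±100 bp window (long-read breakpoint
jitter).  The burden test conditions on the total event count: under equal
exposure, the case count is Binomial(n, ½); an exposure ratio shifts the
null proportion.  The choice of this test is the package's own — upstream
conventions for this comparison vary and are rarely stated.

## Telomeric reads and peak classes

A read is telomeric when, in the best of six phase offsets on either strand,
whole repeat units (TTAGGG) matching with at most `max_mismatches_per_unit`
mismatches cover at least `min_coverage_fraction` (default 0.7) of the read.
This aligner-free rule replaces "map reads to (TTAGGG)n" because aligner
seed parameters do not transfer between tools; the defaults classify every
pure-repeat read of any phase while uniform-random 150-mers pass at < 10⁻⁴.
Counting is vectorised by grouping reads of equal length so each
(strand, phase) test is one array comparison.

Peak classification uses any-overlap (≥ 1 bp) for "on retrotransposon" and
the peak start for subtelomere membership, consistent with the interval
convention above; the four exclusive cells of the 2×2 tally always sum to
the peak count.  The metagene's "5′/3′ sides" are genomic left/right of the
peak interval (not gene strand); for window *w* a gene contributes on a side
when its TSS lies within (0, *w*] of the peak boundary, and a gene may
contribute to several peaks.  Window sizes are a required user parameter.

## Hi-C subtelomere counting

Valid pairs (Hi-C-Pro allValidPairs dialect) are counted into
[exclusion, *w*) windows at each arm of each chromosome for an ascending
window ladder (defaults 5/10/20/30/60 Mb at mouse scale, 100 kb exclusion for
the unreliable terminal heterochromatin).  One pair counts once per
(chromosome, arm, window) bucket it touches: both ends in the same bucket is
one interaction within the region; ends in two buckets credit each once.
Trans contacts count toward the window holding their end ("interactions with
other regions"); `cis_only` restricts them.  No matrix balancing is applied —
counting operates on raw pairs.  Windows beyond the chromosome length are
truncated to half the length with a warning.  Percentages are of the total
valid-pair count; centre windows of the same widths, centred at L/2, give
the baseline for the centre-vs-subtelomere comparison.

## Synthetic data

The generator emits a miniature genome — five chromosomes of 20/16/12/8/5 Mb
— with every distance threshold scaled by the ratio of the miniature median
chromosome (12 Mb) to the mouse median (~130 Mb), so 1 Mb ↦ ~92 kb, 100 kb ↦
~9.2 kb, and the 5–60 Mb Hi-C ladder ↦ ~0.46–5.5 Mb.  Each sub-simulator
draws from its own generator spawned from the master seed; emitted files are
byte-identical across same-seed runs (gzip members are written with a fixed
mtime for this reason).

- **Genes**: uniform non-overlapping placements at 2 genes/Mb, 20 kb bodies,
  three equal-spaced exons covering half the body.
- **TE instances**: per family, chromosomes chosen by length, then a
  per-chromosome mixture putting probability ρ·s/(ρ·s+1−s) on the terminal
  zones (zone fraction s), i.e. zone density ρ× the interior.
- **DE labels**: expressed instances (≥ 5 reads, default 90 %) are labelled
  up with probability `fraction_up` away from ends and `enrichment_factor`
  times that inside them; labelled rows draw log2FC and p that pass the
  filters, unlabelled rows values that fail them.
- **Reads**: telomeric reads are phase-randomised (TTAGGG)n tracts on either
  strand with a configurable substitution rate; background reads are uniform
  random.  Default 100 000 reads of 125 bp with a 1 % telomeric fraction.
- **Valid pairs**: the anchor end falls in the terminal boost zones with
  odds β times the neutral length-proportional odds, normalised globally and
  uniform within the chosen stratum, so the planted β is exactly the
  case/control odds ratio of zone-anchored fractions
  (`hic.estimate_boost` inverts it).  Cis partners sit at a truncated
  power-law distance s^(−α) (default α = 1.5, minimum 1 kb) from the anchor;
  trans partners (default 10 %) are uniform on another chromosome.  α = 1.5
  is steeper than the classic ~1 contact-decay exponent; it is chosen so cis
  partner ends rarely straddle a zone boundary, which keeps the planted
  boost identifiable from window counts (recovered as 1.94 for a planted
  2.0 at 10⁵ pairs).  With α = 1 the partner-end contamination biases the
  estimate ~10 % low — a known trade-off, documented rather than hidden.
- **Variants/insertions**: a shared baseline appears in both VCFs;
  case-specific variants are placed into categories by rejection sampling
  with the production classifier (so planted labels are exact, and spectrum
  recovery is checked by chi-square against the weights); insertions are cut
  from the consensus library, substituted at 5 %, strand-randomised, and
  jittered by ≤ 50 bp in the control when shared.

The consensus library is a **synthetic stand-in**: seeded random sequences
under real mouse family names (L1MdTf/L1MdA/L1MdGf, IAPEY3, ERVB4, B1) at
realistic lengths.  Random consensus sequences are *easier* to tell apart
than real families, which share diagnostic subsequences; real-library family
calls (especially within young LINE1 subfamilies) will be less clean than
the planted-data recovery rates suggest.

What the generator does not emulate: alignment artifacts, mappability,
PCR duplicates, sequencing error profiles, real TE sequence phylogeny,
chromatin-structure features beyond distance decay plus the planted boost,
and real gene architecture.  Passing tests demonstrate that the
*measurement* layer recovers planted truth, not that upstream callers are
accurate.

## Determinism and provenance

Identical configuration and seed give byte-identical output tables.  Output
tables carry a provenance comment block (tool version, seed, configuration
hash over parameters — the output directory is excluded from the hash);
wall-clock timestamps appear only in the run log (`report.json`), never in
tables.

## Study sizes

Validation studies run at: 1000 null replicates and 200 power replicates for
the enrichment test; 10⁵ reads for telomeric recovery and false positives;
500 insertions for family recovery; all ~46 000 2×2 tables with N ≤ 30 for
the Fisher oracle sweep and all splits of n ≤ 60 for the burden oracle; 10⁵
pairs per sample for boost recovery; 10⁴ positions for the partition check.
The end-to-end determinism demonstration uses a reduced simulation (5000
reads, 20 000 pairs) — determinism does not depend on size.

## Known limitations

- The exact Fisher test is conservative for small discrete tables (see
  calibration above).
- Insertion family assignment is resolution-limited by the synthetic
  library; no subfamily phylogenetics, TSD detection or split-read logic.
- The telomeric-read rule ignores base qualities.
- Hi-C counting double-counts a pair across *different* buckets by design
  ("within the region and with other regions"); percentages over disjoint
  regions can therefore sum above the per-pair total.
- Enrichment pools instances genome-wide before testing; a per-chromosome
  breakdown, sometimes reported in this kind of analysis, is not built in
  (run the scan on per-chromosome subsets if needed).
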