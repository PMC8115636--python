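# Methods

This note records the models, parameter choices, numerical conventions and
known limitations behind `splicehotspot`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate and format conventions

All internal intervals are 0-based half-open; splice sites are boundary
coordinates (position *p* lies between bases *p−1* and *p*). GTF/GFF3
(1-based closed) is converted on read through gffutils and written back as
GTF; STAR `SJ.out.tab` junction files (1-based closed introns) and BED12
junction records are converted on read; VCF positions are 1-based on disk
and 0-based in memory. The averaged-usage track is exported as BED6 with
score = round(1000 × mean usage) and name = side+strand.

## Splice-site usage

Usage of a site is A/(A+B+C) over junction reads: A uses the site as its
same-side end, B spans it strictly, C has its same-side end strictly inside
an annotated flanking intron of the site. Decisions taken where the
definition leaves room:

* **Annotation filter.** A junction is kept only when *both* ends match
  annotated sites (donor end on an annotated donor, acceptor end on an
  annotated acceptor). The filter exists to remove aligner artifacts, and
  artifacts can corrupt either end.
* **Category precedence A > B > C**, so no read is counted twice for one
  site. Ties at the site position are A.
* **Flanking introns** are the union over isoforms of the introns adjacent
  to the site on its own side. A consequence worth knowing: an annotated
  exon-skipping intron spans downstream exons, so canonical junctions of
  downstream introns inside it are counted as C for the upstream site. The
  synthetic ground truth applies the same convention, so planted and
  estimated usage agree; on real annotations this makes usage of sites
  adjacent to skipping isoforms slightly conservative.
* **Sites with no evidence (A+B+C = 0) are undefined, not zero.** In the
  cross-cell-line track a site's mean/variance is computed over the lines
  where it is defined; sites defined in fewer than half the lines (or fewer
  than two) are dropped, and only sites with population variance < 0.001
  are exported.
* The switch score is max pairwise |ΔPSI| across conditions, computed as
  max − min; it is 0 with a warning flag below two conditions.

## Allelic-ratio statistics

log2 AR = log2((m_o/m_i)/(w_o/w_i)). When any of the four counts is zero
the Haldane–Anscombe correction adds 0.5 to each count; a species with no
reads at all yields NaN. A variant is splice-disrupting iff |log2 AR| ≥
1.5 (inclusive) and FDR < 0.05 (strict). When no FDR column is supplied it
is computed as a stand-in — two-sided Fisher exact test on the
mutant-vs-wild-type output/input 2×2 table with Benjamini–Hochberg across
the table; externally supplied FDRs always pass through untouched, since
the assay's own dispersion model is unknown to us.

**Exon-SD shuffle test.** Per-exon sample SD (ddof = 1) of log2 AR for
exons with ≥ 2 variants, paired with the SD under one seeded global
permutation of ratios across all variant slots, one-sided Wilcoxon
signed-rank for observed < shuffled. This pairing mirrors the published
figure, but it is *not calibrated*: both columns are built from the same
multiset of ratios, the pairs are negatively dependent, and under the null
the p-value concentrates mid-range (simulated type-I error at α = 0.05 is
≈ 0 — conservative, never anticonservative). The module therefore also
computes, for `n_shuffles > 1`, an empirical permutation p-value on the
median per-exon SD, which is calibrated by construction; the acceptance
suite verifies its type-I error sits in the binomial confidence band of
the nominal level. Use the permutation p for error-controlled inference
and the Wilcoxon p for comparability with the figure-style analysis.

**Conditional probabilities.** Over ordered pairs of distinct variants
within an exon, P(second disrupting) and P(second | first disrupting).
Exhaustive mode enumerates all pairs (pair-weighted); sampled mode draws
one pair per exon per repeat without replacement (exon-weighted) and
reports the Monte-Carlo SE. The two modes estimate slightly different
functionals when exon sizes vary.

## Variant classifier

The learner is scikit-learn's gradient boosting (`rf` selects a random
forest behind the same interface); the module's own content is the feature
pipeline and the ablation protocol. Defaults follow the standard recipe
for this analysis: 1000 trees, learning rate 0.05, interaction depth 3,
bag fraction 0.5, minimum 10 observations per node, 3 CV folds, seeded
stratified 70/30 split. Features are tagged into exactly one of four
groups:

* *mutation* — one-hot of the 12 substitution types in transcript
  orientation; optional hybridization indicators from a pluggable
  structure scorer (none is bundled; its absence is recorded in the model
  manifest).
* *motif* — sum and mean of hexamer-score changes over the ≤ 6 windows
  covering the variant (windows crossing the exon boundary use genomic,
  intron-inclusive sequence), and mutant−wild-type splice-site score deltas
  over the donor (3 exonic + 6 intronic) and acceptor (20 intronic + 3
  exonic) windows. The default splice-site scorer is a log-odds PWM built
  from the annotation's own sites against a uniform background
  (pseudocount 0.5); any scorer exposing `donor_score`/`acceptor_score`
  over the same windows can be dropped in.
* *exon* — donor and acceptor usage, exon length, mean hexamer score over
  the exon's L−5 hexamers, and optionally the wild-type assay outcome.
* *transcript* — exon count and gene length.

Missing features are imputed with the training-set median plus a
missingness indicator; medians live in the manifest. Ablation retrains on
one identical seeded split with each group left out and each group alone.
The call rule is strictly score > 0.5 (a score exactly at the cutoff is
no-effect); the boundary is pinned by tests.

## Hotspot calling and tolerance

An exon with scores for all 3L possible SNVs is a hotspot iff strictly
more than 10% are called splice-altering; incomplete score coverage makes
the exon uncallable rather than silently non-hotspot. Variants per base =
distinct (position, alt) variants / exon length. The tolerance comparison
draws, for each hotspot exon, the unused non-hotspot exon of closest
length from the same genes (greedy, without replacement, seeded tie
order), then applies a one-sided Welch t test (hotspot < control); Welch
because group variances have no reason to be equal. The HI filter assigns
each exon the HI score of its dominant transcript (supplied usage weights,
lexicographic tie-break) and removes exons below the median over genes;
the median is computed once from the input and may be passed explicitly,
since re-deriving it from an already-filtered table would tighten the cut
on every application. The cutoff sweep reports, per proportion cutoff, the
hotspot count and the mean variants-per-base difference, and selects the
difference-maximizing cutoff among those retaining at least a configurable
fraction of exons (default 1%) — the retention floor makes the stated
trade-off well-defined.

## Functional RBP sites

The exon window runs from the end of the upstream exon to the start of
the downstream exon (exon body included — binding "in or near" the exon);
terminal exons truncate at the transcript boundary since no competing
splice site lies beyond it. A peak labels every exon whose window it
overlaps (one label per peak–exon pair); the label is functional iff that
exon is differentially spliced at FDR < 0.1 under knockdown of the peak's
RBP in the peak's cell line. Cell lines are never pooled. Sites-per-exon
counts *distinct RBPs*, not raw peaks, for both the observed histogram
and the null; the null draws the observed number of functional sites from
the non-functional pool without replacement (default 1000 iterations) and
reports mean ± SEM (SD/√n_iter) per k. With distinct-RBP counting the
per-draw mass Σ k·count_k is ≤ the draw size (equality holds in the
alternative raw-peak counting mode, available via `count="peaks"`).

## Minigene ESCo analysis

Reads arrive as junction chains over the construct (E1, TEST, FLANK, E4);
a chain must start at E1, end at E4, move strictly forward and be
contiguous, else it is unassignable (assigned + unassignable = total).
Skipping rate = (test-skipped + both-skipped)/total with a Wilson
interval. Per library group, ESCo is a positive Spearman association
between skipping rate and flank efficiency with a one-sided permutation p
(default 10⁴ permutations, computed vectorized on rank matrices);
permutation rather than parametric because groups hold ≤ 8 species.
Groups with < 3 species are untestable. Splicing efficiencies are inputs,
never computed here.

## The synthetic study

The generator writes every input the pipeline reads, in the real formats,
with planted truth. Defaults define the study conditions: 40 genes of 3–6
exons (60–150 bp exons, 80–300 bp introns) on both strands across several
chromosomes, consensus-like donor/acceptor motifs planted at boundaries;
mean junction depth 200 per site (4 cell lines × 2 replicates); hotspot
fraction 0.2 among internal exons; per-variant disruption probability 0.85
in hotspot exons (mildly graded by the exon's planted inclusion) vs 0.03
in background; mean |log2 AR| 2.5 for disrupting variants at assay depth
300; 400 assayed variants; 8 RBPs, 200 functional / 400 non-functional /
40 unlabeled peaks with clustering strength 3; population variant rate
0.08 per exonic base with 0.3 depletion in hotspots; a 7 × 8 minigene
efficiency grid at depth 2000 with logistic competition (α = −1,
β_t = 4, β_f = 6, τ = the boundary after the 2nd-weakest test group).
These sizes keep the full validation suite around a minute on one CPU
while leaving every planted effect recoverable at high power.

**Junction reads** come from an isoform mixture per gene — canonical,
exon-skipping (weight 0.25–0.55 on hotspot exons, 0.02–0.10 on ~30% of
background exons), and occasional donor/acceptor-extension isoforms that
create annotated cryptic sites inside introns — with Poisson counts per
isoform junction. A per-site independent count model cannot be realized as
a single junction table because neighboring sites share junctions, so the
planted usage stored in the ground truth is the exact expected A/(A+B+C)
under the mixture, computed by a small enumerator kept independent of the
analysis module it validates. **MaPSy effects** are exon-level: each exon
draws one characteristic effect (magnitude ~N(2.5, 0.4) floored at 1.6,
negative with probability 0.8) shared by its disrupting variants — this is
what makes within-exon allelic ratios similar, the structure the shuffle
test and conditional probabilities are designed to detect. Counts are
Poisson around input depth and a wild-type output rate tied to the exon's
planted inclusion; the assay's true dispersion is unknown, so this noise
model is a stated assumption, not a validated one. **RBP peaks** sit in
exon bodies (so each peak belongs to exactly one window and planted labels
are unambiguous), functional ones placed with probability ∝
exp(strength × hotspot); every functional (exon, RBP) pair gets a
knockdown row with FDR < 0.1. **Population variants** are Poisson per
exon at rate × depletion for hotspots. **Minigene reads** are multinomial
over the four isoforms with independent test/flank inclusion; the
competition model — logit P(include) = α + β_t·s_t − β_f·max(0, τ−s_t)·s_f
— is our own invention to reproduce the qualitative weak-exon pattern, as
no generative model is given for the assay.

What the generator does **not** emulate: read-level sequencing (FASTQ),
alignment and mapping bias, GC and expression confounders in peak data
(non-functional peaks are length-matched only; sequence composition is
near-uniform), assay amplification bias, isoform correlations across cell
lines (lines differ only by sampling noise), and realistic exon/intron
length or conservation distributions. Passing tests therefore demonstrate
correctness of the estimators and calibration of the resampling tests
under the stated models — not performance on real data.

## Determinism and numerical notes

Every generator derives its RNG from `(seed, stream-id)` (cell lines and
replicates add a CRC32 of their name), so identical configs produce
byte-identical files. Per-exon SDs in the shuffle test use the two-pass
(centered) variance form; the naive sums-of-squares form leaves ~1e-8
residues on constant exons. The acceptance script's variance bisection
nudges the constructed spread upward by ulps until the achieved population
variance meets the nominal one, so the retained/excluded transition is
measured at the threshold itself rather than one float below it. Scores,
proportions and the variance threshold are compared with the strictness
stated for each rule (≥ 1.5, < 0.05, > 0.5, > 10%, < 0.001); all are pinned
by boundary tests.

## Problem sizes used in validation

Tests run the default 40-gene study; usage recovery uses 30 genes at depth
2000; calibration/power suites use 100–200 repetitions per test (the
shuffle test's power repetitions redraw the assay on a fixed annotation);
hotspot precision/recall averages 3 seeded end-to-end repetitions with
300-tree fits. The library default of 1000 trees is unchanged.
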