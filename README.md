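# splicehotspot

Tools for finding **hotspot exons** — exons in which an unusually large
fraction of possible single-nucleotide variants disrupts splicing — and for
validating such calls against orthogonal evidence: splice-site usage from
RNA-seq junction reads, massively parallel splicing-assay (MaPSy-style)
allelic ratios, RNA-binding-protein (RBP) binding/knockdown integration,
population-variant tolerance, and minigene competition reporters.

The package is aimed at computational splicing researchers who want each of
these analyses as a tested, reusable library with a matching CLI, plus a
synthetic-data generator that plants known parameters so every estimator can
be validated end to end without external downloads.

## The statistics at the core

**Splice-site usage.** For an annotated donor or acceptor site, junction
reads split into three classes: *A* — reads whose junction uses the site;
*B* — reads whose junction spans the site (both ends beyond it in transcript
orientation); *C* — reads splicing from within the adjacent intron (donor
end in the downstream intron for a 5'ss, acceptor end in the upstream intron
for a 3'ss). Usage is

```
usage = A / (A + B + C)
```

Junctions are kept only when both ends match annotated splice sites,
replicates are summed before the ratio is taken, and a cross-cell-line
browser track reports mean usage for sites whose usage variance across cell
lines is below 0.001.

**Allelic ratio and disruption calls.** Each assayed variant has output
(spliced) and input counts for mutant and wild-type species; its effect is

```
log2 AR = log2( (m_o / m_i) / (w_o / w_i) )
```

and the variant is *splice-disrupting* when |log2 AR| ≥ 1.5 at FDR < 0.05.
Exon-level clustering of effects is tested by comparing per-exon standard
deviations of log2 AR against a global shuffle (paired Wilcoxon signed-rank,
plus a calibrated permutation p-value), and by the conditional probability
that a second variant in an exon disrupts splicing given that a first one
does.

**Variant classifier and hotspot rule.** A gradient-boosted classifier
(1000 trees, learning rate 0.05, depth 3, bag fraction 0.5, ≥10
observations per node, 3 CV folds, 70/30 split) scores each possible exonic
SNV from features tagged into four groups — mutation, motif, exon,
transcript — and a leave-one-group-out / single-group ablation ranks the
groups. A variant is called splice-altering when its score is strictly
above 0.5, and an exon is a **hotspot** when strictly more than 10% of its
3L possible SNVs are called splice-altering. Hotspot calls are validated by
variants-per-base (distinct population variants / exon length) against
size-matched non-hotspot exons from the same genes (one-sided Welch t),
optionally restricted to genes above the median haploinsufficiency score.

**Functional RBP sites.** A binding peak is *functional* for an exon when
it overlaps the window from the end of the upstream exon to the start of the
downstream exon and knockdown of its RBP changes that exon's splicing at
FDR < 0.1. Clustering of functional sites is judged against a null built by
drawing equally many sites from the non-functional pool without replacement
(1000 draws) and tallying distinct RBPs per exon.

**ESCo.** In 4-exon minigene reporters (constant–test–flank–constant), test
exon skipping is regressed on the flanking exon's splicing efficiency per
library group (Spearman, one-sided permutation p). A positive association —
enhancement by suppression of competitors — appears only for test exons
below a competition threshold.

## Worked example

```bash
splicehotspot simulate --seed 7 --out data/
```

writes a synthetic study (GTF + FASTA gene models, STAR-style junction
tables, MaPSy counts, peak BED + knockdown TSV, VCF, minigene reads, ground
truth). Running the pipeline on it in Python:

```python
from splicehotspot.synthetic import SimulationConfig, simulate_annotation, ...
cfg = SimulationConfig(seed=7, n_genes=40)
# ... junction usage, MaPSy statistics, classifier, hotspot calls ...
```

prints (seed 7, 40 genes, 300 trees):

```
sites scored: 343 | usage == 1.0: 0.286
variants: 402 | called disrupting: 81
shuffle test: median SD 0.236 vs 1.094 shuffled, Wilcoxon p=1.4e-06, permutation p=0.010
P(2nd disrupting)=0.21 -> 0.64 given 1st (delta 0.43)
held-out AUC 0.917 | CV AUC 0.821
hotspot exons: 23 of 102 internal exons (planted: 23)
variants/base: 0.030 hotspot vs 0.073 matched controls (one-sided Welch t, p=2.6e-07, n=23)
```

Reading the output: 81 of 402 assayed variants exceed the ≥1.5 / FDR<0.05
disruption rule, matching the planted mixture; within-exon SDs of allelic
ratio are far below their shuffled counterparts, so effects cluster by exon;
one disrupting variant raises the probability of a second from 0.21 to 0.64;
the classifier recovers the planted exon-level signal (held-out AUC 0.92);
scoring all 3L SNVs per exon calls 23 hotspot exons against 23 planted; and
called hotspots carry less than half the population variants per base of
their size-matched controls.

The same steps are available as CLI subcommands (`usage compute`, `usage
track`, `mapsy stats|shuffle-test|condprob`, `model
extract|train|ablate|predict`, `rbp label|enrich`, `hotspot
call|tolerance`, `minigene classify|esco`).

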