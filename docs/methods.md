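# Methods

`stressweave` reimplements, as a tested pipeline, an integrative
transcriptome/proteome analysis of the fission-yeast osmotic stress
response: a two-strain (wild type and a SAPK-pathway mutant) time course at
0, 15, 30, 60, 120 and 180 minutes after stress, three biological
replicates of strand-specific RNA-seq coverage per condition and five
technical replicates of label-free protein quantification. The pipeline
starts from per-base unique-read coverage tracks (read alignment is
upstream and out of scope) and ends at four analyses: a coverage-derived
transcription map, re-mapped 5′/3′ transcript boundary dynamics,
sense–antisense pair analysis linked to protein-level change, and
guilt-by-association functional annotation of non-coding RNAs.

## Transcription map

A transcribed locus is a maximal run of nonzero unique-read coverage on one
strand; runs separated by at most `merge_gap` = 50 zero-coverage bases are
merged (the merged locus spans the gap), and merged loci whose maximum
depth is below `min_peak_height` = 2 are discarded. Strands are segmented
independently. Loci are labelled with every annotated gene they overlap by
≥ 1 bp on the same strand; loci without a same-strand overlap are
"unannotated" and carry a note of any opposite-strand (antisense)
neighbours.

Expression of a feature is its RPKM,
`raw_count / (length/1000) / (library_size/1e6)`. Time-course profiles are
log2 fold changes of replicate-mean RPKM relative to t = 0 with a
pseudocount of 1 RPKM unit (configurable); the pseudocount guards ratios
for weakly expressed features and is negligible at the expression levels
the filters admit.

Coordinates are 0-based half-open in memory; GFF3 and BED I/O convert to
the 1-based/0-based conventions of those formats. Throughout the package
one "read" is one base of depth (unit read length): a feature's raw count
is its summed per-base depth and a sample's library size is the total
depth over all its tracks. This keeps counts, coverage and RPKM mutually
consistent without modelling read length.

## Boundary dynamics

The extent of a gene's boundary in a sample is the distance (nt) from the
observed transcript terminus — the edge of the same-strand locus covering
the gene's CDS — to the CDS edge, computed separately for the 5′ and 3′
ends and strand-adjusted. If coverage gaps split a gene across loci, the
locus covering most of the CDS is used. Eligibility filters: (1) loci
spanning multiple open reading frames are discarded, (2) genes with mean
CDS expression below log2 RPKM = 2 are removed, (3) a gene/end/timepoint
needs extents in at least two of three replicates.

The descriptive null range is `L = [mean(y) − 2·sd(y), mean(y) + 2·sd(y)]`
over t = 0 extents pooled across both strains (sample sd, ddof = 1; lower
bound clamped at 0); stressed extents falling beyond L are flagged.

Significance uses a label permutation test, run per strain course. The
observed statistic at a stress timepoint is the mean replicate extent minus
the mean t = 0 extent of the same course (difference of means, the
simplest statistic for "consistently longer under stress"). Sample labels
of the whole course are randomly permuted (10,000 draws by default, drawn
independently without uniqueness enforcement, one shared draw per course);
the empirical p is the plain proportion of permutations whose statistic is
at least the observed one — one-sided toward elongation. A zero p is
reported as "< 1/n_perm"; a +1/(n+1) smoothed estimator is available as an
option, off by default. A boundary change is called significant when the
extent changed by ≥ 30 nt *in every present replicate* at that timepoint
AND the empirical p is < 0.05. BH FDR over all (gene, end, strain,
timepoint) tests is reported alongside, not used as an extra gate, because
the ≥30-nt + p rule is the complete stated call criterion. Shortened
boundaries are classified by the sign of the observed delta only (the
permutation test is one-sided).

Note on calibration: the plain-proportion estimator on an n-permutation
grid has null exceedance P(p ≤ 0.05) = (⌊0.05·n⌋+1)/(n+1) (≈ 0.051 at
n = 1000), slightly above 0.05. Calibration checks therefore centre their
binomial band at that exact grid value.

## Sense–antisense pairs

Opposite-strand gene pairs whose transcript spans overlap by ≥ 1 bp are
`antisense_overlap` pairs (spans optionally enlarged by significant
re-mapped boundary extensions; convergent pairs that overlap only after
extension are flagged `from_convergent`). Non-overlapping opposite-strand
nearest neighbours within a configurable gap (default 1,000 nt,
configurable) are `convergent` when their 3′ ends face
each other (left gene on +) and `divergent` when their 5′ ends face.

Pair profiles are correlated (Pearson) over the concatenated per-strain
log2FC time courses. Members must pass an expression floor (mean log2 RPKM
≥ 2 in at least one strain course, mirroring the boundary filter);
zero-variance profiles are excluded with a reason. Pairs are clustered
(Euclidean/complete linkage on the joined member profiles) into a small
number of groups for reporting.

"Antisense in excess" at a stressed timepoint means the non-coding
member's replicate-mean RPKM exceeds the coding member's; exact ties are
excluded from both groups. The protein log2FC of the coding member at the
matching timepoint (replicate-mean abundance relative to t = 0) is
collected per group and the two groups compared with a two-sided Welch
t-test. Default granularity is one observation per (pair, timepoint), matching
the two-group display this analysis produces; per-pair aggregation (mean over
timepoints) is an option and is what the calibration checks use, because
per-timepoint observations of one pair share the t = 0 protein baseline
and are therefore positively correlated — the per-timepoint t-test is
descriptive, not calibrated. CESR over-representation among genes opposite
responsive antisense transcripts uses the hypergeometric upper tail; both
whole-coding-genome and antisense-bearing background universes are
supported, since either is defensible.

## ncRNA guilt-by-association

Each candidate (stress-responsive) ncRNA's log2FC profile over one strain
course is correlated with the CDS-region profiles of all usable coding
genes. Genes with ρ strictly above +0.7 form the positive set, strictly
below −0.7 the negative set (|ρ| = 0.7 exactly is excluded: the
threshold is a strict inequality). Each gene family is tested for
over-representation in each set (hypergeometric upper tail, universe =
coding genes with usable profiles); positive and negative sets are tested
separately so the association matrix can be signed, with a config switch
for the single combined |ρ| set. BH FDR is applied jointly across all
(ncRNA × family × direction) tests; a matrix cell is non-zero only when
its best direction reaches FDR < 0.05 and carries that direction's sign.
Rows and columns are ordered by Euclidean/complete-linkage clustering of
the +1/−1/0 encoding. Strain comparison reports per-ncRNA families gained,
lost, or sign-flipped between the two matrices.

Dendrogram determinism: clustering uses scipy's nearest-neighbour-chain
complete linkage, which is deterministic for a fixed input row order; tie
cases therefore resolve reproducibly, by scipy's ordering rather than by
an explicit lowest-index rule.

## Synthetic data generator

The generator emulates the study design and plants a known truth for every
downstream stage. Defaults: 200 coding genes and 60 ncRNAs on a 100 kb
chromosome; 30 antisense-overlapping (mRNA:ncRNA), 15 convergent and 15
divergent pairs, the rest isolated; CDS 100–200 nt with 20–50 nt UTRs,
ncRNAs 80–200 nt, inter-gene gaps of 150–200 nt (safely above the 50-nt
merge threshold, so called loci match planted transcripts at high depth).

* **Coverage** — per-base negative-binomial depth (variance
  m + 0.1·m², mean 5 reads/base scaled by each gene's expression
  multiplier) over the transcript span; zero between genes. Each terminus
  jitters per sample by round(N(0, 10 nt)) — the biological boundary
  variation that makes null extents vary — never retreating past the CDS.
  Planted extensions add 50–60 nt beyond one terminus in all replicates of
  one stressed timepoint.
* **Expression** — baseline RPKM log-normal (log2 mean 11, sd 1; on a
  100 kb genome at a 1 M-read library this yields expected feature counts
  in the hundreds, so measured profiles track the truth). A configurable
  30% of features are stress-responsive with a transient peak at 30 min
  (relative amplitudes 0.55/1.0/0.65/0.30/0.15 at 15–180 min). Planted
  ncRNA–family modules share a standardized latent profile over the
  stressed timepoints; in-module genes mix latent and independent noise
  with weights ρ and √(1−ρ²), hitting the target correlation in
  expectation. Replicate counts are negative-binomial around the RPKM
  identity, and RPKM is recomputed from observed counts.
* **Dosage pairs** — repression-pair ncRNAs start at 0.3× their sense
  partner's baseline and are induced ~11-fold under stress, so antisense
  exceeds sense at every stressed timepoint; control-pair ncRNAs stay at
  0.05× and flat. Repression-pair sense transcripts are flat so the
  protein effect is attributable to the planted repression alone.
* **Protein** — true protein log2FC is a one-step-lagged exponential
  smoothing (α = 0.5) of the transcript log2FC — delayed, gradual,
  persistent — plus the planted repression effect (−1 log2 unit by
  default) at stressed timepoints of repression pairs. One biological
  Gaussian draw per (protein, strain, timepoint) (sd 0.15 log2) is shared
  by five technical replicates (sd 0.05).
* **Gene sets** — planted module families (50 genes, 80% correlated with
  the module ncRNA), random background families (15–40 genes), and a CESR
  set drawn with 5× the background rate among coding genes opposite
  repression-pair antisense.

What the generator does *not* emulate: multi-exon structure, mappability
gaps, 3′ bias, overlapping same-strand isoforms, batch effects, and
missing protein values. Passing tests therefore demonstrate correctness of
the algorithms and their calibration under the stated noise model, not
robustness to those real-data artefacts.

## Validation runs and problem sizes

`scripts/acceptance.py` recomputes, per seed: segmentation exactness on 50
constructed multi-transcript tracks plus the 50/51-nt gap boundary case;
the hypergeometric tail against exact combinatorial counting for all
parameter combinations with universe ≤ 20; permutation-test calibration on
200 null genes × 2 strain courses (3 replicates × 6 timepoints, 1,000
permutations); boundary recovery over 20 seeds of 30-gene genomes with 10
planted 50–60-nt extensions at depth 5 (1,000 permutations); exhaustive
permutation enumeration on an 8-sample design vs 10,000 random draws;
dosage-effect recovery over 10 seeds and type-I error over 100 seeds of
40-gene / 20-antisense-pair datasets; association module recovery over 20
seeds at the default scale plus a 60-draw uniform-null family
false-positive rate; RPKM closed-form checks; and two full pipeline runs
compared byte-for-byte. These sizes are the package's chosen trade-off
between statistical resolution and a single-CPU run of about a minute.

## Known limitations

* The per-timepoint dosage t-test ignores within-pair correlation (see
  above); use per-pair aggregation when calibrated inference matters.
* Only elongation is tested by permutation; shortening is descriptive.
* With six timepoints per course, |ρ| > 0.7 occurs in roughly 13% of null
  profiles; guilt-by-association power and specificity come from the
  family-level enrichment and joint FDR, not from the correlation cut
  alone.
* The segmentation threshold is applied to the merged locus (equivalent to
  the pre-merge reading for qualifying regions, and switchable).
* Coverage-derived extents are integers; heavy ties would make the
  permutation p conservative at very high depth with no boundary jitter.
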