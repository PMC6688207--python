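# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic-data generator does and does not emulate,
and the design decisions that were genuinely open.

## Coordinates and interval algebra

All coordinates are 0-based, half-open (BED convention); readers convert on
input. Strand is carried through I/O but ignored by overlap, distance and
merge operations — the peak/repeat analyses here are strand-agnostic, and the
only strand-aware computation is locating a gene's TSS. `merge` joins
book-ended intervals (gap = 0), matching the common bedtools default, so
consensus regions stay contiguous.

`shuffle` re-places each interval with a uniform random start, preserving its
length. The default policy keeps each interval on its own chromosome; a
genome-wide policy (chromosome chosen with probability proportional to the
number of valid start positions) and an optional exclusion set
(rejection-sampled) are available. Nothing is known about gap or mappability
masking in the motivating analyses, so the default excludes nothing.
Shuffled intervals may overlap one another; the null only needs the marginal
placement distribution to be uniform.

The container is columnar (numpy arrays sorted by chromosome and start)
because the permutation null executes tens of thousands of shuffle +
overlap-count cycles; merged-subject binary search makes each count
O(n log m).

## Consensus peaks

Candidates are the merged union of all replicate peaks. A replicate supports
a candidate if any of its peaks overlaps it by ≥ 1 bp; candidates supported
by fewer than `min_support` replicates (default 2 of 3) are dropped, and the
retained consensus interval is the merged span. Two open choices were
resolved as follows: support is counted on the merged region (any-bp overlap)
rather than requiring summit-level agreement, because it is the simplest
reproducible geometry; and the consensus coordinate is the merged span rather
than the intersection, because intersections can vanish for staggered peaks
that clearly describe one site. Replicate peak scores are averaged into an
informational consensus score; no reproducibility model (IDR) is applied.

With per-replicate sensitivity *s* and no false positives, a planted site
survives 2-of-3 with probability 3s²(1−s) + s³ (0.972 at s = 0.9); the
acceptance suite checks recovery against the binomial 95% interval of that
expectation at 500 sites.

## Peak categorization

Precedence ICR > repeat > unique. The ICR override exists so the
internal-control set supplied by the user is never absorbed into TE counts.
Among overlapping repeat elements the one with maximal overlap wins, ties
resolving to the leftmost element, which makes the call independent of
annotation order; a ≥ 1 bp overlap suffices (no reciprocal-overlap
requirement). TE status follows the repeat class (LTR, LINE, SINE, DNA).
Category percentages are rounded half-up to one decimal, the convention of
printed count tables; when supplied counts do not exhaust the total, the
residual is reported as an explicit `other` class instead of being forced
into the named ones.

Gene features use precedence promoter > exon > intron > intergenic with a
promoter window of ±1 kb around the strand-aware TSS (configurable; no
standard definition exists).

## Permutation enrichment

Each iteration shuffles the peak set and counts shuffled peaks overlapping
the annotation (≥ 1 bp). The null per-peak hit probability is pooled:
p₀ = total null hits / (iterations × peaks). The observed hit count is then
tested as Binomial(n peaks, p₀), one-sided "greater" by default. Pooling is
what lets 100 iterations support p-values far below 1/100 — the iteration
count controls the precision of p₀, not the p-value floor. A per-iteration
empirical p (add-one corrected) is also reported; if the annotation is never
hit under the null, the p-value is floored at 1/(iterations × peaks) and
flagged. Treating the estimated p₀ as known slightly understates the
variance; the calibration test (200 true-null runs) shows the realized
type-I rate stays at or below nominal for the problem sizes used here.

The nearest-distance group comparison uses Welch's unequal-variance t test on
log10(1 + d)-transformed distances by default (genomic distances are
heavy-tailed); the raw scale is available. Peaks on chromosomes with no
subject interval are dropped from the test.

## Chromatin-state calling

Enrichment of a peak in a track is the mean coverage over the peak ± 250 bp,
divided by the genome-wide mean of that track (uncovered bases count as
zero). This total-coverage normalization stands in for library-size scaling;
input subtraction is not modeled. The state rule, with defaults
floor b = 1.5, r_lost = 0.25, r_retained = 0.75, ε = 0.01:

- not-enriched-in-WT if WT enrichment < b (excluded from tallies),
- LOST if mutant enrichment < b and (mut+ε)/(wt+ε) ≤ r_lost,
- RETAINED if the ratio ≥ r_retained,
- PARTIAL otherwise.

The three-state scheme reflects the empirical distinction between complete
loss and intermediate loss at a minority of loci; the thresholds are explicit
and tunable rather than inferred. Because the call depends only on the
ratio (plus the background floor), it is invariant to rescaling both tracks
by a common factor. For two-state concordance PARTIAL collapses to RETAINED
(conservative toward retention); agreement is reported with Cohen's κ.

Heatmap matrices bin mean coverage across peak center ± flank (default
2 kb, 40 bins); windows clipped at chromosome ends are zero-filled and
flagged. Aggregate profiles are column means with standard errors and a
paired difference.

Co-binding partitions count a region as co-bound if it overlaps (≥ 1 bp)
both a ZFP57 peak and a KAP1 peak. Note that when the region universe is
itself the ZFP57 consensus set, co-binding is high by construction; the
operation is meaningful for independently derived region sets, and the
percentage arithmetic (e.g. 91 of 583 → 15.6%) is covered by the worked
examples.

## Target integration

Gene–peak distance is measured gene-span-to-peak (TSS anchoring available)
with a strict `<` at the 20 kb default cutoff. The differential-expression
flag defaults to adjusted p < 0.05 and |log2FC| ≥ 1; the generator plants
effects far beyond both, so results are insensitive to the exact rule.
Direct-target nomination requires, by default: proximal, DE, upregulated in
the knockout, upregulated in the DNMT-TKO, and H3K9me3 LOST at the gene's
nearest peak; each clause can be toggled. Multi-KZFP overlap reports counts
per exact membership pattern (summing to the primary set size) plus the full
intersection.

## Methylation dynamics

Germline-DMR classes use only the gamete methylomes: OOCYTE if oocyte ≥ hi
and sperm ≤ lo (defaults 0.75/0.25, following common gDMR practice), SPERM
symmetric, BOTH if both ≥ hi, else NONE; missing gamete data gives NONE.
Blastocyst retention is the ICM methylation divided by that of the
methylated gamete (mean of both for BOTH); it is undefined (NaN) below a
minimum gamete methylation of 0.05. The blastocyst-equivalent stage is ICM
by default and selectable.

A transient DMR requires allele layers: maternal − paternal ≥ δ (default
0.3) at blastocyst *and* resolution in the epiblast (allele difference below
δ with total epiblast methylation ≥ hi). A persistent allele difference — an
imprint — is therefore not transient by definition.

Group comparisons use the Mann–Whitney rank-sum test, two-sided. For groups
of ≤ 12 each, an exact permutation distribution is computed by dynamic
programming over doubled midranks (exact under ties, where the classical
no-tie tables do not apply); larger groups use the tie-corrected normal
approximation with continuity correction. The two branches agree within
|Δp| ≤ 0.01 at the crossover size on random data.

## Synthetic-data generator

The generator plants, by default, 300 sites on a 4 × 2 Mb genome: 20
ICR-like internal controls (17 losing H3K9me3 completely in mutants, 3
partially; 3 paternal), and the remainder split TE 0.839 / unique 0.133 /
non-TE repeat 0.013 with unique sites 52/48 lose/retain and TE sites 2.2%
lose — the proportions of the motivating study. Two thirds of TE sites sit
on one dominant IAP-like LTR name. Retained unique sites get a planted LTR
element 0.5–2 kb away, losing unique sites are kept ≥ 12 kb clear of any
repeat, so the nearest-LTR distance contrast is real by construction.
Unique/ICR sites keep ≥ 22 kb clearance from all other sites so that a gene
anchored to one of them has it as the unambiguous nearest peak.

Replicate peak calls apply sensitivity 0.9, ±30 bp edge jitter and a 10%
false-positive rate per replicate. Signal tracks are 50 bp-binned gamma
background (mean 1, sd 0.25) plus Gaussian bumps (σ = 150 bp) with
amplitude 12 × a state factor (LOST 0, PARTIAL 0.40, RETAINED 1; KAP1 at
retained TE sites 0.55 in the knockout, emulating reduced co-repressor
recruitment without H3K9me3 loss) and 10% lognormal amplitude noise. The
dedicated state benchmark spaces peaks 20 kb apart so bump mass stays a
small fraction of the genome mean — at realistic peak densities the
genome-mean normalization otherwise biases mutant/WT ratios upward.

Expression tables plant direct targets (anchored to losing unique sites) and
imprinted-like genes (anchored to fully losing ICRs) upregulated in both
mutants (log2FC ≈ 3 and 2.5); secondary DE genes are placed ≥ 25 kb from
every site with knockout-only effects, and a small proximal-down group sits
near retained sites, giving the planted asymmetry between up- and
down-direction cross-mutant agreement.

The methylation matrix plants bound regions in classes BOTH/OOCYTE/SPERM at
42/6/11 with 100 unbound controls, gamete methylation 0.85 (0.04 for the
unmethylated gamete), maternal-allele retention 0.60 when bound and
protected versus 0.30 otherwise (the 0.3 gap used by the power checks),
paternal alleles unprotected (0.38 at bound both-gamete regions, keeping
their allele difference below δ), ICR retention 0.90 with persistent
asymmetry, epiblast remethylation to 0.85 for non-imprinted regions, and
Gaussian noise of 0.03 (0 for noiseless-limit checks). Sperm-class regions
are planted unprotected regardless of binding. An H3K9me3-level matrix
mirrors the bound/unbound gap in the oocyte and post-fertilization stages,
with sperm chromatin near zero.

Every output draws from its own RNG stream derived from the master seed by
stable sub-seeding, so adding outputs never perturbs existing ones, and two
runs with the same seed are byte-identical.

**What the generator does not emulate:** read-level sampling and mapping
(no FASTQ, no mappability structure, no multi-mapping ambiguity at repeats),
GC or chromatin-state-matched backgrounds, correlated replicate noise,
peak-width/signal heterogeneity beyond lognormal amplitudes, overlapping or
nested repeat annotation of real genomes, and biological coupling between
methylation and expression beyond the planted flags. Passing tests therefore
demonstrate that the statistical machinery recovers planted structure under
idealized noise — not that the defaults are robust to the full messiness of
real ChIP-seq.

## Problem sizes and determinism

Default scales (300 sites, 8 Mb genome, 100-iteration permutations,
200-run calibrations, 200+200-region cohorts) keep the full test suite under
about a minute of compute and an end-to-end pipeline run at a few seconds,
while leaving every statistical check well-powered. Reports contain no
timestamps; JSON is written with sorted keys, so identical configuration and
seed reproduce every artifact byte for byte.

## Known limitations

- The pooled-null binomial treats the estimated null probability as known;
  at very small iteration counts the p-value is anti-conservative in
  principle (empirically controlled at the sizes used here, and the
  per-iteration empirical p is available).
- Enrichment quantification has no input-track subtraction; tracks with
  strong background structure would need external normalization first.
- Nearest-peak attribution for genes ignores farther peaks that are still
  within the window; a gene whose nearest peak retained H3K9me3 is not
  nominated even if a lost peak lies slightly farther away.
- The exact rank-sum branch enumerates up to 12-per-group; above that the
  normal approximation is used even when ties are extensive.
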