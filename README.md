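# kzfpchip

Analysis pipeline for KRAB zinc-finger protein (KZFP) ChIP-seq target studies
of the ZFP57 type: where does a methylation-sensitive KZFP bind (imprinting
control regions, unique sequence, transposable elements), which of its targets
lose the repressive KAP1/H3K9me3 machinery when the protein is knocked out,
how does that interact with DNA methylation (DNMT triple-knockout
comparison), which nearby genes respond transcriptionally, and which bound
germline-methylated regions stay protected from the post-fertilization wave
of demethylation.

It is written for epigenomics analysts who have replicate peak calls, repeat
annotation, coverage tracks, differential-expression tables and stage-resolved
methylation matrices, and want the downstream classification and statistics
reproducible end to end. A synthetic-data generator with planted ground truth
exercises every stage without any external download.

## What it computes

- **Consensus peaks** — regions called in ≥ k of n replicates (default 2 of 3).
  Candidates are the merged union of all replicate peaks; a replicate supports
  a candidate by ≥ 1 bp overlap.
- **Peak categories** — precedence ICR > repeat > unique; repeat assignment by
  maximal overlap; TE iff the element class is LTR/LINE/SINE/DNA. Percentages
  use half-up one-decimal rounding, e.g. counts {unique 189, non-TE repeat 19,
  TE 1194} of 1423 → 13.3 / 1.3 / 83.9 %.
- **TE enrichment** — a length-preserving permutation null: each peak is
  re-placed uniformly (same chromosome by default), the per-peak null hit
  probability is pooled over all iterations, and the observed hit count is
  tested with a binomial tail, so 100 iterations can still resolve
  p ≪ 0.01.
- **Chromatin-state calls** — per peak, mean coverage over peak ± 250 bp
  normalized to the genome-wide mean, in wild type and mutant; LOST if the
  mutant is at background (< 1.5×) with ratio ≤ 0.25, RETAINED at
  ratio ≥ 0.75, PARTIAL between; plus signal heatmap matrices, aggregate
  profiles, cross-genotype concordance (agreement + Cohen's κ) and
  ZFP57/KAP1 co-binding partitions.
- **Target integration** — genes strictly closer than 20 kb to a peak,
  crossed with differential expression, cross-mutant fold-change direction
  concordance, direct-target nomination (proximal ∧ DE ∧ up in both mutants ∧
  peak H3K9me3 LOST), and multi-KZFP Venn counts.
- **Methylation dynamics** — germline-DMR classes from gamete methylomes
  (oocyte/sperm ≥ 0.75 vs ≤ 0.25), blastocyst retention scores, transient
  maternal DMRs (allele difference ≥ 0.3 at blastocyst, resolved in the
  epiblast), and bound-vs-unbound Mann–Whitney comparisons per stage (exact
  permutation distribution for small groups, tie-corrected normal
  approximation otherwise).

## Worked example

```bash
kzfpchip simulate --seed 2 --outdir sim/
kzfpchip run-all --input-dir sim/ --outdir out/ --seed 2
```

The simulated bundle plants 300 binding sites (20 ICR-like controls; 84 % of
the rest on TEs, mostly on an IAP-like LTR name; unique sites split 52/48 into
losing/retaining). `out/report.json` from the run above contains, among
others:

```
"consensus":  {"n_consensus_peaks": 296, "n_replicates": 3}
"classify":   {"percentages": {"TE": 79.4, "UNIQUE": 12.5, "ICR": 6.8, "NONTE_REPEAT": 1.4}}
"enrich":     {"fold_enrichment": 9.40, "p_value": 3.5e-191}
"states":     {"concordance": {"KO_vs_TKO": {"agreement": 1.0, "kappa": 1.0}}}
"integrate":  {"n_direct_targets": 19,
               "direction_concordance": {"up_agreement": 1.0, "down_agreement": 0.75}}
"methdyn":    {"gdmr_classes": {"BOTH": 91, "NONE": 1, "OOCYTE": 53, "SPERM": 34},
               "icm_p": 5.3e-13}
```

Reading: 296 of the 300 planted sites survive the 2-of-3 rule (replicate
sensitivity is 0.9, so ≈ 97 % is expected); the shuffled-null enrichment of
peaks in TE annotation is ~9-fold and overwhelmingly significant; knockout and
DNMT-TKO H3K9me3 states agree perfectly because they were planted from the
same truth; 19 of the 20 planted direct-target genes are recovered (one anchor
site fell below the replicate-support threshold), and only upregulated genes
agree in direction across the two mutants; bound regions keep significantly
more methylation at the blastocyst (ICM) stage than unbound ones.

Every number in the report is recomputable from the stage TSVs next to it;
rerunning with the same config and seed reproduces every output byte for
byte.

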