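# Methods

## The design being modeled

One library per genotype: an F1 hybrid (H) and its two parental species
(P1 = tiger puffer, P2 = tawny puffer), each a pool of tissues from a
single individual, sequenced as 50 bp single-end fragments. With no
biological replicates, "differential expression" can only mean a
difference in relative fragment abundance between two libraries, and
every downstream claim (gene action, heterosis mode) is a statement about
the three point estimates per transcript. The package makes those
limitations explicit rather than hiding them: the test is a conditional
two-library test, and the gene-action rule is a tolerance rule on point
estimates.

## Quantification

FPKM for transcript *t* in sample *s* is

    fpkm_ts = count_ts / ((len_t / 10^3) · (N_s / 10^6))

with `len_t` the summed exon length from the gene models and `N_s` the
fragment total used as the depth denominator. Two choices of `N_s`
coexist deliberately:

* **realized totals** (the literal definition) for the per-sample
  abundance summaries — detected = FPKM > 0, low-abundance bin
  0 < FPKM < 1, high-abundance bin FPKM > 100, per-sample unique sets,
  union/intersection sizes;
* **effective library sizes** for everything comparative (DE test
  margins, fold changes, gene-action classification), see
  *Normalization* below.

Gene-locus coverage is the fraction of locus bases (min exon start to max
exon end over the gene's transcripts) covered by ≥ 1 read interval,
computed by interval union; a per-base oracle checks it in the tests.
Coordinates are 0-based half-open internally; GTF's 1-based closed
convention is converted at the reader boundary (gffutils does the
parsing).

The alignment score is `len − nm·(1+mp) − jp`, where `len` counts
alignment hits, `nm` mismatches, `mp` is the mismatch penalty (default
1.0) and `jp` a flat junction penalty (default 0.0) applied only to reads
flagged as junction alignments. Score CDFs report, per threshold, the
fraction of reads at or above it. Reported percentages throughout use
half-up rounding at one decimal place.

## Normalization

With overdominance-heavy gene action the hybrid library carries far more
FPKM mass than either parent at equal depth, so realized totals misstate
relative sequencing depth — the classic composition problem, made severe
here because the changed fraction can exceed a third of transcripts and
is almost entirely one-sided. The median-of-ratios estimator (DESeq
style) breaks down in that regime: the median of the hybrid's count
ratios lands inside the *changed* tail, not the unchanged block. The
package therefore estimates relative depth as the **mode** of the log
count ratios to the per-transcript geometric mean (kernel-density peak
over transcripts expressed in all samples): unchanged transcripts form
the largest coherent ratio cluster, so the density peak tracks them even
under heavy one-sided change. `median_ratio` and raw `total` remain
available as config options (`normalize=`); with fewer than 50 usable
transcripts the estimator falls back to the median. Size factors are
rescaled so their mean equals the mean realized total, keeping FPKM on a
familiar scale.

## Differential test

For a transcript with counts (a, b) in two libraries with effective sizes
(T_a, T_b), condition on n = a + b: under equal relative abundance,
a ~ Binomial(n, T_a/(T_a+T_b)). With extra-Poisson noise the conditional
law is wider; for gamma–Poisson (negative binomial) counts with common
dispersion d at balanced totals it is beta-binomial with shape k = 1/d,
inflating the binomial variance by

    φ(n) = (n + 2k) / (1 + 2k).

`call_de` plugs this per-transcript φ into a quasi-binomial normal
approximation (two-sided); with d = 0 it uses the exact binomial test.
The assumed dispersion is a config knob (`nb_dispersion`, default 0.1),
since one library per genotype gives no way to estimate it. The normal
approximation of the platykurtic beta-binomial is slightly conservative,
which the null-calibration tests confirm (raw rejections ≤ α).

FDR is Benjamini–Hochberg within each comparison separately (subgroup
membership is defined per comparison). A call is significant iff
fdr ≤ α (default 0.05) and |ln ratio| ≥ `min_abs_ln_ratio` (default 0).
Fold changes are ln(x/H) with x the parent (ln(P1/P2) for the parental
comparison) on FPKM plus a pseudocount (`pseudo_fpkm`, default 0.1 FPKM)
so zero-expression transcripts stay finite; up_in_hybrid ⇔ ln(x/H) < 0.

## Subgroups and gene action

The significance pattern over (H vs P1, H vs P2, P1 vs P2) maps each DT
to exactly one subgroup: unique patterns give HTiU/HTaU/PPU, the
two-comparison patterns give HP1 (= HTi ∩ PP), HP2 (= HTa ∩ PP) and HPco
(= HTi ∩ HTa, the hybrid-specific core), and the all-three pattern gives
co. PPU members are not hybrid DTs and are excluded from gene-action
summaries.

Classification works on pseudocount-adjusted FPKM with m = min(P1,P2),
M = max(P1,P2), mid = (P1+P2)/2:

* ln(H/M) > τ → `above_high`; ln(m/H) > τ → `below_low`;
* otherwise the nearest of {m, mid, M} in |log distance| gives
  `low_parent` / `mid_parent` / `high_parent`; any exact tie goes to
  `mid_parent` (identical parents collapse all three anchors, and calling
  additivity there is the conservative reading).

τ operationalizes "approximately equal"; the default ln 1.5 means levels
within 1.5-fold of an anchor count as that anchor. Low/high parent follow
the *values*, not the sample labels, so relabeling P1↔P2 never changes a
category. Fold-change bins split at |ln| = 2: Up1 (−2 ≤ ln < 0), Up2
(ln < −2), Down1 (0 < ln ≤ 2), Down2 (ln > 2); exact boundaries join the
bin nearer zero and ln = 0 falls in no bin.

## Enrichment

Per GO term annotating ≥ 1 test-set member, a 2×2 table of test vs
reference-minus-test membership; p is the upper hypergeometric tail
(identical to one-tailed Fisher, over-representation only), FDR is BH
across tested terms, and a term is enriched iff fdr < 0.01
(`filter_value`). The reference margin excludes test members so the two
columns are disjoint. Annotations are first propagated to all is_a
ancestors (true-path rule) when an ontology is supplied. Levels follow
the summary-tool convention: a namespace root is level 1 and
level(t) = 1 + min over parents; projecting an annotation to level L
replaces it by its ancestors at exactly L (terms nearer the root than L
project to nothing). Per-term fold-change crosstabs count one entry per
member transcript per parental comparison, so a transcript with both
ln(P1/H) and ln(P2/H) non-zero contributes twice.

## The synthetic generator

`simulate.SimulationConfig` fixes the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_genes | 2000 | gene loci; isoform count per gene from `isoforms_per_gene` ({1: .55, 2: .30, 3: .15}) |
| baseline_log_mean/sd | 1.0 / 1.0 | log-normal baseline abundance (FPKM scale) |
| frac_null | 0.5 | transcripts with H = P1 = P2 |
| mode_proportions | 6.8/10.3/4.6/9.5/68.7 % | mode mix among non-null transcripts, mirroring the reported category marginals |
| effect_size_delta | 2.0 | log-scale parent separation and over/under-dominance margin |
| nb_dispersion | 0.1 | count noise, var = μ + d·μ² (gamma–Poisson) |
| library_size | 10^6 | nominal fragments per sample |
| seed | 0 | master seed; each stage uses a derived substream |

Non-null transcripts draw a mode; parents sit `effect_size_delta` apart
in log space wherever the mode needs distinct parents (always for
low/mid/high parent — the modes coincide otherwise — and with
probability 1/2 for above_high/below_low, whose equal-parent half is the
planted hybrid-specific core that seeds HPco and the GO truth set). The
hybrid mean is then *exact*: mid-parent mean, the lower/higher parent, or
`effect_size_delta` beyond the extreme parent. Expected fragment counts
are fpkm·(len/10^3)·(library_size/10^6).

One shared scale factor sets the *average* per-sample FPKM mass to 10^6
kb-normalized units, so the average expected library equals
`library_size` while every planted ratio stays exact. A per-sample
normalization would equalize each library's expected depth but destroy
the exact hybrid/parent relations whenever the mode mix is
mass-asymmetric (above_high at δ = 2 contributes e³ × baseline), and
the two cannot hold simultaneously; with the default overdominance-heavy
mix the hybrid library is genuinely heavier, which is precisely the
composition effect the normalization section addresses. Per-sample depth
conservation is therefore exact under balanced mixes (all-null or
mid-parent-only), and that is how the property is tested.

GO truth: every transcript is annotated to each of `n_terms` synthetic
terms at `background_rate` (0.05); the first `n_enriched` (5) terms hit
the planted hybrid-specific set at `enrichment_factor` (5) times that
rate. Factor 1 plants nothing and flags nothing as truth.

What the generator does *not* emulate: multi-tissue pooling within a
genotype, sequence content and alignment (counts are assigned, not
mapped), multi-mapping ambiguity, isoform-level quantification
uncertainty (isoforms draw independent abundances), length biases, and
between-individual biological variation. Passing recovery tests
therefore show the pipeline's logic and calibration are right under its
own noise model, not that single-individual designs estimate gene action
robustly in real fish.

## Numerical and degenerate-input choices

* Contract violations (negative counts, empty loci, empty score sets,
  p-values outside [0,1]) raise typed errors; configuration errors name
  the offending field.
* n = 0 fragment pairs give p = 1 ("no evidence"); φ is clipped to ≥ 1.
* FPKM conservation (Σ fpkm·kb·N_s/10^6 = Σ counts) holds to 1e−9
  relative and is tested.
* The density-peak size factor uses a 512-point grid over the observed
  ratio range with scipy's default KDE bandwidth.
* Determinism: one master seed, `numpy` Generator substreams per stage
  ([seed, stage] seeding); identical config ⇒ byte-identical GTF/TSV/JSON
  outputs, which the pipeline tests assert.

## Problem sizes used in validation

Null calibration runs 200 Monte-Carlo count replicates over ~2,000
transcripts (≈1.2 M tests) and 60 annotation replicates × 50 terms;
recovery runs one study-sized pipeline (2,000 genes, ≈3,200 transcripts)
at δ = 2, τ = ln 1.5, d = 0.1, library 10^6. At these sizes the whole
suite completes in well under a minute; recovery of planted categories
among called hybrid DTs sits at 91–93% across seeds, dominated by the
above_high majority — the mid/high/low-parent anchors are only ~0.57 log
units apart at δ = 2 while the per-sample log-FPKM noise at d = 0.1 is
~0.32, so those rarer categories individually misclassify more often, an
honest reflection of how close those hypotheses are at this noise level.

## Known limitations

* The DE test treats the assumed dispersion as known; misspecifying
  `nb_dispersion` shifts calibration (conservative if set too high).
* The mode-based size factor needs the unchanged transcripts to form the
  largest ratio cluster; designs where most transcripts change in the
  same direction will still defeat it.
* Gene-action categories are point-estimate classifications with a fixed
  tolerance; no uncertainty is attached to a category call.
* Enrichment tests terms marginally (no parent-child conditioning), so
  related terms rise and fall together.
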