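# Methods

Definitions and design decisions for every analysis in `hybvigor`. All
thresholds quoted here are surfaced as named keys in the pipeline config
(`hybvigor.pipeline.DEFAULT_CONFIG`) and default to the values below.

## Study design

Three rice varieties — maternal line, F1 hybrid, paternal line — with
three biological replicates each (a full 3×3 design). `iolib.CountTable`
validates the design; analyses that need all nine samples (MPV test,
presence patterns) refuse partial designs.

## Normalization

- **Median-of-ratios size factors** (`express.size_factors_median_ratio`):
  for each sample, the median over all-positive features of
  count / geometric-mean-across-samples. When no feature is positive
  everywhere, a per-million fallback (column sums scaled to geometric
  mean 1) is used with a warning. The estimator assumes a non-DE
  majority; with most features shifted in one group the factors absorb
  the shift (composition bias). The synthetic benchmarks therefore
  include a 10× null background (see below).
- **FPKM** for linear transcripts: `count / (length/1e3) / (library/1e6)`.
- **SRPBM** for circRNA junctions: `junction_reads / mapped_reads × 1e9`.

## Differential expression

Self-contained negative-binomial Wald test (`express.nb_wald_test`):

1. Per-feature method-of-moments dispersion pooled over varieties,
   `alpha = (var − mean) / mean²`, shrunk 50/50 toward a fitted
   `a0 + a1/mu` mean–dispersion trend, floored at 1e-8.
2. Group mean of normalized counts with model-based variance
   `Var(K/s) = mu/s + alpha·mu²`.
3. Wald statistic on `log2(mu_b / mu_a)` (0.5 pseudo-count) with a
   delta-method standard error and a normal reference.

**DE call**: `|log2FC| > 1` and `p < 0.05` (raw p; Benjamini–Hochberg
available as an option, off by default to match the headline rule).
On 2,000 simulated null NB features the realized type-I rate at
`p < 0.05` falls in [0.03, 0.08] (acceptance criterion).

## Mid-parent value and non-additivity

MPV is the arithmetic mean of the two parental means. The MPV test
(`express.mpv_test`) compares the hybrid mean to the MPV using a
reference that pools the six parental replicates rescaled to the MPV
(parental within-group noise without the parental gap). Reported
`log2_mpv_f1 = log2(MPV / F1)`. **Non-additive**: `|log2(MPV/F1)| > 1`
and `p < 0.05`.

## 12-state inheritance classification

States: additive-high/low, ELD-M-high/low, ELD-P-high/low,
transgressive-up/down-{M,P}, equivalent, ambiguous
(`express.classify_inheritance_one`). Decision order:

1. **equivalent** — no pairwise comparison passes the full DE rule.
2. **transgressive** — hybrid full-DE beyond both parents in the same
   direction.
3. Parents full-DE different → **nearest reference**: the hybrid is
   assigned to the maternal level (ELD-M), the MPV (additive) or the
   paternal level (ELD-P), whichever reference it sits fewest standard
   errors from (Wald |z| of the corresponding test, recovered from the
   two-sided p-value).
4. Nearest the MPV but still non-additive → **ambiguous**; everything
   else unresolvable → **ambiguous**.

Why nearest-reference rather than a significance test on the
hybrid-vs-parent legs: with an arithmetic MPV an exactly intermediate
hybrid is always within 2-fold of the high parent, so a test-based
additive rule has no power at the fold-change threshold. Measuring
distance in standard errors also weights each reference by its
precision (the MPV pools six replicates). On 200 planted features per
state (effect 2 log2 units, dispersion 0.05, n = 3) per-state recovery
is ≥ 90% and additive/equivalent features are flagged non-additive in
≤ 10% of cases (acceptance criterion; observed misflag ≈ 0).

## Presence patterns

A feature is expressed in a variety when ≥ 2 of 3 replicates exceed the
threshold (default 0 on normalized counts). The seven non-empty subsets
of {maternal, hybrid, paternal} map to patterns 1–7; nowhere-expressed
features get `none`.

## lncRNA annotation

- **Screen**: keep unknown transcripts > 200 nt whose longest ORF (both
  strands, three frames, ATG..stop inclusive) is < 300 nt (100 codons).
- **Positional classes**, most-specific-first precedence
  intronic > antisense > sense > lincRNA:
  - *intronic*: fully inside one intron, either strand, no exon overlap;
  - *antisense*: overlaps a gene span on the opposite strand;
  - *sense*: overlaps the gene on the same strand;
  - *lincRNA*: no gene-span overlap.
- **Meta-features** (one per locus, priority order): TE > ncRNA-locus >
  genic > gene-proximal (≤ 2 kb) > intergenic; `no-annotation` for
  chromosomes absent from the annotation set.
- **Small-RNA QC**: keep reads of 18–30 nt with ≤ 10% N bases.

## circRNA / back-splice detection

A junction read's 20 bp head anchor maps downstream of its 20 bp tail
anchor. Anchors align with ≤ 2 mismatches via a k-mer index (exact
20-mers plus three disjoint one-third seeds — pigeonhole guarantees one
exact seed under two substitutions). For each reversed-order placement
pair the breakpoint scan chooses the split minimizing total mismatches,
preferring splits flanked by the canonical signal (GT after the donor,
AG before the acceptor; CT..AC on the plus strand for minus-strand
circles). Score: match +1, mismatch −5 over the full read.

Grouped candidates (by chrom, acceptor, donor, strand) pass six rules:

1. GT/AG splice signal;
2. a single signal-consistent best breakpoint;
3. ≤ 2 mismatches per supporting read;
4. breakpoint ambiguity ≤ 2 nt;
5. ≥ 2 supporting reads;
6. best placement > 35 points above the runner-up.

On the seeded benchmark (50 kb genome, 20 planted junctions, one decoy
per rule, colinear reads) recall is 100%, every decoy is rejected, and
coordinates are exact (acceptance criterion). Reported coordinates are
0-based `[acceptor, donor)` in the plus-strand frame, id
`chrom:acceptor|donor`.

## Target prediction

- **miRNA sites** (`target.mirna_target_score`): ungapped antiparallel
  duplex; mismatch 1.0, G:U wobble 0.5, weights doubled at miRNA
  positions 2–13 (1-based); sites with penalty ≤ 4.0 kept. Gapped sites
  are a documented limitation.
- **lncRNA cis targets**: genes within 100 kb of the locus.
- **lncRNA trans targets**: mRNAs sharing a reverse-complement match of
  ≥ 100 nt at ≥ 90% identity (exact 20-mer seeding, greedy symmetric
  ungapped extension).
- **circRNA hosts**: smallest gene span containing `[acceptor, donor)`;
  otherwise intergenic.

## Networks

- **DE sets**: DE_HP = union of hybrid-vs-maternal and hybrid-vs-paternal
  significant features; DE_PP = parent-vs-parent significant set.
- **Regulator–target edges** keep pairs whose endpoints are both DE_HP.
- **ceRNA triads**: (sponge, miRNA, mRNA) where one miRNA targets both a
  DE_HP ncRNA and a DE_HP mRNA by complementarity.
- **Co-expression modules**: DE genes clustered by average linkage on
  (1 − Pearson) distance into k modules (default 4) on log2(norm+1)
  expression; genes with |r| < 0.3 to their module profile move to
  `unassigned`. Non-additive ncRNAs are called positively (r > 0.8) or
  negatively (r < −0.8) associated per module profile. This stands in
  for a full WGCNA: module membership is used only as a correlation
  target, so soft-thresholding/TOM machinery is out of scope.
- **circRNA–host correlation**: Pearson r between junction abundance and
  host expression over variety-level means, per pair and pooled.
- **Over-representation**: one-sided hypergeometric test against a
  user-supplied feature→term map.

## Synthetic data and benchmarks

`simdata.simulate_all` generates a complete study under one seed:
genome with genic/intergenic/TE structure and written splice signals,
lncRNA loci of all four classes, back-splice reads (plus one decoy per
screening rule and colinear reads), 18–30 nt small-RNA reads peaking at
21/24 nt with QC decoys, planted perfect miRNA sites (one mRNA and one
ncRNA sponge per miRNA, plus scrambled decoys), and NB count tables
with planted inheritance states, presence patterns and per-sample size
factors log-uniform in [0.7, 1.4].

`simulate_inheritance_benchmark` plants 200 features per state plus a
10× null background: median-of-ratios normalization needs a non-DE
majority, and without the background the hybrid's size factor absorbs
the planted composition (the arithmetic MPV exceeds the geometric mean,
so an all-DE panel shifts the hybrid's median ratio by ~0.7 log2).

## Determinism

All randomness flows through `numpy.random.default_rng` seeded from the
config; the pipeline writes a SHA-256 manifest and a rerun with the
same seed reproduces every hash (acceptance criterion).
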