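# Methods

`hybrase` infers allele-specific expression (ASE) in an interspecific
prokaryotic hybrid — a single cell line carrying two complete,
syntenic parental genomes — and tests whether groups of functionally
related genes show coordinated allelic bias toward one parental
lineage, the signature of polygenic lineage-specific selection on
cis-regulation. Because both alleles share one trans-acting
environment, any reproducible allelic imbalance must be cis-encoded.
This note documents the model, its assumptions, the tunable
parameters, and the design decisions taken where the procedure was
genuinely open.

## Mappability masking

Hybrid reads can only be assigned to a parent where the local sequence
is unique across *both* genomes. A window of the mapping read length
(default 75 bp) slides with step 1 over every replicon of both
parents; a window is unique iff its sequence occurs exactly once among
all windows of both genomes, counting reverse complements (windows and
their reverse complements are compared through a strand-canonical
form). Every base overlapped by at least one duplicated window is
masked; bases covered by no window (replicons shorter than the window)
are masked too. Windows containing non-ACGT symbols are treated as
non-unique — conservative, since such positions cannot be matched
confidently.

Uniqueness here is **exact-match**: a deterministic, self-contained
criterion that a brute-force window-multiset enumeration can verify
base by base (the test suite does exactly that). Aligner-based
mappability with mismatch tolerance would mask somewhat more sequence;
exact matching keeps the semantics reproducible without an external
tool, and every downstream quantity consumes the mask identically
either way.

## Quantification and filtering

Per-ortholog coverage is summed over mappable positions only. RPKM
uses read equivalents (summed base coverage / read length), the
*mappable* length as the gene length, and the summed ortholog coverage
of that series as the library size. Allelic ratios are ratios of
coverage sums, so RPKM's global normalization cancels between alleles;
RPKM matters only where a per-unit density is needed (the copy-number
filter).

Three filters define the analysis set, applied in a fixed precedence:

1. **plasmid** — plasmid-borne units are excluded outright; plasmid
   copy number varies too much between the parents for coverage
   ratios to be meaningful.
2. **cnv** — a chromosome unit whose DNA RPKM lies more than 2 sample
   standard deviations from the across-unit mean is excluded. The
   mean/SD are computed per allele x replicate (four series) and a
   unit flagged in *any* series is dropped — the most conservative
   pooling against spurious ASE; a `pooled` switch computes one
   mean/SD over all four series. A degenerate series (SD 0) flags
   nothing. Note the rule intrinsically flags ~5% of units per series
   even without true CNVs; this is a property of the rule, not a bug.
3. **low_reads** — a unit needs at least `min_reads` (default 100)
   allele-summed RNA read equivalents in *every* replicate
   (unscaled coverage; the filter guards raw evidence, not normalized
   values). Units with zero mappable length are caught here or
   flagged `zero_mappable` when `min_reads` would pass vacuously.

**Chromosome scaling.** Parental chromosomal abundance in a hybrid is
not exactly 1:1. Per replicate, the higher-coverage parent and the
scaling factor are both taken from the chromosome DNA totals over
mappable positions (DNA coverage is the ploidy proxy); that parent's
DNA *and* RNA chromosome tracks are multiplied by the factor
`sum(low)/sum(high)`. DNA totals become equal; RNA ratios are
thereby measured against the copy-number baseline. We deliberately do
**not** force RNA totals equal: doing so re-centers every allelic
ratio by a global offset, and when the true effect distribution is
asymmetric (e.g., a planted directional gene set) that offset makes
genuinely null genes appear uniformly biased in the opposite
direction — at deep coverage, significantly so. Scaling against the
DNA baseline keeps null genes at ratio 0 and preserves genuinely
asymmetric genome-wide shifts as identifiable signal.

## The resampling ASE test

For each ortholog and replicate the observed cis ratio is

    log2( (sum cov_v + 1) / (sum cov_m + 1) )

with sums over mappable coding positions and a pseudocount of 1
against division by zero. Its significance is judged against two
empirical nulls that capture how much ratio variation the sequence
differences *alone* can generate. Let pi_v, pi_m be the marginal
nucleotide frequencies over each allele's mappable positions, and
length_v, length_m the mappable lengths. The sampling operator
X(cov, P(pi)) picks a nucleotide by pi, then uniformly one of the
source allele's positions carrying that nucleotide, and returns its
(scaled) coverage. One null draw from the v allele's perspective is

    H_v0 = log2( (sum over length_v of X(cov_v, P(pi_v)) + 1)
               / (sum over length_m of X(cov_v, P(pi_m)) + 1) )

and symmetrically H_m0 from the m allele. The numerator resamples the
allele at its own length and composition; the denominator resamples
the *same* coverage at the other allele's length and composition, so
a composition- or length-driven artifact appears in the null and is
absorbed. Under the source's own composition the operator reduces
exactly to a uniform bootstrap of its positions; the implementation
exploits this, and decomposes the cross-composition draw into a
multinomial over the four nucleotide classes followed by uniform picks
within each class — an exact, vectorizable identity (verified against
full enumeration on small alleles).

Numerical choices:

- If the other allele's composition puts mass on a base absent from
  the source allele, the frequencies are renormalized over the bases
  present; if *no* base is shared (possible only for degenerate,
  few-position alleles), the draw falls back to the source's own
  composition so it stays well-defined.
- Two-tailed empirical p-values use the add-one estimator,
  p = 2 min( (1+#{null >= obs})/(N+1), (1+#{null <= obs})/(N+1) ),
  capped at 1 — never zero, as appropriate for a Monte Carlo null.
  A `symmetric` tail rule (distance from the null median) is available
  as a config switch.
- Replicates combine conservatively: if both replicates agree in the
  sign of the ratio, the call keeps the *largest* of the four
  p-values (two nulls x two replicates); disagreeing (or exactly
  zero) ratios make the call discordant, which is excluded from FDR
  adjustment and can never be significant.
- Benjamini–Hochberg step-up with monotone q-values at FDR 5%
  (statsmodels implementation, cross-checked against a hand step-up
  in the tests). Positive ratios denote the first-listed allele;
  the convention is recorded in every output header.

The test is deliberately conservative (max-of-four combination plus an
add-one floor); on pure-null synthetic data the realized false-call
proportion is far below the nominal FDR.

## Operon similarity test

Adjacent co-transcribed genes share a promoter, so operon annotations
predict shared ASE. Genes on the first parent's chromosome are
ordered by coordinate; consecutive pairs where both genes share an
operon form one category, pairs where neither gene is in any operon
the other, and boundary-straddling pairs are dropped. Per-gene ratios
inside operons come from the member genes' own coordinates (the
annotation carries per-member intervals). The test samples
`n_resamples` pairs per category with replacement, takes the absolute
difference of the two genes' log2 ratios for each sampled pair, and
compares the two delta samples with a Kruskal–Wallis statistic whose
p-value comes from permuting category labels over the pooled sample
(ranks are fixed under permutation, so only rank sums are recomputed).

## The gene-set sign test

Significant calls are split by favored lineage and ranked by the
magnitude of their mean cis ratio; the test runs on all biased
orthologs and, optionally, on the top 50% most biased (floor(n/2),
ties broken lexicographically for determinism). For each catalog
category with at least `min_category_size` (default 10) members in the
biased set (a config switch counts annotated members instead), the
statistic is the 1-df chi-square goodness of fit of the direction
counts against 1:1, chi2 = (2k - n)^2 / n.

Because many categories are tested, the reported p-value is
permutation-based with a max-statistic null: direction labels are
shuffled across *all* biased orthologs (preserving both the
genome-wide direction split and every category's membership), every
eligible category's nominal p is recomputed, and the per-shuffle
minimum forms the reference distribution;
perm_p = (1 + #{min p <= observed p}) / (N+1). This yields
familywise (category-specific FDR) control: under a null catalog,
P(any category's perm_p <= a) <= a, which the tests verify by Monte
Carlo and, at small size, against exhaustive enumeration of label
placements. Operons count as single members (the ortholog unit is the
unit of evidence). Category eligibility is fixed before permuting
(membership does not change under label shuffles).

## The synthetic-data generator

The generator emulates the study system end to end with known ground
truth. Defaults (all configurable):

- **Genomes** — one chromosome plus one plasmid carrying 25% of the
  genome; 60% GC; ortholog units laid out sequentially with 20–100 bp
  intergenic gaps; 23% of units are operons of 2–4 genes (200–400 bp
  each, 10 bp intra-operon gaps). The second parent is derived from
  the first by i.i.d. substitutions at 13.4% per coding site —
  uniform over the three alternatives, with an optional GC-shifted
  mode that makes the alleles differ in composition (exercising
  exactly the artifact the resampling null corrects). Intergenic
  sequence is shared, so it is masked as ambiguous, as in a real
  hybrid's conserved regions.
- **Effects** — a point-mass null (fraction 0.5 of units at log2
  ratio 0) plus N(0, 1) cis effects; operon members share their
  unit's ratio. A planted category adds a directional shift (default
  20 members, 80% of them at -1 log2 unit toward the second lineage)
  against background categories of unshifted units.
- **Coverage** — independent Poisson counts per base per allele.
  DNA: mean depth (default 50x) x replicon copy factor x local CNV
  fold, genome-wide. RNA: restricted to unit bodies, with the allelic
  effect split symmetrically (2^(+t/2) vs 2^(-t/2)) so the expected
  allelic log2 ratio equals the true t. The chromosomal copy factor
  alternates which parent is over-represented across replicates
  (default ratio 1.2); each plasmid draws an independent copy ratio
  per parent and replicate (default 0.5–3x). A per-ortholog locus
  efficiency factor (lognormal, sd 0.1 log-units) multiplies a unit's
  mean coverage identically across alleles, assays and replicates,
  emulating reproducible capture/mappability bias: it disperses
  across-unit RPKM the way real libraries do — which is what makes
  the any-of-four CNV rule's union behave like its single-series rate
  — while cancelling exactly in every allelic ratio.
- **Determinism** — every stage derives an independent stream from
  (seed, stage-name); one seed reproduces the scenario byte for byte.

What the generator does *not* model: read-level sampling (fragments,
duplicates, sequencing error), rRNA contamination, GC-dependent
amplification curves, strand effects, or mismatch-tolerant mapping.
Passing tests therefore demonstrate the statistical machinery —
masking semantics, null calibration, error control, power on planted
structure — not robustness to alignment artifacts in real libraries.

## Calibration experiments and problem sizes

`hybrase.calibration` packages the standing experiments; the defaults
are sized for a desktop run (the package's own choice of scale):

- **Type-I error** — 1,000 chromosome orthologs, all null, 13.4%
  divergence with GC-shifted substitutions, 50x depth, two
  replicates, 2,000 resamples: the FDR-significant fraction is
  binomially consistent with <= 5% (in practice ~0, reflecting the
  conservative combination rule).
- **Recovery** — 500 orthologs, N(0,1) effects, 50x depth: Spearman
  rho between planted and observed mean ratios >= 0.9 (observed
  ~0.9999).
- **Sign-test power** — 400-ortholog background, half null, a
  20-member planted category (80% directional, shift 1) among three
  25-member background categories, 2,000 permutations: the planted
  category reaches perm_p < 0.01 in >= 90% of 50 seeded runs. The
  margin is real but modest (~93% across seed ranges); the binding
  losses are non-directional members voting the other way and
  residual filter attrition.
- **Sign-test calibration** — under random directions and a null
  catalog the familywise rate at alpha = 0.1 stays below 0.1.
- **Operon contrast** — 40% operons with shared effects: the median
  within-operon |delta log2 ratio| is far below the non-operon median,
  permutation p < 0.05 per replicate.

`scripts/acceptance.py` reruns all of the above from scratch plus the
two exact-oracle comparisons (window-multiset mappability;
enumeration of the resampling null on tiny alleles, total-variation
distance < 0.02 at 100,000 draws) and writes the measured numbers as
JSON.

## Known limitations

- Exact-match mappability understates the masking an aligner with
  mismatch tolerance would produce; masked fractions are therefore
  not comparable to aligner-derived figures.
- The 2-SD CNV rule's chance-flag rate means a few percent of clean
  units are always sacrificed; pooling (`cnv_pooling="pooled"`)
  halves the loss at some risk of missing allele-specific CNVs.
- With point-mass nulls and deep coverage, any residual global
  normalization error of order the ratio SE would surface as
  correlated weak calls; the DNA-baseline scaling keeps this below
  Poisson noise in the simulated regimes but real libraries may need
  a dedicated normalization check.
- The operon test consumes the annotation's member-gene coordinates;
  annotations without them cannot be tested per-gene.
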