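# Methods

This note documents the models and procedures implemented in `cernakit`,
the defaults they ship with, and what the synthetic benchmarks do and do
not demonstrate.

## Study design assumed

The toolkit targets short developmental time courses: S stages (default
4, labelled ST1, ST2, ST3-1, ST3-2) with R biological replicates each
(default 3), profiled with matched RNA-seq (genes + lncRNAs, raw counts)
and small-RNA-seq (miRNAs, RPM-scale abundances).  Comparisons are made
between adjacent stages.

## lncRNA identification cascade

A transcript is called lncRNA iff it passes, in order:

1. class code ∈ {u, i, x, o} (GffCompare vocabulary: intergenic,
   intronic, antisense-overlap, other same-strand overlap) — transcripts
   matching reference coding models are excluded;
2. spliced length strictly greater than 200 nt (200 exactly is rejected);
   the rule is applied to mature length, i.e. `len(sequence)`;
3. a non-coding call from a self-contained ORF rule: scanning the three
   forward frames for ATG..stop ORFs, the transcript is *coding* when the
   longest ORF reaches `min_orf_aa` (default 100) amino acids **or**
   covers `min_coverage` (default 0.5) of the transcript.  This single
   transparent rule plays the role that a consensus of coding-potential
   classifiers plays in practice; both thresholds are exposed in the API,
   CLI and pipeline config.  Gene lists from external classifiers will
   not be identical.

Records failing the cascade are labelled `other`, never dropped.

Small-RNA reads shorter than 18 nt are discarded; the remainder are
matched to known mature miRNAs by equal-length ungapped comparison at
Hamming distance ≤ 1 (mirroring one-mismatch short-read alignment);
ties resolve to the lowest mismatch count, then the lexicographically
smallest mature id.  Hairpin-based novel-miRNA prediction is out of
scope.

The lncRNA-vs-mRNA descriptive comparison reports mean length, the
exon-count distribution and per-transcript GC content, with a two-sided
Welch t-test on GC.  Welch (unequal variances) is used although the
classical presentation of such comparisons says "Student's t-test":
group variances are unknown and Welch is the safer default; with the
group sizes involved the two are practically indistinguishable.

## Normalisation and differential expression

FPKM_fs = counts_fs · 10⁹ / (length_f · libsize_s) and
RPM_fs = counts_fs · 10⁶ / libsize_s, with library size the column sum.

The DE test is a negative-binomial Wald test:

* size factors by median-of-ratios (geometric-mean reference), falling
  back to column-sum ratios when no feature is positive in all samples;
* log₂FC = log₂((mean_b + c)/(mean_a + c)) on normalised means with
  pseudocount c = 0.5 for stability near zero (exposed);
* per-feature dispersion φ by method of moments, pooling the within-group
  variances of the two groups (Var = μ + φμ²), floored at 10⁻⁸;
* the per-feature estimate is then shrunk toward the across-feature mean
  with prior weight `prior_df` = 50 against the feature's ~4 residual df.
  The heavy pooling is deliberate: with 2–3 replicates the per-feature
  estimate is nearly uninformative, and features with extreme chance fold
  changes also show deceptively small within-group variance, so weak
  pooling hands exactly those features spuriously small standard errors.
  With heavy pooling the test is close to a common-dispersion test with a
  mild tagwise adjustment, and its null behaviour is near nominal
  (measured raw-p < 0.05 fraction ≈ 0.05 on 2,000 simulated null
  features at μ = 100, φ = 0.1, 3 vs 3).  The across-feature *mean* is
  the shrinkage target because the MoM estimator is approximately
  unbiased, whereas its median sits systematically low at few df;
* Wald z = log₂FC / SE with the delta-method SE under NB variance,
  two-sided p from the normal reference; features all-zero in both
  groups are reported with log₂FC = 0, p = 1;
* Benjamini–Hochberg adjustment across features; significance means
  |log₂FC| > 1 **and** padj < 0.05.

Out of scope by design: fold-change shrinkage, GLM covariates, Cook's
outlier handling, independent filtering.  Consequently a genuinely
extreme chance draw (a ~3-fold split with small within-group variance)
can occasionally reach BH significance under the global null even with a
perfectly calibrated reference; tools that suppress such calls do so by
outlier replacement, which this test intentionally omits.

"Adjusted p-value" is read as Benjamini–Hochberg throughout (the default
of the standard NB-DE tools).  Significance of enrichment (below) is
instead flagged on raw p at α = 0.05, matching how over-representation
cutoffs are conventionally quoted; BH values are always reported
alongside.

## Temporal clustering

Stage means (not individual replicates) are row-standardised to mean 0,
population SD 1 — clustering sees only temporal shape.  Zero-variance
rows are flagged and excluded.  Standard fuzzy c-means with Euclidean
distance follows:

    u_ij = d_ij^(−2/(m−1)) / Σ_l d_il^(−2/(m−1)),
    c_j  = Σ_i u_ij^m x_i / Σ_i u_ij^m,

with k = 4 by default (the number of temporal patterns typical of staged
bud series: up, down, and two transient peaks; k is exposed since the
choice is conventional, and membership/centre diagnostics are emitted).
A point coinciding with a centre receives crisp membership there.
Initialisation is k-means++-style seeding from data rows under a fixed
RNG with 10 restarts, keeping the lowest objective — results are
deterministic given the seed.  The objective Σ u^m d² is asserted
non-increasing at every iteration; convergence is a maximum centre shift
below 10⁻⁶ (500 iteration cap).  The fuzzifier defaults to 1.25 and can
be estimated from the data dimensions by the Schwämmle–Jensen rule,
clipped to [1.05, 3].  Hard labels take the argmax membership when it
reaches 0.5 (ties to the lowest cluster index), else "unassigned".

## Target prediction

**miRNA sites.**  The reverse complement of the miRNA (18–26 nt) slides
ungapped along the transcript.  Per aligned position: match 0, G:U
wobble 0.5, mismatch 1.0; penalties are doubled at miRNA positions 2–13
(5'→3'), the seed-like region of plant-miRNA target schemas.  The
expectation of a site is the total penalty; the best site per
(miRNA, transcript) — plus exact ties — is reported when expectation ≤
cutoff (default 5.0, boundary inclusive).  The ungapped scan replaces a
Smith–Waterman variant on purpose: it is deterministic and verifiable
against an exhaustive brute-force scorer (a gap penalty of 2.0 is part
of the schema but unused by the default scan).  Cleavage-vs-inhibition
classification is out of scope.

**cis pairs.**  Coordinates are 1-based inclusive; the gap between
disjoint [a₁,b₁] and [a₂,b₂] (b₁ < a₂) is a₂ − b₁ − 1, overlap counts
as 0.  A lncRNA–gene pair is cis when on the same chromosome with gap ≤
10,000 bp ("10 kb" is inclusive; 10,001 fails).  Strand is ignored for
the distance and used only to orient the reported relation
(upstream/downstream of the lncRNA).  Distances are measured between
interval ends, not TSSs — a documented convention choice.

**trans pairs.**  An lncTar-flavoured stand-in: the best ungapped
antiparallel window duplex (default 40 nt) under per-pair energies
GC = −3, AU = −2, GU = −1, other 0 (arbitrary units); dg is minimised
over all offset pairs and ndg = dg / min(lengths).  Pairs with ndg ≤
threshold (default −0.1, boundary inclusive) are reported.  This is not
a thermodynamic model; it preserves the logical shape of pairing-energy
screening with fully specified arithmetic.

## ceRNA network

Candidate triplets are all (lncRNA, miRNA, mRNA) with the miRNA
targeting both partners (hit lists deduplicated to the (miRNA, target)
level, so the count is a product over shared miRNAs).  Filtering
computes, over the shared sample set (all 12 samples by default — more
points stabilise rank correlations; a sample subset can be passed):

* Spearman ρ(miRNA RPM, lncRNA FPKM) < −0.6,
* Spearman ρ(miRNA RPM, mRNA FPKM) < −0.6,
* Pearson r(lncRNA, mRNA) > 0.6, computed on log₂(FPKM+1) by default
  (rank-based ρ is scale-free; log stabilisation is standard for r, and
  a flag switches to raw values).

All three inequalities are strict; an undefined correlation (constant
member) fails the triplet.  The network keeps unique (miRNA, target)
edges of passed triplets; lncRNA–mRNA co-expression links are *not*
edges.  Both the triplet count and the deduplicated edge count are
reported, since "pair" totals in the literature can refer to either.
Exports: full candidate table with correlations and pass flags, edge
list TSV, and SIF (`node1 TAB interaction TAB node2`, interaction ∈
{mir-lnc, mir-mrna}).

## Enrichment

Over-representation by the hypergeometric upper tail P(X ≥ k) for k
study hits of a K-gene term, study size n, background N (all expressed
features by default, overridable), computed in log space via the stable
survival function.  One row per term with ≥ 1 study hit; raw-p
significance at 0.05 with BH alongside (whether published workflows
adjust GO p-values is often unstated, so both are emitted).

## Synthetic data generator

The generator is the test harness's ground truth and models:

* **counts**: NB via Gamma–Poisson mixture (Var = μ + φμ²; φ = 0
  degenerates to Poisson), lognormal baselines (log-mean 5.0, sd 0.5);
  miRNA abundances are emitted directly on an RPM-like scale because
  downstream stages consume miRNA expression in that unit;
* **temporal prototypes**: "up" is a geometric ramp 1 → effect (default
  4-fold) whose largest step sits at the middle transition — staged bud
  series concentrate their differential signal mid-course — with
  exponents (0, 1/12, 11/12, 1) at 4 stages; "down" is its mirror;
  "peak2"/"peak3" rise linearly to a maximum at stages 2/3; "flat"
  (the majority class, so null behaviour is testable) is constant.
  Within-stage dispersion defaults to φ = 0.02, the low-noise regime the
  recovery benchmarks assume; it is a free parameter because real
  tree-to-tree variability is design-specific;
* **planted triplets**: the miRNA takes the "down" prototype and its
  lncRNA/mRNA partners "up", and an exact 21-nt reverse-complement site
  is written into both partners.  Decoy transcripts are
  rejection-sampled so *no* miRNA scores ≤ the scanner cutoff anywhere
  in the background — target-scan truth is unambiguous;
* **sequences**: mRNAs carry a guaranteed long ORF (120–300 codons) with
  UTRs; lncRNAs are rejection-sampled to fail the coding rule; lncRNA GC
  content is drawn lower than mRNA GC (0.38 vs 0.45), mirroring the
  usual empirical contrast;
* **genome**: two chromosomes (2 Mb each by default), both strands,
  1-based inclusive coordinates.  Planted cis pairs are placed at a
  recorded gap ≤ 10 kb; every other neighbouring feature is placed
  > 10 kb away, so decoys are unambiguous.  Infeasible placements raise
  a generation error naming the constraint;
* **truth tables**: planted triplets, per-feature prototype labels,
  per-comparison DE truth (|log₂ prototype ratio| > 1), cis pair
  distances, and a term→gene map whose prototype terms cover exactly the
  mRNAs of each temporal class.

Identical configs (including seed) produce byte-identical files.

What the generator does **not** emulate: read-level artefacts (GC/length
bias, mapping ambiguity), splice isoforms, partially complementary or
multi-site miRNA targeting, correlated dispersion structure, batch
effects.  Passing recovery benchmarks therefore demonstrates the
pipeline's logic and statistics under its stated model, not performance
on real libraries.

## Benchmark problem sizes

The shipped benchmarks use: a recovery run with 10 planted triplets
among 200 decoy features (110 mRNA / 70 lncRNA / 50 miRNA, φ = 0.02,
4-fold effect); a 2,000-feature global-null calibration (μ = 100,
φ = 0.1, 3 vs 3); a 400-profile cluster-recovery set (noise sd 0.1 on
z-scored prototypes); and a paired determinism check of the demo
pipeline.  These sizes keep a full verification run under a minute on
one CPU while leaving the statistical conclusions stable across seeds.

## Known limitations

* The coding-potential, target-scoring and pairing-energy rules are
  transparent stand-ins for external tools (coding-potential
  classifiers, psRNATarget, lncTar); they preserve each filter's logical
  role but will not reproduce those tools' gene lists.
* The DE test has no outlier handling or fold-change shrinkage; see
  above for the tail-behaviour consequence.
* Heavy dispersion pooling assumes features share a broadly similar
  dispersion scale; strongly heterogeneous dispersions would be
  under-served at these replicate counts.
* The miRNA abundance matrix is small in typical designs, so
  median-of-ratios normalisation carries a compositional bias when a
  large fraction of miRNAs shift in one direction; results stabilise
  once a majority of miRNAs are stable.
* cis distances use interval ends; analyses defined from TSSs will
  differ for long genes.
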