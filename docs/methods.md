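# Methods

This note documents the models, rules and numerical choices behind
`pdxevo`, and what the synthetic engraftment simulator does and does not
emulate.

## Variant consensus filtering

Somatic calls are represented per sample as `(chrom, pos, ref, alt)` records
(1-based VCF coordinates; indels assumed left-normalized upstream — caller
reconciliation of alternative indel representations is out of scope). The
matched-normal roster has four callers (MuTect2, VarScan, Strelka, Pindel)
and keeps records called by at least two; tumor-only mode uses a
three-caller roster (Pindel needs a matched normal) and requires unanimity.
The threshold cascade is a pure conjunction, so predicate order is
irrelevant: tumor depth ≥ 14, normal depth ≥ 8, tumor VAF ≥ 0.05, normal
VAF ≤ 0.01, tumor alt reads ≥ 4 (boundaries inclusive), population allele
frequency < 0.001 and indel length < 50 bp (strict), exonic/splicing region
class only, multiallelic/DNP/TNP records excluded via a pre-pass flag, and
an optional upstream strand/PCR-bias flag honored when present. A missing
population frequency means the variant was absent from the population
databases and passes that cut; a missing *required* field is a validation
error, reported with the record, never a silent drop.

Paired rescue is exact-key: a mutation passing all filters in one sample is
added to the other iff any caller reported that exact key there in the raw
(pre-filter) output. Rescue never removes records and is idempotent;
rescued records carry `provenance=rescued`.

Mutational similarity is |shared| / |union| over a pair's final records;
mutation rate is mutations per Mb of capture.

## CCF estimation and consensus clonality

The CCF of a mutation with VAF *f* at purity ρ, tumor copy number n_t,
normal copy number n_n and multiplicity m is
`f (ρ n_t + (1−ρ) n_n) / (ρ m)`, with
`m = clamp(round(f/ρ (ρ n_t + (1−ρ) n_n)), 1, max(1, n_t))` estimated from
the same VAF. The 95% CI applies the identical linear map to a **Wilson**
binomial interval on (alt reads, depth); Wilson was chosen for its behavior
at low counts (the interval flavor is otherwise a free choice). CCFs and CI
bounds are clamped to [0, 2] internally and capped at 1 for reporting.

Three classifiers vote per sample:

* **ccf_ci** — clonal iff the CCF CI overlaps 1 (a CI entirely above 1 is
  also clonal).
* **binomial_mixture** — EM over k = 1..5 components in CCF space with
  binomial read-count emissions; the expected VAF of component θ at
  mutation *i* is c_i·θ with c_i = ρ·m_i / (ρ·n_t,i + (1−ρ)·n_n). The
  M-step uses the weighted moment solution Σr·alt / Σr·depth·c, exact when
  c_i is constant (the diploid common case) and a close quasi-Newton step
  otherwise. Ten random restarts per k with a fixed seed; model order by
  BIC with 2k−1 parameters.
* **kmeans_bic** — k-means on CCF point estimates (scikit-learn), k = 1..5,
  scored under the equal-variance Gaussian-*mixture* likelihood. The
  classic X-means hard-assignment likelihood is inconsistent and splits
  single Gaussian clusters; the mixture BIC does not. A Gaussian-mixture
  voter (`gaussian_mixture`, scikit-learn, BIC-selected) is also available.

Cluster labels become calls via: a single cluster is wholly clonal;
otherwise the highest-mean cluster is clonal (ties broken toward clonal)
and any other cluster with mean CCF > 0.9 is clonal too — a deliberate
slack for CCF uncertainty; the rest are subclonal. The consensus needs at
least two agreeing methods; with four methods a 2–2 split is ambiguous.
Mutations lacking copy number or purity stay `unclassified` and are
excluded, together with ambiguous calls, from the genetic-heterogeneity
denominator (whether ambiguous mutations should count there is not settled;
exclusion is this package's choice). Samples are clustered independently —
no joint PT/PDX clustering.

## Clonality flow and evolutionary patterns

Every mutation in a pair's union falls in exactly one cell of a
(PT state × PDX state) matrix with states clonal / subclonal / ambiguous
(ambiguous pools the unclassified) / absent. The flow records *promotions*:
shared mutations subclonal in the PT but clonal in the PDX, with their CCF
increase.

The original study classified patterns with manual review of VAFs and copy
number; `pdxevo` formalizes that as a fixed cascade with three exposed
thresholds (defaults chosen to reproduce the study's worked cases and then
left alone):

1. **branch seeding** if the lost-clonal fraction (PT-clonal mutations
   absent from the PDX, over all PT-clonal mutations) is ≥ `t_loss` = 0.5
   and at least one shared mutation is retained;
2. else **clone sweeping** if any promotion has CCF increase ≥
   `t_promote` = 0.4;
3. else **clone retention** if the retained-clonal fraction (PT-clonal that
   are also PDX-clonal) is ≥ `t_retain` = 0.8;
4. else unclassifiable. Pairs sharing no mutations are unclassifiable by
   construction (the cohort analysis excludes them).

Branch seeding precedes sweeping because clonal loss is its defining
signature — a branch-seeded pair usually *also* shows promotions of the
seeding branch. Group 1 = retention; group 2 = sweeping ∪ branch seeding;
the group is a pure function of the pattern.

Group comparisons use two-sided tests: Wilcoxon rank-sum (exact null for
n ≤ 25 per group without ties), paired t (zero-variance differences are
signalled, not NaN'd), Spearman correlation, and chi-square on 2×2 tables
without continuity correction.

Clonal neoantigens are counted from an external binding table as mutations
with best MHC IC50 ≤ 500 nM (inclusive) and consensus clonality clonal.
HLA typing, peptide generation and binding prediction are upstream and out
of scope.

## SCNA concordance

Coordinates are 0-based half-open internally; SEG files are 1-based
inclusive and converted on read. "Copy number ratio" always means the log2
ratio. Arm definitions come from a UCSC-style cytoband table; the exclusion
mask covers acen (centromere) bands plus a configurable `telomere_bp`
(default 10 kb) at each chromosome end.

* **WGD**: ploidy strictly above 2.5.
* **GI score**: per arm, the base-pair fraction of covered unmasked
  territory with |log2| > 0.3 (strict); the sample score is the unweighted
  mean over covered arms. Whether the original "proportion" was over
  segments, markers or base pairs is unstated; base-pair weighting is the
  package's choice, and both it and the binning are verified against
  per-base brute-force oracles.
* **Binned profiles**: 1-Mb windows, overlap-length-weighted mean of
  segment log2 ratios, NaN where uncovered; pairwise Pearson over jointly
  covered bins (≥ 3 required, zero variance signalled).
* **Focal events**: segments shorter than 50% of their arm (assigned by
  maximal overlap) with |log2| > 0.3 strict. Matching between samples is
  greedy 1-to-1 — same chromosome, same direction, both breakpoints within
  ± 10 kb inclusive — with ties resolved by the smallest summed breakpoint
  distance; the matching is symmetric in its arguments. Unmatched events
  are rescued when the paired sample's segmentation has a same-direction
  segment within the window at the relaxed strict threshold |log2| > 0.1.

Segmentation itself, purity/ploidy inference and recurrence-peak calling
are out of scope; purity and ploidy are inputs.

## Signature refitting

Spectra are tallied over the canonical 96 pyrimidine-centered trinucleotide
classes. Refitting minimizes ||spectrum − M·w||₂ over nonnegative w
(scipy NNLS) and renormalizes w to sum to 1 — a deliberate replacement of
deconstructSigs' iterative forward-selection heuristic by the direct
solution of the same objective family: deterministic, testable, and without
per-signature pre-exclusion or exposure scaling. Weights are invariant to
scaling the counts. Samples need ≥ 20 SNVs to be *eligible*; a fit is still
returned below that, flagged. For display, a signature is retained when its
weight reaches 0.25 in at least one sample, with a per-sample flag strictly
above 0.25. The signature matrix is an input file, never bundled; tests use
small synthetic Dirichlet matrices.

## The synthetic engraftment simulator

The simulator is the package's ground truth. A `ScenarioConfig` fixes a
clone tree whose CCF geometry defines one of four engraftment outcomes:

* **retention** — PDX clone CCFs equal PT CCFs (default tree 1.0 → 0.5 →
  0.25 as a nested chain);
* **sweeping** — a minor PT clone (default CCF 0.2, matching promoted
  mutations observed around VAF 0.09–0.12 at typical purities) reaches
  CCF 1 in the PDX while the former PT-major subclone (0.6) collapses to
  0.15;
* **branch seeding** — the PT major clone (0.95) holds most of the PT's
  mutations (default counts 5 truncal / 35 major / 10 branch, mirroring a
  pair that shared only 2 of 41 mutations) and vanishes from the PDX,
  whose major clone (CCF 1) is a sibling branch at PT CCF 0.05;
* **unrelated** — two disjoint trees, one per sample (the no-overlap
  pairs); this is the one scenario where PT and PDX copy-number profiles
  also differ.

Default purities are 0.7 (PT) and 0.9 (PDX) — xenografts run purer than
patient specimens — and the default depth is 300, a WES-like coverage.
Reads are drawn per mutation and sample: depth ~ Poisson(mean) truncated at
1 (the simplest defensible WES depth model; no overdispersion), alt reads ~
Binomial(depth, expected VAF) with the expected VAF following the purity /
copy-number dilution at the locus's integer CN. Mutations with zero sampled
alt reads are absent from that sample's table while remaining in the truth.
Trinucleotide contexts are drawn from a signature mixture when a matrix is
supplied, else uniformly. True variants are marked called by k of 4 callers
(k = 2, 3, 4 with probabilities 0.05 / 0.15 / 0.80); single-caller
artifacts are injected at 10% of the true count to exercise the consensus
filter. Multiplicity is fixed at 1 (no multi-copy mutations); the estimator
still exercises the multiplicity formula because CN-1/3/5 regions exist in
the default profile.

The toy genome has four chromosomes (360 Mb total) with p/q arms and acen
bands; the shared default CN profile carries one arm-level gain, one
chromosome loss, one focal amplification (CN 5) and one focal deletion on a
diploid background. Segment log2 ratios are purity-corrected
(`log2(cn/2)`), consistent with absolute-CN callers, and carry no noise —
so joint-origin pairs have *identical* PT/PDX segmentations. The operational
truth label calls a clone "clonal" in a sample when its true CCF ≥ 0.9,
matching the relaxed > 0.9 cluster rule: sibling clones cannot all sit at
CCF exactly 1, and near-fixed clones are what the field operationally calls
clonal.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (alignment, mouse-read
contamination, FFPE damage), overdispersed coverage, segmentation noise and
discordant breakpoints, germline leakage, sex chromosomes (autosomal
n_n = 2 throughout), multi-copy mutations, and sampling bias between tumor
blocks. The PT CCF ranges of the seeding clone under sweeping versus branch
seeding are assumptions exposed in the configuration, not measured facts.

## Benchmarks and problem sizes

The recovery benchmarks simulate 100 pairs per joint-origin scenario at
depth 300 over a seed sweep, run the full filter → clonality → flow →
pattern cascade, and score pattern recovery (≥ 90% expected per scenario)
and consensus-clonality accuracy against truth (≥ 95%; ambiguous counts as
incorrect). CI coverage draws 4,000 mutations at depths ≥ 200 across a
spread of true CCFs and checks that the 95% interval covers the truth
(expected within 0.93–0.97). Signature recovery uses a 5-signature
synthetic matrix, exact single-signature spectra, and 20 multinomial draws
of a 0.6/0.4 mixture at n = 5,000 (L1 weight error ≤ 0.05). These sizes
are the package's standard benchmark conditions; `scripts/acceptance.py`
re-runs all of them from scratch.

## Degenerate inputs and determinism

Undefined quantities (empty unions, empty spectra, zero-variance profiles,
all-ambiguous heterogeneity) raise a dedicated `DegenerateDataError` rather
than returning NaN; the pipeline driver converts per-pair failures into
reported rows without aborting the cohort. All randomness flows through
numpy Generators seeded from the configuration, so fixed seeds give
byte-identical simulator output and identical pipeline reports. The CLI
maps validation/configuration errors to exit 1 and internal errors to
exit 2.
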