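# Methods

This note documents the models, estimators and numerical choices behind
`ibcnet`, and what the synthetic-data generator does and does not emulate.

## Differential-expression signature and IBC score

Expression values are assumed log2-scale (the RMA convention), so the
linear fold-change filter is applied to log2 differences: a gene enters the
signature when |mean(IBC) − mean(nIBC)| ≥ log2(1.5) **and** a two-sided
two-sample Student t-test with pooled variance gives p ≤ 0.05. The two
filters are per-gene and independent of each other, so their order is
immaterial; no multiple-testing correction is applied inside the filter —
the signature is deliberately the raw-p gene list, with FDR control
reserved for the master-regulator stage. Each group must contain at least
two samples (the pooled variance is otherwise undefined).

The centroid classifier averages the signature-gene log2 profile over the
IBC learning samples only. A sample's IBC score is its Pearson correlation
*r* with this centroid over the signature genes; *r* > 0 is called
IBC-like and *r* ≤ 0 (including exactly 0) nIBC-like, so the decision
boundary treats a perfectly uncorrelated sample as non-IBC. Signature
membership and scores are invariant to any common additive shift of all
samples (log-scale location invariance); zero-variance profiles are
rejected rather than scored.

## Mutual-information network

Pairwise dependence is estimated with the first
Kraskov–Stögbauer–Grassberger (KSG) k-nearest-neighbour estimator:
distances use the Chebyshev (max) norm in the joint space, the radius is
the distance to the k-th neighbour, and marginal neighbour counts use
strict inequality, giving MI = ψ(k) + ψ(n) − ⟨ψ(n_x+1) + ψ(n_y+1)⟩ nats.
Defaults are k = 3 and a uniform jitter on [0, 1e-12) whose only purpose is
breaking ties in discretised values. Small negative estimates are clipped
to 0 (MI is non-negative; negatives are estimator noise). Estimation is
deterministic for a fixed seed: jitter is drawn once per matrix build,
which also makes the TF×TF block exactly symmetric.

Implementation notes: one TF row is estimated against all gene rows at
once; the joint k-NN radius comes from a batched max/partition over
pairwise-distance planes and the marginal counts from binary search on the
sorted marginals. The bulk matrix path computes distance planes in float32
(≈4× throughput; the induced MI error is ~1e-3 nats, two orders below the
estimator's sampling noise at n ≈ 200), while the single-pair function
keeps float64 so the 1e-12 jitter remains resolvable. A warning (not an
error) is raised below ~100 expression profiles, where k-NN MI estimates
degrade.

Indirect edges are removed with the data-processing inequality (DPI): for
every triple whose three pairwise MI values were all estimated (the middle
node is necessarily a TF, since gene–gene MI is not computed), the edge
(t, g) is cut when mi(t, g) < min(mi(t, u), mi(u, g)) − eps. Decisions are
evaluated on the unpruned matrix and applied simultaneously, making the
operation idempotent; exactly equal MI values never trigger removal
(strict inequality, eps default 0), a conservative and deterministic
tie-break. TF–TF edges are eligible for removal like any other. No MI
significance threshold is applied before DPI by default; a permutation
null threshold (MI of permuted profile pairs, 1−α quantile) is available
as an option. With ~20 TFs, DPI alone already removes most noise edges:
a spurious weak edge only survives if it is not the weakest edge in any of
its triangles.

A TF's regulon is its neighbourhood in the pruned network (edges in either
orientation); TFs with no surviving edges yield no regulon.

## Master regulator analysis

Each regulon is tested for over-representation of signature genes with the
one-sided Fisher exact test on the [in-regulon × in-signature] table over a
gene universe: p = P(X ≥ overlap) for the hypergeometric tail. The full
regulon enters the test, not only its differentially expressed members.
The default universe is the set of genes that were eligible as network
targets (the expression-matrix genes) — the least biased choice given that
the background is otherwise arbitrary; it is an explicit argument and can
be overridden. p-values are Benjamini–Hochberg corrected across all tested
TFs, and TFs are ranked by ascending p with deterministic tie-breaks
(descending overlap, then TF id). The one-sided test is used because the
question is over-representation only; a two-sided p would roughly double
borderline values.

## Motif first-occurrence enrichment

Promoters are represented TSS-proximal-end-first: position 0 is the base
nearest the TSS and distance increases upstream. A window is a motif hit
when its log-odds score — uniform 0.25 background, PWM probabilities
floored at 1e-3 before the log to avoid −∞ from zero counts — reaches
`score_fraction` (default 0.8) of the maximal achievable score. Both
strands are scanned; a reverse-strand hit starting at index i in a window
of W positions is assigned distance (W − L) − i, i.e. its start read along
that strand. This convention makes the scan exactly strand-symmetric
(reverse-complementing every promoter changes no first-occurrence
distance); its one visible quirk is that a palindromic site is assigned
the smaller of its two strand distances.

Enrichment is judged against `n_random` (default 100) PWMs of the same
length with columns drawn from a flat Dirichlet: the empirical p is the
add-one rank of the observed median first-occurrence distance among the
null medians, bounded below by 1/(n_random+1); null PWMs with no hits
never count as closer. A two-sample Kolmogorov–Smirnov statistic against
the pooled null distances is reported descriptively only. The median-based
null is weak for very short query motifs (short random PWMs often match
promiscuously, producing small null medians); it behaves well for
information-rich motifs of ~10 bp and longer, which is what curated TF
matrices typically are.

## IHC contingency statistics

Marker positivity is strict: a case is positive when more than
`positivity_cutoff_percent` (default 5) percent of tumour cells stain —
exactly 5% is negative. Subcellular patterns are dichotomised as follows:
β-catenin M or Neg → inactive, M/C or N/C → active; NFAT5 N or N/C →
nuclear, C or Neg → non-nuclear. 2×2 tables are tested with
χ² = n·max(0, |ad−bc| − y·n/2)² / ((a+b)(c+d)(a+c)(b+d)), where y = 1
applies the Yates continuity correction (the default, and the max(0,·)
guard prevents over-correction from producing a negative statistic) and
y = 0 the uncorrected statistic; p is the upper χ²₁ tail. The
grade-stratified comparisons bundled with the package use the uncorrected
statistic, which is what reproduces their published p-values, while the
cohort-level tables use Yates — both modes are exposed. Sensitivity,
specificity, PPV and NPV are reported in percent with half-up rounding to
one decimal. Fisher's exact test is available for small cells but is not
used for the reference values. The bundled β-catenin subcellular table is
a reconstruction: its denominators are the β-catenin-positive cases
(37 IBC / 66 nIBC), the only integer counts consistent with the published
percentages and p-value.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes, at
the cohort proportions of the motivating study design:

* 63 IBC / 134 nIBC learning samples (and a 41/55 validation split in the
  tests), 20 TFs with disjoint regulons of 30 targets, 3 master-regulator
  TFs, 500 background genes.
* Per-gene baselines μ_g ~ N(8, 1), a plausible log2-intensity range
  (cosmetic only).
* A master-regulator TF is shifted by ±`effect`·σ (default 1.5σ) in IBC
  samples; ordinary TFs are phenotype-independent.
* A target gene is μ_t + s·β·(TF − μ_TF) + N(0, σ²) with sign s = ±1
  equiprobable and coupling β = 0.8 — the simplest linear-Gaussian model
  that yields the MI structure an ARACNe-style step assumes while keeping
  closed-form checks (Gaussian MI = −½ln(1−ρ²)). The coupling acts on the
  centred TF value so that baselines remain in the log2-intensity range
  regardless of edge sign; group differences, correlations and MI are
  unaffected by this centring.
* Promoters are i.i.d. background (configurable GC content) of length
  `window` (default 2000 bp); regulon genes of a chosen TF carry one site
  sampled from the PWM at an exponential distance from the TSS (mean
  200 bp), reproducing the near-TSS concentration of genuine binding
  sites.

Regulons are pairwise disjoint so planted-truth recovery is unambiguous.
The generator does **not** emulate probe-level effects, probe→gene
multiplicity, batch effects, overlapping or hierarchical regulons,
nonlinear regulation, copy-number structure, or realistic promoter
composition — so passing recovery tests demonstrates correctness of the
inference chain under its own model assumptions, not performance on real
microarray cohorts. Cohort-scale outputs (hundreds of signature
probe-sets, tens of thousands of network edges) require the original GEO
data and are intentionally out of scope; the pipeline emits the same
report schema at desk scale.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed, and the CLI
derives all stage seeds from a single `--seed`, recorded in each JSON
report. The test suite exercises the full default cohort
(1,120 genes × 197 samples) for planted master-regulator recovery over
20 generator seeds (~2 min), and reduced cohorts (≈150 genes × 100
samples) elsewhere; `scripts/acceptance.py` uses 10 cohorts for the
recovery rate and 100 repetitions for the motif null calibration, which
keeps a complete run around one minute on a single CPU.
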