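# Methods

## Model and procedure

Let G = {g_1..g_n} be genes with normalized expression vectors e_i over
samples S = {s_1..s_m}, each sample labelled case or control (≥ 2 per
class). For a pathway P with k genes present in the matrix, every one of
the C(k, 2) unordered pairs is summarised per sample by one of four
interaction profiles — sum (cooperation), difference (competition), max
(redundancy), min (dependency) — and scored with a two-sample t-statistic
Z_ij between classes (pooled variance by default, Welch via
`equal_var=False`; positive means higher in cases). The pathway statistic
is the maxmean of Z(P): the mean of the positive part or the magnitude of
the mean of the negative part, whichever is larger; zeros belong to
neither part, an empty part contributes 0, and the statistic is therefore
non-negative. Three elementwise identities are maintained and tested:
cooperation = redundancy + dependency, redundancy ≥ dependency with
equality iff e_i = e_j, and antisymmetry of competition in the gene order.
Because maxmean considers both signs, the pathway statistic — and hence
the p-value — is invariant to the lexicographic orientation chosen for the
competition profile; this is asserted in the test suite.

Significance is assessed by permuting sample labels (class sizes
preserved): B label shuffles per run are shared across all pathways (each
pathway's marginal null is unchanged; sharing makes the computation a pair
of matrix products per pathway), the raw maxmean is recomputed under each
shuffle, and the observed statistic is standardized by the mean/SD of this
null catalog. The p-value is the fraction of permuted statistics at least
as large as the observed one — by design a count/B estimator, so p = 0 is
possible (a `smooth_pvalues` switch adds the +1 correction but is off by
default). Because standardization is a common monotone transform of
observed and permuted values, the p-value is identical whether statistics
are compared raw, standardized against the permutation catalog (default),
or against the pooled pair-score catalog (`standardization="pooled_pairs"`,
the gene-set-analysis restandardization convention); this invariance is
asserted in the tests. When C(m, n_case) ≤ B, exact enumeration of all
label assignments replaces sampling.

The permutation test is repeated over `runs` independent runs (default 4)
with substreams derived from the master seed, and the run p-values are
averaged. Per profile kind, pathway p-values are converted to Storey
q-values: π0 is estimated by the smoother method (π0(λ) = #{p > λ}/(n(1−λ))
over λ = 0.05..0.95, cubic fit evaluated at λ = 0.95, clipped to (0, 1]);
for fewer than 50 p-values π0 estimation is too unstable and falls back to
π0 = 1, which makes the q-values exactly Benjamini–Hochberg adjusted
p-values (asserted against an independent implementation). The
multiple-testing universe is the pathway collection within one profile
kind, not pooled across kinds.

## Network construction and overlap test

Within each pathway called dysregulated (q ≤ 0.01) for a kind, every pair
is re-tested individually: two-sided p from the t distribution with
n_case + n_control − 2 degrees of freedom, kept at an uncorrected p < 0.05
— deliberately loose, since the pathway already passed the enrichment
gate. Pairs flagged under several kinds become one edge with merged
annotations. Optional filters reproduce the published network views:
removal of genes differentially expressed on their own (per-gene t-test,
Storey q < 0.01) together with their incident edges, then removal of
zero-degree nodes. Edges are marked physical iff present in the supplied
interaction network; nodes whose edges span ≥ 2 pathways are cross-pathway
hubs. Hub ranking is by degree with lexicographic tie-break.

The overlap between dysregulated and physical pairs is an urn model:
N = Σ_i C(a_i, 2) with a_i the number of pathway-i genes having at least
one physical interaction (the *literal* mode follows this per-pathway sum,
double-counting pairs shared by pathways; m is likewise summed per
pathway to keep the urn coherent). The *dedup* mode counts each distinct
pair once throughout. n is the number of distinct significantly
dysregulated pairs inside the testable universe and k those that are also
physical. P(X ≥ k) is evaluated exactly in log-gamma space (no overflow up
to N ~ 1e6; verified against exhaustive enumeration and Monte-Carlo
sampling), with no multiple-testing correction since one test is performed
per dataset. In literal mode the urn is not perfectly coherent (N
double-counts shared pairs while n, k do not); both conventions are
exposed and neither guesses beyond the printed formulas.

## Synthetic data

The generator produces i.i.d. standard-normal baseline expression (no
gene–gene correlation), disjoint pathways of configurable size, and an
Erdős–Rényi physical network with optional planted edges. Signal pathways
receive injected pair-level dysregulation of one profile kind at a
requested effect size δ, expressed in pooled within-group SDs of the
profile. Defaults mirror the study conditions exercised throughout:
20 vs 20 samples, 10-gene pathways, 10 of 45 pairs injected at δ = 2,
B = 5000 and 4 runs for production-scale enrichment (tests and the
acceptance script use B = 500–1000 to keep runtimes in seconds; results at
those sizes are already decisive, with Monte-Carlo error ~ sqrt(p(1−p)/B)).

Injected pairs are laid out as disjoint complete-bipartite components
(every left–right pair within a component is a signal pair), which
requires n_signal_pairs to decompose as Σ l_c·r_c with Σ (l_c+r_c) ≤ k —
counts close to C(k, 2) are not representable and are rejected with a
clear error. The constructions:

* **Pinned sum/difference (cooperation, competition).** A per-sample
  latent q with SD sqrt(1−τ²) (τ = 0.05) is shared within a component and
  *centred within each class*, so its between-class t-statistic is exactly
  zero; left genes carry +q and right genes −q (cooperation) or both +q
  (competition), plus independent N(0, τ²) noise. The targeted profile
  collapses to a band of SD √2·τ whose centre shifts by δ·√2·τ in cases.
  The shift must appear in the genes' class means; it is split
  asymmetrically (left −γ, right the remainder, γ staggered per component)
  so that the *stray* pairs a signal gene forms with other genes are
  deflected to the negative side of the maxmean statistic rather than
  accumulating as small positives that dilute its positive side — small
  positive entries lower the positive-part mean, which is the statistic's
  one structural sensitivity. Per-gene mean shifts stay ≤ ~0.5 SD
  (undetectable at 20 vs 20); per-gene variances are exactly 1. An
  exactly-zero gene shift is impossible here: the profile mean shift is by
  definition the sum/difference of the two gene-mean shifts.
* **Pinned extreme (redundancy, dependency).** Per sample one side of the
  component is "high" (values μ_c + τη, τ = 0.12, side assignment balanced
  within each class) and the other "low" (−μ_c ± 2a_c + τη with a
  per-gene branch sign), with a_c chosen so each gene's marginal has mean
  0 and variance exactly 1 in both classes. The pair maximum then sits in
  the narrow high band; μ_case is solved by root-finding against the exact
  closed-form moments of the maximum of independent normals so the
  *realized* pooled effect equals δ (feasible up to δ ≈ 2.5 at the default
  μ_control = 0.6). Dependency negates the construction, pinning the
  minimum instead. Gene-level means and variances are identical across
  classes; only higher moments differ, which a mean-based test cannot see.
* Without `preserve_marginals`, plain location shifts are applied (scaled
  by the null profile SD: √2 for sum/difference, sqrt(1−1/π) for max/min),
  which *do* move gene means visibly and shift redundancy and dependency
  together — a deliberately naive mode for exploratory use.

What the generator does **not** emulate: gene–gene correlation outside
injected components, microarray noise models (probe effects, batch
effects, heteroskedasticity), non-normal marginals, and overlapping
pathway membership. Passing tests therefore demonstrate the statistical
machinery — calibration of the permutation null, power against pair-level
signal without gene-level signal, exactness of the combinatorial parts —
not robustness to real-data artefacts.

## Numerical choices and degenerate inputs

* Constant profiles (zero pooled variance) score z = 0 with a flag instead
  of being dropped, so |Z(P)| has the same length across permutations;
  constant genes get p = 1 in the differential-expression test.
* A degenerate null catalog (SD = 0) yields a flagged statistic of 0.
* Group sums of squares are clipped at 0 before the square root to absorb
  floating-point cancellation in the matrix-product t-statistics.
* Seeds: a single master seed derives all substreams via fixed
  `SeedSequence` spawn keys (per run, per signal, per generator
  component), so adding a component never perturbs earlier streams and
  every artefact is bit-reproducible from (seed, config).
* Pathways with fewer than `min_genes` (default 2) matched genes are
  skipped with a logged reason, never scored; `max_genes` is off by
  default and available for the 15–500 filtering convention.
* Duplicate expression rows collapse to the highest-mean row by default
  ("max_mean"; "mean" and "error" selectable); genes with missing values
  are dropped with a logged count (imputation is out of scope). Symbols
  are upper-cased on ingest because the pipeline joins expression, gene
  sets and interactions by human gene symbol.
* CLS labels: a class literally named control/normal/wt (or case/tumor/
  mut) is honoured; otherwise the first declared class is control, and
  `case_class` overrides.

## Known limitations

* The bipartite layout constrains representable signal-pair counts (see
  above); primes larger than k−1 and counts near C(k, 2) are infeasible.
* π0 estimation below 50 p-values silently becomes BH — conservative, and
  logged.
* The literal overlap urn inherits the incoherence of its definition
  (documented above); use dedup mode for a self-consistent universe.
* Single-process execution; the permutation engine is vectorized but not
  parallelized.
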