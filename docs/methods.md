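# Methods

## The problem

Comparative metabolomics asks how metabolite levels evolve across related
lineages: how fast profiles diverge, whether divergence tracks the
phylogeny, and whether independent transitions to a shared niche (here,
domestication of budding yeast) leave a *convergent* metabolome signature
beyond what shared ancestry predicts. `phylometab` implements the full
analysis chain for a replicate-level metabolome survey of strains nested in
populations on a known phylogeny.

## Divergence statistics

For two log-scale, normalized profiles over N metabolites,

    D(k, l) = (1/N) Σ_i (m_{k,i} − m_{l,i})² .

Population-pair divergence is the mean of D over all *cross* strain pairs
(one strain from each population); within-population pairs never enter, and
species-level divergence is defined analogously over cross-species strain
pairs. Phylogenetic distance-adjusted divergence divides each pair's D by
the patristic distance between the populations (sum of branch lengths
through the MRCA), turning divergence into an empirical per-unit-time rate.
Yield profiles (maximum theoretical production per amino acid, mol/mol) are
compared with the same mean-squared statistic; profiles with distance
strictly below 1e-3 are classified *identical* (the strict inequality
absorbs finite-precision arithmetic in yield computation).

## Inference

**Mantel test.** Pearson's r between the vectorized upper triangles of two
distance matrices; the null relabels one matrix. Two schemes: `uniform`
(classical) and `phylogenetic` — sequential label placement with weight
exp(−d/μ) on the patristic distance d between old and new tip position
(μ = mean off-diagonal distance), concentrating the null on permutations
that respect phylogenetic proximity. One-sided p with the add-one rule
p = (#{r* ≥ r} + 1)/(B + 1). The observed r is scheme-independent.

**Group-ratio permutation test.** Statistic: ratio of mean (adjusted)
divergence over within-group pairs of two groups of populations, reported
with the larger observed mean in the numerator. The null shuffles the
*population* group labels (without replacement), preserving the pair-level
dependence induced by shared populations. Permuted ratios are folded as
max(r, 1/r) before the inclusive comparison: without folding, the
data-dependent orientation of the observed ratio (larger mean on top) makes
the one-sided count roughly double the nominal type-I error, while the
folded statistic is exact under exchangeability (the test suite checks this
calibration directly). An optional pair-eligibility mask (e.g. only same-clade
domesticated pairs, or wild pairs below a patristic-distance cap) is a
fixed property of the population pairs and survives the shuffle; shuffles
that leave a group without an eligible pair are redrawn and counted.

**Phylogenetic ANOVA (PGLS).** Per metabolite, y = Xβ + ε with
Cov(ε) = σ²V, V the Brownian covariance of the population tree
(V_ij = root-to-MRCA depth). Solved by Cholesky whitening;
σ̂² = RSS/(n − p); two-sided t tests on n − p df. X contains an intercept,
a domesticated/wild indicator, and optionally the population-mean growth
state (OD_sampling − OD_inoculation)/OD_stationary, in which case the group
coefficient's p is the domestication effect independent of growth. Singular
V (zero-length branches) receives a ridge of 1e-8 · mean(diag V) with a
warning. The per-metabolite scan reports estimate, sign, p, and a
significance flag at α = 0.05 with no multiple-testing correction by
default (raw significance counting; correction can be applied downstream).

Bartlett's variance-homogeneity test, one-way ANOVA, and Fisher's exact
overlap test are delegated to scipy behind the module surface; the test
suite re-derives each from its textbook form.

## Normalization

Fixed order: feature filters → kNN imputation → PQN → OD regression → log +
aggregation.

* **Feature filters** (non-targeted channel): detection (non-missing and
  > 0) in ≥ 87.5% of pooled-extract QC samples (inclusive), QC
  coefficient of variation of peak area strictly < 25% (SD/mean, linear
  scale), detection in ≥ 90% of biological samples.
* **Imputation:** k-nearest neighbours (k = 5) on log intensities,
  uniform-weight mean of neighbours (scikit-learn `KNNImputer`); observed
  entries are never modified.
* **PQN:** reference = per-metabolite median over biological samples;
  per-sample factor = median quotient against the reference; division by
  the factor. Removes multiplicative dilution/biomass effects. Note the
  identifiability limit: a strain whose whole profile sits higher shifts
  its median quotient exactly like a dilution, so dilution recovery is only
  exact when biological level variation is absent — the recovery tests
  plant dilution in isolation.
* **OD regression:** per metabolite, OLS of log intensity on OD at sampling
  across biological samples; output = residual + fit at the mean OD, so
  mean levels are preserved and a refit slope is 0. Log-scale
  residualization is the default (linear available); the log scale composes
  cleanly with the log-scale divergence statistic.
* **Aggregation:** natural log, replicates → strain mean → population mean
  (→ species mean), so each strain counts equally regardless of replicate
  count. Fold changes divide each label's linear-scale average by the
  median label average; studentization z-scores each metabolite (sample
  SD).

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the analysis assumes:
a random rooted bifurcating population tree (pairwise joining, exponential
branch lengths, mean 0.05 substitutions/site), Brownian traits on the
natural-log scale (σ² = 1 per unit branch length), strains nested in
populations (2–5 per population, SD 0.10), 4 replicates per strain, and a
measurement layer of log-normal per-sample dilution (SD 0.30), per-trait
growth leakage into log intensities (slopes ~ 0.5·U(0.5, 1.5) on OD at
sampling — a purely common slope would be indistinguishable from dilution),
replicate noise (SD 0.20), pooled QC samples (8 leading + 1 per 20), and
5% missing-at-random dropout in the non-targeted channel (kept below the
90% detection filter so the emitted feature count is approximately the
post-filter count, matching how the emulated study reports features).

The domestication syndrome has two facets, both planted:

1. a **convergent mean shift** on 7 of 19 targeted and 27 of 78 untargeted
   traits, same signed displacement in both domesticated clades; "2 SD"
   resolves to twice the RMS Brownian tip SD under the generating model;
2. an **elevated diversification rate** inside the two domesticated clades
   (branch lengths below each clade MRCA × 2.6, the adjusted-divergence
   ratio the analysis is designed to detect). A mean shift alone cannot
   alter within-group pairwise divergences — identical displacements cancel
   in differences — so rate elevation is what gives the ratio test its
   signal.

The two clades are chosen deterministically as disjoint subtrees of ~3 and
~4 populations (9 same-clade domesticated pairs), preferring maximal
separation, mimicking two independent domestication events.

Not emulated: mass-spectral artifacts (adducts, isotopes, batch drift),
selection models beyond a fixed shift, within-population structure, or any
claim about real branch-length distributions. Passing tests therefore
demonstrate correctness of the statistical machinery under its assumed
model plus realistic measurement noise — not robustness to instrument
artifacts.

## Calibration and power

The test suite and `scripts/acceptance.py` measure these directly; in
brief:

* With no domestication effect, the signature scan flags slightly *under*
  α of traits (mild conservatism): replicate/strain noise adds an
  unmodeled iid component to the population means, and GLS with a pure
  Brownian covariance is then conservative — the same behaviour
  corBrownian-style fits have on real data. The group-ratio test's type-I
  error is within Monte-Carlo error of nominal.
* Under the full syndrome the ratio test on adjusted divergence rejects in
  roughly nine of ten simulations, while the scan recovers most but not
  all shifted traits with the correct sign. The ceiling is informational,
  not computational: with only two independent domestication events among
  17 populations, Brownian drift on the two clade stems is the
  irreducible competitor of a convergent shift, and the noncentral-t power
  of the group contrast is bounded well below 1 even for a detector given
  the true covariance and noise-free data.

## Numerical choices and problem sizes

Permutation counts default to 1e5 at the function level and 9,999 in the
pipeline configuration; calibration experiments in the test suite use
B = 499–999 with 200–500 simulated datasets — sizes chosen so the whole
suite re-runs comfortably on one CPU. Ties in permutation counting are
inclusive (≥, with a 1e-15 guard); permutation p-values are floored at
1/(B+1) by the add-one rule. kNN imputation tie handling follows
scikit-learn's internal ordering. All randomness flows from
`numpy.random.default_rng` seeds; (config, seed) pairs reproduce every
output byte for byte.

## Known limitations

* The phylogenetic permutation scheme is one member of the
  proximity-weighted family; Mantel p-values under it are
  scheme-dependent (r is not).
* PGLS ignores measurement-error variance in population means (as does the
  emulated analysis); with heavy replicate noise it is conservative.
* PQN cannot separate a global profile shift from dilution (see above).
* Yield profiles are consumed, never computed: flux-balance analysis is out
  of scope.
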