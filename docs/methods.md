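# Methods

## The liability-threshold model over pedigrees

Liability for individual i in a family of n is
l_i = g_i + s + e_i, with (g_1, …, g_n) ~ N(0, h²A), a single shared
household component s ~ N(0, c²) added to every member, and independent
residuals e_i ~ N(0, 1 − h² − c²). A is the additive genetic relationship
matrix (twice the kinship coefficient), built by the tabular recursion:
processing parents before children, A(i, j) = ½(A(fa, j) + A(mo, j)) with a
missing parent contributing 0, and A(i, i) = 1 + ½A(fa, mo). The recursion
handles inbreeding loops (diagonal > 1) but the package warns when it sees
them, because the accuracy theory below assumes outbred families. Disease
status is D_i = 1{l_i ≥ T}, T = Φ⁻¹(1 − f); the affected region is the
closed set l ≥ T (the boundary carries no probability mass; the choice is
cosmetic).

The shared-environment term is deliberately crude: a single rank-one
component gives every pair of relatives the same environmental covariance
c², so siblings share no more environment than grandparents. It is an
upper-bound construction for how much household environment could help a
family-history model, not a realistic household model.

**Sex-limited diseases.** When one sex cannot express the disease, those
relatives' phenotypes are unobserved; by Gaussian marginalization this is
identical to deleting their rows/columns. `Pedigree.marginalize_sex`
implements the deletion while retaining the sub-block of A (so
relationships routed through removed individuals survive); if the index's
own sex is non-applicable the caller must flip all sexes first
(`flip_sexes`). Unknown-sex individuals are conservatively kept.
Sex-specific thresholds (different f by sex within one pedigree) are out of
scope.

## Pattern probabilities

All 2ⁿ disease-status patterns are enumerated in binary-counting order with
the index individual as bit 0; n is capped at 16 by default (2¹⁶ MVN
integrals is the practical desk limit; the cap is an argument).

Each pattern probability is an axis-aligned rectangle probability of the
joint normal. Rather than calling a rectangle routine per pattern (which
performs its own 2^k inclusion–exclusion internally), the package evaluates
one *upper-orthant* CDF per subset of individuals — P(l_i < T ∀ i ∈ W),
obtained by simply dropping the other coordinates — and recovers every
pattern probability at once through the signed superset Möbius transform
P(pattern with affected set a) = Σ_{W ⊇ complement(a)} (−1)^{|W∖comp(a)|} q_W.
This shares the inclusion–exclusion work across all patterns: 2ⁿ CDF calls
total, most of low dimension, with an O(n·2ⁿ) transform. Cancellation can
leave tiny negative values; they are clipped to zero, and relative patterns
with probability below 10⁻¹² keep the prior risk f (with a warning) so that
classifier bookkeeping stays total.

CDFs of dimension ≥ 2 are computed with scipy's Genz quasi–Monte-Carlo
multivariate-normal integrator at absolute tolerance 10⁻⁶ (configurable)
under a fixed integration seed, so repeated runs are bit-identical on one
platform. In practice the realized error is far below the requested
tolerance: the index individual's marginal risk, reassembled from all 2ⁿ
pattern probabilities, matches f to ~10⁻⁷ on the test pedigrees.

## Risk classifiers and their metrics

A classifier is a finite list of items (risk r_j, P(item|case),
P(item|control)). The complete family-history model has one item per
relatives' pattern with r_j the conditional index risk; the restricted
model pools patterns into equivalence classes of a summary statistic —
by default the thresholded count (0, 1, >1) of affected *first-degree*
relatives, identified from pedigree links (parents, full siblings,
children) rather than from a user-supplied list. Class risk is the
pattern-probability-weighted mean of member risks, i.e. the classes are
conditioned on the full pedigree distribution, not on a first-degree-only
sub-pedigree.

The classifier's case/control weights are normalized by the *realized*
mean risk Σ r_j P_j rather than the nominal f. The two agree to integration
error (~10⁻⁷); using the realized value makes the internal identities
(columns summing to one, control-weighted mean likelihood ratio exactly 1)
hold identically, so any drift of mean risk from f is a clean measure of
integration error rather than being silently renormalized away.

ROC vertices are cumulative case/control masses over items sorted by
non-increasing risk; items tied in risk (within 10⁻¹²) are merged first, so
a tie is a single segment under the trapezoid rule. Operating points
between vertices use deterministic linear interpolation — the standard
randomized-classifier construction realizes any convex combination of
vertices, but no RNG is consulted at metric time. PPV/NPV follow from
Bayes' rule at the prior; at sensitivity exactly 0 the PPV is reported as
its limit along the curve (the top item's risk). Likelihood ratios are
post-test over pre-test odds, r(1 − f)/((1 − r)f); a risk of exactly 1
yields a genuine +inf, serialized as the string `"+inf"` in JSON rather
than a float overflow.

## SNP-based model closed forms

With v = π h² and g the measured genetic liability (Cov(g, l) = Var(g) = v),
selection theory gives exact conditional moments of g among cases and
controls: μ = v·i and σ² = v(1 − v·i(i − T)) with i = φ(T)/f for cases and
i = −φ(T)/(1 − f) for controls. Treating both conditional laws as normal —
the standard approximation in this literature; the exact non-normal
densities are used only as quadrature oracles in the tests — yields the
closed-form AUC and the two-parameter ROC curve. Posterior risk is
r(g) = 1 − Φ((T − g)/√(1 − v)); it averages to f exactly and is strictly
increasing in g, so likelihood-ratio tail fractions reduce to two normal
tails of g after bracketed root-finding for the boundary g values (initial
bracket ±12√v, doubled on failure; an unattainable fold change contributes
zero). The "equivalent π" of any AUC target inverts the strictly increasing
π ↦ AUC map by Brent root-finding to 10⁻⁸; the round trip is verified to
10⁻⁶ in the tests.

## Combined family-history + SNP model

Conditioning the joint liabilities on the index's measured g shifts the
mean to A(:, 1)·g and subtracts v·A(:, 1)A(1, :) from the covariance; the
index's conditional variance is 1 − v, so the combined model's index
marginal reproduces the univariate SNP closed form exactly (asserted to
10⁻⁶ in tests). The continuous g is replaced by K equiprobable cells of
N(0, v) with weight 1/K each, represented by their *conditional means*
E[g | cell] = √v·K·(φ(z_k) − φ(z_{k+1})). Moment-matched cell means were
chosen over mid-quantile points after measuring convergence: on the trio
test case the AUC moves by 1.6·10⁻⁴ when doubling K = 200 → 400 with
mid-quantiles but only 4·10⁻⁶ with cell means. K defaults to 200 and the
total work K·2ⁿ is guarded by a budget parameter. Classifier items are
(relatives' pattern, cell) pairs; genetic measurements on relatives are not
modeled, but all conditioning code works against the index column of A so
that extension is localized.

The overlap between the two information sources is reported on the
heritability scale: each of AUC_FH, AUC_SNP, AUC_combined is converted to
its equivalent π and the shared variance is π_FH + π_SNP − π_combined
(clipped at zero with a warning if the combined model appears
super-additive, which can only arise from numerical error).

## Heritability explained by an association list

Selection first drops associations above the significance threshold
α (default 5·10⁻⁸, the canonical genome-wide level; exposed as `--alpha`),
orders the rest by effective sample size (harmonic mean of case and control
counts, ties by smaller p-value), and greedily accepts markers whose
pairwise r² with everything already accepted is at most 0.005. A missing r²
entry is treated as 1 — conservative exclusion — with a warning.

The winner's-curse correction models the observed z = b/s as a draw from
N(μ, 1) truncated to |z| > c = Φ⁻¹(1 − α/2), and solves the mean-matching
equation μ + (φ(c − μ) − φ(c + μ))/(Φ(μ − c) + Φ(−μ − c)) = z for μ. This
equation is simultaneously the score equation of the truncated likelihood,
so the estimator is the conditional MLE. It is odd-symmetric, strictly
shrinks toward zero, and is designed for the true curse regime (effects at
or below the discovery threshold, observed only when they fluctuate past
it); for true effects comfortably above the threshold it can overshoot the
mean — a known property of conditional-MLE corrections — which the test
suite documents by probing both regimes. A missing standard error is
back-computed from the two-sided p-value as |b|/Φ⁻¹(1 − p/2).

Per-SNP liability variance uses the genotype-threshold construction: under
HWE and multiplicative allelic odds (1 : R : R²), the baseline odds are
solved so genotype risks average to f; each genotype class then gets mean
liability shift m_j = T − Φ⁻¹(1 − f_j) against a unit residual, and the
between-genotype variance V = Var(m) rescales to the unit-variance
liability scale as V/(1 + V). Per-SNP contributions are summed under the
independence assumption established by the r² screen (duplicating a marker
deliberately doubles its contribution) and divided by h²; totals above 1
are clipped with a prominent warning. The small-effect limit
V ≈ 2p(1 − p)[β f(1 − f)/φ(T)]² and a 10⁶-genotype forward simulation both
validate the construction in the tests.

## The simulator

`simulate_families` draws, per replicate, a genetic vector from N(0, h²A)
via an eigendecomposition factor (eigenvalues clipped at −10⁻¹⁰ to absorb
the rank-one c² term's round-off), one shared component, independent
residuals, and the index's measured liability
g_m = (v/h²)g_index + N(0, v − v²/h²). Randomness comes from a
counter-based Philox stream keyed by one integer seed, with all variates of
a replicate in one contiguous block — so the first N replicates are
bit-identical regardless of how many are requested, and fixed seeds give
bit-identical output.

The simulator emulates exactly the generative model above, which means
passing tests demonstrate the *internal* consistency of the analytic
machinery, not realism: real family data additionally involve age-varying
risk and censoring, recall error and incomplete histories, non-additive
genetic effects, structured (non-exchangeable) household environments, and
ascertainment of families through affected members. None of these are
generated or modeled.

Default problem sizes in the test suite were chosen to keep the full run at
a few minutes on one CPU while leaving Monte-Carlo standard errors well
below the effects being checked: 10⁶ replicates for the pattern/AUC
validation grid (two pedigrees × four (f, h²) combinations), 10⁶ genotypes
for the variance-explained oracle, 3–5·10⁵ for secondary checks.
Monte-Carlo agreement is asserted at 3 standard errors, with a Bonferroni
adjustment when many cells are tested simultaneously so the familywise
false-alarm rate stays at the 3σ level.

## Known limitations

- Additive liability only: no dominance, epistasis, major loci, or
  gene–environment interaction; no age-of-onset structure.
- Lifetime risk semantics: family histories are patterns of *lifetime*
  disease, so computed accuracies are upper bounds on what is achievable
  with histories observed mid-life.
- The shared-environment extension is an upper-bound construction, not a
  household model.
- The SNP model works on the aggregate measured liability; it does not
  score individual genotype vectors, and relatives' genotypes are ignored.
- Association-list inputs are assumed pre-curated (allele stranding,
  population-matched frequencies, and the r² matrix are the caller's
  responsibility).
- Exact enumeration limits pedigrees to the pattern cap (default 16);
  larger families need the restricted model on a reduced pedigree.
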