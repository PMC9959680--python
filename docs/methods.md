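# Methods

This note documents the models and procedures implemented in `radqsar`, the
parameter choices that matter, what the synthetic-data generators do and do
not emulate, and the numerical decisions taken where the design was open.

## Data model and scales

Activities are stored on the **percent/10 scale**: a compound scavenging
85% of a radical has activity 8.5, and all values must lie in [0, 10].
Readers accept raw percentages via a flag and divide by 10. The three
responses are Y1 (hydroxyl radical •OH), Y2 (superoxide anion O₂•⁻) and
Y3 (DPPH•). Descriptors are numeric molecular properties; ids X1–X23 denote
quantum-chemically computed properties and X24–X33 cheminformatic ones.
Seven identities are fixed by the published regression models: X16 (N1–C13
bond), X17 (C2–R(b) bond), X19 (C4–C11 bond), X20 (polarizability), X21
(HOMO energy), X26 (AlogP), X30 (Connolly surface area). Descriptor
computation itself (quantum chemistry) is out of scope; tables arrive as
CSV/TSV.

Autoscaling standardizes each descriptor column to mean 0 and unit *sample*
(ddof = 1) standard deviation — the chemometric convention, under which the
column [1, 2, 3] maps to [−1, 0, 1]. Constant columns are dropped with a
warning; the scaling record supports exact inversion.

## Kennard–Stone splitting

The training set is chosen by the maximin rule: seed with the globally most
distant pair of compounds, then repeatedly add the compound whose minimum
Euclidean distance to the selected set is largest, until the requested
fraction (default 80%, rounded to nearest with ties upward — 12 of 15) is
reached; the remainder is the test set. Distances are computed on the
autoscaled full descriptor matrix so that large-magnitude descriptors
(surface area ~400 Å², polarizability ~150 a.u.) do not drown bond lengths
(~1.4 Å). Ties are broken toward the lowest row index, making the split a
pure function of the data. Selecting the *training* set (rather than the
test set) is the standard use of the algorithm: training compounds should
span descriptor space. Which exact compounds end up in the test set depends
on whether the original analysis scaled its descriptors and on which columns
it used — neither is recoverable — so specific test-set membership is
reported, never asserted.

## GA-MLR descriptor selection

Candidate models are descriptor subsets of exactly `equation_length`
(default 3) columns, fit by OLS with an always-included intercept, scored by
training R². Defaults mirror a classical genetic-function-approximation
setup: population 1000, at most 500 generations, mutation probability 0.1.
Choices the method description leaves open, fixed here once:

- **Selection**: tournament of size 2 — robust and selection-pressure-mild
  at this population size.
- **Elitism**: the 10 best individuals survive unchanged, which makes the
  best-so-far fitness non-decreasing (a tested invariant).
- **Crossover**: each offspring is a uniform draw of `equation_length`
  distinct ids from the union of its parents' ids (each parent's genes
  appear in offspring with probability ½ for disjoint parents).
- **Mutation**: with the configured probability, one uniformly chosen gene
  is replaced by a uniformly chosen unused descriptor.
- **Stagnation**: the run stops after 50 generations without best-fitness
  improvement (or at the generation cap).
- **Memoization**: fitness is cached per descriptor set — the fitness
  landscape is static, so each of the C(33,3) = 5456 subsets is fit at most
  once; PRESS/R²(CV) are *not* computed inside the fitness loop (fitness is
  plain R²) but afterwards for reported models.
- Singular subsets (collinear columns) score fitness 0 with a warning.

`exhaustive_best` enumerates every subset and serves as the exact oracle;
on planted-signal instances with C(8,3) = 56 subsets the GA's top model
matches it in ≥ 95% of seeded replicates (a tested acceptance property), and
on the 15×33 reference fixture it matches the C(33,3) enumeration for all
three responses.

A caution inherent to the method, visible in our synthetic experiments: with
12 training compounds and 5456 candidate subsets, the R²-maximal subset
frequently beats the true generating subset through chance correlation. The
acceptance script therefore reports how many of the three planted subsets
the search recovered, alongside the fit statistics — at this sample size the
selected model should be read as *a* well-fitting description, not *the*
mechanism.

## Regression diagnostics

For an OLS fit with intercept on n observations and p parameters
(p = descriptors + 1):

- RSS = Σ(ŷᵢ − yᵢ)², TSS = Σ(yᵢ − ȳ)², ESS = Σ(ŷᵢ − ȳ)²; the identity
  TSS = ESS + RSS holds to 1e-9 relative and is asserted on every fit.
- R² = ESS/TSS (equal to 1 − RSS/TSS for intercept OLS).
- Significance-of-regression F = (ESS/(p−1)) / (RSS/(n−p)), compared with
  the upper-5% quantile of F(p−1, n−p) (e.g. 4.066 for p = 4, n = 12). We
  use the standard convention of explained mean square over residual mean
  square; a perfect fit reports F = ∞ with a warning rather than raising.
- PRESS is computed by explicit leave-one-out refitting (the hat-matrix
  closed form Σ(eᵢ/(1−hᵢᵢ))² serves as the independent oracle in tests);
  R²(CV) = 1 − PRESS/TSS, which may be negative for hopeless models. LOO
  needs n ≥ p + 1 so every subfit is determined.
- RMSE = √(Σ(yᵢ − ŷᵢ)²/N) with N the number of observations evaluated.

Diagnostics for network predictions reuse the same formulas (R² = ESS/TSS,
RMSE); PRESS and F are OLS-specific and reported only there. Note that
ESS/TSS can exceed 1 for non-OLS predictions on small test sets.

## Bayesian-regularized 3-3-1 network

Architecture: 3 inputs (the descriptors of the corresponding GA-MLR
equation — {X17, X19, X20} for Y1, {X19, X20, X21} for Y2, {X16, X26, X30}
for Y3), one hidden layer of 3 tanh units, one linear output; 16 weights
total. Inputs and the target are affinely mapped to [−1, 1] before training
(stored and inverted on prediction). Initial weights are uniform ±0.5.

Training minimizes F(w) = β·E_D + α·E_W with E_D = ½Σr², E_W = ½Σw², by
Levenberg–Marquardt: Δw = −(βJᵀJ + (μ+α)I)⁻¹(βJᵀr + αw), with μ starting at
1e-3, ×10 on rejection, ×0.1 on acceptance, capped at 1e10; up to 1000
epochs or gradient ∞-norm below 1e-7. J is the analytic Jacobian of the
residuals (validated against central differences to 1e-6 relative).

After each accepted step the MacKay evidence updates run:
γ = N_w − α·tr(H⁻¹) with H = βJᵀJ + αI, then α = γ/(2E_W),
β = (n − γ)/(2E_D). Four numerical decisions, all motivated by the
n < N_w regime (12 compounds, 16 weights) this tool targets:

1. **γ is clamped to [0, min(N_w, n−1)]**: no more effective parameters
   than observations can be constrained, and an unclamped γ > n would make
   β negative.
2. **Warm-up**: the updates start after 10 plain LM epochs (under the
   initial weak prior) so the error fit takes shape before the
   hyperparameters adapt; updating from a random-weight state drives α to
   meaningless values.
3. **α starts at 0.1** (β at 1): a weak initial weight prior that prevents
   the warm-up from fully interpolating tiny data sets.
4. **Restarts selected by evidence**: training runs from 5 seeded
   initializations plus one conservative run with no warm-up, and the
   solution with the highest log evidence
   log E = −αE_W − βE_D − ½log det H + (N_w/2)log α + (n/2)log β
   is kept. The α/β iteration has two self-consistent basins on
   near-structureless small data (an interpolating one and a heavily
   regularized one); the evidence — the framework's own model-comparison
   criterion — reliably prefers the regularized basin on noise and the
   fitted basin on signal. α and β are capped at 1e12 so βJᵀJ stays
   representable when E_D collapses on noise-free targets.

Everything is a pure function of the configured seed; refitting with the
same seed is bit-identical. On 12-point pure-noise targets the trained
network ends with γ < N_w/2 (typically < 4) and near-zero training R²,
while an unregularized LM fit of the same net interpolates (R² ≈ 1) — the
tested statement of what the regularization buys.

## Screening

Candidates arrive as a descriptor table containing at least the seven
columns used by the three published equations (coefficients embedded as
data):

    Y1 = −90.879·X17 − 47.988·X19 + 0.016·X20 + 207.384
    Y2 = −43.836·X19 + 0.005·X20 − 75.277·X21 + 47.527
    Y3 =  61.220·X16 − 1.240·X26 + 0.052·X30 − 102.072

Pass rules are strict inequalities on the percent/10 scale: y1 > 8.0 and
y2 > 8.0 for the radical pair, y3 > 7.0 for DPPH•; a prediction exactly at
a threshold fails. When trained networks are supplied, per-activity flags
are computed for both model families plus an agreement flag. Counts are
monotone non-increasing in the thresholds (a tested property). Fitted
equations can be used in place of the published ones; the designed-compound
descriptors themselves are inputs, never hard-coded.

## Synthetic data

The generators emulate the statistical structure this workflow assumes:

- **Descriptors**: multivariate-normal latent blocks (contiguous blocks of
  5 columns, within-block correlation 0.3 by default) mapped affinely into
  physical ranges — bond lengths 1.30–1.60 Å, atomic charges −0.8–0.1 a.u.,
  HOMO energy −0.40 to −0.25 a.u., polarizability 80–250 a.u., AlogP −1–6,
  Connolly area 250–600 Å² — with the declared range at ±3 sd and clipping
  beyond.
- **Linear activities**: y = b₀ + Σbⱼxⱼ + N(0, σ), clipped to [0, 10] with
  a warning. The default planted model (on X2, X5, X7 of a 10-descriptor,
  60-compound table) is calibrated by variance arithmetic so each term
  contributes ~0.5 activity units of sd and the population R² is ~0.85 —
  the fit-quality regime of the application.
- **Nonlinear activities**: y = baseline + Σaⱼ·tanh(gain·zⱼ) + noise on
  standardized planted columns, with the form fixed in code so the
  attainable R² ceiling is computable; gain ≤ 0.5 is near-linear, gain ≥ 2
  saturating (where the 3-3-1 net beats the linear model by ≥ 0.05 R², a
  tested property).
- **Reference fixture**: 15 compounds × 33 descriptors with all three
  activities planted from the published equations on their subsets, using
  narrow per-descriptor ranges realistic for 15 close analogues (bond-length
  spread ~0.01 Å — under the broad default ranges those equations would
  produce activities far outside [0, 10]). Noise sds 0.345/0.344/0.44 give
  population R² ≈ 0.85/0.85/0.81, consistent with training RMSEs ~0.3 at
  this scale.

What the generators do **not** emulate: the real data's inter-activity
correlation structure beyond shared descriptors (the fixture's Y1–Y2
correlation is ~0.2, not the 0.84 of the original table, because Y2's
dominant planted term X21 is independent of Y1's X17), heavy-tailed
measurement error, and any systematic relation between descriptor blocks
and chemistry. Passing tests therefore demonstrate the *machinery* —
selection, fitting, diagnostics, regularization — under the assumed
statistical model, not the chemical conclusions of any particular study.

## Problem sizes

The test suite and acceptance script use the sizes natural to this
application: the 15×33 fixture with 12/3 splits for the end-to-end paths;
n = 30, m = 8 (C(8,3) = 56 subsets) for GA-vs-exhaustive equivalence over
20 replicates; n = 60, m = 10 for 20-seed pipeline parameter recovery;
12-point sets for the regularization-efficacy checks. These are the regimes
the method is designed for; larger tables work unchanged but exhaustive
enumeration is capped at 1e5 subsets.

## Known limitations

- PRESS uses explicit refits (O(n) OLS solves); fine for n ≤ a few
  thousand, not tuned beyond that.
- The GA assumes a fixed equation length; it does not search across lengths
  or add spline/knot terms.
- The evidence approximation is Gauss–Newton (JᵀJ); far from a minimum the
  reported γ is only indicative.
- Exact reproduction of third-party splits or GFA trajectories is not a
  goal; equivalence is established at the level of selected subsets and
  statistics.
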