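# Methods

This note documents the statistical model behind `acqstruct`, the
assumptions of its synthetic-data generator, the numerical choices made
where the design was genuinely open, and what the tests do and do not
establish about real data.

## Instrument model

The default blueprint is a balanced social-emotional skills inventory:
5 domains × 18 facets (3/5/3/4/3 facets under O, C, E, A, N), 9 items per
facet — 3 positively keyed identity items, 3 negatively keyed identity
items forming antonym pairs with the positive ones, and 3 positively keyed
self-efficacy items; 162 items, 108 identity items, 54 pairs. Item
identifiers are synthetic tokens (`empathy_idpos_1`); item wording is out
of scope. Items are canonically ordered by (domain, facet, framing) so that
loading tables are comparable across runs; the facet order within domains
follows the published loading tables of the field instrument.

## Acquiescence index and correction

ACQ is the per-respondent mean of raw (un-reversed) identity responses.
On a balanced scale this mean is content-free in expectation, and exactly 3
for fully symmetric pair profiles — an invariant tested exactly. Correction
subtracts ACQ from *all* items, including self-efficacy items, which cannot
carry their own acquiescence information (they have no reverse-keyed
counterparts). Corrected scores are centered reals and are deliberately not
re-clipped to the 1–5 range.

Order of operations matters and is enforced by a regression test: centering
must precede key orientation. Reversing as 6 − x first and centering second
leaves `−2(ACQ − 3)` of style variance in every negative item (an exact
algebraic identity the test asserts), i.e. doubles rather than removes the
bias.

Missing data: ACQ is the mean over answered identity items; respondents
with fewer than 54 answered identity items (half) or more than 25% broken
antonym pairs are flagged `balanced_flag = False` (thresholds
configurable). The field administration was forced-choice, so no published
rule exists; this is the package's own documented choice. Cluster scales
require at least 2 of 3 (4 of 6) member items; the correlation stage uses
listwise-complete indicator rows by default (pairwise available).

## Synthetic-data generator

The generator is the test bed standing in for the undeposited field sample.
Its generative model, content first:

- domain scores θ ~ MVN(0, Φ), Φ unit-diagonal, default off-diagonal 0.3
  (moderate positive manifold typical of broad trait domains);
- facet scores f = γ·θ + √(1−γ²)·u, default γ = 0.8;
- latent item value y = key·(λ·f + secondary terms) + ε, default λ = 0.7,
  ε scaled so var(y) = 1;
- acquiescence as an additive latent shift a ~ N(μ_a − 3, σ_a) added
  *before* any keying is undone and blind to content; defaults
  μ_a = 2.95, σ_a = 0.37 on the response scale, the values observed in the
  field sample;
- four equally spaced thresholds (−1.5, −0.5, 0.5, 1.5) map the latent
  value to categories 1..5 (half-open: a value on a cut-point falls in the
  upper category);
- 5% uniform-random (insufficient-effort) responders; missingness
  completely at random (default 0).

Default secondary loadings (0.25) mimic the theoretically expected
cross-loadings reported for the instrument: responsibility → Amity,
self-confidence → Engaging, and the enthusiasm and respect self-efficacy
parcels → Negative-emotion regulation. They make the population structure
non-simple, so structure-recovery tests are not graded on an unrealistically
easy target.

The additive-shift-then-threshold response process is an assumption; the
field study gives no access to the latent response scale. Its observable
consequence — bounded categories attenuate the shift — is quantified
empirically by tests: at n = 10,000 the sample ACQ SD is within 0.05 of the
configured σ_a (attenuation factor ≈ 0.96 at these thresholds). What the
generator does **not** emulate: non-normal trait distributions, item-level
wording effects, differential item functioning, longitudinal structure, or
systematic (non-random) missingness. Passing recovery tests therefore show
the pipeline is correct under the stated model, not that real responses
follow it.

## Factor model

The measurement model is exploratory: Σ = ΛΦΛᵀ + Ψ with m = 5 factors on
k = 54 indicator correlations (df = k(k+1)/2 − (km + k − m(m−1)/2) = 1171).
Extraction:

- **ml** (default): Lawley's profile likelihood — uniquenesses ψ are
  optimized by L-BFGS-B (bounds [0.005, 1], ftol 1e-10) with loadings
  concentrated out through the eigendecomposition of Ψ^{−1/2}RΨ^{−1/2};
  returns canonical loadings (cross-checked in tests against R's
  `factanal`).
- **minres**: same profile structure, minimizing the off-diagonal residual
  sum of squares (closed-form-verified on equicorrelation matrices).
- **pca**: eigenvector loadings scaled by √eigenvalue, for the
  unconstrained-structure analyses of the identity-only, self-efficacy-only
  and joint indicator sets.

Uniquenesses at the 0.005 floor are Heywood cases; they are clamped,
flagged on the solution and logged. Within-person centering makes the
identity-indicator correlation matrix exactly singular (centered identity
items sum to zero per respondent), so correlation matrices with smallest
eigenvalue below 1e-6 are ridge-repaired to that floor with a warning; this
is a structural property of ipsatized data, not a numerical accident, and
it inflates the corrected branch's absolute χ² (the model cannot reproduce
a null direction) — consistent with the field study, where the corrected
model also fit worse in χ² terms despite the cleaner loading structure.

**Target rotation.** The rotation criterion is the weighted sum of squared
deviations from a partially specified target: theory-driven zeros outside
an indicator's intended domain, free cells elsewhere. Minimization uses
gradient projection (statsmodels' GPA core) on the oblique manifold by
default (orthogonal available), gradient-norm tolerance 1e-6, at most 1000
iterations, from the identity start plus 10 seeded random orthonormal
starts; the best criterion wins and non-convergence warns rather than
raises. The same machinery accepts fully specified targets (e.g. a known
population pattern), which the population-recovery tests use as their
oracle: on the exact population correlation matrix, rotation toward the
true pattern reproduces loadings and factor correlations to machine
precision, while the zero-target rotation is biased by design wherever true
secondary loadings conflict with the all-zero target (max error ≈ 0.08
under the default generator — documented, bounded, and expected).

This ML/minres-plus-target-rotation pipeline reproduces the point-estimate
structure of ESEM as fitted in SEM software; standard errors, robust
estimators and measurement-invariance machinery are intentionally out of
scope. That substitution is the package's central methodological
simplification.

**Alignment.** Factor order and sign are arbitrary after rotation;
solutions are aligned by exhaustive search over all m!·2^m permutations and
sign patterns (m ≤ 6), maximizing the summed diagonal congruence against
the one-hot target, with Φ transformed consistently.

**Fit statistics.** χ² = (n−1)·F_ML on the model-implied correlation
matrix; RMSEA = √(max(χ²−df,0)/(df(n−1))); CFI/TLI against the independence
baseline; SRMR over the lower triangle including the diagonal; BIC in the
χ²-based convention BIC = χ² − df·ln(n) (SEM programs differ here — the
label matters more than the constant). Saturated models report explicit
nulls.

## Congruence

The idealized target assigns each indicator a loading of 1 on its intended
domain and 0 elsewhere — deliberately ignoring known secondary loadings.
Congruence of empirical factor f with domain target d is computed as

- **Tucker** (default): Λ_f·T_d / (‖Λ_f‖‖T_d‖) — scale-invariant,
- **Pearson** (option): correlation over the k indicator rows —
  affine-invariant,

and both are written side by side by the report stage. Tucker is the
default because it is what the published congruence table for this
instrument contains: recomputed from the published loading matrices, Tucker
matches every printed cell to within 0.005, while row-centered Pearson runs
systematically lower (diagonal means 0.79 vs the printed 0.84 on the
corrected branch). The published raw-branch loading matrix is kept exactly
as printed — including its sign-reversed Amity factor — because the
published congruence values were evidently computed without re-alignment.

## Problem sizes and seeds

Simulation-based tests run at the study-condition scale the generator
encodes: n = 2000 for acquiescence-recovery checks (recovery r ≥ 0.9),
n = 5000 for structure-recovery and raw-vs-corrected congruence-gap checks
(gap ≥ 0.10 with acquiescence at the calibrated σ_a, |gap| ≤ 0.03 without),
n = 10,000 for the ACQ moment calibration. All randomness flows through
explicit integer seeds; the pipeline is deterministic end to end (byte
-identical report files under identical inputs and seed, asserted in tests).

## Known limitations

- No standard errors or confidence intervals for loadings or congruence
  coefficients; no robust (mean/variance-adjusted) test statistics.
- The χ²-based BIC is not comparable across software conventions.
- Pearson correlations of discretized 5-category responses are attenuated
  relative to the latent scale; the package does not use polychoric
  correlations, matching the published analysis rather than improving on it.
- The acquiescence index requires a balanced identity set; instruments
  without antonym pairing cannot be corrected this way and are rejected.
- Exhaustive factor alignment is limited to m ≤ 6 factors.
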