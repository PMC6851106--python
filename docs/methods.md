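# Methods

## Affected fraction and median-effect fitting

The affected fraction at dose *D* is computed at the **group level**:
fa(D) = 1 − (mean treated lesion area at D) / (mean control area). One
dose–effect curve is fitted per treatment, matching how such studies
report a single median-effect plot; per-animal areas are retained only
for bootstrap resampling. Whether group means or per-animal ratios are
the "right" sampling unit is genuinely open; group means are the default
and the per-animal information re-enters through the bootstrap.

fa ∈ {0, 1} has no log-odds, so fa is clamped into [ε, 1−ε],
ε = `clamp_eps` = 0.01 by default (allowed range (0, 0.05]); every clamp
emits a warning. Dose-0 records only define the denominator and never
enter the regression. Duplicate doses are pooled by mean area before fa
is formed.

The fit is ordinary least squares of log10[fa/(1−fa)] on log10 D. Any
log base gives identical (Dm, m); base 10 matches the conventional
median-effect plot. The linearization is exact, so noiseless synthetic
data refits to machine precision (asserted to 1e−9 relative in tests).
A non-positive slope (non-monotone dose–response) is flagged on the fit
(`increasing_ = False`) with a warning rather than an error, so
pathological bootstrap replicates can be detected and dropped upstream.
At least three distinct positive doses are required.

## Combination index

The "1:1" combination is **equipotent**: component doses stand in the
ratio Dm1:Dm2, each level multiplying both median doses by the same
factor (default ladder 0.25, 0.5, 1, 2, 4). Under this convention the
Loewe-additive expectation for the combination's total median dose is
(Dm1 + Dm2)/2, and CI(0.5) = Dm_comb/Dm_theo exactly — an identity
asserted over random parameter draws in the tests.

CI is computed in its constant-ratio two-term form (no mutually
nonexclusive third term). Each single drug's own m inverts its curve;
the combination's total-dose fit supplies one m for the pair. The
closed-form evaluation is cross-checked against brute-force bisection
inversion of the median-effect curve to 1e−9.

Classification bands are configurable. The default additive band is
(0.90, 1.30): in-vivo CI estimates inherit substantial propagation error
from two-significant-figure fit parameters, and this band reproduces the
reference study's printed labels (e.g. 1.28 additive, 1.35 antagonism,
0.32 synergism). The strict Chou-style band (0.90, 1.10) is available as
`CHOU_CI_BANDS`.

CI at extreme fa is hypersensitive to rounding of m (a 0.01 change in a
shape parameter moves CI(0.1) by tens of percent when m < 0.5); CI
values at fa = 0.1 are therefore reported but should be read as orders
of magnitude, not point estimates.

### Closure caveat

The median-effect family is **not closed under Loewe addition** unless
the component shapes are equal. A Loewe-additive combination of drugs
with very different m (say 0.2 vs 1.5) has a combined dose–response that
is visibly non-linear in log-odds/log-dose; refitting a straight line
and recomputing CI then gives curves that deviate from 1 away from
fa = 0.5 even with zero noise. This is a property of the method, not a
bug — empirically, max |CI − 1| over fa ∈ [0.1, 0.9] is 0 for equal m,
≈ 0.04 for an m-ratio of 0.9/1.1, and order 1 for strongly mismatched
shapes. Exact flatness claims in the tests are therefore made for
like-shaped components.

## Isobologram

Normalized coordinates a = D1/Dm1, b = D2/Dm2. The curved additivity
envelope is b_concave = (1−a)^(m1/m2) and b_convex = 1 − a^(m1/m2); both
run from (0, 1) to (1, 0) and collapse onto b = 1 − a when m1 = m2. The
published printed forms of these curves mix normalized and absolute
doses and are not dimensionally consistent in normalized space; the
closed forms above are the normalization (setting the normalized median
dose to 1) that reproduces the stated endpoints and the equal-shape
limit, and they are flagged as this package's interpretation rather
than asserted as the original authors' algebra.

The equipotent combination's experimental point sits at
a = b = Dm_exp/(Dm1 + Dm2), so a + b equals CI(0.5). Classification is
inclusive on the envelope boundary with a 1e−9 tolerance absorbing
floating-point jitter; any point with a or b beyond 1 is antagonism
outright.

## Rheology

Synergy parameters ΔG′ = G′_mix − (G′_sus + G′_muc) and likewise ΔG′′;
"mucoadhesive" requires both strictly positive. Sweeps are aligned by
log-log linear interpolation (exact for power-law moduli, which weak
gels approximate; plain linear interpolation is available and is used
automatically for a channel containing zeros). Extrapolation outside a
sweep's measured range is refused. A target frequency that was actually
measured is returned bit-exactly. Default reporting frequencies are 2.5,
5 and 10 rad/s.

Conventions disagree on whether G′′ > G′ or G′ > G′′ marks the
structured "pseudo-solid" regime; `pseudo_solid_check` reports strict
viscous dominance per frequency and never gates the synergy computation.

## Statistics

**Bootstrap.** Animals are resampled with replacement within each dose
group (control included), fa recomputed from resampled group means, and
the line refitted; replicates with non-finite fits or non-positive
slopes are dropped and counted (> 50% failures is an error). With n = 6
animals per group the naive bootstrap understates the variance of a
group mean by (n−1)/n, so replicate log-spread is inflated by
√(n/(n−1)) about its mean (`variance_correction`, on by default).
Percentile intervals at this design cover the generating Dm ≈ 92–93% of
the time at nominal 95% (measured in the test suite).

**Experimental vs theoretical Dm.** The additive expectation's bootstrap
distribution is (Dm1,b + Dm2,b)/2 over paired independent replicates.
The two distributions are compared by the Mann–Whitney overlap statistic
P = Pr(Dm_exp,b > Dm_theo,b′) over all pairs, with two-sided bootstrap
achieved-significance level p = 2·min(P, 1−P). A literal two-sample
rank-test p-value between replicate vectors would sharpen without bound
as n_boot grows — an algorithm parameter would drive the science — so
the achieved-significance form, whose power is set by the data, is used
instead. Verdicts at α = 0.05: subadditive if significantly above,
synergistic if significantly below, additive otherwise. Identical
replicate sets give p = 1; fully separated sets give p ≈ 0.

**Damage-area comparisons.** One-way ANOVA across groups, then Dunnett's
many-to-one comparisons against the ulcerated control via
`scipy.stats.dunnett` (simulation-based multivariate-t critical values;
seeded for reproducibility).

## Synthetic data

Generators are exact forward models of the equations above. Lesion areas
are lognormal about their group mean (positive, right-skewed; a
truncated-normal alternative sits behind the `noise` flag). Defaults:
6 animals/group, control mean 100 mm², dose ladder 0.25–4 × Dm,
`area_noise_sigma_log = 0.15`. The combination generator inverts the CI
equation by monotone root-finding in fa at every dose level, so a
prescribed constant CI (or a callable fa → CI profile) is honoured
exactly at each level; CI = 1 yields exact Loewe additivity. All
randomness flows from one seed; regeneration is bit-identical.

What the generator does **not** emulate: between-animal correlation,
dose-measurement error, non-lognormal outliers (moribund animals),
litter effects, and any pharmacokinetic mechanism behind an interaction
(the constant-CI model is purely phenomenological). Passing tests
therefore demonstrate correctness of the estimators on their own forward
model, not robustness to every feature of real lesion data.

## Simulation sizes and calibration checks

Problem sizes used by the test suite were chosen to keep the full run
around a few seconds while leaving comfortable statistical margins:
parameter recovery uses 500 replicate studies at σ_log = 0.1 with the
mid-slope reference parameterization (Dm 17.40, m 0.62), where the
median relative Dm error is ≈ 11% against a 15% bound; null (CI = 1)
calibration uses 100 simulated experiments, ≈ 93% of which return
"additive" against a 90% bound; qualitative verdict reproduction uses
the modal verdict over 25 independently seeded studies per drug pair,
because one six-animal study returns its expected verdict with only
~65–95% probability depending on the pair. Flat dose–response curves
(m ≈ 0.2) are intrinsically harder to recover than the mid-slope case
and carry correspondingly wider bootstrap distributions.

## Known limitations

* Group-mean fa discards within-group information at the fitting stage;
  the bootstrap reintroduces it only for uncertainty, not the point fit.
* CI confidence statements rest on the constant-ratio design; nothing
  here addresses non-constant-ratio response surfaces (Bliss, ZIP, HSA)
  or combinations of more than two agents.
* The isobologram envelope is the package's normalization of an
  ambiguous printed construction (see above).
* The rank-based verdict compares bootstrap distributions conditioned on
  one observed experiment; it is a plug-in test, not an exact
  small-sample procedure, and its type-I rate at n = 6/group is ≈ 7%
  rather than 5%.
* Rheometer data are taken at face value: no strain-amplitude check, no
  inertia or gap-loading corrections, and mucoadhesion is inferred, not
  mechanistically modelled.
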