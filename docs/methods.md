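# Methods

## Data model and conventions

A census (one tank-day) is a pair of occupation vectors, one per sex, over
slots 0..N with slot 0 the open tank.  Replicates are series of censuses
for one tank; they are grouped but never concatenated — replicate
boundaries matter for autocorrelation and for per-design partition
functions.  Slot 0 always exists in the data model; a design in which a sex
was never found outside carries a `delta` flag meaning "outsiders of this
sex are excluded from the configuration space".  For combined fits the
flags are recomputed from the pooled days, so one outsider day in either
replicate opens slot 0 for the whole combined series (this reproduces the
published configuration counts: 462 for the all-female design, 4704 for
the combined mixed design with female outsiders allowed).

The daily sharing level S_d sums the occupants of every den holding at
least two animals, pooling sexes; the linkage statistics count within-den
pairs by sex combination.  Animals outside dens never contribute to either.

## Canonical ensemble

Energies are dimensionless (k_B T = 1).  The Hamiltonian is
H = mu*(n0_f + n0_m) + U_ff*sigma_ff + U_mm*sigma_mm + U_fm*sigma_fm, with
the 1/2 pair factors absorbed into the pair counts.  The statistical weight
of a configuration is g * exp(-H), with g the product over sexes of
multinomial assignment counts.  Configuration spaces are ordered weak
compositions over distinguishable dens (pot symmetry is not quotiented;
the data support this — per-den mean occupancies are statistically
identical).  All spaces in scope have at most a few thousand states, so
partition functions, moments, connected 2- and 4-point correlations and
the sharing distribution are exact enumerations; weights accumulate in log
space, keeping |U| up to ~30 safe.

Tracing a parameter out (its statistic has no empirical support) is
implemented as a hard constraint on the space: no outsiders for `mu`, no
same-sex pairs for `u_ff`/`u_mm`, no mixed dens for `u_fm`.  This equals
the finite-U limit: at U = 30 the full-space ensemble agrees with the
constrained space to ~1e-13, which also reconciles the two published
configuration counts for the mixed design (4704 on the full space vs 1680
with male pairs excluded).

## Inference

The model is an exponential family, so the MLE solves the moment
conditions (ensemble = empirical means of the sufficient statistics) and
the log-likelihood is concave.  Newton iterations on the moment conditions
start at zero, use the statistic covariance as exact Jacobian, backtrack
on residual growth, and stop when every per-day moment residual is below
1e-10; estimates are confined to [-30, 30] (the numerical limit of the
enumeration weights).  Parameters whose statistic is identically zero
across the days of a fit are traced out automatically before fitting.
Heterogeneous designs (e.g. the 5-pot and 6-pot all-male replicates)
combine through the summed log-likelihood with shared parameters and
design-specific partition functions — equivalently, a day-weighted
effective free energy.  Standard errors come from the inverse Fisher
matrix of the active parameters, M times the (weighted) statistic
covariance at the optimum; traced parameters carry no error.

The empirical mean of an active statistic must lie strictly inside the
attainable range of the (day-weighted) configuration spaces; means on or
beyond the boundary raise an "unattainable moment" error rather than
drifting to the box bound.

The joint all-conditions fit keeps each treatment group's outsider flags
(pooled within the group) and decides interaction tracing from the pooled
statistics of the whole fit, so nothing is traced there; an
inverse-variance-weighted mean of the per-group estimates is reported as a
cross-check.  The two methods agree within one combined standard error on
the study data.  Published combined values lie within their quoted errors
of both, but neither method reproduces them exactly; the aggregation
behind the published set is not documented, and we report our own.

Sex contrasts use t = |a - b| / sqrt(se_a^2 + se_b^2) with a one-sided
standard-normal p-value.

### Model comparison

Three one-site Hamiltonian families are compared on the all-female days:
the one-parameter on-site (Hubbard-type) energy, a "linear" energy
proportional to the sharing level above a threshold nu (nu profiled over
2..K; p = 2), and a three-level energy with free values at occupancy 1, 2
and >= 3.  The comparison uses the small-sample AIC
(-2 log L + 2p + 2p(p+1)/(M-p-1)) and, for continuity with the published
table, BIC = -2 log L + 2p log M (the standard p log M variant is reported
alongside).  The three-level family has an approximate gauge direction
(sum_i n_i = K nearly fixes a linear combination of its level counts), so
its likelihood surface has a flat valley: the fit stops when the
likelihood plateaus and the row is flagged unconverged; its maximized
likelihood is what the comparison needs and is well determined.  For the
linear family our exact maximum (V = 1.09 in the half-convention, log L =
-49.36) differs from the published row (0.52, -49.07), which we could not
reproduce under any variant of the printed definition; the substantive
conclusion — the one-parameter on-site model has the lowest AIC — is
unchanged and is what the tests pin.

### Predicted-observable uncertainty

The error matrix of the observables combines the intrinsic day-to-day
fluctuation (connected 2-point covariance) with a parameter-uncertainty
term, (2M)^-1 times the connected 4-point correlations contracted with the
parameter covariance.  The correction vanishes as M grows; because it is
built from 4-point cumulants it can be marginally negative for individual
entries (measured -0.1% at worst here).  Monte-Carlo refitting (sample M
days, refit, look at the spread of the predicted means) validates the
parameter-propagation identity: for an exponential family that spread
equals the intrinsic covariance divided by M, which the simulations
reproduce within 25% for well-supported observables at M as small as 7.

## Neutral null and power

Neutral animals are a multinomial: K labeled animals thrown uniformly into
N dens, no outsiders.  Its mean sharing level has the closed form
S0 = K[1 - (1 - 1/N)^(K-1)], verified against enumeration (3.59 for
N = K = 6, 2.95 for N = K = 5).

The power analysis treats the M-day sample-mean sharing as Gaussian.  The
departure is parametrised by a per-den entry probability theta; the mean
uses m1(theta) = N K theta [1 - (1-theta)^(K-1)], the form that equals S0
at theta = 1/N and makes the effect-ratio scale meaningful.  The variance
uses m2 = [N(N-1) theta^2 + N theta (1 - (1-theta)^N)] / M; at the neutral
theta this evaluates to 1.50 per day, within 3% of the exact enumerated
variance of S_d (1.535), whereas substituting the mean-consistent form
would overstate the variance threefold.  The test is two-sided at level
alpha against the Gaussian null, so the power at ratio 1 is alpha exactly.
Under this construction, five days detect sharing at 55% of neutral with
91% power; the social side is harder — at 135% of neutral, five days give
only 61% power, less than earlier design claims — and the Gaussian
approximation is crude (within 0.2 of the exact-null oracle) below M = 4.

## Classical tests

Location tests are one-sided one-sample t-tests with the sample (M-1)
standard deviation; this convention reproduces the published p-values,
including the pots-limited rows once the neutral reference is corrected to
the exact 5.8125.  The treatment ANOVA is the standard unbalanced one-way
decomposition recomputed from the daily sharing columns
(126.7/60.1/186.8, F = 28.8 on 3 and 41 df); the published table's sums of
squares are inconsistent with its own data columns and are asserted as a
documented discrepancy.  Welch post-hocs are one-sided with
Welch–Satterthwaite df, corrected by 12 (six contrasts, two sidednesses).
The sharing-level autocovariance is computed within replicates (each
demeaned separately) and pooled; the relaxation time is twice the
main-lobe area of C(tau)/C(0) — the trapezoidal integral to the first
interpolated zero crossing — because side lobes of 5-7-day demeaned
series are finite-sample noise.  This gives 0.82 days on the study data
and ~0.9 on white-noise simulations, supporting day-level independence.

## Predictions

Design surfaces evaluate the fitted ensemble over any (N, K_f) at fixed
K; every cell is an exact enumeration.  The equation of state traces
(mean outsiders, mean f-m linkage) as dens are removed: both grow together
until N = 2, beyond which linkage falls while outsiders keep rising.
Uncertainty is emitted twice — a one-sigma contour from the error matrix
and a 10%-relative-error box per observable, since published "10%
uncertainty" ellipses follow the relative convention.  Outlier screening
uses relative errors: the mixed equal-pots point sits ~90% away from its
predicted outsider count (its total absence of male-male sharing is the
culprit), while both pots-limited points sit within ~25%.

The dense limit (1 << N << K) treats each den as a grand-canonical site
with weight exp[U(r n - n(n-1)/2)], r = mu/U, truncated at relative weight
1e-15.  The weight deliberately omits the 1/n! labeled-animal factor: the
unlabeled convention is the one whose discrete saddle point yields the
reference forms rho = r + 1/2 and xi = r^2/2 (the labeled canonical model
instead approaches a 1/n!-weighted ensemble at a shifted fugacity and does
not obey those forms).  The closed forms hold within 10% (rho, r >= 2) and
15% (xi, r >= 4) at U = 0.5; deviations at small r are the n >= 0 boundary,
and xi carries a variance offset (1/U - 1/4)/2.  At U ~ 12 the occupancy
locks into a Mott-like staircase with steps at integer r.

## Synthetic data

Days are sampled exactly from the enumerated canonical distribution by
inverse-CDF lookup (no MCMC); a master seed spawns an independent child
stream per replicate, so any replicate is reproducible in isolation and a
fixed seed gives bit-identical datasets.  The generator's presets mirror
the eight experimental setups (designs, day counts and outsider flags as
realised).  Sampler exactness is tested in total variation against the
enumerated pmf at 10^6 draws (an exact sampler's expected TV on the
462-state neutral space is ~0.008 there; at 10^5 draws the noise floor of
a perfect sampler is ~0.024, so smaller draws cannot certify a 0.01 bound)
and by per-configuration 3-sigma checks at 10^5 draws.

The recovery study refits datasets drawn at the combined-fit parameters.
Its default scenario pairs a pots-equal arm (N = 6, 3f:3m) with a
pots-limited arm (N = 2, 2f:4m), 25 days each, fitted jointly — mirroring
the study's combination of heterogeneous designs, with the male-heavy
limited arm ensuring the strongly suppressed male-male pairs are observed
in essentially every draw so that all four parameters stay identifiable.
At that size all absolute biases are below 0.1 (the residual being
ordinary O(1/M) ML bias) and one-sigma Fisher intervals cover within a few
points of the nominal 68%.  Fits that lose support for a parameter are
counted and excluded, never silently absorbed.

## What the simulations do and do not show

The generator emulates exchangeable days from the fitted model — the
correlation-time analysis justifies exchangeability for this study — but
not individual identity, size classes, within-day dynamics, or any
behavioural heterogeneity between animals (the study itself flags one
highly anti-social female).  Passing recovery tests therefore validates
the estimator under the model's own assumptions, not the model's adequacy
for new animals; the KL diagnostics and the model-selection table are the
in-sample adequacy checks.

## Known limitations

- Estimates at the study's M (5-14 days) carry large errors; the Fisher
  (asymptotic) errors are honest but approximate at such M.
- The published combined parameter set and two published table rows (the
  treatment-ANOVA sums of squares, the linear-model row of the model
  comparison) are not exactly reproducible from the published data; the
  package reports its own recomputed values and the tests document the
  gaps.
- The power analysis is a Gaussian design heuristic; below M = 4 use the
  exact convolution of the enumerated null instead.
- Exact enumeration is the design point: the implementation targets
  laboratory-scale systems (configuration spaces up to ~10^4-10^5 states),
  not field-scale populations.
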