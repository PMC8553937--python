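# Methods

## Model

`catiam` estimates unowned-cat abundance at sighting-defined sites by
fusing three observation streams through a shared latent abundance.
Each site *i* carries an occupancy indicator `z_i ~ Bernoulli(Ω)` and a
positive intensity `λ_i` with
`log λ_i = μ + Σ_j β_j x_ij + ε_i`, `ε_i ~ N(0, σ²)`; the true abundance
is `N_i = z_i λ_i` (a continuous intensity — no integer latent abundance
is imposed, since `N_i` only ever enters Poisson means). Survey
replicates are `Poisson(N_i p_survey + m_survey)`, report replicates
`Poisson(N_i p_report + m_report)`, and expert consensus counts
`Poisson(N_i)`. The two citizen streams have separate detection
probabilities `p` and false-positive rates `m` because their collection
mechanisms differ; the expert stream is unbiased by design and is what
identifies `p` and `m` at all. Expert information is also treated as
exact at the presence/absence level: a positive consensus fixes
`z_i = 1`, a confirmed absence fixes `z_i = 0`, and `z_i` is sampled
only at sites without expert data.

Priors: `p, Ω ~ U(0,1)`; `m ~ U(0,5)`; `μ ~ Normal(0, SD 10)` — the
"N(0,100)" convention is read as variance 100, since an SD of 0.1 would
pin the intercept; `σ ~ U(0,3)`; `β_j ~ U(−5,5)`, with the half-width
configurable for the prior-sensitivity arm.

## Data preparation

Survey responses are multiple-choice; categories are encoded by their
midpoints (none → 0, 1–2 → 1.5, 3–4 → 3.5, 5–9 → 7) and the open top
category "10 or more" as 15. Sites are single-linkage clusters at a
500 m cutoff: records within 500 m of each other share a site, chained
transitively (connected components of the proximity graph). Single
linkage was chosen over complete linkage because the cutoff exists to
merge duplicate reports of the same animals, and duplicates chain
through intermediate sightings; the partition is invariant to record
order and coordinate translation. Distances are Euclidean on metre
coordinates (projection distortion is negligible at 500 m); lon/lat
input is accepted and measured by haversine. Expert consensus per site
is the sum of distinct-individual expert counts (the expert protocol
precludes double counting). Half-integer survey midpoints are kept
as-is at this stage; the likelihood handles them (below). The IMD
decile enters the model unstandardized on its 1–10 scale (decile 1 =
most deprived, the official English convention, so `β_IMD < 0` means
more cats in more-deprived areas); population density is standardized
against the fitting data and the transform is retained so new areas
standardize against the same frame.

Half-integer counts and the Poisson pmf: the default
`likelihood_mode="round_half_up"` rounds 1.5 → 2 and 3.5 → 4 for a
proper pmf; `continuous_gamma` instead evaluates the Poisson density
with the factorial replaced by Γ(y+1). The two differ only in
parameter-independent constants for integer data and agree in the sign
and magnitude of fitted effects on simulations.

## Sampler

Because replicate means are constant within a site, the citizen
likelihood reduces to per-site sufficient statistics (replicate sums
and counts), so every full-likelihood evaluation is O(n_sites). The
sampler is Metropolis-within-Gibbs with exact conjugate steps wherever
they exist:

* `μ` — conjugate normal given the site log-intensities. `μ` and the
  mean log-intensity are nearly collinear; Gibbs sampling this pair's
  conditional removes the slow random-walk mixing a pure
  component-wise scheme suffers here.
* `β_j` — conjugate normal truncated to the uniform prior bounds
  (inverse-CDF sampling, with a far-tail fallback).
* `Ω` — Beta conjugate given all `z_i`.
* `p`, `m`, `σ` — adaptive random walks on logit-transformed scales
  (logit of `x/upper`), with the uniform-prior Jacobian in the
  acceptance ratio. Proposal scales adapt in batches of 50 during
  burn-in toward 44% acceptance and are frozen afterwards.
* `log λ_i` — vectorized per-site random walk for occupied sites
  (sites are conditionally independent given the globals), with
  per-site adaptive scales; for currently unoccupied sites `λ_i` is
  likelihood-free and is refreshed from its lognormal prior.
* free `z_i` — Bernoulli full-conditional Gibbs.

Chains are initialized overdispersed around crude data-informed values
(log of the pooled site count, or the expert count where present, plus
unit-scale noise); runs default to 3 chains × 20,000 iterations with
10,000 burn-in, and a thinned 100,000/60,000/4 preset is provided for
slower-converging covariates (UK-adjusted deprivation quintiles).
Convergence is summarized by the classic Gelman–Rubin statistic
(`sqrt(((n−1)/n W + B/n) / W)`) on retained draws; any R̂ ≥ 1.1 flags
the result and logs a warning rather than silently passing. Identical
seeds give identical draws; chain streams are spawned from a single
seed sequence.

## Synthetic studies

The generator emulates the study design: 162 sites over five urban
areas, survey replicates per site uniform on 5–30 and reports on 1–10
(matching ~3,100 surveys and ~880 reports over 162 sites), expert
counts at 64% of sites, survey detection 0.179 / misidentification
0.72, report detection 0.245 / misidentification 1.8, and effects
−0.32 (IMD decile) and 0.31 (standardized density). IMD deciles are
drawn uniformly on 1–10 and density as standard normal, independently
by default (an option injects correlation, since real areas confound
them). Random streams are split per data type so changing replicate
ranges does not perturb the latent states.

The intercept, residual SD and occupancy are not published, so the
defaults are set once on scientific grounds: `μ = 2.7` puts the median
occupied site at ≈2.6 cats per 0.2 km² site (≈13 per km², inside the
reported 1.9–57 per km² range of site averages); `σ = 1.27` makes the
two covariates explain ≈37% of site-level log-abundance variance, as
in the study; `Ω = 0.8` reflects that sighting-defined sites are
mostly, but not certainly, occupied. Expert confirmed absence is
encoded as `w_i = 0` from the same Poisson draw, with the occupancy
flag set by the count's positivity.

What the generator does not emulate: spatial autocorrelation in
abundance, temporal dynamics, the empirical joint covariate
distribution of real urban areas (deciles are uniform here; the real
campaign oversampled deprived areas), and owned-cat populations.
Passing recovery tests therefore show the estimator is calibrated for
data meeting the model's assumptions at the study's scale — not that
real sightings meet them.

## A known, deliberate approximation

Fixing `z_i = 0` at expert "confirmed absence" sites treats the expert
as infallible at the presence level, but the generator (and plausibly
reality) lets an occupied site with small `λ` yield an expert count of
zero — probability `e^{−λ}`. Clamping such sites to `z = 0` censors
low-abundance sites: their counts are attributed to misidentification
and their covariate signal is lost. On 20-replicate recovery batteries
this appears as a downward bias in `Ω` (≈ −0.18) and `σ`, a small
upward bias in `m`, and mild attenuation of `β` — while `μ`, `p` and
`β` still achieve ≥75–95% coverage of 95% credible intervals. A
dedicated test refits on data whose absence labels reflect the true
occupancy (the inference model's own assumption) and recovers nominal
coverage for `Ω` and `σ` too, isolating the bias to the labelling
convention rather than the sampler. The convention is retained because
it mirrors how expert consensus is used in practice.

## Projection

Predicted abundance for a small area is
`exp(μ + β_IMD·IMD + β_PD·min(PD_std, cap)) · A / 0.2` per posterior
draw. Choices:

* The reference site area is 0.2 km² — the 20 ha assumed-maximum home
  range that defined the 500 m clusters; it is configurable because the
  area implied by the scaling parameter is not uniquely determined.
* The density cap defaults to 15,129 people per km² (the largest
  density among fitted sites) and is applied on the standardized scale;
  extrapolating a positive log-linear density effect into denser areas
  (central London) would otherwise inflate totals without support.
* The formula is evaluated literally: no site random effect, no
  occupancy factor, no lognormal mean correction (`exp(σ²/2)` is
  available behind a flag, default off). Site-level predictions are
  therefore systematically imprecise relative to fitted site
  posteriors; aggregation over many areas is where the projection is
  meaningful, and draw-wise aggregation (totals formed per draw, then
  summarized) keeps interval widths honest about posterior dependence.
* UK-adjusted deprivation quintiles (1–5) are supported as an
  alternative covariate scale; this requires a refit — no
  decile-to-quintile coefficient conversion is attempted.

## Validation battery

Six arms, mirroring how a hierarchical abundance model should be
checked: (1) simulate-and-refit recovery reporting per-parameter 95%
CRI coverage and signed bias, with non-converged replicates reported,
never dropped; (2) Gelman–Rubin convergence plus the null-vs-covariate
residual-variance comparison — variance explained is
`1 − E[σ²_cov]/E[σ²_null]` over retained draws (posterior means by
default, medians as an option), reported unclamped; (3)
leave-one-study-area-out cross-validation (five refits, each
withholding one area's sites entirely); (4) single citizen-source
refits (survey-only and report-only, expert data untouched); (5)
refits under β prior half-widths 0.5, 5 and 10, flagging posteriors
that pile within 5% of a bound; (6) a quasi-Poisson GLM screen
(log link, Pearson-dispersion-scaled SEs, two-sided t-tests at 0.05)
on per-site abundance estimates from the null model.

## Problem sizes and numerics

The recovery battery runs at a reduced preset (3 × 4,000 iterations,
burn-in 2,000) over 20 replicates of the full 162-site design; the
worked analysis uses full-length runs (3 × 20,000). The acceptance
script thins the posterior to 1,000 draws before projecting onto the
33,988-area table to keep the draw-by-area matrix modest. Truncated
normal draws fall back to a robust tail sampler when the interval mass
is below 1e−12; `0·log 0` terms in the Poisson likelihood are defined
as 0; proposals that saturate the logit transform numerically are
rejected in place.

## Limitations

Site abundances are exchangeable given covariates — no spatial random
field; detection and misidentification are homogeneous across
observers and sites; the projection inherits the fitted covariate
ranges and is conservative (capped) beyond them; occupancy and
residual site effects are absent from the prediction formula, so
fine-scale predictions carry irreducible error; and national totals
from synthetic runs depend on the generator's intercept, which the
study did not publish, so only their relative structure is
interpretable.
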