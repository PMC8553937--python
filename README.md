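# catiam — integrated abundance modelling of unowned urban cats

Unowned (stray and feral) domestic cats are hard to count: most records
come from residents, who both miss cats that are present and report owned
cats as unowned. `catiam` implements an **Integrated Abundance Model
(IAM)** that corrects those biases by fusing two error-prone
citizen-science count streams — door-to-door survey responses and ad-hoc
resident reports — with accurate expert counts available at a subset of
sites, and then projects the fitted effects of area deprivation and human
population density onto small-area census geographies to obtain spatially
explicit, national-scale abundance estimates with full posterior
uncertainty.

The package is aimed at quantitative ecologists and animal-welfare
analysts working with opportunistic urban wildlife records.

## The model

Sites are clusters of geo-referenced sightings within 500 m of each other
(the diameter of a circular 20 ha home range is 504 m), with individual
records kept as replicate counts. For site *i* and replicate *j*:

```
y_ij ~ Poisson(N_i p_y + m_y)        survey counts
u_ij ~ Poisson(N_i p_u + m_u)        report counts
w_i  ~ Poisson(N_i)                  expert consensus counts (subset of sites)

N_i = z_i λ_i,   z_i ~ Bernoulli(Ω)
log λ_i = μ + Σ_j β_j x_ij + ε_i,    ε_i ~ N(0, σ²)
```

`p` is the per-replicate detection probability of a truly present unowned
cat, `m` the expected number of owned cats misidentified as unowned per
replicate (false positives), `Ω` the occupancy probability, and the
covariates `x` are the English Index of Multiple Deprivation decile
(1 = most deprived, unstandardized) and standardized human population
density. Where an expert consensus exists, occupancy is taken as known and
`z_i` is fixed. Priors: `p, Ω ~ U(0,1)`, `m ~ U(0,5)`, `μ ~ N(0,10²)`,
`σ ~ U(0,3)`, `β ~ U(−5,5)`.

Fitting is by an adaptive Metropolis-within-Gibbs sampler with a
vectorized sufficient-statistic likelihood (`catiam.model`); convergence
is monitored with the Gelman–Rubin statistic (R̂ < 1.1). Predicted
abundance for a small area with deprivation IMD, standardized density PD
and land area A is

```
exp(μ + β_IMD·IMD + β_PD·min(PD, PD_max)) · A / 0.2
```

evaluated per posterior draw, with density truncated at the largest value
seen during fitting and totals aggregated draw-wise.

Because the raw sighting data are not public, `catiam.synthetic`
generates studies with the same structure (162 sites in five urban areas,
replicated survey/report counts, ~64% expert coverage) for testing,
calibration and worked examples.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on a
synthetic study and write their tables under `results/`:

```
python analysis/01_simulate.py    # synthetic study + UK-shaped area table
python analysis/02_preprocess.py  # 500 m clustering, site construction
python analysis/03_fit.py         # null + covariate IAM (3 chains x 20,000)
python analysis/04_validate.py    # recovery, cross-validation, priors, GLM
python analysis/05_predict.py     # projection to small areas
```

`03_fit.py` prints the posterior summaries, for example (truth in
parentheses: p_survey 0.179, p_report 0.245, m_survey 0.72, m_report 1.8,
β = −0.32, 0.31):

```
      p_survey:   0.183 (  0.167 to   0.200; 95% CRI)  R-hat 1.002
      p_report:   0.234 (  0.208 to   0.262; 95% CRI)  R-hat 1.002
      m_survey:   0.770 (  0.724 to   0.816; 95% CRI)  R-hat 1.000
      m_report:   1.900 (  1.788 to   2.017; 95% CRI)  R-hat 1.000
      beta_imd:  -0.285 ( -0.392 to  -0.182; 95% CRI)  R-hat 1.000
  beta_popdens:   0.233 ( -0.016 to   0.484; 95% CRI)  R-hat 1.000

P(beta_imd < 0)     = 100.0%
P(beta_popdens > 0) = 96.7%
variance explained by covariates = 28.6%
```

i.e. the sampler recovers the generating detection and misidentification
rates, finds more cats in more-deprived and denser areas with high
posterior certainty, and attributes about a third of the site-level
log-abundance variance to the two covariates.

A `catiam` console script exposes the same stages
(`simulate | cluster | fit | validate | predict`) for ad-hoc use.

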