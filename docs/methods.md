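# Methods

## Model

`dynocc` implements the standard multi-season (dynamic) site-occupancy
model. Each surveyed site i carries a latent binary state z[i,t] per
primary period t (here a summer or winter camera-trapping season, within
which occupancy is assumed closed). The state is initialized by the
initial-occupancy probability psi1_i, and evolves as a two-state Markov
chain: an unoccupied site becomes occupied with colonization probability
gamma[i,t], an occupied site empties with extirpation probability
epsilon[i,t]. Observation is a weekly detection/non-detection y[i,t,j]
per secondary occasion j: Bernoulli(p_i) given occupancy, and
structurally zero otherwise (no false positives). Occasions outside a
deployment window are missing and contribute nothing to the likelihood;
a site-period with no deployment contributes an emission of one for both
latent states, so sites that entered the survey late are still modelled
from the first period (their early periods are simply uninformative).

All four probabilities sit on logit-linear predictors with fixed column
layouts (intercept-first):

- psi1: moth damage severity, percent cover, road distance;
- p: percent cover, zone area, plus a site-level random intercept
  eta_i ~ Normal(0, sigma_eta) absorbing unmodelled detection
  heterogeneity (lure placement, camera angle, microsite);
- gamma and epsilon (separate coefficient vectors, same design):
  precipitation, season, precipitation x season, zone area, cover,
  zone area x cover, moth, time-since-disturbance (tsd), moth x tsd,
  one row per site x transition.

Continuous covariates are mean-centred and scaled by the sample standard
deviation (n-1 denominator), so a coefficient is the logit effect of a
one-standard-deviation change; the fit-time constants are stored and
always reused for prediction grids. The ordinal moth score (0-4) is
standardized like a numeric covariate so it can enter interactions on a
comparable scale. The season column is the transition-class dummy:
0 for autumn (summer -> winter, carrying the preceding summer's rain),
1 for spring (winter -> summer, carrying the preceding winter's snow).
The transition at index t carries period t's precipitation total and
tsd. Precipitation is a statewide per-period total by default, but the
design accepts a site x period table because the transition predictor
indexes precipitation by both site and time; the recovery scenario uses
spatially varying totals (see below).

## Inference

The latent chain is marginalized with the two-state hidden-Markov
forward algorithm rather than sampled. Emissions are computed from the
per-site-period sufficient statistics (detections d, surveyed occasions
m, valid because p is constant within a site) with a per-cell log-scale
shift to avoid underflow; the general per-occasion-p form is kept as a
reference implementation and tested against brute-force enumeration
over all 2^T latent sequences.

Priors are weakly informative on the standardized scale:
Normal(0, 2.5) on every coefficient, half-Normal(0, 1) on sigma_eta
(sampled as log sigma with the Jacobian), and a non-centred
parameterization eta_i = sigma_eta * eta_raw_i with eta_raw ~ Normal(0,1),
which removes the funnel geometry. All prior scales are configurable in
`RunConfig`.

Sampling is plain Hamiltonian Monte Carlo written in-package (no
probabilistic-programming dependency): exact gradients come from the
forward-backward state and pairwise marginals (the logit-scale score of
a transition probability is the expected flow through its branch minus
the probability-weighted complement; the detection score is the
occupied-state marginal times the Bernoulli residual d - m p, verified
against finite differences to 1e-5 relative). Each chain draws a random
normal(0, 0.5) start, moves it with a short deterministic L-BFGS ascent
(<= 150 iterations) so warmup adapts on near-stationary draws, then runs
dual-averaging step-size adaptation (target acceptance 0.85) with a
diagonal mass matrix estimated from the middle half of warmup, and
jittered trajectory lengths of 5-15 leapfrog steps (measured to give the
same mixing as longer trajectories at half the cost on this posterior).
Defaults are 3 chains x (2500 warmup + 5000 draws), scaled down in
experiments; chains are seeded from (seed, chain index) and runs are
bit-reproducible. Starting every chain from the same mode
neighbourhood would mask genuine multimodality; none has been observed
in this unimodal marginalized posterior, and chains still start from
distinct random draws.

Convergence uses the split-chain rank-normalized R-hat (arviz) over all
sampled coordinates including the random effects. Coefficients are
summarized by the posterior median, central 95% interval, and
p_pos = P(beta > 0 | data) on the pooled post-warmup draws, graded as
strong support at p_pos >= 0.90 or <= 0.10 and moderate at >= 0.70 or
<= 0.30, with strong taking precedence on the shared boundary; medians
with |median| > 1 are flagged as large effects.

## Derived dynamics and grid prediction

Per posterior draw and grid cell: psi trajectories by the recursion
psi[t+1] = psi[t](1-eps[t]) + (1-psi[t])gamma[t]; turnover
tau'[t] = psi[t] eps[t] + (1-psi[t]) gamma[t]; the seasonal rate of
change lambda = psi_last/psi_first comparing the first and last year
within each season class; and the stable state psi_eq = gamma/(gamma+eps),
the unique fixed point of the recursion under constant rates. Quantities
are derived draw-wise and summarized afterwards (the contract), never
derived from summaries. Cells with more than 40% high-development cover
or water are removed before anything is computed. Decline proportions
c_s/c_w count cells with lambda strictly below 1 on the posterior-median
lambda map (a draw-wise posterior of c is also reported). Seasonal
stable states evaluate gamma and epsilon at the season's entering
transition (autumn for winter, spring for summer) with precipitation and
tsd fixed at that transition class's mean standardized values — the
covariate settings for psi_eq are otherwise under-determined, and this
choice makes the two maps interpretable as "average autumn/spring
conditions held fixed". Degenerate cells (psi_first = 0, or
gamma = eps = 0) are flagged NaN, never silently dropped.

## Synthetic data

The generator emulates the survey that motivated the package: eight
alternating summer/winter seasons (2019-2023 calendar), a staggered
roll-in of 100 -> 200 -> 240 sites with a draw-down to 100 in the final
winter, twelve weekly occasions per season, paired cameras pooled at the
site. Covariate marginals are chosen to be realistic for a small,
densely roaded coastal state: log-normal zone areas (median 1.5 km^2),
beta-distributed percent cover skewed toward forest, exponential road
distances (mean 0.6 km), a damage-severity distribution favouring light
damage, and truncated-normal seasonal precipitation (rain mean 22 in,
snow mean 32 in). Detected occasions can be expanded into clustered
photo bursts (1 + Poisson(4) photos, exponential ~2-min gaps, burst span
capped at 15 min so one burst is one independent event, optional
>4-hour revisits) so the independence filter is exercised end-to-end;
with revisits disabled, filter + history rebuild reproduces the directly
simulated y exactly, and that identity is tested.

What the generator does not emulate: spatial autocorrelation between
sites, animal movement (detections are conditionally independent given
occupancy), camera failure mid-deployment, misidentification, or
species interactions. Passing recovery tests therefore demonstrates
correctness of the estimator under the model's own assumptions, not
robustness to their violation in field data.

Two named scenarios ship with the package. The "paper" scenario uses
published bobcat posterior medians as generating truth where reported
(season 1.63 and precipitation x season 1.27 on colonization, cover
-1.07, tsd 1.14; zone area -1.18, cover -0.32, interaction -0.36 on
extirpation; moth -0.76 and road distance 1.14 on initial occupancy)
with unreported terms at zero and intercepts set for a sparsely detected
felid. The "recovery" scenario (120 sites, all periods, moderate
effects |beta| <= 1.1, sigma_eta 0.5) drives the calibration
experiments; it gives precipitation a spatial standard deviation of 4 in
around the statewide total because with a purely statewide value the
precipitation coefficients rest on only seven distinct design points and
are weakly identified — a known-latent-state GLM oracle shows
per-realization errors up to ~1 for those terms at this size, an
information limit no estimator can beat.

## Recovery experiment and numerical choices

The recovery experiment simulates and refits the recovery scenario
(3 chains x 500 warmup + 1000 draws per replicate) and reports three
things: worst R-hat across replicates (convergence), pooled 90%
credible-interval coverage of the generating coefficients
(calibration; binomially compatible with 0.9 across 20 replicates x 27
coefficients means staying within [0.7, 1.0]), and the replicate-
averaged posterior-median bias per non-intercept coefficient (within
0.35 of truth). Bias is assessed on replicate averages because a single
realization's posterior median carries irreducible sampling noise of
0.3-0.5 for the weakly replicated temporal covariates; the average over
20 replicates isolates systematic error. Problem sizes throughout the
tests (20-120 sites, 4-8 periods, 6-12 occasions, hundreds to a few
thousand draws) are chosen to exercise every code path at scales where
the statistical checks are sharp.

Other numerical choices: probabilities inside the likelihood are
clipped to [1e-12, 1 - 1e-12] before logs; a detection at a site the
parameters make unoccupiable returns -inf rather than raising;
standardization requires at least two distinct values and fails loudly
on constants; grid covariates more than 4 standardized units outside
the fit range only warn (extrapolation is the user's decision);
posterior draws are thinned evenly (never resampled) for grid
prediction, 500 draws by default.

## Limitations

Detection probability is constant across occasions within a site
(no behavioural or temporal detection covariates); the random effect is
on detection only; no goodness-of-fit machinery, model selection, or
spatial smoothing is provided; the CLI's `all` command runs
detect-fit-derive-predict as one pass with file-based intermediates
rather than separately resumable subcommands.
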