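# dynocc

Dynamic (multi-season) occupancy modelling for camera-trap surveys, built
for mesocarnivore-style monitoring programs: paired trail cameras at
gridded sites, seasonal primary periods, weekly secondary occasions, and
questions about where a species persists, colonizes, or disappears as the
landscape changes.

The package covers the full path from raw photo records to occupancy
dynamics:

1. **Detections** — photos are collapsed into independent detection events
   (a photo counts when at least 20 min — configurable — has elapsed since
   the last kept photo of that species at that site, cameras pooled), then
   binned into weekly detection histories `y[site, season, week]` with
   missing values outside deployment windows.
2. **Design** — covariates (moth-defoliation severity, percent vegetation
   cover, road distance, road-bounded zone area, seasonal precipitation,
   season, time since disturbance) are mean-centred and scaled, and
   assembled into the fixed linear predictors of the four submodels.
3. **Model** — the classic dynamic occupancy model: latent occupancy
   z\[i,t\] starts at ψ₁ᵢ and evolves with colonization γᵢₜ (0→1) and
   extirpation εᵢₜ (1→0); detection is imperfect with probability pᵢ per
   occasion when occupied and impossible when not. On the logit scale,

       logit ψ₁ᵢ = x′ᵢ β_ψ₁
       logit γᵢₜ = β₀ + β₁ precipᵢₜ + β₂ seasonₜ + β₃ precipᵢₜ·seasonₜ
                 + β₄ zoneᵢ + β₅ coverᵢ + β₆ zoneᵢ·coverᵢ
                 + β₇ mothᵢ + β₈ tsdₜ + β₉ mothᵢ·tsdₜ
       logit εᵢₜ =  (same ten terms, separate coefficients)
       logit pᵢ  = x′ᵢ β_p + ηᵢ,   ηᵢ ~ Normal(0, σ_η)

   The latent states are marginalized with the two-state hidden-Markov
   forward algorithm (never sampled), and the posterior — Normal(0, 2.5)
   priors on coefficients, half-Normal(0, 1) on σ_η — is explored with
   Hamiltonian Monte Carlo using exact forward–backward gradients.
   Convergence is checked with split-chain rank-normalized R-hat, and
   coefficients are graded by p_pos = P(β > 0 | data): strong support at
   ≥ 0.90 / ≤ 0.10, moderate at ≥ 0.70 / ≤ 0.30.
4. **Dynamics** — draw-wise derived quantities per prediction-grid cell
   (cells with > 40 % high-development cover or water are masked):
   occupancy trajectories ψₜ₊₁ = ψₜ(1−εₜ) + (1−ψₜ)γₜ, turnover
   τ′ₜ = ψₜεₜ + (1−ψₜ)γₜ, seasonal rate of change λ = ψ_last/ψ_first,
   decline proportions c_s/c_w (fraction of cells with λ < 1), and the
   stable-state occupancy ψᵉᑫ = γ/(γ+ε).
5. **Synthetic data** — a first-class generator reproducing the survey
   structure (staggered 100→200→240-site seasons over four summers and
   four winters, twelve weekly occasions, clustered photo bursts within
   occupied weeks) with the generating truth retained for recovery tests.

## Worked example

```python
import numpy as np
from dynocc import (RunConfig, fit_dynamic_occupancy, predict_grid,
                    recovery_scenario, simulate_study)
from dynocc.simulate import generate_grid

scenario = recovery_scenario(n_sites=120)        # 8 seasons x 12 weeks
study = simulate_study(scenario, seed=7)
cfg = RunConfig.from_dict(
    {"mcmc": {"chains": 3, "warmup": 500, "draws": 1000, "seed": 11}})
fit = fit_dynamic_occupancy(study["history"], study["site_cov"],
                            study["season_cov"], cfg,
                            precip_site=study["precip_site"])
print(fit.summary.loc[["gamma_season", "epsilon_cover", "sigma_eta"],
                      ["median", "q2.5", "q97.5", "p_pos", "support"]])
print("max R-hat:", round(fit.max_rhat, 3))

grid = generate_grid(scenario, seed=7, n_cells=200)
pred = predict_grid(fit, grid, study["season_cov"])
print(pred.decline_proportions())
```

Output from this exact script:

```
                 median      q2.5     q97.5     p_pos  support
parameter
gamma_season   0.554905 -0.162090  1.274436  0.933333  strong+
epsilon_cover -0.267613 -0.503766 -0.035529  0.011333  strong-
sigma_eta      0.437872  0.347050  0.538913       NaN
max R-hat: 1.008
{'c_summer': 0.6832298136645962, 'c_winter': 0.8198757763975155,
 'c_summer_drawwise_mean': 0.6583354037267081,
 'c_winter_drawwise_mean': 0.8368571428571429}
```

`gamma_season` is the colonization contrast between the spring and autumn
transitions on the logit scale (truth 0.8 in this scenario);
`epsilon_cover` says sites with more vegetation cover are extirpated less
often; `sigma_eta` is the site-level detection heterogeneity (truth 0.5; p_pos
is blanked because sign support is meaningless for a scale parameter).
`c_summer`/`c_winter` are the fractions of grid
cells whose occupancy declined between the first and last year of each
season.

A command-line interface mirrors the library:

```sh
dynocc simulate --scenario paper --seed 1 --out data/
dynocc detect   --inputs data/ --out work/
dynocc all      --inputs data/ --out results/ --seed 1
dynocc recover  --scenario recovery --replicates 5 --seed 1 --out rec/
```

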