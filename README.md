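# cachechoice

Probabilistic site-choice modeling for food-caching birds in laboratory
arenas.

Black-capped chickadees hide seeds in concealed sites and retrieve them
later. In an arena with an 8 × 8 grid of flap-covered cache sites plus
four feeders (S = 68 sites total), every cache, site check and retrieval
can be logged automatically. The scientific question is how much of each
site choice is explained by memory-independent strategies — a stable
per-bird spatial bias, a tendency to act near the previous site — and how
much requires memory of which sites hold seeds and which were checked and
found empty.

`cachechoice` is for behavioral and systems neuroscientists who want to
fit and compare these models on real or simulated event logs: it provides
the event-table containers, derived arena state, the likelihood machinery,
AIC model comparison with bootstrap significance, the spatial-bias and
retrieval-order analyses, ROI-trace event detection, and generative
simulators of both task protocols.

## The model

The probability that interaction *i* lands at site *s* is a baseline bias
scaled by five multiplicative factors and renormalized:

    p_i(s) ∝ p_bias(s) · ∏ₖ 10^(α_k[i, s])

with log10 factors

* **proximity** — a Gaussian bump of amplitude γ_prv and width σ_prv (cm)
  around the previous interaction site (zero at that site itself),
* **occupied sites** — Gaussian bumps of amplitude γ_occ, width σ_occ at
  every seed-containing site, optionally damped by a memory timescale
  e^(−t/τ_occ) and a capacity e^(−N/ν_occ),
* **checked-empty sites** — the analogous γ_emp, σ_emp, τ_emp, ν_emp term
  over sites checked this trial and currently empty,
* **recaches / older caches** — site-local amplitudes γ_occr and γ_occc
  separating feeder-closed recaches from feeder-open caches.

Fitting minimizes the Ridge-penalized negative log-likelihood
J(θ) = −L(θ) + λ‖θ‖² (λ = 1 for the free Caching task, λ = 10 for the
trial-structured Retrieval task) over a nested family of twelve models
(#0 = bias only … #11), and compares models by
AIC = −2·L_pool + 2·f with significance from bootstrapping birds.

## Worked example

Simulate ten birds whose caches carry all three factor effects
(γ_prv = 0.94, σ_prv = 15.5 cm, γ_occ = −0.32, γ_emp = 0.13), then climb
the model ladder:

```python
import numpy as np
from cachechoice import ParameterVector, default_arena, simulate_bird
from cachechoice.simulate import AgentPolicy, dirichlet_bias
from cachechoice.fitting import build_likelihood_data, bootstrap_aic

arena = default_arena()
truth = ParameterVector(gamma_prv=0.94, sigma_prv=15.5,
                        gamma_occ=-0.32, gamma_emp=0.13)
rng = np.random.default_rng(3)
birds = [
    simulate_bird(
        AgentPolicy(theta=truth, pbias=dirichlet_bias(arena, 2.0, rng)),
        arena, n_sessions=10, task="caching",
        seed=int(rng.integers(2**31)), bird=f"b{b}")
    for b in range(10)
]
datas = build_likelihood_data(birds, arena, "caches_caching")
full, boot = bootstrap_aic([0, 1, 2, 3], datas, lam=1.0,
                           n_boot=200, seed=0)
for small, big in [(0, 1), (1, 2), (2, 3)]:
    d = full[big].aic - full[small].aic
    p = np.mean(boot[big] - boot[small] > 0)
    print(f"model {big} vs {small}:  dAIC = {d:8.1f}   p = {p:.3f}")
```

prints

```
model 1 vs 0:  dAIC =   -755.1   p = 0.000
model 2 vs 1:  dAIC =   -191.1   p = 0.000
model 3 vs 2:  dAIC =    -21.5   p = 0.000
```

Each rung adds the factor that truly shaped the data, and the bootstrap
over birds confirms the AIC drop: proximity first (ΔAIC ≈ −755), then
avoidance of occupied sites, then the smaller preference for
checked-empty sites (ΔAIC ≈ −22, still significant because the effect is
consistent across birds).

A command-line interface mirrors the library
(`cachechoice simulate | validate | fit | compare | bias | order |
diagnostics | detect | report`).

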