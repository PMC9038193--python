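"""Model fitting and comparison.

Fitting minimizes the Ridge-penalized negative log-likelihood over each
model's permitted parameter box with L-BFGS-B and analytic gradients,
restarted from several random initial points; the converged start with the
lowest cost wins. Model comparison uses AIC on the pooled fit,

    AIC(M) = -2 * L_pool(theta_hat_pool) + 2 * f_M,

with significance from bootstrapping birds: resample birds with
replacement, refit the pooled models on each sample, and report the
fraction of bootstrap AIC differences above zero as the p-value.

Two parameter-significance procedures are provided: a one-tailed Wilcoxon
signed-rank test on per-bird best-fit values, and a per-bird session
bootstrap (refit on resampled sessions; p is the fraction of bootstrap
estimates on the opposite side of zero from the population-level
direction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .arena import ArenaGeometry
from .choice import BiasDistribution, LikelihoodData, compute_pbias
from .events import BirdDataset
from .models import DEFAULT_LAMBDA, DEFAULT_MASK, ModelSpec, get_model
from .params import PARAM_NAMES, ParameterVector
from .state import compute_mask, derive_state

#: initial-point sampling boxes for the multi-start optimizer
START_GAMMA = (-2.0, 2.0)
START_SIGMA = (1.0, 30.0)
START_INV = (0.0, 0.1)

COST_TOL = 1e-8


@dataclass
class StartRecord:
    x0: np.ndarray
    converged: bool
    cost: float


@dataclass
class FitResult:
    """Outcome of one (possibly pooled) model fit."""

    model_id: int
    theta: ParameterVector
    log_likelihood: float
    cost: float
    aic: float
    n_free: int
    lam: float
    seed: int | None
    starts: list[StartRecord] = field(default_factory=list)


def aic(log_likelihood: float, n_free: int) -> float:
    """Akaike Information Criterion: -2 L + 2 f."""
    return -2.0 * log_likelihood + 2.0 * n_free


def build_likelihood_data(
    datasets: list[BirdDataset],
    arena: ArenaGeometry,
    mask_label: str,
    on_zero: str = "raise",
    pbias: dict[str, BiasDistribution] | None = None,
) -> list[LikelihoodData]:
    """Per-bird likelihood designs for a mask subset.

    The baseline bias is the empirical per-bird distribution of G-masked
    interactions unless explicit distributions are supplied.
    """
    out = []
    for ds in datasets:
        st = derive_state(ds, arena)
        mask = compute_mask(ds, st, mask_label)
        if pbias is not None and ds.bird in pbias:
            pb = pbias[ds.bird]
        else:
            pb = compute_pbias(ds, mask, arena.n_sites)
        out.append(LikelihoodData(ds, st, mask, pb, arena, on_zero=on_zero))
    return out


def _draw_start(model: ModelSpec, rng: np.random.Generator) -> np.ndarray:
    x = np.zeros(12)
    for i, name in zip(model.free_indices, model.free_names):
        if name.startswith("gamma"):
            lo, hi = START_GAMMA
            if model.permitted(name) == "half":
                lo = 0.0
        elif name.startswith("sigma"):
            lo, hi = START_SIGMA
        else:
            lo, hi = START_INV
        x[i] = rng.uniform(lo, hi)
    return x[model.free_indices]


def _sign_seeded_starts(model: ModelSpec) -> list[np.ndarray]:
    """Two deterministic starts with all amplitudes at +1 and at -1.

    A Gaussian amplitude/width pair has a flat stationary region at
    (gamma, sigma) = (0, 0) that can capture descent from a wrong-signed
    start; seeding both signs guarantees one start descends from the
    correct side regardless of the random draws.
    """
    out = []
    for sign in (1.0, -1.0):
        x = np.zeros(12)
        for i, name in zip(model.free_indices, model.free_names):
            if name.startswith("gamma"):
                x[i] = sign if model.permitted(name) == "real" else abs(sign)
            elif name.startswith("sigma"):
                x[i] = 10.0
            else:
                x[i] = 0.01
        out.append(x[model.free_indices])
    return out


def _minimize(
    model: ModelSpec,
    datas: list[LikelihoodData],
    lam: float,
    starts: list[np.ndarray],
    weights: np.ndarray | None = None,
    row_weights: list | None = None,
    pbias_override: list | None = None,
):
    free = model.free_indices
    bounds = [model.bounds[i] for i in free]
    w = np.ones(len(datas)) if weights is None else np.asarray(weights, float)
    rw = row_weights or [None] * len(datas)
    po = pbias_override or [None] * len(datas)

    def objective(xfree):
        theta_arr = np.zeros(12)
        theta_arr[free] = xfree
        theta = ParameterVector.from_array(theta_arr)
        L, g = 0.0, np.zeros(12)
        for wb, d, rwb, pob in zip(w, datas, rw, po):
            if wb == 0:
                continue
            Lb, gb = d.log_likelihood_and_grad(
                theta, row_weights=rwb, pbias=pob
            )
            L += wb * Lb
            g += wb * gb
        J = -L + lam * np.sum(theta_arr**2)
        gJ = -g[free] + 2.0 * lam * theta_arr[free]
        return J, gJ

    records, best = [], None
    for x0 in starts:
        res = optimize.minimize(
            objective,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": COST_TOL, "gtol": 1e-8, "maxiter": 500},
        )
        records.append(StartRecord(np.asarray(x0), bool(res.success), float(res.fun)))
        # a line search occasionally stalls (status 2) with the iterate at
        # the optimum to numerical precision; keep such finite solutions
        usable = np.isfinite(res.fun) and (res.success or res.status == 2)
        if usable and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"no optimizer start converged for model {model.model_id}; "
            f"final costs: {[r.cost for r in records]}"
        )
    theta_arr = np.zeros(12)
    theta_arr[free] = best.x
    return ParameterVector.from_array(theta_arr), float(best.fun), records


def fit_model(
    model: ModelSpec | int,
    datas: list[LikelihoodData],
    lam: float,
    seed: int | None = 0,
    n_starts: int = 5,
    warm_start: ParameterVector | None = None,
    weights: np.ndarray | None = None,
    row_weights: list | None = None,
    pbias_override: list | None = None,
) -> FitResult:
    """Pooled constrained MLE for one model on prebuilt likelihood designs.

    Deterministic given the seed. ``warm_start`` adds the given vector to
    the start list (used to accelerate bootstrap refits with
    ``n_starts=0``). ``weights`` multiply each bird's log-likelihood
    contribution (integer weights realize bird resampling);
    ``row_weights`` and ``pbias_override`` realize per-bird session
    resampling on a fixed design.
    """
    if isinstance(model, int):
        model = get_model(model)
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    w = np.ones(len(datas)) if weights is None else np.asarray(weights, float)
    rw = row_weights or [None] * len(datas)
    po = pbias_override or [None] * len(datas)
    if model.n_free == 0:
        theta = ParameterVector()
        L = float(
            sum(
                wb * d.log_likelihood(theta, row_weights=rwb, pbias=pob)
                for wb, d, rwb, pob in zip(w, datas, rw, po)
                if wb
            )
        )
        return FitResult(
            model.model_id, theta, L, -L, aic(L, 0), 0, lam, seed, []
        )
    rng = np.random.default_rng(seed)
    starts = [_draw_start(model, rng) for _ in range(n_starts)]
    if n_starts > 0:
        starts.extend(_sign_seeded_starts(model))
    if warm_start is not None:
        starts.insert(0, warm_start.to_array()[model.free_indices])
    if not starts:
        raise ValueError("need at least one start (n_starts or warm_start)")
    theta, J, records = _minimize(
        model, datas, lam, starts, weights=w,
        row_weights=row_weights, pbias_override=pbias_override,
    )
    # recover L from the converged cost (J = -L + penalty)
    L = float(-(J - lam * np.sum(theta.to_array() ** 2)))
    return FitResult(
        model.model_id, theta, L, J, aic(L, model.n_free), model.n_free,
        lam, seed, records,
    )


def fit_task(
    model: ModelSpec | int,
    datasets: list[BirdDataset],
    arena: ArenaGeometry,
    task: str = "caching",
    lam: float | None = None,
    mask_label: str | None = None,
    seed: int | None = 0,
    n_starts: int = 5,
    on_zero: str = "raise",
    per_bird: bool = False,
):
    """Convenience wrapper: build designs for a task and fit.

    Returns the pooled :class:`FitResult`, or a dict of per-bird results
    when ``per_bird`` is set (each bird fit on its own likelihood only).
    """
    lam = DEFAULT_LAMBDA[task] if lam is None else lam
    mask_label = DEFAULT_MASK[task] if mask_label is None else mask_label
    datas = build_likelihood_data(datasets, arena, mask_label, on_zero=on_zero)
    if not per_bird:
        return fit_model(model, datas, lam, seed=seed, n_starts=n_starts)
    return {
        d.bird: fit_model(model, [d], lam, seed=seed, n_starts=n_starts)
        for d in datas
    }


# ---------------------------------------------------------------------------
# bootstrap model comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """Bootstrap AIC comparison of model A against model B (lower AIC wins)."""

    model_a: int
    model_b: int
    delta_aic: float            # AIC(A) - AIC(B) on the full pooled data
    boot_delta_aic: np.ndarray  # per-bootstrap-sample differences
    p_value: float              # fraction of bootstrap differences > 0


def bootstrap_aic(
    models,
    datas: list[LikelihoodData],
    lam: float,
    n_boot: int = 1000,
    seed: int | None = 0,
    refit: bool = True,
) -> tuple[dict[int, FitResult], dict[int, np.ndarray]]:
    """Full-data fits plus bootstrap-over-birds AIC values for many models.

    One common set of ``n_boot`` bird resamples is used for every model so
    that AIC differences are paired. With ``refit`` (the default) the
    pooled optimum is recomputed on every bootstrap sample, warm-started
    at the full-data solution; the fast mode recombines per-bird
    log-likelihood contributions at the fixed full-data pooled optimum.
    """
    models = [get_model(m) if isinstance(m, int) else m for m in models]
    rng = np.random.default_rng(seed)
    full = {
        m.model_id: fit_model(m, datas, lam, seed=rng.integers(2**31))
        for m in models
    }
    B = len(datas)
    draws = rng.integers(0, B, size=(n_boot, B))
    boot = {m.model_id: np.empty(n_boot) for m in models}
    per_bird_L = {
        m.model_id: np.array(
            [d.log_likelihood(full[m.model_id].theta) for d in datas]
        )
        for m in models
    }
    for k in range(n_boot):
        sample = draws[k]
        counts = np.bincount(sample, minlength=B).astype(float)
        for m in models:
            if not refit or m.n_free == 0:
                L = per_bird_L[m.model_id] @ counts
            else:
                res = fit_model(
                    m,
                    datas,
                    lam,
                    seed=None,
                    n_starts=0,
                    warm_start=full[m.model_id].theta,
                    weights=counts,
                )
                L = res.log_likelihood
            boot[m.model_id][k] = aic(L, m.n_free)
    return full, boot


def compare_models(
    model_a,
    model_b,
    datas: list[LikelihoodData],
    lam: float,
    n_boot: int = 1000,
    seed: int | None = 0,
    refit: bool = True,
) -> ComparisonResult:
    """Bootstrap AIC comparison; p = fraction of bootstrap dAIC > 0.

    Ties at exactly zero count as "not improved".
    """
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    ida = model_a if isinstance(model_a, int) else model_a.model_id
    idb = model_b if isinstance(model_b, int) else model_b.model_id
    if ida == idb:
        # identical models tie exactly; ties count as "not improved"
        return ComparisonResult(ida, idb, 0.0, np.zeros(n_boot), 0.0)
    full, boot = bootstrap_aic(
        [model_a, model_b], datas, lam, n_boot=n_boot, seed=seed, refit=refit
    )
    delta = full[ida].aic - full[idb].aic
    boot_delta = boot[ida] - boot[idb]
    return ComparisonResult(
        ida, idb, float(delta), boot_delta,
        float(np.mean(boot_delta > 0)),
    )


# ---------------------------------------------------------------------------
# parameter significance
# ---------------------------------------------------------------------------

def significance_across_birds(
    per_bird_values, direction: int | None = None, min_birds: int = 5
) -> float:
    """One-tailed Wilcoxon signed-rank p for a median different from zero.

    The tail is the direction of the pooled sign unless given. Exact
    enumeration is used for small samples.
    """
    v = np.asarray(per_bird_values, dtype=float)
    if v.size < min_birds:
        raise ValueError(f"need at least {min_birds} birds, got {v.size}")
    if np.all(v == 0):
        return 1.0
    if direction is None:
        direction = 1 if np.median(v) >= 0 else -1
    alternative = "greater" if direction > 0 else "less"
    n = v.size
    if n <= 20:
        method = stats.PermutationMethod(
            n_resamples=2**n, rng=np.random.default_rng(0)
        )
    else:
        method = "auto"
    return float(
        stats.wilcoxon(v, alternative=alternative, method=method).pvalue
    )


def significance_per_bird(
    dataset: BirdDataset,
    model: ModelSpec | int,
    arena: ArenaGeometry,
    lam: float,
    mask_label: str,
    direction: dict[str, int],
    n_boot: int = 1000,
    seed: int | None = 0,
    on_zero: str = "raise",
    pbias: dict[str, "BiasDistribution"] | None = None,
) -> dict[str, float]:
    """Session-bootstrap significance of each free parameter for one bird.

    Sessions are resampled with replacement, the model is refit to each
    resample, and the p-value for a parameter is the fraction of bootstrap
    estimates on the opposite side of zero from ``direction`` (+1 or -1,
    the population-level direction of the effect). Parameters at exactly
    zero count against the effect.
    """
    if isinstance(model, int):
        model = get_model(model)
    if n_boot <= 0:
        raise ValueError("n_boot must be positive")
    if dataset.n_sessions < 2:
        raise ValueError(
            f"bird {dataset.bird} has a single session; bootstrap degenerate"
        )
    rng = np.random.default_rng(seed)
    full_datas = build_likelihood_data(
        [dataset], arena, mask_label, on_zero, pbias=pbias
    )
    data = full_datas[0]
    full = fit_model(model, full_datas, lam, seed=rng.integers(2**31))
    names = [n for n in model.free_names if n.startswith("gamma")]
    boots = {n: np.empty(n_boot) for n in names}
    n_sessions = len(data.session_ids)
    fixed_pbias = pbias is not None and dataset.bird in pbias
    for k in range(n_boot):
        draws = rng.integers(0, n_sessions, size=n_sessions)
        rw = data.session_weights(draws)
        pb = None if fixed_pbias else data.resampled_pbias(draws)
        res = fit_model(
            model, full_datas, lam, seed=None, n_starts=0,
            warm_start=full.theta, row_weights=[rw], pbias_override=[pb],
        )
        for n in names:
            boots[n][k] = getattr(res.theta, n)
    out = {}
    for n in names:
        d = direction.get(n, 1)
        opposite = boots[n] <= 0 if d > 0 else boots[n] >= 0
        out[n] = float(np.mean(opposite))
    return out
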