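"""The probabilistic site-choice model.

The probability that interaction i occurs at site s is a baseline spatial
bias, multiplied by five log10-parameterized scaling factors and
renormalized over all S sites:

    p_i(s)     = p_bias(s) * prod_k 10^(alpha_k[i, s])
    p_hat_i(s) = p_i(s) / sum_s' p_i(s')

The factors are

    alpha_1: gamma_prv * Gaussian(d(prev, s); sigma_prv), 0 at s = prev
    alpha_2: gamma_occ * sum over occupied sites s' of
             Gaussian(d(s, s'); sigma_occ) * exp(-t[s']/tau_occ)
                                           * exp(-N/nu_occ)
    alpha_3: same as alpha_2 for checked-empty sites, with gamma_emp,
             sigma_emp, tau_emp, nu_emp and the count C
    alpha_4: gamma_occr * recache-flag
    alpha_5: gamma_occc * (occupancy - recache-flag)

The log-likelihood of a masked set of observed choices is the sum of
ln p_hat at the chosen sites; the fitting cost adds a Ridge penalty on the
raw 12-vector. Scaling factors are base-10 by convention; the likelihood
uses the natural log.

A Gaussian whose width falls below :data:`~cachechoice.params.SIGMA_LOCAL_CM`
is treated as an exact site-local indicator (a bump only at distance 0);
best fits on real data put sigma_occ and sigma_emp in that regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .arena import ArenaGeometry
from .events import BirdDataset
from .params import SIGMA_LOCAL_CM, ParameterVector
from .state import DerivedState, InteractionMask

LN10 = np.log(10.0)


class ZeroProbabilityError(ValueError):
    """A masked event fell on a site whose modeled probability is zero."""


# ---------------------------------------------------------------------------
# baseline bias
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BiasDistribution:
    """Empirical baseline distribution of interaction locations."""

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if np.any(p < 0):
            raise ValueError("bias probabilities must be non-negative")
        total = p.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError("bias probabilities must sum to 1")
        object.__setattr__(self, "p", p)

    @property
    def n_sites(self) -> int:
        return self.p.shape[0]

    def floored(self, n_masked: int) -> "BiasDistribution":
        """Epsilon-floored copy: add 1/(2 * n_masked) everywhere, renormalize.

        A robustness option for masks whose likelihood events can land on
        sites with zero baseline mass.
        """
        eps = 1.0 / (2.0 * n_masked)
        q = self.p + eps
        return BiasDistribution(q / q.sum())


def compute_pbias(
    dataset: BirdDataset, maskG: np.ndarray | InteractionMask, n_sites: int
) -> BiasDistribution:
    """Per-site frequency of masked interactions (the baseline bias)."""
    G = maskG.G if isinstance(maskG, InteractionMask) else np.asarray(maskG, bool)
    sites = dataset.events["site"].to_numpy()[G]
    if sites.size == 0:
        raise ValueError("empty mask: baseline bias is undefined")
    counts = np.bincount(sites, minlength=n_sites).astype(float)
    return BiasDistribution(counts / counts.sum())


# ---------------------------------------------------------------------------
# per-event API
# ---------------------------------------------------------------------------

@dataclass
class EventState:
    """State of the arena immediately before a single choice."""

    prev_site: int
    occupancy: np.ndarray
    checked_empty: np.ndarray
    recache: np.ndarray
    time_since: np.ndarray
    total_occupancy: float
    total_checked_empty: float


def state_at(state: DerivedState, i: int) -> EventState:
    """Single-event view of a derived state."""
    return EventState(
        prev_site=int(state.prev_site[i]),
        occupancy=state.occupancy[i].astype(float),
        checked_empty=state.checked_empty[i].astype(float),
        recache=state.recache[i].astype(float),
        time_since=state.time_since[i],
        total_occupancy=float(state.total_occupancy[i]),
        total_checked_empty=float(state.total_checked_empty[i]),
    )


def _kernel(d2: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian spatial kernel over squared distances; indicator as sigma->0."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma < SIGMA_LOCAL_CM:
        return (d2 == 0.0).astype(float)
    return np.exp(-d2 / (2.0 * sigma**2))


def _decay(t: np.ndarray, inv_tau: float) -> np.ndarray:
    """exp(-t/tau); defined as 0 where t is infinite (inert by construction)."""
    out = np.zeros_like(t)
    finite = np.isfinite(t)
    out[finite] = np.exp(-t[finite] * inv_tau)
    return out


def log_scaling_factors(
    state_i: EventState, theta: ParameterVector, arena: ArenaGeometry
) -> np.ndarray:
    """The five per-site log10 scaling factors, as a (5, S) array."""
    D = arena.distance_matrix()
    S = arena.n_sites
    alphas = np.zeros((5, S))

    if state_i.prev_site >= 0 and theta.gamma_prv != 0:
        d2 = D[state_i.prev_site] ** 2
        k = _kernel(d2, theta.sigma_prv)
        k[state_i.prev_site] = 0.0  # the previous site itself is excluded
        alphas[0] = theta.gamma_prv * k

    if theta.gamma_occ != 0:
        w = (
            state_i.occupancy
            * _decay(state_i.time_since, theta.inv_tau_occ)
            * np.exp(-state_i.total_occupancy * theta.inv_nu_occ)
        )
        alphas[1] = theta.gamma_occ * (_kernel(D**2, theta.sigma_occ) @ w)

    if theta.gamma_emp != 0:
        w = (
            state_i.checked_empty
            * _decay(state_i.time_since, theta.inv_tau_emp)
            * np.exp(-state_i.total_checked_empty * theta.inv_nu_emp)
        )
        alphas[2] = theta.gamma_emp * (_kernel(D**2, theta.sigma_emp) @ w)

    alphas[3] = theta.gamma_occr * state_i.recache
    alphas[4] = theta.gamma_occc * (state_i.occupancy - state_i.recache)
    return alphas


@dataclass
class ChoiceDistribution:
    """Site-choice probabilities for a single interaction."""

    alphas: np.ndarray  # (5, S) log10 factors
    p_unnormalized: np.ndarray
    p_hat: np.ndarray

    @property
    def betas(self) -> np.ndarray:
        return 10.0**self.alphas


def site_probabilities(
    state_i: EventState,
    theta: ParameterVector,
    pbias: BiasDistribution,
    arena: ArenaGeometry,
) -> ChoiceDistribution:
    """Normalized probability of the next interaction landing at each site."""
    alphas = log_scaling_factors(state_i, theta, arena)
    p = pbias.p * 10.0 ** alphas.sum(axis=0)
    total = p.sum()
    if total <= 0:
        raise ZeroProbabilityError("all-zero unnormalized probability vector")
    return ChoiceDistribution(alphas, p, p / total)


# ---------------------------------------------------------------------------
# vectorized likelihood
# ---------------------------------------------------------------------------

class LikelihoodData:
    """Precomputed design for fast repeated likelihood/cost evaluation.

    Restricts the derived state to the events selected by mask H, caches
    the squared-distance structures, and evaluates the masked
    log-likelihood and its analytic gradient for any parameter vector.
    """

    def __init__(
        self,
        dataset: BirdDataset,
        state: DerivedState,
        mask: InteractionMask,
        pbias: BiasDistribution,
        arena: ArenaGeometry,
        on_zero: str = "raise",
    ):
        if on_zero not in ("raise", "floor"):
            raise ValueError("on_zero must be 'raise' or 'floor'")
        H = mask.H
        sites = dataset.events["site"].to_numpy()
        sessions = dataset.events["session"].to_numpy()
        self.bird = dataset.bird
        self.mask_label = mask.label
        self.chosen = sites[H]
        self.n_events = int(H.sum())
        self.arena = arena
        # session bookkeeping for session-bootstrap reweighting
        self.session_ids = np.unique(sessions)
        self.event_session = np.searchsorted(self.session_ids, sessions[H])
        self.G_sites = sites[mask.G]
        self.G_session = np.searchsorted(self.session_ids, sessions[mask.G])
        D = arena.distance_matrix()
        self.D2 = D**2

        prev = state.prev_site[H]
        self.has_prev = prev >= 0
        self.prev = prev
        # squared distance from the previous site (rows with no previous
        # site are filled with inf so the kernel is 0 there)
        self.d2_prev = np.full((self.n_events, arena.n_sites), np.inf)
        self.d2_prev[self.has_prev] = self.D2[prev[self.has_prev]]

        self.occ = state.occupancy[H].astype(float)
        self.ce = state.checked_empty[H].astype(float)
        self.rec = state.recache[H].astype(float)
        self.N = state.total_occupancy[H].astype(float)
        self.C = state.total_checked_empty[H].astype(float)
        t = state.time_since[H]
        self.t_finite = np.where(np.isfinite(t), t, 0.0)

        if on_zero == "floor":
            pbias = pbias.floored(self.n_events)
        zero_hit = pbias.p[self.chosen] == 0
        if np.any(zero_hit):
            offending = np.flatnonzero(zero_hit)[:10]
            raise ZeroProbabilityError(
                f"bird {self.bird}, mask {self.mask_label}: "
                f"{int(zero_hit.sum())} masked event(s) at sites with zero "
                f"baseline bias (first event rows {offending.tolist()}); "
                f"use on_zero='floor' to epsilon-floor the bias"
            )
        with np.errstate(divide="ignore"):
            self.log_pbias = np.log(pbias.p)
        self.pbias = pbias

    # -- factor assembly -------------------------------------------------
    def _prv_kernel(self, sigma: float) -> np.ndarray:
        if sigma < SIGMA_LOCAL_CM:
            return np.zeros_like(self.d2_prev)
        with np.errstate(over="ignore"):
            k = np.exp(-self.d2_prev / (2.0 * sigma**2))
        k[np.isinf(self.d2_prev)] = 0.0
        k[self.has_prev, self.prev[self.has_prev]] = 0.0
        return k

    def _bump(self, flags, t_scaled, count, sigma, inv_tau, inv_nu):
        """sum over flagged sites of kernel * time decay * capacity decay."""
        w = flags * np.exp(-t_scaled * inv_tau) * np.exp(-count * inv_nu)[:, None]
        if sigma < SIGMA_LOCAL_CM:
            return w, w
        kernel = np.exp(-self.D2 / (2.0 * sigma**2))
        return w @ kernel, w

    def alpha_total(self, theta: ParameterVector):
        """Summed log10 factors (I_H, S) plus intermediates for gradients."""
        cache = {}
        A = np.zeros((self.n_events, self.arena.n_sites))
        k1 = self._prv_kernel(theta.sigma_prv)
        cache["k1"] = k1
        A += theta.gamma_prv * k1
        occ_t = self.t_finite * self.occ  # finite wherever occ = 1
        bump_occ, w_occ = self._bump(
            self.occ, occ_t, self.N, theta.sigma_occ,
            theta.inv_tau_occ, theta.inv_nu_occ,
        )
        cache["bump_occ"], cache["w_occ"], cache["t_occ"] = bump_occ, w_occ, occ_t
        A += theta.gamma_occ * bump_occ
        ce_t = self.t_finite * self.ce
        bump_emp, w_emp = self._bump(
            self.ce, ce_t, self.C, theta.sigma_emp,
            theta.inv_tau_emp, theta.inv_nu_emp,
        )
        cache["bump_emp"], cache["w_emp"], cache["t_emp"] = bump_emp, w_emp, ce_t
        A += theta.gamma_emp * bump_emp
        A += theta.gamma_occr * self.rec + theta.gamma_occc * (self.occ - self.rec)
        return A, cache

    def session_weights(self, draws: np.ndarray) -> np.ndarray:
        """Per-event multiplicities for a session resample (session indices)."""
        counts = np.bincount(draws, minlength=len(self.session_ids))
        return counts[self.event_session].astype(float)

    def resampled_pbias(self, draws: np.ndarray) -> BiasDistribution:
        """Empirical baseline recomputed on a session resample."""
        counts = np.bincount(draws, minlength=len(self.session_ids))
        w = counts[self.G_session].astype(float)
        sums = np.bincount(
            self.G_sites, weights=w, minlength=self.arena.n_sites
        )
        if sums.sum() == 0:
            raise ValueError("session resample contains no masked interactions")
        return BiasDistribution(sums / sums.sum())

    def _log_pbias(self, pbias: BiasDistribution | None) -> np.ndarray:
        if pbias is None:
            return self.log_pbias
        # clamp to a large negative so zero-weight rows cannot produce nan
        return np.log(np.maximum(pbias.p, 1e-300))

    def log_likelihood(
        self,
        theta: ParameterVector,
        row_weights: np.ndarray | None = None,
        pbias: BiasDistribution | None = None,
    ) -> float:
        """Masked log-likelihood L(theta) (natural log).

        ``row_weights`` multiply per-event contributions (session
        bootstrap); ``pbias`` overrides the baked-in baseline.
        """
        A, _ = self.alpha_total(theta)
        logp = self._log_pbias(pbias)[None, :] + LN10 * A
        logZ = logsumexp(logp, axis=1)
        rows = np.arange(self.n_events)
        terms = logp[rows, self.chosen] - logZ
        if row_weights is None:
            return float(np.sum(terms))
        return float(np.sum(np.where(row_weights > 0, terms, 0.0) * row_weights))

    def log_likelihood_and_grad(
        self,
        theta: ParameterVector,
        row_weights: np.ndarray | None = None,
        pbias: BiasDistribution | None = None,
    ):
        """L(theta) and its gradient with respect to the raw 12-vector."""
        A, cc = self.alpha_total(theta)
        logp = self._log_pbias(pbias)[None, :] + LN10 * A
        logZ = logsumexp(logp, axis=1)
        rows = np.arange(self.n_events)
        terms = logp[rows, self.chosen] - logZ
        phat = np.exp(logp - logZ[:, None])
        if row_weights is None:
            L = float(np.sum(terms))
            wcol = None
        else:
            L = float(
                np.sum(np.where(row_weights > 0, terms, 0.0) * row_weights)
            )
            wcol = row_weights[:, None]
            phat = phat * wcol

        def contract(dA):
            picked = dA[rows, self.chosen]
            if row_weights is not None:
                picked = picked * row_weights
            return LN10 * float(np.sum(picked) - np.sum(phat * dA))

        g = np.zeros(12)
        k1, w_occ, w_emp = cc["k1"], cc["w_occ"], cc["w_emp"]
        bump_occ, bump_emp = cc["bump_occ"], cc["bump_emp"]
        g[0] = contract(k1)
        if theta.sigma_prv >= SIGMA_LOCAL_CM and theta.gamma_prv != 0:
            dk = np.where(np.isinf(self.d2_prev), 0.0, self.d2_prev) * k1
            g[1] = contract(theta.gamma_prv * dk / theta.sigma_prv**3)
        g[2] = contract(bump_occ)
        if theta.sigma_occ >= SIGMA_LOCAL_CM and theta.gamma_occ != 0:
            dkern = self.D2 / theta.sigma_occ**3 * np.exp(
                -self.D2 / (2.0 * theta.sigma_occ**2)
            )
            g[3] = contract(theta.gamma_occ * (w_occ @ dkern))
        g[4] = contract(bump_emp)
        if theta.sigma_emp >= SIGMA_LOCAL_CM and theta.gamma_emp != 0:
            dkern = self.D2 / theta.sigma_emp**3 * np.exp(
                -self.D2 / (2.0 * theta.sigma_emp**2)
            )
            g[5] = contract(theta.gamma_emp * (w_emp @ dkern))
        g[6] = contract(self.occ - self.rec)
        g[7] = contract(self.rec)

        def bump_like(w, t_or_n, sigma):
            dw = -t_or_n * w
            if sigma < SIGMA_LOCAL_CM:
                return dw
            return dw @ np.exp(-self.D2 / (2.0 * sigma**2))

        if theta.gamma_occ != 0:
            g[8] = contract(
                theta.gamma_occ * bump_like(w_occ, cc["t_occ"], theta.sigma_occ)
            )
            g[10] = contract(theta.gamma_occ * (-self.N[:, None]) * bump_occ)
        if theta.gamma_emp != 0:
            g[9] = contract(
                theta.gamma_emp * bump_like(w_emp, cc["t_emp"], theta.sigma_emp)
            )
            g[11] = contract(theta.gamma_emp * (-self.C[:, None]) * bump_emp)
        return L, g


def log_likelihood(
    dataset: BirdDataset,
    theta: ParameterVector,
    maskH: InteractionMask,
    pbias: BiasDistribution,
    arena: ArenaGeometry,
    state: DerivedState | None = None,
    on_zero: str = "raise",
) -> float:
    """Masked log-likelihood of one bird's observed choices."""
    from .state import derive_state

    if state is None:
        state = derive_state(dataset, arena)
    if not maskH.H.any():
        return 0.0
    data = LikelihoodData(dataset, state, maskH, pbias, arena, on_zero=on_zero)
    return data.log_likelihood(theta)


def log_likelihood_pooled(likelihood_datas, theta: ParameterVector) -> float:
    """Pooled log-likelihood: sum of per-bird masked log-likelihoods."""
    return float(sum(d.log_likelihood(theta) for d in likelihood_datas))


def ridge_penalty(theta: ParameterVector, lam: float) -> float:
    """lambda * sum of squared raw parameters."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return float(lam * np.sum(theta.to_array() ** 2))


def cost(
    likelihood_datas, theta: ParameterVector, lam: float
) -> float:
    """Ridge-penalized negative log-likelihood J(theta).

    Accepts a single :class:`LikelihoodData` or a list (pooled: one penalty
    term is added to the summed negative log-likelihoods).
    """
    if isinstance(likelihood_datas, LikelihoodData):
        likelihood_datas = [likelihood_datas]
    return -log_likelihood_pooled(likelihood_datas, theta) + ridge_penalty(
        theta, lam
    )
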