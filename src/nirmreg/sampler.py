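"""Nested Dirichlet-process regression prior and its blocked Gibbs sampler.

Model
-----
For standardized observed/expected distances ``y*_{i,j}`` and ``x*_{i,j}``
(site i = 1..I, property j = 1..J) with per-site nonsynonymous counts
``n_i``, the likelihood is

    y*_{i,j} ~ N(beta_{i,j} x*_{i,j}, sigma2_{i,j})        if beta_{i,j} = 0
    y*_{i,j} ~ N(beta_{i,j} x*_{i,j}, sigma2_{i,j}/n_i)    if beta_{i,j} != 0.

The matrix of (beta, sigma2) pairs gets a nested infinite relational model
prior: property columns are clustered by an outer stick-breaking process
with weights Pi_k (sticks v_k ~ Beta(1, rho)), and within each column
cluster k the sites are clustered by an inner process with weights w_{l,k}
(sticks u_{l,k} ~ Beta(1, gamma_k)).  Each (row-cluster, column-cluster)
atom carries (phi_{l,k}, theta2_{l,k}) drawn from a spike-and-slab base
measure: with probability lambda, phi = 0 and theta2 ~ InvGamma(a_kappa,
b_kappa); otherwise phi | theta2 ~ N(alpha_k, theta2/V0) and theta2 ~
InvGamma(a_sigma*, b_sigma*).  Hyperpriors: alpha_k ~ N(m_alpha, C_alpha),
rho ~ Ga(a_rho, b_rho), gamma_k ~ Ga(a_gamma, b_gamma), lambda ~
Beta(a_lambda, b_lambda).

Inverse-gamma convention: ``InvGamma(a, b)`` here has prior mean
``1/(b (a-1))`` (scipy scale ``1/b``), the parameterization under which the
default (2, 100) and (2, 4) choices imply prior means 0.01 and 0.25.

Sampling
--------
Both stick-breaking processes are truncated at finite K and L and the
state is updated by a sweep of closed-form full conditionals: column
indicators zeta_j, column sticks, row indicators xi_{i,k} (for every k,
including clusters currently owning no columns), row sticks, the atoms
(psi, theta2, phi jointly, with phi and theta2 integrated out of the
spike-vs-slab choice), lambda, alpha_k, and the two concentration
parameters via the auxiliary-variable (Escobar-West) mixture-of-gammas
step.  All categorical updates run in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .distances import DistanceDataset

logger = logging.getLogger(__name__)

LOG2PI = float(np.log(2.0 * np.pi))
_VAR_FLOOR = 1e-30  # trap-only floor: hitting it signals a bug, never clamps


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Hyperpriors:
    """Fixed hyperparameters of the hierarchical model (lysin defaults)."""

    m_alpha: float = 1.0
    C_alpha: float = 0.25
    a_rho: float = 1.0
    b_rho: float = 1.0
    a_gamma: float = 1.0
    b_gamma: float = 1.0
    a_lambda: float = 2.0
    b_lambda: float = 8.0
    a_kappa: float = 2.0
    b_kappa: float = 100.0
    a_sigma_star: float = 2.0
    b_sigma_star: float = 10.0
    V0: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "C_alpha", "a_rho", "b_rho", "a_gamma", "b_gamma", "a_lambda",
            "b_lambda", "a_kappa", "b_kappa", "a_sigma_star", "b_sigma_star",
            "V0",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def inv_gamma_prior_mean(a: float, b: float) -> float:
    """Prior mean of InvGamma(a, b) in the convention used here: 1/(b(a-1))."""
    if a <= 1:
        return float("inf")
    return 1.0 / (b * (a - 1.0))


@dataclass(frozen=True)
class SamplerConfig:
    """Truncation levels and MCMC run lengths."""

    K: int = 25
    L: int = 25
    n_iter: int = 5000
    burn_in: int = 1000
    thin: int = 1
    seed: int = 0
    n_chains: int = 1
    #: move property columns with the site indicators marginalized out
    #: (partially collapsed update; mixes far better across partitions).
    collapsed_columns: bool = True

    def __post_init__(self) -> None:
        if self.K < 1 or self.L < 1:
            raise ValueError("truncation levels K and L must be >= 1")
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("require 0 <= burn_in < n_iter")
        if self.thin < 1 or self.n_chains < 1:
            raise ValueError("thin and n_chains must be >= 1")

    @property
    def n_saved(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def choose_truncation(rho_guess: float, tol: float) -> int:
    """Smallest K whose expected stick-breaking tail mass is <= tol.

    Conditional on the concentration rho, the truncated tail
    ``sum_{k>=K} Pi_k`` has expectation ``(rho/(1+rho))**(K-1)``.
    """
    if rho_guess <= 0 or not (0 < tol < 1):
        raise ValueError("require rho_guess > 0 and 0 < tol < 1")
    r = rho_guess / (1.0 + rho_guess)
    K = 1
    while r ** (K - 1) > tol:
        K += 1
    return K


# ---------------------------------------------------------------------------
# state
# ---------------------------------------------------------------------------

@dataclass
class ChainState:
    """All latent quantities touched by one Gibbs sweep (0-based indices)."""

    zeta: np.ndarray       # (J,) int in [0, K)
    Pi: np.ndarray         # (K,) column weights, sum 1
    v: np.ndarray          # (K,) column sticks, v[K-1] = 1
    log1m_v: np.ndarray    # (K,) log(1 - v), exact even when v rounds to 1
    xi: np.ndarray         # (I, K) int in [0, L)
    w: np.ndarray          # (L, K) row weights, each column sums to 1
    u: np.ndarray          # (L, K) row sticks, u[L-1, :] = 1
    log1m_u: np.ndarray    # (L, K) log(1 - u)
    phi: np.ndarray     # (L, K) slab coefficients (0 at spike atoms)
    theta2: np.ndarray  # (L, K) atom variances
    psi: np.ndarray     # (L, K) bool, True where phi != 0
    alpha: np.ndarray   # (K,) cluster slab means
    rho: float
    gamma: np.ndarray   # (K,)
    lam: float

    @property
    def K(self) -> int:
        return self.Pi.shape[0]

    @property
    def L(self) -> int:
        return self.w.shape[0]

    def copy(self) -> "ChainState":
        return ChainState(
            self.zeta.copy(), self.Pi.copy(), self.v.copy(),
            self.log1m_v.copy(), self.xi.copy(), self.w.copy(),
            self.u.copy(), self.log1m_u.copy(), self.phi.copy(),
            self.theta2.copy(), self.psi.copy(), self.alpha.copy(),
            float(self.rho), self.gamma.copy(), float(self.lam),
        )

    def implied_beta(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-cell (beta, sigma2, spike flag) implied by the partitions."""
        k_j = self.zeta
        l_ij = self.xi[:, k_j]                       # (I, J)
        beta = self.phi[l_ij, k_j[None, :]]
        sigma2 = self.theta2[l_ij, k_j[None, :]]
        spike = ~self.psi[l_ij, k_j[None, :]]
        return beta, sigma2, spike


def _stick_weights(sticks: np.ndarray) -> np.ndarray:
    v = np.asarray(sticks, dtype=float).copy()
    v[-1] = 1.0
    out = v * np.concatenate([[1.0], np.cumprod(1.0 - v[:-1])])
    return out


def _log_gamma_draw(shape: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """log of a Gamma(shape, 1) variate, stable down to tiny shapes.

    Uses G(a) = G(a+1) * U^{1/a}, which keeps the logarithm finite where a
    direct draw would underflow to zero.
    """
    shape = np.asarray(shape, dtype=float)
    boost = np.log(rng.gamma(shape + 1.0))
    return boost + np.log(rng.random(size=shape.shape)) / shape


def _beta_sticks(
    a: np.ndarray, b: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Beta(a, b) sticks via the two-gamma representation, returning
    (v, log(1-v)) with the log-complement exact even when v rounds to 1.

    Stick-breaking conditionals can have b (the concentration) far below
    float resolution of 1 - v; carrying log(1-v) separately keeps the
    concentration updates unbiased in that regime.
    """
    log_x = _log_gamma_draw(np.broadcast_to(a, np.shape(b)).astype(float), rng)
    log_y = _log_gamma_draw(np.asarray(b, dtype=float), rng)
    log_sum = np.logaddexp(log_x, log_y)
    v = np.exp(log_x - log_sum)
    log1m_v = log_y - log_sum
    return v, log1m_v


def init_state(
    I: int, J: int, K: int, L: int, hyper: Hyperpriors, rng: np.random.Generator
) -> ChainState:
    """Random initialization: partitions uniform, everything else from the
    prior hierarchy (also serves as an exact prior draw of the state)."""
    rho = rng.gamma(hyper.a_rho) / hyper.b_rho
    gamma = rng.gamma(hyper.a_gamma, size=K) / hyper.b_gamma
    lam = rng.beta(hyper.a_lambda, hyper.b_lambda)
    alpha = rng.normal(hyper.m_alpha, np.sqrt(hyper.C_alpha), size=K)
    v, log1m_v = _beta_sticks(np.ones(K), np.full(K, rho), rng)
    v[-1], log1m_v[-1] = 1.0, -np.inf
    Pi = _stick_weights(v)
    u = np.empty((L, K))
    log1m_u = np.empty((L, K))
    for k in range(K):
        u[:, k], log1m_u[:, k] = _beta_sticks(
            np.ones(L), np.full(L, gamma[k]), rng
        )
    u[-1, :], log1m_u[-1, :] = 1.0, -np.inf
    w = np.column_stack([_stick_weights(u[:, k]) for k in range(K)])
    psi = rng.random((L, K)) > lam
    theta2 = np.where(
        psi,
        (1.0 / hyper.b_sigma_star) / rng.gamma(hyper.a_sigma_star, size=(L, K)),
        (1.0 / hyper.b_kappa) / rng.gamma(hyper.a_kappa, size=(L, K)),
    )
    phi = np.where(
        psi,
        rng.normal(alpha[None, :], np.sqrt(theta2 / hyper.V0)),
        0.0,
    )
    zeta = rng.integers(0, K, size=J)
    xi = rng.integers(0, L, size=(I, K))
    return ChainState(zeta, Pi, v, log1m_v, xi, w, u, log1m_u, phi, theta2,
                      psi, alpha, rho, gamma, lam)


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------

def log_likelihood_cell(
    y_star: float, x_star: float, n_obs_i: int, phi: float, var: float
) -> float:
    """Log-density of one cell under the two-regime likelihood.

    The variance is ``var`` when phi = 0 and ``var / n_obs_i`` otherwise.
    """
    if var <= 0:
        raise ValueError("var must be strictly positive")
    if n_obs_i < 1:
        raise ValueError("n_obs_i must be >= 1")
    v = var if phi == 0.0 else var / n_obs_i
    resid = y_star - phi * x_star
    return -0.5 * (LOG2PI + np.log(v)) - resid * resid / (2.0 * v)


def _effective_var(state: ChainState, n_obs: np.ndarray) -> np.ndarray:
    """(I, K) effective variance of the atom currently governing each (i, k)."""
    idx = np.arange(state.K)
    th = state.theta2[state.xi, idx]          # (I, K)
    ps = state.psi[state.xi, idx]
    return np.where(ps, th / n_obs[:, None], th)


def _check_theta2(theta2: np.ndarray) -> None:
    if (theta2 <= _VAR_FLOOR).any():
        raise FloatingPointError(
            "atom variance fell below the numerical trap floor; this "
            "indicates an implementation or input defect"
        )


# ---------------------------------------------------------------------------
# full conditionals
# ---------------------------------------------------------------------------

def column_logprobs(state: ChainState, data: DistanceDataset) -> np.ndarray:
    """Unnormalized log P(zeta_j = k | ...) as a (J, K) matrix.

    For candidate cluster k, row i contributes the normal likelihood at the
    atom indicated by xi_{i,k} with the spike/slab effective variance.
    """
    y, x, n = data.y_star, data.x_star, data.n_obs
    idx = np.arange(state.K)
    phi_sel = state.phi[state.xi, idx]                    # (I, K)
    var = _effective_var(state, n)                        # (I, K)
    a = 1.0 / var
    const = -0.5 * np.log(2.0 * np.pi * var).sum(axis=0)  # (K,)
    sq = (y ** 2).T @ a                                   # (J, K)
    cross = (y * x).T @ (phi_sel * a)
    quad = (x ** 2).T @ (phi_sel ** 2 * a)
    with np.errstate(divide="ignore"):
        log_pi = np.log(state.Pi)
    return log_pi[None, :] + const[None, :] - 0.5 * (sq - 2.0 * cross + quad)


def _categorical_rows(logp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Sample one category per row of a log-probability matrix (Gumbel-max)."""
    finite = np.isfinite(logp).any(axis=1)
    if not finite.all():
        raise FloatingPointError(
            "all categories have zero probability for some unit; "
            "numerically degenerate state"
        )
    g = rng.gumbel(size=logp.shape)
    return np.argmax(logp + g, axis=1)


def sample_column_indicators(
    state: ChainState, data: DistanceDataset, rng: np.random.Generator
) -> None:
    state.zeta = _categorical_rows(column_logprobs(state, data), rng)


def _cell_loglik_tensor(
    state: ChainState, data: DistanceDataset
) -> np.ndarray:
    """(J, I, L, K) log N(y*_{i,j} | phi_{l,k} x*_{i,j}, vartilde_{l,k,i})."""
    y, x, n = data.y_star, data.x_star, data.n_obs
    I, J = y.shape
    var = np.where(
        state.psi[None, :, :],
        state.theta2[None, :, :] / n[:, None, None],
        state.theta2[None, :, :],
    )                                                     # (I, L, K)
    log_norm = -0.5 * np.log(2.0 * np.pi * var)
    cell = np.empty((J, I, state.L, state.K))
    for j in range(J):
        resid = y[:, j, None, None] - state.phi[None, :, :] * x[:, j, None, None]
        cell[j] = log_norm - resid ** 2 / (2.0 * var)
    return cell


def sample_column_indicators_collapsed(
    state: ChainState, data: DistanceDataset, rng: np.random.Generator
) -> None:
    """Move each column with the row indicators xi integrated out.

    For candidate cluster k the weight is the ratio of inner-mixture
    marginal likelihoods of the cluster's columns with and without column j:

        q_jk ∝ Pi_k *
            prod_i [ sum_l w_{l,k} prod_{j' in B_k ∪ {j}} N_{l,k}(i,j') ]
                 / [ sum_l w_{l,k} prod_{j' in B_k}       N_{l,k}(i,j') ]

    where B_k is the cluster's current membership excluding j.  This is a
    valid partially collapsed step because xi is redrawn from its exact
    conditional immediately afterwards in the sweep; it mixes far better
    than the configuration update because candidate clusters are evaluated
    through their whole atom mixture rather than one sampled assignment.
    """
    cell = _cell_loglik_tensor(state, data)               # (J, I, L, K)
    J = cell.shape[0]
    with np.errstate(divide="ignore"):
        log_w = np.log(state.w)                           # (L, K)
        log_pi = np.log(state.Pi)                         # (K,)
    S = np.zeros_like(cell[0])                            # (I, L, K)
    for j in range(J):
        S[:, :, state.zeta[j]] += cell[j][:, :, state.zeta[j]]
    zeta = state.zeta.copy()
    for j in range(J):
        S[:, :, zeta[j]] -= cell[j][:, :, zeta[j]]
        a = log_w[None, :, :] + S
        base = logsumexp(a, axis=1)                       # (I, K)
        with_j = logsumexp(a + cell[j], axis=1)
        logq = log_pi + (with_j - base).sum(axis=0)
        zeta[j] = _categorical_rows(logq[None, :], rng)[0]
        S[:, :, zeta[j]] += cell[j][:, :, zeta[j]]
    state.zeta = zeta


def sample_column_weights(state: ChainState, rng: np.random.Generator) -> None:
    """v_k ~ Beta(1 + m_k, rho + sum_{s>k} m_s), v_K = 1."""
    K = state.K
    m = np.bincount(state.zeta, minlength=K).astype(float)
    tail = np.concatenate([np.cumsum(m[::-1])[::-1][1:], [0.0]])
    v, log1m_v = _beta_sticks(1.0 + m, state.rho + tail, rng)
    v[-1], log1m_v[-1] = 1.0, -np.inf
    state.v = v
    state.log1m_v = log1m_v
    state.Pi = _stick_weights(v)


def row_logprobs(state: ChainState, data: DistanceDataset, k: int) -> np.ndarray:
    """Unnormalized log P(xi_{i,k} = l | ...) as an (I, L) matrix.

    The likelihood product runs over the columns currently in cluster k;
    for an empty cluster the prior weights w_{., k} remain.
    """
    y, x, n = data.y_star, data.x_star, data.n_obs
    with np.errstate(divide="ignore"):
        log_w = np.log(state.w[:, k])                     # (L,)
    cols = state.zeta == k
    if not cols.any():
        return np.broadcast_to(log_w, (y.shape[0], state.L)).copy()
    ysub, xsub = y[:, cols], x[:, cols]
    sy2 = (ysub ** 2).sum(axis=1)                         # (I,)
    sxy = (ysub * xsub).sum(axis=1)
    sx2 = (xsub ** 2).sum(axis=1)
    nJ = int(cols.sum())
    phi_l = state.phi[:, k]                               # (L,)
    th_l = state.theta2[:, k]
    var = np.where(state.psi[:, k][None, :], th_l[None, :] / n[:, None],
                   th_l[None, :])                         # (I, L)
    quad = (sy2[:, None] - 2.0 * sxy[:, None] * phi_l[None, :]
            + sx2[:, None] * phi_l[None, :] ** 2)
    return log_w[None, :] - 0.5 * nJ * np.log(2.0 * np.pi * var) - quad / (2.0 * var)


def sample_row_indicators(
    state: ChainState, data: DistanceDataset, rng: np.random.Generator
) -> None:
    """Resample xi_{i,k} for every site and every column cluster k."""
    xi = np.empty_like(state.xi)
    for k in range(state.K):
        xi[:, k] = _categorical_rows(row_logprobs(state, data, k), rng)
    state.xi = xi


def sample_row_weights(state: ChainState, rng: np.random.Generator) -> None:
    """u_{l,k} ~ Beta(1 + n_{l,k}, gamma_k + sum_{r>l} n_{r,k}), u_{L,k} = 1."""
    L = state.L
    w = np.empty_like(state.w)
    u_all = np.empty_like(state.u)
    log1m_all = np.empty_like(state.log1m_u)
    for k in range(state.K):
        counts = np.bincount(state.xi[:, k], minlength=L).astype(float)
        tail = np.concatenate([np.cumsum(counts[::-1])[::-1][1:], [0.0]])
        u, log1m_u = _beta_sticks(1.0 + counts, state.gamma[k] + tail, rng)
        u[-1], log1m_u[-1] = 1.0, -np.inf
        u_all[:, k] = u
        log1m_all[:, k] = log1m_u
        w[:, k] = _stick_weights(u)
    state.w = w
    state.u = u_all
    state.log1m_u = log1m_all


def _escobar_west(
    conc: float, n_star: int, n_items: int, a: float, b: float,
    rng: np.random.Generator,
) -> float:
    """Two-step auxiliary-variable refresh of a DP concentration parameter."""
    eta = rng.beta(conc + 1.0, n_items)
    rate = b - np.log(eta)
    w1 = a + n_star - 1.0
    w2 = n_items * rate
    if rng.random() < w1 / (w1 + w2):
        shape = a + n_star
    else:
        shape = a + n_star - 1.0
    return float(rng.gamma(shape) / rate)


def _stick_conditional_gamma(
    log1m_sticks: np.ndarray, a: float, b: float, rng: np.random.Generator
) -> float:
    """Exact conditional of a concentration given its Beta(1, conc) sticks:
    Ga(a + K - 1, b - sum_{k<K} log(1 - v_k)), using the exactly carried
    log-complements."""
    free = log1m_sticks[:-1]
    rate = b - free.sum()
    return float(rng.gamma(a + free.size) / rate)


def sample_concentrations(
    state: ChainState, hyper: Hyperpriors, rng: np.random.Generator
) -> None:
    """Refresh rho (outer DP) and every gamma_k (inner DPs) from their
    exact conditionals given the current stick variables."""
    state.rho = _stick_conditional_gamma(
        state.log1m_v, hyper.a_rho, hyper.b_rho, rng
    )
    gamma = np.empty_like(state.gamma)
    for k in range(state.K):
        gamma[k] = _stick_conditional_gamma(
            state.log1m_u[:, k], hyper.a_gamma, hyper.b_gamma, rng
        )
    state.gamma = gamma


def sample_concentrations_escobar_west(
    state: ChainState, hyper: Hyperpriors, rng: np.random.Generator
) -> None:
    """Auxiliary-variable (mixture-of-gammas) concentration refresh.

    Conditions on the number of distinct indicators only, which is the
    exact conditional under the Polya-urn (marginal) representation; in
    the truncated sampler with explicit stick labels it is an
    approximation, so the default sweep uses the stick-conditional update
    instead.
    """
    J = state.zeta.shape[0]
    I = state.xi.shape[0]
    n_star = int(np.unique(state.zeta).size)
    state.rho = _escobar_west(state.rho, n_star, J, hyper.a_rho, hyper.b_rho, rng)
    gamma = np.empty_like(state.gamma)
    for k in range(state.K):
        m_star = int(np.unique(state.xi[:, k]).size)
        gamma[k] = _escobar_west(
            state.gamma[k], m_star, I, hyper.a_gamma, hyper.b_gamma, rng
        )
    state.gamma = gamma


def _atom_sufficient_stats(
    state: ChainState, data: DistanceDataset, k: int
) -> dict[str, np.ndarray]:
    """Per-row-atom cell sums over Omega_{l,k} = {(i,j): xi_{i,k}=l, zeta_j=k}."""
    L = state.L
    y, x, n = data.y_star, data.x_star, data.n_obs
    cols = state.zeta == k
    labels = state.xi[:, k]
    if not cols.any():
        z = np.zeros(L)
        return {"count": z, "S_y2": z, "S_ny2": z, "S_nyx": z, "S_nx2": z,
                "S_logn": z}
    ysub, xsub = y[:, cols], x[:, cols]
    nJ = int(cols.sum())
    ry2 = (ysub ** 2).sum(axis=1)
    rnyx = n * (ysub * xsub).sum(axis=1)
    rnx2 = n * (xsub ** 2).sum(axis=1)
    rny2 = n * ry2
    rlogn = nJ * np.log(n.astype(float))
    count = np.bincount(labels, minlength=L).astype(float) * nJ
    return {
        "count": count,
        "S_y2": np.bincount(labels, weights=ry2, minlength=L),
        "S_ny2": np.bincount(labels, weights=rny2, minlength=L),
        "S_nyx": np.bincount(labels, weights=rnyx, minlength=L),
        "S_nx2": np.bincount(labels, weights=rnx2, minlength=L),
        "S_logn": np.bincount(labels, weights=rlogn, minlength=L),
    }


def spike_log_marginal(
    count: np.ndarray, S_y2: np.ndarray, hyper: Hyperpriors
) -> np.ndarray:
    """log integral of prod N(y|0, theta2) against the spike InvGamma prior."""
    a, s0 = hyper.a_kappa, 1.0 / hyper.b_kappa
    return (
        -0.5 * count * LOG2PI
        + a * np.log(s0)
        + gammaln(a + count / 2.0)
        - gammaln(a)
        - (a + count / 2.0) * np.log(s0 + S_y2 / 2.0)
    )


def slab_log_marginal(
    count: np.ndarray,
    S_ny2: np.ndarray,
    S_nyx: np.ndarray,
    S_nx2: np.ndarray,
    S_logn: np.ndarray,
    alpha_k: float,
    hyper: Hyperpriors,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """log marginal of the slab branch (phi and theta2 integrated out).

    Also returns the conjugate quantities A = V0 + sum n x^2 and
    m = (alpha_k V0 + sum n x y) / A reused by the theta2 and phi draws.
    """
    a, s1, V0 = hyper.a_sigma_star, 1.0 / hyper.b_sigma_star, hyper.V0
    A = V0 + S_nx2
    m = (alpha_k * V0 + S_nyx) / A
    Q = alpha_k ** 2 * V0 + S_ny2 - m ** 2 * A
    if (Q < -1e-8).any():
        raise FloatingPointError("negative residual quadratic form")
    Q = np.maximum(Q, 0.0)
    logm = (
        -0.5 * count * LOG2PI
        + 0.5 * S_logn
        + 0.5 * (np.log(V0) - np.log(A))
        + a * np.log(s1)
        + gammaln(a + count / 2.0)
        - gammaln(a)
        - (a + count / 2.0) * np.log(s1 + Q / 2.0)
    )
    return logm, A, m


def sample_atoms(
    state: ChainState, data: DistanceDataset, hyper: Hyperpriors,
    rng: np.random.Generator,
) -> None:
    """Jointly refresh (psi, theta2, phi) for every atom.

    psi is drawn from its marginalized two-point conditional (spike weight
    lambda times the phi=0 marginal vs slab weight (1-lambda) times the
    normal-inverse-gamma marginal), then theta2 from the matching
    inverse-gamma, then phi = 0 or N(m_phi, theta2/A).  Atoms with empty
    cell sets reduce exactly to base-measure draws.
    """
    L, K = state.L, state.K
    lam = state.lam
    psi = np.empty((L, K), dtype=bool)
    theta2 = np.empty((L, K))
    phi = np.zeros((L, K))
    s0, s1 = 1.0 / hyper.b_kappa, 1.0 / hyper.b_sigma_star
    for k in range(K):
        st = _atom_sufficient_stats(state, data, k)
        log_m0 = spike_log_marginal(st["count"], st["S_y2"], hyper)
        log_m1, A, m = slab_log_marginal(
            st["count"], st["S_ny2"], st["S_nyx"], st["S_nx2"], st["S_logn"],
            float(state.alpha[k]), hyper,
        )
        if lam <= 0.0:
            p_slab = np.ones(L)
        elif lam >= 1.0:
            p_slab = np.zeros(L)
        else:
            log_odds = np.log1p(-lam) + log_m1 - np.log(lam) - log_m0
            p_slab = 1.0 / (1.0 + np.exp(-log_odds))
        psi_k = rng.random(L) < p_slab
        shape = np.where(psi_k, hyper.a_sigma_star, hyper.a_kappa) + st["count"] / 2.0
        scale = np.where(psi_k, s1 + _slab_scale(st, A, m, state.alpha[k], hyper),
                         s0 + st["S_y2"] / 2.0)
        if (scale <= 0).any():
            raise FloatingPointError("non-positive inverse-gamma scale")
        th_k = scale / rng.gamma(shape)
        ph_k = np.where(psi_k, rng.normal(m, np.sqrt(th_k / A)), 0.0)
        psi[:, k], theta2[:, k], phi[:, k] = psi_k, th_k, ph_k
    _check_theta2(theta2)
    state.psi, state.theta2, state.phi = psi, theta2, phi


def _slab_scale(
    st: dict[str, np.ndarray], A: np.ndarray, m: np.ndarray, alpha_k: float,
    hyper: Hyperpriors,
) -> np.ndarray:
    """Residual quadratic form Q/2 of the slab branch."""
    Q = alpha_k ** 2 * hyper.V0 + st["S_ny2"] - m ** 2 * A
    return np.maximum(Q, 0.0) / 2.0


def sample_lambda(
    state: ChainState, hyper: Hyperpriors, rng: np.random.Generator
) -> None:
    """lambda ~ Beta(a_lambda + #{psi=0}, b_lambda + #{psi=1})."""
    n_slab = int(state.psi.sum())
    n_spike = state.psi.size - n_slab
    state.lam = float(rng.beta(hyper.a_lambda + n_spike, hyper.b_lambda + n_slab))


def alpha_posterior_params(
    state: ChainState, hyper: Hyperpriors, k: int
) -> tuple[float, float]:
    """Posterior (mean, variance) of alpha_k given the cluster's slab atoms.

    With no slab atoms the prior (m_alpha, C_alpha) is returned unchanged.
    """
    slab = state.psi[:, k]
    prec = 1.0 / hyper.C_alpha + hyper.V0 * (1.0 / state.theta2[slab, k]).sum()
    mean_num = hyper.m_alpha / hyper.C_alpha + hyper.V0 * (
        state.phi[slab, k] / state.theta2[slab, k]
    ).sum()
    C_star = 1.0 / prec
    return C_star * mean_num, C_star


def sample_alpha(
    state: ChainState, hyper: Hyperpriors, rng: np.random.Generator
) -> None:
    """Conjugate normal refresh of each cluster slab mean alpha_k."""
    alpha = np.empty(state.K)
    for k in range(state.K):
        m_star, C_star = alpha_posterior_params(state, hyper, k)
        alpha[k] = rng.normal(m_star, np.sqrt(C_star))
    state.alpha = alpha


# ---------------------------------------------------------------------------
# the sweep and the driver
# ---------------------------------------------------------------------------

def gibbs_sweep(
    state: ChainState, data: DistanceDataset, hyper: Hyperpriors,
    rng: np.random.Generator, collapsed_columns: bool = True,
) -> None:
    """One full scan over all conditionals, in place."""
    if collapsed_columns:
        sample_column_indicators_collapsed(state, data, rng)
    else:
        sample_column_indicators(state, data, rng)
    sample_column_weights(state, rng)
    sample_row_indicators(state, data, rng)
    sample_row_weights(state, rng)
    sample_atoms(state, data, hyper, rng)
    sample_lambda(state, hyper, rng)
    sample_alpha(state, hyper, rng)
    sample_concentrations(state, hyper, rng)


def sample_data_given_state(
    state: ChainState, x_star: np.ndarray, n_obs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw y* from the likelihood at the current state (for sampler
    validation by joint-distribution testing)."""
    beta, sigma2, spike = state.implied_beta()
    var = np.where(spike, sigma2, sigma2 / n_obs[:, None])
    return rng.normal(beta * x_star, np.sqrt(var))


@dataclass
class PosteriorSamples:
    """Retained post-burn-in draws, possibly pooled over chains."""

    zeta: np.ndarray     # (S, J)
    xi: np.ndarray       # (S, I, K)
    phi: np.ndarray      # (S, L, K)
    psi: np.ndarray      # (S, L, K) bool
    theta2: np.ndarray   # (S, L, K)
    alpha: np.ndarray    # (S, K)
    rho: np.ndarray      # (S,)
    gamma: np.ndarray    # (S, K)
    lam: np.ndarray      # (S,)
    chain: np.ndarray    # (S,) chain index per draw
    sites: tuple[int, ...]
    properties: tuple[str, ...]
    n_obs: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.zeta.shape[0]

    def beta_draws(self) -> np.ndarray:
        """(S, I, J) implied regression coefficients per draw."""
        S, I, J = self.xi.shape[0], self.xi.shape[1], self.zeta.shape[1]
        out = np.empty((S, I, J))
        for s in range(S):
            k_j = self.zeta[s]
            l_ij = self.xi[s][:, k_j]
            out[s] = self.phi[s][l_ij, k_j[None, :]]
        return out

    def spike_draws(self) -> np.ndarray:
        """(S, I, J) indicator that the governing atom sits in the spike."""
        S, I, J = self.xi.shape[0], self.xi.shape[1], self.zeta.shape[1]
        out = np.empty((S, I, J), dtype=bool)
        for s in range(S):
            k_j = self.zeta[s]
            l_ij = self.xi[s][:, k_j]
            out[s] = ~self.psi[s][l_ij, k_j[None, :]]
        return out

    def n_column_clusters(self) -> np.ndarray:
        """(S,) number of occupied column clusters per draw."""
        return np.array([np.unique(z).size for z in self.zeta])


def run_gibbs(
    data: DistanceDataset,
    hyper: Hyperpriors | None = None,
    config: SamplerConfig | None = None,
) -> PosteriorSamples:
    """Run the truncated blocked Gibbs sampler; deterministic given the seed.

    With ``config.n_chains > 1``, each chain starts from an independent
    random partition (seeds derived from ``config.seed``) and the retained
    draws are pooled, tagged by chain index.
    """
    hyper = hyper or Hyperpriors()
    config = config or SamplerConfig()
    I, J = data.n_sites, data.n_properties
    K, L = config.K, config.L

    store: dict[str, list] = {k: [] for k in (
        "zeta", "xi", "phi", "psi", "theta2", "alpha", "rho", "gamma", "lam",
        "chain",
    )}
    for c in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, c]))
        state = init_state(I, J, K, L, hyper, rng)
        for it in range(config.n_iter):
            gibbs_sweep(state, data, hyper, rng, config.collapsed_columns)
            if (it + 1) % 1000 == 0:
                n_col = np.unique(state.zeta).size
                mean_row = np.mean(
                    [np.unique(state.xi[:, k]).size for k in range(K)]
                )
                logger.info(
                    "chain=%d iter=%d property_clusters=%d "
                    "mean_site_clusters=%.2f rho=%.3f lambda=%.3f",
                    c, it + 1, n_col, mean_row, state.rho, state.lam,
                )
            if it >= config.burn_in and (it - config.burn_in) % config.thin == 0:
                store["zeta"].append(state.zeta.copy())
                store["xi"].append(state.xi.copy())
                store["phi"].append(state.phi.copy())
                store["psi"].append(state.psi.copy())
                store["theta2"].append(state.theta2.copy())
                store["alpha"].append(state.alpha.copy())
                store["rho"].append(state.rho)
                store["gamma"].append(state.gamma.copy())
                store["lam"].append(state.lam)
                store["chain"].append(c)
    return PosteriorSamples(
        zeta=np.array(store["zeta"]),
        xi=np.array(store["xi"]),
        phi=np.array(store["phi"]),
        psi=np.array(store["psi"]),
        theta2=np.array(store["theta2"]),
        alpha=np.array(store["alpha"]),
        rho=np.array(store["rho"]),
        gamma=np.array(store["gamma"]),
        lam=np.array(store["lam"]),
        chain=np.array(store["chain"]),
        sites=data.sites,
        properties=data.properties,
        n_obs=data.n_obs.copy(),
    )
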