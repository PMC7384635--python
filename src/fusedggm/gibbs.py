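"""Column-wise block Gibbs sampler for the Bayesian fused graphical lasso.

The prior puts independent double-exponential laws on off-diagonal precision
elements, exponential laws on the diagonal, and double-exponential laws on the
element-wise *differences* between corresponding entries of different groups'
precision matrices (the fusion part).  A scale-mixture-of-normals
representation of the double exponential introduces latent scales tau, after
which every conditional is standard: one column/row of each Omega_t at a time
is drawn from a Gaussian-times-Gamma conditional that preserves positive
definiteness by construction, the scales follow inverse-Gaussian conditionals,
and the penalties lambda follow gamma conditionals.

With T = 1 the fusion terms vanish and the sampler is exactly the single-group
Bayesian graphical lasso.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_solve, solve_triangular

from .core import (
    FusedChainState,
    GroupedDataset,
    Hyperparameters,
    InvalidStateError,
    _pair_key,
    scatter_matrix,
)

_LAMBDA_FLOOR = 1e-6     # truncation of hyperprior penalty draws
_IG_MEAN_CAP = 1e10      # inverse-Gaussian mean cap for degenerate |omega| ~ 0
_OMEGA_EPS = 1e-10


@dataclass
class FusionWeights:
    """Zero-diagonal symmetric matrices entering the column conditional.

    A holds the total prior precision on each off-diagonal element (own lasso
    scale plus all fusion scales); B holds the fusion-scale-weighted sum of the
    other groups' corresponding elements (the shrinkage target, unnormalized).
    """

    A: np.ndarray
    B: np.ndarray


# ---------------------------------------------------------------------------
# elementary samplers


def sample_inverse_gaussian(mean, shape, rng) -> np.ndarray | float:
    """Draw from the inverse-Gaussian distribution IG(mean, shape).

    Uses the transformation-with-rejection scheme of Michael, Schucany & Haas;
    ``mean`` and ``shape`` broadcast, so the call is vectorized.
    """
    mean = np.asarray(mean, dtype=float)
    shape = np.asarray(shape, dtype=float)
    if (mean <= 0).any() or (shape <= 0).any():
        raise ValueError("inverse-Gaussian mean and shape must be positive")
    mean, shape = np.broadcast_arrays(mean, shape)
    nu = rng.standard_normal(mean.shape)
    y = nu * nu
    x = (
        mean
        + mean * mean * y / (2.0 * shape)
        - mean / (2.0 * shape) * np.sqrt(4.0 * mean * shape * y + (mean * y) ** 2)
    )
    # numerical guard: the smaller root can underflow to <= 0 for extreme y
    x = np.maximum(x, np.finfo(float).tiny)
    u = rng.uniform(size=mean.shape)
    take_other = u > mean / (mean + x)
    with np.errstate(over="ignore"):
        out = np.where(take_other, mean * mean / x, x)
    out = np.minimum(out, 1e15)  # keeps reciprocals representable
    return out if out.shape else float(out)


def _offdiag_mask(p: int) -> np.ndarray:
    return ~np.eye(p, dtype=bool)


# ---------------------------------------------------------------------------
# conditional updates


def _fusion_partners(T: int, t: int, adjacent_only: bool) -> list[int]:
    partners = [u for u in range(T) if u != t]
    if adjacent_only:
        partners = [u for u in partners if abs(u - t) == 1]
    return partners


def compute_fusion_weights(state: FusedChainState, t: int,
                           adjacent_only: bool = False) -> FusionWeights:
    """A_t and B_t for group ``t`` (0-based index into ``state.Omega``).

    (A_t)_{j1j2} = 1/tau^t_{j1j2} + Σ_{t'≠t} 1/tau^{t,t'}_{j1j2}
    (B_t)_{j1j2} = Σ_{t'≠t} omega^{t'}_{j1j2} / tau^{t,t'}_{j1j2}

    where tau^{t,t'} is the fusion scale of the unordered pair {t, t'}.
    """
    p = state.Omega[t].shape[0]
    mask = _offdiag_mask(p)
    for tau in [state.tau_lasso[t]] + [
        state.tau_fuse[_pair_key(t, u)]
        for u in _fusion_partners(len(state.Omega), t, adjacent_only)
    ]:
        if (tau[mask] <= 0).any():
            raise InvalidStateError("non-positive latent scale")
    A = np.zeros((p, p))
    B = np.zeros((p, p))
    A[mask] = 1.0 / state.tau_lasso[t][mask]
    for u in _fusion_partners(len(state.Omega), t, adjacent_only):
        tau_pair = state.tau_fuse[_pair_key(t, u)]
        A[mask] += 1.0 / tau_pair[mask]
        B[mask] += state.Omega[u][mask] / tau_pair[mask]
    return FusionWeights(A=A, B=B)


def sample_column_block(Omega: np.ndarray, S: np.ndarray, A: np.ndarray,
                        B: np.ndarray, lam: float, n_t: int, j: int,
                        rng) -> np.ndarray:
    """One column/row update of a precision matrix (in place).

    Column/row ``j`` (0-based) is moved to the last position; writing the
    2x2 block partition of the permuted matrix as (X11, x12, x22), the update
    draws

        gamma ~ Gamma(n_t/2 + 1, rate = (s22 + lam)/2)
        delta ~ N(-Sigma (s12 - b12), Sigma),
        Sigma = [diag(a12) + (s22 + lam) * Omega11^{-1}]^{-1}

    and sets omega_12 = delta, omega_22 = gamma + delta' Omega11^{-1} delta,
    which keeps the matrix positive definite whenever Omega11 is.
    """
    p = Omega.shape[0]
    idx = np.concatenate([np.arange(j), np.arange(j + 1, p)])
    Om11 = Omega[np.ix_(idx, idx)]
    try:
        L11 = np.linalg.cholesky(Om11)
    except np.linalg.LinAlgError as exc:
        raise InvalidStateError("Omega11 block is not positive definite") from exc
    inv11 = cho_solve((L11, True), np.eye(p - 1), check_finite=False)
    a12 = A[idx, j]
    b12 = B[idx, j]
    s12 = S[idx, j]
    s22 = S[j, j]
    C = np.diag(a12) + (s22 + lam) * inv11          # = Sigma^{-1}
    Lc = np.linalg.cholesky(C)
    mean = -cho_solve((Lc, True), s12 - b12, check_finite=False)
    z = rng.standard_normal(p - 1)
    delta = mean + solve_triangular(Lc.T, z, lower=False, check_finite=False)
    gamma = rng.gamma(0.5 * n_t + 1.0, 2.0 / (s22 + lam))
    Omega[idx, j] = delta
    Omega[j, idx] = delta
    Omega[j, j] = gamma + float(delta @ inv11 @ delta)
    return Omega


def sample_scales(state: FusedChainState, rng,
                  adjacent_only: bool = False) -> FusedChainState:
    """Redraw every latent scale from its inverse-Gaussian conditional.

    For each off-diagonal element, 1/tau ~ IG(lam/|omega|, lam^2) (lasso
    scales) and 1/tau ~ IG(lam_pair/|omega_t - omega_t'|, lam_pair^2) (fusion
    scales, drawn once per unordered pair).  Near-zero |omega| caps the mean.
    """
    T = len(state.Omega)
    p = state.Omega[0].shape[0]
    mask = _offdiag_mask(p)
    for t in range(T):
        lam = state.lambda_lasso[t]
        om = np.abs(state.Omega[t][mask])
        mean = np.minimum(lam / np.maximum(om, _OMEGA_EPS), _IG_MEAN_CAP)
        inv_tau = sample_inverse_gaussian(mean, lam * lam, rng)
        tau = np.empty((p, p))
        tau[mask] = 1.0 / inv_tau
        tau[np.eye(p, dtype=bool)] = 1.0
        # symmetrize: keep upper draw for both triangles
        tau = np.triu(tau, 1)
        state.tau_lasso[t] = tau + tau.T + np.eye(p)
    for (t1, t2) in list(state.tau_fuse):
        if adjacent_only and abs(t1 - t2) != 1:
            continue
        lam = state.lambda_fuse[(t1, t2)]
        diff = np.abs((state.Omega[t1] - state.Omega[t2])[mask])
        mean = np.minimum(lam / np.maximum(diff, _OMEGA_EPS), _IG_MEAN_CAP)
        inv_tau = sample_inverse_gaussian(mean, lam * lam, rng)
        tau = np.empty((p, p))
        tau[mask] = 1.0 / inv_tau
        tau = np.triu(tau, 1)
        state.tau_fuse[(t1, t2)] = tau + tau.T + np.eye(p)
    return state


def _abs_upper_sum(M: np.ndarray) -> float:
    """Σ_{j1<=j2} |m_{j1j2}| including the diagonal."""
    return float(np.abs(np.triu(M)).sum())


def sample_penalties(state: FusedChainState, hyper: Hyperparameters,
                     rng) -> FusedChainState:
    """Gamma conditionals for the lasso and fusion penalties.

    lambda_t ~ G(r + p(p+1)/2, s + Σ_{j1<=j2}|omega^t|) and, per unordered
    pair, lambda ~ G(r + p(p+1)/2, s + Σ_{j1<=j2}|omega^{t'} - omega^t|).
    """
    p = state.Omega[0].shape[0]
    shape = hyper.r + 0.5 * p * (p + 1)
    for t in range(len(state.Omega)):
        rate = hyper.s + _abs_upper_sum(state.Omega[t])
        state.lambda_lasso[t] = rng.gamma(shape, 1.0 / rate)
    for (t1, t2) in state.lambda_fuse:
        rate = hyper.s + _abs_upper_sum(state.Omega[t1] - state.Omega[t2])
        state.lambda_fuse[(t1, t2)] = rng.gamma(shape, 1.0 / rate)
    return state


# ---------------------------------------------------------------------------
# prior draws


def _draw_lambda_prior(size, hyper: Hyperparameters, rng) -> np.ndarray:
    return np.maximum(rng.gamma(hyper.r, 1.0 / hyper.s, size=size), _LAMBDA_FLOOR)


def _symmetric_offdiag(values: np.ndarray, p: int) -> np.ndarray:
    """(..., p, p) symmetric matrix with unit diagonal from (..., p, p) raw draws."""
    upper = np.triu(values, 1)
    return upper + np.swapaxes(upper, -1, -2) + np.eye(p)


def init_state_from_prior(T: int, p: int, hyper: Hyperparameters,
                          rng) -> FusedChainState:
    """Identity precisions; penalties from their (truncated) gamma hyperprior;
    scales from their exponential conditionals given the penalties."""
    lam = _draw_lambda_prior(T, hyper, rng)
    tau_lasso = []
    for t in range(T):
        raw = rng.exponential(scale=2.0 / lam[t] ** 2, size=(p, p))
        tau_lasso.append(_symmetric_offdiag(raw, p))
    tau_fuse: dict[tuple[int, int], np.ndarray] = {}
    lambda_fuse: dict[tuple[int, int], float] = {}
    for t1 in range(T):
        for t2 in range(t1 + 1, T):
            lf = float(_draw_lambda_prior(None, hyper, rng))
            lambda_fuse[(t1, t2)] = lf
            raw = rng.exponential(scale=2.0 / lf**2, size=(p, p))
            tau_fuse[(t1, t2)] = _symmetric_offdiag(raw, p)
    return FusedChainState(
        Omega=[np.eye(p) for _ in range(T)],
        tau_lasso=tau_lasso,
        tau_fuse=tau_fuse,
        lambda_lasso=lam,
        lambda_fuse=lambda_fuse,
    )


def draw_prior_components(M: int, p: int, hyper: Hyperparameters, rng,
                          kernel_sweeps: int = 10,
                          penalty: float | None = None):
    """Batch of M (mu, Omega, lam, tau) draws from the component prior.

    The graphical-lasso prior has no direct sampler, so each precision draw is
    produced constructively: starting from the identity, run ``kernel_sweeps``
    data-free column sweeps of the block-Gibbs kernel (S = 0, n_t = 0, no
    fusion) followed by a scale refresh — a short prior-kernel run that stays
    positive definite.  The penalty is ``penalty`` when given, else a draw of
    λ from its G(r, s) hyperprior truncated below.  Means follow mu | Omega ~
    N(mu0, (kappa0 Omega)^{-1}).

    All M draws evolve together, vectorized over the batch dimension.
    """
    if penalty is None:
        lam = _draw_lambda_prior(M, hyper, rng)
    else:
        lam = np.full(M, float(penalty))
    tau = _symmetric_offdiag(
        rng.exponential(scale=2.0 / lam[:, None, None] ** 2, size=(M, p, p)), p
    )
    Omega = np.broadcast_to(np.eye(p), (M, p, p)).copy()
    mask = _offdiag_mask(p)
    for _ in range(kernel_sweeps):
        for j in range(p):
            idx = np.concatenate([np.arange(j), np.arange(j + 1, p)])
            Om11 = Omega[:, idx[:, None], idx[None, :]]
            inv11 = np.linalg.inv(Om11)
            a12 = 1.0 / tau[:, idx, j]
            C = inv11 * lam[:, None, None]
            C[:, np.arange(p - 1), np.arange(p - 1)] += a12
            Lc = np.linalg.cholesky(C)
            z = rng.standard_normal((M, p - 1, 1))
            delta = np.linalg.solve(np.swapaxes(Lc, 1, 2), z)[:, :, 0]
            gamma = rng.gamma(1.0, 2.0 / lam)
            om22 = gamma + np.einsum("mi,mij,mj->m", delta, inv11, delta)
            Omega[:, idx, j] = delta
            Omega[:, j, idx] = delta
            Omega[:, j, j] = om22
        om = np.abs(Omega[:, mask])
        mean = np.minimum(
            lam[:, None] / np.maximum(om, _OMEGA_EPS), _IG_MEAN_CAP
        )
        inv_tau = sample_inverse_gaussian(mean, (lam * lam)[:, None], rng)
        tau_new = np.zeros((M, p, p))
        tau_new[:, mask] = 1.0 / inv_tau
        tau = _symmetric_offdiag(np.triu(tau_new, 1), p)
    mu0 = hyper.mu0_vector(p)
    L = np.linalg.cholesky(hyper.kappa0 * Omega)
    z = rng.standard_normal((M, p, 1))
    mu = mu0 + np.linalg.solve(np.swapaxes(L, 1, 2), z)[:, :, 0]
    return mu, Omega, lam, tau


# ---------------------------------------------------------------------------
# the full chain


@dataclass
class FusedChain:
    """Post-burn-in draws of the fused sampler.

    omega : (n_kept, T, p, p); mu : (n_kept, T, p);
    lambda_lasso : (n_kept, T); lambda_fuse : pair -> (n_kept,).
    """

    omega: np.ndarray
    mu: np.ndarray
    lambda_lasso: np.ndarray
    lambda_fuse: dict[tuple[int, int], np.ndarray]

    @property
    def n_kept(self) -> int:
        return self.omega.shape[0]

    def posterior_mean_omega(self) -> np.ndarray:
        return self.omega.mean(axis=0)

    def posterior_mean_mu(self) -> np.ndarray:
        return self.mu.mean(axis=0)


def _sample_group_mean(rows: np.ndarray, Omega: np.ndarray, mu0: np.ndarray,
                       kappa0: float, rng) -> np.ndarray:
    """Conjugate draw mu | Omega, Y ~ N(m, [(n + kappa0) Omega]^{-1})."""
    n = rows.shape[0]
    ybar = rows.mean(axis=0) if n else mu0
    m = (n * ybar + kappa0 * mu0) / (n + kappa0)
    L = np.linalg.cholesky((n + kappa0) * Omega)
    z = rng.standard_normal(len(mu0))
    return m + solve_triangular(L.T, z, lower=False, check_finite=False)


def run_fused_chain(dataset: GroupedDataset, hyper: Hyperparameters,
                    rng=None) -> FusedChain:
    """Fused graphical lasso MCMC over all T groups of ``dataset``.

    Each sweep: conjugate group-mean draws, then per group the fusion weights
    and a full column sweep of the precision matrix, then latent scales, then
    penalties.  Post-burn-in states are returned (thinned by ``hyper.thin``).
    p > n_t is allowed; the prior regularizes.
    """
    if rng is None:
        rng = np.random.default_rng(hyper.seed)
    T, p = dataset.T, dataset.p
    mu0 = hyper.mu0_vector(p)
    state = init_state_from_prior(T, p, hyper, rng)
    group_rows = [dataset.rows_of(t + 1) for t in range(T)]
    kept_omega, kept_mu, kept_ll = [], [], []
    kept_lf: dict[tuple[int, int], list[float]] = {k: [] for k in state.lambda_fuse}
    for it in range(hyper.n_iter):
        mus = [
            _sample_group_mean(group_rows[t], state.Omega[t], mu0, hyper.kappa0, rng)
            for t in range(T)
        ]
        S_list = scatter_matrix(dataset, mus)
        for t in range(T):
            w = compute_fusion_weights(state, t, hyper.adjacent_fusion_only)
            for j in range(p):
                sample_column_block(
                    state.Omega[t], S_list[t].S, w.A, w.B,
                    state.lambda_lasso[t], S_list[t].n_t, j, rng,
                )
        sample_scales(state, rng, hyper.adjacent_fusion_only)
        sample_penalties(state, hyper, rng)
        if it >= hyper.burn_in and (it - hyper.burn_in) % hyper.thin == 0:
            kept_omega.append(np.stack([Om.copy() for Om in state.Omega]))
            kept_mu.append(np.stack(mus))
            kept_ll.append(state.lambda_lasso.copy())
            for k in kept_lf:
                kept_lf[k].append(state.lambda_fuse[k])
    return FusedChain(
        omega=np.stack(kept_omega),
        mu=np.stack(kept_mu),
        lambda_lasso=np.stack(kept_ll),
        lambda_fuse={k: np.asarray(v) for k, v in kept_lf.items()},
    )
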