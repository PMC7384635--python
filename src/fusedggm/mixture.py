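"""Mixture-of-GGMs estimation with data-integrative CRP allocation.

Within each known group the data may stem from several unknown sub-populations
(components), each with its own mean and precision matrix.  Component
memberships follow a Chinese-restaurant-process-style prior; the
data-integrative variant (DI-CRP) rescales the weight of an existing component
by two similarity-derived quantities built from an external pairwise
similarity matrix S: a majority count n*_{-i,k} (how many members of k are
"similar enough" to i, judged against i's own third-quartile threshold) and a
cohesion score h_i(k) = 1 + sum of similarities between i and k's members.
With S = 0 both reduce to cluster size and 1, i.e. the plain CRP, exactly.

The MCMC alternates birth-death Metropolis moves on the component count,
membership exchange moves, conjugate component-mean updates, graphical-lasso
precision updates (stage-wise per component, or fused jointly across all
components of all groups), and an auxiliary-variable update of the
concentration parameter alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import GroupedDataset, Hyperparameters, _pair_key, mvn_logpdf
from .gibbs import (
    _IG_MEAN_CAP,
    _OMEGA_EPS,
    _abs_upper_sum,
    _draw_lambda_prior,
    _offdiag_mask,
    _sample_group_mean,
    _symmetric_offdiag,
    draw_prior_components,
    sample_column_block,
    sample_inverse_gaussian,
)

# ---------------------------------------------------------------------------
# similarity side-information


@dataclass
class SimilarityMatrix:
    """Symmetric nonnegative pairwise similarity with per-row quartile thresholds.

    thresholds[i] is the 0.75 empirical quantile (linear interpolation) of
    {s_ii' : i' != i}; flags[i, i'] marks s_ii' >= thresholds[i] (row-wise, so
    flags need not be symmetric).  The diagonal is zero and never flagged.
    """

    S: np.ndarray
    thresholds: np.ndarray = field(init=False)
    flags: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        m = self.S.shape[0]
        if self.S.shape != (m, m):
            raise ValueError("similarity matrix must be square")
        if not np.allclose(self.S, self.S.T):
            raise ValueError("similarity matrix must be symmetric")
        if (self.S < 0).any():
            raise ValueError("similarities must be nonnegative")
        np.fill_diagonal(self.S, 0.0)
        off = ~np.eye(m, dtype=bool)
        self.thresholds = np.array(
            [np.quantile(self.S[i, off[i]], 0.75) for i in range(m)]
        )
        self.flags = self.S >= self.thresholds[:, None]
        np.fill_diagonal(self.flags, False)

    @classmethod
    def zero(cls, m: int) -> "SimilarityMatrix":
        """The no-information similarity (plain CRP behaviour)."""
        return cls(np.zeros((m, m)))

    @classmethod
    def from_csv(cls, path, sep: str = ",") -> "SimilarityMatrix":
        import pandas as pd

        return cls(pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# component bookkeeping


@dataclass
class Component:
    """One mixture component: Gaussian parameters plus its latent lasso scales."""

    mu: np.ndarray
    Omega: np.ndarray
    tau: np.ndarray


@dataclass
class MixtureState:
    """Per-group allocation state: labels, live components, concentration.

    The lasso penalty ``lam`` is group-level, shared by all of the group's
    components (the penalty is indexed by group in the model); its gamma
    conditional aggregates over the components.
    """

    Z: np.ndarray                       # (n_t,) component ids
    comps: dict[int, Component]
    alpha: float
    lam: float = 1.0

    @property
    def K(self) -> int:
        return len(self.comps)

    def size_of(self, k: int) -> int:
        return int(np.sum(self.Z == k))


# ---------------------------------------------------------------------------
# allocation weights


def _nstar_h(i: int, Z: np.ndarray, sim: SimilarityMatrix,
             k: int) -> tuple[int, float]:
    members = Z == k
    members_i = members.copy()
    members_i[i] = False
    nstar = int(np.sum(sim.flags[i] & members_i))
    h = 1.0 + float(sim.S[i] @ members_i)
    return nstar, h


def dicrp_weights(i: int, Z: np.ndarray, sim: SimilarityMatrix,
                  alpha: float) -> tuple[list[int], np.ndarray, float]:
    """Unnormalized DI-CRP prior weights for observation ``i``.

    Existing component k weighs n*_{-i,k} * h_i(k); a new component weighs
    alpha.  Returns (component ids, their weights, new-component weight).
    """
    ids = sorted(set(np.unique(Z)))
    weights = np.empty(len(ids))
    for a, k in enumerate(ids):
        nstar, h = _nstar_h(i, Z, sim, k)
        weights[a] = nstar * h
    return ids, weights, float(alpha)


def _batch_logphi(Y: np.ndarray, comp: Component) -> np.ndarray:
    return np.asarray(mvn_logpdf(Y, comp.mu, comp.Omega))


def _pool_logphi(Y: np.ndarray, pool_mu: np.ndarray,
                 pool_Omega: np.ndarray) -> np.ndarray:
    """(M, n) log-densities of every row of Y under every pool draw."""
    L = np.linalg.cholesky(pool_Omega)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L, axis1=1, axis2=2)), axis=1)
    d = Y[None, :, :] - pool_mu[:, None, :]
    quad = np.einsum("mij,mjk,mik->mi", d, pool_Omega, d)
    p = Y.shape[1]
    return 0.5 * logdet[:, None] - 0.5 * p * np.log(2 * np.pi) - 0.5 * quad


def posterior_membership_weights(
    y_i: np.ndarray, i: int, Z: np.ndarray, sim: SimilarityMatrix,
    comps: dict[int, Component], alpha: float, hyper: Hyperparameters,
    rng, pool=None,
) -> tuple[list[int | None], np.ndarray]:
    """Normalized membership posterior over existing components plus "new".

    Existing k: proportional to n*_{-i,k} h_i(k) phi_k(y_i); the new-component
    weight is alpha times a Monte-Carlo estimate (M prior draws) of the
    marginal likelihood of y_i.  The returned ids end with None for "new";
    probabilities sum to one.  When every weight underflows to zero the
    observation goes to a new component with probability one.
    """
    ids = sorted(comps)
    logw = np.empty(len(ids) + 1)
    for a, k in enumerate(ids):
        nstar, h = _nstar_h(i, Z, sim, k)
        if nstar == 0:
            logw[a] = -np.inf
        else:
            logw[a] = np.log(nstar * h) + float(
                mvn_logpdf(y_i, comps[k].mu, comps[k].Omega)
            )
    if pool is None:
        pool = draw_prior_components(hyper.M, len(y_i), hyper, rng,
                                     penalty=hyper.birth_penalty)
    pool_mu, pool_Omega = pool[0], pool[1]
    lps = _pool_logphi(y_i[None, :], pool_mu, pool_Omega)[:, 0]
    logw[-1] = np.log(alpha) + logsumexp(lps) - np.log(len(lps))
    if np.all(np.isinf(logw) & (logw < 0)):
        probs = np.zeros(len(logw))
        probs[-1] = 1.0
    else:
        probs = np.exp(logw - logsumexp(logw))
        probs /= probs.sum()
    return ids + [None], probs


# ---------------------------------------------------------------------------
# Metropolis moves


def birth_death_step(i: int, state: MixtureState, sim: SimilarityMatrix,
                     Y: np.ndarray, pool, pool_logphi: np.ndarray,
                     n_t: int, rng, id_counter: list[int]) -> None:
    """Box-style birth/death move for observation ``i`` (in place).

    Non-singleton i: propose a brand-new component with prior-drawn
    parameters; accept with min{1, [alpha/(n_t-1)] phi'/phi}.  Singleton i:
    propose an existing component k' with probability proportional to
    n*_{-i,k'}; accept with min{1, [(n_t-1)/alpha] h'phi'/(h phi)}; the emptied
    component is deleted.
    """
    k = int(state.Z[i])
    logphi_cur = float(mvn_logpdf(Y[i], state.comps[k].mu, state.comps[k].Omega))
    if state.size_of(k) > 1:
        m = int(rng.integers(pool_logphi.shape[0]))
        log_acc = (
            np.log(state.alpha) - np.log(n_t - 1)
            + pool_logphi[m, i] - logphi_cur
        )
        if np.log(rng.uniform()) < log_acc:
            new_id = id_counter[0]
            id_counter[0] += 1
            state.comps[new_id] = Component(
                mu=pool[0][m].copy(), Omega=pool[1][m].copy(),
                tau=pool[3][m].copy(),
            )
            state.Z[i] = new_id
    else:
        others = [kk for kk in state.comps if kk != k]
        if not others:
            return
        nstars = np.array(
            [_nstar_h(i, state.Z, sim, kk)[0] for kk in others], dtype=float
        )
        if nstars.sum() == 0:
            return
        kp = others[int(rng.choice(len(others), p=nstars / nstars.sum()))]
        _, h_cur = _nstar_h(i, state.Z, sim, k)
        _, h_new = _nstar_h(i, state.Z, sim, kp)
        logphi_new = float(
            mvn_logpdf(Y[i], state.comps[kp].mu, state.comps[kp].Omega)
        )
        log_acc = (
            np.log(n_t - 1) - np.log(state.alpha)
            + np.log(h_new) + logphi_new - np.log(h_cur) - logphi_cur
        )
        if np.log(rng.uniform()) < log_acc:
            state.Z[i] = kp
            del state.comps[k]


def membership_step(i: int, state: MixtureState, sim: SimilarityMatrix,
                    Y: np.ndarray, rng) -> None:
    """Exchange move: redraw Z_i among existing components (in place).

    Only acts when i's component has more than one occupant; weights are
    n*_{-i,k} h_i(k) phi_k(Y_i).  A zero total weight leaves i in place.
    """
    k = int(state.Z[i])
    if state.size_of(k) <= 1:
        return
    ids = sorted(state.comps)
    logw = np.empty(len(ids))
    for a, kk in enumerate(ids):
        nstar, h = _nstar_h(i, state.Z, sim, kk)
        if nstar == 0:
            logw[a] = -np.inf
        else:
            logw[a] = np.log(nstar * h) + float(
                mvn_logpdf(Y[i], state.comps[kk].mu, state.comps[kk].Omega)
            )
    if np.all(np.isinf(logw) & (logw < 0)):
        return
    probs = np.exp(logw - logsumexp(logw))
    probs /= probs.sum()
    state.Z[i] = ids[int(rng.choice(len(ids), p=probs))]


def sample_alpha(K: int, n_t: int, a: float, b: float, alpha: float,
                 rng) -> float:
    """Auxiliary-variable update of the concentration parameter.

    zeta ~ Beta(alpha+1, n_t); with mixing odds (a+K-1)/(n_t (b - log zeta))
    draw alpha from G(a+K, b - log zeta) or G(a+K-1, b - log zeta).
    """
    zeta = rng.beta(alpha + 1.0, n_t)
    rate = b - np.log(zeta)
    odds = (a + K - 1.0) / (n_t * rate)
    rho = odds / (1.0 + odds)
    shape = a + K if rng.uniform() < rho else a + K - 1.0
    shape = max(shape, 1e-8)  # guards a=1, K=1 second branch
    return float(rng.gamma(shape, 1.0 / rate))


def sample_component_means(rows: np.ndarray, Omega_k: np.ndarray,
                           mu0: np.ndarray, kappa0: float, rng) -> np.ndarray:
    """Conjugate mean draw mu_k ~ N(m_k, [(n_k + kappa0) Omega_k]^{-1}) with
    m_k the precision-weighted convex combination of the data mean and mu0."""
    return _sample_group_mean(rows, Omega_k, mu0, kappa0, rng)


# ---------------------------------------------------------------------------
# initialization


def initialize_clusters(Y: np.ndarray, hyper: Hyperparameters, rng,
                        id_counter: list[int],
                        seed_at_data: bool = True) -> MixtureState:
    """Sequential density-argmax initialization capped at K_max components.

    Observations are visited in order; while fewer than K_max components
    exist, each observation also competes a freshly drawn candidate component
    against the existing ones and joins the argmax-density one (the candidate
    is kept only if it wins).  Candidate precisions come from the lasso prior
    kernel at the reference penalty; with ``seed_at_data`` (default) the
    candidate mean's prior is centered at the observation under
    consideration, which guarantees that every region of the data can open a
    component regardless of where the hyperprior mean sits.
    """
    n_t, p = Y.shape
    K_max = min(hyper.K_max, n_t)
    comps: dict[int, Component] = {}
    Z = np.full(n_t, -1, dtype=int)
    cand_batch = None
    cand_used = 0
    for i in range(n_t):
        candidate = None
        if len(comps) < K_max:
            if cand_batch is None or cand_used >= cand_batch[0].shape[0]:
                m = min(64, n_t - i)
                cand_batch = draw_prior_components(m, p, hyper, rng,
                                                   penalty=hyper.init_penalty)
                cand_used = 0
            mu_c = cand_batch[0][cand_used].copy()
            if seed_at_data:
                mu_c = mu_c - hyper.mu0_vector(p) + Y[i]
            candidate = Component(
                mu=mu_c,
                Omega=cand_batch[1][cand_used].copy(),
                tau=cand_batch[3][cand_used].copy(),
            )
            cand_used += 1
        ids = sorted(comps)
        scores = [float(mvn_logpdf(Y[i], comps[k].mu, comps[k].Omega)) for k in ids]
        if candidate is not None:
            scores.append(float(mvn_logpdf(Y[i], candidate.mu, candidate.Omega)))
        best = int(np.argmax(scores))
        if candidate is not None and best == len(ids):
            new_id = id_counter[0]
            id_counter[0] += 1
            comps[new_id] = candidate
            Z[i] = new_id
        else:
            Z[i] = ids[best]
    alpha = float(rng.gamma(hyper.a, 1.0 / hyper.b))
    lam = float(_draw_lambda_prior(None, hyper, rng))
    return MixtureState(Z=Z, comps=comps, alpha=alpha, lam=lam)


# ---------------------------------------------------------------------------
# precision updates


def _update_component_scales(comp: Component, lam: float, rng) -> None:
    p = comp.Omega.shape[0]
    mask = _offdiag_mask(p)
    om = np.abs(comp.Omega[mask])
    mean = np.minimum(lam / np.maximum(om, _OMEGA_EPS), _IG_MEAN_CAP)
    inv_tau = sample_inverse_gaussian(mean, lam * lam, rng)
    tau = np.zeros((p, p))
    tau[mask] = 1.0 / inv_tau
    comp.tau = _symmetric_offdiag(np.triu(tau, 1), p)


def _update_group_lambda(state: MixtureState, hyper: Hyperparameters,
                         rng) -> None:
    """Group-level penalty conditional aggregated over the group's components:
    lam_t ~ G(r + K p(p+1)/2, s + Σ_k Σ_{j1<=j2}|omega^{t,k}|)."""
    p = next(iter(state.comps.values())).Omega.shape[0]
    shape = hyper.r + 0.5 * p * (p + 1) * state.K
    rate = hyper.s + sum(_abs_upper_sum(c.Omega) for c in state.comps.values())
    state.lam = float(rng.gamma(shape, 1.0 / rate))


def _component_scatter(Y: np.ndarray, Z: np.ndarray, k: int,
                       mu: np.ndarray) -> tuple[np.ndarray, int]:
    rows = Y[Z == k]
    d = rows - mu
    return d.T @ d, rows.shape[0]


def _bsm_precision_update(Y: np.ndarray, state: MixtureState,
                          hyper: Hyperparameters, rng) -> None:
    """Stage-wise graphical lasso sweep per component (group-level penalty).

    Components with fewer than two members keep the precision they were born
    with: one observation cannot inform a p x p precision matrix, and under
    the near-flat penalty hyperprior the singleton conditionals drift to
    unbounded precisions, which would lock the component in permanently.
    """
    p = Y.shape[1]
    mask = _offdiag_mask(p)
    for k in sorted(state.comps):
        comp = state.comps[k]
        S, n_k = _component_scatter(Y, state.Z, k, comp.mu)
        if n_k < 2:
            continue
        A = np.zeros((p, p))
        A[mask] = 1.0 / comp.tau[mask]
        B = np.zeros((p, p))
        for j in range(p):
            sample_column_block(comp.Omega, S, A, B, state.lam, n_k, j, rng)
        _update_component_scales(comp, state.lam, rng)
    _update_group_lambda(state, hyper, rng)


class _FusionLinks:
    """Fusion scales and penalties between every unordered pair of live
    components (across all groups), created from priors at birth and dropped
    at death."""

    def __init__(self, hyper: Hyperparameters, rng):
        self.hyper = hyper
        self.rng = rng
        self.tau: dict[tuple[int, int], np.ndarray] = {}
        self.lam: dict[tuple[int, int], float] = {}

    def sync(self, all_comps: dict[int, Component], p: int) -> None:
        live = sorted(all_comps)
        wanted = {
            _pair_key(a, b) for ai, a in enumerate(live) for b in live[ai + 1:]
        }
        for key in list(self.tau):
            if key not in wanted:
                del self.tau[key]
                del self.lam[key]
        for key in wanted - set(self.tau):
            lam = float(_draw_lambda_prior(None, self.hyper, self.rng))
            self.lam[key] = lam
            raw = self.rng.exponential(scale=2.0 / lam**2, size=(p, p))
            self.tau[key] = _symmetric_offdiag(raw, p)


def _bfm_precision_update(datasets: list[np.ndarray],
                          states: list[MixtureState], links: _FusionLinks,
                          hyper: Hyperparameters, rng) -> None:
    """One fused sweep treating every live component of every group as a
    "group" of the fused sampler: fusion weights couple all component pairs."""
    p = datasets[0].shape[1]
    mask = _offdiag_mask(p)
    all_comps: dict[int, Component] = {}
    scatters: dict[int, tuple[np.ndarray, int]] = {}
    group_lam: dict[int, float] = {}
    for Y, st in zip(datasets, states):
        for k, comp in st.comps.items():
            all_comps[k] = comp
            scatters[k] = _component_scatter(Y, st.Z, k, comp.mu)
            group_lam[k] = st.lam
    links.sync(all_comps, p)
    live = sorted(all_comps)
    for k in live:
        comp = all_comps[k]
        S, n_k = scatters[k]
        if n_k < 2:   # singleton precisions stay at their birth draw
            continue
        A = np.zeros((p, p))
        A[mask] = 1.0 / comp.tau[mask]
        B = np.zeros((p, p))
        for kk in live:
            if kk == k:
                continue
            tau_pair = links.tau[_pair_key(k, kk)]
            A[mask] += 1.0 / tau_pair[mask]
            B[mask] += all_comps[kk].Omega[mask] / tau_pair[mask]
        for j in range(p):
            sample_column_block(comp.Omega, S, A, B, group_lam[k], n_k, j, rng)
    for k in live:
        if scatters[k][1] >= 2:
            _update_component_scales(all_comps[k], group_lam[k], rng)
    for st in states:
        _update_group_lambda(st, hyper, rng)
    shape = hyper.r + 0.5 * p * (p + 1)
    for (k1, k2) in links.tau:
        diff = all_comps[k1].Omega - all_comps[k2].Omega
        lam = links.lam[(k1, k2)]
        dd = np.abs(diff[mask])
        mean = np.minimum(lam / np.maximum(dd, _OMEGA_EPS), _IG_MEAN_CAP)
        inv_tau = sample_inverse_gaussian(mean, lam * lam, rng)
        tau = np.zeros((p, p))
        tau[mask] = 1.0 / inv_tau
        links.tau[(k1, k2)] = _symmetric_offdiag(np.triu(tau, 1), p)
        rate = hyper.s + _abs_upper_sum(diff)
        links.lam[(k1, k2)] = float(rng.gamma(shape, 1.0 / rate))


# ---------------------------------------------------------------------------
# results


@dataclass
class ComponentPosterior:
    """Posterior summary of one surviving component."""

    mu_mean: np.ndarray
    omega_mean: np.ndarray
    omega_samples: np.ndarray        # (n_samples, p, p) over the comp's lifetime
    n_members: int
    weight: float


@dataclass
class GroupMixtureResult:
    k_trace: np.ndarray
    k_estimate: int
    k_final: int
    z_final: np.ndarray              # relabeled 0..K-1
    z_chain: np.ndarray              # (n_kept, n_t) relabeled per stored sweep
    alpha_trace: np.ndarray
    components: list[ComponentPosterior]


@dataclass
class MixtureResult:
    groups: list[GroupMixtureResult]

    @property
    def k_per_group(self) -> list[int]:
        return [g.k_estimate for g in self.groups]


def _modal_k(k_trace: np.ndarray, burn_in: int) -> int:
    kept = k_trace[burn_in:]
    vals, counts = np.unique(kept, return_counts=True)
    return int(vals[np.argmax(counts)])  # ties -> smallest K


def run_mixture(dataset: GroupedDataset, method: str = "bsm",
                allocation: str = "dicrp",
                similarity: list[SimilarityMatrix] | None = None,
                hyper: Hyperparameters | None = None,
                rng=None) -> MixtureResult:
    """Full mixture MCMC (BSM or BFM) with CRP or DI-CRP allocation.

    ``similarity`` is required for DI-CRP (one matrix per group, row order
    matching the group's observation order); CRP runs the identical code path
    with an all-zero similarity, so the two coincide draw for draw at S = 0
    under the same seed.
    """
    method = method.lower()
    allocation = allocation.lower()
    if method not in ("bsm", "bfm"):
        raise ValueError("method must be 'bsm' or 'bfm'")
    if allocation not in ("crp", "dicrp"):
        raise ValueError("allocation must be 'crp' or 'dicrp'")
    hyper = hyper or Hyperparameters()
    if rng is None:
        rng = np.random.default_rng(hyper.seed)
    T, p = dataset.T, dataset.p
    group_Y = [dataset.rows_of(t + 1) for t in range(T)]
    if allocation == "dicrp":
        if similarity is None:
            raise ValueError("DI-CRP allocation requires a similarity matrix per group")
        sims = list(similarity)
        if len(sims) != T:
            raise ValueError("one similarity matrix per group is required")
        for Y, sm in zip(group_Y, sims):
            if sm.S.shape[0] != Y.shape[0]:
                raise ValueError("similarity matrix size must match the group size")
    else:
        sims = [SimilarityMatrix.zero(Y.shape[0]) for Y in group_Y]
    mu0 = hyper.mu0_vector(p)
    id_counter = [0]
    states = [initialize_clusters(Y, hyper, rng, id_counter) for Y in group_Y]
    links = _FusionLinks(hyper, rng) if method == "bfm" else None

    k_traces = [[] for _ in range(T)]
    alpha_traces = [[] for _ in range(T)]
    z_chains: list[list[np.ndarray]] = [[] for _ in range(T)]
    comp_mu_samples: dict[int, list[np.ndarray]] = {}
    comp_om_samples: dict[int, list[np.ndarray]] = {}

    def allocation_and_means(t: int) -> None:
        Y, st, sm = group_Y[t], states[t], sims[t]
        n_t = Y.shape[0]
        pool = draw_prior_components(hyper.M, p, hyper, rng,
                                     penalty=hyper.birth_penalty)
        plogphi = _pool_logphi(Y, pool[0], pool[1])
        for i in range(n_t):
            birth_death_step(i, st, sm, Y, pool, plogphi, n_t, rng, id_counter)
        for i in range(n_t):
            membership_step(i, st, sm, Y, rng)
        for k in sorted(st.comps):
            rows = Y[st.Z == k]
            st.comps[k].mu = sample_component_means(
                rows, st.comps[k].Omega, mu0, hyper.kappa0, rng
            )

    for it in range(hyper.n_iter):
        if method == "bsm":
            for t in range(T):
                allocation_and_means(t)
                _bsm_precision_update(group_Y[t], states[t], hyper, rng)
        else:
            for t in range(T):
                allocation_and_means(t)
            _bfm_precision_update(group_Y, states, links, hyper, rng)
        for t in range(T):
            states[t].alpha = sample_alpha(
                states[t].K, group_Y[t].shape[0], hyper.a, hyper.b,
                states[t].alpha, rng,
            )
            k_traces[t].append(states[t].K)
            alpha_traces[t].append(states[t].alpha)
        if it >= hyper.burn_in and (it - hyper.burn_in) % hyper.thin == 0:
            live = {k for st in states for k in st.comps}
            for dead in set(comp_mu_samples) - live:
                del comp_mu_samples[dead]
                del comp_om_samples[dead]
            for st in states:
                for k, comp in st.comps.items():
                    comp_mu_samples.setdefault(k, []).append(comp.mu.copy())
                    comp_om_samples.setdefault(k, []).append(comp.Omega.copy())
            for t in range(T):
                z_chains[t].append(states[t].Z.copy())

    results = []
    for t in range(T):
        st = states[t]
        n_t = group_Y[t].shape[0]
        ids = sorted(st.comps)
        relabel = {k: a for a, k in enumerate(ids)}
        z_final = np.array([relabel[int(k)] for k in st.Z])
        z_chain = np.array(
            [
                [relabel.get(int(k), -1) for k in z]
                for z in z_chains[t]
            ]
        )
        comps = []
        for k in ids:
            mus = np.array(comp_mu_samples.get(k, [st.comps[k].mu]))
            oms = np.array(comp_om_samples.get(k, [st.comps[k].Omega]))
            n_members = st.size_of(k)
            comps.append(
                ComponentPosterior(
                    mu_mean=mus.mean(axis=0),
                    omega_mean=oms.mean(axis=0),
                    omega_samples=oms,
                    n_members=n_members,
                    weight=n_members / n_t,
                )
            )
        k_trace = np.asarray(k_traces[t])
        results.append(
            GroupMixtureResult(
                k_trace=k_trace,
                k_estimate=_modal_k(k_trace, hyper.burn_in),
                k_final=int(k_trace[-1]),
                z_final=z_final,
                z_chain=z_chain,
                alpha_trace=np.asarray(alpha_traces[t]),
                components=comps,
            )
        )
    return MixtureResult(groups=results)
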