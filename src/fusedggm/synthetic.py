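"""Synthetic data generators: sparse precision structures, multi-group
Gaussian samples, mixtures with evolving sub-networks, and ground-truth
similarity matrices.

Precision matrices are built from explicit edge sets (a banded backbone plus
random extras) with off-diagonal entries of fixed magnitude and per-edge sign
and diagonally dominant diagonals, which guarantees positive definiteness
while keeping exact control of the sparsity pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GroupedDataset
from .mixture import SimilarityMatrix


@dataclass
class GeneratorConfig:
    """Knobs of the simulation designs.

    K_t gives the number of mixture components per group (length T); in
    "shared" mode a shared_frac fraction of edges forms a core common to all
    precision matrices while the rest evolve; edge_strength is the magnitude
    of off-diagonal precision entries; mean_separation the distance between
    adjacent component means within a group.
    """

    p: int = 10
    T: int = 3
    K_t: tuple[int, ...] | None = None
    n_t: int = 100
    structure: str = "shared"
    shared_frac: float = 0.8
    edge_strength: float = 0.4
    mean_separation: float = 3.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.shared_frac <= 1.0:
            raise ValueError("shared_frac must lie in [0, 1]")
        if self.K_t is None:
            self.K_t = tuple([1] * self.T)
        if len(self.K_t) != self.T:
            raise ValueError("K_t must have length T")
        if any(k > self.n_t for k in self.K_t):
            raise ValueError("K_t components cannot exceed n_t observations")
        if self.structure not in ("shared", "random"):
            raise ValueError("structure must be 'shared' or 'random'")


def _all_pairs(p: int) -> list[tuple[int, int]]:
    return [(j1, j2) for j1 in range(p) for j2 in range(j1 + 1, p)]


def _edges_to_precision(edges, signs: dict, p: int,
                        strength: float) -> np.ndarray:
    Om = np.zeros((p, p))
    for e in edges:
        v = signs[e] * strength
        Om[e[0], e[1]] = v
        Om[e[1], e[0]] = v
    np.fill_diagonal(Om, np.abs(Om).sum(axis=1) + 0.1)
    return Om


def _adjacency(edges, p: int) -> np.ndarray:
    A = np.zeros((p, p), dtype=int)
    for j1, j2 in edges:
        A[j1, j2] = A[j2, j1] = 1
    return A


def make_shared_structure_precisions(config: GeneratorConfig, rng,
                                     n_matrices: int | None = None):
    """Matrices sharing a core sparsity pattern with per-matrix evolution.

    A base graph (chain backbone + random extras, ~1.5 p edges) is built; a
    shared_frac fraction of it forms the common core present in every matrix,
    and each matrix replaces the remaining edges with its own random picks —
    mimicking sub-networks that partly persist and partly evolve.  Returns
    (list of PD matrices, list of 0/1 adjacency matrices).
    """
    p = config.p
    if p < 3:
        raise ValueError("p must be at least 3")
    n_matrices = n_matrices if n_matrices is not None else config.T
    backbone = [(j, j + 1) for j in range(p - 1)]
    pool = [e for e in _all_pairs(p) if e not in set(backbone)]
    n_extra = p // 2
    if n_extra > len(pool):
        raise ValueError("requested edge count is infeasible for this p")
    extra_idx = rng.choice(len(pool), size=n_extra, replace=False)
    base = backbone + [pool[i] for i in extra_idx]
    m = len(base)
    n_core = int(round(config.shared_frac * m))
    core_idx = rng.choice(m, size=n_core, replace=False)
    core = [base[i] for i in core_idx]
    signs = {e: (1.0 if rng.uniform() < 0.5 else -1.0) for e in _all_pairs(p)}
    outside = [e for e in _all_pairs(p) if e not in set(core)]
    mats, adjs = [], []
    for _ in range(n_matrices):
        n_own = m - n_core
        own_idx = rng.choice(len(outside), size=n_own, replace=False)
        edges = core + [outside[i] for i in own_idx]
        mats.append(_edges_to_precision(edges, signs, p, config.edge_strength))
        adjs.append(_adjacency(edges, p))
    return mats, adjs


def make_random_precisions(p: int, T: int, rng, ridge: float = 0.1):
    """Independent random PD matrices with no shared structure.

    Random factor product: Omega = G G^T + ridge*I with G a p x p standard
    normal factor, drawn independently per matrix — dense matrices whose
    element-wise differences are large, so no similarity is imposed.
    """
    if p < 2:
        raise ValueError("p must be at least 2")
    mats, adjs = [], []
    for _ in range(T):
        G = rng.standard_normal((p, p))
        Om = G @ G.T + ridge * np.eye(p)
        mats.append(Om)
        A = (Om != 0).astype(int)
        np.fill_diagonal(A, 0)
        adjs.append(A)
    return mats, adjs


def sample_gaussian_rows(n: int, mu: np.ndarray, Omega: np.ndarray,
                         rng) -> np.ndarray:
    """n draws from N(mu, Omega^{-1}) via the triangular factor of Omega."""
    p = len(mu)
    L = np.linalg.cholesky(Omega)
    z = rng.standard_normal((n, p))
    return mu + np.linalg.solve(L.T, z.T).T


@dataclass
class SimulatedMixture:
    """Ground truth bundle returned by simulate_mixture_dataset."""

    dataset: GroupedDataset
    z_true: list[np.ndarray]                 # per group, 0-based labels
    means: list[list[np.ndarray]]            # per group, per component
    precisions: list[list[np.ndarray]]       # per group, per component
    adjacencies: list[list[np.ndarray]]
    similarity: list[SimilarityMatrix] = field(default_factory=list)


def simulate_mixture_dataset(config: GeneratorConfig, rng) -> SimulatedMixture:
    """Multi-group mixture data with ground-truth binary similarity.

    The component precision matrices follow the shared-structure (or random)
    generator across the full component sequence; component means within a
    group sit on a common direction, ``mean_separation`` apart.  Memberships
    are balanced and shuffled; the per-group similarity matrix is 1 within a
    true cluster and 0 across.
    """
    total_K = sum(config.K_t)
    if config.structure == "shared":
        mats, adjs = make_shared_structure_precisions(config, rng, total_K)
    else:
        mats, adjs = make_random_precisions(config.p, total_K, rng)
    direction = np.ones(config.p) / np.sqrt(config.p)
    Y_parts, group_parts = [], []
    z_true, means, precisions, adjacencies, sims = [], [], [], [], []
    c = 0
    for t in range(config.T):
        K = config.K_t[t]
        mus = [
            (k - (K - 1) / 2.0) * config.mean_separation * direction
            for k in range(K)
        ]
        oms = mats[c:c + K]
        ads = adjs[c:c + K]
        c += K
        z = np.array([i % K for i in range(config.n_t)])
        rng.shuffle(z)
        rows = np.empty((config.n_t, config.p))
        for k in range(K):
            members = z == k
            rows[members] = sample_gaussian_rows(
                int(members.sum()), mus[k], oms[k], rng
            )
        S = (z[:, None] == z[None, :]).astype(float)
        np.fill_diagonal(S, 0.0)
        Y_parts.append(rows)
        group_parts.append(np.full(config.n_t, t + 1))
        z_true.append(z)
        means.append(mus)
        precisions.append(oms)
        adjacencies.append(ads)
        sims.append(SimilarityMatrix(S))
    dataset = GroupedDataset(np.vstack(Y_parts), np.concatenate(group_parts))
    return SimulatedMixture(
        dataset=dataset, z_true=z_true, means=means,
        precisions=precisions, adjacencies=adjacencies, similarity=sims,
    )


def simulate_grouped_dataset(precisions, n_t: int, rng,
                             means=None) -> GroupedDataset:
    """Plain multi-group Gaussian data (one component per group, zero means
    by default) from the supplied precision matrices."""
    T = len(precisions)
    p = precisions[0].shape[0]
    if means is None:
        means = [np.zeros(p)] * T
    Y = np.vstack(
        [sample_gaussian_rows(n_t, means[t], precisions[t], rng) for t in range(T)]
    )
    groups = np.repeat(np.arange(1, T + 1), n_t)
    return GroupedDataset(Y, groups)
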