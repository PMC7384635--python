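"""Posterior summarization, sparsification and predictive scoring.

Point estimates are element-wise posterior means; an edge is declared when
the equal-tailed credible interval of the corresponding precision element
excludes zero; networks are reported as partial correlations (standardized
negated off-diagonal precision elements).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import GroupedDataset, Hyperparameters, mvn_logpdf
from .gibbs import FusedChain, run_fused_chain
from .mixture import SimilarityMatrix, run_mixture

_LOG_FLOOR = -1e10

METHODS = ("nonmixture", "bsm-crp", "bsm-dicrp", "bfm-crp", "bfm-dicrp")


@dataclass
class PosteriorSummary:
    """Element-wise posterior mean, credible bounds, adjacency and partial
    correlations for one precision matrix."""

    omega_mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    adjacency: np.ndarray
    partial_corr: np.ndarray
    credible_level: float


def summarize_chain(samples, credible_level: float = 0.95):
    """Summarize precision-matrix posterior draws.

    ``samples`` may be an (n_samples, p, p) array (returns one
    PosteriorSummary) or a FusedChain (returns a list, one per group).
    Credible bounds are the equal-tailed (1±level)/2 empirical quantiles;
    adjacency marks elements whose interval excludes zero (diagonal zeroed).
    """
    if isinstance(samples, FusedChain):
        return [
            summarize_chain(samples.omega[:, t], credible_level)
            for t in range(samples.omega.shape[1])
        ]
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 3 or samples.shape[0] == 0:
        raise ValueError("need a nonempty (n_samples, p, p) stack of draws")
    lo_q = (1.0 - credible_level) / 2.0
    omega_mean = samples.mean(axis=0)
    ci_lo = np.quantile(samples, lo_q, axis=0)
    ci_hi = np.quantile(samples, 1.0 - lo_q, axis=0)
    adjacency = ((ci_lo > 0) | (ci_hi < 0)).astype(int)
    np.fill_diagonal(adjacency, 0)
    return PosteriorSummary(
        omega_mean=omega_mean,
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        adjacency=adjacency,
        partial_corr=partial_correlations(omega_mean),
        credible_level=credible_level,
    )


def partial_correlations(Omega: np.ndarray) -> np.ndarray:
    """rho_{jk} = -omega_{jk} / sqrt(omega_jj omega_kk), unit diagonal."""
    Omega = np.asarray(Omega, dtype=float)
    d = np.diag(Omega)
    if (d <= 0).any():
        raise ValueError("precision diagonal must be positive")
    denom = np.sqrt(np.outer(d, d))
    rho = -Omega / denom
    np.fill_diagonal(rho, 1.0)
    return rho


def predictive_loglik(components: list[tuple[float, np.ndarray, np.ndarray]],
                      heldout: np.ndarray) -> float:
    """Plug-in mixture predictive log-likelihood of held-out rows.

    ``components`` is a list of (weight, mu, Omega); weights are occupancy
    proportions and parameters posterior means.  Rows whose total density
    underflows contribute the floor -1e10 (with a warning).
    """
    heldout = np.atleast_2d(np.asarray(heldout, dtype=float))
    if not components:
        raise ValueError("at least one component is required")
    weights = np.array([w for w, _, _ in components], dtype=float)
    logw = np.log(np.maximum(weights, np.finfo(float).tiny))
    lps = np.stack(
        [np.asarray(mvn_logpdf(heldout, mu, Om)) for _, mu, Om in components]
    )  # (K, n)
    row_ll = logsumexp(lps + logw[:, None], axis=0)
    bad = ~np.isfinite(row_ll) | (row_ll < _LOG_FLOOR)
    if bad.any():
        warnings.warn(f"{bad.sum()} held-out rows had zero predictive density")
        row_ll = np.where(bad, _LOG_FLOOR, row_ll)
    return float(row_ll.sum())


# ---------------------------------------------------------------------------
# model fitting wrappers used by cross-validation


def _fit_components(train: GroupedDataset, method: str,
                    similarity: list[SimilarityMatrix] | None,
                    hyper: Hyperparameters, rng):
    """Fit one method; return per-group component lists (weight, mu, Omega)."""
    if method == "nonmixture":
        out = []
        for t in range(1, train.T + 1):
            rows = train.rows_of(t)
            sub = GroupedDataset(rows, np.ones(rows.shape[0], dtype=int))
            chain = run_fused_chain(sub, hyper, rng)
            out.append(
                [(1.0, chain.posterior_mean_mu()[0], chain.posterior_mean_omega()[0])]
            )
        return out
    kind, allocation = method.split("-")
    result = run_mixture(
        train, method=kind, allocation=allocation,
        similarity=similarity, hyper=hyper, rng=rng,
    )
    return [
        [(c.weight, c.mu_mean, c.omega_mean) for c in g.components]
        for g in result.groups
    ]


def kfold_cv(dataset: GroupedDataset, methods=METHODS, k: int = 5,
             hyper: Hyperparameters | None = None,
             similarity: list[SimilarityMatrix] | None = None,
             seed: int | None = None) -> pd.DataFrame:
    """k-fold cross-validated predictive log-likelihood per method.

    Folds are stratified by group; held-out rows are scored against the
    mixture fitted to their own group.  Returns a (k x methods) table.
    Reproducible: fold splits and every fit derive from ``seed``.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    hyper = hyper or Hyperparameters()
    if seed is None:
        seed = hyper.seed or 0
    if (dataset.n_t // k < 2).any():
        raise ValueError("every group needs at least 2 observations per fold")
    split_rng = np.random.default_rng([int(seed), 815])
    fold_of = np.empty(dataset.n, dtype=int)
    for t in range(1, dataset.T + 1):
        idx = dataset.indices_of(t)
        perm = split_rng.permutation(idx)
        for f in range(k):
            fold_of[perm[f::k]] = f
    table = np.empty((k, len(methods)))
    for f in range(k):
        train_mask = fold_of != f
        train = GroupedDataset(
            dataset.Y[train_mask], dataset.groups[train_mask], dataset.var_names
        )
        if similarity is not None:
            sub_sims = []
            for t in range(1, dataset.T + 1):
                keep = train_mask[dataset.indices_of(t)]
                sub_sims.append(
                    SimilarityMatrix(similarity[t - 1].S[np.ix_(keep, keep)])
                )
        else:
            sub_sims = None
        for m, method in enumerate(methods):
            needs_sim = method.endswith("dicrp")
            if needs_sim and sub_sims is None:
                raise ValueError(f"method {method} requires similarity matrices")
            rng = np.random.default_rng([int(seed), f, m])
            comps = _fit_components(
                train, method, sub_sims if needs_sim else None, hyper, rng
            )
            total = 0.0
            for t in range(1, dataset.T + 1):
                ho = dataset.Y[(~train_mask) & (dataset.groups == t)]
                if ho.shape[0]:
                    total += predictive_loglik(comps[t - 1], ho)
            table[f, m] = total
    return pd.DataFrame(table, columns=list(methods),
                        index=[f"fold{f + 1}" for f in range(k)])


# ---------------------------------------------------------------------------
# export


def edge_list(summary: PosteriorSummary,
              var_names: list[str] | None = None) -> pd.DataFrame:
    """TSV-ready edge list: term pair, partial correlation, credible bounds."""
    p = summary.adjacency.shape[0]
    names = var_names or [f"v{j + 1}" for j in range(p)]
    rows = []
    for j1 in range(p):
        for j2 in range(j1 + 1, p):
            if summary.adjacency[j1, j2]:
                rows.append(
                    {
                        "term1": names[j1],
                        "term2": names[j2],
                        "partial_corr": summary.partial_corr[j1, j2],
                        "ci_lo": summary.ci_lo[j1, j2],
                        "ci_hi": summary.ci_hi[j1, j2],
                    }
                )
    return pd.DataFrame(rows, columns=["term1", "term2", "partial_corr",
                                       "ci_lo", "ci_hi"])


def export_summary(summary: PosteriorSummary, out_dir: str | Path,
                   prefix: str, var_names: list[str] | None = None,
                   graphml: bool = False) -> None:
    """Write matrices as CSV, edges as TSV, optionally a GraphML network."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, mat in [
        ("omega_mean", summary.omega_mean),
        ("ci_lo", summary.ci_lo),
        ("ci_hi", summary.ci_hi),
        ("adjacency", summary.adjacency),
        ("partial_corr", summary.partial_corr),
    ]:
        np.savetxt(out / f"{prefix}_{name}.csv", mat, delimiter=",",
                   header=f"{name} {mat.shape[0]}x{mat.shape[1]}")
    edge_list(summary, var_names).to_csv(
        out / f"{prefix}_edges.tsv", sep="\t", index=False
    )
    if graphml:
        import networkx as nx

        p = summary.adjacency.shape[0]
        names = var_names or [f"v{j + 1}" for j in range(p)]
        G = nx.Graph()
        G.add_nodes_from(names)
        for j1 in range(p):
            for j2 in range(j1 + 1, p):
                if summary.adjacency[j1, j2]:
                    G.add_edge(names[j1], names[j2],
                               weight=float(summary.partial_corr[j1, j2]))
        nx.write_graphml(G, out / f"{prefix}_network.graphml")
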