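"""Shared domain types and density helpers.

The model: observations in T known groups, each group t following a
p-variate Gaussian N(mu_t, Omega_t^{-1}).  Sparse precision matrices
Omega_t encode conditional-independence networks; a fused-lasso-type
prior shrinks corresponding elements of different groups toward each
other.  This module holds the containers shared by the samplers plus the
log-density primitives everything else is built on.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml


class InvalidStateError(ValueError):
    """A matrix that must be positive definite is not, or a scale is not positive."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class GroupedDataset:
    """n x p data matrix with an exhaustive, exclusive group label per row.

    Parameters
    ----------
    Y : (n, p) float array
        One row per observation, one column per variable.
    groups : (n,) int array
        Group label per row, values in 1..T with every group nonempty.
    var_names : optional sequence of p variable names.
    """

    Y: np.ndarray
    groups: np.ndarray
    var_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        self.groups = np.asarray(self.groups, dtype=int)
        if self.Y.ndim != 2 or self.Y.shape[1] < 2:
            raise ValueError("Y must be a 2-d matrix with p >= 2 variables")
        if self.groups.shape != (self.Y.shape[0],):
            raise ValueError("one group label per row is required")
        if np.isnan(self.Y).any():
            raise ValueError("data matrix contains NaN")
        labels = np.unique(self.groups)
        if not np.array_equal(labels, np.arange(1, labels.size + 1)):
            raise ValueError("group labels must be 1..T with every group nonempty")
        if self.var_names is not None and len(self.var_names) != self.Y.shape[1]:
            raise ValueError("var_names length must equal p")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    @property
    def T(self) -> int:
        return int(self.groups.max())

    @property
    def n_t(self) -> np.ndarray:
        return np.bincount(self.groups, minlength=self.T + 1)[1:]

    def rows_of(self, t: int) -> np.ndarray:
        """Data rows of group t (1-based label)."""
        return self.Y[self.groups == t]

    def indices_of(self, t: int) -> np.ndarray:
        return np.flatnonzero(self.groups == t)

    # -- delimited text I/O ------------------------------------------------

    @classmethod
    def from_csv(cls, path: str | Path, group_col: str = "group",
                 sep: str = ",") -> "GroupedDataset":
        df = pd.read_csv(path, sep=sep)
        if group_col not in df.columns:
            raise ValueError(f"group column {group_col!r} not found in {path}")
        groups = df[group_col].to_numpy(dtype=int)
        data = df.drop(columns=[group_col])
        return cls(data.to_numpy(dtype=float), groups, list(data.columns))

    def to_csv(self, path: str | Path, group_col: str = "group",
               sep: str = ",") -> None:
        names = self.var_names or [f"v{j + 1}" for j in range(self.p)]
        df = pd.DataFrame(self.Y, columns=names)
        df.insert(0, group_col, self.groups)
        df.to_csv(path, sep=sep, index=False)


@dataclass
class Hyperparameters:
    """Prior and sampler settings.

    r, s : gamma shape and rate of the penalty hyperpriors λ ~ G(r, s).
    a, b : gamma hyperparameters of the concentration parameter α.
    mu0, kappa0 : mean-prior location and precision multiplier, μ|Ω ~ N(mu0, (kappa0·Ω)^{-1}).
    credible_level : probability mass of the equal-tailed credible intervals.
    K_max : cap on the number of mixture components created at initialization.
    M : Monte-Carlo draws approximating the new-component marginal likelihood.
    n_iter, burn_in, thin : MCMC budget.
    birth_penalty : lasso penalty for birth-move candidate precisions; None
        (default) draws λ from its G(r, s) hyperprior.
    init_penalty : reference lasso penalty for the candidate components of
        the sequential initialization, which needs data-scale candidates.
    """

    r: float = 0.001
    s: float = 1.0
    a: float = 1.0
    b: float = 1.0
    mu0: np.ndarray | None = None
    kappa0: float = 1.0
    credible_level: float = 0.95
    K_max: int = 10
    M: int = 50
    n_iter: int = 1000
    burn_in: int = 100
    thin: int = 1
    seed: int | None = None
    birth_penalty: float | None = None
    init_penalty: float = 1.0
    adjacent_fusion_only: bool = False

    def __post_init__(self) -> None:
        for name in ("r", "s", "a", "b", "kappa0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.credible_level < 1.0:
            raise ValueError("credible_level must lie in (0, 1)")
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.mu0 is not None:
            self.mu0 = np.asarray(self.mu0, dtype=float)

    def mu0_vector(self, p: int) -> np.ndarray:
        if self.mu0 is None:
            return np.zeros(p)
        if self.mu0.shape != (p,):
            raise ValueError("mu0 must have length p")
        return self.mu0

    @classmethod
    def from_file(cls, path: str | Path) -> "Hyperparameters":
        """Flat YAML/JSON config with exactly the field names of this class."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown hyperparameter fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if isinstance(d.get("mu0"), np.ndarray):
            d["mu0"] = d["mu0"].tolist()
        return d


def _pair_key(t1: int, t2: int) -> tuple[int, int]:
    return (t1, t2) if t1 < t2 else (t2, t1)


@dataclass
class FusedChainState:
    """One sweep's worth of fused-sampler state.

    Omega : list of T symmetric PD (p, p) precision matrices.
    tau_lasso : list of T (p, p) symmetric positive latent-scale matrices
        (off-diagonal entries are the ones with meaning).
    tau_fuse : dict keyed by unordered group pair (t1, t2), t1 < t2, 0-based,
        holding a (p, p) symmetric positive scale matrix per pair.
    lambda_lasso : (T,) positive lasso penalties.
    lambda_fuse : dict keyed like tau_fuse holding positive fusion penalties.
    """

    Omega: list[np.ndarray]
    tau_lasso: list[np.ndarray]
    tau_fuse: dict[tuple[int, int], np.ndarray]
    lambda_lasso: np.ndarray
    lambda_fuse: dict[tuple[int, int], float]

    def validate(self) -> None:
        for Om in self.Omega:
            w = np.linalg.eigvalsh(Om)
            if w.min() <= 0:
                raise InvalidStateError("precision matrix is not positive definite")
        for tau in self.tau_lasso:
            off = tau[~np.eye(tau.shape[0], dtype=bool)]
            if (off <= 0).any():
                raise InvalidStateError("non-positive lasso scale")
        for tau in self.tau_fuse.values():
            off = tau[~np.eye(tau.shape[0], dtype=bool)]
            if (off <= 0).any():
                raise InvalidStateError("non-positive fusion scale")
        if (self.lambda_lasso <= 0).any() or any(
            lam <= 0 for lam in self.lambda_fuse.values()
        ):
            raise InvalidStateError("non-positive penalty parameter")


@dataclass
class ScatterStatistics:
    """Un-normalized scatter S_t = Σ_i (y_i − μ_t)(y_i − μ_t)^T and the group count."""

    S: np.ndarray
    n_t: int


# ---------------------------------------------------------------------------
# density / score helpers


def chol_logdet(Omega: np.ndarray) -> tuple[np.ndarray, float]:
    """Cholesky factor and log-determinant of a PD matrix.

    Raises InvalidStateError when the matrix is not PD (the factorization is
    the PD check — no separate eigendecomposition).
    """
    try:
        L = np.linalg.cholesky(Omega)
    except np.linalg.LinAlgError as exc:
        raise InvalidStateError("matrix is not positive definite") from exc
    return L, 2.0 * float(np.sum(np.log(np.diag(L))))


def mvn_logpdf(y: np.ndarray, mu: np.ndarray, Omega: np.ndarray) -> float | np.ndarray:
    """Log-density of N(mu, Omega^{-1}) parameterized by the precision matrix.

    ``y`` may be a single length-p vector or an (n, p) batch; the return is a
    scalar or an (n,) array accordingly.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    _, logdet = chol_logdet(Omega)
    d = np.atleast_2d(y) - mu
    quad = np.einsum("ij,jk,ik->i", d, Omega, d)
    out = 0.5 * logdet - 0.5 * d.shape[1] * np.log(2.0 * np.pi) - 0.5 * quad
    return out if y.ndim == 2 else float(out[0])


def scatter_matrix(dataset: GroupedDataset,
                   means: Sequence[np.ndarray]) -> list[ScatterStatistics]:
    """Per-group un-normalized scatter about the supplied means."""
    out = []
    for t in range(1, dataset.T + 1):
        rows = dataset.rows_of(t)
        if rows.shape[0] == 0:
            raise ValueError(f"group {t} is empty")
        mu = np.asarray(means[t - 1], dtype=float)
        if mu.shape != (dataset.p,):
            raise ValueError("each mean must have length p")
        d = rows - mu
        out.append(ScatterStatistics(S=d.T @ d, n_t=rows.shape[0]))
    return out


def penalized_loglik(S_list: Sequence[ScatterStatistics],
                     Omega: Sequence[np.ndarray],
                     lambda_lasso: Sequence[float],
                     lambda_fuse: dict[tuple[int, int], float] | None = None) -> float:
    """Fused graphical lasso objective (a diagnostic score, never maximized).

    Σ_t [log|Ω_t| − tr(S_t Ω_t)] − Σ_t λ_t‖Ω_t‖₁ − Σ_{t1<t2} λ_{t1,t2}‖Ω_{t1}−Ω_{t2}‖₁
    with ‖·‖₁ the element-wise absolute sum.
    """
    lambda_fuse = lambda_fuse or {}
    total = 0.0
    for stats, Om, lam in zip(S_list, Omega, lambda_lasso):
        _, logdet = chol_logdet(Om)
        total += logdet - float(np.trace(stats.S @ Om))
        total -= lam * float(np.abs(Om).sum())
    for (t1, t2), lam in lambda_fuse.items():
        total -= lam * float(np.abs(Omega[t1] - Omega[t2]).sum())
    return total
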