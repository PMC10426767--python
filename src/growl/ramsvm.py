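"""Weighted reinforced angle-based multicategory SVM (RAMSVM).

This module carries the supervised half of the method: given a fixed
partition of the M treatments into K groups, learning the group decision
function f : X -> R^{K-1} reduces to a weighted K-category classification
problem.  The pieces, in the order they run:

1. :func:`fit_main_effect` — least-squares main effect s(X), used only to
   residualise the outcome R - s(X) and shrink the IPW weights.
2. :func:`transform_residuals` — subjects with positive residual keep their
   observed group with weight (R - s)/p(group|X); subjects with negative
   residual switch to the other K-1 groups (deterministically expanded, or
   sampled) with weight proportional to -(R - s)/p(group|X).  This restores
   non-negative weights without changing the population minimiser.
3. :func:`solve_dual_linear` / :func:`solve_dual_kernel` — the RAMSVM hinge
   surrogate (:func:`ramsvm_loss`, mixing parameter gamma) leads to a
   box-constrained quadratic dual, solved by exact cyclic coordinate descent;
   the primal decision function is recovered from the multipliers.
4. :func:`predict` — evaluate f and assign each point to
   ``argmax_k <W_k, f(x)>``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterator, Literal, Sequence

import numpy as np
from scipy.linalg import cho_factor
from scipy.spatial.distance import cdist

from . import _cd
from .simplex_coding import SimplexCode, decide_groups

logger = logging.getLogger("growl")

__all__ = [
    "GrowlError",
    "SingularGramError",
    "NoMatchError",
    "TrialDataset",
    "Partition",
    "WeightedRecord",
    "RecordSet",
    "KernelSpec",
    "LinearDecisionModel",
    "KernelDecisionModel",
    "DualState",
    "ramsvm_loss",
    "group_propensity",
    "fit_main_effect",
    "transform_residuals",
    "solve_dual_linear",
    "solve_dual_kernel",
    "predict",
]


class GrowlError(Exception):
    """Base class for errors raised by this package."""


class SingularGramError(GrowlError):
    """Gram matrix is numerically singular and jitter is disabled/failed."""


class NoMatchError(GrowlError):
    """No subject's observed group matches the recommended group."""


# --------------------------------------------------------------------------
# data containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrialDataset:
    """Single-stage trial data: covariates, treatments, outcomes, propensities.

    Attributes
    ----------
    X : (n, d) float array
        Covariates (without intercept column).
    A : (n,) int array
        Treatment labels in ``1..M``.
    R : (n,) float array
        Outcomes; larger is better.
    prop : (n, M) float array
        ``prop[i, a-1] = p(a | X_i)``; rows strictly positive, summing to 1.
    """

    X: np.ndarray
    A: np.ndarray
    R: np.ndarray
    prop: np.ndarray

    def __post_init__(self):
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        A = np.asarray(self.A, dtype=int)
        R = np.asarray(self.R, dtype=float)
        prop = np.atleast_2d(np.asarray(self.prop, dtype=float))
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "R", R)
        object.__setattr__(self, "prop", prop)
        n, d = X.shape
        if n < 1 or d < 1:
            raise ValueError("need n >= 1 subjects and d >= 1 covariates")
        if A.shape != (n,) or R.shape != (n,):
            raise ValueError("A and R must be length-n vectors")
        M = prop.shape[1]
        if prop.shape != (n, M) or M < 2:
            raise ValueError("prop must be an (n, M) matrix with M >= 2")
        if A.min() < 1 or A.max() > M:
            raise ValueError("treatment labels must lie in 1..M")
        if np.any(prop <= 0):
            raise ValueError("propensities must be strictly positive (positivity)")
        if np.max(np.abs(prop.sum(axis=1) - 1.0)) > 1e-8:
            raise ValueError("each propensity row must sum to 1 (tol 1e-8)")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def d(self) -> int:
        return self.X.shape[1]

    @property
    def M(self) -> int:
        return self.prop.shape[1]

    def subset(self, idx: np.ndarray) -> "TrialDataset":
        return TrialDataset(self.X[idx], self.A[idx], self.R[idx], self.prop[idx])


@dataclass(frozen=True)
class Partition:
    """Surjective map from M treatments onto group labels ``1..K``.

    ``labels[a-1]`` is the group of treatment ``a``.  Identified only up to
    a permutation of the group labels; see :func:`growl.partition_search.canonicalize`.
    """

    labels: tuple
    K: int

    def __init__(self, labels: Sequence[int], K: int | None = None):
        labels = tuple(int(v) for v in labels)
        if K is None:
            K = max(labels)
        K = int(K)
        present = set(labels)
        if present != set(range(1, K + 1)):
            raise ValueError(
                f"every group 1..{K} must be non-empty; got labels {labels}"
            )
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "K", K)

    @property
    def M(self) -> int:
        return len(self.labels)

    def group_of(self, A: np.ndarray) -> np.ndarray:
        """Vectorised delta(A) for treatment labels in 1..M."""
        return np.asarray(self.labels)[np.asarray(A, dtype=int) - 1]

    def members(self, k: int) -> np.ndarray:
        """Treatments (1-based) in group k."""
        lab = np.asarray(self.labels)
        return np.nonzero(lab == k)[0] + 1


@dataclass(frozen=True)
class WeightedRecord:
    """One transformed training record: a (possibly switched) group label
    with a non-negative IPW weight."""

    index: int
    x: np.ndarray
    group_label: int
    weight: float


class RecordSet:
    """Array-backed sequence of :class:`WeightedRecord` (solver input)."""

    def __init__(self, X: np.ndarray, labels: np.ndarray, weights: np.ndarray,
                 subject: np.ndarray, n_subjects: int):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.labels = np.asarray(labels, dtype=int)
        self.weights = np.asarray(weights, dtype=float)
        self.subject = np.asarray(subject, dtype=int)
        self.n_subjects = int(n_subjects)
        if np.any(self.weights < 0):
            raise ValueError("record weights must be non-negative")

    def __len__(self) -> int:
        return self.labels.shape[0]

    def __iter__(self) -> Iterator[WeightedRecord]:
        for i in range(len(self)):
            yield WeightedRecord(int(self.subject[i]), self.X[i],
                                 int(self.labels[i]), float(self.weights[i]))

    def __getitem__(self, i: int) -> WeightedRecord:
        return WeightedRecord(int(self.subject[i]), self.X[i],
                              int(self.labels[i]), float(self.weights[i]))


@dataclass(frozen=True)
class KernelSpec:
    """Kernel choice for the decision function.

    ``sigma2`` is the squared inverse bandwidth in
    ``kappa(x, x') = exp(-sigma2 * ||x - x'||^2)`` (RBF only).
    """

    kernel: Literal["linear", "rbf"] = "linear"
    sigma2: float | None = None

    def __post_init__(self):
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.kernel == "rbf" and (self.sigma2 is None or self.sigma2 <= 0):
            raise ValueError("rbf kernel needs sigma2 > 0")

    def gram(self, X: np.ndarray, Y: np.ndarray | None = None) -> np.ndarray:
        Y = X if Y is None else Y
        if self.kernel == "linear":
            return X @ Y.T
        d2 = cdist(X, Y, metric="sqeuclidean")
        return np.exp(-self.sigma2 * d2)


@dataclass
class LinearDecisionModel:
    """f_k(x) = <beta_k, (1, x)>; rows of B are beta_k, k = 1..K-1."""

    B: np.ndarray  # (K-1, d+1); column 0 multiplies the constant 1

    @property
    def K(self) -> int:
        return self.B.shape[0] + 1

    @property
    def d(self) -> int:
        return self.B.shape[1] - 1

    def decision_values(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.d:
            raise ValueError(
                f"model trained with d={self.d} covariates, got {X_new.shape[1]}"
            )
        return self.B[:, 0][None, :] + X_new @ self.B[:, 1:].T

    def penalty_norm2(self) -> float:
        """sum_k beta_k' beta_k (intercept included in the penalised vector)."""
        return float(np.sum(self.B**2))


@dataclass
class KernelDecisionModel:
    """f_k(x) = theta_{k,0} + sum_i theta_{k,i} kappa(X_i, x)."""

    spec: KernelSpec
    train_X: np.ndarray          # (n_rec, d)
    Theta: np.ndarray            # (n_rec, K-1), columns theta_k
    intercepts: np.ndarray       # (K-1,)

    @property
    def K(self) -> int:
        return self.Theta.shape[1] + 1

    @property
    def d(self) -> int:
        return self.train_X.shape[1]

    def decision_values(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
        if X_new.shape[1] != self.d:
            raise ValueError(
                f"model trained with d={self.d} covariates, got {X_new.shape[1]}"
            )
        Knm = self.spec.gram(X_new, self.train_X)
        return self.intercepts[None, :] + Knm @ self.Theta

    def penalty_norm2(self) -> float:
        """sum_k theta_k' G theta_k (the RKHS squared norm; intercept free)."""
        G = self.spec.gram(self.train_X)
        return float(np.sum(self.Theta * (G @ self.Theta)))


@dataclass
class DualState:
    """Solution state of a box-constrained dual QP."""

    alpha: np.ndarray            # (n_rec, K)
    upper: np.ndarray            # (n_rec, K)
    objective: float
    objective_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_sweeps: int = 0
    converged: bool = True
    kkt_residual: float = 0.0


# --------------------------------------------------------------------------
# loss and transforms
# --------------------------------------------------------------------------


def ramsvm_loss(group_label: int, f_value: np.ndarray, gamma: float,
                code: SimplexCode) -> float:
    """Reinforced angle-based hinge loss.

    ``(1-gamma) * sum_{k != label} (1 + <W_k, f>)_+
    + gamma * (K - 1 - <W_label, f>)_+``.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    f_value = np.asarray(f_value, dtype=float)
    if f_value.shape != (code.K - 1,):
        raise ValueError("f_value must have length K-1")
    scores = code.W @ f_value
    lab = group_label - 1
    others = np.delete(scores, lab)
    return float(
        (1.0 - gamma) * np.sum(np.maximum(1.0 + others, 0.0))
        + gamma * max(code.K - 1.0 - scores[lab], 0.0)
    )


def ramsvm_loss_matrix(labels: np.ndarray, f_values: np.ndarray, gamma: float,
                       code: SimplexCode) -> np.ndarray:
    """Vectorised :func:`ramsvm_loss` over (label_i, f_i) pairs."""
    scores = f_values @ code.W.T                       # (m, K)
    m = scores.shape[0]
    lab0 = np.asarray(labels, dtype=int) - 1
    own = scores[np.arange(m), lab0]
    hinge_all = np.maximum(1.0 + scores, 0.0)
    sum_others = hinge_all.sum(axis=1) - np.maximum(1.0 + own, 0.0)
    return (1.0 - gamma) * sum_others + gamma * np.maximum(
        code.K - 1.0 - own, 0.0
    )


def group_propensity(dataset: TrialDataset, partition: Partition) -> np.ndarray:
    """(n, K) matrix of group propensities p(group k | X_i): within-group sums
    of the treatment propensities.  Rows sum to 1."""
    if partition.M != dataset.M:
        raise ValueError("partition and dataset disagree on M")
    out = np.empty((dataset.n, partition.K))
    lab = np.asarray(partition.labels)
    for k in range(1, partition.K + 1):
        out[:, k - 1] = dataset.prop[:, lab == k].sum(axis=1)
    return out


def fit_main_effect(dataset: TrialDataset) -> Callable[[np.ndarray], np.ndarray]:
    """Ordinary least squares of R on (1, X); returns the fitted function.

    Used only to residualise the outcome.  Falls back to a ridge-stabilised
    solve (with a warning) if the design is rank deficient.
    """
    n, d = dataset.X.shape
    Xa = np.column_stack([np.ones(n), dataset.X])
    coef, _, rank, _ = np.linalg.lstsq(Xa, dataset.R, rcond=None)
    if rank < d + 1:
        warnings.warn(
            "rank-deficient design in main-effect fit; using ridge-stabilised solve",
            RuntimeWarning,
        )
        coef = np.linalg.solve(Xa.T @ Xa + 1e-8 * np.eye(d + 1), Xa.T @ dataset.R)

    def s(Xq: np.ndarray) -> np.ndarray:
        Xq = np.atleast_2d(np.asarray(Xq, dtype=float))
        return coef[0] + Xq @ coef[1:]

    s.coef_ = coef  # type: ignore[attr-defined]
    return s


def transform_residuals(
    dataset: TrialDataset,
    partition: Partition,
    s: Callable[[np.ndarray], np.ndarray] | None,
    mode: Literal["expand", "sample"] = "expand",
    seed: int | np.random.Generator | None = None,
) -> RecordSet:
    """Residualise outcomes and switch groups for negative residuals.

    For subject i with residual ``r_i = R_i - s(X_i)`` and group propensity
    ``p_i = p(delta(A_i) | X_i)``:

    * ``r_i > 0`` — one record with the observed group, weight ``r_i / p_i``;
    * ``r_i < 0`` and ``mode='expand'`` — K-1 records, one per other group,
      each with weight ``-r_i / p_i`` (the exact expectation of the uniform
      group switch);
    * ``r_i < 0`` and ``mode='sample'`` — one record with a group drawn
      uniformly from the K-1 other groups, weight ``(K-1)(-r_i)/p_i``;
    * ``r_i = 0`` — no record.
    """
    if mode not in ("expand", "sample"):
        raise ValueError(f"mode must be 'expand' or 'sample', got {mode!r}")
    K = partition.K
    resid = dataset.R - (s(dataset.X) if s is not None else 0.0)
    gp = group_propensity(dataset, partition)
    delta_A = partition.group_of(dataset.A)
    p_own = gp[np.arange(dataset.n), delta_A - 1]

    pos = resid > 0
    neg = resid < 0
    xs, labels, weights, subject = [], [], [], []
    if np.any(pos):
        xs.append(dataset.X[pos])
        labels.append(delta_A[pos])
        weights.append(resid[pos] / p_own[pos])
        subject.append(np.nonzero(pos)[0])
    if np.any(neg):
        idx = np.nonzero(neg)[0]
        base_w = -resid[idx] / p_own[idx]
        if mode == "expand":
            for i, w in zip(idx, base_w):
                own = delta_A[i]
                for j in range(1, K + 1):
                    if j == own:
                        continue
                    xs.append(dataset.X[i][None, :])
                    labels.append(np.array([j]))
                    weights.append(np.array([w]))
                    subject.append(np.array([i]))
        else:
            rng = (seed if isinstance(seed, np.random.Generator)
                   else np.random.default_rng(seed))
            for i, w in zip(idx, base_w):
                own = delta_A[i]
                choices = [j for j in range(1, K + 1) if j != own]
                j = int(rng.choice(choices))
                xs.append(dataset.X[i][None, :])
                labels.append(np.array([j]))
                weights.append(np.array([(K - 1) * w]))
                subject.append(np.array([i]))
    if not xs:
        return RecordSet(np.empty((0, dataset.d)), np.empty(0, int),
                         np.empty(0), np.empty(0, int), dataset.n)
    return RecordSet(np.vstack(xs), np.concatenate(labels),
                     np.concatenate(weights), np.concatenate(subject), dataset.n)


# --------------------------------------------------------------------------
# dual solvers
# --------------------------------------------------------------------------


def _dual_arrays(records: RecordSet, code: SimplexCode, gamma: float):
    K = code.K
    labels0 = records.labels - 1
    upper = np.where(
        np.arange(K)[None, :] == labels0[:, None],
        gamma * records.weights[:, None],
        (1.0 - gamma) * records.weights[:, None],
    )
    lin = np.where(
        np.arange(K)[None, :] == labels0[:, None], -(K - 1.0), -1.0
    )
    return labels0.astype(np.int64), upper, lin


def _check_args(records: RecordSet, lam: float, gamma: float):
    if lam <= 0:
        raise ValueError(f"lambda must be positive, got {lam}")
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if len(records) == 0:
        raise ValueError("records must be non-empty")


def solve_dual_linear(
    records: RecordSet,
    code: SimplexCode,
    lam: float,
    gamma: float = 0.5,
    tol: float = 1e-6,
    max_sweeps: int = 500,
) -> tuple[DualState, LinearDecisionModel]:
    """Solve the linear-kernel dual by cyclic coordinate descent.

    Covariates are augmented with a leading constant 1, so the intercept is
    part of the penalised coefficient vector.  Recovers
    ``beta_k = (1/(n lam)) sum_{i,j} alpha_ij s_ij W_{j,k} x_i`` where n is
    the number of underlying subjects.
    """
    _check_args(records, lam, gamma)
    n = records.n_subjects
    Xa = np.ascontiguousarray(
        np.column_stack([np.ones(len(records)), records.X])
    )
    labels0, upper, lin = _dual_arrays(records, code, gamma)
    inv_nlam = 1.0 / (n * lam)
    alpha, u, trace, sweeps, max_delta = _cd.cd_linear(
        Xa, code.W, labels0, upper, lin, inv_nlam, tol, max_sweeps
    )
    kkt = _cd.kkt_residual_linear(Xa, code.W, labels0, upper, lin,
                                  inv_nlam, alpha, u)
    converged = max_delta < tol
    if not converged:
        logger.debug(
            "linear dual stopped at %d sweeps with max coordinate change "
            "%.2e (tol %.0e); returning best iterate", max_sweeps, max_delta, tol,
        )
    state = DualState(alpha=alpha, upper=upper,
                      objective=float(trace[-1]) if trace.size else 0.0,
                      objective_trace=trace, n_sweeps=int(sweeps),
                      converged=bool(converged), kkt_residual=kkt)
    model = LinearDecisionModel(B=inv_nlam * u)
    return state, model


def solve_dual_kernel(
    records: RecordSet,
    code: SimplexCode,
    kernel: KernelSpec,
    lam: float,
    gamma: float = 0.5,
    tol: float = 1e-6,
    max_sweeps: int = 500,
    jitter: bool = True,
) -> tuple[DualState, KernelDecisionModel]:
    """Solve the kernel dual by cyclic coordinate descent.

    The dual couples the multipliers through the Gram matrix G and, via the
    unpenalised intercepts, through an additional all-ones quadratic block;
    coordinate descent runs on ``G + 11'`` directly.  Recovery:
    ``theta_k = U_k / (n lam)`` and ``theta_{k,0} = (1/(n lam)) sum_i U_{ik}``
    (the stationarity condition ``G theta_k = (1/(n lam)) G U_k`` is solved
    without inverting G).  A numerically singular G triggers a diagonal
    jitter of ``1e-8 * mean(diag G)`` with a warning when ``jitter`` is true,
    and :class:`SingularGramError` otherwise.
    """
    _check_args(records, lam, gamma)
    n = records.n_subjects
    G = kernel.gram(records.X)
    try:
        cho_factor(G + 0.0)
        singular = False
    except np.linalg.LinAlgError:
        singular = True
    if singular:
        if not jitter:
            raise SingularGramError(
                "Gram matrix over the record covariates is singular "
                "(duplicate rows?); enable jitter or deduplicate"
            )
        warnings.warn("singular Gram matrix; adding diagonal jitter",
                      RuntimeWarning)
        G = G + (1e-8 * float(np.mean(np.diag(G))) + 1e-12) * np.eye(G.shape[0])
        try:
            cho_factor(G + 0.0)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise SingularGramError("Gram matrix singular even after jitter") from exc
    Ktil = np.ascontiguousarray(G + 1.0)
    labels0, upper, lin = _dual_arrays(records, code, gamma)
    inv_nlam = 1.0 / (n * lam)
    alpha, U, trace, sweeps, max_delta = _cd.cd_kernel(
        Ktil, code.W, labels0, upper, lin, inv_nlam, tol, max_sweeps
    )
    kkt = _cd.kkt_residual_kernel(Ktil, code.W, labels0, upper, lin,
                                  inv_nlam, alpha, U)
    converged = max_delta < tol
    if not converged:
        logger.debug(
            "kernel dual stopped at %d sweeps with max coordinate change "
            "%.2e (tol %.0e); returning best iterate", max_sweeps, max_delta, tol,
        )
    state = DualState(alpha=alpha, upper=upper,
                      objective=float(trace[-1]) if trace.size else 0.0,
                      objective_trace=trace, n_sweeps=int(sweeps),
                      converged=bool(converged), kkt_residual=kkt)
    model = KernelDecisionModel(
        spec=kernel,
        train_X=records.X.copy(),
        Theta=inv_nlam * U,
        intercepts=inv_nlam * U.sum(axis=0),
    )
    return state, model


def predict(model: LinearDecisionModel | KernelDecisionModel,
            X_new: np.ndarray, code: SimplexCode) -> tuple[np.ndarray, np.ndarray]:
    """Decision values (m, K-1) and group labels (m,) for new covariates."""
    if model.K != code.K:
        raise ValueError("model and simplex code disagree on K")
    f = model.decision_values(X_new)
    return f, decide_groups(code, f)
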