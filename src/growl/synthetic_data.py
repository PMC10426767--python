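"""Simulation designs with a latent grouping of many treatment arms.

All scenarios share the outcome model

    R | A, X  ~  Normal( 1 + 2 X1 + X2 + 0.5 X3 + T0(X, A), 1 ),

with X1..X10 iid U[-1, 1] and a treatment-covariate interaction T0 that is
(exactly or nearly) constant within latent arm groups:

* S1 — 10 arms, 2 groups {1..5}, {6..10};
  T0 = 1.8 (0.2 - X1 - X2) * (-1 for group 1, +1 for group 2): linear
  decision boundary.
* S2 — as S1 but T0 = 3.5 (0.8 - X1^2 - X2^2) * (+-1): circular boundary.
* S3 — 15 arms, 3 groups of five;
  T0 = 5 [ (-0.2 + X1 + 2 X2) 1{group 1} + (0.3 + 2 X1 + X2) 1{group 2}
           + (-0.2 + 3 X1) 1{group 3} ].
* S4 — 10 arms, nearly homogeneous: the S1 interaction with arm-specific
  multipliers (-1 - a/theta) for arms a = 1..5 and (+1 + (a-5)/theta) for
  arms a = 6..10; theta = +inf recovers S1 exactly, smaller theta makes the
  within-group effects more diverse.

Propensities are covariate independent: uniform 1/M under the balanced
design, or the fixed unbalanced vectors (exact fractions) that starve some
arms of observations.  The module also exposes the true mean outcome as an
oracle for evaluation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Callable

import numpy as np

from .ramsvm import Partition, TrialDataset

__all__ = [
    "ScenarioSpec",
    "make_scenario",
    "oracle_mu",
    "propensity_vector",
    "generate",
    "oracle_group_rule",
    "oracle_optimal_value",
]

_F = Fraction
_UNBALANCED_S1 = (_F(1, 20), _F(1, 20), _F(1, 20), _F(3, 20), _F(1, 5),
                  _F(1, 20), _F(1, 20), _F(1, 10), _F(1, 10), _F(1, 5))
_UNBALANCED_S3 = (_F(1, 20), _F(1, 20), _F(1, 20), _F(11, 120), _F(11, 120),
                  _F(1, 20), _F(1, 20), _F(1, 20), _F(11, 120), _F(11, 120),
                  _F(1, 20), _F(1, 20), _F(7, 90), _F(7, 90), _F(7, 90))


@dataclass(frozen=True)
class ScenarioSpec:
    """One of the four fixed simulation designs."""

    id: str                      # S1 | S2 | S3 | S4
    M: int
    K0: int
    delta0: Partition
    design: str = "balanced"     # balanced | unbalanced
    theta: float = math.inf      # S4 only
    d: int = 10
    propensity_fn: Callable[[np.ndarray], np.ndarray] | None = None
    """Optional hook: maps an (n, d) covariate array to (n, M) propensities,
    overriding the fixed covariate-independent vector."""


def make_scenario(scenario_id: str, design: str = "balanced",
                  theta: float = math.inf) -> ScenarioSpec:
    """Build the spec for one of the four scenarios."""
    sid = scenario_id.upper()
    if design not in ("balanced", "unbalanced"):
        raise ValueError(f"design must be balanced|unbalanced, got {design!r}")
    if sid in ("S1", "S2", "S4"):
        delta0 = Partition([1] * 5 + [2] * 5, 2)
        if sid == "S4" and not theta > 0:
            raise ValueError("S4 needs theta > 0 (possibly inf)")
        return ScenarioSpec(sid, 10, 2, delta0, design,
                            theta if sid == "S4" else math.inf)
    if sid == "S3":
        delta0 = Partition([1] * 5 + [2] * 5 + [3] * 5, 3)
        return ScenarioSpec(sid, 15, 3, delta0, design)
    raise ValueError(f"unknown scenario {scenario_id!r}")


def _interaction(spec: ScenarioSpec, a: np.ndarray, X: np.ndarray) -> np.ndarray:
    """T0(X, A) for arrays a (n,) and X (n, d)."""
    x1, x2 = X[:, 0], X[:, 1]
    if spec.id == "S1":
        sign = np.where(a <= 5, -1.0, 1.0)
        return 1.8 * (0.2 - x1 - x2) * sign
    if spec.id == "S2":
        sign = np.where(a <= 5, -1.0, 1.0)
        return 3.5 * (0.8 - x1**2 - x2**2) * sign
    if spec.id == "S3":
        g1 = -0.2 + x1 + 2 * x2
        g2 = 0.3 + 2 * x1 + x2
        g3 = -0.2 + 3 * x1
        return 5.0 * np.select([a <= 5, a <= 10], [g1, g2], default=g3)
    if spec.id == "S4":
        # arm-specific multiplier; theta = inf gives +-1 (S1)
        pert = np.where(
            a <= 5,
            -1.0 - (0.0 if math.isinf(spec.theta) else a / spec.theta),
            1.0 + (0.0 if math.isinf(spec.theta) else (a - 5) / spec.theta),
        )
        return 1.8 * (0.2 - x1 - x2) * pert
    raise ValueError(f"unknown scenario {spec.id!r}")


def oracle_mu(spec: ScenarioSpec, a, x) -> np.ndarray | float:
    """True mean outcome E[R | A=a, X=x].

    Accepts scalars or arrays; broadcasting a scalar arm over an (n, d)
    covariate matrix returns a length-n vector.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    if X.shape[1] != spec.d:
        raise ValueError(f"covariates must have d={spec.d} columns")
    a_arr = np.broadcast_to(np.asarray(a, dtype=int), (X.shape[0],)).copy()
    if a_arr.min() < 1 or a_arr.max() > spec.M:
        raise ValueError(f"treatment labels must lie in 1..{spec.M}")
    mu = 1.0 + 2 * X[:, 0] + X[:, 1] + 0.5 * X[:, 2] + _interaction(spec, a_arr, X)
    if np.isscalar(a) and np.asarray(x).ndim == 1:
        return float(mu[0])
    return mu


def propensity_vector(spec: ScenarioSpec) -> np.ndarray:
    """The design's covariate-independent propensity vector (sums to 1 exactly)."""
    if spec.design == "balanced":
        fracs = (_F(1, spec.M),) * spec.M
    elif spec.id == "S3":
        fracs = _UNBALANCED_S3
    else:
        fracs = _UNBALANCED_S1
    assert sum(fracs) == 1
    return np.array([float(f) for f in fracs])


def generate(spec: ScenarioSpec, n: int, seed) -> TrialDataset:
    """Draw a trial dataset of size n from the scenario, reproducibly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    X = rng.uniform(-1.0, 1.0, size=(n, spec.d))
    if spec.propensity_fn is not None:
        prop = np.asarray(spec.propensity_fn(X), dtype=float)
    else:
        prop = np.broadcast_to(propensity_vector(spec), (n, spec.M)).copy()
    cum = np.cumsum(prop, axis=1)
    u = rng.uniform(size=n)
    A = 1 + (u[:, None] > cum).sum(axis=1)
    R = oracle_mu(spec, A, X) + rng.standard_normal(n)
    return TrialDataset(X=X, A=A, R=R, prop=prop)


def _group_values(spec: ScenarioSpec, X: np.ndarray,
                  partition: Partition | None = None,
                  prop: np.ndarray | None = None) -> np.ndarray:
    """(n, K) matrix of propensity-weighted within-group mean effects."""
    partition = partition or spec.delta0
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if prop is None:
        prop = np.broadcast_to(propensity_vector(spec), (X.shape[0], spec.M))
    out = np.zeros((X.shape[0], partition.K))
    for k in range(1, partition.K + 1):
        arms = partition.members(k)
        pk = prop[:, arms - 1]
        mus = np.stack([oracle_mu(spec, a, X) for a in arms], axis=1)
        out[:, k - 1] = (pk * mus).sum(axis=1) / pk.sum(axis=1)
    return out


def oracle_group_rule(spec: ScenarioSpec, x) -> np.ndarray | int:
    """Best delta0-group at x: argmax over groups of the within-group
    propensity-weighted mean effect (ties to the smaller label)."""
    X = np.atleast_2d(np.asarray(x, dtype=float))
    vals = _group_values(spec, X)
    rule = np.argmax(vals, axis=1) + 1
    if np.asarray(x).ndim == 1:
        return int(rule[0])
    return rule


def oracle_optimal_value(spec: ScenarioSpec, n_mc: int = 100_000,
                         seed=0) -> float:
    """Monte-Carlo estimate of E_X[ max_a E[R | A=a, X] ]."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    X = rng.uniform(-1.0, 1.0, size=(n_mc, spec.d))
    best = np.max(
        np.stack([oracle_mu(spec, a, X) for a in range(1, spec.M + 1)], axis=1),
        axis=1,
    )
    return float(best.mean())
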