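"""Search over treatment partitions for the empirical-risk minimiser.

For a candidate partition ``delta`` the inner problem (fit the RAMSVM
decision function ``f_delta``) is convex and solved exactly; plugging
``(delta, f_delta)`` back into the regularised empirical objective

    J(delta) = (1/n) sum_rec w * L_phi(label, f(x))
             - (K/n) sum_rec w  +  lambda * ||f||^2

(both sums over the transformed records; smaller is better) scores the
partition.  The outer problem over partitions is a non-convex integer
programme, attacked three ways:

* :func:`exhaustive_search` — enumerate all set partitions of M treatments
  into exactly K blocks (restricted-growth strings); exact oracle, feasible
  for small M.
* :func:`greedy_search` — cyclic single-treatment reassignment, accepting the
  best improving move per treatment; monotone, stops at a local optimum.
* :func:`genetic_search` — tournament selection + uniform crossover +
  per-gene mutation over label vectors, with empty-group repair.

:func:`init_partition` provides the warm start by k-means clustering the
arms' fitted outcome profiles.  Partitions are identified only up to group
relabelling; :func:`canonicalize` / :func:`partitions_equal` handle that.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .ramsvm import (
    KernelSpec,
    Partition,
    TrialDataset,
    fit_main_effect,
    group_propensity,
    ramsvm_loss_matrix,
    solve_dual_kernel,
    solve_dual_linear,
    transform_residuals,
)
from .simplex_coding import build_simplex

__all__ = [
    "PartitionFit",
    "objective_for_partition",
    "exhaustive_search",
    "greedy_search",
    "genetic_search",
    "init_partition",
    "canonicalize",
    "partitions_equal",
    "iter_set_partitions",
]


@dataclass
class PartitionFit:
    """A scored partition with its fitted decision model and search trace."""

    partition: Partition
    model: object
    objective: float
    trace: list = field(default_factory=list)


class _ZeroModel:
    """Decision model that is identically zero (all weights vanished)."""

    def __init__(self, K: int, d: int):
        self.K, self.d = K, d

    def decision_values(self, X_new: np.ndarray) -> np.ndarray:
        X_new = np.atleast_2d(X_new)
        return np.zeros((X_new.shape[0], self.K - 1))

    def penalty_norm2(self) -> float:
        return 0.0


def objective_for_partition(
    dataset: TrialDataset,
    partition: Partition,
    lam: float,
    gamma: float = 0.5,
    kernel_spec: KernelSpec | None = None,
    seed: int | None = None,
    s=None,
    mode: str = "expand",
    tol: float = 1e-6,
    max_sweeps: int = 500,
):
    """Fit f under a fixed partition and return (objective, model).

    ``s`` is the main-effect function; pass the one fitted once on the
    training data so that all candidate partitions are scored on the same
    residuals.  ``s=None`` fits it here.
    """
    if s is None:
        s = fit_main_effect(dataset)
    kernel_spec = kernel_spec or KernelSpec("linear")
    records = transform_residuals(dataset, partition, s, mode=mode, seed=seed)
    code = build_simplex(partition.K)
    n = dataset.n
    if len(records) == 0:
        model = _ZeroModel(partition.K, dataset.d)
    elif kernel_spec.kernel == "linear":
        _, model = solve_dual_linear(records, code, lam, gamma,
                                     tol=tol, max_sweeps=max_sweeps)
    else:
        _, model = solve_dual_kernel(records, code, kernel_spec, lam, gamma,
                                     tol=tol, max_sweeps=max_sweeps)
    # Score with the ORIGINAL objective — signed residual weights
    # r_i / p(group(A_i)|X_i) in both the loss and the centring term — not
    # with the switched records used for the convex fit.  The switched form
    # differs from the original by K(K-1) E[r_- / p(group(A)|X)], an additive
    # constant in f but NOT in the partition, so scoring candidate partitions
    # with it would systematically reward groupings that inflate residual
    # magnitudes (e.g. singleton groups under IPW noise).
    resid = dataset.R - s(dataset.X)
    gp = group_propensity(dataset, partition)
    delta_A = partition.group_of(dataset.A)
    p_own = gp[np.arange(n), delta_A - 1]
    w_signed = resid / p_own
    f_vals = model.decision_values(dataset.X)
    losses = ramsvm_loss_matrix(delta_A, f_vals, gamma, code)
    obj = (float(w_signed @ losses) - partition.K * float(w_signed.sum())) / n
    obj += lam * model.penalty_norm2()
    return obj, model


# --------------------------------------------------------------------------
# canonical forms
# --------------------------------------------------------------------------


def canonicalize(partition: Partition) -> Partition:
    """Relabel groups in order of first appearance (treatment 1's group
    becomes 1, the next new group 2, ...).  Idempotent."""
    mapping: dict[int, int] = {}
    new = []
    for lab in partition.labels:
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        new.append(mapping[lab])
    return Partition(new, partition.K)


def partitions_equal(a: Partition, b: Partition) -> bool:
    """Equality of partitions up to group relabelling."""
    if a.M != b.M or a.K != b.K:
        return False
    return canonicalize(a).labels == canonicalize(b).labels


def iter_set_partitions(M: int, K: int):
    """Yield canonical label vectors of all partitions of ``1..M`` into
    exactly ``K`` non-empty groups, via restricted-growth strings."""
    def rec(prefix, used):
        if len(prefix) == M:
            if used == K:
                yield tuple(prefix)
            return
        remaining = M - len(prefix)
        for lab in range(1, min(used + 1, K) + 1):
            new_used = max(used, lab)
            # prune: still need K - new_used new labels in remaining - 1 slots
            if K - new_used > remaining - 1:
                continue
            yield from rec(prefix + [lab], new_used)

    yield from rec([], 0)


# --------------------------------------------------------------------------
# search strategies
# --------------------------------------------------------------------------

_MAX_EXHAUSTIVE = 100_000


def _stirling2(M: int, K: int) -> int:
    table = {(0, 0): 1}
    for m in range(1, M + 1):
        for k in range(1, min(m, K) + 1):
            table[(m, k)] = k * table.get((m - 1, k), 0) + table.get((m - 1, k - 1), 0)
    return table.get((M, K), 0)


def exhaustive_search(
    dataset: TrialDataset, K: int, lam: float, gamma: float = 0.5,
    kernel_spec: KernelSpec | None = None, seed: int | None = None,
    **solver_kw,
) -> PartitionFit:
    """Score every partition of the M treatments into K groups; exact oracle.

    Ties go to the lexicographically smallest canonical label vector (the
    enumeration order), so the result is deterministic.
    """
    M = dataset.M
    if _stirling2(M, K) > _MAX_EXHAUSTIVE:
        raise ValueError(
            f"S({M},{K}) partitions exceed {_MAX_EXHAUSTIVE}; "
            "use greedy_search or genetic_search"
        )
    s = fit_main_effect(dataset)
    best = None
    trace = []
    for labels in iter_set_partitions(M, K):
        part = Partition(labels, K)
        obj, model = objective_for_partition(
            dataset, part, lam, gamma, kernel_spec, seed=seed, s=s, **solver_kw
        )
        trace.append((part, obj))
        if best is None or obj < best.objective - 1e-12:
            best = PartitionFit(part, model, obj)
    best.trace = trace
    return best


def greedy_search(
    dataset: TrialDataset, K: int, init: Partition, lam: float,
    gamma: float = 0.5, kernel_spec: KernelSpec | None = None,
    max_cycles: int = 10, seed: int | None = None, **solver_kw,
) -> PartitionFit:
    """Cyclic single-treatment coordinate exchange.

    For each treatment in turn, try all K-1 alternative group assignments
    (skipping moves that would empty a group), keep the best improvement;
    stop when a full cycle changes nothing.  The objective never increases
    across accepted moves.
    """
    if init.K != K or init.M != dataset.M:
        raise ValueError("init partition inconsistent with dataset/K")
    s = fit_main_effect(dataset)
    current = list(init.labels)
    obj, model = objective_for_partition(
        dataset, Partition(current, K), lam, gamma, kernel_spec,
        seed=seed, s=s, **solver_kw,
    )
    trace = [(Partition(current, K), obj)]
    for _ in range(max_cycles):
        changed = False
        for t in range(dataset.M):
            own = current[t]
            if sum(1 for v in current if v == own) == 1:
                continue  # moving t would empty its group
            best_lab, best_obj, best_model = own, obj, model
            for lab in range(1, K + 1):
                if lab == own:
                    continue
                cand = list(current)
                cand[t] = lab
                cobj, cmodel = objective_for_partition(
                    dataset, Partition(cand, K), lam, gamma, kernel_spec,
                    seed=seed, s=s, **solver_kw,
                )
                trace.append((Partition(cand, K), cobj))
                if cobj < best_obj - 1e-10:
                    best_lab, best_obj, best_model = lab, cobj, cmodel
            if best_lab != own:
                current[t] = best_lab
                obj, model = best_obj, best_model
                changed = True
        if not changed:
            break
    return PartitionFit(Partition(current, K), model, obj, trace)


def genetic_search(
    dataset: TrialDataset, K: int, lam: float, gamma: float = 0.5,
    kernel_spec: KernelSpec | None = None, population: int = 50,
    generations: int = 100, p_mutate: float = 0.1, p_crossover: float = 0.8,
    seed: int | None = None, tournament: int = 3, init: Partition | None = None,
    **solver_kw,
) -> PartitionFit:
    """Genetic algorithm over label vectors (alphabet 1..K).

    Tournament selection, uniform crossover, per-gene mutation; offspring
    with empty groups are repaired by reassigning a random treatment from
    the largest group.  Deterministic given ``seed``.  Returns the best
    individual ever evaluated.
    """
    if population < 4:
        raise ValueError("population must be >= 4")
    rng = np.random.default_rng(seed)
    M = dataset.M
    s = fit_main_effect(dataset)
    cache: dict[tuple, tuple] = {}

    def score(labels: tuple):
        key = canonicalize(Partition(labels, K)).labels
        if key not in cache:
            cache[key] = objective_for_partition(
                dataset, Partition(key, K), lam, gamma, kernel_spec,
                seed=seed, s=s, **solver_kw,
            )
        return cache[key]

    def repair(vec: np.ndarray) -> np.ndarray:
        present, counts = np.unique(vec, return_counts=True)
        missing = [k for k in range(1, K + 1) if k not in present]
        for k in missing:
            largest = present[np.argmax(counts)]
            idx = rng.choice(np.nonzero(vec == largest)[0])
            vec[idx] = k
            present, counts = np.unique(vec, return_counts=True)
        return vec

    def random_individual() -> np.ndarray:
        return repair(rng.integers(1, K + 1, size=M))

    pop = []
    if init is not None:
        pop.append(np.array(init.labels))
    while len(pop) < population:
        pop.append(random_individual())
    fitness = np.array([score(tuple(v))[0] for v in pop])
    best_i = int(np.argmin(fitness))
    best_labels, best_obj = tuple(pop[best_i]), float(fitness[best_i])
    trace = [(Partition(best_labels, K), best_obj)]

    for _ in range(generations):
        new_pop = [np.array(best_labels)]  # elitism
        while len(new_pop) < population:
            contenders = rng.integers(0, population, size=tournament)
            p1 = pop[contenders[np.argmin(fitness[contenders])]]
            contenders = rng.integers(0, population, size=tournament)
            p2 = pop[contenders[np.argmin(fitness[contenders])]]
            if rng.random() < p_crossover:
                mask = rng.random(M) < 0.5
                child = np.where(mask, p1, p2)
            else:
                child = p1.copy()
            mut = rng.random(M) < p_mutate
            child[mut] = rng.integers(1, K + 1, size=int(mut.sum()))
            new_pop.append(repair(child))
        pop = new_pop
        fitness = np.array([score(tuple(v))[0] for v in pop])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_obj - 1e-12:
            best_labels, best_obj = tuple(pop[gen_best]), float(fitness[gen_best])
            trace.append((Partition(best_labels, K), best_obj))

    obj, model = score(best_labels)
    return PartitionFit(Partition(best_labels, K), model, obj, trace)


def init_partition(dataset: TrialDataset, K: int, seed: int | None = None) -> Partition:
    """Warm-start partition: cluster the arms' fitted outcome profiles.

    A linear outcome model is fitted within each arm (ridge shrinkage toward
    the pooled fit, with strength d/n_a, so sparsely observed arms borrow
    from the global model), each arm's fitted values are evaluated on the
    full covariate sample, and the M profiles are k-means clustered into K
    groups.
    """
    M = dataset.M
    counts = np.bincount(dataset.A, minlength=M + 1)[1:]
    if np.any(counts == 0):
        missing = np.nonzero(counts == 0)[0] + 1
        raise ValueError(f"treatments never observed: {missing.tolist()}")
    n, d = dataset.X.shape
    Xa = np.column_stack([np.ones(n), dataset.X])
    beta_g = np.linalg.solve(Xa.T @ Xa + 1e-8 * np.eye(d + 1), Xa.T @ dataset.R)
    profiles = np.empty((M, n))
    for a in range(1, M + 1):
        sel = dataset.A == a
        Xa_a, R_a = Xa[sel], dataset.R[sel]
        lam_r = d / max(1, int(counts[a - 1]))
        lhs = Xa_a.T @ Xa_a + lam_r * np.eye(d + 1)
        rhs = Xa_a.T @ R_a + lam_r * beta_g
        beta_a = np.linalg.solve(lhs, rhs)
        profiles[a - 1] = Xa @ beta_a
    km = KMeans(n_clusters=K, n_init=10, random_state=seed)
    labels = km.fit_predict(profiles) + 1
    # degenerate profiles (e.g. constant outcomes) can leave clusters empty;
    # fill them from the largest cluster so the partition stays surjective
    for k in range(1, K + 1):
        if not np.any(labels == k):
            counts = np.bincount(labels, minlength=K + 1)
            largest = int(np.argmax(counts[1:])) + 1
            labels[np.nonzero(labels == largest)[0][0]] = k
    return canonicalize(Partition(labels, K))
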