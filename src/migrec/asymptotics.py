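"""Limiting and quasi-limiting behaviour.

Forward in time, under a primitive backward migration matrix and a
recombination distribution whose support separates every pair of sites,
the metapopulation converges geometrically to spatial stationarity and
linkage equilibrium: every deme carries the product of the site marginals
mixed by the stationary migration law ``q``.

Backward in time, the unlabelled partitioning process is absorbed in the
all-singleton partition; conditioned on non-absorption it settles on the
set ``F`` of reachable states with maximal sojourn probability ``eta``
(the largest diagonal entry of the unlabelled transition matrix among
reachable, non-absorbed states).  The quasi-limiting law is computed
exactly from hitting-time generating functionals, and the labelled version
garnishes it with independent stationary labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import product as iproduct

import numpy as np

from .errors import DomainError, ValidationError
from .linear import UnlabelledT, build_T_unlabelled
from .model import (
    MetaPopulation,
    MigrationModel,
    Model,
    PopulationMeasure,
    RecombinationDistribution,
    tensor,
)
from .partitions import (
    LabelledPartition,
    Partition,
    bottom,
    meet,
    top,
)


# ---------------------------------------------------------------------------
# migration: primitivity and stationarity
# ---------------------------------------------------------------------------

def is_primitive(M) -> tuple[bool, int | None]:
    """Primitivity check with witness exponent.

    True iff some power ``M^k`` is entrywise positive for
    ``k <= (|L| - 1)^2 + 1`` (the Wielandt bound); returns the smallest
    such ``k``, or ``(False, None)``.
    """
    A = np.asarray(M.backward if isinstance(M, MigrationModel) else M, dtype=float)
    L = A.shape[0]
    if L == 1:
        return True, 1
    B = A > 0
    P = B.copy()
    bound = (L - 1) ** 2 + 1
    for k in range(1, bound + 1):
        if P.all():
            return True, k
        P = (P.astype(int) @ B.astype(int)) > 0
    return False, None


@dataclass(frozen=True)
class StationaryDistribution:
    """The unique left fixed probability vector of a primitive M."""

    demes: tuple[str, ...]
    q: np.ndarray

    def __call__(self, alpha: str) -> float:
        return float(self.q[self.demes.index(str(alpha))])


def stationary_distribution(migration: MigrationModel) -> StationaryDistribution:
    """Solve ``q^T M = q^T`` with ``sum(q) = 1``; requires primitivity."""
    ok, _ = is_primitive(migration)
    if not ok:
        raise ValidationError(
            "backward migration matrix is not primitive (irreducible and "
            "aperiodic); no unique attracting stationary distribution"
        )
    M = migration.backward
    L = M.shape[0]
    A = (M.T - np.eye(L)).copy()
    A[-1, :] = 1.0
    b = np.zeros(L)
    b[-1] = 1.0
    q = np.linalg.solve(A, b)
    return StationaryDistribution(migration.demes, q)


# ---------------------------------------------------------------------------
# separability and the forward limit
# ---------------------------------------------------------------------------

def check_separability(r: RecombinationDistribution) -> tuple[bool, list[tuple[int, ...]]]:
    """True iff the meet over the support of ``r`` is the all-singleton
    partition; otherwise the blocks of that meet are the site clusters
    that recombination never separates."""
    support = r.support()
    if not support:
        raise ValidationError("empty recombination support")
    m = support[0]
    for p in support[1:]:
        m = meet(m, p)
    return m == bottom(r.ground), list(m.blocks)


def limiting_metapopulation(mu0: MetaPopulation, model: Model) -> MetaPopulation:
    """The forward limit: every deme receives the product over sites of the
    ``q``-mixed one-site marginals of ``mu0``.

    Requires a primitive migration matrix and a separating recombination
    distribution; convergence of the iteration to this limit is geometric.
    """
    ok, _ = is_primitive(model.migration)
    if not ok:
        raise ValidationError(
            "limit formula assumes a primitive backward migration matrix"
        )
    sep, clusters = check_separability(model.recombination)
    if not sep:
        raise ValidationError(
            "limit formula assumes recombination eventually separates all "
            f"sites; never-separated clusters: {clusters} "
            "(collapse them into super-sites first)"
        )
    q = stationary_distribution(model.migration).q
    factors = []
    for i in model.ground:
        tabs = [m.marginal([i]).table.astype(float) for m in mu0.measures]
        mixed = sum(q[j] * tabs[j] for j in range(len(tabs)))
        factors.append(PopulationMeasure(mu0.space, (i,), mixed, validate=False))
    limit = tensor(factors)
    return MetaPopulation(mu0.demes, [limit] * len(mu0.demes))


# ---------------------------------------------------------------------------
# reachability, sojourn maxima
# ---------------------------------------------------------------------------

def reachable_states(
    r: RecombinationDistribution,
    start: Partition | None = None,
    tul: UnlabelledT | None = None,
) -> set[Partition]:
    """All partitions reachable from *start* (default the one-block
    partition) along positive entries of the unlabelled transition matrix,
    including *start* itself."""
    if tul is None:
        tul = build_T_unlabelled(r)
    if start is None:
        start = top(r.ground)
    idx = tul.index
    if start not in idx:
        raise DomainError(f"{start} is not a partition of {r.ground}")
    n = len(tul.states)
    seen = {idx[start]}
    frontier = [idx[start]]
    while frontier:
        i = frontier.pop()
        for j in range(n):
            if j not in seen and tul.matrix[i, j] > 0:
                seen.add(j)
                frontier.append(j)
    return {tul.states[i] for i in seen}


def sojourn_eta_F(
    r: RecombinationDistribution,
    start: Partition | None = None,
    tul: UnlabelledT | None = None,
):
    """Maximal sojourn probability ``eta`` over reachable non-absorbed
    states, its argmax set ``F``, and the runner-up ``eta'`` (None when
    every reachable non-absorbed state attains ``eta``).

    From any member of ``F`` the chain can only stay put or absorb, so the
    structural identity ``T[d, d] + T[d, bottom] = 1`` is verified for
    every member and a violation raises.
    """
    if tul is None:
        tul = build_T_unlabelled(r)
    zero_part = bottom(r.ground)
    if r[zero_part] == 1:
        raise ValidationError(
            "r puts all mass on the all-singleton partition; the chain "
            "absorbs immediately and sojourn maxima are undefined"
        )
    reach = reachable_states(r, start, tul)
    live = [d for d in reach if d != zero_part]
    if not live:
        raise DomainError("no non-absorbed state is reachable from start")
    idx = tul.index
    diag = {d: tul.matrix[idx[d], idx[d]] for d in live}
    eta = max(diag.values())
    Fset = {d for d, v in diag.items() if v == eta}
    rest = [v for d, v in diag.items() if d not in Fset]
    eta_prime = max(rest) if rest else None
    j0 = idx[zero_part]
    for d in Fset:
        if diag[d] + tul.matrix[idx[d], j0] != (
            Fraction(1) if isinstance(diag[d], Fraction) else 1
        ):
            resid = float(diag[d] + tul.matrix[idx[d], j0]) - 1.0
            if abs(resid) > 1e-12:
                raise AssertionError(
                    f"maximal-sojourn state {d} admits a transition that is "
                    "neither staying nor absorbing; bookkeeping bug"
                )
    return eta, Fset, eta_prime


# ---------------------------------------------------------------------------
# quasi-limiting laws
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuasiLimitingLaw:
    """Quasi-limiting distribution of the (labelled) partitioning process,
    supported on the maximal-sojourn set ``F``."""

    eta: object
    Fset: frozenset[Partition]
    eta_prime: object
    unlabelled_law: dict[Partition, object]
    labelled_law: dict[LabelledPartition, object] | None = None


def _hitting_functional(
    tul: UnlabelledT, eta, target: Partition, live_states: list[Partition]
):
    """h(eps) = E_eps[eta^(-tau_target); tau_target < infinity].

    The chain only refines, so processing states from finest to coarsest
    makes each equation explicit: the one-step decomposition gives
    ``h(eps) (1 - T[eps,eps]/eta) = (1/eta) sum over strictly finer eps'
    of T[eps, eps'] h(eps')`` with ``h(target) = 1``.
    """
    idx = tul.index
    h: dict[Partition, object] = {target: 1 if isinstance(eta, Fraction) else 1.0}
    order = sorted(live_states, key=lambda p: -len(p.blocks))
    for eps in order:
        if eps == target:
            continue
        i = idx[eps]
        num = 0
        for eps2, h2 in h.items():
            if eps2 == eps or h2 == 0:
                continue
            tij = tul.matrix[i, idx[eps2]]
            if tij != 0:
                num = num + tij * h2
        if num == 0:
            h[eps] = 0
            continue
        stay = tul.matrix[i, i]
        if stay >= eta:
            raise ValidationError(
                f"state {eps} can reach {target} but has sojourn >= eta; "
                "F-membership bookkeeping is inconsistent"
            )
        h[eps] = (num / eta) / (1 - stay / eta)
    return h


def qlim_unlabelled(
    r: RecombinationDistribution,
    start: Partition | None = None,
    tul: UnlabelledT | None = None,
) -> QuasiLimitingLaw:
    """Quasi-limiting law of the unlabelled partitioning process started
    at *start* (default the one-block partition).

    The mass of each maximal-sojourn state ``d`` is proportional to the
    hitting functional ``E[eta^(-tau_d); tau_d < infinity]`` evaluated at
    the start state; distinct members of ``F`` are never both hit, so the
    normaliser is the plain sum.  Exact when ``r`` has Fraction weights.
    """
    if tul is None:
        tul = build_T_unlabelled(r)
    if start is None:
        start = top(r.ground)
    eta, Fset, eta_prime = sojourn_eta_F(r, start, tul)
    zero_part = bottom(r.ground)
    live = [d for d in reachable_states(r, start, tul) if d != zero_part]
    weights = {}
    for d in Fset:
        h = _hitting_functional(tul, eta, d, live)
        weights[d] = h.get(start, 0)
    total = sum(weights.values())
    if total == 0:
        raise ValidationError("start state cannot reach the maximal-sojourn set")
    law = {d: w / total for d, w in weights.items()}
    return QuasiLimitingLaw(eta, frozenset(Fset), eta_prime, law)


def conditional_law_exact(
    r: RecombinationDistribution,
    start: Partition | None = None,
    t: int = 0,
    tul: UnlabelledT | None = None,
) -> dict[Partition, float]:
    """Exact law of the unlabelled chain at time *t* conditioned on
    non-absorption, by powering the substochastic restriction of the
    transition matrix to non-absorbed states."""
    if tul is None:
        tul = build_T_unlabelled(r)
    if start is None:
        start = top(r.ground)
    zero_part = bottom(r.ground)
    live = [p for p in tul.states if p != zero_part]
    lidx = {p: i for i, p in enumerate(live)}
    if start == zero_part:
        raise DomainError("start state is already absorbed")
    Q = np.array(
        [[float(tul.matrix[tul.index[a], tul.index[b]]) for b in live] for a in live]
    )
    v = np.zeros(len(live))
    v[lidx[start]] = 1.0
    for _ in range(t):
        v = v @ Q
    mass = v.sum()
    if mass <= 0:
        raise ValidationError(f"survival probability at t={t} is zero")
    v = v / mass
    return {p: float(v[lidx[p]]) for p in live if v[lidx[p]] != 0}


def qlim_labelled(
    model: Model,
    start_deme: str | None = None,
    start: Partition | None = None,
) -> QuasiLimitingLaw:
    """Quasi-limiting law of the labelled partitioning process: the
    unlabelled law times independent stationary labels,
    ``law(bdelta) = unlabelled_law(base) * prod over blocks of q(label)``.

    The starting deme label does not affect the limit (label chains forget
    their start geometrically); it is accepted for interface symmetry.
    """
    r = model.recombination
    ul = qlim_unlabelled(r, start)
    q = stationary_distribution(model.migration)
    lab: dict[LabelledPartition, object] = {}
    for delta, w in ul.unlabelled_law.items():
        for labs in iproduct(model.demes, repeat=len(delta)):
            p = float(w)
            for g in labs:
                p *= q(g)
            lab[LabelledPartition(list(zip(delta.blocks, labs)))] = p
    return QuasiLimitingLaw(ul.eta, ul.Fset, ul.eta_prime, ul.unlabelled_law, lab)


# ---------------------------------------------------------------------------
# cluster collapse for non-separating recombination
# ---------------------------------------------------------------------------

def collapse_clusters(model: Model, mu0: MetaPopulation | None = None):
    """Collapse never-separated site clusters into super-sites.

    Returns ``(reduced_model, reduced_mu0, clusters)`` where each cluster
    (block of the meet over the recombination support) becomes one site
    whose alphabet is the product of the member alphabets.  The reduced
    model satisfies separability by construction.
    """
    sep, clusters = check_separability(model.recombination)
    if sep:
        return model, mu0, [tuple(b) for b in bottom(model.ground).blocks]
    from .model import Model as _Model, RecombinationDistribution as _RD, TypeSpace

    clusters = [tuple(c) for c in clusters]
    new_alphabets = []
    for c in clusters:
        letters = [
            "".join(t)
            for t in iproduct(*(model.space.alphabets[s - 1] for s in c))
        ]
        new_alphabets.append(letters)
    new_space = TypeSpace(new_alphabets)
    site_of = {s: k + 1 for k, c in enumerate(clusters) for s in c}
    new_weights: dict[Partition, object] = {}
    for p, w in model.recombination.weights.items():
        blocks = [sorted({site_of[s] for s in b}) for b in p.blocks]
        q = Partition(blocks)
        new_weights[q] = new_weights.get(q, 0) + w
    new_r = _RD(new_space.sites, new_weights)
    new_model = _Model(new_space, new_r, model.migration)
    new_mu = None
    if mu0 is not None:
        order = [s for c in clusters for s in c]
        perm = [mu0.sites.index(s) for s in order]
        meas = []
        for m in mu0.measures:
            tab = np.transpose(m.table, axes=perm)
            tab = tab.reshape(new_space.shape())
            meas.append(PopulationMeasure(new_space, new_space.sites, tab, validate=False))
        new_mu = MetaPopulation(mu0.demes, meas)
    return new_model, new_mu, clusters
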