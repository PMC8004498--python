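"""Haldane linearisation of the migration-recombination equation.

The nonlinear generation map becomes linear when lifted to the vector
``R(mu) = (R_bdelta(mu))`` of labelled-recombinator values indexed by the
labelled partitions of the site set: ``R(mu_{t+1}) = T R(mu_t)`` for a
stochastic matrix ``T``, so ``R(mu_t) = T^t R(mu_0)`` and the solution of
the nonlinear system is read off the single-block components.

``T`` moves only towards refinements: ``T[bdelta, beps] > 0`` requires the
base of ``beps`` to refine the base of ``bdelta``.  Its entries are built
in two independent ways - the product over blocks of marginal
migration-recombination probabilities, and the factorisation into the
unlabelled matrix times a product of migration entries - which the test
suite plays against each other.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .errors import DomainError
from .model import (
    MetaPopulation,
    Model,
    PopulationMeasure,
    RecombinationDistribution,
    marginal_mr_probabilities,
    recombinator,
)
from .partitions import (
    LabelledPartition,
    Partition,
    enumerate_labelled_partitions,
    enumerate_partitions,
    is_finer,
    labelled_top,
    restrict,
)


@dataclass(frozen=True)
class UnlabelledT:
    """Transition matrix of the unlabelled partitioning process.

    ``matrix[i, j] = prod over blocks d of delta_i of r^d at the induced
    partition`` when state j refines state i, else 0.  Exact (Fraction)
    when the recombination weights are exact.
    """

    states: tuple[Partition, ...]
    matrix: np.ndarray

    @property
    def index(self) -> dict[Partition, int]:
        return {p: i for i, p in enumerate(self.states)}

    def sojourn(self, delta: Partition):
        """Diagonal entry: probability of staying in *delta* one step."""
        return self.matrix[self.index[delta], self.index[delta]]


@dataclass(frozen=True)
class TransitionMatrixT:
    """Transition matrix of the labelled partitioning process."""

    states: tuple[LabelledPartition, ...]
    matrix: np.ndarray

    @property
    def index(self) -> dict[LabelledPartition, int]:
        return {p: i for i, p in enumerate(self.states)}


def build_T_unlabelled(r: RecombinationDistribution) -> UnlabelledT:
    """Unlabelled transition matrix from the recombination distribution."""
    states = tuple(enumerate_partitions(r.ground))
    exact = r.exact
    zero = Fraction(0) if exact else 0.0
    n = len(states)
    mat = np.full((n, n), zero, dtype=object if exact else float)
    # marginal distributions per distinct block
    marg: dict[tuple[int, ...], dict[Partition, object]] = {}
    for delta in states:
        for d in delta.blocks:
            if len(d) > 1 and d not in marg:
                marg[d] = r.marginal(d)
    for i, delta in enumerate(states):
        for j, eps in enumerate(states):
            if not is_finer(eps, delta):
                continue
            val = 1 if exact else 1.0
            for d in delta.blocks:
                if len(d) == 1:
                    continue  # singleton marginal is the unit mass exactly
                val = val * marg[d].get(restrict(eps, d), zero)
                if val == 0:
                    break
            mat[i, j] = Fraction(val) if exact else float(val)
    return UnlabelledT(states, mat)


def build_T(model: Model) -> TransitionMatrixT:
    """Labelled transition matrix: for refining bases,
    ``T[bdelta, beps] = prod over labelled blocks (d, l) of bdelta of
    p^d at (beps induced on d) given label l``."""
    r = model.recombination
    states = tuple(enumerate_labelled_partitions(r.ground, model.demes))
    n = len(states)
    mat = np.zeros((n, n), dtype=float)
    # p^d(lambda) per distinct block and deme
    pmarg: dict[tuple[tuple[int, ...], str], dict[LabelledPartition, object]] = {}
    blocks_seen: set[tuple[int, ...]] = set()
    for bdelta in states:
        for d, _ in bdelta:
            blocks_seen.add(d)
    for d in blocks_seen:
        for lam in model.demes:
            pmarg[(d, lam)] = marginal_mr_probabilities(model, d, lam).probs
    restr: dict[tuple[int, tuple[int, ...]], LabelledPartition] = {}

    def _restr(j: int, beps: LabelledPartition, d: tuple[int, ...]) -> LabelledPartition:
        key = (j, d)
        out = restr.get(key)
        if out is None:
            out = restrict(beps, d)
            restr[key] = out
        return out

    bases = [b.base for b in states]
    for i, bdelta in enumerate(states):
        base_i = bases[i]
        for j, beps in enumerate(states):
            if not is_finer(bases[j], base_i):
                continue
            val = 1.0
            for d, lam in bdelta:
                val *= float(pmarg[(d, lam)].get(_restr(j, beps, d), 0))
                if val == 0.0:
                    break
            mat[i, j] = val
    return TransitionMatrixT(states, mat)


def build_T_factorised(model: Model) -> TransitionMatrixT:
    """The same matrix via the label-marginalisation factorisation:
    ``T[bdelta, beps] = T_ul[delta, eps] * prod over blocks (d, l) of
    bdelta, prod over blocks (e, g) of beps induced on d, of M(l, g)``.

    Serves as an independent oracle for :func:`build_T`.
    """
    tul = build_T_unlabelled(model.recombination)
    uidx = tul.index
    M = model.migration.backward
    didx = {d: i for i, d in enumerate(model.demes)}
    states = tuple(enumerate_labelled_partitions(model.recombination.ground, model.demes))
    n = len(states)
    mat = np.zeros((n, n), dtype=float)
    for i, bdelta in enumerate(states):
        base_i = bdelta.base
        for j, beps in enumerate(states):
            if not is_finer(beps.base, base_i):
                continue
            val = float(tul.matrix[uidx[base_i], uidx[beps.base]])
            if val == 0.0:
                continue
            for d, lam in bdelta:
                for _, gam in restrict(beps, d):
                    val *= M[didx[lam], didx[gam]]
            mat[i, j] = val
    return TransitionMatrixT(states, mat)


@dataclass(frozen=True)
class RecombinatorVector:
    """The measure-valued column vector ``R(mu)``: one probability table
    per labelled partition, stored as a (states x type-space) matrix."""

    states: tuple[LabelledPartition, ...]
    values: np.ndarray  # shape (|states|, |A|), rows in state order
    mu_template: MetaPopulation

    def component(self, bdelta: LabelledPartition) -> PopulationMeasure:
        i = self.states.index(bdelta)
        mu = self.mu_template
        return PopulationMeasure(mu.space, mu.sites, self.values[i], validate=False)


def recombinator_vector(mu: MetaPopulation, model: Model) -> RecombinatorVector:
    """Evaluate every labelled recombinator of the full site set at ``mu``."""
    states = tuple(enumerate_labelled_partitions(model.ground, model.demes))
    if set(mu.sites) != set(model.ground):
        raise DomainError("metapopulation must live on the full site set")
    vals = np.stack([recombinator(b, mu).flat().astype(float) for b in states])
    return RecombinatorVector(states, vals, mu)


def solve_by_matrix_powers(
    mu0: MetaPopulation, model: Model, t: int, T: TransitionMatrixT | None = None
) -> MetaPopulation:
    """Solve the migration-recombination equation at generation ``t`` as
    ``R(mu_t) = T^t R(mu_0)``, reading off the single-block components.

    ``T`` acts block-wise on the measure-valued vector, i.e. as an ordinary
    matrix product with the (states x type-space) value matrix.  Powers are
    applied by iterated multiplication.
    """
    if t < 0:
        raise DomainError("t must be nonnegative")
    if T is None:
        T = build_T(model)
    R = recombinator_vector(mu0, model)
    vals = R.values
    for _ in range(t):
        vals = T.matrix @ vals
    out = []
    for alpha in mu0.demes:
        i = T.index[labelled_top(model.ground, alpha)]
        out.append(PopulationMeasure(mu0.space, mu0.sites, vals[i], validate=False))
    return MetaPopulation(mu0.demes, out)
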