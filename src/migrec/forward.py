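"""The nonlinear forward dynamics of the migration-recombination equation.

One generation consists of migration followed by recombination: the
population at deme ``alpha`` is first replaced by the ``M(alpha, .)``-
mixture of the deme populations, then by the ``r``-mixture of block-wise
product measures of its own marginals.  The composite map is also exposed
in its one-shot form as a mixture of labelled recombinators weighted by the
migration-recombination probabilities; the two agree exactly and tests
assert this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .errors import DomainError
from .model import (
    MetaPopulation,
    Model,
    PopulationMeasure,
    marginal_mr_probabilities,
    recombinator,
    tensor,
)
from .partitions import _canon_sites


@dataclass(frozen=True)
class Trajectory:
    """A recorded forward orbit: states at integer times 0..T, and
    optionally the post-migration states at half-integer times."""

    times: tuple[float, ...]
    states: tuple[MetaPopulation, ...]

    def __getitem__(self, t) -> MetaPopulation:
        try:
            return self.states[self.times.index(t)]
        except ValueError:
            raise DomainError(f"time {t} not recorded (times: {self.times})") from None

    @property
    def final(self) -> MetaPopulation:
        return self.states[-1]


def migration_step(mu: MetaPopulation, model: Model) -> MetaPopulation:
    """Post-migration metapopulation: ``mu'(a) = sum_b M(a,b) mu(b)``."""
    M = model.migration.backward
    if mu.demes != model.demes:
        raise DomainError("metapopulation demes do not match the model")
    tables = [m.table for m in mu.measures]
    out = []
    for i in range(len(mu.demes)):
        tab = sum(M[i, j] * tables[j] for j in range(len(tables)))
        out.append(PopulationMeasure(mu.space, mu.sites, tab, validate=False))
    return MetaPopulation(mu.demes, out)


def recombination_step(mu: MetaPopulation, model: Model) -> MetaPopulation:
    """Replace each deme by the ``r``-mixture of its block-product measures."""
    weights = (
        model.recombination.marginal(mu.sites)
        if mu.sites != model.ground
        else dict(model.recombination.weights)
    )
    out = []
    for m in mu.measures:
        tab = None
        for delta, r in weights.items():
            prod = tensor([m.marginal(b) for b in delta.blocks]).table
            tab = r * prod if tab is None else tab + r * prod
        # block products square any float mass drift, so a one-ulp deficit
        # would grow like (#blocks)^t over an orbit; renormalise each step
        if tab.dtype != object:
            tab = tab / tab.sum()
        out.append(PopulationMeasure(mu.space, mu.sites, tab, validate=False))
    return MetaPopulation(mu.demes, out)


def mre_step(mu: MetaPopulation, model: Model) -> MetaPopulation:
    """One generation of the migration-recombination equation."""
    return recombination_step(migration_step(mu, model), model)


def mre_step_labelled(mu: MetaPopulation, model: Model) -> MetaPopulation:
    """The same generation map written as a mixture of labelled
    recombinators: ``mu_{t+1}(a) = sum_bdelta p_bdelta(a) R_bdelta(mu_t)``.

    Mathematically identical to :func:`mre_step`; kept as an independent
    code path so the two formulas can validate each other.
    """
    out = []
    for alpha in mu.demes:
        p = marginal_mr_probabilities(model, mu.sites, alpha)
        tab = None
        for bdelta, w in p.probs.items():
            prod = recombinator(bdelta, mu).table
            tab = w * prod if tab is None else tab + w * prod
        if tab.dtype != object:
            tab = tab / tab.sum()
        out.append(PopulationMeasure(mu.space, mu.sites, tab, validate=False))
    return MetaPopulation(mu.demes, out)


def marginal_mre_step(muU: MetaPopulation, model: Model, U: Iterable[int]) -> MetaPopulation:
    """One generation of the marginal system on the site subset ``U``.

    The dynamics is consistent under marginalisation: marginalising a
    full-system step to ``U`` equals stepping the marginal system.
    """
    u = _canon_sites(U)
    if muU.sites != u:
        raise DomainError(f"metapopulation sites {muU.sites} do not match U={u}")
    return mre_step(muU, model)


def iterate(
    mu0: MetaPopulation,
    model: Model,
    T: int,
    record: bool = False,
    half_steps: bool = False,
) -> Trajectory:
    """Iterate the generation map ``T`` times.

    With ``record`` the whole orbit is kept (plus post-migration states at
    half-integer times when ``half_steps`` is set); otherwise only the
    initial and final states are stored.
    """
    if T < 0:
        raise DomainError("T must be nonnegative")
    times: list[float] = [0.0]
    states: list[MetaPopulation] = [mu0]
    mu = mu0
    for t in range(T):
        half = migration_step(mu, model)
        mu = recombination_step(half, model)
        if record:
            if half_steps:
                times.append(t + 0.5)
                states.append(half)
            times.append(float(t + 1))
            states.append(mu)
    if not record and T > 0:
        times.append(float(T))
        states.append(mu)
    return Trajectory(tuple(times), tuple(states))
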