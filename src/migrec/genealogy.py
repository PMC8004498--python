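"""The labelled partitioning process (LPP) and duality-based Monte Carlo.

Backward in time, the genome of one sampled individual fragments across an
increasing number of ancestors: each labelled block ``(d, l)`` of the
current state is independently split according to the marginal
recombination distribution ``r^d``, and every resulting fragment is then
relabelled independently by one step of the backward migration kernel
``M(l, .)`` (splitting before relabelling, matching the forward order of
migration-then-recombination read in reverse).  In the law-of-large-numbers
regime there is no coalescence, so the base partition only ever refines.

Duality links this chain to the forward flow:
``mu_t(alpha) = E[ R_{Sigma_t}(mu_0) | Sigma_0 = single block, label alpha ]``,
which the :func:`duality_estimate` Monte Carlo exploits.

Reproducibility: every public sampler takes an integer seed; replicate
streams are spawned with :class:`numpy.random.SeedSequence`, one child per
trajectory, and within a step the block decisions consume the stream in
canonical block order.  Results are bit-reproducible for a fixed
(seed, model, start, T).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from itertools import accumulate

import numpy as np

from .errors import DomainError
from .model import MetaPopulation, Model, PopulationMeasure, recombinator
from .partitions import (
    LabelledPartition,
    Partition,
    is_finer,
    labelled_top,
)


class LPPSampler:
    """Sampling tables for a model: per-block marginal recombination
    distributions and cumulative migration rows, built lazily."""

    def __init__(self, model: Model):
        self.model = model
        self.demes = model.demes
        M = model.migration.backward
        self._mig_cum = [list(accumulate(M[i])) for i in range(len(self.demes))]
        self._didx = {d: i for i, d in enumerate(self.demes)}
        self._split: dict[tuple[int, ...], tuple[list[Partition], list[float]]] = {}

    def _split_table(self, d: tuple[int, ...]):
        tab = self._split.get(d)
        if tab is None:
            marg = self.model.recombination.marginal(d)
            parts = list(marg)
            cum = list(accumulate(float(marg[p]) for p in parts))
            cum[-1] = 1.0  # guard against rounding
            tab = (parts, cum)
            self._split[d] = tab
        return tab

    def step(self, state: LabelledPartition, rng: np.random.Generator) -> LabelledPartition:
        """One backward generation; block decisions in canonical order."""
        new_blocks: list[tuple[tuple[int, ...], str]] = []
        for d, lam in state:
            if len(d) == 1:
                eps_blocks = (d,)
            else:
                parts, cum = self._split_table(d)
                eps = parts[bisect_left(cum, rng.random())]
                eps_blocks = eps.blocks
            li = self._didx[lam]
            row = self._mig_cum[li]
            for e in eps_blocks:
                g = bisect_left(row, rng.random())
                if g >= len(self.demes):
                    g = len(self.demes) - 1
                new_blocks.append((e, self.demes[g]))
        return LabelledPartition(new_blocks)


def lpp_step(
    state: LabelledPartition, model: Model, rng: np.random.Generator,
    sampler: LPPSampler | None = None,
) -> LabelledPartition:
    """One step of the LPP: independently replace each labelled block
    ``(d, l)`` by a draw from the marginal migration-recombination
    distribution ``p^d(l)`` and take the union."""
    if sampler is None:
        sampler = LPPSampler(model)
    return sampler.step(state, rng)


@dataclass(frozen=True)
class LPPTrajectory:
    """A sampled LPP path; the base partition is monotone under refinement
    and generations at which it strictly refines are the jump times."""

    seed: int | None
    states: tuple[LabelledPartition, ...]
    jump_times: tuple[int, ...]

    @property
    def final(self) -> LabelledPartition:
        return self.states[-1]

    def absorption_time(self) -> int | None:
        """First generation with an all-singleton base, or None."""
        for t, s in enumerate(self.states):
            if all(len(b) == 1 for b, _ in s):
                return t
        return None


def sample_trajectory(
    start: LabelledPartition,
    model: Model,
    T: int,
    seed,
    sampler: LPPSampler | None = None,
) -> LPPTrajectory:
    """Sample ``T`` LPP generations from *start*, bit-reproducible in
    (seed, model, start, T).  *seed* may be an int or a SeedSequence."""
    if T < 0:
        raise DomainError("T must be nonnegative")
    if sampler is None:
        sampler = LPPSampler(model)
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    states = [start]
    jumps: list[int] = []
    for t in range(T):
        nxt = sampler.step(states[-1], rng)
        if nxt.base != states[-1].base:
            jumps.append(t + 1)
        states.append(nxt)
    traj = LPPTrajectory(
        seed if isinstance(seed, int) else None, tuple(states), tuple(jumps)
    )
    # progressive refinement is structural; guard against sampler bugs
    for a, b in zip(traj.states, traj.states[1:]):
        if not is_finer(b.base, a.base):
            raise AssertionError("LPP base coarsened; sampler is inconsistent")
    return traj


@dataclass(frozen=True)
class DualityEstimate:
    """Monte-Carlo estimate of one deme's type distribution at time t."""

    alpha: str
    estimate: PopulationMeasure
    stderr: np.ndarray  # per-cell standard error, same shape as the table
    replicates: int


def duality_estimate(
    mu0: MetaPopulation,
    model: Model,
    t: int,
    alpha: str,
    replicates: int,
    seed: int,
) -> DualityEstimate:
    """Estimate ``mu_t(alpha)`` as the empirical mean of
    ``R_{Sigma_t}(mu_0)`` over independent LPP trajectories started from
    the single-block state labelled ``alpha``.

    The recombinator value depends on the trajectory only through its final
    state, so values are cached per visited final state; the per-cell
    standard error is the sample standard deviation over replicates divided
    by ``sqrt(replicates)``.
    """
    if replicates < 1:
        raise DomainError("need at least one replicate")
    sampler = LPPSampler(model)
    start = labelled_top(model.ground, alpha)
    root = np.random.SeedSequence(seed)
    streams = root.spawn(replicates)
    counts: dict[LabelledPartition, int] = {}
    for ss in streams:
        rng = np.random.default_rng(ss)
        state = start
        for _ in range(t):
            state = sampler.step(state, rng)
        counts[state] = counts.get(state, 0) + 1
    values = {s: recombinator(s, mu0).flat().astype(float) for s in counts}
    R = float(replicates)
    mean = sum((c / R) * values[s] for s, c in counts.items())
    second = sum((c / R) * values[s] ** 2 for s, c in counts.items())
    var = np.maximum(second - mean**2, 0.0)
    if replicates > 1:
        var = var * (R / (R - 1.0))
    se = np.sqrt(var / R)
    est = PopulationMeasure(mu0.space, mu0.sites, mean, validate=False)
    shape = est.table.shape
    return DualityEstimate(str(alpha), est, se.reshape(shape), replicates)


def two_site_closed_form(
    mu0: MetaPopulation, model: Model, t: int, alpha: str
) -> PopulationMeasure:
    """Closed-form solution for two sites.

    Either the two sites were never separated (probability ``r_top^t``) and
    both descend from one ancestor whose deme followed a ``t``-step
    migration walk, or they split at backward generation ``sigma`` at some
    deme ``gamma``, after which the two site-marginals evolve independently:

    ``mu_t(a) = r1^t (M^t mu0)(a)
    + sum_gamma sum_{sigma=1..t} r1^(sigma-1) r0 M^(sigma-1)[a, gamma]
    (M^(t-sigma+1) mu0)^{1}(gamma) x (M^(t-sigma+1) mu0)^{2}(gamma)``.
    """
    if model.space.n != 2:
        raise DomainError("closed form requires exactly two sites")
    from .partitions import bottom, top

    r1 = float(model.recombination[top(model.ground)])
    r0 = float(model.recombination[bottom(model.ground)])
    M = model.migration.backward
    a = model.migration.index(alpha)
    L = len(model.demes)
    stack0 = mu0.stack()  # (L, |A|)
    shape = mu0.space.shape()
    # M^k mu0 for k = 0..t
    pow_mu = [stack0]
    pow_M = [np.eye(L)]
    for _ in range(t):
        pow_mu.append(M @ pow_mu[-1])
        pow_M.append(M @ pow_M[-1])
    out = (r1**t) * pow_mu[t][a].reshape(shape)
    for sigma in range(1, t + 1):
        w = (r1 ** (sigma - 1)) * r0
        mu_rem = pow_mu[t - sigma + 1]  # (L, |A|)
        for g in range(L):
            tab = mu_rem[g].reshape(shape)
            m1 = tab.sum(axis=1)  # marginal of site 1
            m2 = tab.sum(axis=0)  # marginal of site 2
            out = out + w * pow_M[sigma - 1][a, g] * np.outer(m1, m2)
    return PopulationMeasure(mu0.space, mu0.sites, out, validate=False)
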