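"""Continuous-time migration-recombination dynamics.

The forward state ``omega_t`` obeys the ODE
``d/dt omega_t(a) = sum_b N(a,b) omega_t(b)
+ sum_delta rho_delta (R_delta - Id) omega_t(a)``,
with a Markov generator ``N`` over demes and nonnegative recombination
rates ``rho`` over partitions.  The dual labelled partitioning process is
a continuous-time chain whose generator splits one labelled block at the
marginal rate ``rho^d`` (fragments keep the label) or relabels one block
at rate ``N``; the solution is read off the matrix exponential of that
generator applied to the recombinator vector, exactly as matrix powers
solve the discrete system.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
from scipy.integrate import quad_vec, solve_ivp
from scipy.linalg import expm

from .errors import DomainError, ValidationError
from .model import (
    MetaPopulation,
    PopulationMeasure,
    TypeSpace,
    tensor,
)
from .partitions import (
    LabelledPartition,
    Partition,
    _canon_sites,
    enumerate_labelled_partitions,
    labelled_top,
    restrict,
    top,
)

logger = logging.getLogger("migrec")

GEN_TOL = 1e-12


@dataclass(frozen=True)
class CTModel:
    """Continuous-time model: per-partition recombination rates and a
    migration generator ``N`` (nonnegative off-diagonals, zero row sums).

    A rate on the one-block partition is a no-op (``R_top = Id``) and is
    dropped with a logged note rather than silently kept.
    """

    space: TypeSpace
    demes: tuple[str, ...]
    rates: Mapping[Partition, float]
    generator: np.ndarray

    def __init__(self, space, demes, rates, generator):
        demes = tuple(str(d) for d in demes)
        N = np.asarray(generator, dtype=float)
        if N.shape != (len(demes), len(demes)):
            raise ValidationError("generator shape does not match deme count")
        off = N - np.diag(np.diag(N))
        if np.any(off < 0):
            raise ValidationError("generator has negative off-diagonal entries")
        if np.max(np.abs(N.sum(axis=1))) > GEN_TOL:
            raise ValidationError("generator rows do not sum to 0")
        clean: dict[Partition, float] = {}
        tp = top(space.sites)
        for p, x in rates.items():
            if p.ground != space.sites:
                raise ValidationError(f"{p} is not a partition of the site set")
            x = float(x)
            if x < 0:
                raise ValidationError(f"negative rate for {p}")
            if p == tp:
                if x > 0:
                    logger.info(
                        "ignoring rate %g on the one-block partition: "
                        "recombining from a single parent changes nothing",
                        x,
                    )
                continue
            if x > 0:
                clean[p] = x
        object.__setattr__(self, "space", space)
        object.__setattr__(self, "demes", demes)
        object.__setattr__(self, "rates", clean)
        object.__setattr__(self, "generator", N)

    @property
    def ground(self) -> tuple[int, ...]:
        return self.space.sites

    def index(self, deme: str) -> int:
        try:
            return self.demes.index(str(deme))
        except ValueError:
            raise DomainError(f"unknown deme {deme!r}") from None

    def marginal_rates(self, d: Iterable[int]) -> dict[Partition, float]:
        """``rho^d_eps = sum of rho over full partitions inducing eps on d``,
        omitting the no-op one-block induced partition."""
        dd = _canon_sites(d)
        out: dict[Partition, float] = {}
        tp = top(dd)
        for p, x in self.rates.items():
            q = restrict(p, dd)
            if q == tp:
                continue
            out[q] = out.get(q, 0.0) + x
        return out


def _recombination_term(m: PopulationMeasure, ct: CTModel) -> np.ndarray:
    """sum_delta rho_delta (R_delta - Id) applied to one deme's table."""
    out = np.zeros_like(m.table, dtype=float)
    for delta, rho in ct.rates.items():
        prod = tensor([m.marginal(b) for b in delta.blocks]).table
        out += rho * (prod - m.table)
    return out


def ct_rhs(omega: MetaPopulation, ct: CTModel) -> list[np.ndarray]:
    """Right-hand side of the forward ODE, one signed table per deme;
    each component sums to zero (mass conservation)."""
    if omega.demes != ct.demes:
        raise DomainError("metapopulation demes do not match the model")
    N = ct.generator
    tables = [m.table.astype(float) for m in omega.measures]
    out = []
    for i in range(len(ct.demes)):
        mig = sum(N[i, j] * tables[j] for j in range(len(tables)))
        rec = _recombination_term(omega.measures[i], ct)
        out.append(mig + rec)
    return out


@dataclass(frozen=True)
class CTGenerator:
    """Generator of the continuous-time labelled partitioning process."""

    states: tuple[LabelledPartition, ...]
    matrix: np.ndarray

    @property
    def index(self) -> dict[LabelledPartition, int]:
        return {p: i for i, p in enumerate(self.states)}


def build_generator_Q(ct: CTModel) -> CTGenerator:
    """Off-diagonals: ``rho^d`` at the induced partition when exactly one
    labelled block ``(d, l)`` is replaced by a proper refinement whose
    fragments all keep label ``l``; ``N(a, b)`` when exactly one block's
    label flips ``a -> b``; zero otherwise.  Diagonal balances the rows."""
    states = tuple(enumerate_labelled_partitions(ct.ground, ct.demes))
    idx = {p: i for i, p in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    N = ct.generator
    for i, bdelta in enumerate(states):
        blocks = list(bdelta)
        for k, (d, lam) in enumerate(blocks):
            others = blocks[:k] + blocks[k + 1 :]
            # splitting transitions of this block
            if len(d) > 1:
                for eps, rho in ct.marginal_rates(d).items():
                    newblocks = others + [(b, lam) for b in eps.blocks]
                    j = idx[LabelledPartition(newblocks)]
                    Q[i, j] += rho
            # relabelling transitions of this block
            li = ct.index(lam)
            for g, gname in enumerate(ct.demes):
                if g == li or N[li, g] == 0:
                    continue
                j = idx[LabelledPartition(others + [(d, gname)])]
                Q[i, j] += N[li, g]
        Q[i, i] = -Q[i].sum() + Q[i, i]
    return CTGenerator(states, Q)


def _clip_measure(space, sites, tab) -> PopulationMeasure:
    if np.any(tab < -1e-10):
        logger.warning(
            "clipping negative probability entries (min %.3g) in a "
            "continuous-time solution",
            float(tab.min()),
        )
    tab = np.clip(tab, 0.0, None)
    tab = tab / tab.sum()
    return PopulationMeasure(space, sites, tab, validate=False)


def ct_solve(
    omega0: MetaPopulation,
    ct: CTModel,
    t: float,
    method: str = "expm",
    rtol: float = 1e-9,
) -> MetaPopulation:
    """Solve the continuous-time system at time ``t``.

    ``method="expm"`` exponentiates the dual generator and applies it to
    the recombinator vector (the continuous analogue of matrix powers);
    ``method="ode"`` integrates the nonlinear forward ODE directly with an
    adaptive Runge-Kutta scheme.  The two agree to solver tolerance and
    are used as mutual oracles in the tests.
    """
    if t < 0:
        raise DomainError("t must be nonnegative")
    if method == "expm":
        from .model import recombinator

        gen = build_generator_Q(ct)
        P = expm(t * gen.matrix)
        vals = np.stack(
            [recombinator(b, omega0).flat().astype(float) for b in gen.states]
        )
        sol = P @ vals
        out = []
        for alpha in omega0.demes:
            i = gen.index[labelled_top(ct.ground, alpha)]
            out.append(_clip_measure(omega0.space, omega0.sites, sol[i]))
        return MetaPopulation(omega0.demes, out)
    if method == "ode":
        shape = omega0.space.shape()
        L = len(omega0.demes)
        size = int(np.prod(shape))

        def rhs(_, y):
            tabs = y.reshape(L, *shape)
            meas = [
                PopulationMeasure(omega0.space, omega0.sites, tabs[i], validate=False)
                for i in range(L)
            ]
            omega = MetaPopulation(omega0.demes, meas)
            return np.concatenate([d.reshape(-1) for d in ct_rhs(omega, ct)])

        y0 = np.concatenate([m.flat().astype(float) for m in omega0.measures])
        res = solve_ivp(rhs, (0.0, t), y0, rtol=rtol, atol=1e-12, dense_output=False)
        if not res.success:
            raise ValidationError(f"ODE integration failed: {res.message}")
        yT = res.y[:, -1].reshape(L, size)
        out = [
            _clip_measure(omega0.space, omega0.sites, yT[i].reshape(shape))
            for i in range(L)
        ]
        return MetaPopulation(omega0.demes, out)
    raise DomainError(f"unknown method {method!r}; use 'expm' or 'ode'")


def ct_two_site(
    omega0: MetaPopulation, ct: CTModel, t: float, alpha: str, atol: float = 1e-9
) -> PopulationMeasure:
    """Closed-form two-site solution.

    With probability ``exp(-rho0 t)`` the sites never separate and the
    single ancestral line runs the migration semigroup for time ``t``;
    otherwise they split at an exponential time ``sigma`` at the deme the
    line occupies then, after which the two site-marginals evolve
    independently.  The ``sigma``-integral is evaluated by adaptive
    quadrature to absolute tolerance *atol*.
    """
    if ct.space.n != 2:
        raise DomainError("closed form requires exactly two sites")
    from .partitions import bottom

    rho0 = float(ct.rates.get(bottom(ct.ground), 0.0))
    N = ct.generator
    a = ct.index(alpha)
    L = len(ct.demes)
    shape = omega0.space.shape()
    stack0 = omega0.stack()

    out = np.exp(-rho0 * t) * (expm(t * N) @ stack0)[a].reshape(shape)
    if rho0 > 0 and t > 0:

        def integrand(sigma):
            Ps = expm(sigma * N)
            rem = expm((t - sigma) * N) @ stack0  # (L, |A|)
            acc = np.zeros(shape)
            for g in range(L):
                tab = rem[g].reshape(shape)
                acc += Ps[a, g] * np.outer(tab.sum(axis=1), tab.sum(axis=0))
            return np.exp(-rho0 * sigma) * acc

        integral, _ = quad_vec(integrand, 0.0, t, epsabs=atol)
        out = out + rho0 * integral
    return PopulationMeasure(omega0.space, omega0.sites, out, validate=False)
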