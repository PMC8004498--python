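"""Model data for the migration-recombination equation.

The forward state is a *metapopulation*: one probability distribution per
deme over the product type space ``A_1 x ... x A_n``.  Recombination is a
probability distribution ``r`` over set partitions of the sites: with
probability ``r_delta`` an offspring is pieced together from ``|delta|``
independently drawn parents, inheriting the sites of each block from one
parent.  Migration is a backward stochastic matrix ``M`` over demes:
``M(alpha, beta)`` is the probability that an individual now at ``alpha``
came from ``beta``.

Probability tables are dense numpy arrays with one axis per site (sites in
ascending order, letters in declared alphabet order); flattening in C order
yields the lexicographic linear order used by all file formats.  Tables may
hold floats (default) or :class:`fractions.Fraction` entries (object dtype)
for exact-rational work; every operation preserves the mode of its inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import DomainError, ValidationError
from .partitions import (
    LabelledPartition,
    Partition,
    _canon_sites,
    restrict,
)

logger = logging.getLogger("migrec")

#: product type-space size cap
TYPE_SPACE_CAP = 1_000_000
#: normalisation tolerance for floating-point probability data
NORM_TOL = 1e-12
#: tolerance for the population-size balance check of backward migration
BALANCE_TOL = 1e-9


def _is_exact(x) -> bool:
    return isinstance(x, (Fraction, int)) and not isinstance(x, bool)


# ---------------------------------------------------------------------------
# type space
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TypeSpace:
    """Per-site finite alphabets; the type space is their product."""

    alphabets: tuple[tuple[str, ...], ...]

    def __init__(self, alphabets: Sequence[Sequence] ):
        alphs = tuple(tuple(str(a) for a in al) for al in alphabets)
        if not alphs:
            raise ValidationError("need at least one site")
        for i, al in enumerate(alphs):
            if not al:
                raise ValidationError(f"alphabet of site {i + 1} is empty")
            if len(set(al)) != len(al):
                raise ValidationError(f"alphabet of site {i + 1} has duplicates")
        size = 1
        for al in alphs:
            size *= len(al)
        if size > TYPE_SPACE_CAP:
            raise ValidationError(
                f"type space size {size} exceeds the cap {TYPE_SPACE_CAP}"
            )
        object.__setattr__(self, "alphabets", alphs)

    @property
    def n(self) -> int:
        return len(self.alphabets)

    @property
    def sites(self) -> tuple[int, ...]:
        return tuple(range(1, self.n + 1))

    def shape(self, sites: Iterable[int] | None = None) -> tuple[int, ...]:
        sites = self.sites if sites is None else _canon_sites(sites)
        return tuple(len(self.alphabets[s - 1]) for s in sites)

    def size(self, sites: Iterable[int] | None = None) -> int:
        return int(np.prod(self.shape(sites), dtype=np.int64)) if (
            sites is None or _canon_sites(sites)
        ) else 1

    def types(self, sites: Iterable[int] | None = None):
        """Iterate marginal types in lexicographic (C-flattening) order."""
        sites = self.sites if sites is None else _canon_sites(sites)
        return product(*(self.alphabets[s - 1] for s in sites))


# ---------------------------------------------------------------------------
# population measures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationMeasure:
    """A probability distribution over marginal types on a site subset.

    The empty site subset carries the trivial unit mass on the empty
    sequence (a 0-d table holding 1) and acts as the scalar 1 in products.
    """

    space: TypeSpace
    sites: tuple[int, ...]
    table: np.ndarray

    def __init__(self, space: TypeSpace, sites: Iterable[int], table, *, validate: bool = True):
        sites = tuple(sorted(set(int(s) for s in sites)))
        if any(s < 1 or s > space.n for s in sites):
            raise DomainError(f"sites {sites} outside 1..{space.n}")
        arr = np.asarray(table)
        expected = space.shape(sites) if sites else ()
        if arr.shape != expected:
            if arr.ndim == 1 and arr.size == int(np.prod(expected, dtype=np.int64)):
                arr = arr.reshape(expected)
            else:
                raise ValidationError(
                    f"table shape {arr.shape} does not match sites {sites} "
                    f"(expected {expected})"
                )
        if validate:
            _check_probability_table(arr)
        object.__setattr__(self, "space", space)
        object.__setattr__(self, "sites", sites)
        object.__setattr__(self, "table", arr)

    # -- views -------------------------------------------------------------
    @property
    def exact(self) -> bool:
        return self.table.dtype == object

    def flat(self) -> np.ndarray:
        """Lexicographic linear order over sites ascending."""
        return self.table.reshape(-1)

    def __getitem__(self, marginal_type) -> float:
        space_axes = {s: i for i, s in enumerate(self.sites)}
        idx = [0] * len(self.sites)
        for (s, letter) in marginal_type:
            idx[space_axes[s]] = self.space.alphabets[s - 1].index(letter)
        return self.table[tuple(idx)]

    # -- operations --------------------------------------------------------
    def marginal(self, V: Iterable[int]) -> "PopulationMeasure":
        """Marginal distribution on ``V`` (a subset of this measure's sites).

        Sums the table over all sites outside V; linear and mass-preserving.
        """
        v = tuple(sorted(set(int(s) for s in V)))
        if not set(v) <= set(self.sites):
            raise DomainError(f"{v} is not a subset of {self.sites}")
        if v == self.sites:
            return self
        drop = tuple(i for i, s in enumerate(self.sites) if s not in v)
        tab = self.table.sum(axis=drop) if drop else self.table
        return PopulationMeasure(self.space, v, tab, validate=False)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PopulationMeasure)
            and self.sites == other.sites
            and np.array_equal(self.table, other.table)
        )

    def __hash__(self):
        return hash((self.sites, self.table.tobytes() if self.table.dtype != object else str(self.table)))


def _check_probability_table(arr: np.ndarray) -> None:
    if arr.dtype == object:
        flat = arr.reshape(-1) if arr.ndim else arr[None]
        if any(x < 0 for x in flat.tolist()):
            raise ValidationError("negative probability entry")
        if sum(flat.tolist()) != 1:
            raise ValidationError("probabilities do not sum to 1 (exact mode)")
    else:
        if np.any(arr < -1e-15):
            raise ValidationError("negative probability entry")
        if abs(float(arr.sum()) - 1.0) > NORM_TOL:
            raise ValidationError(
                f"probabilities sum to {float(arr.sum())}, not 1 (tol {NORM_TOL})"
            )


def trivial_measure(space: TypeSpace, exact: bool = False) -> PopulationMeasure:
    """Unit mass on the empty sequence; the scalar 1 of measure products."""
    one = np.array(Fraction(1) if exact else 1.0, dtype=object if exact else float)
    return PopulationMeasure(space, (), one, validate=False)


def tensor(measures: Sequence[PopulationMeasure]) -> PopulationMeasure:
    """Product measure of measures on pairwise disjoint site subsets.

    The product respects site order: axes of the result follow ascending
    sites regardless of the order the factors are given in.
    """
    measures = [m for m in measures if m.sites]
    if not measures:
        raise DomainError("tensor of zero non-trivial measures; use trivial_measure")
    space = measures[0].space
    seen: set[int] = set()
    for m in measures:
        if m.space is not space and m.space != space:
            raise DomainError("measures live on different type spaces")
        if seen.intersection(m.sites):
            raise DomainError("site subsets overlap in tensor product")
        seen.update(m.sites)
    tab = measures[0].table
    sites: list[int] = list(measures[0].sites)
    for m in measures[1:]:
        tab = np.multiply.outer(tab, m.table)
        sites.extend(m.sites)
    order = np.argsort(np.array(sites, dtype=int), kind="stable")
    tab = np.transpose(tab, axes=tuple(order))
    return PopulationMeasure(space, sorted(sites), tab, validate=False)


def marginalise(nu: PopulationMeasure, V: Iterable[int]) -> PopulationMeasure:
    """Functional alias for :meth:`PopulationMeasure.marginal`."""
    return nu.marginal(V)


# ---------------------------------------------------------------------------
# metapopulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaPopulation:
    """One :class:`PopulationMeasure` per deme, over a common site subset."""

    demes: tuple[str, ...]
    measures: tuple[PopulationMeasure, ...]

    def __init__(self, demes: Sequence[str], measures: Sequence[PopulationMeasure]):
        demes = tuple(str(d) for d in demes)
        measures = tuple(measures)
        if len(demes) != len(measures):
            raise ValidationError("need exactly one measure per deme")
        if len(set(demes)) != len(demes):
            raise ValidationError("duplicate deme names")
        if measures:
            s0 = measures[0].sites
            for m in measures[1:]:
                if m.sites != s0:
                    raise ValidationError("all demes must share the same site subset")
        object.__setattr__(self, "demes", demes)
        object.__setattr__(self, "measures", measures)

    @property
    def sites(self) -> tuple[int, ...]:
        return self.measures[0].sites

    @property
    def space(self) -> TypeSpace:
        return self.measures[0].space

    def __call__(self, deme: str) -> PopulationMeasure:
        try:
            return self.measures[self.demes.index(str(deme))]
        except ValueError:
            raise DomainError(f"unknown deme {deme!r}") from None

    def marginal(self, V: Iterable[int]) -> "MetaPopulation":
        return MetaPopulation(self.demes, [m.marginal(V) for m in self.measures])

    def stack(self) -> np.ndarray:
        """(|L|, |A_U|) array of flattened tables, rows in deme order."""
        return np.stack([m.flat() for m in self.measures])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MetaPopulation)
            and self.demes == other.demes
            and all(a == b for a, b in zip(self.measures, other.measures))
        )

    def sup_distance(self, other: "MetaPopulation") -> float:
        """Largest absolute cellwise difference across demes."""
        return float(
            max(
                np.max(np.abs(a.flat().astype(float) - b.flat().astype(float)))
                for a, b in zip(self.measures, other.measures)
            )
        )


# ---------------------------------------------------------------------------
# recombination distribution
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecombinationDistribution:
    """Sparse probability distribution ``r`` over partitions of the sites.

    Partitions outside the stored support have ``r_delta = 0``.  Weights
    may be floats or Fractions; a Fraction-weighted distribution keeps all
    derived quantities (marginals, transition matrices, sojourn
    probabilities) exact.
    """

    ground: tuple[int, ...]
    weights: Mapping[Partition, object]
    _marginal_cache: dict = field(default_factory=dict, compare=False, repr=False)

    def __init__(self, ground: Iterable[int], weights: Mapping[Partition, object]):
        g = _canon_sites(ground)
        w = {}
        for p, x in weights.items():
            if p.ground != g:
                raise ValidationError(
                    f"partition {p} is not a partition of the ground set {g}"
                )
            if x < 0:
                raise ValidationError(f"negative weight for {p}")
            if x != 0:
                w[p] = x
        total = sum(w.values())
        if all(_is_exact(x) for x in w.values()):
            if total != 1:
                raise ValidationError(f"weights sum to {total}, not 1 (exact mode)")
        elif abs(float(total) - 1.0) > NORM_TOL:
            raise ValidationError(f"weights sum to {float(total)}, not 1")
        object.__setattr__(self, "ground", g)
        object.__setattr__(self, "weights", dict(w))
        object.__setattr__(self, "_marginal_cache", {})

    @property
    def exact(self) -> bool:
        return all(_is_exact(x) for x in self.weights.values())

    def __getitem__(self, delta: Partition):
        return self.weights.get(delta, Fraction(0) if self.exact else 0.0)

    def support(self) -> list[Partition]:
        return list(self.weights)

    def marginal(self, U: Iterable[int]) -> dict[Partition, object]:
        """Marginal recombination distribution on the site subset ``U``:
        ``r^U_delta = sum of r over full partitions inducing delta on U``."""
        u = _canon_sites(U)
        if not u:
            raise DomainError("marginal to the empty site set is not defined")
        if not set(u) <= set(self.ground):
            raise DomainError(f"{u} is not a subset of {self.ground}")
        if u in self._marginal_cache:
            return dict(self._marginal_cache[u])
        out: dict[Partition, object] = {}
        for p, x in self.weights.items():
            q = restrict(p, u)
            out[q] = out.get(q, 0) + x
        self._marginal_cache[u] = dict(out)
        return out

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, RecombinationDistribution)
            and self.ground == other.ground
            and self.weights == other.weights
        )

    def __hash__(self):
        return hash((self.ground, frozenset(self.weights.items())))


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MigrationModel:
    """Backward migration matrix over an ordered deme set."""

    demes: tuple[str, ...]
    backward: np.ndarray
    forward: np.ndarray | None = None
    sizes: np.ndarray | None = None

    def __init__(self, demes, backward, forward=None, sizes=None):
        demes = tuple(str(d) for d in demes)
        if len(set(demes)) != len(demes):
            raise ValidationError("duplicate deme names")
        M = np.asarray(backward, dtype=float)
        if M.shape != (len(demes), len(demes)):
            raise ValidationError(
                f"backward matrix shape {M.shape} does not match {len(demes)} demes"
            )
        _check_stochastic(M, "backward migration matrix")
        object.__setattr__(self, "demes", demes)
        object.__setattr__(self, "backward", M)
        object.__setattr__(self, "forward", None if forward is None else np.asarray(forward, float))
        object.__setattr__(self, "sizes", None if sizes is None else np.asarray(sizes, float))

    def index(self, deme: str) -> int:
        try:
            return self.demes.index(str(deme))
        except ValueError:
            raise DomainError(f"unknown deme {deme!r}") from None

    def __call__(self, alpha: str, beta: str) -> float:
        return float(self.backward[self.index(alpha), self.index(beta)])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, MigrationModel)
            and self.demes == other.demes
            and np.array_equal(self.backward, other.backward)
        )


def _check_stochastic(M: np.ndarray, what: str) -> None:
    if np.any(M < 0):
        raise ValidationError(f"{what} has negative entries")
    if np.max(np.abs(M.sum(axis=1) - 1.0)) > NORM_TOL:
        raise ValidationError(f"{what} rows do not sum to 1 (tol {NORM_TOL})")


def backward_from_forward(
    forward, sizes, demes: Sequence[str]
) -> MigrationModel:
    """Backward matrix ``M(a,b) = c(b) Mfwd(b,a) / c(a)`` from the forward
    matrix and constant deme sizes, with rows normalised.

    If the sizes are not reproduced by one round of forward migration
    (constant-size balance), the backward rows do not sum to one before
    normalisation; this is legitimate when population regulation happens
    after migration, so it is logged as a warning rather than raised.
    """
    F = np.asarray(forward, dtype=float)
    c = np.asarray(sizes, dtype=float)
    if np.any(c <= 0):
        raise DomainError("deme sizes must be strictly positive")
    _check_stochastic(F, "forward migration matrix")
    M = (c[None, :] * F.T) / c[:, None]
    rowsums = M.sum(axis=1)
    if np.max(np.abs(rowsums - 1.0)) > BALANCE_TOL:
        logger.warning(
            "deme sizes are not constant under the forward matrix "
            "(max row-sum deviation %.3g); assuming regulation after "
            "migration and renormalising backward rows",
            float(np.max(np.abs(rowsums - 1.0))),
        )
        M = M / rowsums[:, None]
    return MigrationModel(demes, M, forward=F, sizes=c)


# ---------------------------------------------------------------------------
# the full model and migration-recombination probabilities
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Model:
    """A migration-recombination model: type space, ``r`` and ``M``."""

    space: TypeSpace
    recombination: RecombinationDistribution
    migration: MigrationModel

    def __post_init__(self):
        if self.recombination.ground != self.space.sites:
            raise ValidationError(
                "recombination distribution ground set does not match the "
                "type-space sites"
            )

    @property
    def demes(self) -> tuple[str, ...]:
        return self.migration.demes

    @property
    def ground(self) -> tuple[int, ...]:
        return self.space.sites


@dataclass(frozen=True)
class MRProbabilities:
    """Migration-recombination distribution at one deme: a probability
    distribution over labelled partitions (optionally of a site subset)."""

    alpha: str
    sites: tuple[int, ...]
    probs: dict[LabelledPartition, object]

    def __getitem__(self, bdelta: LabelledPartition):
        return self.probs.get(bdelta, 0)

    def total(self):
        return sum(self.probs.values())


def recombinator(bdelta: LabelledPartition, nu: MetaPopulation) -> PopulationMeasure:
    """Labelled recombinator: the product over labelled blocks ``(d, l)``
    of the ``d``-marginal of the population at deme ``l``.

    This is the type distribution of an offspring pieced together
    block-wise from independent parents living in the labelled demes.
    """
    if set(bdelta.ground) != set(nu.sites):
        raise DomainError(
            f"labelled partition ground {bdelta.ground} does not match "
            f"population sites {nu.sites}"
        )
    factors = [nu(lab).marginal(block) for block, lab in bdelta]
    return tensor(factors)


def _labelled_refinements(delta: Partition, demes: Sequence[str]):
    """All labelings of a fixed base partition, in lexicographic label order."""
    for labs in product(demes, repeat=len(delta)):
        yield LabelledPartition(list(zip(delta.blocks, labs)))


def mr_probabilities(model: Model, alpha: str) -> MRProbabilities:
    """Joint law of (base partition, block labels) one generation back:
    ``p_bdelta(alpha) = r_delta * prod over blocks of M(alpha, label)``."""
    a = model.migration.index(alpha)
    M = model.migration.backward
    probs: dict[LabelledPartition, object] = {}
    for delta, r in model.recombination.weights.items():
        for bdelta in _labelled_refinements(delta, model.demes):
            p = r
            for _, lab in bdelta:
                m = M[a, model.migration.index(lab)]
                if m != 1.0:  # keep Fraction weights exact when labels are forced
                    p = p * m
            if p != 0:
                probs[bdelta] = probs.get(bdelta, 0) + p
    return MRProbabilities(str(alpha), model.ground, probs)


def marginal_recombination(
    r: RecombinationDistribution, U: Iterable[int]
) -> dict[Partition, object]:
    """Functional alias for :meth:`RecombinationDistribution.marginal`."""
    return r.marginal(U)


def marginal_mr_probabilities(model: Model, U: Iterable[int], alpha: str) -> MRProbabilities:
    """Marginal migration-recombination probabilities on a site subset:
    ``p^U_bdelta(alpha) = r^U_delta * prod over blocks of M(alpha, label)``,
    which equals the sum of full-system probabilities over labelled
    partitions inducing ``bdelta`` on ``U``."""
    u = _canon_sites(U)
    a = model.migration.index(alpha)
    M = model.migration.backward
    rU = model.recombination.marginal(u)
    probs: dict[LabelledPartition, object] = {}
    for delta, r in rU.items():
        if r == 0:
            continue
        for bdelta in _labelled_refinements(delta, model.demes):
            p = r
            for _, lab in bdelta:
                m = M[a, model.migration.index(lab)]
                if m != 1.0:
                    p = p * m
            if p != 0:
                probs[bdelta] = probs.get(bdelta, 0) + p
    return MRProbabilities(str(alpha), u, probs)
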