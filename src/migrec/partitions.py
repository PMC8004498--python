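"""Set partitions and deme-labelled partitions of a finite site set.

These are the state spaces of the partitioning processes that solve the
migration-recombination equation: an unlabelled partition of the site set
``{1, ..., n}`` records which sites descend from a common ancestor, and a
labelled partition additionally records the deme each ancestor lives in.

Canonical form
--------------
Sites are 1-based throughout.  A block is a sorted tuple of sites; the
blocks of a partition are sorted by their smallest element.  Equality and
hashing operate on canonical forms, so two partitions are equal iff they
partition the same ground set into the same blocks.  Enumeration follows
restricted-growth-string order, which gives every matrix built on these
state spaces a stable, reproducible index.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Iterable, Iterator, Sequence

from .errors import DomainError, SizeCapError

Block = tuple[int, ...]

#: default cap on |ground| for exhaustive partition enumeration
PARTITION_ENUM_CAP = 10
#: default cap on the number of labelled partitions enumerated
LABELLED_ENUM_CAP = 200_000


def _canon_sites(sites: Iterable[int]) -> tuple[int, ...]:
    out = tuple(sorted(set(int(s) for s in sites)))
    if any(s < 1 for s in out):
        raise DomainError(f"sites must be positive integers, got {out}")
    return out


@dataclass(frozen=True)
class Partition:
    """A set partition of a finite ground set of sites."""

    ground: tuple[int, ...]
    blocks: tuple[Block, ...]

    def __init__(self, blocks: Iterable[Iterable[int]]):
        blks = tuple(sorted((_canon_sites(b) for b in blocks), key=lambda b: b[0] if b else 0))
        if not blks:
            raise DomainError("a partition needs at least one block")
        seen: set[int] = set()
        for b in blks:
            if not b:
                raise DomainError("empty block in partition")
            if seen.intersection(b):
                raise DomainError(f"blocks overlap: {blks}")
            seen.update(b)
        object.__setattr__(self, "ground", tuple(sorted(seen)))
        object.__setattr__(self, "blocks", blks)

    # -- basic structure ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.blocks)

    def __iter__(self) -> Iterator[Block]:
        return iter(self.blocks)

    def block_of(self, site: int) -> Block:
        for b in self.blocks:
            if site in b:
                return b
        raise DomainError(f"site {site} not in ground set {self.ground}")

    def __str__(self) -> str:
        return "{" + ", ".join("{" + ",".join(map(str, b)) + "}" for b in self.blocks) + "}"

    def to_lists(self) -> list[list[int]]:
        """Serialisable form: sorted list of sorted 1-based site lists."""
        return [list(b) for b in self.blocks]


def bottom(ground: Iterable[int]) -> Partition:
    """The minimal partition: every site a singleton block."""
    g = _canon_sites(ground)
    return Partition([[s] for s in g])


def top(ground: Iterable[int]) -> Partition:
    """The maximal partition: a single block."""
    return Partition([_canon_sites(ground)])


@dataclass(frozen=True)
class LabelledPartition:
    """A partition whose blocks each carry a deme label.

    Distinct blocks may carry equal labels; the *base* is the partition
    obtained by stripping labels.
    """

    ground: tuple[int, ...]
    labelled_blocks: tuple[tuple[Block, str], ...]

    def __init__(self, labelled_blocks: Iterable[tuple[Iterable[int], str]]):
        lbs = tuple(
            sorted(
                ((_canon_sites(b), str(lab)) for b, lab in labelled_blocks),
                key=lambda bl: bl[0][0] if bl[0] else 0,
            )
        )
        if not lbs:
            raise DomainError("a labelled partition needs at least one block")
        seen: set[int] = set()
        for b, _ in lbs:
            if not b:
                raise DomainError("empty block in labelled partition")
            if seen.intersection(b):
                raise DomainError(f"blocks overlap: {lbs}")
            seen.update(b)
        object.__setattr__(self, "ground", tuple(sorted(seen)))
        object.__setattr__(self, "labelled_blocks", lbs)

    @property
    def base(self) -> Partition:
        return Partition([b for b, _ in self.labelled_blocks])

    def __len__(self) -> int:
        return len(self.labelled_blocks)

    def __iter__(self) -> Iterator[tuple[Block, str]]:
        return iter(self.labelled_blocks)

    def __str__(self) -> str:
        return (
            "{"
            + ", ".join(
                "({" + ",".join(map(str, b)) + "}, " + lab + ")"
                for b, lab in self.labelled_blocks
            )
            + "}"
        )

    def to_objects(self) -> list[dict]:
        """Serialisable form: list of {"block": [...], "label": name}."""
        return [{"block": list(b), "label": lab} for b, lab in self.labelled_blocks]


def labelled_top(ground: Iterable[int], label: str) -> LabelledPartition:
    """The maximal labelled partition: one block carrying *label*."""
    return LabelledPartition([(_canon_sites(ground), label)])


def labelled_bottom(ground: Iterable[int], labels: Sequence[str]) -> LabelledPartition:
    """All-singleton labelled partition with per-site labels in site order."""
    g = _canon_sites(ground)
    if len(labels) != len(g):
        raise DomainError("need one label per site")
    return LabelledPartition([((s,), lab) for s, lab in zip(g, labels)])


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def _rgs_iter(n: int) -> Iterator[tuple[int, ...]]:
    """Iterate restricted growth strings of length n in lexicographic order.

    An RGS (a_1..a_n) with a_1 = 0 and a_{i+1} <= 1 + max(a_1..a_i) encodes
    the partition whose j-th block (by smallest element) holds the positions
    with a_i = j.
    """
    def rec(prefix: list[int], mx: int) -> Iterator[tuple[int, ...]]:
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in range(mx + 2):
            prefix.append(v)
            yield from rec(prefix, max(mx, v))
            prefix.pop()

    yield from rec([0], 0)


def enumerate_partitions(
    ground: Iterable[int], cap: int = PARTITION_ENUM_CAP
) -> list[Partition]:
    """All partitions of *ground* in restricted-growth-string order.

    The count equals the Bell number of ``|ground|``; grounds larger than
    *cap* raise :class:`SizeCapError`.
    """
    g = _canon_sites(ground)
    if not g:
        raise DomainError("ground set must be non-empty")
    if len(g) > cap:
        raise SizeCapError("partition enumeration", len(g), cap)
    out = []
    for rgs in _rgs_iter(len(g)):
        nblocks = max(rgs) + 1
        blocks: list[list[int]] = [[] for _ in range(nblocks)]
        for site, j in zip(g, rgs):
            blocks[j].append(site)
        out.append(Partition(blocks))
    return out


def enumerate_labelled_partitions(
    ground: Iterable[int],
    demes: Sequence[str],
    cap: int = LABELLED_ENUM_CAP,
) -> list[LabelledPartition]:
    """All labelled partitions of *ground* with labels drawn from *demes*.

    Order: partitions in restricted-growth-string order, then label tuples
    lexicographically in declared deme order.  The count is
    ``sum over partitions delta of |demes| ** |delta|``.
    """
    demes = list(demes)
    if not demes:
        raise DomainError("need at least one deme")
    parts = enumerate_partitions(ground)
    total = sum(len(demes) ** len(p) for p in parts)
    if total > cap:
        raise SizeCapError("labelled partition enumeration", total, cap)
    out = []
    for p in parts:
        for labs in product(demes, repeat=len(p)):
            out.append(LabelledPartition(list(zip(p.blocks, labs))))
    return out


# ---------------------------------------------------------------------------
# lattice operations
# ---------------------------------------------------------------------------

def _require_same_ground(a, b) -> None:
    if a.ground != b.ground:
        raise DomainError(f"ground sets differ: {a.ground} vs {b.ground}")


def meet(delta: Partition, epsilon: Partition) -> Partition:
    """Coarsest common refinement: all non-empty pairwise intersections."""
    _require_same_ground(delta, epsilon)
    blocks = []
    for d in delta.blocks:
        dset = set(d)
        for e in epsilon.blocks:
            inter = dset.intersection(e)
            if inter:
                blocks.append(sorted(inter))
    return Partition(blocks)


def is_finer(epsilon, delta) -> bool:
    """True iff every block of *epsilon* lies inside some block of *delta*.

    Labelled arguments are compared through their bases.
    """
    e = epsilon.base if isinstance(epsilon, LabelledPartition) else epsilon
    d = delta.base if isinstance(delta, LabelledPartition) else delta
    _require_same_ground(e, d)
    dsets = [set(b) for b in d.blocks]
    return all(any(set(be) <= bd for bd in dsets) for be in e.blocks)


def restrict(delta, V: Iterable[int]):
    """The partition induced on ``V``: non-empty intersections of blocks
    with V; labelled blocks keep the label of their originating block."""
    v = set(_canon_sites(V))
    if not v:
        raise DomainError("restriction to the empty set is not defined")
    if not v <= set(delta.ground):
        raise DomainError(f"{sorted(v)} is not a subset of ground {delta.ground}")
    if isinstance(delta, LabelledPartition):
        lbs = []
        for b, lab in delta.labelled_blocks:
            inter = v.intersection(b)
            if inter:
                lbs.append((sorted(inter), lab))
        return LabelledPartition(lbs)
    blocks = []
    for b in delta.blocks:
        inter = v.intersection(b)
        if inter:
            blocks.append(sorted(inter))
    return Partition(blocks)


def union_labelled(parts: Iterable[LabelledPartition]) -> LabelledPartition:
    """Concatenate labelled partitions over pairwise disjoint grounds.

    Restricting the result to each input ground recovers that input; this
    is one direction of the bijection between labelled refinements of a
    partition and collections of labelled partitions of its blocks.
    """
    parts = list(parts)
    if not parts:
        raise DomainError("union of an empty collection is not defined")
    lbs: list[tuple[Block, str]] = []
    seen: set[int] = set()
    for p in parts:
        if seen.intersection(p.ground):
            raise DomainError("ground sets of the inputs overlap")
        seen.update(p.ground)
        lbs.extend(p.labelled_blocks)
    return LabelledPartition(lbs)


def bell_number(n: int) -> int:
    """Bell number by the Bell-triangle recurrence (used as a test oracle)."""
    if n == 0:
        return 1
    row = [1]
    for _ in range(n - 1):
        nxt = [row[-1]]
        for x in row:
            nxt.append(nxt[-1] + x)
        row = nxt
    return row[-1]
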