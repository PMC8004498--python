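"""Configuration I/O, seeded random-model generation, and named fixtures.

A model file (YAML or JSON) declares the type space, the ordered deme set,
the recombination distribution over partitions (probabilities may be given
as ``"p/q"`` strings for exact-rational work), the migration matrix (either
backward directly, or forward plus deme sizes), and optionally the initial
per-deme probability tables in lexicographic linear order and the
continuous-time ``rates`` / ``generator`` keys.  ``model_schema.json``
in this package documents the format.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml

from .ctime import CTModel
from .errors import ValidationError
from .model import (
    MetaPopulation,
    MigrationModel,
    Model,
    PopulationMeasure,
    RecombinationDistribution,
    TypeSpace,
    backward_from_forward,
)
from .partitions import Partition, bottom, enumerate_partitions, top

SCHEMA_VERSION = 1


@dataclass
class ModelConfig:
    """A parsed model file plus provenance."""

    model: Model
    initial: MetaPopulation | None = None
    ct: CTModel | None = None
    seed: int | None = None
    path: str | None = None
    schema_version: int = SCHEMA_VERSION

    @property
    def content_hash(self) -> str:
        """Git-style content hash of the canonical serialised form."""
        payload = json.dumps(config_to_dict(self), sort_keys=True).encode()
        return hashlib.sha1(b"blob %d\0" % len(payload) + payload).hexdigest()


def _parse_prob(x):
    if isinstance(x, str):
        return Fraction(x)
    if isinstance(x, int):
        return Fraction(x)
    return float(x)


def _fmt_prob(x):
    if isinstance(x, Fraction):
        return str(x)
    return float(x)


def config_from_dict(data: dict, path: str | None = None) -> ModelConfig:
    """Build a validated :class:`ModelConfig` from a parsed mapping."""
    if not isinstance(data, dict):
        raise ValidationError("model config must be a mapping")
    required = {"n", "demes", "recombination", "migration"}
    missing = required - set(data)
    if missing:
        raise ValidationError(f"model config is missing keys: {sorted(missing)}")
    n = int(data["n"])
    alphabets = data.get("alphabets") or [["0", "1"]] * n
    if len(alphabets) != n:
        raise ValidationError(f"expected {n} alphabets, got {len(alphabets)}")
    space = TypeSpace(alphabets)
    demes = [str(d) for d in data["demes"]]

    weights: dict[Partition, object] = {}
    for item in data["recombination"]:
        p = Partition(item["partition"])
        weights[p] = weights.get(p, 0) + _parse_prob(item["prob"])
    recomb = RecombinationDistribution(space.sites, weights)

    mig = data["migration"]
    if "backward" in mig:
        migration = MigrationModel(demes, np.asarray(mig["backward"], float))
    elif "forward" in mig:
        migration = backward_from_forward(mig["forward"], mig["sizes"], demes)
    else:
        raise ValidationError("migration needs a 'backward' or a 'forward' matrix")

    model = Model(space, recomb, migration)

    initial = None
    if data.get("initial") is not None:
        init = data["initial"]
        meas = []
        for d in demes:
            if d not in init:
                raise ValidationError(f"initial tables missing deme {d!r}")
            tab = np.asarray([float(_parse_prob(x)) for x in init[d]])
            meas.append(PopulationMeasure(space, space.sites, tab))
        initial = MetaPopulation(demes, meas)

    ct = None
    if data.get("rates") is not None or data.get("generator") is not None:
        if data.get("rates") is None or data.get("generator") is None:
            raise ValidationError(
                "continuous time needs both 'rates' and 'generator'"
            )
        rates = {
            Partition(item["partition"]): float(item["rate"])
            for item in data["rates"]
        }
        ct = CTModel(space, demes, rates, np.asarray(data["generator"], float))

    return ModelConfig(
        model=model,
        initial=initial,
        ct=ct,
        seed=data.get("seed"),
        path=path,
        schema_version=int(data.get("schema_version", SCHEMA_VERSION)),
    )


def config_to_dict(cfg: ModelConfig) -> dict:
    """Canonical serialisable form; write-then-read is semantically the
    identity."""
    model = cfg.model
    out: dict = {
        "schema_version": cfg.schema_version,
        "n": model.space.n,
        "alphabets": [list(a) for a in model.space.alphabets],
        "demes": list(model.demes),
        "recombination": [
            {"partition": p.to_lists(), "prob": _fmt_prob(w)}
            for p, w in sorted(
                model.recombination.weights.items(), key=lambda kv: str(kv[0])
            )
        ],
        "migration": {"backward": model.migration.backward.tolist()},
    }
    if cfg.seed is not None:
        out["seed"] = cfg.seed
    if cfg.initial is not None:
        out["initial"] = {
            d: [float(x) for x in cfg.initial(d).flat()] for d in model.demes
        }
    if cfg.ct is not None:
        out["rates"] = [
            {"partition": p.to_lists(), "rate": float(x)}
            for p, x in sorted(cfg.ct.rates.items(), key=lambda kv: str(kv[0]))
        ]
        out["generator"] = cfg.ct.generator.tolist()
    return out


def load_config(path) -> ModelConfig:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return config_from_dict(data, path=str(path))


def save_config(cfg: ModelConfig, path) -> None:
    path = Path(path)
    data = config_to_dict(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=True))


# ---------------------------------------------------------------------------
# random models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RandomModelSpec:
    """Recipe for a seeded random model.

    Generated models always put mass at least ``min_r0`` on the
    all-singleton partition (so recombination separates every site pair)
    and draw strictly positive migration rows (so the backward matrix is
    primitive); both standing assumptions of the limit theory hold by
    construction.
    """

    seed: int
    n: int = 3
    alphabet_sizes: tuple[int, ...] | None = None
    n_demes: int = 2
    support_size: int = 3
    dirichlet_r: float = 1.0
    dirichlet_m: float = 5.0
    min_r0: float = 0.05
    mode: str = "discrete"


def generate_random_model(spec: RandomModelSpec) -> ModelConfig:
    """Deterministic-in-seed random model with initial tables."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    sizes = spec.alphabet_sizes or (2,) * spec.n
    if len(sizes) != spec.n:
        raise ValidationError("alphabet_sizes length must equal n")
    alphabets = [[str(k) for k in range(s)] for s in sizes]
    space = TypeSpace(alphabets)
    demes = [f"d{i}" for i in range(spec.n_demes)]

    parts = enumerate_partitions(space.sites)
    zero = bottom(space.sites)
    others = [p for p in parts if p != zero]
    k = min(max(spec.support_size - 1, 0), len(others))
    chosen = [zero] + [others[i] for i in sorted(rng.choice(len(others), size=k, replace=False))]
    w = rng.dirichlet([spec.dirichlet_r] * len(chosen))
    # guarantee separability: keep a floor on the all-singleton mass
    w = (1.0 - spec.min_r0) * w
    w[0] += spec.min_r0
    recomb = RecombinationDistribution(
        space.sites, {p: float(x) for p, x in zip(chosen, w)}
    )

    M = rng.dirichlet([spec.dirichlet_m] * spec.n_demes, size=spec.n_demes)
    migration = MigrationModel(demes, M)
    model = Model(space, recomb, migration)

    meas = []
    for _ in demes:
        tab = rng.dirichlet(np.ones(space.size()))
        meas.append(PopulationMeasure(space, space.sites, tab.reshape(space.shape())))
    initial = MetaPopulation(demes, meas)

    ct = None
    if spec.mode == "continuous":
        rates = {
            p: float(rng.exponential(1.0))
            for p in chosen
            if p != top(space.sites)
        }
        N = rng.exponential(1.0, size=(spec.n_demes, spec.n_demes))
        np.fill_diagonal(N, 0.0)
        N -= np.diag(N.sum(axis=1))
        ct = CTModel(space, demes, rates, N)
    elif spec.mode != "discrete":
        raise ValidationError(f"unknown mode {spec.mode!r}")

    return ModelConfig(model=model, initial=initial, ct=ct, seed=spec.seed)


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

def fixture_sojourn_nonmonotone() -> ModelConfig:
    """Four binary sites, one deme; recombination puts mass 1/2 on the
    all-singleton partition, 1/10 on {{1,2},{3,4}} and 2/5 on the one-block
    partition (exact rationals).

    Along the refinement path one-block -> {{1,2},{3,4}} -> finer, the
    sojourn probabilities run 2/5 -> 1/4 -> 1/2: staying probabilities are
    not monotone along refinement paths.  The uniform initial state makes
    the config directly solvable.
    """
    space = TypeSpace([["0", "1"]] * 4)
    g = space.sites
    weights = {
        bottom(g): Fraction(1, 2),
        Partition([[1, 2], [3, 4]]): Fraction(1, 10),
        top(g): Fraction(2, 5),
    }
    recomb = RecombinationDistribution(g, weights)
    migration = MigrationModel(["pop"], [[1.0]])
    model = Model(space, recomb, migration)
    size = space.size()
    uniform = PopulationMeasure(space, g, np.full(space.shape(), 1.0 / size))
    initial = MetaPopulation(["pop"], [uniform])
    return ModelConfig(model=model, initial=initial)


# kept under the name used in model files and the CLI
FIXTURES = {
    "sojourn-nonmonotone": fixture_sojourn_nonmonotone,
}
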