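"""Snapshots, run configuration and deterministic test fixtures.

A snapshot is a versioned, canonical-JSON container holding everything a run
needs to resume or replay bit-exactly: model parameters, lattice, species
table, score matrix, both population matrices and the random-generator
state.  The content hash (sha256 over the canonical payload) changes iff the
state changes and is stable across platforms.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import yaml

from .assembly import AssemblyConfig, assemble, initialize_metacommunity
from .core_model import ModelParams, Species, generate_score_matrix
from .dynamics import Lattice, MetacommunityState

__all__ = [
    "FORMAT_VERSION",
    "SnapshotFormatError",
    "state_to_dict",
    "state_from_dict",
    "save_snapshot",
    "load_snapshot",
    "snapshot_hash",
    "RunConfig",
    "make_fixture",
    "FIXTURE_NAMES",
]

FORMAT_VERSION = 1


class SnapshotFormatError(ValueError):
    """Raised when a snapshot file is malformed, truncated or too new."""


def _canonical(payload: dict) -> str:
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def state_to_dict(state: MetacommunityState, provenance: Optional[dict] = None) -> dict:
    lat = state.lattice
    payload = {
        "format_version": FORMAT_VERSION,
        "params": dataclasses.asdict(state.params),
        "lattice": {
            "rows": lat.rows,
            "cols": lat.cols,
            "active": lat.active.astype(int).tolist(),
            "resource_of": lat.resource_of.tolist(),
        },
        "species": [
            {
                "id": sp.id,
                "traits": sorted(sp.traits),
                "bodysize": sp.bodysize,
                "is_resource": sp.is_resource,
                "parent_id": sp.parent_id,
                "birth_step": sp.birth_step,
            }
            for sp in state.species
        ],
        "beta": state.beta.tolist(),
        "N": state.N.tolist(),
        "N_prev": state.N_prev.tolist(),
        "evo_step": state.evo_step,
        "eco_step": state.eco_step,
        "rng": state.rng.bit_generator.state,
        "provenance": provenance or {},
    }
    return payload


def snapshot_hash(state: MetacommunityState) -> str:
    """sha256 of the state content (provenance excluded)."""
    payload = state_to_dict(state)
    payload.pop("provenance")
    return hashlib.sha256(_canonical(payload).encode()).hexdigest()


def _hash_payload(payload: dict) -> str:
    content = {k: v for k, v in payload.items() if k not in ("provenance", "hash")}
    return hashlib.sha256(_canonical(content).encode()).hexdigest()


def save_snapshot(
    state: MetacommunityState, path, provenance: Optional[dict] = None
) -> str:
    """Write a snapshot file; returns its content hash."""
    payload = state_to_dict(state, provenance)
    payload["hash"] = _hash_payload(payload)
    Path(path).write_text(_canonical(payload))
    return payload["hash"]


def state_from_dict(payload: dict) -> MetacommunityState:
    try:
        version = payload["format_version"]
    except KeyError as exc:
        raise SnapshotFormatError("missing format_version") from exc
    if version > FORMAT_VERSION:
        raise SnapshotFormatError(
            f"snapshot format {version} is newer than supported {FORMAT_VERSION}"
        )
    try:
        params = ModelParams(**payload["params"])
    except (KeyError, TypeError) as exc:
        raise SnapshotFormatError(f"bad params section: {exc}") from exc
    try:
        lat_d = payload["lattice"]
        lattice = Lattice(lat_d["rows"], lat_d["cols"])
        lattice.active = np.array(lat_d["active"], dtype=bool)
        lattice.resource_of = np.array(lat_d["resource_of"], dtype=np.int64)
    except (KeyError, TypeError) as exc:
        raise SnapshotFormatError(f"bad lattice section: {exc}") from exc
    try:
        species = [
            Species(
                id=d["id"],
                traits=frozenset(d["traits"]),
                bodysize=d["bodysize"],
                is_resource=d["is_resource"],
                parent_id=d["parent_id"],
                birth_step=d["birth_step"],
            )
            for d in payload["species"]
        ]
    except (KeyError, TypeError) as exc:
        raise SnapshotFormatError(f"bad species section: {exc}") from exc
    try:
        beta = np.array(payload["beta"], dtype=float)
        N = np.array(payload["N"], dtype=float)
        N_prev = np.array(payload["N_prev"], dtype=float)
    except (KeyError, ValueError) as exc:
        raise SnapshotFormatError(f"bad array section: {exc}") from exc
    try:
        rng_state = payload["rng"]
        bg = getattr(np.random, rng_state["bit_generator"])()
        bg.state = rng_state
        rng = np.random.Generator(bg)
    except (KeyError, AttributeError, TypeError) as exc:
        raise SnapshotFormatError(f"bad rng section: {exc}") from exc
    state = MetacommunityState(params, lattice, species, beta, N, rng)
    state.N_prev = N_prev
    state.evo_step = int(payload.get("evo_step", 0))
    state.eco_step = int(payload.get("eco_step", 0))
    return state


def load_snapshot(path) -> MetacommunityState:
    text = Path(path).read_text()
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SnapshotFormatError(f"not valid JSON (truncated?): {exc}") from exc
    if not isinstance(payload, dict):
        raise SnapshotFormatError("snapshot root must be a JSON object")
    stored = payload.get("hash")
    if stored is not None and stored != _hash_payload(payload):
        raise SnapshotFormatError("content hash mismatch: file corrupt")
    return state_from_dict(payload)


# -- run configuration ---------------------------------------------------------


@dataclass
class RunConfig:
    """Structured configuration bundling every knob of a run.

    Round-trips through YAML; unknown keys are rejected so a typo cannot
    silently fall back to a default.
    """

    params: ModelParams = field(default_factory=ModelParams)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    relax_steps: int = 100

    def to_dict(self) -> dict:
        return {
            "params": dataclasses.asdict(self.params),
            "assembly": dataclasses.asdict(self.assembly),
            "relax_steps": self.relax_steps,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"params", "assembly", "relax_steps"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        params_d = dict(data.get("params", {}))
        bad = set(params_d) - {f.name for f in dataclasses.fields(ModelParams)}
        if bad:
            raise ValueError(f"unknown params keys: {sorted(bad)}")
        asm_d = dict(data.get("assembly", {}))
        bad = set(asm_d) - {f.name for f in dataclasses.fields(AssemblyConfig)}
        if bad:
            raise ValueError(f"unknown assembly keys: {sorted(bad)}")
        return cls(
            params=ModelParams(**params_d),
            assembly=AssemblyConfig(**asm_d),
            relax_steps=int(data.get("relax_steps", 100)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# -- fixtures ------------------------------------------------------------------

FIXTURE_NAMES = (
    "single-patch-chain",
    "two-patch-subsidy",
    "grid-3x3-seeded",
    "invasion-playground",
)


def _block_beta(pool: int, blocks) -> np.ndarray:
    """Hand-set antisymmetric score matrix from (rows, cols, value) blocks."""
    beta = np.zeros((pool, pool))
    for rows, cols, value in blocks:
        for a in rows:
            for b in cols:
                beta[a, b] = value
                beta[b, a] = -value
    return beta


def make_fixture(name: str) -> MetacommunityState:
    """Deterministic tiny meta-communities for tests and examples.

    * ``single-patch-chain`` — one patch, resource -> A -> B with a hand-set
      score matrix guaranteeing the chain (B cannot feed on the resource).
    * ``two-patch-subsidy`` — source-sink pair: the consumer is
      self-sustaining in patch (1,1) and persists in patch (1,2) only
      through immigration subsidy.
    * ``grid-3x3-seeded`` — small assembled state at a fixed seed.
    * ``invasion-playground`` — empty 6x6 resources-only meta-network.
    """
    if name == "single-patch-chain":
        params = ModelParams(trait_pool_size=30)
        r_tr, a_tr, b_tr = range(0, 10), range(10, 20), range(20, 30)
        beta = _block_beta(
            30,
            [
                (a_tr, r_tr, 0.05),   # A feeds on the resource
                (b_tr, a_tr, 0.05),   # B feeds on A
                (r_tr, b_tr, 0.05),   # i.e. B's pair-sum on the resource < 0
            ],
        )
        lattice = Lattice(1, 1)
        lattice.resource_of[0] = 0
        species = [
            Species(0, frozenset(r_tr), 1.0, is_resource=True),
            Species(1, frozenset(a_tr), np.e),
            Species(2, frozenset(b_tr), np.e**4),
        ]
        N = np.array([[params.resource_abundance], [3000.0], [20.0]])
        return MetacommunityState(
            params, lattice, species, beta, N, np.random.default_rng(1)
        )
    if name == "two-patch-subsidy":
        params = ModelParams(trait_pool_size=30)
        r0_tr, r1_tr, c_tr = range(0, 10), range(10, 20), range(20, 30)
        beta = _block_beta(
            30,
            [
                (c_tr, r0_tr, 0.05),  # consumer feeds on resource of patch (1,1)
                (r1_tr, c_tr, 0.05),  # but cannot feed on resource of patch (1,2)
            ],
        )
        lattice = Lattice(1, 2)
        lattice.resource_of[:] = (0, 1)
        species = [
            Species(0, frozenset(r0_tr), 1.0, is_resource=True),
            Species(1, frozenset(r1_tr), 1.0, is_resource=True),
            Species(2, frozenset(c_tr), np.e),
        ]
        R = params.resource_abundance
        N = np.array([[R, 0.0], [0.0, R], [7000.0, 40.0]])
        return MetacommunityState(
            params, lattice, species, beta, N, np.random.default_rng(2)
        )
    if name == "grid-3x3-seeded":
        params = ModelParams(foraging_iters_per_eco=50)
        config = AssemblyConfig(
            rows=3, cols=3, evo_steps=30, eco_steps_per_evo=5, seed=1234
        )
        return assemble(config, params)
    if name == "invasion-playground":
        params = ModelParams()
        rng = np.random.default_rng(99)
        beta = generate_score_matrix(params.trait_pool_size, rng)
        lattice = Lattice(6, 6)
        species = []
        N = np.zeros((36, 36))
        for p in range(36):
            traits = frozenset(
                int(t) for t in rng.choice(params.trait_pool_size, 10, replace=False)
            )
            species.append(Species(p, traits, 1.0, is_resource=True))
            lattice.resource_of[p] = p
            N[p, p] = params.resource_abundance
        return MetacommunityState(params, lattice, species, beta, N, rng)
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
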