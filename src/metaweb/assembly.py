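"""Evolutionary assembly: speciation events interleaved with ecology.

A meta-community is grown from a single founder consumer and one randomly
drawn resource per patch.  Each evolutionary time step runs a block of
ecological time steps and then a speciation event: one local (species, patch)
population is chosen with probability proportional to population size, one
individual becomes the propagule of a child species inheriting nine of the
parent's ten traits with the tenth replaced, and a bodysize scaled by a
uniform factor in [0.8, 1.2].
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .core_model import ModelParams, Species, feeding_score, generate_score_matrix
from .dynamics import Lattice, MetacommunityState, run_ecology

__all__ = [
    "AssemblyConfig",
    "initialize_metacommunity",
    "select_parent",
    "speciation_event",
    "assemble",
]

logger = logging.getLogger(__name__)


@dataclass
class AssemblyConfig:
    """Loop lengths, grid shape and randomness for one assembly run."""

    rows: int = 6
    cols: int = 6
    evo_steps: int = 10_000
    eco_steps_per_evo: int = 1000
    seed: int = 0
    mutation_lo: float = 0.8
    mutation_hi: float = 1.2
    log_every: int = 0  # 0 disables progress logging

    def __post_init__(self) -> None:
        if self.evo_steps < 1 or self.eco_steps_per_evo < 1:
            raise ValueError("loop lengths must be >= 1")
        if not (0 < self.mutation_lo < self.mutation_hi):
            raise ValueError("mutation interval must satisfy 0 < lo < hi")


def _draw_traits(params: ModelParams, rng: np.random.Generator) -> frozenset:
    return frozenset(
        int(t)
        for t in rng.choice(
            params.trait_pool_size, size=params.traits_per_species, replace=False
        )
    )


def initialize_metacommunity(
    params: ModelParams,
    rows: int = 6,
    cols: int = 6,
    rng: Optional[np.random.Generator] = None,
) -> MetacommunityState:
    """Fresh meta-community: score matrix, one resource per patch, founder.

    Resources get independent random trait sets, bodysize 1 and the fixed
    resource abundance in their home patch.  The founder consumer (bodysize
    s0 = e, population 1) starts in patch (1, 1); its trait set is redrawn
    until it can feed on that patch's resource, since a founder unable to do
    so is culled within one ecological step and no assembly takes place.
    """
    if rng is None:
        rng = np.random.default_rng()
    beta = generate_score_matrix(params.trait_pool_size, rng)
    lattice = Lattice(rows, cols)
    n_patches = lattice.n_patches
    species = []
    N = np.zeros((n_patches + 1, n_patches))
    for p in range(n_patches):
        res = Species(
            id=p,
            traits=_draw_traits(params, rng),
            bodysize=params.resource_bodysize,
            is_resource=True,
        )
        species.append(res)
        lattice.resource_of[p] = p
        N[p, p] = params.resource_abundance
    home = lattice.index((1, 1))
    home_resource = species[home]
    for _ in range(10_000):
        founder = Species(
            id=n_patches,
            traits=_draw_traits(params, rng),
            bodysize=params.founder_bodysize,
        )
        if feeding_score(founder, home_resource, beta, params) > 0:
            break
    else:  # pragma: no cover - probability ~2^-10000
        raise RuntimeError("could not draw a founder able to feed in patch (1,1)")
    species.append(founder)
    N[n_patches, home] = 1.0
    return MetacommunityState(params, lattice, species, beta, N, rng)


def select_parent(
    state: MetacommunityState, rng: Optional[np.random.Generator] = None
) -> Optional[Tuple[int, int]]:
    """Pick a (species row, patch index) pair proportional to population.

    Eligible pairs are local non-resource populations of at least one
    individual.  Returns None when the meta-community holds no consumers.
    """
    if rng is None:
        rng = state.rng
    W = state.N.copy()
    W[state.is_resource, :] = 0.0
    W[W < 1.0] = 0.0
    total = W.sum()
    if total == 0.0:
        return None
    flat = rng.choice(W.size, p=(W / total).ravel())
    return int(flat // W.shape[1]), int(flat % W.shape[1])


def speciation_event(
    state: MetacommunityState,
    rng: Optional[np.random.Generator] = None,
    mutation_lo: float = 0.8,
    mutation_hi: float = 1.2,
) -> MetacommunityState:
    """One speciation: parent loses one individual, child gains one.

    The child keeps nine parent traits; the dropped trait is replaced by a
    trait outside the parent's set (so child and parent share exactly nine
    traits and the replacement differs from the discarded trait).  Total
    population is conserved at the event.
    """
    if rng is None:
        rng = state.rng
    picked = select_parent(state, rng)
    if picked is None:
        logger.warning("speciation skipped: no eligible parent (meta-community extinct)")
        return state
    row, p = picked
    parent = state.species[row]
    dropped = int(rng.choice(sorted(parent.traits)))
    pool = np.setdiff1d(
        np.arange(state.params.trait_pool_size), sorted(parent.traits)
    )
    new_trait = int(rng.choice(pool))
    child_traits = (parent.traits - {dropped}) | {new_trait}
    factor = rng.uniform(mutation_lo, mutation_hi)
    child = Species(
        id=max(sp.id for sp in state.species) + 1,
        traits=child_traits,
        bodysize=parent.bodysize * factor,
        parent_id=parent.id,
        birth_step=state.evo_step,
    )
    state.N[row, p] -= 1.0
    state.add_species(child, p, 1.0)
    return state


def assemble(
    config: AssemblyConfig, params: Optional[ModelParams] = None
) -> MetacommunityState:
    """Assemble a meta-community: ecology and speciation for ``evo_steps``.

    Fully reproducible from ``config.seed``; the per-evolutionary-step global
    diversity is recorded in ``state.diversity_log``.
    """
    if params is None:
        params = ModelParams()
    rng = np.random.default_rng(config.seed)
    state = initialize_metacommunity(params, config.rows, config.cols, rng)
    for step in range(config.evo_steps):
        state.evo_step = step
        run_ecology(state, config.eco_steps_per_evo, params)
        speciation_event(state, rng, config.mutation_lo, config.mutation_hi)
        if config.log_every and (step + 1) % config.log_every == 0:
            logger.info(
                "evo step %d/%d: diversity=%d consumers=%d",
                step + 1,
                config.evo_steps,
                state.global_diversity(),
                state.consumer_diversity(),
            )
    state.evo_step = config.evo_steps
    return state
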