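"""Perturbation experiments on assembled meta-communities.

Four families of in-silico experiment, all on snapshot copies so the source
state is never altered:

* **species deletion** — zero every local population of one species, relax
  the ecology, count secondary extinctions;
* **whole-network invasion** — after deletion, reintroduce the species to
  every live patch with a minimal population (1.0) and count the patches it
  holds after relaxation, plus random-species baselines;
* **single patch disruption** — temporary (pulse) or permanent (press)
  removal, with residents either eliminated or displaced evenly into the
  adjacent patches;
* **sequential disruption** — long sequences of patch perturbations with up
  to six patches designated as reserves exempt from direct perturbation,
  under fixed or state-dependent reserve placement schemes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core_model import ModelParams, Species, generate_score_matrix
from .dynamics import MetacommunityState, Patch, relax_ecology
from .metrics import _species_range

__all__ = [
    "PerturbationRecord",
    "ReserveScheme",
    "SequencePlan",
    "SequenceResult",
    "delete_species",
    "reintroduce_everywhere",
    "generate_random_species",
    "perturb_patch",
    "displacement_vs_elimination_differential",
    "resolve_reserves",
    "reserve_boundary_edges",
    "isolated_reserve_interior",
    "named_reserve_schemes",
    "run_sequence",
    "enumerate_experiment_plan",
    "consumption_probability",
    "expected_disconnected_invasions",
]

logger = logging.getLogger(__name__)


@dataclass
class PerturbationRecord:
    kind: str  # species-delete | species-invade | patch
    target: object
    mode: Optional[str] = None  # patches: "temporary-eliminate" etc.
    secondary_extinctions: int = 0
    relative_secondary_extinctions: float = 0.0
    patches_invaded: Optional[int] = None
    diversity_before: int = 0
    diversity_after: int = 0
    extra: Dict[str, float] = field(default_factory=dict)


def _extant_consumers(state: MetacommunityState) -> Set[int]:
    mask = state.extant_mask() & ~state.is_resource
    return {state.species[row].id for row in np.flatnonzero(mask)}


# -- species-level experiments -------------------------------------------------


def delete_species(
    state: MetacommunityState,
    species_id: int,
    relax_steps: int = 100,
    return_state: bool = False,
):
    """Primary extinction of one species; count the knock-on losses.

    Works on a snapshot copy: zeroes every local population of the species,
    relaxes the ecology, and counts previously extant consumers (other than
    the primary) extinct at the end.  The source state is untouched.
    """
    row = state.index_of(species_id)
    if state.species[row].is_resource:
        raise ValueError("cannot delete a resource species")
    before = _extant_consumers(state)
    work = state.copy()
    if species_id not in before:
        record = PerturbationRecord(
            "species-delete", species_id,
            diversity_before=state.global_diversity(),
            diversity_after=state.global_diversity(),
        )
        return (record, work) if return_state else record
    work.N[row, :] = 0.0
    relax_ecology(work, relax_steps)
    after = _extant_consumers(work)
    lost = before - after - {species_id}
    denom = len(before) - 1
    record = PerturbationRecord(
        "species-delete",
        species_id,
        secondary_extinctions=len(lost),
        relative_secondary_extinctions=len(lost) / denom if denom else 0.0,
        diversity_before=state.global_diversity(),
        diversity_after=work.global_diversity(),
    )
    return (record, work) if return_state else record


def reintroduce_everywhere(
    state: MetacommunityState,
    species_id: int,
    intro_pop: float = 1.0,
    relax_steps: int = 100,
) -> PerturbationRecord:
    """Introduce a species to every live patch with a minimal population.

    Intended to follow :func:`delete_species` on the same copy (the
    deletion-then-reintroduction protocol); mutates ``state``.  Records the
    number of live patches held with population >= 1 after relaxation and
    the secondary extinctions among the other consumers.
    """
    row = state.index_of(species_id)
    before = _extant_consumers(state) - {species_id}
    div_before = state.global_diversity()
    for p in state.lattice.live_indices():
        state.N[row, p] = intro_pop
    relax_ecology(state, relax_steps)
    after = _extant_consumers(state)
    lost = before - after
    invaded = int(
        (state.N[row, state.lattice.live_indices()] >= 1.0).sum()
    )
    return PerturbationRecord(
        "species-invade",
        species_id,
        secondary_extinctions=len(lost),
        relative_secondary_extinctions=len(lost) / len(before) if before else 0.0,
        patches_invaded=invaded,
        diversity_before=div_before,
        diversity_after=state.global_diversity(),
    )


def generate_random_species(
    n: int,
    bodysize_dist: Tuple,
    rng: np.random.Generator,
    params: Optional[ModelParams] = None,
    start_id: int = 0,
) -> List[Species]:
    """Random invader species with 10 random distinct traits each.

    ``bodysize_dist`` is ``("uniform", lo, hi)`` or
    ``("empirical", samples)`` (bodysizes resampled with replacement from an
    observed list, to control for bodysize distribution).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if params is None:
        params = ModelParams()
    kind = bodysize_dist[0]
    if kind == "uniform":
        _, lo, hi = bodysize_dist
        sizes = rng.uniform(lo, hi, size=n)
    elif kind == "empirical":
        samples = np.asarray(bodysize_dist[1], dtype=float)
        if samples.size == 0:
            raise ValueError("empirical bodysize resampling needs a non-empty list")
        sizes = rng.choice(samples, size=n, replace=True)
    else:
        raise ValueError(f"unknown bodysize distribution {kind!r}")
    out = []
    for k in range(n):
        traits = frozenset(
            int(t)
            for t in rng.choice(
                params.trait_pool_size, size=params.traits_per_species, replace=False
            )
        )
        out.append(Species(id=start_id + k, traits=traits, bodysize=float(sizes[k])))
    return out


# -- patch-level experiments ---------------------------------------------------


def _apply_patch_perturbation(
    state: MetacommunityState,
    patch: Patch,
    permanence: str,
    fate: str,
) -> None:
    """Mutate ``state`` with one patch perturbation (no relaxation)."""
    if permanence not in ("temporary", "permanent"):
        raise ValueError(f"unknown permanence {permanence!r}")
    if fate not in ("eliminate", "displace"):
        raise ValueError(f"unknown fate {fate!r}")
    lat = state.lattice
    p = lat.index(patch)
    if not lat.active[p]:
        raise ValueError(f"patch {patch} is not live")
    cons = ~state.is_resource
    if fate == "displace":
        nbrs = lat.neighbors(p)
        if not nbrs:
            logger.warning(
                "displacement from isolated patch %s falls back to elimination", patch
            )
        else:
            share = state.N[cons, p] / len(nbrs)
            for q in nbrs:
                state.N[cons, q] += share
    state.N[cons, p] = 0.0
    if permanence == "permanent":
        res = lat.resource_of[p]
        if res >= 0:
            state.N[res, :] = 0.0
        lat.remove_patch(patch)
        state.N[:, p] = 0.0


def _residency_bookkeeping(
    state: MetacommunityState, patch: Patch
) -> Dict[str, float]:
    """Unique-resident / unique-neighbour counts before a perturbation."""
    lat = state.lattice
    p = lat.index(patch)
    cons = ~state.is_resource
    resident = np.flatnonzero((state.N[:, p] > 0) & cons)
    nbrs = lat.neighbors(p)
    nbr_rows = (
        np.flatnonzero((state.N[:, nbrs] > 0).any(axis=1) & cons)
        if nbrs
        else np.array([], dtype=int)
    )
    elsewhere = state.N.copy()
    elsewhere[:, p] = 0.0
    unique_res = [r for r in resident if elsewhere[r].sum() == 0]
    not_in_patch = set(nbr_rows) - set(resident)
    return {
        "n_residents": float(len(resident)),
        "n_unique_residents": float(len(unique_res)),
        "n_neighbour_species": float(len(nbr_rows)),
        "n_unique_neighbours": float(len(not_in_patch)),
        "degree": float(len(nbrs)),
    }


def perturb_patch(
    state: MetacommunityState,
    patch: Patch,
    permanence: str,
    fate: str,
    relax_steps: int = 100,
    return_state: bool = False,
):
    """One pulse/press patch perturbation on a snapshot copy.

    ``eliminate`` zeroes the patch's non-resource populations; ``displace``
    first splits each resident population evenly over the live neighbours
    (merging with conspecifics already there).  ``permanent`` additionally
    removes the patch and its resource from the lattice; ``temporary``
    leaves the patch open to immediate recolonization.
    """
    before = _extant_consumers(state)
    div_before = state.global_diversity()
    book = _residency_bookkeeping(state, patch)
    work = state.copy()
    _apply_patch_perturbation(work, patch, permanence, fate)
    relax_ecology(work, relax_steps)
    after = _extant_consumers(work)
    lost = before - after
    record = PerturbationRecord(
        "patch",
        patch,
        mode=f"{permanence}-{fate}",
        secondary_extinctions=len(lost),
        relative_secondary_extinctions=len(lost) / len(before) if before else 0.0,
        diversity_before=div_before,
        diversity_after=work.global_diversity(),
        extra=book,
    )
    return (record, work) if return_state else record


def displacement_vs_elimination_differential(
    state: MetacommunityState,
    patch: Patch,
    permanence: str,
    relax_steps: int = 100,
) -> float:
    """Relative diversity change under displacement minus under elimination.

    Both fates start from the same snapshot; a positive value means
    re-settling the residents in neighbouring patches preserves more global
    diversity than eliminating them.
    """
    div0 = state.global_diversity()
    rec_d = perturb_patch(state, patch, permanence, "displace", relax_steps)
    rec_e = perturb_patch(state, patch, permanence, "eliminate", relax_steps)
    return (rec_d.diversity_after - rec_e.diversity_after) / div0


# -- reserves ------------------------------------------------------------------


@dataclass
class ReserveScheme:
    """Reserve placement rule; ``patches`` resolved once on the initial state."""

    name: str
    selector: str = "fixed"  # fixed | highest-diversity | lowest-average-range
    patches: Optional[Tuple[Patch, ...]] = None
    n_reserves: int = 6


_REMOTE_BLOCK = ((1, 1), (1, 2), (1, 3), (2, 1), (2, 2), (2, 3))
_CENTRAL_BLOCK = ((3, 3), (3, 4), (3, 5), (4, 3), (4, 4), (4, 5))
_MAX_DISPERSAL = ((2, 2), (2, 5), (5, 2), (5, 5), (1, 1), (6, 6))


def named_reserve_schemes() -> Dict[str, ReserveScheme]:
    """Shipped placement schemes for the 6x6 lattice.

    ``none`` is the no-reserve control; ``remote-block`` is the 2x3 corner
    block (5 boundary edges, fully isolating patches (1,1) and (1,2));
    ``central-block`` a fully interior 2x3 block (10 boundary edges);
    ``max-dispersal-individuals`` six pairwise non-adjacent patches of summed
    degree 20; plus the two state-dependent selectors.
    """
    return {
        "none": ReserveScheme("none", "fixed", (), 0),
        "remote-block": ReserveScheme("remote-block", "fixed", _REMOTE_BLOCK),
        "central-block": ReserveScheme("central-block", "fixed", _CENTRAL_BLOCK),
        "max-dispersal-individuals": ReserveScheme(
            "max-dispersal-individuals", "fixed", _MAX_DISPERSAL
        ),
        "highest-diversity": ReserveScheme("highest-diversity", "highest-diversity"),
        "lowest-average-range": ReserveScheme(
            "lowest-average-range", "lowest-average-range"
        ),
    }


def resolve_reserves(
    state: MetacommunityState, scheme: ReserveScheme
) -> Tuple[Patch, ...]:
    """Resolve a scheme to concrete reserve patches on the given state.

    State-dependent selectors (highest local diversity, lowest average
    resident range) are evaluated once, with deterministic row-major
    tie-breaking.
    """
    lat = state.lattice
    live = lat.live_indices()
    if scheme.selector == "fixed":
        patches = tuple(scheme.patches or ())
        for patch in patches:
            if not lat.is_live(patch):
                raise ValueError(f"reserve {patch} is not a live patch")
        if len(patches) != scheme.n_reserves:
            raise ValueError(
                f"scheme {scheme.name!r} must name {scheme.n_reserves} reserves"
            )
        return patches
    if len(live) < scheme.n_reserves:
        raise ValueError("fewer live patches than reserves")
    if scheme.selector == "highest-diversity":
        keys = [
            (-state.local_diversity(lat.coord(p)), lat.coord(p)) for p in live
        ]
    elif scheme.selector == "lowest-average-range":
        ranges = _species_range(state)
        keys = []
        for p in live:
            present = state.present_in(p)
            cons = present[~state.is_resource[present]]
            avg = float(ranges[cons].mean()) if len(cons) else math.inf
            keys.append((avg, lat.coord(p)))
    else:
        raise ValueError(f"unknown selector {scheme.selector!r}")
    keys.sort()
    return tuple(coord for _, coord in keys[: scheme.n_reserves])


def reserve_boundary_edges(
    state: MetacommunityState, patches: Sequence[Patch]
) -> int:
    """Number of lattice edges joining a reserve to a non-reserve patch."""
    lat = state.lattice
    inside = {lat.index(patch) for patch in patches}
    edges = 0
    for p in inside:
        for q in lat.neighbors(p):
            if q not in inside:
                edges += 1
    return edges


def isolated_reserve_interior(
    state: MetacommunityState, patches: Sequence[Patch]
) -> Tuple[Patch, ...]:
    """Reserve patches all of whose live neighbours are also reserves."""
    lat = state.lattice
    inside = {lat.index(patch) for patch in patches}
    out = [
        lat.coord(p)
        for p in sorted(inside)
        if all(q in inside for q in lat.neighbors(p))
    ]
    return tuple(out)


# -- sequential disruption -----------------------------------------------------


@dataclass
class SequencePlan:
    permanence: str  # temporary | permanent
    fate: str  # eliminate | displace
    scheme: ReserveScheme
    target_rule: str = "random"  # targeted-highest-diversity | random
    n_events: Optional[int] = None  # default: 1000 temporary / 30 (36) permanent
    replicate: int = 0
    seed: int = 0


@dataclass
class SequenceResult:
    plan: SequencePlan
    reserves: Tuple[Patch, ...]
    diversity_series: List[int]
    final_relative_diversity: float
    events_executed: int
    status: str = "completed"


def _default_event_count(permanence: str, n_reserves: int, lattice_size: int) -> int:
    if permanence == "temporary":
        return 1000
    return lattice_size - n_reserves  # 30 with six reserves on 6x6, 36 without


def run_sequence(
    state: MetacommunityState,
    plan: SequencePlan,
    relax_steps: int = 100,
) -> SequenceResult:
    """Sequence of patch perturbations with reserves exempted.

    Temporary sequences may hit a patch repeatedly (default 1000 events);
    permanent sequences destroy every non-reserve patch once (30 with six
    reserves on the 6x6 grid, 36 without).  The target rule either picks the
    currently highest-diversity eligible patch (row-major tie-break) or draws
    uniformly at random.  Runs on a copy with ``relax_steps`` of ecology
    between events.
    """
    work = state.copy()
    reserves = resolve_reserves(state, plan.scheme)
    reserve_idx = {work.lattice.index(patch) for patch in reserves}
    rng = np.random.default_rng(plan.seed)
    n_events = plan.n_events
    if n_events is None:
        n_events = _default_event_count(
            plan.permanence, len(reserves), len(state.lattice.live_indices())
        )
    div0 = work.global_diversity()
    series: List[int] = []
    status = "completed"
    executed = 0
    for _ in range(n_events):
        eligible = [
            p for p in work.lattice.live_indices() if p not in reserve_idx
        ]
        if not eligible:
            status = "exhausted"
            break
        if plan.target_rule == "targeted-highest-diversity":
            target = min(
                eligible,
                key=lambda p: (
                    -work.local_diversity(work.lattice.coord(p)),
                    work.lattice.coord(p),
                ),
            )
        elif plan.target_rule == "random":
            target = int(eligible[rng.integers(len(eligible))])
        else:
            raise ValueError(f"unknown target rule {plan.target_rule!r}")
        _apply_patch_perturbation(
            work, work.lattice.coord(target), plan.permanence, plan.fate
        )
        relax_ecology(work, relax_steps)
        executed += 1
        series.append(work.global_diversity())
    final = series[-1] if series else div0
    return SequenceResult(
        plan=plan,
        reserves=reserves,
        diversity_series=series,
        final_relative_diversity=final / div0 if div0 else 0.0,
        events_executed=executed,
        status=status,
    )


# -- invasion analytics --------------------------------------------------------


def _trait_pair_sums(
    beta: np.ndarray,
    species_traits: np.ndarray,
    resource_traits: np.ndarray,
) -> np.ndarray:
    """Trait-pair score sums of one species against many resources."""
    col_sums = beta[species_traits].sum(axis=0)
    return col_sums[resource_traits].sum(axis=1)


def consumption_probability(
    n_draws: int,
    params: Optional[ModelParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """Monte-Carlo P(random species has S > 0 on a random resource).

    Each draw uses an independent score matrix, species trait set and
    resource trait set.  The antisymmetric construction makes the trait-pair
    sum symmetric about zero, so the probability is 1/2.  Returns
    (estimate, binomial standard error).
    """
    if params is None:
        params = ModelParams()
    if rng is None:
        rng = np.random.default_rng()
    pool, k = params.trait_pool_size, params.traits_per_species
    hits = 0
    for _ in range(n_draws):
        beta = generate_score_matrix(pool, rng)
        traits = rng.random((2, pool)).argsort(axis=1)[:, :k]
        if _trait_pair_sums(beta, traits[0], traits[1:])[0] > 0:
            hits += 1
    p = hits / n_draws
    return p, math.sqrt(p * (1.0 - p) / n_draws)


def expected_disconnected_invasions(
    n_draws: int,
    n_patches: int = 36,
    params: Optional[ModelParams] = None,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[float, float]:
    """Monte-Carlo expected number of patches a random species can invade in
    a fully disconnected resource-only meta-network.

    With dispersal off, a patch is invadable iff the species has a positive
    feeding score on its (independent random) resource, so the count is
    Binomial(n_patches, 1/2) with mean n_patches / 2.  Returns
    (mean estimate, standard error of the mean).
    """
    if params is None:
        params = ModelParams()
    if rng is None:
        rng = np.random.default_rng()
    pool, k = params.trait_pool_size, params.traits_per_species
    counts = np.empty(n_draws)
    for d in range(n_draws):
        beta = generate_score_matrix(pool, rng)
        draws = rng.random((1 + n_patches, pool)).argsort(axis=1)[:, :k]
        sums = _trait_pair_sums(beta, draws[0], draws[1:])
        counts[d] = (sums > 0).sum()
    return float(counts.mean()), float(counts.std(ddof=1) / math.sqrt(n_draws))


# -- experiment-plan combinatorics --------------------------------------------


def enumerate_experiment_plan(
    n_metacommunities: int = 15,
    n_schemes: int = 13,
    replicates: Tuple[int, int] = (1, 10),
    modes: Sequence[Tuple[str, str]] = (
        ("temporary", "eliminate"),
        ("temporary", "displace"),
        ("permanent", "eliminate"),
        ("permanent", "displace"),
    ),
    lattice_size: int = 36,
    n_reserves: int = 6,
    temporary_events: int = 1000,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Enumerate the full sequential-disruption design without running it.

    One scheme of the ``n_schemes`` is the no-reserve control (36 permanent
    events instead of 30); ``replicates`` is (targeted, random) sequence
    counts per cell.  Returns the per-sequence plan table and grand totals.
    """
    if n_metacommunities < 1 or n_schemes < 1:
        raise ValueError("counts must be >= 1")
    targeted, random_reps = replicates
    rows = []
    for mc in range(n_metacommunities):
        for permanence, fate in modes:
            for scheme in range(n_schemes):
                is_control = scheme == 0
                if permanence == "temporary":
                    events = temporary_events
                else:
                    events = lattice_size - (0 if is_control else n_reserves)
                for rep in range(targeted + random_reps):
                    rows.append(
                        {
                            "metacommunity": mc,
                            "permanence": permanence,
                            "fate": fate,
                            "scheme": "control" if is_control else f"scheme-{scheme}",
                            "rule": "targeted" if rep < targeted else "random",
                            "replicate": rep,
                            "n_events": events,
                        }
                    )
    table = pd.DataFrame(rows)
    totals = {
        "n_sequences": len(table),
        "n_events": int(table["n_events"].sum()),
    }
    return table, totals
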