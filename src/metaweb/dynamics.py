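"""One ecological time step on the patch lattice.

Order of operations per ecological step:

1. **Foraging fixed point** — in every live patch, all local consumers
   simultaneously iterate foraging efforts f (relative allocation over their
   local prey) and ratio-dependent functional responses g until the efforts
   converge.
2. **Allometric Euler update** — each local non-resource population takes one
   Euler step combining natural mortality (-2 s^-0.25 N), gain from feeding
   (lambda/s * N * sum_j g_ij s_j) and loss to predation (sum_k N_k g_ki).
3. **Dispersal** — a constant trickle (0.001 s/s0 of a local population per
   step, split evenly over adjacent patches) plus decline-triggered emigration
   of up to 0.03 s/s0 proportional to the relative loss since the end of the
   previous ecological step.  Movement requires a local population of at
   least one; resources never move.  Dispersal exactly conserves each
   species' global population.
4. **Culling** — local populations below the extinction threshold are
   removed; species with no population anywhere are globally extinct.

Patch resources are external, non-dynamic populations of fixed abundance held
in their home patch; they enter the foraging and growth equations as prey but
are never updated, never disperse, and vanish only with their patch.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core_model import (
    ModelParams,
    ScoreMatrix,
    Species,
    competition_matrix,
    feeding_matrix,
)

__all__ = [
    "Lattice",
    "MetacommunityState",
    "ForagingState",
    "foraging_equilibrium",
    "population_update",
    "total_emigration_rate",
    "emigration_fraction",
    "dispersal_step",
    "cull_step",
    "ecological_step",
    "run_ecology",
    "relax_ecology",
]

Patch = Tuple[int, int]  # 1-based (row, column), matching patch (1,1)..(6,6)


class Lattice:
    """Rectangular patch lattice with von-Neumann adjacency.

    Patches are addressed by 1-based (row, column) coordinates.  Adjacency is
    4-neighbour, no diagonals, no wrap-around, and only between *live*
    patches; the degree of a patch is its number of live neighbours (2-4 on a
    full grid, decreasing as patches are removed).  Each live patch owns
    exactly one resource species.
    """

    def __init__(self, rows: int, cols: int):
        if rows < 1 or cols < 1:
            raise ValueError("lattice must have at least one row and column")
        self.rows = rows
        self.cols = cols
        n = rows * cols
        self.active = np.ones(n, dtype=bool)
        self.resource_of = np.full(n, -1, dtype=np.int64)
        self._nbrs: Optional[List[List[int]]] = None

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols

    def index(self, patch: Patch) -> int:
        r, c = patch
        if not (1 <= r <= self.rows and 1 <= c <= self.cols):
            raise ValueError(f"patch {patch} outside {self.rows}x{self.cols} lattice")
        return (r - 1) * self.cols + (c - 1)

    def coord(self, p: int) -> Patch:
        return (p // self.cols + 1, p % self.cols + 1)

    def live_indices(self) -> np.ndarray:
        return np.flatnonzero(self.active)

    def is_live(self, patch: Patch) -> bool:
        return bool(self.active[self.index(patch)])

    def _rebuild_neighbors(self) -> None:
        nbrs: List[List[int]] = [[] for _ in range(self.n_patches)]
        for p in range(self.n_patches):
            if not self.active[p]:
                continue
            r, c = self.coord(p)
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 1 <= rr <= self.rows and 1 <= cc <= self.cols:
                    q = (rr - 1) * self.cols + (cc - 1)
                    if self.active[q]:
                        nbrs[p].append(q)
        self._nbrs = nbrs

    def neighbors(self, p: int) -> List[int]:
        """Live neighbours of live patch index ``p``."""
        if self._nbrs is None:
            self._rebuild_neighbors()
        return self._nbrs[p]

    def degree(self, p: int) -> int:
        return len(self.neighbors(p))

    def adjacency(self, p: int, q: int) -> int:
        """Adjacency indicator between live patches (1 or 0)."""
        return int(q in self.neighbors(p))

    def remove_patch(self, patch: Patch) -> None:
        p = self.index(patch)
        if not self.active[p]:
            raise ValueError(f"patch {patch} is not live")
        self.active[p] = False
        self._nbrs = None

    def is_full_rectangle(self) -> bool:
        return bool(self.active.all())

    def copy(self) -> "Lattice":
        lat = Lattice(self.rows, self.cols)
        lat.active = self.active.copy()
        lat.resource_of = self.resource_of.copy()
        return lat

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Lattice)
            and self.rows == other.rows
            and self.cols == other.cols
            and np.array_equal(self.active, other.active)
            and np.array_equal(self.resource_of, other.resource_of)
        )


@dataclass
class ForagingState:
    """Converged foraging efforts and functional responses for one patch.

    ``present`` maps local rows of ``f``/``g`` back to global species
    indices.  For every consumer with a non-empty local prey set the efforts
    sum to one; rows of species without prey (and all resources) are zero.
    """

    patch_index: int
    present: np.ndarray  # global species indices, local row order
    f: np.ndarray  # (n_local, n_local) efforts
    g: np.ndarray  # (n_local, n_local) functional responses
    iterations: int = 0


class MetacommunityState:
    """Full simulator state: species table, lattice, populations, rng.

    ``N[i, p]`` is the population of species ``i`` in patch index ``p``;
    ``N_prev`` holds the populations at the end of the previous ecological
    step (the reference point for decline-triggered dispersal).  Interaction
    matrices S (feeding scores) and alpha (competition) are cached dense and
    rebuilt whenever a species is added.
    """

    def __init__(
        self,
        params: ModelParams,
        lattice: Lattice,
        species: List[Species],
        beta: ScoreMatrix,
        N: np.ndarray,
        rng: np.random.Generator,
    ):
        self.params = params
        self.lattice = lattice
        self.species = list(species)
        self.beta = beta
        self.N = np.asarray(N, dtype=float)
        self.N_prev = self.N.copy()
        self.rng = rng
        self.evo_step = 0
        self.eco_step = 0
        self.diversity_log: List[Tuple[int, int, int, float]] = []
        self._rebuild_arrays()

    # -- species-table caches -------------------------------------------------

    def _rebuild_arrays(self) -> None:
        n = len(self.species)
        pool = self.params.trait_pool_size
        self.traits_mat = np.zeros((n, pool), dtype=np.int8)
        for row, sp in enumerate(self.species):
            self.traits_mat[row, sorted(sp.traits)] = 1
        self.bodysize = np.array([sp.bodysize for sp in self.species])
        self.is_resource = np.array([sp.is_resource for sp in self.species])
        self.S = feeding_matrix(
            self.traits_mat, self.bodysize, self.is_resource, self.beta, self.params
        )
        self.alpha = competition_matrix(self.traits_mat, self.bodysize, self.params)

    def add_species(self, sp: Species, patch_index: int, population: float) -> None:
        """Append a species row with ``population`` in one patch."""
        if any(s.id == sp.id for s in self.species):
            raise ValueError(f"species id {sp.id} already present")
        self.species.append(sp)
        zero = np.zeros((1, self.lattice.n_patches))
        self.N = np.vstack([self.N, zero])
        self.N_prev = np.vstack([self.N_prev, zero])
        self.N[-1, patch_index] = population
        self._rebuild_arrays()

    # -- queries --------------------------------------------------------------

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index_of(self, species_id: int) -> int:
        for row, sp in enumerate(self.species):
            if sp.id == species_id:
                return row
        raise KeyError(f"unknown species id {species_id}")

    def extant_mask(self) -> np.ndarray:
        return self.N.sum(axis=1) > 0

    def global_diversity(self) -> int:
        """Number of extant species, resources included."""
        return int(self.extant_mask().sum())

    def consumer_diversity(self) -> int:
        return int((self.extant_mask() & ~self.is_resource).sum())

    def present_in(self, p: int) -> np.ndarray:
        return np.flatnonzero(self.N[:, p] > 0)

    def local_diversity(self, patch: Patch) -> int:
        return int(len(self.present_in(self.lattice.index(patch))))

    def total_population(self) -> float:
        return float(self.N[~self.is_resource].sum())

    # -- copy / equality ------------------------------------------------------

    def copy(self) -> "MetacommunityState":
        new = MetacommunityState.__new__(MetacommunityState)
        new.params = self.params
        new.lattice = self.lattice.copy()
        new.species = list(self.species)
        new.beta = self.beta
        new.N = self.N.copy()
        new.N_prev = self.N_prev.copy()
        bg = type(self.rng.bit_generator)()
        bg.state = _copy.deepcopy(self.rng.bit_generator.state)
        new.rng = np.random.Generator(bg)
        new.evo_step = self.evo_step
        new.eco_step = self.eco_step
        new.diversity_log = list(self.diversity_log)
        new.traits_mat = self.traits_mat
        new.bodysize = self.bodysize
        new.is_resource = self.is_resource
        new.S = self.S
        new.alpha = self.alpha
        return new


# -- foraging -----------------------------------------------------------------


def foraging_equilibrium(
    state: MetacommunityState, patch: Patch, params: Optional[ModelParams] = None
) -> ForagingState:
    """Iterate efforts/responses to their fixed point in one patch.

    Starting from uniform efforts over each consumer's local prey set
    K_i = {j present, S_ij > 0}, alternately and synchronously applies

        g_ij = S_ij f_ij N_j / (c N_j + sum_k alpha_ik S_kj f_kj N_k)
        f_ij = g_ij / sum_{k in K_i} g_ik

    for up to ``foraging_iters_per_eco`` iterations, exiting early once the
    max absolute change in f drops below ``foraging_tol``.  Consumers with no
    local prey keep zero rows (they suffer mortality only).
    """
    if params is None:
        params = state.params
    p = patch if isinstance(patch, (int, np.integer)) else state.lattice.index(patch)
    if not state.lattice.active[p]:
        raise ValueError(f"patch {patch} is not live")
    present = state.present_in(p)
    return _forage_patch(state, p, present, params)


def _forage_patch(
    state: MetacommunityState,
    p: int,
    present: np.ndarray,
    params: ModelParams,
) -> ForagingState:
    n = len(present)
    if n == 0:
        empty = np.zeros((0, 0))
        return ForagingState(p, present, empty, empty, 0)
    Sl = state.S[np.ix_(present, present)]
    K = Sl > 0.0  # resource rows are all-zero already
    prey_counts = K.sum(axis=1)
    if not prey_counts.any():
        z = np.zeros((n, n))
        return ForagingState(p, present, z, z.copy(), 0)
    al = state.alpha[np.ix_(present, present)]
    Nl = state.N[present, p]
    sat = params.saturation

    f = np.where(K, 1.0 / np.maximum(prey_counts, 1)[:, None], 0.0)
    g = _g_from_f(Sl, al, Nl, K, f, sat)
    iters = 0
    for iters in range(1, params.foraging_iters_per_eco + 1):
        rows = g.sum(axis=1)
        f_new = np.divide(
            g, rows[:, None], out=np.zeros_like(g), where=rows[:, None] > 0
        )
        g = _g_from_f(Sl, al, Nl, K, f_new, sat)
        if np.max(np.abs(f_new - f)) < params.foraging_tol:
            f = f_new
            break
        f = f_new
    return ForagingState(p, present, f, g, iters)


def _g_from_f(Sl, al, Nl, K, f, sat):
    W = Sl * f * Nl[:, None]  # W[k, j] = S_kj f_kj N_k
    den = sat * Nl[None, :] + al @ W
    num = Sl * f * Nl[None, :]
    return np.divide(num, den, out=np.zeros_like(num), where=K & (den > 0))


# -- population dynamics ------------------------------------------------------


def population_update(
    state: MetacommunityState,
    forages: Sequence[ForagingState],
    params: Optional[ModelParams] = None,
) -> MetacommunityState:
    """One allometric Euler step for every local non-resource population.

    N <- N + dt * (-2 s^-0.25 N + lambda/s * N * sum_j g_ij s_j
                   - sum_k N_k g_ki),
    clamped below at zero.  Resource rows are untouched.
    """
    if params is None:
        params = state.params
    dt = params.delta_t
    lam = params.lambda_eff
    for fs in forages:
        present = fs.present
        if len(present) == 0:
            continue
        p = fs.patch_index
        Nl = state.N[present, p]
        s_l = state.bodysize[present]
        cons = ~state.is_resource[present]
        if fs.g.size:
            gain = lam / s_l * Nl * (fs.g @ s_l)
            loss = (Nl[:, None] * fs.g).sum(axis=0)
        else:
            gain = np.zeros_like(Nl)
            loss = np.zeros_like(Nl)
        mort = 2.0 * s_l ** -0.25 * Nl
        new = Nl + dt * (-mort + gain - loss)
        new = np.maximum(new, 0.0)
        out = np.where(cons, new, Nl)
        state.N[present, p] = out
    return state


# -- dispersal ----------------------------------------------------------------


def total_emigration_rate(
    bodysize: float, n_prev: float, n_now: float, params: ModelParams
) -> float:
    """Total fraction of a local population emigrating this step (all
    neighbours combined; the per-neighbour fraction divides by the degree).

    rate = (s/s0) * max(0.001, 0.03 * (N_prev - N)/N_prev)   if declining
           (s/s0) * 0.001                                     otherwise

    Zero below the movement threshold (a population of at least one is
    required for any movement).
    """
    if n_now < params.movement_threshold:
        return 0.0
    if n_prev > n_now and n_prev > 0:
        r = max(
            params.base_emigration,
            params.decline_emigration * (n_prev - n_now) / n_prev,
        )
    else:
        r = params.base_emigration
    return min(1.0, bodysize / params.founder_bodysize * r)


def emigration_fraction(
    i: Species,
    source: Patch,
    state: MetacommunityState,
    params: Optional[ModelParams] = None,
) -> float:
    """Per-neighbour emigration fraction mu of species ``i`` from ``source``."""
    if params is None:
        params = state.params
    p = state.lattice.index(source)
    D = state.lattice.degree(p)
    if D == 0:
        return 0.0
    row = state.index_of(i.id)
    rate = total_emigration_rate(
        i.bodysize, state.N_prev[row, p], state.N[row, p], params
    )
    return rate / D


def _emigration_rates(
    state: MetacommunityState, params: ModelParams
) -> np.ndarray:
    """Total emigration rate per (species, patch); zero for resources,
    sub-threshold populations and isolated patches."""
    N, Np = state.N, state.N_prev
    safe_prev = np.where(Np > 0, Np, 1.0)
    declining = (Np > N) & (Np > 0)
    r = np.where(
        declining,
        np.maximum(
            params.base_emigration,
            params.decline_emigration * (Np - N) / safe_prev,
        ),
        params.base_emigration,
    )
    r *= state.bodysize[:, None] / params.founder_bodysize
    np.minimum(r, 1.0, out=r)
    r[N < params.movement_threshold] = 0.0
    r[state.is_resource, :] = 0.0
    return r


def dispersal_step(
    state: MetacommunityState, params: Optional[ModelParams] = None
) -> MetacommunityState:
    """Simultaneous redistribution of all non-resource populations.

    Each emigrating population is split evenly over its patch's live
    neighbours; the per-species global population is exactly conserved.
    """
    if params is None:
        params = state.params
    lat = state.lattice
    live = lat.live_indices()
    rates = _emigration_rates(state, params)
    N_old = state.N
    new = N_old.copy()
    for p in live:
        nbrs = lat.neighbors(p)
        D = len(nbrs)
        if D == 0:
            continue
        out = rates[:, p] * N_old[:, p]
        new[:, p] -= out
        share = out / D
        for q in nbrs:
            new[:, q] += share
    state.N = new
    return state


# -- step drivers -------------------------------------------------------------


def cull_step(
    state: MetacommunityState, params: Optional[ModelParams] = None
) -> MetacommunityState:
    """Remove local non-resource populations below the extinction threshold."""
    if params is None:
        params = state.params
    cons = ~state.is_resource
    sub = state.N[cons]
    sub[sub < params.extinction_threshold] = 0.0
    state.N[cons] = sub
    return state


def ecological_step(
    state: MetacommunityState, params: Optional[ModelParams] = None
) -> MetacommunityState:
    """Foraging -> Euler update -> dispersal -> cull -> advance counters."""
    if params is None:
        params = state.params
    lat = state.lattice
    forages = []
    for p in lat.live_indices():
        present = state.present_in(p)
        if not (~state.is_resource[present]).any():
            continue  # resource-only patch: nothing to forage or update
        forages.append(_forage_patch(state, p, present, params))
    population_update(state, forages, params)
    dispersal_step(state, params)
    cull_step(state, params)
    state.N_prev = state.N.copy()
    state.eco_step += 1
    return state


def run_ecology(
    state: MetacommunityState, n_steps: int, params: Optional[ModelParams] = None
) -> MetacommunityState:
    """Apply ``n_steps`` ecological steps, logging the diversity series."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    for _ in range(n_steps):
        ecological_step(state, params)
        state.diversity_log.append(
            (
                state.evo_step,
                state.eco_step,
                state.global_diversity(),
                state.total_population(),
            )
        )
    return state


def relax_ecology(
    state: MetacommunityState,
    max_steps: int,
    rel_tol: float = 1.0e-4,
    params: Optional[ModelParams] = None,
) -> int:
    """Run ecological steps until populations settle or ``max_steps`` hit.

    Convergence: max over (species, patch) of |dN| / max(N, 1) below
    ``rel_tol``.  Returns the number of steps executed.
    """
    steps = 0
    for steps in range(1, max_steps + 1):
        before = state.N.copy()
        ecological_step(state, params)
        denom = np.maximum(before, 1.0)
        if np.max(np.abs(state.N - before) / denom) < rel_tol:
            break
    return steps
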