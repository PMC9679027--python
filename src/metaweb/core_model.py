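"""Trait pool, score matrix, species, and the two interaction kernels.

The model describes species by a set of 10 discrete traits drawn from a pool
of 500 plus a single continuous bodysize.  All trophic interactions derive
from an antisymmetric matrix ``beta`` of pairwise trait scores:

* the *feeding score* of consumer ``i`` on prey ``j`` is the clipped sum of
  the 100 trait-pair scores, weighted by a Gaussian feeding window in
  log-bodysize difference centred three log-units below the consumer;
* the *competition coefficient* between two consumers sharing a prey grows
  linearly with the number of shared traits and decays with the squared
  log-bodysize difference, so intraspecific competition is always strongest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "ModelParams",
    "Species",
    "ScoreMatrix",
    "generate_score_matrix",
    "shared_traits",
    "trait_pair_sum",
    "feeding_score",
    "competition_coefficient",
    "feeding_matrix",
    "competition_matrix",
]

#: A score matrix is a plain square ndarray with beta + beta.T == 0.
ScoreMatrix = np.ndarray

_SQRT_2PI = math.sqrt(2.0 * math.pi)

#: Trait-pair sums smaller than this are treated as exact zero.  In real
#: arithmetic the sum of a species' scores against itself cancels exactly by
#: antisymmetry; floating summation leaves O(1e-14) residues that would
#: otherwise create spurious feeding links.  Genuine pair sums this small
#: occur with probability ~1e-13.
PAIR_SUM_TOLERANCE = 1.0e-12


@dataclass
class ModelParams:
    """All tunable constants of the simulator.

    Defaults are the standard parameterisation of this model family:
    ecological efficiency
    ``lambda_eff`` = 0.3, Euler step ``delta_t`` = 0.1, competition kernel
    (a1, a2, a3) = (0.866, 0.6/a1, 0.6*sqrt(2*pi)), feeding kernel
    (b1, b2) = (1/(1.5*sqrt(2*pi)), 2*1.5**2), ratio-dependent saturation
    constant 0.005, base/decline emigration rates 0.001/0.03, founder
    bodysize e, resource bodysize 1.

    ``resource_abundance`` is the fixed external population of each patch
    resource; it is never stated in the source model family and calibrates
    all population magnitudes (see docs/methods.md).
    """

    trait_pool_size: int = 500
    traits_per_species: int = 10
    lambda_eff: float = 0.3
    delta_t: float = 0.1
    a1: float = 0.866
    a2: float = 0.6 / 0.866
    a3: float = 0.6 * _SQRT_2PI
    b1: float = 1.0 / (1.5 * _SQRT_2PI)
    b2: float = 2.0 * 1.5**2
    saturation: float = 0.005
    base_emigration: float = 0.001
    decline_emigration: float = 0.03
    founder_bodysize: float = math.e
    resource_bodysize: float = 1.0
    resource_abundance: float = 1.0e5
    extinction_threshold: float = 1.0
    movement_threshold: float = 1.0
    evo_steps: int = 10_000
    eco_steps_per_evo: int = 1000
    foraging_iters_per_eco: int = 1000
    foraging_tol: float = 1.0e-8
    link_effort_threshold: float = 0.01

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.trait_pool_size < 2:
            raise ValueError("trait_pool_size must be >= 2")
        if not (0 < self.traits_per_species <= self.trait_pool_size):
            raise ValueError("traits_per_species must be in 1..trait_pool_size")
        if not (0.0 < self.lambda_eff <= 1.0):
            raise ValueError("lambda_eff must lie in (0, 1]")
        for name in (
            "delta_t", "a1", "a3", "b1", "b2", "saturation",
            "base_emigration", "decline_emigration", "founder_bodysize",
            "resource_bodysize", "resource_abundance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.a1 * self.a2 - 0.6) > 1e-9:
            raise ValueError("competition kernel floor a1*a2 must equal 0.6")

    def copy(self, **changes) -> "ModelParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class Species:
    """One species: immutable identity, trait set, bodysize, lineage.

    Resources are non-evolving basal species of bodysize 1 that never feed;
    consumers descend from the founder by single-trait mutations.
    """

    id: int
    traits: frozenset
    bodysize: float
    is_resource: bool = False
    parent_id: Optional[int] = None
    birth_step: int = 0

    def __post_init__(self) -> None:
        if self.bodysize <= 0:
            raise ValueError("bodysize must be positive")
        if self.is_resource and self.parent_id is not None:
            raise ValueError("resources have no parent lineage")
        object.__setattr__(self, "traits", frozenset(int(t) for t in self.traits))


def generate_score_matrix(pool_size: int, rng: np.random.Generator) -> ScoreMatrix:
    """Draw the antisymmetric trait-pair score matrix.

    Strict upper-triangle magnitudes are Uniform(0, 1); the lower triangle is
    the negation and the diagonal is exactly zero, so ``beta + beta.T == 0``
    and a random trait-pair sum is symmetric about zero.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    upper = np.triu(rng.random((pool_size, pool_size)), k=1)
    return upper - upper.T


def shared_traits(i: Species, k: Species) -> int:
    """Number of traits possessed by both species (0..traits_per_species)."""
    return len(i.traits & k.traits)


def trait_pair_sum(i: Species, j: Species, beta: ScoreMatrix) -> float:
    """Sum of the pairwise scores beta[i_m, j_n] over both trait sets.

    Sub-tolerance residues (imperfect floating cancellation of antisymmetric
    terms, e.g. a species against itself) are flushed to exact zero.
    """
    total = float(beta[np.ix_(sorted(i.traits), sorted(j.traits))].sum())
    return 0.0 if abs(total) < PAIR_SUM_TOLERANCE else total


def feeding_score(
    i: Species, j: Species, beta: ScoreMatrix, params: ModelParams
) -> float:
    """Feeding score S_ij of consumer ``i`` on prey ``j``.

    S_ij = max(0, sum_mn beta[i_m, j_n]) * b1 * exp(-(ln s_i - ln s_j - 3)^2 / b2)

    The clip applies to the trait-pair sum only, so a species whose traits
    confer no advantage scores exactly zero at any bodysize; antisymmetry of
    beta forces S_ii = 0.  Resources never feed.
    """
    if i.is_resource:
        raise ValueError("resources do not feed; consumer must be non-resource")
    base = max(0.0, trait_pair_sum(i, j, beta))
    if base == 0.0:
        return 0.0
    d = math.log(i.bodysize) - math.log(j.bodysize) - 3.0
    return base * params.b1 * math.exp(-d * d / params.b2)


def competition_coefficient(i: Species, k: Species, params: ModelParams) -> float:
    """Competition coefficient alpha_ik between consumers of a shared prey.

    alpha_ik = a1 * (a2 + (1 - a2) * (q_ik / 10) * exp(-(ln s_i - ln s_k)^2 / a3))

    ranges over [a1*a2, a1] = [0.6, 0.866]: the floor for fully dissimilar
    pairs, the ceiling (intraspecific) for identical trait set and bodysize.
    """
    q = shared_traits(i, k) / params.traits_per_species
    d = math.log(i.bodysize) - math.log(k.bodysize)
    return params.a1 * (
        params.a2 + (1.0 - params.a2) * q * math.exp(-d * d / params.a3)
    )


def feeding_matrix(
    traits_mat: np.ndarray,
    bodysize: np.ndarray,
    is_resource: np.ndarray,
    beta: ScoreMatrix,
    params: ModelParams,
) -> np.ndarray:
    """Dense S[i, j] over a species table (consumer rows for resources are 0).

    ``traits_mat`` is the (n_species, pool) 0/1 trait indicator.
    """
    T = traits_mat.astype(float)
    pair_sums = T @ beta @ T.T
    # true pair sums are antisymmetric; antisymmetrize and flush residues so
    # self-scores (and identical-trait pairs) are exactly zero
    pair_sums = 0.5 * (pair_sums - pair_sums.T)
    pair_sums[np.abs(pair_sums) < PAIR_SUM_TOLERANCE] = 0.0
    ln_s = np.log(bodysize)
    d = ln_s[:, None] - ln_s[None, :] - 3.0
    S = np.clip(pair_sums, 0.0, None) * params.b1 * np.exp(-d * d / params.b2)
    S[is_resource, :] = 0.0
    return S


def competition_matrix(
    traits_mat: np.ndarray,
    bodysize: np.ndarray,
    params: ModelParams,
) -> np.ndarray:
    """Dense alpha[i, k] over a species table."""
    T = traits_mat.astype(float)
    q = (T @ T.T) / params.traits_per_species
    ln_s = np.log(bodysize)
    d = ln_s[:, None] - ln_s[None, :]
    return params.a1 * (
        params.a2 + (1.0 - params.a2) * q * np.exp(-d * d / params.a3)
    )
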