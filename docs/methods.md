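# Methods

## Model overview

`metaweb` simulates the co-evolutionary assembly of trophic meta-communities
on a rectangular lattice of habitat patches and their response to
perturbation. It belongs to the Webworld lineage of trait-based
eco-evolutionary food-web models: species are abstract bundles of 10
discrete traits (from a pool of 500) plus a continuous bodysize, and all
trophic structure emerges from an antisymmetric matrix β of pairwise trait
scores drawn once per simulation. The model is not parameterised to any
real ecosystem; its purpose is to generate ecologically plausible community
structure (connectance, trophic levels, omnivory, species-area scaling)
from evolutionary first principles and to measure how that structure
responds to species loss, invasion and habitat destruction.

Three nested time scales:

1. **Foraging** — within each patch, all consumers simultaneously adjust
   foraging efforts toward the fixed point of the ratio-dependent
   functional response (adaptive foraging).
2. **Ecology** — one Euler step of allometric population dynamics, then
   dispersal between adjacent patches, then extinction culling.
3. **Evolution** — a block of ecological steps followed by one speciation
   event (parent chosen proportional to local population size).

## Equations and constants

Feeding score of consumer *i* on prey *j*:

    S_ij = max(0, Σ_{m,n} β[i_m, j_n]) · b1 · exp(−(ln s_i − ln s_j − 3)² / b2)

with b1 = (1.5·√(2π))⁻¹ ≈ 0.2660 and b2 = 2·1.5² = 4.5, i.e. a Gaussian
feeding window of width σ = 1.5 in log-bodysize, optimal on prey three
log-units smaller. The clip applies to the trait-pair sum only, so trait
incompatibility gives an exact zero at any bodysize, and antisymmetry of β
forces S_ii = 0.

Competition between consumers *i*, *k* of a shared prey:

    α_ik = a1·(a2 + (1−a2)·(q_ik/10)·exp(−(ln s_i − ln s_k)² / a3))

with a1 = 0.866, a2 = 0.6/a1, a3 = 0.6·√(2π), q_ik the shared-trait count.
The bracket placement is chosen so that α spans exactly [a1·a2, a1] =
[0.6, 0.866]: the floor for fully dissimilar pairs, the ceiling for a
species against itself — intraspecific competition is always strongest.
(The decay width a3 = 0.6·√(2π) mirrors the √(2π) convention of the feeding
kernel; the plausible alternative 2·0.6² changes only the width, never the
kernel endpoints.)

Foraging fixed point, iterated synchronously from uniform efforts:

    f_ij = g_ij / Σ_{k∈K_i} g_ik
    g_ij = S_ij f_ij N_j / (0.005·N_j + Σ_{k∈P_j} α_ik S_kj f_kj N_k)

K_i is the set of locally present prey with S_ij > 0. Iteration stops at an
effort change below 10⁻⁸ or at the iteration cap (default 1000; scaled-down
runs use 50). Efforts are re-initialised uniform at every ecological step so
each step's fixed point is well defined and independent of history.

Population update (Euler step Δ = 0.1, ecological efficiency λ = 0.3):

    N_i ← max(0, N_i + Δ·(−2 s_i^{−1/4} N_i + (λ/s_i) N_i Σ_j g_ij s_j
                          − Σ_k N_k g_ki))

Dispersal from patch with degree D (live von-Neumann neighbours): the
per-neighbour fraction of species *i* leaving is

    μ = D⁻¹ · (s_i/s₀) · r,   r = max(0.001, 0.03·(N^{t−1} − N^t)/N^{t−1})
                                  if declining, else 0.001

with s₀ = e the founder bodysize and N^{t−1} the population at the end of
the previous ecological step (post-dispersal, post-cull). Movement requires
a local population of at least 1; resources never move; the total fraction
is defensively clipped at 1 (unreachable below bodysize ≈ 90·s₀). Dispersal
conserves each species' global population exactly.

Culling removes local non-resource populations strictly below 1. The
threshold is 1 (not, e.g., 1 + ε) so that invasion introductions at exactly
1.0 survive the cull.

## Resources

The basal resource of each patch is modelled as an external, non-dynamic
population of fixed abundance R = 10⁵ (configurable): it enters the
foraging and growth equations as prey but is never updated, never
disperses, and vanishes only when its patch is removed. A dynamic-regrowth
resource would be the main alternative; the fixed-R choice keeps the patch
carrying capacity stationary. R calibrates all population magnitudes, so
absolute population/biomass tables are only comparable between runs sharing
R.

## Initialization and assembly

Each patch draws an independent random 10-trait resource (bodysize 1); the
founder consumer (bodysize e, population 1) starts in patch (1,1). Under
the antisymmetric β the founder can consume its home resource with
probability exactly ½, and a founder that cannot is culled within one
ecological step, leaving nothing to assemble. The founder's trait set is
therefore redrawn until its feeding score on the home resource is positive
— conditioning the run on viable establishment, as any successfully
assembled ensemble implicitly is. Establishment can still fail (~5% of
seeds) when the positive trait-pair sum is too small to outweigh mortality.

Speciation deducts one individual from the parent's local population and
introduces the child with population 1 in the same patch. The child keeps
nine parent traits; the replacement trait is drawn outside the parent's
full 10-trait set, so it differs from the discarded trait and the
parent-child overlap is exactly 9. Children are inserted without
deduplication — species are lineages, not trait-set equivalence classes.
Parent selection pools local (species, patch) populations with N ≥ 1, not
species totals.

## Metrics

- **Realized link**: prey *j* → consumer *i* counts when S_ij > 0, both are
  locally present, and the converged foraging effort f_ij exceeds 0.01
  (configurable). Pure S > 0 would overcount links the adaptive forager
  abandons.
- **Connectance** uses the directed denominator S² (locally present species
  including the resource); link density is L/S.
- **SCTL** (shortest-chain trophic level) is the BFS distance from the
  resource along realized links; omnivores feed on ≥ 2 local prey of
  distinct SCTL. Patch-level SCTL averages are unweighted over consumers;
  species-level SCTL is weighted by local population across patches.
- **Range/residency**: population ≥ 1, aligned with the movement and cull
  thresholds.
- **True local diversity** isolates a patch and relaxes it (default 200
  ecological steps with convergence early-exit). Isolation is implemented
  by extracting the patch into a single-patch state — the dynamics of a
  patch with all dispersal severed are independent of the rest of the
  lattice, so this is exact and much cheaper than simulating the full grid.
- **Species-area curve**: mean γ-diversity over every axis-aligned i×j
  rectangle (18 distinct areas on 6×6), power-law fit by least squares on
  (ln A, ln S).
- **Event-size distributions** are histogrammed (unit bins for integer
  sizes) and fitted from the peak-frequency bin to the last non-zero bin:
  power law on log-log axes, exponential on semi-log, normal directly.
  Bins with zero counts (and non-positive centres, for the power law)
  cannot enter the log transforms and are dropped; fewer than three usable
  bins yields an explicit fit-unavailable marker.

## Perturbation experiments

All experiments run on snapshot copies; a full deletion sweep leaves the
source state bit-identical (verified by content hash). The relaxation
length between/after perturbation events is not dictated by the model;
the default is 100 ecological steps with early exit when the maximum
relative population change drops below 10⁻⁴.

Displacement splits each resident population evenly over the live
neighbours, merging additively with conspecifics, and applies below the
movement threshold too (eviction is forced, not voluntary). Displacing from
a fully isolated patch falls back to elimination with a warning. Permanent
perturbation removes the patch and its resource and decrements neighbour
degrees; temporary perturbation leaves the patch open to recolonization.

Reserve schemes ship as: the no-reserve control; remote 2×3 corner block
(5 boundary edges, interior patches (1,1) and (1,2) fully isolated);
central 2×3 interior block (10 boundary edges); six pairwise non-adjacent
maximum-dispersal patches (summed degree 20 — the specific layout
{(2,2),(2,5),(5,2),(5,5),(1,1),(6,6)} is one of several with these
properties and is configurable); and two state-dependent selectors (highest
local diversity, lowest average resident range), resolved once on the
initial state with deterministic row-major tie-breaking. Patches without
consumers rank last for the lowest-average-range selector.

Sequential disruption uses 1000 events for temporary perturbation and
destroys every non-reserve patch once for permanent (30 with six reserves
on the 6×6 grid, 36 without). Replicate sequences derive per-replicate
seeds by seed-sequence spawning.

## Numerical choices

- Trait-pair sums are antisymmetrized ((P − Pᵀ)/2) and residues below
  10⁻¹² flushed to zero: in exact arithmetic a species' sum against itself
  cancels, but floating summation leaves O(10⁻¹⁴) residues that would
  otherwise create spurious self-links with effort 1. Genuine sums that
  small arise with probability ~10⁻¹³.
- Negative Euler excursions are clamped to zero before culling.
- The foraging loop alternates g-from-f and f-from-g synchronously across
  all species; the returned responses are consistent with the returned
  efforts.
- Snapshots are canonical JSON (sorted keys); floats round-trip exactly via
  shortest-repr, so save→load→save is byte-identical and the sha256 content
  hash is platform-stable.

## Scaled-down runs and what they show

Full-scale assemblies (6×6, 10,000 evolutionary × 1000 ecological × 1000
foraging steps, 15 replicates) are cluster-scale. The test suite instead
uses desk-scale problem sizes chosen as the smallest runs that still
exercise every mechanism: a 3×3 grid with 200 evolutionary × 20 ecological
× 50 foraging steps for the assembly smoke test, 10,000 draws for the
Monte-Carlo invasion analytics, and hand-built 1–2-patch fixtures whose
dynamics are verifiable by straight-line arithmetic. Scaled-down
assemblies produce small webs (a handful of consumers, SCTL mostly 1);
they demonstrate establishment, speciation, dispersal and coexistence, but
not the full-scale emergent statistics (hundreds of species, SCTL up to 5,
the species-area exponent and secondary-extinction rates reported for
cluster-scale runs of this model family), which depend on the long
evolutionary horizon.

The synthetic fixtures emulate specific mechanisms — a two-level food
chain, a source-sink subsidy, a marginally viable victim of displaced
predators — with hand-set score matrices. They share the model's dynamics
but not the statistical structure of evolved communities (their β values
are designed, not drawn), so tests on them validate mechanics, not
emergent patterns.

## Known limitations

- The resource model (fixed external abundance) is a modelling choice, not
  uniquely determined by the model family; absolute abundances scale with R.
- Only von-Neumann, nearest-neighbour dispersal; no diagonal or long-range
  movement, no toroidal wrap.
- Desk-scale assemblies cannot reproduce ensemble statistics (see above).
- Only three of the fixed reserve layouts used in studies of this design
  are pinned down by recoverable geometric properties; the package ships
  those, plus the dynamic selectors, and accepts user-defined fixed layouts.
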