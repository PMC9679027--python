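"""Species deletion, invasion, patch disruption, reserves and sequences."""

import numpy as np
import pytest

from metaweb import (
    SequencePlan,
    delete_species,
    displacement_vs_elimination_differential,
    enumerate_experiment_plan,
    generate_random_species,
    isolated_reserve_interior,
    make_fixture,
    named_reserve_schemes,
    perturb_patch,
    reintroduce_everywhere,
    reserve_boundary_edges,
    resolve_reserves,
    run_ecology,
    run_sequence,
    snapshot_hash,
)
from metaweb.perturbation import _apply_patch_perturbation


class TestSpeciesDeletion:
    def test_removing_the_prey_cascades_to_its_predator(self, relaxed_chain):
        rec = delete_species(relaxed_chain, 1, relax_steps=100)
        assert rec.secondary_extinctions == 1  # B starves without A
        assert rec.relative_secondary_extinctions == 1.0

    def test_removing_the_top_predator_has_no_cascade(self, relaxed_chain):
        rec = delete_species(relaxed_chain, 2, relax_steps=100)
        assert rec.secondary_extinctions == 0

    def test_source_state_restored_bit_exactly(self, relaxed_chain):
        before = snapshot_hash(relaxed_chain)
        for sid in (1, 2):
            delete_species(relaxed_chain, sid, relax_steps=50)
        assert snapshot_hash(relaxed_chain) == before

    def test_resource_deletion_rejected_and_extinct_noop(self, relaxed_chain):
        with pytest.raises(ValueError):
            delete_species(relaxed_chain, 0)
        work = relaxed_chain.copy()
        work.N[2, :] = 0.0
        rec = delete_species(work, 2, relax_steps=10)
        assert rec.secondary_extinctions == 0


class TestReintroduction:
    def test_formerly_resident_species_reenters_its_habitat(self, relaxed_chain):
        _, work = delete_species(relaxed_chain, 1, relax_steps=50,
                                 return_state=True)
        rec = reintroduce_everywhere(work, 1, relax_steps=100)
        assert rec.patches_invaded >= 1

    def test_unopposed_consumer_invades_every_patch(self, subsidy_state):
        # make the consumer able to feed on both resources, then wipe it out
        state = subsidy_state
        state.beta[np.ix_(range(20, 30), range(10, 20))] = 0.05
        state.beta[np.ix_(range(10, 20), range(20, 30))] = -0.05
        state._rebuild_arrays()
        _, work = delete_species(state, 2, relax_steps=50, return_state=True)
        rec = reintroduce_everywhere(work, 2, relax_steps=200)
        assert rec.patches_invaded == 2


class TestRandomSpecies:
    def test_uniform_bodysizes_respect_bounds(self):
        rng = np.random.default_rng(8)
        species = generate_random_species(200, ("uniform", 0.81, 12.64), rng)
        sizes = np.array([sp.bodysize for sp in species])
        assert np.all((sizes >= 0.81) & (sizes <= 12.64))
        assert all(len(sp.traits) == 10 for sp in species)

    def test_empirical_resampling_draws_from_the_supplied_multiset(self):
        rng = np.random.default_rng(9)
        observed = [1.5, 2.5, 7.0]
        species = generate_random_species(50, ("empirical", observed), rng)
        assert {sp.bodysize for sp in species} <= set(observed)

    def test_empty_empirical_list_rejected(self):
        with pytest.raises(ValueError):
            generate_random_species(5, ("empirical", []), np.random.default_rng(0))


class TestPatchPerturbation:
    def test_displacement_conserves_population_at_the_instant(self, seeded_grid):
        work = seeded_grid.copy()
        before = work.N.sum(axis=1)
        _apply_patch_perturbation(work, (2, 2), "temporary", "displace")
        assert np.allclose(work.N.sum(axis=1), before, rtol=1e-12)
        assert work.N[~work.is_resource, work.lattice.index((2, 2))].sum() == 0.0

    def test_elimination_strictly_removes_population(self, seeded_grid):
        work = seeded_grid.copy()
        p = work.lattice.index((1, 1))
        had = work.N[~work.is_resource, p].sum()
        assert had > 0
        _apply_patch_perturbation(work, (1, 1), "temporary", "eliminate")
        assert work.N[~work.is_resource, p].sum() == 0.0

    def test_displacement_splits_evenly_over_neighbours(self, subsidy_state):
        # 1x2 strip: D = 1, the whole population moves next door
        work = subsidy_state.copy()
        _apply_patch_perturbation(work, (1, 1), "temporary", "displace")
        assert work.N[2, 0] == 0.0
        assert work.N[2, 1] == pytest.approx(40.0 + 7000.0)

    def test_permanent_removal_decrements_neighbour_degrees(self, playground):
        lat = playground.lattice
        target = (3, 3)
        nbr_degrees = {
            q: lat.degree(q) for q in lat.neighbors(lat.index(target))
        }
        rec = perturb_patch(playground, target, "permanent", "eliminate",
                           relax_steps=1)
        assert rec.diversity_after == rec.diversity_before - 1  # its resource
        # public op copies; now apply for real and check the degrees
        _apply_patch_perturbation(playground, target, "permanent", "eliminate")
        for q, d in nbr_degrees.items():
            assert playground.lattice.degree(q) == d - 1
        assert not playground.lattice.is_live(target)

    def test_temporary_keeps_the_patch_set_invariant(self, seeded_grid):
        rec, work = perturb_patch(seeded_grid, (2, 2), "temporary", "eliminate",
                                  relax_steps=5, return_state=True)
        assert np.array_equal(work.lattice.active, seeded_grid.lattice.active)
        assert rec.mode == "temporary-eliminate"

    def test_differential_zero_without_residents(self, playground):
        diff = displacement_vs_elimination_differential(
            playground, (4, 4), "temporary", relax_steps=1
        )
        assert diff == 0.0

    def test_differential_positive_when_displacement_rescues(self, subsidy_state):
        # unique resident of (1,1) that could also live in (1,2) but is not
        # there yet: elimination kills the species, displacement re-settles it
        state = subsidy_state
        state.beta[np.ix_(range(20, 30), range(10, 20))] = 0.05
        state.beta[np.ix_(range(10, 20), range(20, 30))] = -0.05
        state._rebuild_arrays()
        state.N[2, 1] = 0.0
        state.N_prev = state.N.copy()
        diff = displacement_vs_elimination_differential(
            state, (1, 1), "temporary", relax_steps=150
        )
        assert diff > 0

    def test_differential_negative_when_displacement_harms(self):
        # displaced residents of (1,1) exterminate a marginally viable
        # unique neighbour in (1,2); elimination would have spared it.
        from metaweb import Lattice, MetacommunityState, ModelParams, Species
        from metaweb.experiment_io import _block_beta

        params = ModelParams(trait_pool_size=40)
        r0, r1 = range(0, 10), range(10, 20)
        inv_tr, vic_tr = range(20, 30), range(30, 40)
        beta = _block_beta(
            40,
            [
                (inv_tr, r0, 0.05),      # invader self-sustains on resource 0
                (inv_tr, vic_tr, 0.1),   # invader preys on the victim
                (vic_tr, r1, 0.00732),   # victim barely viable on resource 1
            ],
        )
        lattice = Lattice(1, 2)
        lattice.resource_of[:] = (0, 1)
        species = [
            Species(0, frozenset(r0), 1.0, is_resource=True),
            Species(1, frozenset(r1), 1.0, is_resource=True),
            Species(2, frozenset(inv_tr), np.e**4),  # optimal window on victim
            Species(3, frozenset(vic_tr), np.e),
        ]
        R = params.resource_abundance
        N = np.array([[R, 0.0], [0.0, R], [7000.0, 0.0], [0.0, 950.0]])
        state = MetacommunityState(params, lattice, species, beta, N,
                                   np.random.default_rng(0))
        diff = displacement_vs_elimination_differential(
            state, (1, 1), "permanent", relax_steps=200
        )
        assert diff < 0


class TestReserves:
    def test_remote_block_geometry(self, playground):
        scheme = named_reserve_schemes()["remote-block"]
        patches = resolve_reserves(playground, scheme)
        assert reserve_boundary_edges(playground, patches) == 5
        assert isolated_reserve_interior(playground, patches) == ((1, 1), (1, 2))

    def test_central_block_geometry(self, playground):
        patches = resolve_reserves(
            playground, named_reserve_schemes()["central-block"]
        )
        assert reserve_boundary_edges(playground, patches) == 10
        assert isolated_reserve_interior(playground, patches) == ()

    def test_max_dispersal_individuals_geometry(self, playground):
        patches = resolve_reserves(
            playground, named_reserve_schemes()["max-dispersal-individuals"]
        )
        lat = playground.lattice
        degs = [lat.degree(lat.index(p)) for p in patches]
        assert sum(degs) == 20
        # pairwise non-adjacent
        idx = {lat.index(p) for p in patches}
        for p in idx:
            assert not (set(lat.neighbors(p)) & idx)

    def test_dynamic_selectors_resolve_six_deterministic_patches(self, seeded_grid):
        hi = resolve_reserves(seeded_grid,
                              named_reserve_schemes()["highest-diversity"])
        lo = resolve_reserves(seeded_grid,
                              named_reserve_schemes()["lowest-average-range"])
        assert len(hi) == len(set(hi)) == 6
        assert len(lo) == len(set(lo)) == 6
        assert hi == resolve_reserves(
            seeded_grid, named_reserve_schemes()["highest-diversity"]
        )

    def test_reserves_must_fit_the_live_lattice(self, relaxed_chain):
        with pytest.raises(ValueError):
            resolve_reserves(relaxed_chain,
                             named_reserve_schemes()["highest-diversity"])


class TestSequences:
    def test_permanent_sequence_with_reserves_leaves_exactly_the_reserves(
        self, playground
    ):
        plan = SequencePlan("permanent", "eliminate",
                            named_reserve_schemes()["remote-block"],
                            target_rule="random", seed=5)
        result = run_sequence(playground, plan, relax_steps=1)
        assert result.events_executed == 30
        # the source lattice is untouched; the worked copy ended with only
        # the six reserves (and their resources) alive
        assert playground.lattice.is_full_rectangle()
        assert result.diversity_series[-1] == 6
        assert result.status == "completed"

    def test_permanent_sequence_without_reserves_destroys_everything(
        self, playground
    ):
        plan = SequencePlan("permanent", "displace",
                            named_reserve_schemes()["none"],
                            target_rule="random", seed=6)
        result = run_sequence(playground, plan, relax_steps=1)
        assert result.events_executed == 36
        assert result.diversity_series[-1] == 0
        assert result.final_relative_diversity == 0.0

    def test_targeted_rule_hits_the_highest_diversity_patch_first(
        self, seeded_grid
    ):
        lat = seeded_grid.lattice
        best = min(
            (p for p in lat.live_indices()),
            key=lambda p: (-seeded_grid.local_diversity(lat.coord(p)),
                           lat.coord(p)),
        )
        plan = SequencePlan("permanent", "eliminate",
                            named_reserve_schemes()["none"],
                            target_rule="targeted-highest-diversity",
                            n_events=1, seed=0)
        result = run_sequence(seeded_grid, plan, relax_steps=1)
        assert result.events_executed == 1
        # the targeted patch is gone from the worked copy, all others remain
        assert seeded_grid.lattice.is_live(lat.coord(best))  # source untouched

    def test_same_seed_gives_identical_trajectories(self, playground):
        plan = SequencePlan("temporary", "eliminate",
                            named_reserve_schemes()["central-block"],
                            target_rule="random", n_events=20, seed=11)
        a = run_sequence(playground, plan, relax_steps=1)
        b = run_sequence(playground, plan, relax_steps=1)
        assert a.diversity_series == b.diversity_series


class TestPlanEnumeration:
    def test_full_design_totals(self):
        table, totals = enumerate_experiment_plan()
        assert totals["n_sequences"] == 8580
        assert totals["n_events"] == 4_420_680
        assert totals["n_events"] == int(table.n_events.sum())

    def test_minimal_design(self):
        table, totals = enumerate_experiment_plan(
            n_metacommunities=1, n_schemes=1, replicates=(1, 0),
            modes=(("temporary", "eliminate"),),
        )
        assert totals == {"n_sequences": 1, "n_events": 1000}
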