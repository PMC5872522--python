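"""Stochastic update algorithm: gates, aborts, phases, determinism."""

import numpy as np
import pytest

from melnest import (
    CapacityError,
    LatticeGeometry,
    ModelParameters,
    MoveOutcome,
    ProliferationOutcome,
    attempt_move,
    attempt_proliferation,
    seed_surface,
    step,
)
from melnest.engine import run, state_from_agents

MEL, SKIN = "melanoma", "skin"


def lone_agent(species=MEL, params=None, geom=None, seed=0):
    geom = geom or LatticeGeometry(21, 21, 21)
    return state_from_agents(
        [(10, 10, 10)], [species], geom, params or ModelParameters(), seed=seed
    )


class TestAttemptMove:
    def test_zero_motility_never_moves(self):
        st = lone_agent(params=ModelParameters(Pm_m=0.0, Pm_s=0.0))
        assert all(
            attempt_move(st, 0) == MoveOutcome.ABORTED_GATE for _ in range(200)
        )

    def test_success_fraction_matches_bernoulli_gate(self):
        # single agent, empty lattice: long-run move fraction ~ Pm
        pm = 0.3
        st = lone_agent(params=ModelParameters(Pm_m=pm, q=0.0), geom=LatticeGeometry(41, 41, 41))
        n = 5000
        moved = sum(attempt_move(st, 0) == MoveOutcome.MOVED for _ in range(n))
        se = (pm * (1 - pm) / n) ** 0.5
        assert abs(moved / n - pm) < 4 * se

    def test_maximal_adhesion_freezes_contacting_melanoma(self):
        st = state_from_agents(
            [(5, 5, 5), (5, 6, 5)], [MEL, MEL],
            LatticeGeometry(11, 11, 11), ModelParameters(Pm_m=1.0, q=1.0),
        )
        outcomes = {attempt_move(st, 0) for _ in range(500)}
        assert outcomes == {MoveOutcome.ABORTED_ADHESION}

    def test_occupied_target_aborts(self):
        # all six von Neumann targets occupied by skin -> crowding abort
        centre = (5, 5, 5)
        nbs = [(6, 5, 5), (4, 5, 5), (5, 6, 5), (5, 4, 5), (5, 5, 6), (5, 5, 4)]
        st = state_from_agents(
            [centre] + nbs, [SKIN] * 7,
            LatticeGeometry(11, 11, 11), ModelParameters(Pm_s=1.0),
        )
        assert all(
            attempt_move(st, 0) == MoveOutcome.ABORTED_CROWDING for _ in range(100)
        )

    def test_vertical_boundary_aborts_instead_of_redrawing(self):
        # agent on the surface layer of a laterally-degenerate-free lattice:
        # 1/6 of passed gates should abort at the boundary
        st = state_from_agents(
            [(10, 10, 0)], [SKIN], LatticeGeometry(21, 21, 21),
            ModelParameters(Pm_s=1.0),
        )
        outcomes = [attempt_move(st, 0) for _ in range(600)]
        boundary = sum(o == MoveOutcome.ABORTED_BOUNDARY for o in outcomes)
        assert boundary > 0  # the up direction is drawn and aborted


class TestAttemptProliferation:
    def test_fully_crowded_parent_aborts(self):
        centre = (5, 5, 5)
        nbs = [(6, 5, 5), (4, 5, 5), (5, 6, 5), (5, 4, 5), (5, 5, 6), (5, 5, 4)]
        st = state_from_agents(
            [centre] + nbs, [MEL] * 7,
            LatticeGeometry(11, 11, 11), ModelParameters(Pp_m=1.0),
        )
        assert attempt_proliferation(st, 0) == ProliferationOutcome.ABORTED_CROWDING
        assert st.n == 7

    def test_isolated_parent_always_births_and_daughter_inherits_species(self):
        for species in (MEL, SKIN):
            st = lone_agent(species, ModelParameters(Pp_m=1.0, Pp_s=1.0))
            out = attempt_proliferation(st, 0)
            assert out == ProliferationOutcome.PLACED_DAUGHTER
            assert st.n == 2
            assert st.species[1] == st.species[0]
            st.validate()

    def test_daughter_uniform_over_vacant_neighbors(self):
        # exactly two vacant von Neumann sites; daughter splits ~50/50
        counts = {(5, 5, 6): 0, (5, 5, 4): 0}
        trials = 800
        for t in range(trials):
            occ = [(6, 5, 5), (4, 5, 5), (5, 6, 5), (5, 4, 5)]
            st = state_from_agents(
                [(5, 5, 5)] + occ, [MEL] + [SKIN] * 4,
                LatticeGeometry(11, 11, 11), ModelParameters(Pp_m=1.0), seed=t,
            )
            assert attempt_proliferation(st, 0) == ProliferationOutcome.PLACED_DAUGHTER
            counts[tuple(st._pos[st.n - 1])] += 1
        frac = counts[(5, 5, 6)] / trials
        assert abs(frac - 0.5) < 4 * (0.25 / trials) ** 0.5


class TestStep:
    def test_clock_advances_by_tau(self):
        st = seed_surface(20, 10, LatticeGeometry(20, 20, 10), seed=1)
        step(st, 10)
        assert st.step_count == 10
        assert st.t == pytest.approx(10 * st.params.tau)

    def test_all_probabilities_zero_leaves_configuration_unchanged(self):
        p = ModelParameters(Pm_m=0, Pm_s=0, Pp_m=0, Pp_s=0)
        st = seed_surface(30, 20, LatticeGeometry(20, 20, 10), p, seed=3)
        before = st.to_dataframe()
        step(st, 20)
        after = st.to_dataframe()
        assert (before[["agent_id", "i", "j", "k"]].values
                == after[["agent_id", "i", "j", "k"]].values).all()

    def test_identical_seeds_give_identical_states(self):
        hashes = []
        for _ in range(2):
            st = seed_surface(50, 30, LatticeGeometry(25, 25, 12), seed=42)
            step(st, 100)
            hashes.append(st.state_hash())
        assert hashes[0] == hashes[1]
        other = seed_surface(50, 30, LatticeGeometry(25, 25, 12), seed=43)
        step(other, 100)
        assert other.state_hash() != hashes[0]

    def test_species_conserved_without_proliferation(self):
        p = ModelParameters(Pp_m=0.0, Pp_s=0.0)
        st = seed_surface(40, 25, LatticeGeometry(20, 20, 12), p, seed=5)
        for _ in range(200):
            step(st)
            assert (st.n_skin, st.n_melanoma) == (40, 25)

    def test_exclusion_and_registry_consistency_after_steps(self):
        p = ModelParameters(Pp_m=0.01, Pp_s=0.01)  # fast growth stresses it
        st = seed_surface(60, 40, LatticeGeometry(18, 18, 10), p, seed=7)
        for _ in range(100):
            step(st)
            st.validate()

    def test_daughters_not_selectable_within_their_birth_step(self):
        # two isolated parents, Pp = 1: exactly two births per step no
        # matter how often a newborn would have been drawn
        st = state_from_agents(
            [(3, 3, 3), (12, 12, 8)], [MEL, MEL],
            LatticeGeometry(16, 16, 12),
            ModelParameters(Pm_m=0.0, Pp_m=1.0, q=0.0),
        )
        step(st)
        assert st.n == 4


class TestSeedSurface:
    def test_counts_and_surface_placement(self):
        st = seed_surface(9549, 2706, LatticeGeometry(150, 150, 100), seed=1)
        assert (st.n_skin, st.n_melanoma) == (9549, 2706)
        assert (st.positions[:, 2] == 0).all()
        st.validate()  # all sites distinct (exclusion)

    def test_empty_seeding(self):
        st = seed_surface(0, 0, LatticeGeometry(10, 10, 5), seed=1)
        assert st.n == 0

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            seed_surface(22500, 1, LatticeGeometry(150, 150, 100), seed=1)


class TestRun:
    def test_four_days_is_9600_steps(self):
        st = seed_surface(5, 2, LatticeGeometry(10, 10, 6),
                          ModelParameters(Pm_m=0, Pm_s=0, Pp_m=0, Pp_s=0), seed=1)
        snaps = run(st, duration_h=96.0 * 0.01)  # scaled: 96 steps of tau
        assert st.step_count == 96
        assert snaps[-1]["t_hours"].iloc[0] == pytest.approx(0.96)

    def test_snapshot_schedule(self):
        st = seed_surface(5, 2, LatticeGeometry(10, 10, 6), seed=1)
        snaps = run(st, duration_h=0.5, snapshot_every_steps=10)
        # 50 steps -> snapshots at 10,20,30,40 plus the final at 50
        assert [s["step"].iloc[0] for s in snaps] == [10, 20, 30, 40, 50]
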