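"""Metropolis mechanics, level/run drivers, determinism, layer logic."""

import numpy as np
import pytest

from annealdock.constants import KB
from annealdock.io_formats import Atom, GridSpec, ProteinStructure, ScalarGrid
from annealdock.ligand_model import (
    AIE_BEAD,
    MOBILE_BEADS,
    Conformation,
    total_energy,
)
from annealdock.sa_engine import (
    InitializationError,
    SAConfig,
    SAState,
    delta_energy,
    init_conformation,
    metropolis_accept,
    placement_layer,
    propose_move,
    run_ensemble,
    run_level,
    simulated_annealing,
)
from conftest import fixture_sa_config


def _open_world(shape=(25, 25, 25), spacing=3.0):
    spec = GridSpec(-(np.array(shape) - 1) / 2 * spacing, np.full(3, spacing), shape)
    gcp = ScalarGrid(spec, np.zeros(shape))
    lys = ScalarGrid(spec, np.zeros(shape))
    return spec, gcp, lys


class TestPlacementLayer:
    def test_no_forbidden_nodes_is_an_error(self):
        spec = GridSpec((0, 0, 0), (1, 1, 1), (5, 5, 5))
        with pytest.raises(ValueError, match="no forbidden nodes"):
            placement_layer(np.zeros((5, 5, 5), bool), spec, 5.0)

    def test_mask_only_fallback_uses_distance_transform(self):
        spec = GridSpec((0, 0, 0), (1.0, 1.0, 1.0), (7, 7, 7))
        mask = np.zeros((7, 7, 7), bool)
        mask[3, 3, 3] = True
        layer = placement_layer(mask, spec, 1.0)
        # exactly the 6 face neighbours are within 1 A of the forbidden node
        assert layer.shape[0] == 6
        assert all(abs(n - 3).sum() == 1 for n in layer)

    def test_layer_excludes_forbidden_nodes(self, planted_instance):
        layer = planted_instance.layer
        m = planted_instance.mask
        assert not any(m[tuple(n)] for n in layer)


class TestInitConformation:
    def test_feasible_on_open_grids(self, ligand, rng):
        _, gcp, lys = _open_world()
        conf = init_conformation(np.array([12, 12, 12]), ligand, gcp, lys, rng)
        assert np.isfinite(total_energy(conf, ligand, gcp, lys))
        assert tuple(conf.bead_nodes[AIE_BEAD]) == (12, 12, 12)

    def test_deterministic_given_seed(self, ligand):
        _, gcp, lys = _open_world()
        c1 = init_conformation(np.array([12, 12, 12]), ligand, gcp, lys,
                               np.random.default_rng(7))
        c2 = init_conformation(np.array([12, 12, 12]), ligand, gcp, lys,
                               np.random.default_rng(7))
        np.testing.assert_array_equal(c1.bead_nodes, c2.bead_nodes)

    def test_walled_in_anchor_raises(self, ligand, rng):
        _, gcp, lys = _open_world()
        forbidden = np.ones(gcp.spec.shape, dtype=bool)
        forbidden[12, 12, 12] = False  # only the anchor itself is allowed
        gcp.forbidden = forbidden
        lys.forbidden = forbidden.copy()
        with pytest.raises(InitializationError, match=r"\(12, 12, 12\)"):
            init_conformation(np.array([12, 12, 12]), ligand, gcp, lys, rng)


class TestProposeMove:
    def test_contract_over_many_draws(self, rng):
        _, gcp, lys = _open_world()
        conf = Conformation(np.array(
            [[8, 12, 12], [10, 12, 12], [12, 12, 12], [14, 12, 12], [16, 12, 12]]
        ))
        config = SAConfig()
        seen_beads = set()
        for _ in range(4000):
            m, cand = propose_move(conf, config, rng)
            seen_beads.add(m)
            assert m != AIE_BEAD
            disp = cand.bead_nodes - conf.bead_nodes
            changed = np.nonzero(np.any(disp != 0, axis=1))[0]
            assert set(changed) <= {m}
            assert np.all(np.abs(disp[m]) <= config.max_displacement)
            np.testing.assert_array_equal(cand.bead_nodes[AIE_BEAD],
                                          conf.bead_nodes[AIE_BEAD])
        assert seen_beads == set(MOBILE_BEADS)

    def test_zero_displacement_is_legal(self, rng):
        _, gcp, lys = _open_world()
        conf = Conformation(np.full((5, 3), 12))
        config = SAConfig(max_displacement=1)
        hits = sum(
            np.array_equal(propose_move(conf, config, rng)[1].bead_nodes,
                           conf.bead_nodes)
            for _ in range(20000)
        )
        # each component uniform on {-1,0,1}: P(null move) = 1/27
        assert hits / 20000 == pytest.approx(1 / 27, abs=4 * np.sqrt((1 / 27) / 20000))


class TestMetropolis:
    def test_downhill_always_accepted(self, rng):
        assert all(metropolis_accept(-5.0, 300.0, rng) for _ in range(100))

    def test_infinite_rejected_without_draw(self):
        class Boom:
            def random(self):  # pragma: no cover
                raise AssertionError("rejection must not consume a draw")
        assert not metropolis_accept(np.inf, 300.0, Boom())

    def test_nonpositive_temperature_rejected(self, rng):
        with pytest.raises(ValueError):
            metropolis_accept(1.0, 0.0, rng)


class TestRunLevel:
    def test_flat_landscape_hits_acceptance_cap(self, ligand):
        _, gcp, lys = _open_world()
        conf = init_conformation(np.array([12, 12, 12]), ligand, gcp, lys,
                                 np.random.default_rng(0))
        state = SAState(conf, total_energy(conf, ligand, gcp, lys))
        config = SAConfig(max_displacement=1)
        stats = run_level(state, 1e8, ligand, gcp, lys, config,
                          np.random.default_rng(1))
        assert stats.acceptances == config.level_max_accepted
        # at (effectively) infinite temperature nearly every feasible
        # proposal is accepted; infeasible ones (hard core) are rare
        assert stats.proposals < 3 * config.level_max_accepted

    def test_trapped_state_only_null_moves_accepted(self, ligand):
        """A conformation walled in by forbidden nodes can accept only
        the zero-displacement proposal (ΔE = 0), so it never moves and
        the acceptance ratio collapses to ~(2d+1)⁻³."""
        _, gcp, lys = _open_world()
        conf = init_conformation(np.array([12, 12, 12]), ligand, gcp, lys,
                                 np.random.default_rng(0))
        forbidden = np.ones(gcp.spec.shape, dtype=bool)
        for b in range(5):
            forbidden[tuple(conf.bead_nodes[b])] = False
        gcp.forbidden = forbidden
        lys.forbidden = forbidden.copy()
        state = SAState(conf, total_energy(conf, ligand, gcp, lys))
        before = conf.bead_nodes.copy()
        config = SAConfig(max_displacement=2)
        stats = run_level(state, 3000.0, ligand, gcp, lys, config,
                          np.random.default_rng(3))
        np.testing.assert_array_equal(state.conf.bead_nodes, before)
        assert stats.proposals == config.level_max_moves
        assert stats.acceptance_ratio == pytest.approx(1 / 125, rel=0.6)

    def test_invariant_acceptances_le_proposals(self, planted_instance, ligand):
        inst = planted_instance
        conf = init_conformation(inst.aie_node, ligand, inst.gcp_grid,
                                 inst.lys_grid, np.random.default_rng(2))
        state = SAState(conf, total_energy(conf, ligand, inst.gcp_grid, inst.lys_grid))
        config = fixture_sa_config(0)
        stats = run_level(state, 500.0, ligand, inst.gcp_grid, inst.lys_grid,
                          config, np.random.default_rng(2))
        assert stats.acceptances <= stats.proposals <= config.level_max_moves

    def test_compiled_level_matches_pure_python_replay(self, planted_instance, ligand):
        """Replaying the compiled kernel's RNG stream through the pure
        Python propose/delta/accept operations reproduces the trajectory
        bit for bit (numba Generator streams match NumPy's)."""
        inst = planted_instance
        conf = init_conformation(inst.aie_node, ligand, inst.gcp_grid,
                                 inst.lys_grid, np.random.default_rng(5))
        config = SAConfig(max_displacement=1, level_max_moves=300,
                          level_max_accepted=100)
        T = 800.0

        state_k = SAState(conf.copy(),
                          total_energy(conf, ligand, inst.gcp_grid, inst.lys_grid))
        stats = run_level(state_k, T, ligand, inst.gcp_grid, inst.lys_grid,
                          config, np.random.default_rng(42))

        state_p = SAState(conf.copy(),
                          total_energy(conf, ligand, inst.gcp_grid, inst.lys_grid))
        rng = np.random.default_rng(42)
        proposals = acceptances = 0
        while (proposals < config.level_max_moves
               and acceptances < config.level_max_accepted):
            m, cand = propose_move(state_p.conf, config, rng)
            de = delta_energy(state_p, m, cand, ligand, inst.gcp_grid, inst.lys_grid)
            proposals += 1
            if metropolis_accept(de, T, rng):
                acceptances += 1
                state_p.conf = cand
                state_p.energy += de
        assert (proposals, acceptances) == (stats.proposals, stats.acceptances)
        np.testing.assert_array_equal(state_k.conf.bead_nodes, state_p.conf.bead_nodes)
        assert state_k.energy == state_p.energy


class TestSimulatedAnnealing:
    def test_schedule_and_invariants(self, planted_instance, ligand):
        inst = planted_instance
        config = fixture_sa_config(11)
        r = simulated_annealing(inst.aie_node, ligand, inst.gcp_grid,
                                inst.lys_grid, config)
        temps = [lv.temperature for lv in r.levels]
        expected = [config.T0 * config.cooling_factor**n for n in range(len(temps))]
        np.testing.assert_allclose(temps, expected, rtol=1e-12)
        best = [lv.best_energy_so_far for lv in r.levels]
        assert all(b2 <= b1 + 1e-12 for b1, b2 in zip(best, best[1:]))
        assert r.terminated_by in ("acceptance", "max_levels")
        # stored final energy must be exactly reproducible from the
        # stored conformation
        assert r.final_total_energy == total_energy(
            r.final_conformation, ligand, inst.gcp_grid, inst.lys_grid
        )

    def test_no_accepted_state_violates_constraints(self, planted_instance, ligand):
        inst = planted_instance
        r = simulated_annealing(inst.aie_node, ligand, inst.gcp_grid,
                                inst.lys_grid, fixture_sa_config(3))
        assert np.isfinite(r.final_total_energy)


class TestEnsemble:
    def test_bit_identical_rerun_and_layer_contract(self, planted_instance, ligand):
        inst = planted_instance
        config = fixture_sa_config(99)
        a = run_ensemble(6, inst.layer, ligand, inst.gcp_grid, inst.lys_grid, config)
        b = run_ensemble(6, inst.layer, ligand, inst.gcp_grid, inst.lys_grid, config)
        layer_set = set(map(tuple, inst.layer))
        for ra, rb in zip(a, b):
            assert ra.aie_node == rb.aie_node
            assert ra.final_total_energy == rb.final_total_energy
            np.testing.assert_array_equal(ra.final_conformation.bead_nodes,
                                          rb.final_conformation.bead_nodes)
            assert ra.aie_node in layer_set

    def test_empty_layer_rejected(self, planted_instance, ligand):
        with pytest.raises(ValueError, match="non-empty"):
            run_ensemble(2, np.empty((0, 3), int), ligand,
                         planted_instance.gcp_grid, planted_instance.lys_grid,
                         SAConfig())

    def test_default_ensemble_size_is_production_scale(self):
        from annealdock.fixtures import sa_config_from_config
        _, n_runs = sa_config_from_config({})
        assert n_runs == 4000
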