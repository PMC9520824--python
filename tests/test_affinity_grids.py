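"""Electrolyte screening, steric masking and the rotational probe scan."""

import itertools

import numpy as np
import pytest

from annealdock.affinity_grids import (
    IonicSolvent,
    Probe,
    ScanConfig,
    dh_potential_grid,
    inverse_debye_length,
    ionic_strength,
    probe_energy,
    probe_scan,
    rotation_set,
    steric_mask,
)
from annealdock.constants import COULOMB_KJ_A, KB
from annealdock.io_formats import Atom, GridSpec, ProteinStructure, ScalarGrid


def _point_protein(charge=1.0, radius=0.0, pos=(0.0, 0.0, 0.0)):
    return ProteinStructure([Atom(1, "C", "TOY", "A", 1, np.array(pos), charge, radius)])


class TestSolvent:
    @pytest.mark.parametrize(
        "solvent, expected",
        [
            (IonicSolvent.from_salts(nacl=0.1), 0.1),
            (IonicSolvent.from_salts(nacl=0.1, mgcl2=0.01), 0.13),
            (IonicSolvent(()), 0.0),
        ],
    )
    def test_ionic_strength(self, solvent, expected):
        assert ionic_strength(solvent) == pytest.approx(expected)

    def test_debye_length_monovalent_textbook(self):
        # 0.1 M 1:1 salt in water near room temperature: 1/kappa ~ 9.6 A
        s = IonicSolvent.from_salts(nacl=0.1, temperature=298.0)
        assert 1.0 / inverse_debye_length(s) == pytest.approx(9.6, rel=0.01)

    def test_kappa_zero_without_ions(self):
        assert inverse_debye_length(IonicSolvent(())) == 0.0

    def test_kappa_sqrt2_scaling(self):
        k1 = inverse_debye_length(IonicSolvent.from_salts(nacl=0.1))
        k2 = inverse_debye_length(IonicSolvent.from_salts(nacl=0.2))
        assert k2 / k1 == pytest.approx(np.sqrt(2.0), rel=1e-12)

    def test_electroneutrality_enforced(self):
        with pytest.raises(ValueError, match="electroneutral"):
            IonicSolvent(((0.1, 1),))


class TestDHPotential:
    def test_coulomb_closed_form_at_10A(self):
        spec = GridSpec((10.0, 0.0, 0.0), (1.0, 1.0, 1.0), (1, 1, 1))
        g = dh_potential_grid(_point_protein(), spec, IonicSolvent((), eps_water=79.0))
        assert g.values[0, 0, 0] == pytest.approx(COULOMB_KJ_A / (79.0 * 10.0), rel=1e-12)

    def test_superposition(self):
        spec = GridSpec((-6.0, -6.0, -6.0), (3.0, 3.0, 3.0), (5, 5, 5))
        solv = IonicSolvent.from_salts(nacl=0.1)
        p1 = _point_protein(1.0, pos=(1.0, 0.0, 0.0))
        p2 = _point_protein(-0.4, pos=(0.0, 2.0, 0.0))
        both = ProteinStructure(p1.atoms + p2.atoms)
        lhs = dh_potential_grid(both, spec, solv).values
        rhs = dh_potential_grid(p1, spec, solv).values + dh_potential_grid(p2, spec, solv).values
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12)

    def test_screening_reduces_magnitude_everywhere(self):
        spec = GridSpec((-6.0, -6.0, -6.0), (2.0, 2.0, 2.0), (7, 7, 7))
        screened = dh_potential_grid(
            _point_protein(), spec, IonicSolvent.from_salts(nacl=0.1)
        ).values
        bare = dh_potential_grid(_point_protein(), spec, IonicSolvent(())).values
        assert np.all(np.abs(screened) <= np.abs(bare) + 1e-15)

    def test_kappa_zero_equals_coulomb_superposition(self, rng):
        """Unscreened limit against an independently coded Coulomb sum."""
        spec = GridSpec((-4.0, -4.0, -4.0), (2.0, 2.0, 2.0), (5, 5, 5))
        atoms = [
            Atom(i, "C", "X", "A", i, rng.uniform(-3, 3, 3), rng.uniform(-1, 1), 1.0)
            for i in range(5)
        ]
        prot = ProteinStructure(atoms)
        g = dh_potential_grid(prot, spec, IonicSolvent((), eps_water=79.0))
        xs, ys, zs = spec.node_coordinates()
        for node in [(0, 0, 0), (2, 3, 1), (4, 4, 4)]:
            x = np.array([xs[node[0]], ys[node[1]], zs[node[2]]])
            ref = sum(
                COULOMB_KJ_A * a.charge / (79.0 * max(np.linalg.norm(x - a.position), 0.5))
                for a in atoms
            )
            assert g.values[node] == pytest.approx(ref, rel=1e-12)

    def test_empty_protein_rejected(self):
        spec = GridSpec((0, 0, 0), (1, 1, 1), (2, 2, 2))
        with pytest.raises(ValueError):
            dh_potential_grid(ProteinStructure([]), spec, IonicSolvent(()))


class TestStericMask:
    def test_counts_and_boundary_convention(self):
        # radius-2 atom on a 1 A lattice: nodes with d^2 < 4 -> 1+6+12+8 = 27
        spec = GridSpec((-5.0, -5.0, -5.0), (1.0, 1.0, 1.0), (11, 11, 11))
        m = steric_mask(_point_protein(radius=2.0), spec)
        assert m.sum() == 27
        assert m[5, 5, 5]  # node at the atom center
        assert not m[5, 5, 7]  # distance exactly == radius stays allowed

    def test_probe_pad_inflates(self):
        spec = GridSpec((-5.0, -5.0, -5.0), (1.0, 1.0, 1.0), (11, 11, 11))
        m0 = steric_mask(_point_protein(radius=2.0), spec)
        m1 = steric_mask(_point_protein(radius=2.0), spec, probe_pad=1.0)
        assert m1.sum() > m0.sum()
        assert np.all(m1[m0])


class TestRotations:
    def test_identity_first_and_n1(self):
        np.testing.assert_allclose(rotation_set(1, seed=3)[0], np.eye(3))
        np.testing.assert_allclose(rotation_set(5, seed=3)[0], np.eye(3))

    def test_deterministic(self):
        np.testing.assert_array_equal(rotation_set(150, 42), rotation_set(150, 42))

    def test_quasi_uniform_mean(self):
        mean = rotation_set(10_000, seed=0).mean(axis=0)
        assert np.all(np.abs(mean) < 0.05)

    def test_n_below_one_rejected(self):
        with pytest.raises(ValueError):
            rotation_set(0)


def _random_potential(rng, shape=(5, 5, 5), forbid=None):
    spec = GridSpec((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), shape)
    pot = ScalarGrid(spec, rng.normal(size=shape))
    mask = np.zeros(shape, bool)
    if forbid:
        mask[forbid] = True
    return pot, mask


class TestProbeEnergy:
    def test_point_probe_equals_potential_all_rotations(self, rng):
        pot, mask = _random_potential(rng)
        probe = Probe(((np.zeros(3), 1.0, 1.0),))
        for rot in rotation_set(6, 0):
            assert probe_energy((2, 3, 1), rot, probe, pot, mask) == pytest.approx(
                pot.values[2, 3, 1]
            )

    def test_charge_negation_negates_energy(self, rng):
        pot, mask = _random_potential(rng)
        off = np.array([0.7, -0.3, 0.2])
        plus = Probe(((off, 1.0, 1.0), (-off, 0.5, 1.0)))
        minus = Probe(((off, -1.0, 1.0), (-off, -0.5, 1.0)))
        rot = rotation_set(3, 1)[2]
        e1 = probe_energy((2, 2, 2), rot, plus, pot, mask)
        e2 = probe_energy((2, 2, 2), rot, minus, pot, mask)
        assert e2 == pytest.approx(-e1, rel=1e-12)

    def test_outside_grid_is_infinite(self, rng):
        pot, mask = _random_potential(rng)
        probe = Probe(((np.array([10.0, 0.0, 0.0]), 1.0, 1.0),))
        assert probe_energy((2, 2, 2), np.eye(3), probe, pot, mask) == np.inf


class TestProbeScan:
    @pytest.mark.parametrize("mode", ["min", "boltzmann"])
    def test_point_probe_identity(self, rng, mode):
        pot, mask = _random_potential(rng, forbid=(2, 2, 2))
        probe = Probe(((np.zeros(3), 2.0, 1.0),))
        aff = probe_scan(pot, mask, probe, ScanConfig(n_rotations=8, mode=mode))
        free = ~aff.forbidden
        np.testing.assert_allclose(aff.values[free], 2.0 * pot.values[free], rtol=1e-12)
        assert aff.forbidden[2, 2, 2]

    def test_boltzmann_never_below_min(self, rng):
        pot, mask = _random_potential(rng, forbid=(1, 1, 1))
        probe = Probe(((np.array([1.1, 0, 0]), 1.0, 1.0), (np.array([-1.1, 0, 0]), -0.5, 1.0)))
        aff_min = probe_scan(pot, mask, probe, ScanConfig(n_rotations=6, mode="min"))
        aff_b = probe_scan(pot, mask, probe, ScanConfig(n_rotations=6, mode="boltzmann"))
        free = ~(aff_min.forbidden | aff_b.forbidden)
        assert np.all(aff_b.values[free] >= aff_min.values[free] - 1e-9)

    @pytest.mark.parametrize("mode", ["min", "boltzmann"])
    def test_matches_per_node_per_rotation_oracle(self, rng, mode):
        """Vectorized scan against a brute-force per-node re-evaluation."""
        pot, mask = _random_potential(rng, forbid=(2, 2, 2))
        probe = Probe(((np.array([1.2, 0, 0]), 1.0, 1.0), (np.array([-1.2, 0, 0]), -0.5, 1.0)))
        cfg = ScanConfig(n_rotations=4, mode=mode, rotation_seed=5)
        aff = probe_scan(pot, mask, probe, cfg)
        rots = rotation_set(4, 5)
        kbt = KB * cfg.reference_temperature
        for node in itertools.product(range(5), repeat=3):
            es = np.array([probe_energy(node, r, probe, pot, mask) for r in rots])
            finite = es[np.isfinite(es)]
            if finite.size == 0:
                assert aff.forbidden[node]
                continue
            if mode == "min":
                ref = finite.min()
            else:
                ref = -kbt * np.log(np.exp(-finite / kbt).sum() / len(rots))
            if not aff.forbidden[node]:
                assert aff.values[node] == pytest.approx(ref, abs=1e-10)

    def test_mask_propagates_to_output(self, rng):
        pot, mask = _random_potential(rng, forbid=(0, 0, 0))
        mask[4, 4, 4] = True
        probe = Probe(((np.zeros(3), 1.0, 1.0),))
        aff = probe_scan(pot, mask, probe, ScanConfig(n_rotations=3))
        assert np.all(aff.forbidden[mask])

    def test_charge_scaling_min_mode(self, rng):
        pot, mask = _random_potential(rng)
        off = np.array([0.9, 0.4, 0.0])
        base = Probe(((off, 1.0, 1.0), (-off, 0.5, 1.0)))
        scaled = Probe(((off, 3.0, 1.0), (-off, 1.5, 1.0)))
        cfg = ScanConfig(n_rotations=5, mode="min", rotation_seed=2)
        a1 = probe_scan(pot, mask, base, cfg)
        a3 = probe_scan(pot, mask, scaled, cfg)
        free = ~(a1.forbidden | a3.forbidden)
        np.testing.assert_allclose(a3.values[free], 3.0 * a1.values[free], rtol=1e-9)

    def test_geometry_mismatch_rejected(self, rng):
        pot, _ = _random_potential(rng)
        with pytest.raises(ValueError, match="mask shape"):
            probe_scan(pot, np.zeros((4, 4, 4), bool), Probe(((np.zeros(3), 1.0, 1.0),)))
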