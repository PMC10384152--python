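"""Generator ground truth: slab profile, chain construction, planted H-bond
geometry and telegraph kinetics."""

import numpy as np
import pytest

from slabstats.box import PeriodicBox
from slabstats.exceptions import ArgumentError, CapacityError, GeometryError
from slabstats.geometry import dihedral_angles
from slabstats.synth import (DIHEDRAL_NAME_QUADS, MonolayerSpec, TelegraphSpec,
                             all_trans_tail_length, build_monolayer,
                             build_ndb_chain, build_water_slab,
                             plant_hbond_partner, simulate_telegraph,
                             telegraph_correlation, water_slab_profile)


class TestWaterSlab:
    def test_sharp_interface_limit_confines_waters(self):
        spec = MonolayerSpec(n_surfactant_per_leaflet=0,
                             interface_width_w=0.005,
                             water_number_density=8.0, seed=11)
        top, frame = build_water_slab(spec, include_hydrogens=False)
        z = frame.positions[:, 2]
        outside = np.mean((z < spec.z_lo) | (z > spec.z_hi))
        assert outside < 0.01

    def test_binned_density_matches_tanh_target(self):
        """Chi-square per bin of order one against the rejection-sampling
        target profile."""
        spec = MonolayerSpec(n_surfactant_per_leaflet=0, interface_width_w=0.3,
                             water_number_density=20.0, seed=12)
        top, frame = build_water_slab(spec, include_hydrogens=False)
        z = frame.positions[:, 2]
        edges = np.arange(0.0, spec.box.lz + 0.2, 0.2)
        counts = np.histogram(z, bins=edges)[0]
        centers = 0.5 * (edges[:-1] + edges[1:])
        expected = water_slab_profile(spec, centers) * spec.box.cross_section * 0.2
        mask = expected > 5
        chi2 = np.mean((counts[mask] - expected[mask]) ** 2 / expected[mask])
        assert 0.2 < chi2 < 3.0

    def test_count_scales_linearly_with_density(self):
        base = dict(n_surfactant_per_leaflet=0, seed=13)
        n1 = build_water_slab(MonolayerSpec(water_number_density=5.0, **base),
                              include_hydrogens=False)[1].n_atoms
        n2 = build_water_slab(MonolayerSpec(water_number_density=10.0, **base),
                              include_hydrogens=False)[1].n_atoms
        assert abs(n2 - 2 * n1) <= 3 * np.sqrt(n2)

    def test_slab_wider_than_box_rejected(self):
        spec = MonolayerSpec(n_surfactant_per_leaflet=0,
                             box=PeriodicBox(8, 8, 6.0),
                             water_slab_halfwidth=4.0)
        with pytest.raises(GeometryError):
            build_water_slab(spec)

    def test_hydrogens_at_rigid_geometry(self):
        spec = MonolayerSpec(n_surfactant_per_leaflet=0,
                             water_number_density=2.0, seed=14)
        top, frame = build_water_slab(spec)
        pos = frame.positions.reshape(-1, 3, 3)
        d1 = np.linalg.norm(pos[:, 1] - pos[:, 0], axis=1)
        d2 = np.linalg.norm(pos[:, 2] - pos[:, 0], axis=1)
        assert np.allclose(d1, 0.09572, atol=1e-9)
        assert np.allclose(d2, 0.09572, atol=1e-9)
        cosv = np.sum((pos[:, 1] - pos[:, 0]) * (pos[:, 2] - pos[:, 0]),
                      axis=1) / (d1 * d2)
        assert np.allclose(np.degrees(np.arccos(cosv)), 104.52, atol=1e-6)


class TestChainBuilder:
    def test_planted_torsions_round_trip(self, rng):
        for _ in range(10):
            t = rng.uniform(0.0, 360.0, size=12)
            pos = build_ndb_chain(t)
            quads = np.array([[pos[n] for n in quad]
                              for quad in DIHEDRAL_NAME_QUADS])
            rec = dihedral_angles(quads[:, 0], quads[:, 1], quads[:, 2],
                                  quads[:, 3])
            assert np.allclose(np.mod(rec - t, 360.0), 0.0, atol=1e-7) or \
                np.allclose(rec, t, atol=1e-7)

    def test_all_trans_matches_closed_form_length(self):
        pos = build_ndb_chain(np.full(12, 180.0))
        length = np.linalg.norm(pos["C15"] - pos["C4"])
        assert length == pytest.approx(all_trans_tail_length(), abs=1e-9)

    def test_even_bond_count_reduces_to_axial_formula(self):
        # 3 carbons, 2 bonds: both endpoints on the zigzag axis
        expected = 2 * 0.153 * np.sin(np.radians(109.4712206) / 2)
        assert all_trans_tail_length(3) == pytest.approx(expected, abs=1e-12)


class TestMonolayer:
    def test_all_trans_zero_tilt_limit(self):
        spec = MonolayerSpec(n_surfactant_per_leaflet=4, tilt_mean=0.0,
                             tilt_sd=0.0, gauche_prob=(0.0,) * 12,
                             include_water=False, seed=3)
        top, traj = build_monolayer(spec)
        for res, qs in top.surfactant_dihedrals().items():
            p = traj[0].positions
            for q in qs:
                ang = dihedral_angles(p[q[0]], p[q[1]], p[q[2]], p[q[3]])
                assert abs(ang - 180.0) < 1e-6

    def test_seed_reproducibility_is_bitwise(self):
        spec = MonolayerSpec(n_surfactant_per_leaflet=3, n_frames=2,
                             water_number_density=2.0, seed=42)
        _, t1 = build_monolayer(spec)
        _, t2 = build_monolayer(spec)
        for f1, f2 in zip(t1, t2):
            assert np.array_equal(f1.positions, f2.positions)

    def test_heads_sit_at_their_interfaces(self):
        spec = MonolayerSpec(n_surfactant_per_leaflet=4, include_water=False,
                             seed=4)
        top, traj = build_monolayer(spec)
        n1 = top.indices_with_role("N1")
        z = traj[0].positions[n1][:, 2]
        assert np.allclose(np.sort(z)[:4], spec.z_lo, atol=1e-9)
        assert np.allclose(np.sort(z)[4:], spec.z_hi, atol=1e-9)

    def test_capacity_error_when_lattice_overfull(self):
        spec = MonolayerSpec(box=PeriodicBox(2.0, 2.0, 24.0),
                             water_slab_halfwidth=2.0,
                             n_surfactant_per_leaflet=100,
                             include_water=False)
        with pytest.raises(CapacityError):
            build_monolayer(spec)

    def test_invalid_gauche_probabilities_rejected(self):
        with pytest.raises(ArgumentError):
            MonolayerSpec(gauche_prob=(1.2,) + (0.0,) * 11)
        with pytest.raises(ArgumentError):
            MonolayerSpec(gauche_prob=(0.1,) * 11)


class TestPlantedHBondGeometry:
    def test_planted_distance_and_hda_angle_exact(self):
        acc = np.array([1.0, 1.0, 1.0])
        water, acceptor = plant_hbond_partner(acc, [0.0, 0.0, 1.0], 0.31, 25.0,
                                              "HDA")
        d = water[0]
        assert np.linalg.norm(d - acc) == pytest.approx(0.31, abs=1e-12)
        dh = water[1] - d
        da = acc - d
        ang = np.degrees(np.arccos(dh @ da / (np.linalg.norm(dh)
                                              * np.linalg.norm(da))))
        assert ang == pytest.approx(25.0, abs=1e-9)

    def test_planted_dha_angle_exact(self):
        acc = np.zeros(3)
        water, _ = plant_hbond_partner(acc, [1.0, 0.0, 0.0], 0.29, 150.0,
                                       "DHA")
        h = water[1]
        hd = water[0] - h
        ha = acc - h
        ang = np.degrees(np.arccos(hd @ ha / (np.linalg.norm(hd)
                                              * np.linalg.norm(ha))))
        assert ang == pytest.approx(150.0, abs=1e-9)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ArgumentError):
            plant_hbond_partner(np.zeros(3), [1, 0, 0], 0.05, 150.0, "DHA")
        with pytest.raises(ArgumentError):
            plant_hbond_partner(np.zeros(3), [1, 0, 0], -0.1, 20.0)


class TestTelegraph:
    def test_absorbing_limit_stays_bound(self):
        spec = TelegraphSpec(k_off=1e-9, k_on=1.0, n_pairs=200, dt=0.1,
                             n_steps=300, seed=5)
        series = simulate_telegraph(spec)
        assert series.h.mean() > 0.999

    def test_symmetric_rates_give_half_occupancy(self):
        spec = TelegraphSpec(k_off=0.2, k_on=0.2, n_pairs=4000, dt=0.5,
                             n_steps=200, seed=6)
        series = simulate_telegraph(spec)
        occ = series.h.mean()
        # binomial error on ~8e5 weakly correlated samples
        assert occ == pytest.approx(0.5, abs=0.01)

    def test_closed_form_correlation_recovered(self):
        from slabstats.hbond import intermittent_acf
        spec = TelegraphSpec(k_off=0.35, k_on=0.15, n_pairs=4000, dt=0.1,
                             n_steps=800, seed=7)
        series = simulate_telegraph(spec)
        acf = intermittent_acf(series, max_lag=200)
        expected = telegraph_correlation(spec, acf.lags)
        assert np.max(np.abs(acf.C - expected)) < 0.03

    def test_undersampling_warns(self):
        spec = TelegraphSpec(k_off=5.0, k_on=5.0, n_pairs=10, dt=0.5,
                             n_steps=10, seed=8)
        with pytest.warns(UserWarning):
            simulate_telegraph(spec)
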