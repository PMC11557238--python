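"""Spur-track generator: stopping power, energy bookkeeping, spur content."""

import numpy as np
import pytest

from pulsechem import Phantom, TrackParams, generate_track, populate_spur
from pulsechem.errors import EnergyRangeError, GeometryError
from pulsechem.tracks import StoppingPower


class TestStoppingPower:
    def test_table_nodes_reproduced_exactly(self, stopping):
        for e, s in zip(stopping.energies, stopping.values):
            assert stopping(e) == pytest.approx(s, rel=1e-12)

    def test_geometric_midpoint_interpolates_geometrically(self, stopping):
        # independent recomputation of the log-log rule between two nodes
        e_mid = np.sqrt(1.0e4 * 2.0e4)
        expected = 10 ** (0.5 * (np.log10(2.26e9) + np.log10(1.32e9)))
        assert stopping(e_mid) == pytest.approx(expected, rel=1e-10)
        assert expected == pytest.approx(1.727194e9, rel=1e-6)

    def test_strictly_decreasing_over_studied_range(self, stopping):
        sel = (stopping.energies >= 1e4) & (stopping.energies <= 1e6)
        vals = stopping.values[sel]
        assert np.all(np.diff(vals) < 0)

    def test_out_of_range_energy_raises(self, stopping):
        with pytest.raises(EnergyRangeError):
            stopping(10.0)
        with pytest.raises(EnergyRangeError):
            stopping(1e7)


class TestGenerateTrack:
    def test_energy_at_cutoff_gives_no_spurs(self, registry, rng):
        params = TrackParams(kinetic_energy=500.0, cutoff_energy=500.0)
        spurs, dep = generate_track(params, 0.0, rng, registry)
        assert spurs == [] and dep == 0.0

    def test_energy_bookkeeping_is_exact(self, registry, params_10kev, rng):
        spurs, dep = generate_track(params_10kev, 0.0, rng, registry)
        assert dep == sum(s.energy for s in spurs)
        assert dep <= params_10kev.kinetic_energy

    def test_mean_spur_count_matches_renewal_oracle(self, registry):
        # independent oracle: the 1-D renewal process of the sampling scheme
        e0, cutoff, lo, hi = 1e4, 400.0, 20.0, 100.0
        params = TrackParams(
            kinetic_energy=e0, cutoff_energy=cutoff, spur_energy_range=(lo, hi)
        )
        n_rep = 300
        rng_trk = np.random.default_rng(11)
        counts = []
        for _ in range(n_rep):
            spurs, _ = generate_track(params, 0.0, rng_trk, registry)
            counts.append(len(spurs))
        rng_orc = np.random.default_rng(12)
        oracle = []
        for _ in range(3000):
            e, k = e0, 0
            while True:
                eps = rng_orc.uniform(lo, hi)
                if e - eps < cutoff:
                    break
                e -= eps
                k += 1
            oracle.append(k)
        se = np.sqrt(np.var(counts) / n_rep + np.var(oracle) / 3000)
        assert abs(np.mean(counts) - np.mean(oracle)) < 3 * se + 1e-9

    def test_track_near_face_exits_with_partial_deposit(self, registry, rng):
        phantom = Phantom(extents=(1e-6, 1e-6, 1e-6), air_gap=0.0)
        params = TrackParams(kinetic_energy=1e4)
        entry = np.array([0.5e-6 - 1e-9, 0.0, 0.0])  # 1 nm inside the x face
        spurs, dep = generate_track(
            params, 0.0, rng, registry, phantom=phantom,
            entry_point=entry, direction=(1.0, 0.0, 0.0),
        )
        assert dep < params.kinetic_energy
        for s in spurs:
            assert phantom.contains(s.center)

    def test_entry_off_face_raises(self, registry, rng, phantom):
        with pytest.raises(GeometryError):
            generate_track(
                TrackParams(), 0.0, rng, registry, phantom=phantom,
                entry_point=np.array([0.0, 0.0, 1e-6]),
            )

    def test_all_particles_inside_phantom(self, registry, params_10kev, rng, phantom):
        spurs, _ = generate_track(params_10kev, 0.0, rng, registry, phantom=phantom)
        pos = np.array([p.position for s in spurs for p in s.particles])
        assert np.all(phantom.contains(pos))

    def test_same_seed_bit_identical_track(self, registry, params_10kev):
        out = []
        for _ in range(2):
            spurs, dep = generate_track(
                params_10kev, 0.0, np.random.default_rng(77), registry
            )
            out.append(
                (
                    dep,
                    [tuple(s.center) for s in spurs],
                    [(p.species, tuple(p.position)) for s in spurs for p in s.particles],
                )
            )
        assert out[0] == out[1]

    def test_max_spurs_caps_segment_mode(self, registry, rng):
        params = TrackParams(kinetic_energy=1e6, max_spurs=25)
        spurs, _ = generate_track(params, 0.0, rng, registry)
        assert len(spurs) == 25


class TestPopulateSpur:
    def test_zero_energy_limit_is_empty(self, registry, params_10kev, rng):
        assert populate_spur(0.0, np.zeros(3), 0.0, params_10kev, registry, rng) == []

    def test_mean_hydroxyl_count_matches_poisson_mean(self, registry, rng):
        params = TrackParams(initial_yields={"OH": 5.5})
        n_draws, total = 20000, 0
        center = np.array([0, 0, 1e-6])
        for _ in range(n_draws):
            total += len(populate_spur(60.0, center, 0.0, params, registry, rng))
        mean = total / n_draws
        expected = 60.0 * 5.5 / 100.0  # 3.3
        se = np.sqrt(expected / n_draws)
        assert abs(mean - expected) < 3 * se

    def test_spur_net_charge_is_zero(self, registry, params_10kev, rng):
        for _ in range(200):
            parts = populate_spur(
                80.0, np.array([0, 0, 1e-6]), 0.0, params_10kev, registry, rng
            )
            q = sum(registry.charges[p.species] for p in parts)
            assert q == 0

    def test_birth_times_carry_physicochemical_offset(self, registry, rng):
        params = TrackParams(pc_offset=1e-12)
        parts = populate_spur(
            100.0, np.array([0, 0, 1e-6]), 2.5e-9, params, registry, rng
        )
        assert parts and all(p.birth_time == 2.5e-9 + 1e-12 for p in parts)
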