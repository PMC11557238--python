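"""IRT engine: closed-form pair statistics, conservation, determinism."""

import numpy as np
import pytest
from scipy.special import erfc

from pulsechem import (
    Ensemble,
    pair_reaction_time,
    propagate_position,
    run_irt,
    ultimate_reaction_probability,
)
from pulsechem.errors import InvalidParameterError
from tests_support import pair_field as _pair_field


class TestPairReactionTime:
    def test_contact_pair_reacts_immediately(self, rng):
        assert pair_reaction_time(1e-10, 2e-10, 5e-9, rng) == 0.0

    def test_invalid_geometry_raises(self, rng):
        with pytest.raises(InvalidParameterError):
            pair_reaction_time(0.0, 1e-10, 5e-9, rng)

    def test_ultimate_fraction_at_twice_radius(self):
        R, Dp = 2e-10, 5e-9
        u = np.random.default_rng(1).random(100_000)
        t = pair_reaction_time(np.full(100_000, 2 * R), R, Dp, u=u)
        frac = np.mean(np.isfinite(t))
        se = np.sqrt(0.25 / 100_000)
        assert abs(frac - 0.5) < 3 * se

    def test_finite_times_follow_conditional_cdf(self):
        # inverse-transform consistency against W(t)/W(inf), sup-norm < 0.01
        R, Dp, r0 = 2e-10, 5e-9, 4e-10
        u = np.random.default_rng(2).random(100_000)
        t = pair_reaction_time(np.full(100_000, r0), R, Dp, u=u)
        t = np.sort(t[np.isfinite(t)])
        emp = np.arange(1, len(t) + 1) / len(t)
        cdf = erfc((r0 - R) / np.sqrt(4 * Dp * t))  # W(t)/W(inf)
        assert np.max(np.abs(emp - cdf)) < 0.01


class TestUltimateProbability:
    def test_contact_is_certain(self):
        assert ultimate_reaction_probability(1e-10, 1e-10) == 1.0

    def test_far_limit_vanishes(self):
        assert ultimate_reaction_probability(1e3, 1e-10) < 1e-12

    def test_quarter_at_four_radii(self):
        assert ultimate_reaction_probability(4e-10, 1e-10) == 0.25

    def test_inside_contact_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert ultimate_reaction_probability(0.5e-10, 1e-10) == 1.0


class TestPropagate:
    def test_zero_step_is_identity(self, rng):
        x = np.array([1.0, 2.0, 3.0])
        assert np.all(propagate_position(x, 5e-9, 0.0, rng) == x)

    def test_negative_step_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            propagate_position(np.zeros(3), 5e-9, -1.0, rng)

    def test_einstein_msd_and_isotropy(self, rng):
        D, dt, n = 5e-9, 1e-9, 100_000
        disp = propagate_position(np.zeros((n, 3)), D, dt, rng)
        msd = np.sum(disp**2, axis=1)
        se = msd.std() / np.sqrt(n)
        assert abs(msd.mean() - 6 * D * dt) < 3 * se
        var = disp.var(axis=0)
        assert np.allclose(var, var.mean(), rtol=0.05)


class TestRunIrt:
    def test_single_particle_survives(self, registry, rng):
        ens = Ensemble(1)
        ens.add([registry.species_index("OH")], np.array([0, 0, 1e-6]), 0.0, 0)
        ens, log = run_irt(ens, registry, 1e-6, rng)
        assert len(log) == 0 and ens.alive[0]

    def test_pair_field_recombination_frequency_is_half(self, registry):
        i_oh = registry.species_index("OH")
        R = registry.pair_radius[i_oh, i_oh]
        ens = _pair_field(registry, 10_000, 2 * R)
        ens, log = run_irt(ens, registry, 1e-4, np.random.default_rng(9))
        freq = len(log) / 10_000
        se = np.sqrt(0.25 / 10_000)
        assert abs(freq - 0.5) < 3 * se
        # every event is the recombination channel making H2O2
        for ev in log:
            assert registry.reactions[ev.reaction].label.startswith("OH + OH")

    def test_staggered_birth_reduces_reaction_frequency(self, registry):
        # diffusion blur of the earlier partner grows the expected separation
        i_oh = registry.species_index("OH")
        R = registry.pair_radius[i_oh, i_oh]
        freqs = []
        for k, delay in enumerate((0.0, 3e-9, 3e-8, 3e-7)):
            ens = _pair_field(registry, 4000, 2 * R, delay=delay)
            ens, log = run_irt(ens, registry, 1e-4, np.random.default_rng(30 + k))
            freqs.append(len(log) / 4000)
        assert all(a > b for a, b in zip(freqs, freqs[1:]))

    def test_charge_and_element_conserved_at_every_event(
        self, registry, params_10kev
    ):
        from pulsechem import PulseSpec, assemble_pulse, scoring_end_time

        spec = PulseSpec(n_electrons=3, pulse_duration=1e-10, kinetic_energy=1e4)
        rng = np.random.default_rng(41)
        ens, dep, _ = assemble_pulse(spec, params_10kev, registry, rng)
        ens, log = run_irt(ens, registry, scoring_end_time(1e-10), rng)
        assert len(log) > 0
        for ev in log:
            rx = registry.reactions[ev.reaction]
            q_in = registry.charges[list(rx.reactants)].sum()
            q_out = registry.charges[list(rx.products)].sum() if rx.products else 0
            assert q_in == q_out

    def test_event_log_sorted_and_no_double_reactions(self, registry, params_10kev):
        from pulsechem import PulseSpec, assemble_pulse, scoring_end_time

        spec = PulseSpec(n_electrons=5, pulse_duration=1e-11, kinetic_energy=1e4)
        rng = np.random.default_rng(43)
        ens, _, _ = assemble_pulse(spec, params_10kev, registry, rng)
        t_end = scoring_end_time(1e-11, "pulse_plus_window", window=1e-8)
        ens, log = run_irt(ens, registry, t_end, rng)
        times = log.times()
        assert len(log) > 0
        assert np.all(np.diff(times) >= 0)
        assert np.all((times > 0) & (times <= t_end))
        seen = set()
        for ev in log:
            for rid in ev.reactant_ids:
                assert rid not in seen
                seen.add(rid)

    def test_particle_count_changes_match_events(self, registry, params_10kev):
        from pulsechem import PulseSpec, assemble_pulse, scoring_end_time

        spec = PulseSpec(n_electrons=2, pulse_duration=1e-11, kinetic_energy=1e4)
        rng = np.random.default_rng(47)
        ens, _, _ = assemble_pulse(spec, params_10kev, registry, rng)
        n0 = ens.n
        t_end = scoring_end_time(1e-11, "pulse_plus_window", window=1e-8)
        ens, log = run_irt(ens, registry, t_end, rng)
        made = sum(len(ev.product_ids) for ev in log)
        used = sum(len(ev.reactant_ids) for ev in log)
        assert ens.n == n0 + made
        assert int(np.sum(~ens.alive[: ens.n])) == used

    def test_seeded_determinism_of_event_log(self, registry, params_10kev):
        from pulsechem import PulseSpec, assemble_pulse, scoring_end_time

        logs = []
        for _ in range(2):
            rng = np.random.default_rng(53)
            spec = PulseSpec(n_electrons=3, pulse_duration=1e-10, kinetic_energy=1e4)
            ens, _, _ = assemble_pulse(spec, params_10kev, registry, rng)
            ens, log = run_irt(ens, registry, scoring_end_time(1e-10), rng)
            logs.append(
                [(ev.time, ev.reaction, ev.reactant_ids, ev.product_ids) for ev in log]
            )
        assert logs[0] == logs[1]
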