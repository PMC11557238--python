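"""Species/reaction registry: radii, balance validation, conventions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsechem import effective_radius
from pulsechem.errors import InvalidParameterError, ValidationError
from pulsechem.registry import (
    AVOGADRO,
    Registry,
    default_registry,
    effective_radius_debye,
    parse_reaction_table,
    parse_species_table,
)

SPECIES_TEXT = """\
name\tcharge\tdiffusion_coefficient_m2_s
e_aq\t-1\t4.9e-9
OH\t0\t2.3e-9
H\t0\t7.0e-9
H2\t0\t4.8e-9
H2O2\t0\t2.3e-9
H3O+\t1\t9.46e-9
OH-\t-1\t5.3e-9
"""


def _reactions(rows: str):
    header = "reactant1\treactant2\tproducts\trate_constant\tunit\n"
    species = parse_species_table(SPECIES_TEXT)
    return parse_reaction_table(header + rows, species)


class TestEffectiveRadius:
    def test_zero_rate_is_zero_radius(self):
        assert effective_radius(0.0, 5.6e-9) == 0.0

    def test_direct_evaluation(self):
        # R = k*1e-3 / (4 pi D' N_A) evaluated by hand
        r = effective_radius(5.5e9, 5.6e-9)
        assert r == pytest.approx(1.2978183e-10, rel=1e-6)

    def test_round_trip_recovers_rate(self):
        r = effective_radius(5.5e9, 5.6e-9)
        k_back = 4.0 * math.pi * r * AVOGADRO * 5.6e-9 * 1e3
        assert abs(k_back - 5.5e9) / 5.5e9 < 1e-12

    def test_nonpositive_diffusion_rejected(self):
        with pytest.raises(InvalidParameterError):
            effective_radius(1e9, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        k=st.floats(1e5, 1e11),
        d=st.floats(1e-10, 1e-8),
        scale=st.floats(0.1, 10.0),
    )
    def test_linear_in_rate_inverse_in_diffusion(self, k, d, scale):
        r = effective_radius(k, d)
        assert effective_radius(scale * k, d) == pytest.approx(scale * r, rel=1e-12)
        assert effective_radius(k, scale * d) == pytest.approx(r / scale, rel=1e-12)

    def test_debye_neutral_pair_reduces_to_smoluchowski(self):
        assert effective_radius_debye(1e10, 1e-8, 0, 0) == effective_radius(1e10, 1e-8)

    def test_debye_like_charges_need_larger_radius(self):
        # repulsion suppresses encounters, so matching the same observed rate
        # requires a larger contact radius than the neutral inversion gives
        r_neutral = effective_radius(1e10, 1e-8)
        r_repulsive = effective_radius_debye(1e10, 1e-8, 1, 1)
        assert r_repulsive > r_neutral
        # attraction concentrates flux, so a smaller contact radius suffices
        assert effective_radius_debye(1e11, 1e-8, 1, -1) < effective_radius(1e11, 1e-8)


class TestTableLoading:
    def test_empty_reaction_table_gives_species_only(self):
        species = parse_species_table(SPECIES_TEXT)
        reg = Registry(species, [])
        assert len(reg) == 7 and len(reg.reactions) == 0

    def test_recombination_row_has_radius_and_balance(self):
        (rx,) = _reactions("OH\tOH\tH2O2\t1.1e10\tM-1s-1\n")
        assert rx.effective_radius > 0
        # observed-loss convention: the pair rate is k/2 for identical reactants
        assert rx.effective_radius == pytest.approx(
            effective_radius(0.55e10, 4.6e-9), rel=1e-12
        )

    def test_distinct_reactants_use_full_rate(self):
        (rx,) = _reactions("e_aq\tOH\tOH-\t3.0e10\tM-1s-1\n")
        assert rx.effective_radius == pytest.approx(
            effective_radius(3.0e10, 4.9e-9 + 2.3e-9), rel=1e-12
        )

    def test_element_imbalance_is_rejected_with_row_cited(self):
        with pytest.raises(ValidationError, match="line 2"):
            _reactions("OH\tOH\tH2O2;H2\t1.1e10\tM-1s-1\n")

    def test_implicit_water_balances_oh_plus_h(self):
        (rx,) = _reactions("OH\tH\t\t1.55e10\tM-1s-1\n")
        assert rx.products == ()

    def test_charge_imbalance_rejected(self):
        with pytest.raises(ValidationError, match="charge"):
            _reactions("e_aq\tH\tH2\t2.5e10\tM-1s-1\n")

    def test_unknown_species_rejected(self):
        with pytest.raises(ValidationError, match="unknown species"):
            _reactions("OH\tXYZ\tH2O2\t1.0e9\tM-1s-1\n")

    def test_negative_rate_rejected(self):
        with pytest.raises(ValidationError, match="negative"):
            _reactions("OH\tOH\tH2O2\t-1.0\tM-1s-1\n")


class TestDefaultRegistry:
    def test_default_registry_charge_and_radii_invariants(self, registry):
        for rx in registry.reactions:
            q_in = registry.charges[list(rx.reactants)].sum()
            q_out = registry.charges[list(rx.products)].sum() if rx.products else 0
            assert q_in == q_out
            assert rx.effective_radius >= 0

    def test_core_radiolysis_species_present(self, registry):
        for name in ("e_aq", "OH", "H", "H2", "H2O2", "H3O+", "OH-", "HO2", "O2-"):
            assert name in registry.index

    def test_o2_rows_absent_without_scavenger(self, registry):
        i_o2 = registry.species_index("O2")
        # O2 appears only as a product in the default (0-concentration) set
        for rx in registry.reactions:
            assert i_o2 not in rx.reactants

    def test_scavenger_mode_creates_first_order_channels(self):
        reg = default_registry(o2_concentration=2.5e-4)
        rates = {
            (reg.names[s],): k for s, _, k in reg.first_order
        }
        assert rates[("e_aq",)] == pytest.approx(1.9e10 * 2.5e-4)
        assert rates[("H",)] == pytest.approx(2.1e10 * 2.5e-4)

    def test_duplicate_pair_channel_rejected(self):
        species = parse_species_table(SPECIES_TEXT)
        rows = (
            "reactant1\treactant2\tproducts\trate_constant\tunit\n"
            "OH\tOH\tH2O2\t1.1e10\tM-1s-1\n"
            "OH\tOH\tH2O2\t2.2e10\tM-1s-1\n"
        )
        reactions = parse_reaction_table(rows, species)
        with pytest.raises(ValidationError, match="duplicate"):
            Registry(species, reactions)
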