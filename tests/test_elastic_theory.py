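"""Wrapping energetics: critical diameters, contact energy, classification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanowrap.elastic_theory import (
    AdhesionSpec,
    MembraneSpec,
    WrappingLabel,
    adhesion_critical_diameter,
    classify_wrapping,
    contact_energy,
    critical_diameter_tensionless,
    critical_diameter_with_tension,
)


class TestCriticalDiameterTensionless:
    @pytest.mark.parametrize(
        "k, W, expected_nm",
        [
            (8.4e-20, 0.042, 4.0),  # bare gold, ~20 kBT membrane
            (1.0e-19, 0.002, 20.0),  # hand arithmetic 2*sqrt(1e-16)
        ],
    )
    def test_known_values(self, k, W, expected_nm):
        membrane = MembraneSpec(bending_modulus=k)
        adhesion = AdhesionSpec(adhesion_strength_W=W)
        assert critical_diameter_tensionless(membrane, adhesion) == pytest.approx(
            expected_nm, rel=1e-12
        )

    def test_vanishing_bending_cost_gives_zero(self):
        membrane = MembraneSpec(bending_modulus=1e-30)
        adhesion = AdhesionSpec(adhesion_strength_W=0.042)
        assert critical_diameter_tensionless(membrane, adhesion) < 1e-3

    def test_no_adhesion_is_an_error(self):
        with pytest.raises(ValueError, match="no adhesion"):
            critical_diameter_tensionless(
                MembraneSpec(), AdhesionSpec(adhesion_strength_W=0.0)
            )

    @given(
        k=st.floats(1e-21, 1e-18),
        w_lo=st.floats(1e-4, 0.05),
        factor=st.floats(1.01, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotonicity_in_adhesion_and_bending(self, k, w_lo, factor):
        """dc strictly decreases with |W| and strictly increases with k."""
        m = MembraneSpec(bending_modulus=k)
        dc_lo = critical_diameter_tensionless(m, AdhesionSpec(adhesion_strength_W=w_lo))
        dc_hi = critical_diameter_tensionless(
            m, AdhesionSpec(adhesion_strength_W=w_lo * factor)
        )
        assert dc_hi < dc_lo
        m_stiff = MembraneSpec(bending_modulus=k * factor)
        assert critical_diameter_tensionless(
            m_stiff, AdhesionSpec(adhesion_strength_W=w_lo)
        ) > dc_lo


class TestCriticalDiameterWithTension:
    def test_tensionless_limit_recovers_dc(self):
        membrane = MembraneSpec(bending_modulus=1e-19, tension=0.0)
        adhesion = AdhesionSpec(adhesion_strength_W=0.002)
        assert critical_diameter_with_tension(
            membrane, adhesion
        ) == critical_diameter_tensionless(membrane, adhesion)

    def test_finite_tension_value(self):
        membrane = MembraneSpec(bending_modulus=1.0e-19, tension=0.001)
        adhesion = AdhesionSpec(adhesion_strength_W=0.002)
        assert critical_diameter_with_tension(membrane, adhesion) == pytest.approx(
            2 * math.sqrt(2e-19 / 1e-3) * 1e9, rel=1e-12
        )

    def test_tension_at_adhesion_strength_diverges(self):
        membrane = MembraneSpec(bending_modulus=1e-19, tension=0.002)
        adhesion = AdhesionSpec(adhesion_strength_W=0.002)
        assert math.isinf(critical_diameter_with_tension(membrane, adhesion))

    @given(
        sigma_frac=st.floats(0.0, 0.999),
        k=st.floats(1e-21, 1e-18),
        w=st.floats(1e-4, 0.05),
    )
    @settings(max_examples=50, deadline=None)
    def test_never_below_tensionless_diameter(self, sigma_frac, k, w):
        """dc_sigma >= dc for all sigma >= 0, equality only at sigma = 0."""
        membrane = MembraneSpec(bending_modulus=k, tension=sigma_frac * w)
        adhesion = AdhesionSpec(adhesion_strength_W=w)
        dc = critical_diameter_tensionless(membrane, adhesion)
        dcs = critical_diameter_with_tension(membrane, adhesion)
        if sigma_frac == 0.0:
            assert dcs == dc
        elif sigma_frac > 1e-9:
            assert dcs > dc
        else:  # tension below float resolution of |W| - sigma
            assert dcs >= dc


class TestContactEnergy:
    def test_flat_surface_limit(self):
        adhesion = AdhesionSpec(flat_strength_kw=0.042)
        assert contact_energy(10.0, adhesion) == pytest.approx(-0.042)

    def test_curvature_corrections(self):
        adhesion = AdhesionSpec(
            flat_strength_kw=0.01, linear_coeff_m=5e-11, slb_modulus=1e-19
        )
        # a = 10 nm: -0.01 + 0.005 - 0.002
        assert contact_energy(10.0, adhesion) == pytest.approx(-0.007, rel=1e-12)

    def test_large_radius_asymptote(self):
        adhesion = AdhesionSpec(
            flat_strength_kw=0.01, linear_coeff_m=5e-11, slb_modulus=1e-19
        )
        assert contact_energy(1e9, adhesion) == pytest.approx(-0.01, rel=1e-6)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            contact_energy(0.0, AdhesionSpec(flat_strength_kw=0.01))


class TestAdhesionCriticalDiameter:
    def test_gold_like_surface_adheres_at_all_sizes(self):
        adhesion = AdhesionSpec(flat_strength_kw=0.042)
        assert adhesion_critical_diameter(adhesion) == 0.0

    def test_negative_discriminant_gives_zero(self):
        adhesion = AdhesionSpec(
            flat_strength_kw=0.01, linear_coeff_m=5e-11, slb_modulus=1e-19
        )
        assert adhesion_critical_diameter(adhesion) == 0.0

    def test_larger_root_doubled(self):
        adhesion = AdhesionSpec(
            flat_strength_kw=0.01, linear_coeff_m=1e-10, slb_modulus=1e-19
        )
        assert adhesion_critical_diameter(adhesion) == pytest.approx(14.47, abs=0.01)

    def test_non_adhesive_flat_limit_rejected(self):
        with pytest.raises(ValueError, match="non-adhesive"):
            adhesion_critical_diameter(AdhesionSpec(flat_strength_kw=0.0))

    def test_agrees_with_sign_scan_of_contact_energy(self):
        """Above the returned diameter the contact energy is adhesive on a
        fine grid; random parameter draws."""
        rng = np.random.default_rng(7)
        grid_nm = np.arange(0.1, 500.0, 0.01)
        for _ in range(25):
            adhesion = AdhesionSpec(
                flat_strength_kw=10 ** rng.uniform(-3, -1),
                linear_coeff_m=10 ** rng.uniform(-11, -9),
                slb_modulus=10 ** rng.uniform(-20, -18),
            )
            d_crit = adhesion_critical_diameter(adhesion)
            a_m = grid_nm * 1e-9
            w_s = (
                -adhesion.flat_strength_kw
                + adhesion.linear_coeff_m / a_m
                - 2 * adhesion.slb_modulus / a_m**2
            )
            adhesive = grid_nm[w_s < 0]
            if d_crit == 0.0:
                # every sufficiently large size must be adhesive
                assert w_s[-1] < 0
            else:
                above = grid_nm > d_crit / 2 + 0.01
                assert np.all(w_s[above] < 0)
                # just below the root the energy is non-adhesive
                below = (grid_nm < d_crit / 2 - 0.01) & (grid_nm > d_crit / 2 * 0.5)
                if below.any():
                    assert np.all(w_s[below] >= 0)
            del adhesive


class TestClassifyWrapping:
    def test_zero_tension_skips_partial_regime(self):
        membrane = MembraneSpec(bending_modulus=1e-19, tension=0.0)
        adhesion = AdhesionSpec(adhesion_strength_W=0.002)
        state = classify_wrapping(25.0, membrane, adhesion)
        assert state.label is WrappingLabel.FULLY_WRAPPED
        assert state.dc == state.dc_sigma

    def test_excess_tension_caps_at_partial(self):
        membrane = MembraneSpec(bending_modulus=1e-19, tension=0.002)
        adhesion = AdhesionSpec(adhesion_strength_W=0.002)
        state = classify_wrapping(1000.0, membrane, adhesion)
        assert state.label is WrappingLabel.PARTIALLY_WRAPPED
        assert math.isinf(state.dc_sigma)

    def test_partial_between_the_two_diameters(self):
        membrane = MembraneSpec(bending_modulus=1e-19, tension=0.001)
        adhesion = AdhesionSpec(adhesion_strength_W=0.002)
        state = classify_wrapping(25.0, membrane, adhesion)
        assert state.label is WrappingLabel.PARTIALLY_WRAPPED
        assert state.dc == pytest.approx(20.0, rel=1e-12)
        assert state.dc_sigma == pytest.approx(28.284, abs=1e-3)

    def test_partition_is_contiguous(self):
        """Sweeping d must produce the three labels as contiguous blocks."""
        membrane = MembraneSpec(bending_modulus=1e-19, tension=0.001)
        adhesion = AdhesionSpec(adhesion_strength_W=0.002)
        labels = [
            classify_wrapping(d, membrane, adhesion).label
            for d in np.linspace(0.5, 60, 400)
        ]
        changes = sum(1 for a, b in zip(labels, labels[1:]) if a is not b)
        assert changes == 2
        assert labels[0] is WrappingLabel.ADHERED_UNWRAPPED
        assert labels[-1] is WrappingLabel.FULLY_WRAPPED
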