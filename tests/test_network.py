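"""Interaction function, switching rates and beta calibration."""

import math

import numpy as np
import pytest

from gcgrn import (
    GENES,
    CalibrationError,
    GeneParameters,
    InteractionParams,
    NetworkModel,
    calibrate_beta,
    compute_kon,
    compute_koff,
    compute_phi,
    load_parameter_version,
)
from gcgrn.network import InvalidThresholdError


def gene(**kw):
    base = dict(
        gene_id="BCL6", s0=1.0, d0=0.1, s1=1.0, d1=0.1,
        kon_init=0.1, koff_init=1.0, kon_min=0.0, kon_max=2.0,
        koff_min=0.0, koff_max=2.0,
    )
    base.update(kw)
    return GeneParameters(**base)


def interactions(theta=None, H=None, gamma=2.0):
    return InteractionParams(theta=theta or {}, H=H or {}, gamma=gamma)


class TestComputePhi:
    def test_empty_state_gives_unity(self):
        inter = interactions({("IRF4", "BCL6"): -3.0}, {("IRF4", "BCL6"): 0.5})
        assert compute_phi([0, 0, 0], {"BCR": 0, "CD40": 0}, "BCL6", inter) == 1.0

    def test_all_zero_theta_gives_unity_at_any_state(self):
        inter = interactions()
        phi = compute_phi([3.0, 1.0, 7.5], {"BCR": 2.0, "CD40": 0.3}, "IRF4", inter)
        assert phi == pytest.approx(1.0, abs=1e-12)

    def test_single_edge_at_threshold(self):
        # theta = ln 2, P_j = H => factor (1 + 2*1)/(1 + 1) = 1.5
        inter = interactions({("IRF4", "BLIMP1"): math.log(2)}, {("IRF4", "BLIMP1"): 4.0})
        phi = compute_phi([0, 4.0, 0], {}, "BLIMP1", inter)
        assert phi == pytest.approx(1.5, rel=1e-12)

    def test_stimulus_factor_uses_exponent_one(self):
        # with gamma = 2 a protein at 2H quadruples r, a stimulus at 2H doubles it
        inter = interactions({("BCR", "BCL6"): 1.0}, {("BCR", "BCL6"): 1.0})
        phi = compute_phi([0, 0, 0], {"BCR": 2.0}, "BCL6", inter)
        assert phi == pytest.approx((1 + math.e * 2) / 3, rel=1e-12)

    def test_factor_bounds(self):
        # each factor lies between min(1, e^theta) and max(1, e^theta)
        rng = np.random.default_rng(1)
        for theta in (-5.0, -0.5, 0.7, 6.0):
            inter = interactions({("BCL6", "BCL6"): theta}, {("BCL6", "BCL6"): 0.3})
            for p in rng.uniform(0, 10, size=20):
                phi = compute_phi([p, 0, 0], {}, "BCL6", inter)
                lo, hi = min(1, math.exp(theta)), max(1, math.exp(theta))
                assert lo - 1e-12 <= phi <= hi + 1e-12

    def test_huge_theta_remains_finite(self):
        inter = interactions({("IRF4", "BCL6"): -500.0}, {("IRF4", "BCL6"): 1e-4})
        phi_off = compute_phi([0, 50.0, 0], {}, "BCL6", inter, negate=True)
        assert np.isfinite(phi_off) and phi_off > 1e10

    def test_invalid_threshold_rejected(self):
        with pytest.raises(InvalidThresholdError):
            interactions({}, {("IRF4", "BCL6"): 0.0})

    def test_structural_zero_enforced(self):
        with pytest.raises(ValueError, match="absent"):
            interactions({("BCL6", "IRF4"): 1.0}, {})


class TestRates:
    def test_kon_limits_and_midpoint(self):
        g = calibrate_beta(gene(kon_init=1.0))  # beta_on = 1 at Phi_ref = 1
        assert g.beta_on == pytest.approx(1.0)
        assert compute_kon(0.0, g) == g.kon_min
        assert compute_kon(1.0, g) == pytest.approx(1.0)  # 2 * 1/(1+1)
        assert compute_kon(1e12, g) == pytest.approx(g.kon_min + g.kon_max, rel=1e-9)

    def test_kon_monotone_in_phi(self):
        g = calibrate_beta(gene())
        values = [compute_kon(phi, g) for phi in np.geomspace(1e-3, 1e3, 25)]
        assert np.all(np.diff(values) > 0)

    def test_uncalibrated_beta_raises(self):
        with pytest.raises(CalibrationError):
            compute_kon(1.0, gene())

    def test_koff_is_kon_form_with_negated_theta(self):
        inter = interactions({("IRF4", "BCL6"): 2.5}, {("IRF4", "BCL6"): 1.0})
        neg = interactions({("IRF4", "BCL6"): -2.5}, {("IRF4", "BCL6"): 1.0})
        P = [0, 3.0, 0]
        assert compute_phi(P, {}, "BCL6", inter, negate=True) == pytest.approx(
            compute_phi(P, {}, "BCL6", neg), rel=1e-12
        )

    def test_activator_lowers_koff(self):
        inter = interactions({("IRF4", "BCL6"): 2.0}, {("IRF4", "BCL6"): 1.0})
        g = calibrate_beta(gene())
        base = compute_koff([0, 0, 0], {}, "BCL6", inter, g)
        high = compute_koff([0, 5.0, 0], {}, "BCL6", inter, g)
        assert base == pytest.approx(g.koff_min + g.koff_max * g.beta_off / (1 + g.beta_off))
        assert high < base

    def test_kon_monotone_in_regulator_by_theta_sign(self):
        for theta, sign in ((3.0, 1), (-3.0, -1)):
            inter = interactions({("IRF4", "BCL6"): theta}, {("IRF4", "BCL6"): 1.0})
            phis = [compute_phi([0, p, 0], {}, "BCL6", inter) for p in np.linspace(0, 5, 30)]
            diffs = np.diff(phis) * sign
            assert np.all(diffs >= -1e-12)


class TestCalibration:
    def test_beta_zero_when_init_equals_min(self):
        g = calibrate_beta(gene(kon_min=0.05, kon_init=0.05 + 1e-15))
        assert g.beta_on == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_inverse(self):
        g = calibrate_beta(gene(kon_min=0.0, kon_max=2.0, kon_init=1.0))
        assert g.beta_on == pytest.approx(1.0)

    def test_init_at_boundary_rejected(self):
        with pytest.raises(CalibrationError):
            gene(kon_init=2.0, kon_min=0.0, kon_max=2.0)

    @pytest.mark.parametrize("tag", ["I", "II", "III"])
    def test_reference_state_roundtrip(self, tag):
        """Calibrated rates reproduce the initial values at the reference
        state to 1e-12 relative error, for every shipped parameter set."""
        model = load_parameter_version(tag)
        _, _, p_ref = model.reference_state()
        kon, koff = model.rates(p_ref, {"BCR": 0.0, "CD40": 0.0})
        for i, g in enumerate(model.genes):
            assert kon[i] == pytest.approx(g.kon_init, rel=1e-12)
            assert koff[i] == pytest.approx(g.koff_init, rel=1e-12)

    def test_reference_state_is_initial_rate_steady_state(self, model_I):
        e, m, p = model_I.reference_state()
        for i, g in enumerate(model_I.genes):
            assert e[i] == pytest.approx(g.kon_init / (g.kon_init + g.koff_init))
            assert m[i] == pytest.approx(g.s0 * e[i] / g.d0)
            assert p[i] == pytest.approx(g.s1 * m[i] / g.d1)


class TestNetworkModel:
    def test_gene_order_enforced(self, model_I):
        with pytest.raises(ValueError, match="ordered"):
            NetworkModel(genes=model_I.genes[::-1], interactions=model_I.interactions)

    def test_with_overrides_roundtrip(self, model_I):
        m = model_I.with_overrides({"theta.IRF4.IRF4": 50.0, "s0.IRF4": 2.1})
        assert m.interactions.theta[("IRF4", "IRF4")] == 50.0
        assert m.gene("IRF4").s0 == 2.1
        assert not m.calibrated  # betas cleared, must re-calibrate
        # untouched parameters preserved
        assert m.gene("BCL6").s0 == model_I.gene("BCL6").s0

    def test_with_overrides_unknown_name(self, model_I):
        with pytest.raises(KeyError):
            model_I.with_overrides({"theta.NOPE.BCL6": 1.0})
        with pytest.raises(KeyError):
            model_I.with_overrides({"volume.BCL6": 1.0})

    def test_fractional_protein_scale(self, model_I):
        g = model_I.gene("BCL6")
        x = model_I.fractional_protein([g.protein_max, 0, 0])
        assert x[0] == pytest.approx(1.0)
        assert GENES[0] == "BCL6"
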