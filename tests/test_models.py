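"""Unit tests of the LQ iso-effect framework and the three RBE models."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from protonrbe.models import (
    CONSTANTS, CarabeModel, FixedRBEModel, LEMTable, LEMTableModel, LQParams,
    RBEEndpoints, TissueParams, WedenbergModel, car_applicable, car_endpoints,
    car_min_applicable_let, endpoints_to_lq, lem_beta_z, lem_table_lq,
    lq_isoeffect_rbe, make_synthetic_lem_table, rbe_from_photon_dose,
    rbe_from_proton_dose, wed_endpoints,
)

# the printed coefficient pairs, as published (ratio 1.9968 for the first)
PRINTED_AB2 = TissueParams(alpha_x=0.123, beta_x=0.0616, name="printed_ab2")
PRINTED_AB10 = TissueParams(alpha_x=0.616, beta_x=0.0616, name="printed_ab10")


class TestTissueParams:
    def test_ratio_is_exact_when_built_from_ratio(self):
        t = TissueParams.from_ratio(alpha_x=0.123, alpha_beta_x=2.0)
        assert t.alpha_beta_x == pytest.approx(2.0, rel=1e-15)

    @pytest.mark.parametrize("kwargs", [
        dict(alpha_x=-0.1, beta_x=0.06),
        dict(alpha_x=0.1, beta_x=0.0),
        dict(alpha_x=0.1, beta_x=0.06, d_t=-5.0),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TissueParams(**kwargs)


class TestIsoeffectRBE:
    def test_identity_when_proton_equals_photon_lq(self):
        lq = LQParams(PRINTED_AB2.alpha_x, PRINTED_AB2.beta_x)
        assert lq_isoeffect_rbe(lq, PRINTED_AB2, 2.0) == pytest.approx(1.0, abs=1e-14)

    def test_against_polynomial_root_oracle(self):
        # independent oracle: bisection on (a_x + b_x D_x) R^2 - a R - b D_x
        lq = LQParams(0.246, 0.0616)
        d_x = 2.0
        poly = lambda r: (PRINTED_AB2.alpha_x + PRINTED_AB2.beta_x * d_x) * r**2 \
            - lq.alpha * r - lq.beta * d_x
        expected = brentq(poly, 1e-9, 100.0, xtol=1e-13)
        got = lq_isoeffect_rbe(lq, PRINTED_AB2, d_x)
        assert got == pytest.approx(expected, rel=1e-10)
        assert got == pytest.approx(1.366, abs=5e-4)

    @pytest.mark.parametrize("d_x", [0.5, 2.0, 8.0])
    def test_doubled_alpha_quadrupled_beta_gives_rbe_two(self, d_x):
        lq = LQParams(2 * PRINTED_AB2.alpha_x, 4 * PRINTED_AB2.beta_x)
        assert lq_isoeffect_rbe(lq, PRINTED_AB2, d_x) == pytest.approx(2.0, rel=1e-12)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            lq_isoeffect_rbe(LQParams(0.2, 0.06), PRINTED_AB2, 0.0)


class TestCarabeEndpoints:
    def test_zero_let_gives_intercepts(self, ab10):
        e = car_endpoints(0.0, ab10)
        assert (e.rbe_max, e.rbe_min) == (0.834, 1.09)

    def test_reference_tissue_unit_scaling(self):
        v79 = TissueParams.from_ratio(0.15, CONSTANTS.car_reference_ab)
        e = car_endpoints(1.0, v79)
        assert e.rbe_max == pytest.approx(0.988, abs=1e-12)
        assert e.rbe_min == pytest.approx(1.096, abs=1e-12)

    def test_direct_substitution(self, ab2):
        e = car_endpoints(6.5, ab2)
        # 0.834 + 0.154 * (2.686/2) * 6.5 and 1.09 + 0.006 * (2.686/2) * 6.5
        assert e.rbe_max == pytest.approx(2.178343, abs=1e-6)
        assert e.rbe_min == pytest.approx(1.142377, abs=1e-6)

    def test_negative_let_rejected(self, ab2):
        with pytest.raises(ValueError):
            car_endpoints(-1.0, ab2)


class TestWedenbergEndpoints:
    def test_intercepts_at_zero_let(self, ab2, ab10):
        for t in (ab2, ab10):
            e = wed_endpoints(0.0, t)
            assert (e.rbe_max, e.rbe_min) == (1.0, 1.0)

    def test_direct_substitution(self, ab2):
        e = wed_endpoints(6.5, ab2)
        assert e.rbe_max == pytest.approx(2.4105, abs=1e-12)
        assert e.rbe_min == 1.0

    def test_validity_bound_value_and_warning(self, ab10):
        e = wed_endpoints(30.0, ab10)
        assert e.rbe_max == pytest.approx(2.302, abs=1e-12)
        with pytest.warns(UserWarning, match="validity"):
            wed_endpoints(30.5, ab10)


class TestEndpointsToLQ:
    def test_unit_endpoints_recover_photon_lq(self, ab2):
        lq = endpoints_to_lq(RBEEndpoints(1.0, 1.0), ab2)
        assert (lq.alpha, lq.beta) == (ab2.alpha_x, ab2.beta_x)

    def test_substitution_cases(self):
        lq = endpoints_to_lq(RBEEndpoints(2.4105, 1.0), PRINTED_AB2)
        assert lq.alpha == pytest.approx(0.2964915, abs=1e-7)
        assert lq.beta == pytest.approx(0.0616, abs=1e-12)
        lq = endpoints_to_lq(RBEEndpoints(0.834, 1.09), PRINTED_AB10)
        assert lq.alpha == pytest.approx(0.513744, abs=1e-6)
        assert lq.beta == pytest.approx(1.09**2 * 0.0616, rel=1e-12)


class TestDoseDependence:
    def test_unit_endpoints_give_unit_rbe(self, ab2):
        e = RBEEndpoints(1.0, 1.0)
        for d in (0.1, 1.0, 10.0):
            assert rbe_from_proton_dose(e, ab2, d) == pytest.approx(1.0, rel=1e-14)
            assert rbe_from_photon_dose(e, ab2, d) == pytest.approx(1.0, rel=1e-14)

    def test_proton_dose_substitution(self, ab2):
        e = RBEEndpoints(2.4105, 1.0)
        assert rbe_from_proton_dose(e, ab2, 2.0) == pytest.approx(1.413243, abs=1e-6)

    def test_photon_proton_fixed_point(self, ab2):
        # D_x = RBE * D maps one formulation onto the other
        e = RBEEndpoints(2.4105, 1.0)
        rbe = rbe_from_proton_dose(e, ab2, 2.0)
        assert rbe_from_photon_dose(e, ab2, rbe * 2.0) == pytest.approx(rbe, rel=1e-12)

    def test_asymptotes(self, ab2):
        e = RBEEndpoints(2.5, 1.2)
        assert rbe_from_photon_dose(e, ab2, 1e-9) == pytest.approx(e.rbe_max, rel=1e-6)
        assert rbe_from_proton_dose(e, ab2, 1e9) == pytest.approx(e.rbe_min, rel=1e-6)

    def test_photon_dose_agrees_with_isoeffect_root(self, ab2, ab10):
        for t in (ab2, ab10):
            for let in (1.0, 6.5):
                e = wed_endpoints(let, t)
                lq = endpoints_to_lq(e, t)
                for d_x in (0.5, 2.0, 6.0):
                    assert rbe_from_photon_dose(e, t, d_x) == pytest.approx(
                        lq_isoeffect_rbe(lq, t, d_x), rel=1e-12)


class TestCarApplicability:
    @pytest.mark.parametrize("ab, let, ok", [
        (2.0, 1.24, False),    # boundary is strictly inapplicable
        (10.0, 6.20, False),
        (2.0, 1.0, False),
        (2.0, 1.2401, True),
        (10.0, 6.21, True),
    ])
    def test_threshold(self, ab, let, ok):
        t = TissueParams.from_ratio(0.1 * ab, ab)
        assert car_applicable(let, t) is ok

    def test_minimum_applicable_let_matches_ratio_bound(self, ab2, ab10):
        let2, _ = car_min_applicable_let(ab2)
        let10, _ = car_min_applicable_let(ab10)
        assert let2 == pytest.approx(1.24, abs=1e-6)
        assert let10 == pytest.approx(6.20, abs=1e-6)


class TestLEMHelpers:
    @pytest.mark.parametrize("d_t", [10.0, 40.0])
    @pytest.mark.parametrize("tissue", [PRINTED_AB2, PRINTED_AB10])
    def test_beta_z_identity_at_alpha_x(self, tissue, d_t):
        t = dataclasses.replace(tissue, d_t=d_t)
        assert lem_beta_z(t.alpha_x, t) == pytest.approx(t.beta_x, rel=1e-12)

    def test_beta_z_substitution(self):
        t = dataclasses.replace(PRINTED_AB2, d_t=10.0)
        assert lem_beta_z(0.5, t) == pytest.approx(0.04275, abs=1e-12)

    def test_beta_z_may_go_negative_unclamped(self):
        t = dataclasses.replace(PRINTED_AB2, d_t=10.0)
        s_max = t.alpha_x + 2 * t.beta_x * t.d_t
        assert lem_beta_z(s_max + 0.2, t) == pytest.approx(-0.01, abs=1e-12)

    def test_beta_z_requires_transition_dose(self):
        with pytest.raises(ValueError, match="d_t"):
            lem_beta_z(0.5, PRINTED_AB2)

    def test_table_interpolation(self):
        table = LEMTable([1.0, 3.0], [0.1, 0.3], [0.06, 0.04])
        assert lem_table_lq(table, 1.0).alpha == 0.1
        mid = lem_table_lq(table, 2.0)
        assert mid.alpha == pytest.approx(0.2)
        assert mid.beta == pytest.approx(0.05)
        with pytest.warns(UserWarning, match="clamping"):
            low = lem_table_lq(table, 0.5)
        assert (low.alpha, low.beta) == (0.1, 0.06)

    @pytest.mark.parametrize("bad", [
        ([1.0], [0.1], [0.06]),                 # too few rows
        ([1.0, 1.0], [0.1, 0.2], [0.06, 0.05]), # non-monotone abscissa
        ([1.0, 2.0], [0.1, -0.2], [0.06, 0.05]),
    ])
    def test_malformed_table_rejected(self, bad):
        with pytest.raises(ValueError):
            LEMTable(*bad)

    def test_synthetic_table_qualitative_shape(self, ab2):
        table = make_synthetic_lem_table(ab2)
        assert np.all(np.diff(table.alpha) > 0)
        assert np.all(np.diff(table.beta) < 0)
        # slope of alpha flattens toward LET -> 0
        slopes = np.diff(table.alpha) / np.diff(table.let)
        assert slopes[0] < 0.2 * slopes[-1]


class TestModelObjects:
    def test_fixed_model_is_exactly_constant(self, ab2):
        m = FixedRBEModel(1.1)
        for d in (0.01, 1.818, 50.0):
            assert m.rbe(7.0, ab2, d) == pytest.approx(1.1, rel=1e-14)

    def test_scalar_and_array_endpoints_agree(self, ab2):
        lets = np.array([0.5, 2.0, 9.0])
        for model in (CarabeModel(), WedenbergModel(),
                      LEMTableModel(make_synthetic_lem_table(ab2))):
            rmax, rmin = model.endpoint_arrays(lets, ab2)
            for k, let in enumerate(lets):
                e = model.endpoints(float(let), ab2)
                assert e.rbe_max == pytest.approx(rmax[k], rel=1e-12)
                assert e.rbe_min == pytest.approx(rmin[k], rel=1e-12)

    def test_low_ab_tissue_has_higher_rbe(self, ab2, ab10):
        # LET sensitivity scales with 1/(alpha/beta)_x for CAR and WED
        for model in (CarabeModel(), WedenbergModel()):
            for let in (2.0, 6.5, 12.0):
                if not car_applicable(let, ab2):
                    continue
                r2 = model.rbe(let, ab2, 2.0)
                r10 = model.rbe(let, ab10, 2.0)
                assert r2 > r10
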