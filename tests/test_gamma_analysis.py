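import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from portalqa import (
    DoseProfile1D,
    GammaCriteria,
    compare_profiles,
    gamma_1d,
    make_dose_curve_pair,
    normalize_profile,
    resample_evaluated,
)
from portalqa.errors import ContractError, DomainError
from oracles import dense_gamma_max


def flat(value=100.0, n=41, x0=0.0, spacing=1.0, normalization="none"):
    x = x0 + spacing * np.arange(n)
    return DoseProfile1D(x, np.full(n, value), normalization=normalization)


class TestNormalization:
    def test_max_mode_scales_to_100(self):
        p = DoseProfile1D(np.arange(4.0), np.array([1.0, 2.0, 4.0, 2.0]))
        out = normalize_profile(p, "max")
        np.testing.assert_allclose(out.dose, [25, 50, 100, 50])
        assert out.normalization == "max"

    def test_idempotent_on_normalized_curve(self):
        p = DoseProfile1D(np.arange(4.0), np.array([25.0, 50.0, 100.0, 50.0]))
        np.testing.assert_allclose(normalize_profile(p, "max").dose, p.dose)

    def test_cax_mode_pins_central_axis(self):
        p = DoseProfile1D(np.array([-10.0, 0.0, 10.0]), np.array([1.0, 2.0, 1.0]))
        out = normalize_profile(p, "cax")
        assert np.interp(0.0, out.positions_mm, out.dose) == pytest.approx(100.0)

    def test_all_zero_profile_rejected(self):
        p = DoseProfile1D(np.arange(3.0), np.zeros(3))
        with pytest.raises(DomainError):
            normalize_profile(p, "max")


class TestResampling:
    def test_linear_ramp_is_exact(self):
        p = DoseProfile1D(np.array([0.0, 10.0]), np.array([0.0, 50.0]))
        out = resample_evaluated(p, 0.7)
        np.testing.assert_allclose(out.dose, 5.0 * out.positions_mm, atol=1e-12)
        assert out.positions_mm[0] == 0.0 and out.positions_mm[-1] == 10.0

    def test_native_grid_recovers_original(self):
        p = DoseProfile1D(np.arange(0.0, 11.0), np.random.default_rng(0).uniform(1, 2, 11))
        out = resample_evaluated(p, 1.0)
        np.testing.assert_allclose(out.dose, p.dose)

    def test_grid_point_count(self):
        p = DoseProfile1D(np.array([0.0, 10.0]), np.array([1.0, 1.0]))
        assert len(resample_evaluated(p, 1.0).positions_mm) == 11

    def test_single_point_rejected(self):
        with pytest.raises(DomainError):
            resample_evaluated(DoseProfile1D(np.array([0.0]), np.array([1.0])), 1.0)


class TestGamma:
    def test_identical_curves_give_exact_zero(self):
        p = flat()
        res = gamma_1d(p, p)
        assert np.all(res.gamma == 0.0)
        assert res.pass_fraction == 1.0 and res.max_gamma == 0.0

    @pytest.mark.parametrize("offset_percent,expected", [(3.0, 1.0), (6.0, 2.0)])
    def test_flat_offset_closed_form(self, offset_percent, expected):
        """A pure dose offset on flat curves cannot be traded for distance:
        gamma = offset / tolerance everywhere."""
        ref = flat(100.0)
        ev = flat(100.0 * (1 + offset_percent / 100))
        res = gamma_1d(ref, ev)
        np.testing.assert_allclose(res.gamma, expected, rtol=1e-9)

    def test_doubling_dose_tolerance_halves_gamma(self):
        ref, ev = flat(100.0), flat(104.0)
        g1 = gamma_1d(ref, ev, GammaCriteria(dose_tolerance_percent=2.0))
        g2 = gamma_1d(ref, ev, GammaCriteria(dose_tolerance_percent=4.0))
        np.testing.assert_allclose(g1.gamma, 2 * g2.gamma, rtol=1e-9)

    @given(st.floats(0.2, 3.0))
    @settings(max_examples=15, deadline=None)
    def test_shift_within_dta_bounded_by_dense_oracle(self, shift):
        ref, ev = make_dose_curve_pair("lateral", (0.0, shift, 0.0), seed=0)
        ref = normalize_profile(ref, "max")
        ev = normalize_profile(ev, "max")
        crit = GammaCriteria()
        dense = dense_gamma_max(ref.positions_mm, ref.dose,
                                ev.positions_mm, ev.dose, 3.0, 3.0)
        assert dense <= shift / 3.0 + 0.01
        res = gamma_1d(ref, resample_evaluated(ev, 1.0), crit)
        # 1 mm grid: nearest point is <=0.5 mm from the optimum; bound the
        # extra cost by the worst profile gradient (percent per mm)
        grad = np.max(np.abs(np.diff(ref.dose) / np.diff(ref.positions_mm)))
        norm = float(ref.dose.max())
        bound = np.sqrt(((shift + 0.5) / 3.0) ** 2
                        + (grad * 0.5 / (0.03 * norm)) ** 2)
        assert dense - 1e-9 <= res.max_gamma <= bound

    def test_pdd_within_1p6_percent_passes_3_3(self):
        ref, ev = make_dose_curve_pair("pdd", (1.2, 0.0, 0.3), seed=4)
        result = compare_profiles(ref, ev, normalize="max")
        assert result["max_dose_diff_percent"] <= 1.6
        assert result["pass_fraction"] == 1.0

    def test_roi_restricts_evaluation(self):
        ref, ev = make_dose_curve_pair("lateral", (0.0, 1.0, 0.0), seed=0)
        res = gamma_1d(normalize_profile(ref, "cax"),
                       resample_evaluated(normalize_profile(ev, "cax"), 1.0),
                       roi_mm=(-80.0, 80.0))
        assert res.positions_mm.min() >= -80 and res.positions_mm.max() <= 80

    def test_normalization_mismatch_rejected(self):
        with pytest.raises(ContractError):
            gamma_1d(flat(normalization="max"), flat(normalization="none"))

    def test_disjoint_supports_rejected(self):
        with pytest.raises(DomainError):
            gamma_1d(flat(x0=0.0), flat(x0=1000.0))
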