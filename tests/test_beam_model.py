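import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from portalqa import (
    BeamSpectrum,
    FilterSpec,
    apply_filter,
    effective_mu,
    electron_survival,
    filter_sweep,
    low_energy_fraction,
    make_toy_spectrum,
)
from portalqa.beam_model import default_polystyrene_filter
from portalqa.errors import ConfigError, DomainError
from portalqa.materials import material_mu


class TestSpectrum:
    def test_al_target_is_low_energy_rich(self, al_beam):
        assert low_energy_fraction(al_beam) > 0.3

    def test_6mv_has_negligible_diagnostic_window(self, mv_beam):
        assert low_energy_fraction(mv_beam) < 0.01

    def test_al_mode_peaks_below_150_kev(self, al_beam):
        mode_energy = al_beam.bin_centers[np.argmax(al_beam.weights)]
        assert mode_energy < 150

    def test_deterministic_for_fixed_params(self):
        a = make_toy_spectrum("al_target")
        b = make_toy_spectrum("al_target")
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ConfigError):
            make_toy_spectrum("cobalt")

    def test_zero_spectrum_rejected(self):
        with pytest.raises(DomainError):
            BeamSpectrum(np.array([1.0, 2.0]), np.array([0.0]))


class TestLowEnergyFraction:
    def test_single_bin_inside_window(self):
        spec = BeamSpectrum(np.array([50.0, 100.0]), np.array([3.0]))
        assert low_energy_fraction(spec) == 1.0

    def test_spectrum_entirely_above_window(self):
        spec = BeamSpectrum(np.array([200.0, 400.0]), np.array([1.0]))
        assert low_energy_fraction(spec) == 0.0

    def test_uniform_spectrum_prorata_overlap(self):
        # uniform fluence on [0, 300] keV: window share is 125/300 exactly
        spec = BeamSpectrum(np.arange(0.0, 301.0), np.ones(300))
        assert low_energy_fraction(spec) == pytest.approx(125 / 300, abs=1e-12)

    def test_invalid_window(self, al_beam):
        with pytest.raises(DomainError):
            low_energy_fraction(al_beam, 150, 25)

    @given(b=st.floats(30, 140))
    @settings(max_examples=20, deadline=None)
    def test_window_additivity(self, b):
        spec = make_toy_spectrum("al_target")
        total = low_energy_fraction(spec, 25, 150)
        split = low_energy_fraction(spec, 25, b) + low_energy_fraction(spec, b, 150)
        assert split == pytest.approx(total, abs=1e-12)


class TestElectronFilter:
    def setup_method(self):
        self.filt = default_polystyrene_filter()

    def test_no_filter_full_survival(self):
        assert electron_survival(self.filt, 0.0) == 1.0

    def test_csda_range_stops_electrons(self):
        assert electron_survival(self.filt, self.filt.csda_range_mm) <= 0.01

    def test_monotone_in_thickness(self):
        s = [electron_survival(self.filt, t) for t in np.linspace(0, 30, 40)]
        assert all(a >= b for a, b in zip(s, s[1:]))
        assert electron_survival(self.filt, 8) >= electron_survival(self.filt, 12) \
            >= electron_survival(self.filt, 16)

    def test_negative_thickness_rejected(self):
        with pytest.raises(DomainError):
            electron_survival(self.filt, -1.0)


class TestApplyFilter:
    def test_zero_thickness_identity(self, al_beam):
        filt = FilterSpec("polystyrene", 0.0, 20.0)
        out = apply_filter(al_beam, filt)
        np.testing.assert_array_equal(out.weights, al_beam.weights)

    def test_constant_mu_half_value_layer(self, al_beam):
        t0 = 7.0
        filt = FilterSpec("custom", t0, 20.0,
                          mu_of_E=lambda e: np.full_like(np.asarray(e, float),
                                                         np.log(2) / t0))
        out = apply_filter(al_beam, filt)
        np.testing.assert_allclose(out.weights, al_beam.weights / 2, rtol=1e-12)

    def test_doubling_thickness_squares_transmission(self, al_beam):
        f1 = FilterSpec("polystyrene", 5.0, 20.0)
        f2 = FilterSpec("polystyrene", 10.0, 20.0)
        nz = al_beam.weights > 0
        t1 = apply_filter(al_beam, f1).weights[nz] / al_beam.weights[nz]
        t2 = apply_filter(al_beam, f2).weights[nz] / al_beam.weights[nz]
        np.testing.assert_allclose(t2, t1 ** 2, rtol=1e-10)

    def test_no_bin_gains_weight(self, al_beam):
        out = apply_filter(al_beam, default_polystyrene_filter(12.0))
        assert np.all(out.weights <= al_beam.weights)


class TestFilterSweep:
    def test_electron_fraction_strictly_decreasing(self, al_beam):
        filt = default_polystyrene_filter()
        mixes = filter_sweep(al_beam, filt, [0.0, 10.0, 20.0])
        e = [m.electron_fraction for m in mixes]
        assert e[0] > e[1] > e[2]

    def test_zero_thickness_equals_unfiltered_yield(self, al_beam):
        mix = filter_sweep(al_beam, default_polystyrene_filter(), [0.0])[0]
        assert mix.electron_fraction == pytest.approx(0.358)
        assert mix.photon_fraction == pytest.approx(0.642)

    def test_low_energy_share_stable_across_sweep(self, al_beam):
        mixes = filter_sweep(al_beam, default_polystyrene_filter(),
                             list(np.arange(4.0, 22.0, 2.0)))
        le = [m.low_energy_photon_fraction for m in mixes]
        assert max(le) - min(le) < 0.02

    def test_empty_and_unsorted_rejected(self, al_beam):
        filt = default_polystyrene_filter()
        with pytest.raises(DomainError):
            filter_sweep(al_beam, filt, [])
        with pytest.raises(DomainError):
            filter_sweep(al_beam, filt, [10.0, 5.0])


def test_effective_mu_orders_beams(al_beam, mv_beam):
    """The soft beam must see a larger aluminum attenuation coefficient."""
    mu = material_mu("aluminum")
    assert effective_mu(al_beam, mu) > 2 * effective_mu(mv_beam, mu)
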