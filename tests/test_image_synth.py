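import numpy as np
import pytest

from portalqa import (
    DoseProfile1D,
    ImagingGeometry,
    PhantomSpec,
    default_detector,
    make_dose_curve_pair,
    make_toy_spectrum,
    render_beam_mode,
    render_phantom_image,
)
from portalqa.errors import DomainError, GeometryError
from portalqa.phantom_model import LamellaBlock
from portalqa.resolution_analysis import lamella_roi, region_contrast


def bar_phantom(width_mm: float) -> PhantomSpec:
    """Single centred bar block, no contrast elements."""
    return PhantomSpec(lamella_blocks=(LamellaBlock(width_mm=width_mm),),
                       contrast_holes=())


CONTACT = ImagingGeometry(ssd_cm=100.0, sid_cm=100.0)


class TestRenderer:
    def test_same_seed_bit_identical(self, phantom, geom):
        a = render_beam_mode(phantom, geom, "al_target", seed=7, scale=0.25)
        b = render_beam_mode(phantom, geom, "al_target", seed=7, scale=0.25)
        np.testing.assert_array_equal(a.pixels, b.pixels)
        assert a.pixels.dtype == np.uint16

    def test_different_seed_differs(self, phantom, geom):
        a = render_beam_mode(phantom, geom, "al_target", seed=7, scale=0.25)
        b = render_beam_mode(phantom, geom, "al_target", seed=8, scale=0.25)
        assert np.any(a.pixels != b.pixels)

    def test_undegraded_bars_are_exact_two_level(self, clean_al_image, phantom, geom):
        block = max(phantom.lamella_blocks, key=lambda b: b.width_mm)
        roi = lamella_roi(block, clean_al_image, geom)
        patch = clean_al_image.pixels[roi.row0:roi.row1, roi.col0:roi.col1]
        levels = np.unique(patch)
        assert len(levels) == 2
        mus = clean_al_image.meta["mu_eff_per_mm"]
        t_bg = np.exp(-mus["base"] * phantom.base_thickness_mm)
        t_bar = t_bg * np.exp(-mus["lamella"] * phantom.lamella_thickness_mm)
        expected = np.rint(np.array([t_bar, t_bg]) * 30000.0)
        np.testing.assert_array_equal(levels, expected)

    @pytest.mark.parametrize("width", [4.0, 1.0, 0.5])
    def test_narrower_psf_gives_higher_contrast(self, width):
        ph = bar_phantom(width)
        beam = make_toy_spectrum("al_target")
        ks = {}
        for sigma in (0.2, 0.6):
            det = default_detector("al_target", noise=False, psf_sigma_mm=sigma)
            img = render_phantom_image(ph, beam, CONTACT, det, seed=0)
            ks[sigma] = region_contrast(img, lamella_roi(ph.lamella_blocks[0],
                                                         img, CONTACT)).k
        assert ks[0.2] > ks[0.6]

    def test_field_smaller_than_phantom_rejected(self, phantom):
        small = ImagingGeometry(ssd_cm=95.2, sid_cm=110.0, field_size_cm=(10, 10))
        with pytest.raises(GeometryError):
            render_beam_mode(phantom, small, "al_target", seed=0)

    def test_supersampled_render_matches_point_sampled_blur(self):
        """Pixel-aperture integration must agree with point sampling once the
        PSF is wide relative to the pixel: same bar contrast within 1%."""
        ph = bar_phantom(2.0)
        beam = make_toy_spectrum("al_target")
        det = default_detector("al_target", noise=False, psf_sigma_mm=0.5)
        imgs = [render_phantom_image(ph, beam, CONTACT, det, seed=0, supersample=s)
                for s in (1, 4)]
        k1, k4 = [region_contrast(i, lamella_roi(ph.lamella_blocks[0], i, CONTACT)).k
                  for i in imgs]
        assert k4 == pytest.approx(k1, rel=0.01)


class TestDoseCurvePairs:
    def test_null_perturbation_is_identity(self):
        ref, ev = make_dose_curve_pair("pdd", (0.0, 0.0, 0.0), seed=1)
        np.testing.assert_array_equal(ref.positions_mm, ev.positions_mm)
        np.testing.assert_array_equal(ref.dose, ev.dose)

    def test_dose_offset_scales_everywhere(self):
        flat = DoseProfile1D(np.arange(0.0, 50.0), np.full(50, 80.0))
        ref, ev = make_dose_curve_pair(flat, (3.0, 0.0, 0.0), seed=1)
        np.testing.assert_allclose(ev.dose, 1.03 * ref.dose, rtol=1e-12)

    def test_spatial_shift_moves_positions(self):
        ref, ev = make_dose_curve_pair("lateral", (0.0, 2.0, 0.0), seed=1)
        np.testing.assert_allclose(ev.positions_mm, ref.positions_mm + 2.0)
        np.testing.assert_array_equal(ev.dose, ref.dose)

    def test_noise_is_seeded_and_recorded(self):
        a = make_dose_curve_pair("pdd", (0.0, 0.0, 0.5), seed=5)[1]
        b = make_dose_curve_pair("pdd", (0.0, 0.0, 0.5), seed=5)[1]
        np.testing.assert_array_equal(a.dose, b.dose)
        assert a.meta["perturbation"]["noise_sigma"] == 0.5

    def test_unknown_shape_rejected(self):
        with pytest.raises(DomainError):
            make_dose_curve_pair("wedge", (0, 0, 0), seed=0)
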