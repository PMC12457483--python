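import numpy as np
import pytest
from hypothesis import given, strategies as st

import demar
from demar.phantom import BasisDensityMaps
from demar.recon import (DegenerateViewError, MetalMask, ReconImage,
                         fbp_reconstruct, inpaint_sinogram, mar_pipeline,
                         metal_trace, segment_metal, to_hounsfield,
                         to_line_integrals)

from conftest import make_disc
from test_projector import density_maps, mono_spectrum


def hu_image(values, spacing=0.45, arm=""):
    return ReconImage(values=np.asarray(values, dtype=float),
                      semantics="HU", pixel_spacing_mm=spacing, arm=arm)


class TestLineIntegrals:
    def test_flat_field_gives_zero(self, small_geometry, library):
        maps = density_maps(np.zeros((64, 64)))
        basis = demar.project_mass_density(maps, small_geometry)
        sino = demar.simulate_polychromatic(
            basis, demar.build_spectrum(100, 9, [], library), library)
        assert np.allclose(to_line_integrals(sino), 0.0, atol=1e-14)

    def test_monochromatic_water_path(self, small_geometry, library):
        maps = density_maps(make_disc(64, 18, 1.0))
        basis = demar.project_mass_density(maps, small_geometry)
        e0 = 80.0
        sino = demar.simulate_polychromatic(basis, mono_spectrum(e0), library)
        mu = library.get("water").mu(e0)
        assert np.allclose(to_line_integrals(sino),
                           mu * basis.sinograms["water"], rtol=1e-12)

    def test_polychromatic_value_within_spectral_bounds(self, small_geometry,
                                                        library):
        maps = density_maps(make_disc(64, 18, 1.0))
        basis = demar.project_mass_density(maps, small_geometry)
        spectrum = demar.build_spectrum(100, 9, [("Al", 2.5)], library)
        sino = demar.simulate_polychromatic(basis, spectrum, library)
        li = to_line_integrals(sino)
        a = basis.sinograms["water"]
        water = library.get("water")
        nz = a > 0.1
        lo = water.mu(spectrum.kvp) * a[nz]
        hi = water.mu(spectrum.energies[0]) * a[nz]
        assert np.all(li[nz] > lo) and np.all(li[nz] < hi)

    def test_non_positive_intensity_rejected(self, small_geometry, library):
        maps = density_maps(np.zeros((64, 64)))
        basis = demar.project_mass_density(maps, small_geometry)
        sino = demar.simulate_polychromatic(
            basis, demar.build_spectrum(100, 9, [], library), library)
        sino.intensity[0, 0] = 0.0
        with pytest.raises(ValueError):
            to_line_integrals(sino)


class TestFBP:
    def test_zero_sinogram_reconstructs_to_zero(self, small_geometry):
        img = fbp_reconstruct(np.zeros(small_geometry.sinogram_shape()),
                              small_geometry)
        assert np.allclose(img.values, 0.0)

    def test_uniform_disc_value_recovered(self, library):
        """Monochromatic water disc: interior mean within 2% of mu*rho."""
        geometry = demar.Geometry(n_views=180, image_size=128)
        maps = density_maps(make_disc(128, 45, 1.0))
        e0 = 80.0
        basis = demar.project_mass_density(maps, geometry)
        sino = demar.simulate_polychromatic(basis, mono_spectrum(e0), library)
        img = fbp_reconstruct(to_line_integrals(sino), geometry)
        mu_true = library.get("water").mu(e0)  # rho = 1
        rr, cc = np.ogrid[:128, :128]
        interior = (rr - 63.5) ** 2 + (cc - 63.5) ** 2 <= (0.8 * 45) ** 2
        assert img.values[interior].mean() == pytest.approx(mu_true,
                                                            rel=0.02)

    def test_reconstruction_is_linear(self, small_geometry):
        rng = np.random.default_rng(0)
        a = rng.random(small_geometry.sinogram_shape())
        b = rng.random(small_geometry.sinogram_shape())
        img_ab = fbp_reconstruct(a + b, small_geometry).values
        img_sum = (fbp_reconstruct(a, small_geometry).values
                   + fbp_reconstruct(b, small_geometry).values)
        assert np.allclose(img_ab, img_sum, atol=1e-10)


class TestHounsfield:
    @pytest.mark.parametrize("mu,expected", [(0.2, 0.0), (0.0, -1000.0),
                                             (0.4, 1000.0)])
    def test_reference_points(self, mu, expected):
        img = ReconImage(values=np.full((4, 4), mu), semantics="mu_cm",
                         pixel_spacing_mm=0.45)
        assert to_hounsfield(img, 0.2).values[0, 0] == pytest.approx(expected)

    def test_non_positive_reference_rejected(self):
        img = ReconImage(values=np.zeros((4, 4)), semantics="mu_cm",
                         pixel_spacing_mm=0.45)
        with pytest.raises(ValueError):
            to_hounsfield(img, 0.0)


class TestSegmentMetal:
    def test_uniform_water_image_yields_empty_mask(self):
        mask = segment_metal(hu_image(np.zeros((32, 32))), 1000.0)
        assert not mask.any()

    def test_constructed_blob_segmented_exactly(self):
        img = np.zeros((32, 32))
        img[10:15, 12] = 8000.0
        mask = segment_metal(hu_image(img), 3000.0)
        assert np.array_equal(mask.mask, img > 3000.0)

    def test_isolated_single_pixel_removed(self):
        img = np.zeros((32, 32))
        img[5, 5] = 9000.0
        mask = segment_metal(hu_image(img), 3000.0)
        assert not mask.any()

    def test_lower_threshold_never_shrinks_mask(self):
        rng = np.random.default_rng(1)
        img = hu_image(rng.normal(2000, 1500, (48, 48)))
        hi = segment_metal(img, 4000.0)
        lo = segment_metal(img, 2500.0)
        assert np.all(lo.mask | ~hi.mask)


class TestMetalTrace:
    def test_empty_mask_gives_empty_trace(self, small_geometry):
        mask = MetalMask(mask=np.zeros((64, 64), dtype=bool))
        assert not metal_trace(mask, small_geometry).any()

    def test_point_mask_traces_a_thin_sinusoid(self, small_geometry):
        mask = np.zeros((64, 64), dtype=bool)
        mask[40, 40] = True
        mask[40, 41] = True  # two pixels so despeckle-scale objects survive
        trace = metal_trace(MetalMask(mask=mask), small_geometry)
        per_view = trace.sum(axis=1)
        assert np.all(per_view >= 1) and np.all(per_view <= 4)

    def test_mask_union_traces_superset(self, small_geometry):
        a = np.zeros((64, 64), dtype=bool)
        b = np.zeros((64, 64), dtype=bool)
        a[20:24, 20:24] = True
        b[40:44, 44:48] = True
        tr_a = metal_trace(MetalMask(mask=a), small_geometry)
        tr_b = metal_trace(MetalMask(mask=b), small_geometry)
        tr_ab = metal_trace(MetalMask(mask=a | b), small_geometry)
        assert np.all(tr_ab[tr_a]) and np.all(tr_ab[tr_b])

    def test_margin_widens_the_trace(self, small_geometry):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:34, 30:34] = True
        plain = metal_trace(MetalMask(mask=mask), small_geometry)
        wide = metal_trace(MetalMask(mask=mask), small_geometry, margin_px=2)
        assert wide.sum() > plain.sum() and np.all(wide[plain])


class TestInpainting:
    def test_empty_trace_is_identity(self):
        rng = np.random.default_rng(0)
        sino = rng.random((10, 20))
        out = inpaint_sinogram(sino, np.zeros_like(sino, dtype=bool))
        assert np.array_equal(out, sino)

    def test_linear_fill_values(self):
        sino = np.zeros((1, 7))
        sino[0] = [0.5, 1.0, 9.0, 9.0, 9.0, 2.0, 2.5]
        trace = np.zeros_like(sino, dtype=bool)
        trace[0, 2:5] = True
        out = inpaint_sinogram(sino, trace)
        assert np.allclose(out[0, 2:5], [1.25, 1.5, 1.75])
        assert np.array_equal(out[0, [0, 1, 5, 6]], sino[0, [0, 1, 5, 6]])

    def test_edge_run_extends_nearest_value(self):
        sino = np.array([[9.0, 9.0, 3.0, 4.0]])
        trace = np.array([[True, True, False, False]])
        out = inpaint_sinogram(sino, trace)
        assert np.allclose(out[0], [3.0, 3.0, 3.0, 4.0])

    @given(st.integers(1, 6), st.floats(0.1, 5.0), st.floats(0.1, 5.0))
    def test_fill_bounded_by_run_boundaries(self, width, left, right):
        sino = np.zeros((1, width + 4))
        sino[0, 1] = left
        sino[0, width + 2] = right
        trace = np.zeros_like(sino, dtype=bool)
        trace[0, 2:width + 2] = True
        out = inpaint_sinogram(sino, trace)
        filled = out[0, 2:width + 2]
        assert np.all(filled >= min(left, right) - 1e-12)
        assert np.all(filled <= max(left, right) + 1e-12)

    def test_fully_traced_view_rejected(self):
        sino = np.ones((2, 5))
        trace = np.zeros_like(sino, dtype=bool)
        trace[1] = True
        with pytest.raises(DegenerateViewError):
            inpaint_sinogram(sino, trace)


class TestMARPipeline:
    def _phantom_line_integrals(self, geometry, library, metal=True):
        n = geometry.image_size
        gel = make_disc(n, int(n * 0.42), 1.0)
        maps = {"water": gel}
        labels = np.where(gel > 0, "water", "")
        if metal:
            ins = make_disc(n, 3, 4.506, center=n // 2 + 6)
            gel[ins > 0] = 0
            maps["titanium"] = ins
            labels = np.where(ins > 0, "titanium", labels)
        dm = BasisDensityMaps(maps=maps, labels=labels,
                              pixel_spacing_mm=geometry.pixel_spacing_mm)
        basis = demar.project_mass_density(dm, geometry)
        spectrum = demar.build_spectrum(100, 18, [("Al", 2.5), ("Cu", 0.2)],
                                        library)
        sino = demar.simulate_polychromatic(basis, spectrum, library)
        mu_ref = demar.effective_mu(spectrum, library.get("water"),
                                    density=1.0)
        return to_line_integrals(sino), mu_ref

    def test_metal_free_input_equals_plain_fbp(self, small_geometry,
                                               library):
        li, mu_ref = self._phantom_line_integrals(small_geometry, library,
                                                  metal=False)
        plain = to_hounsfield(fbp_reconstruct(li, small_geometry), mu_ref)
        mar = mar_pipeline(li, small_geometry, mu_ref, 2500.0)
        assert np.array_equal(mar.values, plain.values)
        assert mar.arm == "MAR"

    def test_masked_pixels_keep_first_pass_values(self, small_geometry,
                                                  library):
        li, mu_ref = self._phantom_line_integrals(small_geometry, library)
        first = to_hounsfield(fbp_reconstruct(li, small_geometry), mu_ref)
        mask = segment_metal(first, 2500.0)
        assert mask.any()
        mar = mar_pipeline(li, small_geometry, mu_ref, 2500.0)
        assert np.array_equal(mar.values[mask.mask], first.values[mask.mask])

    def test_mar_reduces_artifact_score_on_metal_phantom(self, library):
        """End-to-end: inpainting MAR scores below plain FBP around a
        titanium insert under the polychromatic beam."""
        geometry = demar.Geometry(n_views=180, image_size=128)
        li, mu_ref = self._phantom_line_integrals(geometry, library)
        li_u, _ = self._phantom_line_integrals(geometry, library, metal=False)
        plain = to_hounsfield(fbp_reconstruct(li, geometry), mu_ref)
        mar = mar_pipeline(li, geometry, mu_ref, 2500.0)
        uniform = to_hounsfield(fbp_reconstruct(li_u, geometry), mu_ref)
        c = 128 // 2 + 6
        rois = demar.ROISpec(
            artifact_rois=tuple((c + 14 * s, c + 14 * t, 4.0)
                                for s, t in [(1, 1), (1, -1), (-1, -1),
                                             (-1, 1)]),
            uniformity_roi=(63.5, 63.5, 6.0))
        score_plain = demar.artifact_score(plain, uniform, rois)
        score_mar = demar.artifact_score(mar, uniform, rois)
        assert score_mar < score_plain
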