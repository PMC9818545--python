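"""Macenko estimation and template normalization against generative truth."""

import numpy as np
import pytest

from histopatch.stain import (
    DegenerateImageError,
    StainModel,
    angle_between_deg,
    concentrations,
    estimate_stains,
    normalize_pixels,
    normalize_to_template,
    od_to_rgb,
    rgb_to_od,
    separate_stains,
)
from histopatch.synthetic import (
    DEFAULT_STAIN_MATRIX,
    FixtureSpec,
    compose_image,
    concentration_fields,
    render_image,
)
from tests.conftest import make_patch


@pytest.fixture(scope="module")
def benign_image(easy_spec):
    return render_image("benign", easy_spec, 0).pixels


class TestOpticalDensity:
    def test_background_pixel_has_zero_od(self):
        od = rgb_to_od(np.full((2, 2, 3), 1.0), background_intensity=1.0)
        assert np.allclose(od, 0.0, atol=1e-5)

    def test_tenth_of_background_is_unit_od(self):
        od = rgb_to_od(np.full((1, 1, 3), 0.1), background_intensity=1.0)
        assert np.allclose(od, 1.0, atol=1e-5)

    def test_unit_od_transmits_ten_percent(self):
        assert np.allclose(od_to_rgb(np.ones((1, 1, 3))), 0.1, atol=1e-6)
        assert np.allclose(od_to_rgb(np.zeros((1, 1, 3))), 1.0)

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        pixels = rng.uniform(0.01, 1.0, (8, 8, 3))
        assert np.allclose(od_to_rgb(rgb_to_od(pixels)), pixels, atol=1e-5)


class TestEstimateStains:
    def test_recovers_generative_vectors_within_5_degrees(self, easy_spec):
        for label in ("normal", "invasive"):
            pixels = render_image(label, easy_spec, 0).pixels
            model = estimate_stains(pixels)
            for k in range(2):
                err = angle_between_deg(model.stain_matrix[:, k], DEFAULT_STAIN_MATRIX[:, k])
                assert err < 5.0, f"{label} column {k}: {err:.2f} degrees"

    def test_columns_unit_norm_and_nonnegative(self, benign_image):
        model = estimate_stains(benign_image)
        assert np.allclose(np.linalg.norm(model.stain_matrix, axis=0), 1.0)
        assert (model.stain_matrix >= 0).all()
        assert (model.max_concentrations > 0).all()

    def test_hematoxylin_column_is_red_od_dominant(self, benign_image):
        model = estimate_stains(benign_image)
        m = model.stain_matrix
        assert m[0, 0] / m[2, 0] > m[0, 1] / m[2, 1]

    def test_pure_white_image_is_degenerate(self):
        with pytest.raises(DegenerateImageError, match="tissue pixels"):
            estimate_stains(np.ones((16, 16, 3)))

    def test_single_stain_image_is_degenerate(self):
        conc = np.linspace(0.5, 2.0, 256).reshape(16, 16)
        pixels = od_to_rgb(conc[:, :, None] * DEFAULT_STAIN_MATRIX[:, 0])
        with pytest.raises(DegenerateImageError, match="rank 1"):
            estimate_stains(pixels)

    def test_pixel_order_invariance(self, benign_image):
        rng = np.random.default_rng(3)
        shuffled = benign_image[rng.permutation(benign_image.shape[0])][:, rng.permutation(benign_image.shape[1])]
        a = estimate_stains(benign_image)
        b = estimate_stains(shuffled)
        assert np.allclose(a.stain_matrix, b.stain_matrix, atol=1e-9)
        assert np.allclose(a.max_concentrations, b.max_concentrations, atol=1e-9)

    def test_recovery_error_grows_with_noise(self):
        errors = []
        for noise_sd in (0.0, 0.01, 0.03):
            spec = FixtureSpec.easy(n_per_class=1, height=512, width=1024, seed=5, noise_sd=noise_sd)
            model = estimate_stains(render_image("benign", spec, 0).pixels)
            errors.append(
                max(
                    angle_between_deg(model.stain_matrix[:, k], DEFAULT_STAIN_MATRIX[:, k])
                    for k in range(2)
                )
            )
        assert errors[0] < 5.0
        assert errors[0] <= errors[1] + 0.5 and errors[1] <= errors[2] + 0.5


class TestConcentrations:
    def test_nnls_solution_is_nonnegative_and_near_exact_on_clean_mixture(self):
        rng = np.random.default_rng(1)
        true_c = rng.uniform(0.0, 2.0, (32, 32, 2))
        pixels = od_to_rgb(true_c @ DEFAULT_STAIN_MATRIX.T)
        for method in ("nnls", "clip"):
            c = concentrations(pixels, DEFAULT_STAIN_MATRIX, method=method)
            assert c.min() >= 0
            assert np.allclose(c, true_c, atol=1e-3)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            concentrations(np.ones((2, 2, 3)) * 0.5, DEFAULT_STAIN_MATRIX, method="magic")


class TestNormalizeToTemplate:
    def test_self_normalization_is_identity_within_2_of_255(self, benign_image):
        template = estimate_stains(benign_image)
        out = normalize_pixels(benign_image, template)
        assert np.abs(out - benign_image).max() <= 2 / 255

    def test_identical_fields_under_different_stains_normalize_alike(self, easy_spec):
        fields = concentration_fields("benign", easy_spec, 0)
        other = np.array([[0.55, 0.15], [0.75, 0.80], [0.37, 0.55]])
        other = other / np.linalg.norm(other, axis=0)
        img_a = compose_image(*fields, DEFAULT_STAIN_MATRIX)
        img_b = compose_image(*fields, other)
        template = estimate_stains(img_a)
        out_a = normalize_pixels(img_a, template)
        out_b = normalize_pixels(img_b, template)
        diff = np.abs(out_a - out_b)
        assert diff.mean() < 0.005 and np.quantile(diff, 0.99) < 0.02

    def test_normalized_output_matches_template_concentration_scale(self, easy_spec, benign_image):
        template = estimate_stains(benign_image)
        source = render_image("insitu", easy_spec, 1).pixels
        re_est = estimate_stains(normalize_pixels(source, template))
        assert np.allclose(re_est.max_concentrations, template.max_concentrations, rtol=0.05)

    def test_patch_metadata_preserved_and_degenerate_fallback(self, benign_image):
        template = estimate_stains(benign_image)
        patch = make_patch(benign_image[:256, :256].copy(), parent_id="p1", row=1, col=2, label="benign")
        out = normalize_to_template(patch, template)
        assert (out.parent_id, out.row, out.col, out.label) == ("p1", 1, 2, "benign")
        assert out.pixels.shape == patch.pixels.shape
        white = make_patch(np.ones((64, 64, 3), dtype=np.float32), parent_id="white")
        with pytest.raises(DegenerateImageError, match="white_r0_c0"):
            normalize_to_template(white, template)
        passthrough = normalize_to_template(white, template, fallback_passthrough=True)
        assert np.array_equal(passthrough.pixels, white.pixels)

    def test_stain_separation_panels_recombine(self, benign_image):
        model = estimate_stains(benign_image)
        h_img, e_img = separate_stains(benign_image, model)
        od_sum = rgb_to_od(h_img) + rgb_to_od(e_img)
        recon = od_to_rgb(od_sum)
        # separated OD panels add back to the two-stain reconstruction
        full = od_to_rgb(
            concentrations(benign_image, model.stain_matrix) @ model.stain_matrix.T
        )
        assert np.abs(recon - full).max() < 0.01


def test_stain_model_roundtrips_through_json(tmp_path, benign_image):
    model = estimate_stains(benign_image)
    model.to_json(tmp_path / "m.json")
    back = StainModel.from_json(tmp_path / "m.json")
    assert np.allclose(back.stain_matrix, model.stain_matrix)
    assert np.allclose(back.max_concentrations, model.max_concentrations)
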