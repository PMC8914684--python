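"""Morph weights, correction polynomials and avatar blending."""

import warnings

import numpy as np
import pytest

from maternshape import (
    AlpCalibration,
    BodyMeasurements,
    MorphWeights,
    alp_corrections,
    base_weights,
    blend,
    morph_weights,
)
from maternshape.errors import InvalidArgumentError, TopologyError
from maternshape.avatars import Mesh


def _body(chest=90, waist=70, hip=95, height=165, inseam=73):
    return BodyMeasurements(chest, waist, hip, 28, 50, inseam, height)


class TestBaseWeights:
    def test_anchor_rescalings(self):
        assert base_weights(_body(chest=57)).k01 == pytest.approx(0.0)
        assert base_weights(_body(chest=200)).k01 == pytest.approx(1.0)
        assert base_weights(_body(waist=40)).k02 == pytest.approx(0.0)
        assert base_weights(_body(hip=180)).k03 == pytest.approx(1.0)

    def test_height_weight_carries_gain_factor(self):
        assert base_weights(_body(height=199)).k04 == pytest.approx(1.36)
        assert base_weights(_body(height=165)).k04 == pytest.approx(0.0)

    def test_inseam_form_uses_published_anchors(self):
        # (inseam - 78) / (120 - 48), shipped as printed even though the
        # thin-avatar inseam is ~73; calibration absorbs the offset
        assert base_weights(_body(inseam=78)).k05 == pytest.approx(0.0)
        assert base_weights(_body(inseam=150)).k05 == pytest.approx(1.0)

    def test_pregnant_belly_base_weight_is_zero(self):
        assert base_weights(_body()).k00 == 0.0


class TestAlpCorrections:
    def test_zero_tensor_gives_zero_corrections(self):
        cal = AlpCalibration.zeros("pregnant")
        assert np.allclose(alp_corrections(cal, 22.0, 24.0), 0.0)

    def test_published_chest_week_coefficient_at_week_24(self):
        rows = AlpCalibration.pregnant_default().rows()
        a, b, c = rows["Alp01"]
        value = c * 24**2 + b * 24 + a
        assert value == pytest.approx(-8.995e-4, abs=1e-6)

    def test_early_pregnancy_belly_ramp(self):
        """Below week 12 the polynomials hold at week 12 and only the belly
        correction is ramped by week/12."""
        cal = AlpCalibration.pregnant_default()
        at6 = alp_corrections(cal, 22.0, 6.0)
        at12 = alp_corrections(cal, 22.0, 12.0)
        assert at6[0] == pytest.approx(0.5 * at12[0])
        assert np.allclose(at6[1:], at12[1:])

    def test_belly_correction_vanishes_at_week_zero(self):
        cal = AlpCalibration.pregnant_default()
        assert alp_corrections(cal, 22.0, 0.0)[0] == 0.0

    def test_postpartum_has_no_belly_correction(self):
        cal = AlpCalibration.postpartum_default()
        assert alp_corrections(cal, 22.0, 12.0)[0] == 0.0

    def test_week_clamped_to_fit_domain(self):
        cal = AlpCalibration.pregnant_default()
        assert np.allclose(alp_corrections(cal, 22.0, 41.0), alp_corrections(cal, 22.0, 40.0))

    def test_continuity_in_week(self):
        cal = AlpCalibration.pregnant_default()
        a = alp_corrections(cal, 22.0, 23.999999)
        b = alp_corrections(cal, 22.0, 24.000001)
        assert np.allclose(a, b, atol=1e-5)

    def test_postpartum_tensor_row_validation(self):
        t = np.zeros((6, 3, 3))
        t[0, 0, 0] = 1.0
        with pytest.raises(InvalidArgumentError):
            AlpCalibration(mode="postpartum", tensor=t)


class TestMorphWeights:
    def test_zero_tensor_weights_equal_base(self):
        body = _body()
        k = morph_weights(body, 22.0, 24.0, AlpCalibration.zeros("pregnant"), "pregnant")
        assert np.allclose(k.as_array(), base_weights(body).as_array())

    def test_postpartum_belly_weight_forced_zero(self):
        k = morph_weights(_body(), 22.0, 12.0, mode="postpartum")
        assert k.k0 == 0.0

    def test_base_coefficient_complements_sum(self):
        k = morph_weights(_body(), 22.0, 24.0, mode="pregnant")
        assert k.base_coefficient == pytest.approx(1.0 - k.as_array().sum())

    def test_sanity_band_warns_but_does_not_clamp(self):
        with pytest.warns(UserWarning, match="sanity band"):
            k = MorphWeights("pregnant", 0.0, 2.0, 0.0, 0.0, 0.0, 0.0)
        assert k.k1 == 2.0

    def test_mode_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            morph_weights(_body(), 22.0, 12.0, AlpCalibration.postpartum_default(), "pregnant")


class TestTensorSerialization:
    @pytest.mark.parametrize("mode", ["pregnant", "postpartum"])
    def test_json_round_trip(self, tmp_path, mode):
        cal = getattr(AlpCalibration, f"{mode}_default")()
        path = tmp_path / "tensor.json"
        cal.to_json(path)
        back = AlpCalibration.from_json(path)
        assert back.mode == mode
        assert np.array_equal(back.tensor, cal.tensor)

    def test_pregnant_tensor_has_18_rows_postpartum_15(self):
        assert len(AlpCalibration.pregnant_default().rows()) == 18
        assert len(AlpCalibration.postpartum_default().rows()) == 15


class TestBlend:
    def test_zero_weights_reproduce_thin_avatar(self, avatars):
        out = blend(avatars, MorphWeights("pregnant", 0, 0, 0, 0, 0, 0))
        assert np.array_equal(out.vertices, avatars.thin.vertices)

    def test_unit_chest_weight_reproduces_big_breast_avatar(self, avatars):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = blend(avatars, MorphWeights("pregnant", 0, 1, 0, 0, 0, 0))
        assert np.allclose(out.vertices, avatars.big_breast.vertices)

    def test_unit_belly_weight_reproduces_pregnant_avatar(self, avatars):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = blend(avatars, MorphWeights("pregnant", 1, 0, 0, 0, 0, 0))
        assert np.allclose(out.vertices, avatars.pregnant_thin.vertices)

    def test_blend_displacement_is_linear_in_weights(self, avatars):
        k = np.array([0.3, 0.2, 0.15, 0.1, -0.05, 0.08])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = blend(avatars, MorphWeights("pregnant", *k)).vertices
            half = blend(avatars, MorphWeights("pregnant", *(0.5 * k))).vertices
        thin = avatars.thin.vertices
        assert np.allclose(half - thin, 0.5 * (full - thin), atol=1e-9)

    def test_affinity_commutes_with_weight_mixing(self, avatars):
        ka = np.array([0.2, 0.1, 0.3, 0.05, 0.0, 0.1])
        kb = np.array([0.0, 0.4, 0.1, 0.2, 0.1, 0.0])
        lam = 0.3
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mixed = blend(avatars, MorphWeights("pregnant", *(lam * ka + (1 - lam) * kb)))
            va = blend(avatars, MorphWeights("pregnant", *ka)).vertices
            vb = blend(avatars, MorphWeights("pregnant", *kb)).vertices
        assert np.allclose(mixed.vertices, lam * va + (1 - lam) * vb, atol=1e-9)

    def test_topology_mismatch_rejected(self, avatars):
        from dataclasses import replace

        broken = replace(
            avatars,
            tall=Mesh(avatars.tall.vertices, avatars.tall.faces[:-2]),
        )
        with pytest.raises(TopologyError):
            blend(broken, MorphWeights("pregnant", 0, 0, 0, 0, 0, 0))

    def test_pregnant_week_zero_equals_belly_free_blend(self, avatars):
        """The belly ramp sends alp0 to zero at conception, so the week-0
        pregnant blend coincides with the same blend without the belly term."""
        body = _body()
        k = morph_weights(body, 22.0, 0.0, mode="pregnant")
        assert k.k0 == 0.0
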