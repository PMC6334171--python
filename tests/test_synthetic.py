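import numpy as np
import pytest

from kdnaquant.rasters import LABEL_NUCLEUS, LABEL_ORGANELLE
from kdnaquant.synthetic import (
    DAPI_TRUTH,
    REDDOT1_TRUTH,
    CellSpec,
    Disk,
    DyeResponseTruth,
    Ellipse,
    OpticsSpec,
    make_species_cell,
    render_field,
    simulate_calibration,
)

TRUTHS = [DAPI_TRUTH, REDDOT1_TRUTH]
CLEAN = OpticsSpec(shot_noise=False, read_noise_sd=0.0, digitize=False)


def brute_force_blur(image, sigma, truncate=8.0):
    """Independent oracle: direct convolution with an explicit Gaussian kernel.

    Zero padding outside the raster, kernel truncated far out (8 sigma) so
    that the oracle is effectively exact.
    """
    radius = int(truncate * sigma + 0.5)
    x = np.arange(-radius, radius + 1)
    k1 = np.exp(-(x**2) / (2 * sigma**2))
    k1 /= k1.sum()
    out = np.zeros_like(image)
    padded = np.pad(image, radius)
    # separable kernel applied by explicit shifting, no scipy convolution
    tmp = np.zeros_like(padded)
    for i, w in enumerate(k1):
        tmp += w * np.roll(padded, i - radius, axis=0)
    res = np.zeros_like(padded)
    for i, w in enumerate(k1):
        res += w * np.roll(tmp, i - radius, axis=1)
    out = res[radius:-radius, radius:-radius]
    return out


class TestSimulateCalibration:
    def test_noise_free_values_exact(self):
        truth = DyeResponseTruth("RedDot1", 0.70, 0.30)
        recs = simulate_calibration([truth], [0.0, 0.5, 1.0], noise_sd=0.0)
        assert [r.fluorescence for r in recs] == [0.70, 0.85, 1.0]

    def test_one_record_per_oligo_dye_pair(self):
        recs = simulate_calibration(TRUTHS, list(np.linspace(0, 1, 21)))
        assert len(recs) == 42
        assert {r.dye for r in recs} == {"DAPI", "RedDot1"}

    def test_seeded_runs_bit_identical(self):
        a = simulate_calibration(TRUTHS, [0.2, 0.4], noise_sd=0.05, seed=9)
        b = simulate_calibration(TRUTHS, [0.2, 0.4], noise_sd=0.05, seed=9)
        assert a == b

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            simulate_calibration(TRUTHS, [0.5], noise_sd=-0.1)

    def test_truth_normalisation_enforced(self):
        with pytest.raises(ValueError, match="normalised"):
            DyeResponseTruth("bad", 0.5, 0.9)


def simple_cell(nucleus_mbp=10.0, organelle_mbp=10.0, nucleus_at=0.5,
                organelle_at=0.5, **kwargs):
    return CellSpec(
        nucleus_mbp=nucleus_mbp,
        organelle_mbp=organelle_mbp,
        nucleus_at=nucleus_at,
        organelle_at=organelle_at,
        nucleus_geom=Ellipse(32, 20, 8, 8),
        organelle_geom=Disk(32, 48, 8),
        **kwargs,
    )


class TestRenderField:
    def test_empty_cell_gives_flat_background(self):
        optics = OpticsSpec(shape=(64, 64), shot_noise=False, read_noise_sd=0.0,
                            digitize=False, background_level=100.0)
        field, _ = render_field([simple_cell(0.0, 0.0)], TRUTHS, optics)
        assert np.all(field.dapi == 100.0)
        assert np.all(field.reddot == 100.0)

    def test_equal_compartments_give_equal_integrated_signal(self):
        optics = OpticsSpec(shape=(64, 64), shot_noise=False, read_noise_sd=0.0,
                            digitize=False)
        field, gt = render_field([simple_cell()], TRUTHS, optics)
        signal = field.reddot - optics.background_level
        s_nuc = signal[gt.labels == LABEL_NUCLEUS].sum()
        s_org = signal[gt.labels == LABEL_ORGANELLE].sum()
        assert s_org == pytest.approx(s_nuc, rel=0.02)  # blur leakage tolerance

    def test_forward_model_matches_brute_force_oracle(self):
        """Rendered channels equal direct per-pixel evaluation of the model."""
        optics = OpticsSpec(shape=(64, 64), shot_noise=False, read_noise_sd=0.0,
                            digitize=False, blur_sigma=1.0)
        cell = simple_cell(nucleus_mbp=77.9, organelle_mbp=4.18,
                           nucleus_at=0.53, organelle_at=0.75)
        field, gt = render_field([cell], TRUTHS, optics)

        for truth, channel in ((DAPI_TRUTH, field.dapi), (REDDOT1_TRUTH, field.reddot)):
            pre_blur = optics.counts_per_mbp * (
                truth.response(cell.nucleus_at) * gt.density_maps["nuclear"]
                + truth.response(cell.organelle_at) * gt.density_maps["organellar"]
            )
            expected = brute_force_blur(pre_blur, optics.blur_sigma) + 100.0
            for label in (LABEL_NUCLEUS, LABEL_ORGANELLE):
                mask = gt.labels == label
                assert channel[mask].sum() == pytest.approx(
                    expected[mask].sum(), rel=1e-4
                )

    def test_ground_truth_proportion(self):
        field, gt = render_field([simple_cell(organelle_mbp=5.0, nucleus_mbp=15.0)],
                                 TRUTHS, CLEAN)
        assert gt.p_true == pytest.approx(0.25)

    def test_determinism_bit_for_bit(self):
        optics = OpticsSpec(shape=(64, 64))
        f1, _ = render_field([simple_cell()], TRUTHS, optics, seed=3)
        f2, _ = render_field([simple_cell()], TRUTHS, optics, seed=3)
        assert np.array_equal(f1.dapi, f2.dapi)
        assert np.array_equal(f1.reddot, f2.reddot)

    def test_linearity_in_dna_amount(self):
        f1, _ = render_field([simple_cell(10.0, 10.0)], TRUTHS, CLEAN)
        f2, _ = render_field([simple_cell(20.0, 20.0)], TRUTHS, CLEAN)
        bg = CLEAN.background_level
        np.testing.assert_allclose(f2.reddot - bg, 2.0 * (f1.reddot - bg),
                                   rtol=1e-9, atol=1e-9)

    def test_density_pixels_carry_labels(self):
        _, gt = render_field([simple_cell()], TRUTHS, CLEAN)
        for cls in ("nuclear", "organellar"):
            assert np.all(gt.labels[gt.density_maps[cls] > 0] > 0)

    def test_overlapping_shapes_rejected(self):
        cell = CellSpec(10, 10, 0.5, 0.5,
                        nucleus_geom=Ellipse(32, 32, 10, 10),
                        organelle_geom=Disk(32, 36, 8))
        with pytest.raises(ValueError, match="overlap"):
            render_field([cell], TRUTHS, CLEAN)

    def test_shape_outside_raster_rejected(self):
        cell = simple_cell()
        bad = CellSpec(10, 10, 0.5, 0.5,
                       nucleus_geom=cell.nucleus_geom,
                       organelle_geom=Disk(2, 60, 8))
        with pytest.raises(ValueError, match="outside"):
            render_field([bad], TRUTHS, OpticsSpec(shape=(64, 64)))

    def test_saturation_reported(self):
        optics = OpticsSpec(shape=(64, 64), bit_depth=8, shot_noise=False,
                            read_noise_sd=0.0, background_level=10.0)
        field, _ = render_field([simple_cell()], TRUTHS, optics)
        assert field.meta["clipped_pixels"]["RedDot1"] > 0
        assert field.reddot.max() == 255


class TestPresets:
    @pytest.mark.parametrize("name,p", [("T_brucei", 0.0509), ("T_borreli", 0.491),
                                        ("D_papillatum", 0.587), ("Perkinsela", 0.928)])
    def test_nominal_cell_hits_configured_proportion(self, name, p):
        cell = make_species_cell(name)
        _, gt = render_field([cell], TRUTHS, CLEAN)
        assert gt.p_true == pytest.approx(p, abs=1e-9)

    def test_host_nucleus_excluded_from_p_true(self):
        cell = make_species_cell("Perkinsela", include_host=True)
        assert cell.host_nucleus_mbp > 0
        _, gt = render_field([cell], TRUTHS, CLEAN)
        assert gt.p_true == pytest.approx(0.928, abs=1e-9)
        assert np.any(gt.labels == 3)

    def test_signal_proportion_reflects_dye_response(self):
        """With AT-differing compartments the RedDot1 signal fraction is biased
        away from the DNA fraction, in the direction of the AT-richer class."""
        cell = make_species_cell("T_brucei")
        _, gt = render_field([cell], TRUTHS, CLEAN)
        assert gt.p_signal > gt.p_true  # organelle is AT-richer, RedDot1-brighter
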