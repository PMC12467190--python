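"""Image-quality metric definitions against loop oracles and hand values."""

import math

import numpy as np
import pytest

from erisnet.metrics import (
    MetricParams,
    epi,
    evaluate_dataset,
    mse,
    noise_variance,
    psnr,
    ssim,
    vif,
)

GLOBAL = MetricParams(ssim_mode="global", epi_mode="paper")


def mse_loop(a, b):
    total = 0.0
    for i in range(a.shape[0]):
        for j in range(a.shape[1]):
            total += (a[i, j] - b[i, j]) ** 2
    return total / a.size


def ssim_global_loop(a, b, c1, c2):
    mx, my = a.mean(), b.mean()
    vx = sum((v - mx) ** 2 for v in a.ravel()) / a.size
    vy = sum((v - my) ** 2 for v in b.ravel()) / b.size
    cov = sum((p - mx) * (q - my) for p, q in zip(a.ravel(), b.ravel())) / a.size
    return ((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))


def epi_paper_loop(ref, out):
    num = den = 0.0
    m, n = ref.shape
    for i in range(m):
        for j in range(n):
            gxr = ref[i, j + 1] - ref[i, j] if j + 1 < n else 0.0
            gyr = ref[i + 1, j] - ref[i, j] if i + 1 < m else 0.0
            gxo = out[i, j + 1] - out[i, j] if j + 1 < n else 0.0
            gyo = out[i + 1, j] - out[i, j] if i + 1 < m else 0.0
            num += (gxr - gxo) ** 2 + (gyr - gyo) ** 2
            den += gxr**2 + gyr**2
    return num / den


class TestMSE:
    def test_identical_images_zero(self, rng):
        a = rng.integers(0, 256, (8, 8)).astype(float)
        assert mse(a, a) == 0.0

    def test_hand_value(self):
        assert mse(np.array([[1.0, 2.0], [3.0, 4.0]]), np.array([[1.0, 2.0], [3.0, 0.0]])) == 4.0

    def test_matches_loop_oracle(self, rng):
        a, b = rng.integers(0, 256, (2, 8, 8)).astype(float)
        assert mse(a, b) == pytest.approx(mse_loop(a, b), abs=1e-9)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_symmetric(self, rng):
        a, b = rng.integers(0, 256, (2, 8, 8)).astype(float)
        assert mse(a, b) == mse(b, a)


class TestPSNR:
    def test_analytic_values(self):
        # MSE = L^2 -> 0 dB
        assert psnr(np.zeros((2, 2)), np.full((2, 2), 255.0)) == pytest.approx(0.0)
        # MSE = L^2/1000 -> 30 dB
        v = math.sqrt(255.0**2 / 1000.0)
        assert psnr(np.zeros((4, 4)), np.full((4, 4), v)) == pytest.approx(30.0)

    def test_identical_images_infinite(self):
        assert psnr(np.ones((3, 3)), np.ones((3, 3))) == math.inf

    def test_strictly_decreasing_in_mse(self, rng):
        ref = np.zeros((8, 8))
        vals = [psnr(ref, np.full((8, 8), v)) for v in (1.0, 2.0, 5.0, 20.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestSSIM:
    def test_identical_images_one_both_modes(self, rng):
        a = rng.integers(0, 256, (16, 16)).astype(float)
        assert ssim(a, a, GLOBAL) == pytest.approx(1.0)
        assert ssim(a, a, MetricParams()) == pytest.approx(1.0)

    def test_constant_images_luminance_only(self):
        # zero variances: SSIM reduces to C1/(255^2 + C1)
        a = np.zeros((8, 8))
        b = np.full((8, 8), 255.0)
        c1 = (0.01 * 255) ** 2
        assert ssim(a, b, GLOBAL) == pytest.approx(c1 / (255.0**2 + c1), rel=1e-9)

    def test_global_matches_formula_oracle(self, rng):
        for _ in range(20):
            a, b = rng.integers(0, 256, (2, 8, 8)).astype(float)
            expected = ssim_global_loop(a, b, GLOBAL.ssim_c1, GLOBAL.ssim_c2)
            assert ssim(a, b, GLOBAL) == pytest.approx(expected, abs=1e-9)

    def test_global_symmetric(self, rng):
        a, b = rng.integers(0, 256, (2, 8, 8)).astype(float)
        assert ssim(a, b, GLOBAL) == pytest.approx(ssim(b, a, GLOBAL), abs=1e-12)

    def test_windowed_needs_minimum_size(self, rng):
        a = rng.integers(0, 256, (8, 8)).astype(float)
        with pytest.raises(ValueError):
            ssim(a, a, MetricParams(ssim_mode="windowed"))


class TestVIF:
    def test_identity_gives_one(self, rng):
        a = rng.integers(0, 256, (32, 32)).astype(float)
        assert vif(a, a) == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_distortion(self, rng):
        ref = np.kron(rng.integers(0, 256, (8, 8)).astype(float), np.ones((4, 4)))
        low = vif(ref, ref + rng.normal(0, 5, ref.shape))
        high = vif(ref, ref + rng.normal(0, 30, ref.shape))
        assert high < low

    def test_constant_reference_rejected(self):
        with pytest.raises(ValueError):
            vif(np.full((16, 16), 7.0), np.zeros((16, 16)))

    def test_not_symmetric(self, rng):
        ref = np.kron(rng.integers(0, 256, (8, 8)).astype(float), np.ones((4, 4)))
        dist = ref + rng.normal(0, 20, ref.shape)
        assert vif(ref, dist) != pytest.approx(vif(dist, ref), abs=1e-3)


class TestEPI:
    def test_identity_cases(self, rng):
        a = rng.integers(0, 256, (8, 8)).astype(float)
        assert epi(a, a, MetricParams(epi_mode="paper")) == 0.0
        assert epi(a, a, MetricParams(epi_mode="correlation")) == pytest.approx(1.0)

    def test_paper_mode_matches_loop_oracle(self, rng):
        for _ in range(20):
            a, b = rng.integers(0, 256, (2, 4, 4)).astype(float)
            assert epi(a, b, GLOBAL) == pytest.approx(epi_paper_loop(a, b), abs=1e-9)

    def test_flat_reference_rejected(self):
        with pytest.raises(ValueError):
            epi(np.full((4, 4), 9.0), np.zeros((4, 4)), GLOBAL)

    def test_reference_anchored_not_symmetric(self, rng):
        a = rng.integers(0, 256, (8, 8)).astype(float)
        b = a + rng.normal(0, 30, a.shape)
        assert epi(a, b, GLOBAL) != pytest.approx(epi(b, a, GLOBAL), abs=1e-6)


class TestNoiseVariance:
    def test_constant_image_zero(self):
        assert noise_variance(np.full((5, 5), 42.0)) == 0.0

    def test_hand_value(self):
        assert noise_variance(np.array([[0.0, 2.0], [0.0, 2.0]])) == 1.0

    def test_matches_two_pass_loop(self, rng):
        a = rng.integers(0, 256, (8, 8)).astype(float)
        mu = sum(a.ravel()) / a.size
        expected = sum((v - mu) ** 2 for v in a.ravel()) / a.size
        assert noise_variance(a) == pytest.approx(expected, abs=1e-9)


class TestPermutationInvariance:
    def test_global_metrics_invariant_under_joint_permutation(self, rng):
        a, b = rng.integers(0, 256, (2, 8, 8)).astype(float)
        perm = rng.permutation(64)
        ap = a.ravel()[perm].reshape(8, 8)
        bp = b.ravel()[perm].reshape(8, 8)
        assert mse(a, b) == pytest.approx(mse(ap, bp), abs=1e-9)
        assert ssim(a, b, GLOBAL) == pytest.approx(ssim(ap, bp, GLOBAL), abs=1e-9)
        assert noise_variance(b) == pytest.approx(noise_variance(bp), abs=1e-9)


class TestEvaluateDataset:
    def test_perfect_denoiser(self, small_pair):
        from erisnet.dicom_io import hu_to_uint8

        outputs = [hu_to_uint8(small_pair.hq)]
        report = evaluate_dataset([small_pair], outputs=outputs)
        out_rows = report.records[report.records.arm == "output"]
        assert (out_rows.MSE == 0).all()
        assert np.allclose(out_rows.SSIM, 1.0)

    def test_identity_denoiser_duplicates_lq_column(self, small_pair):
        from erisnet.dicom_io import hu_to_uint8

        outputs = [hu_to_uint8(small_pair.lq)]
        report = evaluate_dataset([small_pair], outputs=outputs)
        lq = report.records[report.records.arm == "LQ"].drop(columns=["arm"]).reset_index(drop=True)
        out = report.records[report.records.arm == "output"].drop(columns=["arm"]).reset_index(drop=True)
        assert lq.equals(out)

    def test_aggregates_recomputable_from_records(self, rng):
        from erisnet.dicom_io import CTImage, DoseTag, ImagePair, hu_to_uint8

        pairs = []
        for i in range(4):
            hq_px = np.full((32, 32), -1000.0)
            hq_px[6:26, 6:26] = rng.uniform(0, 80)
            hq = CTImage(hq_px, patient_id="P", slice_index=i, dose_tag=DoseTag.HQ)
            lq = hq.with_pixels(hq_px + rng.normal(0, 25, hq_px.shape), DoseTag.LQ)
            pairs.append(ImagePair(hq=hq, lq=lq, dose_fraction=0.5))
        outputs = [hu_to_uint8(p.lq) for p in pairs]
        report = evaluate_dataset(pairs, outputs=outputs)
        agg = report.aggregate()
        recs = report.records
        row = agg[(agg.metric == "MSE") & (agg.arm == "LQ")].iloc[0]
        vals = recs[recs.arm == "LQ"].MSE
        assert row["mean"] == pytest.approx(vals.mean())
        assert row["sd"] == pytest.approx(vals.std(ddof=1))
        assert row["median"] == pytest.approx(vals.median())
        assert row["min"] == pytest.approx(vals.min())
        assert row["max"] == pytest.approx(vals.max())

    def test_metric_failures_recorded_not_dropped(self, rng):
        from erisnet.dicom_io import CTImage, DoseTag, ImagePair, hu_to_uint8

        # flat HQ reference: EPI/VIF undefined
        hq = CTImage(np.zeros((32, 32)), dose_tag=DoseTag.HQ)
        lq = hq.with_pixels(rng.normal(0, 5, (32, 32)), DoseTag.LQ)
        pair = ImagePair(hq=hq, lq=lq, dose_fraction=0.5)
        report = evaluate_dataset([pair], outputs=[hu_to_uint8(pair.lq)])
        assert report.failures
        assert len(report.records) == 2  # both arms still present
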