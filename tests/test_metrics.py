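"""Loss functions, image quality metrics, and classification statistics."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import ctenhance as ce
from ctenhance import nn
from ctenhance.metrics import format_class_report

RNG = np.random.default_rng(7)


class TestPixelLoss:
    def test_hand_arithmetic(self):
        a = np.zeros((2, 2))
        b = np.full((2, 2), 0.5)
        assert ce.pixel_loss(a, b) == pytest.approx(0.25)
        assert ce.pixel_loss(a, a) == 0.0
        assert ce.pixel_loss(a, b) == ce.pixel_loss(b, a)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            ce.pixel_loss(np.zeros((2, 2)), np.zeros((3, 3)))


@pytest.fixture(scope="module")
def extractor():
    return ce.RandomVGGExtractor(layer_index=4, width_scale=1 / 8, seed=3)


class TestPerceptualLoss:

    def test_identical_images_give_zero(self, extractor):
        img = RNG.random((32, 32))
        assert ce.perceptual_loss(img, img, extractor) == 0.0

    def test_nonnegative(self, extractor):
        a, b = RNG.random((32, 32)), RNG.random((32, 32))
        assert ce.perceptual_loss(a, b, extractor) >= 0.0

    def test_matches_explicit_norm_oracle(self, extractor):
        """Reproducible value equal to a loop-based squared-norm over the
        raw feature stacks."""
        a, b = RNG.random((16, 16)), RNG.random((16, 16))
        got = ce.perceptual_loss(a, b, extractor)
        with nn.no_grad():
            fa = extractor.features(nn.Tensor(a[None, None])).data[0]
            fb = extractor.features(nn.Tensor(b[None, None])).data[0]
        total = 0.0
        for c in range(fa.shape[0]):
            for i in range(fa.shape[1]):
                for j in range(fa.shape[2]):
                    total += (fa[c, i, j] - fb[c, i, j]) ** 2
        hi, wi = fa.shape[1:]
        assert got == pytest.approx(total / (hi * wi), rel=1e-12)
        assert ce.perceptual_loss(a, b, extractor) == got

    def test_too_small_input_rejected(self):
        deep = ce.RandomVGGExtractor(layer_index=8, width_scale=1 / 8, seed=0)
        with pytest.raises(ValueError, match="small"):
            ce.perceptual_loss(np.zeros((4, 4)), np.zeros((4, 4)), deep)


class TestJointLoss:
    def test_mu_zero_degenerates_to_pixel_loss(self):
        a, b = RNG.random((16, 16)), RNG.random((16, 16))
        w = ce.LossWeights(mu=0.0)
        assert ce.joint_loss(a, b, None, w) == ce.pixel_loss(a, b)

    def test_additivity_and_mu_affinity(self):
        ext = ce.RandomVGGExtractor(layer_index=2, width_scale=1 / 8, seed=0)
        a, b = RNG.random((16, 16)), RNG.random((16, 16))
        pix = ce.pixel_loss(a, b)
        perc = ce.perceptual_loss(a, b, ext)
        assert ce.joint_loss(a, b, ext, ce.LossWeights(mu=1.0)) == \
            pytest.approx(pix + perc, abs=1e-12)
        # affine in mu with slope = perceptual loss
        for mu in (0.01, 0.5, 2.0):
            got = ce.joint_loss(a, b, ext, ce.LossWeights(mu=mu))
            assert got == pytest.approx(pix + mu * perc, rel=1e-12)

    def test_identical_images_give_zero(self):
        ext = ce.RandomVGGExtractor(layer_index=2, width_scale=1 / 8, seed=0)
        img = RNG.random((16, 16))
        assert ce.joint_loss(img, img, ext, ce.LossWeights(mu=0.7)) == 0.0

    def test_calibrate_mu_balances_terms(self):
        ext = ce.RandomVGGExtractor(layer_index=2, width_scale=1 / 8, seed=0)
        pairs = [(RNG.random((16, 16)), RNG.random((16, 16))) for _ in range(3)]
        mu = ce.calibrate_mu(pairs, ext)
        pix = np.mean([ce.pixel_loss(a, b) for a, b in pairs])
        perc = np.mean([ce.perceptual_loss(a, b, ext) for a, b in pairs])
        assert mu * perc == pytest.approx(pix, rel=1e-9)


class TestPsnr:
    def test_identical_images_hit_the_cap(self):
        img = RNG.random((16, 16))
        assert ce.psnr(img, img) == 100.0

    def test_constant_offset_closed_form(self):
        a = np.full((8, 8), 100 / 255)
        b = np.full((8, 8), 116 / 255)
        assert ce.psnr(a, b) == pytest.approx(20 * np.log10(255 / 16), abs=1e-9)
        assert ce.psnr(a, b) == ce.psnr(b, a)

    def test_monotone_in_mse(self):
        base = np.full((16, 16), 0.5)
        values = [ce.psnr(base, base + off) for off in (0.01, 0.02, 0.05, 0.1)]
        assert all(x > y for x, y in zip(values, values[1:]))


def _ssim_oracle(a, b):
    """Independent windowed-statistics SSIM (11x11 Gaussian, sigma 1.5)."""
    a = a * 255.0
    b = b * 255.0
    # truncate the Gaussian to an 11x11 window, normalized
    half = 5
    ax = np.arange(-half, half + 1)
    g = np.exp(-(ax ** 2) / (2 * 1.5 ** 2))
    win = np.outer(g, g)
    win /= win.sum()

    def filt(x):
        return ndimage.correlate(x, win, mode="reflect")

    mu_a, mu_b = filt(a), filt(b)
    va = filt(a * a) - mu_a ** 2
    vb = filt(b * b) - mu_b ** 2
    cov = filt(a * b) - mu_a * mu_b
    c1, c2 = (0.01 * 255) ** 2, (0.03 * 255) ** 2
    ssim_map = ((2 * mu_a * mu_b + c1) * (2 * cov + c2)) / (
        (mu_a ** 2 + mu_b ** 2 + c1) * (va + vb + c2)
    )
    pad = half
    return float(ssim_map[pad:-pad, pad:-pad].mean())


class TestSsim:
    def test_self_similarity_is_one(self):
        img = RNG.random((32, 32))
        assert ce.ssim(img, img) == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_windowed_oracle(self):
        rng = np.random.default_rng(12)
        a = ce.generate_phantom(64, seed=1)
        b = np.clip(a + rng.normal(0, 0.05, a.shape), 0, 1)
        assert ce.ssim(a, b) == pytest.approx(_ssim_oracle(a, b), abs=1e-6)

    def test_independent_noise_is_bounded(self):
        a = np.clip(RNG.normal(0.5, 0.2, (32, 32)), 0, 1)
        b = np.clip(RNG.normal(0.5, 0.2, (32, 32)), 0, 1)
        assert -1.0 < ce.ssim(a, b) < 1.0

    def test_small_images_rejected(self):
        with pytest.raises(ValueError, match="11"):
            ce.ssim(np.zeros((8, 8)), np.zeros((8, 8)))


class TestDifferenceMap:
    def test_contracts(self):
        a, b = RNG.random((8, 8)), RNG.random((8, 8))
        d = ce.difference_map(a, b)
        assert np.array_equal(d, ce.difference_map(b, a))
        assert np.all((d >= 0) & (d <= 1))
        assert np.all(ce.difference_map(a, a) == 0)


class TestClassificationReport:
    def test_reference_matrix_reproduces_printed_rows(self, reference_confusion):
        """Recomputing P/R/F1 from the printed count matrix matches the
        printed rows at their two-decimal precision (the level-2
        confusion-rate entry is the documented exception)."""
        report = ce.classification_report(reference_confusion["matrix"])
        printed = reference_confusion["printed"]
        for i in range(10):
            assert report.precision[i] == pytest.approx(printed["precision"][i], abs=0.008)
            assert report.recall[i] == pytest.approx(printed["recall"][i], abs=0.008)
            assert report.f1[i] == pytest.approx(printed["f1"][i], abs=0.008)
            if i != 1:  # printed 0.160 vs recomputed 31/200 = 0.155
                assert report.confusion_rate[i] == pytest.approx(
                    printed["confusion_rate"][i], abs=0.008
                )
        assert report.confusion_rate[1] == pytest.approx(0.155, abs=1e-12)
        # worked-example spot values: level 0 and the level-8 confusion rate
        assert round(report.precision[0], 2) == 0.86
        assert round(report.recall[0], 2) == 0.96
        assert round(report.f1[0], 2) == 0.91
        assert report.confusion_rate[4] == pytest.approx(0.020, abs=1e-12)
        assert report.accuracy == pytest.approx(1954 / 2000, abs=1e-12)

    def test_perfect_matrix(self):
        classes = ce.NoiseLevelClassSet((0.0, 9.0, 18.0))
        m = ce.ConfusionMatrix(counts=np.eye(3, dtype=int) * 50, class_levels=classes)
        report = ce.classification_report(m)
        assert np.all(report.precision == 1.0)
        assert np.all(report.recall == 1.0)
        assert np.all(report.f1 == 1.0)
        assert np.all(report.confusion_rate == 0.0)
        assert report.accuracy == 1.0

    def test_zero_column_precision_flagged(self):
        classes = ce.NoiseLevelClassSet((0.0, 9.0))
        counts = np.array([[0, 10], [0, 10]])
        report = ce.classification_report(
            ce.ConfusionMatrix(counts=counts, class_levels=classes)
        )
        assert report.precision[0] == 0.0
        assert report.zero_precision_flag[0]
        assert not report.zero_precision_flag[1]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 50), min_size=3, max_size=3),
                    min_size=3, max_size=3))
    def test_report_consistency_properties(self, rows):
        counts = np.array(rows)
        if counts.sum() == 0:
            return
        classes = ce.NoiseLevelClassSet((0.0, 9.0, 18.0))
        report = ce.classification_report(
            ce.ConfusionMatrix(counts=counts, class_levels=classes)
        )
        assert np.allclose(report.confusion_rate + report.recall, 1.0)
        assert report.accuracy == pytest.approx(
            np.trace(counts) / counts.sum(), abs=1e-12
        )
        for arr in (report.precision, report.recall, report.f1):
            assert np.all((arr >= 0) & (arr <= 1))

    def test_format_includes_all_rows(self, reference_confusion):
        text = format_class_report(
            ce.classification_report(reference_confusion["matrix"])
        )
        for token in ("P", "R", "F1", "Conf", "accuracy 0.977"):
            assert token in text


class _OraclePredictor:
    """Perfect predictor stub: probability 1 on the true class, cycling
    through patches in dataset order."""

    def __init__(self, labels, n_classes):
        self.labels = list(labels)
        self.n = n_classes
        self.pos = 0

    def predict_proba(self, batch):
        out = np.zeros((len(batch), self.n))
        for i in range(len(batch)):
            out[i, self.labels[self.pos]] = 1.0
            self.pos += 1
        return out


class TestEvaluateClassifier:
    def _dataset(self, per_class, classes):
        data = []
        for c in range(classes.n_classes):
            for _ in range(per_class):
                data.append(ce.LabeledPatch(patch=np.zeros((4, 4)), class_index=c))
        return data

    def test_perfect_predictor_gives_diagonal(self):
        classes = ce.NoiseLevelClassSet((0.0, 9.0, 18.0))
        data = self._dataset(5, classes)
        model = _OraclePredictor([d.class_index for d in data], 3)
        cm = ce.evaluate_classifier(model, data, classes)
        assert np.array_equal(cm.counts, np.eye(3, dtype=int) * 5)

    def test_row_sums_and_total_conservation(self):
        classes = ce.NoiseLevelClassSet(tuple(float(v) for v in range(0, 19, 2)))
        data = self._dataset(200, classes)  # balanced 2000-item testing set
        rng = np.random.default_rng(0)
        model = _OraclePredictor(rng.integers(0, 10, len(data)), 10)
        cm = ce.evaluate_classifier(model, data, classes)
        assert np.all(cm.counts.sum(axis=1) == 200)
        assert cm.counts.sum() == 2000

    def test_empty_dataset_rejected(self):
        classes = ce.NoiseLevelClassSet((0.0, 9.0))
        with pytest.raises(ValueError, match="empty"):
            ce.evaluate_classifier(None, [], classes)
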