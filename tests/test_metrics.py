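"""Evaluation metrics: closed-form PSNR/SSIM/entropy cases, a brute-force
sliding-window SSIM oracle, and masked per-tissue behaviour."""

import numpy as np
import pytest

from ricianet import entropy, evaluate_pair, masked_metrics, psnr, ssim


def test_psnr_closed_forms(rng):
    ref = rng.random((8, 8, 8))
    assert psnr(ref, ref.copy()) == np.inf
    uniform = np.full((8, 8), 0.5)
    assert psnr(uniform, uniform + 0.1, max_val=1.0) == pytest.approx(20.0,
                                                                      abs=1e-9)
    assert psnr(uniform, uniform + 1.0, max_val=1.0) == pytest.approx(0.0,
                                                                      abs=1e-9)
    with pytest.raises(ValueError, match="shape"):
        psnr(ref, ref[:4])


def test_ssim_is_one_for_identical_volumes(rng):
    x = rng.random((16, 16, 16))
    assert ssim(x, x.copy(), max_val=1.0) == pytest.approx(1.0, abs=1e-9)


def test_ssim_constant_images_closed_form():
    # zero variances: SSIM = (2 mu mu' + C1) / (mu^2 + mu'^2 + C1)
    c, delta, max_val = 0.5, 0.1, 1.0
    c1 = (0.01 * max_val) ** 2
    expected = (2 * c * (c + delta) + c1) / (c * c + (c + delta) ** 2 + c1)
    ref = np.full((16, 16), c)
    test = np.full((16, 16), c + delta)
    assert ssim(ref, test, max_val=max_val) == pytest.approx(expected, rel=1e-9)


def brute_force_ssim(x, y, max_val):
    """Independent evaluation of the SSIM definition: Gaussian window
    (sigma 1.5, 11 taps), K1=0.01, K2=0.03, weighted moments."""
    radius = 5
    ax = np.arange(-radius, radius + 1)
    g = np.exp(-(ax ** 2) / (2 * 1.5 ** 2))
    w = np.outer(g, g)
    w /= w.sum()
    c1 = (0.01 * max_val) ** 2
    c2 = (0.03 * max_val) ** 2
    values = []
    for i in range(radius, x.shape[0] - radius):
        for j in range(radius, x.shape[1] - radius):
            xw = x[i - radius:i + radius + 1, j - radius:j + radius + 1]
            yw = y[i - radius:i + radius + 1, j - radius:j + radius + 1]
            mx, my = (w * xw).sum(), (w * yw).sum()
            vx = (w * xw * xw).sum() - mx * mx
            vy = (w * yw * yw).sum() - my * my
            cxy = (w * xw * yw).sum() - mx * my
            values.append(((2 * mx * my + c1) * (2 * cxy + c2))
                          / ((mx * mx + my * my + c1) * (vx + vy + c2)))
    return float(np.mean(values))


def test_ssim_matches_bruteforce_definition(rng):
    x = rng.random((24, 24))
    y = np.clip(x + 0.1 * rng.standard_normal((24, 24)), 0, 1)
    assert ssim(x, y, max_val=1.0) == pytest.approx(
        brute_force_ssim(x, y, 1.0), abs=1e-6)


def test_ssim_is_symmetric(rng):
    x = rng.random((16, 16))
    y = rng.random((16, 16))
    assert ssim(x, y, max_val=1.0) == pytest.approx(ssim(y, x, max_val=1.0),
                                                    abs=1e-9)


def test_entropy_closed_forms():
    assert entropy(np.full((8, 8), 3.0)) == 0.0
    two_level = np.array([0.25] * 32 + [0.75] * 32)
    assert entropy(two_level, n_bins=2, value_range=(0, 1)) == pytest.approx(
        np.log(2), abs=1e-12)
    skewed = np.array([0.1] * 2 + [0.3] * 1 + [0.9] * 1)
    assert entropy(skewed, n_bins=4, value_range=(0, 1)) == pytest.approx(
        1.5 * np.log(2), abs=1e-12)


def test_entropy_is_maximal_for_uniform_histogram():
    n_bins = 16
    centers = (np.arange(n_bins) + 0.5) / n_bins
    image = np.repeat(centers, 10)
    assert entropy(image, n_bins=n_bins, value_range=(0, 1)) == pytest.approx(
        np.log(n_bins), abs=1e-12)


def test_entropy_invariant_under_bin_relabeling():
    n_bins = 8
    centers = (np.arange(n_bins) + 0.5) / n_bins
    counts = [1, 5, 2, 8, 3, 1, 9, 4]
    image = np.concatenate([np.full(c, v) for c, v in zip(counts, centers)])
    permuted = np.concatenate([np.full(c, v) for c, v in
                               zip(counts, centers[::-1])])
    a = entropy(image, n_bins=n_bins, value_range=(0, 1))
    b = entropy(permuted, n_bins=n_bins, value_range=(0, 1))
    assert a == pytest.approx(b, abs=1e-12)


def test_entropy_rejects_bad_range(rng):
    with pytest.raises(ValueError):
        entropy(rng.random(10), value_range=(1.0, 0.0))


def test_psnr_decreases_with_noise_variance(rng):
    ref = rng.random((32, 32, 32))
    values = [psnr(ref, ref + sigma * rng.standard_normal(ref.shape),
                   max_val=1.0) for sigma in (0.02, 0.05, 0.1, 0.2)]
    assert values == sorted(values, reverse=True)


def test_full_mask_reproduces_unmasked_metrics(rng):
    ref = rng.random((16, 16, 16))
    test = np.clip(ref + 0.05 * rng.standard_normal(ref.shape), 0, 1)
    full = masked_metrics(ref, test, np.ones(ref.shape, bool), max_val=1.0)
    assert full.psnr == pytest.approx(psnr(ref, test, 1.0), abs=1e-12)
    assert full.ssim == pytest.approx(ssim(ref, test, 1.0), abs=1e-9)
    assert full.entropy == pytest.approx(
        entropy(test, value_range=(0, float(test.max()))), abs=1e-12)


def test_mask_of_identical_region_gives_infinite_psnr(rng):
    ref = rng.random((8, 8, 8))
    test = ref.copy()
    test[4:] += 0.3  # differences only outside the mask
    mask = np.zeros(ref.shape, bool)
    mask[:4] = True
    assert masked_metrics(ref, test, mask).psnr == np.inf


def test_masked_psnr_hand_example():
    ref = np.zeros((4, 4))
    test = np.zeros((4, 4))
    test[:2, :2] = [[0.1, 0.2], [0.0, 0.1]]
    test[2:, 2:] = 9.0  # ignored by the mask
    mask = np.zeros((4, 4), bool)
    mask[:2, :2] = True
    mse = (0.1**2 + 0.2**2 + 0.0**2 + 0.1**2) / 4
    report = masked_metrics(ref, test, mask, max_val=1.0)
    assert report.psnr == pytest.approx(10 * np.log10(1.0 / mse), abs=1e-9)
    assert report.ssim is None  # bounding box smaller than the SSIM window


def test_masked_metrics_rejects_empty_mask(rng):
    ref = rng.random((4, 4))
    with pytest.raises(ValueError, match="empty"):
        masked_metrics(ref, ref, np.zeros((4, 4), bool))


def test_evaluate_pair_reports_per_tissue(small_phantom, rng):
    clean = small_phantom.intensity.astype(np.float64)
    noisy = np.abs(clean + 0.05 * rng.standard_normal(clean.shape))
    report = evaluate_pair(clean, noisy, labels=small_phantom.labels)
    assert set(report.per_label) == {0, 1, 2, 3}
    assert np.isfinite(report.psnr)
    for sub in report.per_label.values():
        assert np.isfinite(sub.psnr)
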