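"""Metric implementations against brute-force and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from esdm.metrics import (ConfusionCounts, MetricReport, SsimConfig,
                          confusion, evaluate_dataset, mdice, miou, psnr,
                          ssim)

RNG = np.random.default_rng(0)


# -- PSNR -------------------------------------------------------------------

def test_psnr_identity_is_infinite():
    x = RNG.random((8, 8))
    assert psnr(x, x) == np.inf


def test_psnr_uniform_error_closed_form():
    y = np.zeros((10, 10))
    assert psnr(y, y + 0.1, i_max=1.0) == pytest.approx(20.0, rel=1e-12)


def test_psnr_matches_formula_on_random_pairs():
    for _ in range(20):
        y, yh = RNG.random((6, 7)), RNG.random((6, 7))
        expected = 10 * np.log10(1.0 / np.mean((y - yh) ** 2))
        assert psnr(y, yh) == pytest.approx(expected, abs=1e-9)


def test_psnr_decreases_with_noise_amplitude():
    y = RNG.random((32, 32))
    noise = RNG.standard_normal((32, 32))
    vals = [psnr(y, y + a * noise) for a in (0.01, 0.05, 0.1, 0.2)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


def test_psnr_rejects_empty_and_bad_range():
    with pytest.raises(ValueError):
        psnr(np.zeros((0,)), np.zeros((0,)))
    with pytest.raises(ValueError):
        psnr(np.zeros((2, 2)), np.zeros((2, 2)), i_max=0.0)


# -- SSIM -------------------------------------------------------------------

def _ssim_windowed_oracle(y, yh, cfg):
    """Direct sliding-window evaluation with an explicit Gaussian kernel."""
    radius = int(cfg.truncate * cfg.sigma + 0.5)
    ax = np.arange(-radius, radius + 1)
    g = np.exp(-0.5 * (ax / cfg.sigma) ** 2)
    g /= g.sum()
    kern = np.outer(g, g)
    h, w = y.shape
    vals = []
    for i in range(radius, h - radius):
        for j in range(radius, w - radius):
            wy = y[i - radius:i + radius + 1, j - radius:j + radius + 1]
            wyh = yh[i - radius:i + radius + 1, j - radius:j + radius + 1]
            mx, my = (kern * wy).sum(), (kern * wyh).sum()
            vx = (kern * wy * wy).sum() - mx ** 2
            vy = (kern * wyh * wyh).sum() - my ** 2
            cov = (kern * wy * wyh).sum() - mx * my
            vals.append(((2 * mx * my + cfg.c1) * (2 * cov + cfg.c2))
                        / ((mx ** 2 + my ** 2 + cfg.c1)
                           * (vx + vy + cfg.c2)))
    return float(np.mean(vals))


def test_ssim_identity_is_one():
    x = RNG.random((16, 16))
    assert ssim(x, x) == pytest.approx(1.0, abs=1e-9)
    assert ssim(x, x, SsimConfig(window="global")) == pytest.approx(1.0,
                                                                    abs=1e-9)


def test_ssim_constant_pair_is_one():
    x = np.full((16, 16), 0.4)
    assert ssim(x, x.copy(), SsimConfig(window="global")) == pytest.approx(
        1.0, abs=1e-9)


def test_global_ssim_negative_for_anticorrelated_ramp():
    y = np.linspace(0, 1, 256).reshape(16, 16)
    yh = 1.0 - y
    assert ssim(y, yh, SsimConfig(window="global")) < 0.0


def test_windowed_ssim_matches_brute_force_oracle():
    cfg = SsimConfig()
    for _ in range(3):
        y, yh = RNG.random((14, 15)), RNG.random((14, 15))
        mine = ssim(y, yh, cfg)
        ref = _ssim_windowed_oracle(y, yh, cfg)
        assert mine == pytest.approx(ref, abs=1e-6)


def test_windowed_equals_global_when_window_covers_image():
    """A single interior evaluation point sees the whole image only in the
    degenerate global mode; instead check that global mode equals the Eq.-10
    statistics computed directly."""
    y, yh = RNG.random((9, 9)), RNG.random((9, 9))
    cfg = SsimConfig(window="global")
    mx, my = y.mean(), yh.mean()
    vx, vy = y.var(), yh.var()
    cov = ((y - mx) * (yh - my)).mean()
    ref = ((2 * mx * my + cfg.c1) * (2 * cov + cfg.c2)) / (
        (mx ** 2 + my ** 2 + cfg.c1) * (vx + vy + cfg.c2))
    assert ssim(y, yh, cfg) == pytest.approx(ref, abs=1e-12)


def test_windowed_ssim_rejects_small_images():
    with pytest.raises(ValueError):
        ssim(np.zeros((8, 8)), np.zeros((8, 8)))


# -- confusion counts / Dice / IoU -----------------------------------------

def test_confusion_perfect_prediction():
    m = RNG.integers(0, 3, (8, 8))
    c = confusion(m, m, 3)
    assert (c.fp == 0).all() and (c.fn == 0).all()
    assert c.tp.sum() == m.size


def test_confusion_rotated_labels_have_zero_tp():
    m = np.arange(9).reshape(3, 3) % 3
    c = confusion((m + 1) % 3, m, 3)
    assert (c.tp == 0).all()


def test_confusion_matches_brute_force_tally():
    pred = RNG.integers(0, 3, (8, 8))
    ref = RNG.integers(0, 3, (8, 8))
    c = confusion(pred, ref, 3)
    for k in range(3):
        tp = sum(1 for p, r in zip(pred.ravel(), ref.ravel())
                 if p == k and r == k)
        fp = sum(1 for p, r in zip(pred.ravel(), ref.ravel())
                 if p == k and r != k)
        fn = sum(1 for p, r in zip(pred.ravel(), ref.ravel())
                 if p != k and r == k)
        assert (c.tp[k], c.fp[k], c.fn[k]) == (tp, fp, fn)
    # invariant: TP + FN equals reference positives per class
    np.testing.assert_array_equal(c.tp + c.fn,
                                  np.bincount(ref.ravel(), minlength=3))


def test_confusion_rejects_out_of_range():
    with pytest.raises(ValueError):
        confusion(np.array([[3]]), np.array([[0]]), 3)


def test_mdice_hand_tally_two_class_toy():
    pred = np.array([0, 0, 1, 1])
    ref = np.array([0, 1, 1, 1])
    c = confusion(pred, ref, 2)
    # Dice0 = 2/3, Dice1 = 4/5 -> mean 11/15
    assert mdice(c) == pytest.approx(11.0 / 15.0, rel=1e-12)
    assert miou(c) == pytest.approx((1.0 / 2.0 + 2.0 / 3.0) / 2, rel=1e-12)


def test_absent_class_counts_as_perfect_agreement():
    pred = np.zeros((4, 4), dtype=int)
    ref = np.zeros((4, 4), dtype=int)
    c = confusion(pred, ref, 3)
    assert mdice(c) == 1.0 and miou(c) == 1.0


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(0, 10 ** 6), st.integers(2, 4))
def test_mdice_never_below_miou(seed, k):
    g = np.random.default_rng(seed)
    pred = g.integers(0, k, (6, 6))
    ref = g.integers(0, k, (6, 6))
    c = confusion(pred, ref, k)
    assert mdice(c) >= miou(c) - 1e-12


def test_metric_oracles_agree_on_many_random_images():
    """psnr/ssim/mdice/miou vs independent evaluation, >= 100 cases."""
    cfg = SsimConfig()
    for i in range(100):
        g = np.random.default_rng(i)
        y, yh = g.random((12, 12)), g.random((12, 12))
        assert psnr(y, yh) == pytest.approx(
            10 * np.log10(1 / np.mean((y - yh) ** 2)), abs=1e-9)
        pred, ref = g.integers(0, 3, (6, 6)), g.integers(0, 3, (6, 6))
        c = confusion(pred, ref, 3)
        dices, ious = [], []
        for k in range(3):
            inter = np.sum((pred == k) & (ref == k))
            a, b = np.sum(pred == k), np.sum(ref == k)
            union = np.sum((pred == k) | (ref == k))
            dices.append(2 * inter / (a + b) if a + b else 1.0)
            ious.append(inter / union if union else 1.0)
        assert mdice(c) == pytest.approx(np.mean(dices), abs=1e-12)
        assert miou(c) == pytest.approx(np.mean(ious), abs=1e-12)
        if i < 10:     # SSIM brute force is slow; 10 cases here, more above
            assert ssim(y, yh, cfg) == pytest.approx(
                _ssim_windowed_oracle(y, yh, cfg), abs=1e-6)


# -- aggregation ------------------------------------------------------------

def test_single_image_report_has_zero_std():
    x = RNG.random((16, 16))
    rep = evaluate_dataset([x], [x + 0.01])
    agg = rep.aggregate().set_index("metric")
    assert agg.loc["psnr", "std"] == 0.0
    assert agg.loc["psnr", "n"] == 1


def test_two_image_aggregation_closed_form():
    rep = MetricReport(per_image=__import__("pandas").DataFrame(
        {"psnr": [20.0, 30.0]}))
    agg = rep.aggregate().set_index("metric")
    assert agg.loc["psnr", "mean"] == pytest.approx(25.0)
    assert agg.loc["psnr", "std"] == pytest.approx(7.0710678, rel=1e-6)


def test_aggregation_matches_recomputation(rng):
    imgs = [rng.random((16, 16)) for _ in range(4)]
    outs = [im + 0.05 * rng.standard_normal(im.shape) for im in imgs]
    rep = evaluate_dataset(imgs, outs)
    vals = np.array([psnr(a, b) for a, b in zip(imgs, outs)])
    agg = rep.aggregate().set_index("metric")
    assert agg.loc["psnr", "mean"] == pytest.approx(vals.mean(), rel=1e-12)
    assert agg.loc["psnr", "std"] == pytest.approx(vals.std(ddof=1),
                                                   rel=1e-9)


def test_empty_collection_rejected():
    with pytest.raises(ValueError):
        evaluate_dataset([], [])
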