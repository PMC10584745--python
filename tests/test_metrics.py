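"""Correctness of the nine FR-IQA metrics: closed forms, brute-force
oracles, bounds, symmetries and degeneracies."""

import numpy as np
import pytest
from skimage.metrics import structural_similarity as sk_ssim

from ctfriqa.metrics import (
    METRIC_NAMES,
    compute_all,
    fsim,
    ifc,
    ifc_band_terms,
    iw_ssim,
    ms_ssim,
    nqm,
    psnr,
    ssim,
    vif,
    vsnr,
)
from ctfriqa.metrics._common import PairingError
from ctfriqa.metrics._ssim import MSSSIM_WEIGHTS, WIN_SIGMA, WIN_SIZE, allowed_levels


def brute_force_ssim(ref, dist):
    """Independent per-window SSIM: explicit loops over every 11x11 window."""
    ref = np.asarray(ref, dtype=float)
    dist = np.asarray(dist, dtype=float)
    r = WIN_SIZE // 2
    x1 = np.arange(-r, r + 1)
    w1 = np.exp(-0.5 * (x1 / WIN_SIGMA) ** 2)
    w = np.outer(w1, w1)
    w /= w.sum()
    c1, c2 = (0.01 * 255) ** 2, (0.03 * 255) ** 2
    vals = []
    h, wid = ref.shape
    for i in range(h - WIN_SIZE + 1):
        for j in range(wid - WIN_SIZE + 1):
            a = ref[i : i + WIN_SIZE, j : j + WIN_SIZE]
            b = dist[i : i + WIN_SIZE, j : j + WIN_SIZE]
            mu1, mu2 = (w * a).sum(), (w * b).sum()
            v1 = (w * a * a).sum() - mu1**2
            v2 = (w * b * b).sum() - mu2**2
            cov = (w * a * b).sum() - mu1 * mu2
            vals.append(
                ((2 * mu1 * mu2 + c1) * (2 * cov + c2))
                / ((mu1**2 + mu2**2 + c1) * (v1 + v2 + c2))
            )
    return float(np.mean(vals))


class TestPerfectScores:
    def test_identical_pair_all_metrics_perfect(self, identical_pair):
        vec = compute_all(identical_pair)
        assert vec.errors == {}
        for name in ("SSIM", "MSSSIM", "IWSSIM", "FSIM"):
            assert vec.scores[name] == pytest.approx(1.0, abs=1e-9), name
        assert vec.scores["VIF"] == pytest.approx(1.0, abs=1e-9)
        for name in ("PSNR", "NQM", "VSNR"):
            assert vec.scores[name] == 100.0
            assert vec.cap_flags[name], name
        assert vec.scores["IFC"] > 1000  # large positive, finite


class TestPSNR:
    def test_hand_example(self):
        ref = np.zeros((2, 2))
        dist = np.array([[10, 0], [0, 0]], dtype=float)
        value, capped = psnr((ref, dist))
        assert not capped
        assert value == pytest.approx(10 * np.log10(255**2 / 25), abs=1e-12)

    def test_matches_closed_form_on_random_pair(self, random_pair_32):
        ref, dist = random_pair_32
        mse = np.mean((ref.astype(float) - dist.astype(float)) ** 2)
        assert psnr((ref, dist))[0] == pytest.approx(10 * np.log10(255**2 / mse), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(PairingError):
            psnr((np.zeros((4, 4)), np.zeros((4, 5))))


class TestSSIMFamily:
    def test_matches_brute_force_oracle(self, random_pair_32):
        ref, dist = random_pair_32
        assert ssim((ref, dist)) == pytest.approx(brute_force_ssim(ref, dist), abs=1e-9)

    def test_matches_skimage_reference(self, head_pair):
        ours = ssim(head_pair)
        theirs = sk_ssim(
            head_pair.reference.pixels,
            head_pair.distorted.pixels,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            data_range=255,
        )
        assert ours == pytest.approx(theirs, abs=1e-4)

    def test_luminance_shift_below_one(self):
        ref = np.full((32, 32), 100.0)
        assert ssim((ref, ref + 10)) < 1.0

    def test_ms_ssim_single_scale_equals_ssim(self, random_pair_32):
        ref, dist = random_pair_32
        assert ms_ssim((ref, dist), levels=1) == pytest.approx(ssim((ref, dist)), abs=1e-9)

    def test_ms_ssim_auto_reduces_scales_on_small_images(self, random_pair_32):
        ref, dist = random_pair_32
        assert allowed_levels((32, 32), 5) == 2
        _, details = ms_ssim((ref, dist), return_details=True)
        assert details["levels_used"] == 2

    def test_msssim_weights_are_canonical(self):
        assert MSSSIM_WEIGHTS == (0.0448, 0.2856, 0.3001, 0.2363, 0.1333)

    def test_iw_ssim_uniform_weights_degenerates_to_ms_ssim(self, head_pair):
        a = iw_ssim(head_pair, uniform_weights=True)
        b = ms_ssim(head_pair)
        assert a == pytest.approx(b, abs=1e-6)

    def test_iw_weights_concentrate_on_texture(self):
        # half flat / half textured reference: information weights should
        # put more mass on the textured half
        rng = np.random.default_rng(0)
        ref = np.full((64, 64), 120.0)
        ref[:, 32:] += rng.normal(0, 25, (64, 32))
        ref = np.clip(ref, 0, 255)
        dist = np.clip(ref + rng.normal(0, 5, ref.shape), 0, 255)
        from ctfriqa.metrics._ssim import _downsample2, _expand2, information_weights

        lap_r = ref - _expand2(_downsample2(ref), ref.shape)
        lap_d = dist - _expand2(_downsample2(dist), dist.shape)
        w = information_weights(lap_r, lap_d)
        assert w[:, 34:].sum() > 1.5 * w[:, :30].sum()


class TestFSIM:
    def test_bounded_on_random_pairs(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            ref = rng.integers(0, 256, (48, 48)).astype(float)
            dist = rng.integers(0, 256, (48, 48)).astype(float)
            assert 0.0 <= fsim((ref, dist)) <= 1.0

    def test_symmetric_in_arguments(self, head_pair):
        a = fsim(head_pair)
        b = fsim((head_pair.distorted.pixels, head_pair.reference.pixels))
        assert a == pytest.approx(b, abs=1e-12)


class TestIFCVIF:
    def test_ifc_additive_over_bands(self, head_pair):
        terms = ifc_band_terms(head_pair)
        assert ifc(head_pair) == pytest.approx(sum(terms), abs=1e-9)

    def test_ifc_near_zero_for_independent_noise(self):
        rng = np.random.default_rng(8)
        ref = np.clip(
            128 + np.cumsum(rng.normal(0, 2, (64, 64)), axis=1), 0, 255
        )  # correlated texture
        noise = rng.integers(0, 256, (64, 64)).astype(float)
        assert ifc((ref, noise)) < 0.02 * ifc((ref, ref))

    def test_ifc_grows_with_image_size(self, displays):
        disp = displays["abdomen"].pixels.astype(float)
        small = disp[:64, :64]
        large = disp[:128, :128]
        assert ifc((large, large)) > ifc((small, small))

    def test_vif_identity_is_one(self, cropped_refs):
        for s, ref in cropped_refs.items():
            assert vif((ref.pixels, ref.pixels)) == pytest.approx(1.0, abs=1e-9), s

    def test_vif_near_zero_for_independent_noise(self):
        rng = np.random.default_rng(9)
        ref = np.clip(128 + np.cumsum(rng.normal(0, 2, (64, 64)), axis=1), 0, 255)
        noise = rng.integers(0, 256, (64, 64)).astype(float)
        assert vif((ref, noise)) < 0.1

    def test_vif_pixel_domain_variant(self, head_pair):
        w = vif(head_pair, domain="wavelet")
        p = vif(head_pair, domain="pixel")
        assert 0 < p < 1 and 0 < w < 1


class TestNQMVSNR:
    def test_nqm_accepts_non_square_even_images(self):
        rng = np.random.default_rng(10)
        ref = rng.integers(0, 256, (48, 64)).astype(float)
        dist = np.clip(ref + rng.normal(0, 10, ref.shape), 0, 255)
        value, capped = nqm((ref, dist))
        assert np.isfinite(value) and not capped

    def test_vsnr_tiny_perturbation_hits_cap(self, cropped_refs):
        ref = cropped_refs["head"].pixels.astype(float)
        dist = ref.copy()
        dist[10, 10] += 1
        value, capped = vsnr((ref, dist))
        assert capped and value == 100.0

    def test_vsnr_finite_above_threshold(self, head_pair):
        value, capped = vsnr(head_pair)
        assert not capped and np.isfinite(value)


class TestComputeAll:
    def test_complete_vector_and_stable_order(self, head_pair):
        a = compute_all(head_pair)
        b = compute_all(head_pair)
        assert list(a.scores) == list(METRIC_NAMES)
        assert a.scores == b.scores
        assert a.errors == {}
        row = a.as_row()
        assert all(np.isfinite(row[m]) for m in METRIC_NAMES)

    def test_batch_has_no_missing_entries(self, displays):
        from ctfriqa.distortions import generate_grid

        pairs = generate_grid(
            [displays["head"]], noise_levels=(9.0, 21.0), blur_levels=(1.4,), base_seed=2
        )
        vecs = [compute_all(p) for p in pairs]
        assert len(vecs) == 5
        for v in vecs:
            assert set(v.scores) == set(METRIC_NAMES)
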