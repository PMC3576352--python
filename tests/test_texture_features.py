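import math

import numpy as np
import pytest

from petquant.texture_features import (DEFAULT_OFFSETS, DegenerateModelError,
                                       GlcmMatrix, compute_glcm, compute_rlm,
                                       descriptive_features, fit_gmrf,
                                       glcm_features, quantize, rlm_features,
                                       simulate_gmrf, window_features)

# ------------------------------------------------------------------ oracles


def brute_glcm(levels, mask, G, offsets, symmetric=True):
    """O(n^2) double-loop co-occurrence counter."""
    counts = np.zeros((G, G))
    nr, nc = levels.shape
    for di, dj in offsets:
        for r in range(nr):
            for c in range(nc):
                r2, c2 = r + di, c + dj
                if 0 <= r2 < nr and 0 <= c2 < nc and mask[r, c] and mask[r2, c2]:
                    counts[levels[r, c] - 1, levels[r2, c2] - 1] += 1
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum()


def brute_glcm_features(P):
    """Direct formula evaluation, independent of the vectorized code."""
    G = P.shape[0]
    out = {}
    ent = eng = contrast = homog = acorr = 0.0
    mu_i = mu_j = 0.0
    for i in range(1, G + 1):
        for j in range(1, G + 1):
            p = P[i - 1, j - 1]
            mu_i += i * p
            mu_j += j * p
    var_i = var_j = cshade = sumsq = 0.0
    for i in range(1, G + 1):
        for j in range(1, G + 1):
            p = P[i - 1, j - 1]
            if p > 0:
                ent -= p * math.log2(p)
            eng += p * p
            contrast += (i - j) ** 2 * p
            homog += p / (1 + abs(i - j))
            acorr += i * j * p
            var_i += (i - mu_i) ** 2 * p
            var_j += (j - mu_j) ** 2 * p
            cshade += (i + j - mu_i - mu_j) ** 3 * p
            sumsq += (i - mu_i) ** 2 * p
    p_sum = {}
    p_diff = {}
    for i in range(1, G + 1):
        for j in range(1, G + 1):
            p_sum[i + j] = p_sum.get(i + j, 0.0) + P[i - 1, j - 1]
            p_diff[abs(i - j)] = p_diff.get(abs(i - j), 0.0) + P[i - 1, j - 1]
    sum_avg = sum(k * v for k, v in p_sum.items())
    sum_var = sum((k - sum_avg) ** 2 * v for k, v in p_sum.items())
    diff_ent = -sum(v * math.log2(v) for v in p_diff.values() if v > 0)
    out.update(ENTROPY=ent, ENERGY=eng, CONTRAST=contrast, HOMOG=homog,
               ACORR=acorr, CSHADE=cshade, **{"MAX.PR": P.max(),
               "SUM.SQR": sumsq, "SUM.AVG": sum_avg, "SUM.VAR": sum_var,
               "DIFFENTROPY": diff_ent})
    if var_i > 0 and var_j > 0:
        out["CORRELATION"] = (acorr - mu_i * mu_j) / math.sqrt(var_i * var_j)
    else:
        out["CORRELATION"] = 0.0
    return out


def brute_runs(levels, mask, direction):
    """Enumerate maximal runs along one direction by explicit scanning."""
    nr, nc = levels.shape
    di, dj = direction
    runs = []
    starts = [(r, c) for r in range(nr) for c in range(nc)
              if not (0 <= r - di < nr and 0 <= c - dj < nc)]
    for r0, c0 in starts:
        r, c = r0, c0
        cur, length = None, 0
        while 0 <= r < nr and 0 <= c < nc:
            if mask[r, c] and levels[r, c] == cur:
                length += 1
            else:
                if cur is not None and length:
                    runs.append((cur, length))
                cur, length = (levels[r, c], 1) if mask[r, c] else (None, 0)
            r, c = r + di, c + dj
        if cur is not None and length:
            runs.append((cur, length))
    return runs


# -------------------------------------------------------------------- tests


class TestQuantize:
    def test_endpoints_map_to_extreme_levels(self):
        win = quantize(np.array([[0.0, 8.0], [4.0, 2.0]]), G=8)
        assert win.levels[0, 0] == 1 and win.levels[0, 1] == 8

    def test_constant_window_all_level_one(self):
        win = quantize(np.full((3, 3), 5.0), G=8)
        assert np.all(win.levels == 1)

    def test_uniform_values_fill_bins_evenly(self, rng):
        vals = rng.uniform(0, 1, (64, 64))
        vals.flat[0], vals.flat[1] = 0.0, 1.0  # pin the range
        win = quantize(vals, G=16)
        counts = np.bincount(win.levels.ravel(), minlength=17)[1:]
        n = vals.size
        assert np.all(np.abs(counts - n / 16) < 3 * np.sqrt(n / 16))


class TestDescriptive:
    def test_hand_computed_small_sample(self):
        f = descriptive_features([1, 2, 3, 4, 5])
        assert f["AVGint"] == 3.0
        assert f["MEDIANint"] == 3.0
        assert f["MADint"] == 1.0
        assert f["MAXDEVint"] == 2.0
        assert f["SKEWNESSint"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_sample_degenerate_spread(self):
        f = descriptive_features(np.full(10, 4.0))
        assert f["SDint"] == 0.0 and f["MADint"] == 0.0
        assert abs(f["IRQint"]) < 0.2

    def test_normal_sample_moments(self, rng):
        x = rng.standard_normal(5000)
        f = descriptive_features(x)
        assert f["KURTOSISint"] == pytest.approx(0.0, abs=0.2)
        assert f["SKEWNESSint"] == pytest.approx(0.0, abs=0.1)
        assert f["IRQint"] == pytest.approx(1.349, abs=0.1)

    def test_too_few_values_flags_higher_moments(self):
        f = descriptive_features([1.0, 2.0])
        assert math.isnan(f["SKEWNESSint"]) and math.isnan(f["IRQint"])
        assert f["AVGint"] == 1.5


class TestGlcm:
    def test_constant_window_single_entry(self):
        win = quantize(np.full((4, 4), 2.0), G=8)
        M = compute_glcm(win)
        assert M.P.max() == 1.0 and np.count_nonzero(M.P) == 1
        f = glcm_features(M)
        assert f["ENTROPY"] == 0.0 and f["ENERGY"] == 1.0 and f["MAX.PR"] == 1.0

    def test_checkerboard_two_equal_mass_points(self):
        board = np.indices((4, 4)).sum(axis=0) % 2
        win = quantize(board.astype(float), G=2)
        M = compute_glcm(win, offsets=((0, 1), (1, 0)), symmetric=True)
        assert M.P[0, 1] == pytest.approx(0.5)
        assert M.P[1, 0] == pytest.approx(0.5)
        f = glcm_features(M)
        assert f["ENTROPY"] == pytest.approx(1.0)  # 1 bit
        assert f["MAX.PR"] == pytest.approx(0.5)
        assert f["ENERGY"] == pytest.approx(0.5)

    def test_uniform_matrix_maximum_entropy(self):
        G = 8
        M = GlcmMatrix(P=np.full((G, G), 1.0 / G ** 2), offsets=())
        assert glcm_features(M)["ENTROPY"] == pytest.approx(2 * math.log2(G))

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_brute_force_on_random_windows(self, trial, rng):
        img = rng.uniform(0, 10, (8, 8))
        mask = rng.uniform(size=(8, 8)) > 0.2
        mask[0, 0] = mask[0, 1] = True
        win = quantize(img, G=6, mask=mask)
        M = compute_glcm(win)
        expected = brute_glcm(win.levels, mask, 6, DEFAULT_OFFSETS)
        np.testing.assert_allclose(M.P, expected, atol=1e-12)
        got = glcm_features(M)
        want = brute_glcm_features(M.P)
        for k, v in want.items():
            assert got[k] == pytest.approx(v, abs=1e-10), k

    def test_shift_invariance_with_lesion_range(self, rng):
        img = rng.uniform(0, 10, (8, 8))
        f1 = glcm_features(compute_glcm(quantize(img, G=8)))
        f2 = glcm_features(compute_glcm(quantize(img + 100.0, G=8)))
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], abs=1e-9), k


class TestRunLength:
    def test_hand_traced_row(self):
        win = quantize(np.array([[1.0, 1.0, 2.0, 2.0, 2.0]]), G=2,
                       value_range=(1, 2))
        R = compute_rlm(win, (0, 1))
        assert R.r[0, 1] == 1 and R.r[1, 2] == 1 and R.n_runs == 2
        f = rlm_features(R)
        assert f["SRE"] == pytest.approx(13 / 72)
        assert f["LRE"] == pytest.approx(6.5)
        assert f["RP"] == pytest.approx(0.4)
        assert f["GLN"] == pytest.approx(1.0)
        assert f["RLN"] == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [3, 5, 8])
    def test_constant_row_closed_form(self, n):
        win = quantize(np.ones((1, n)), G=4)
        f = rlm_features(compute_rlm(win, (0, 1)))
        assert f["LRE"] == pytest.approx(n ** 2)
        assert f["SRE"] == pytest.approx(1 / n ** 2)
        assert f["RP"] == pytest.approx(1 / n)

    def test_alternating_row_all_unit_runs(self):
        row = np.array([[1.0, 2.0] * 4])
        win = quantize(row, G=2, value_range=(1, 2))
        f = rlm_features(compute_rlm(win, (0, 1)))
        assert f["SRE"] == 1.0 and f["LRE"] == 1.0 and f["RP"] == 1.0

    @pytest.mark.parametrize("direction", [(0, 1), (1, 0), (1, 1), (1, -1)])
    @pytest.mark.parametrize("trial", range(3))
    def test_matches_brute_force_runs(self, direction, trial, rng):
        img = rng.integers(1, 4, (7, 6)).astype(float)
        mask = rng.uniform(size=(7, 6)) > 0.2
        win = quantize(img, G=3, value_range=(1, 3), mask=mask)
        R = compute_rlm(win, direction)
        runs = brute_runs(win.levels, mask, direction)
        expected = np.zeros_like(R.r)
        for lev, length in runs:
            expected[lev - 1, length - 1] += 1
        np.testing.assert_array_equal(R.r, expected)
        # pixel conservation: sum_j j * r[:, j] = number of valid pixels
        lengths = np.arange(1, R.r.shape[1] + 1)
        assert (R.r * lengths).sum() == mask.sum() == R.n_pixels

    def test_masked_pixels_terminate_runs(self):
        img = np.ones((1, 5))
        mask = np.array([[True, True, False, True, True]])
        win = quantize(img, G=2, mask=mask)
        R = compute_rlm(win, (0, 1))
        assert R.n_runs == 2 and R.r[0, 1] == 2


class TestGmrf:
    def test_white_noise_has_no_interaction(self, rng):
        model = fit_gmrf(rng.standard_normal((64, 64)))
        assert np.all(np.abs(model.theta) < 0.05)
        assert model.sigma == pytest.approx(1.0, abs=0.05)

    def test_parameter_recovery_from_gibbs_samples(self):
        theta = np.array([0.2, 0.1, 0.05])
        errs = []
        for rep in range(5):
            img = simulate_gmrf(theta, 1.0, (64, 64), sweeps=100, seed=rep)
            errs.append(np.abs(fit_gmrf(img).theta - theta))
        assert np.mean(errs) < 0.05

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateModelError):
            fit_gmrf(np.full((16, 16), 3.0))

    def test_half_turn_rotation_invariance(self, rng):
        img = simulate_gmrf([0.2, 0.1, 0.05], 1.0, (32, 32), sweeps=50, seed=3)
        a = fit_gmrf(img).theta
        b = fit_gmrf(np.rot90(img, 2)).theta
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_unstable_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_gmrf([0.3, 0.2, 0.1], 1.0, (8, 8))


class TestWindowFeatures:
    def test_full_registry_present_and_finite(self, rng):
        from petquant.texture_features import FEATURE_REGISTRY

        img = rng.uniform(1, 9, (11, 11))
        feats = window_features(img, G=16)
        assert set(FEATURE_REGISTRY) <= set(feats)
        assert all(math.isfinite(feats[k]) for k in FEATURE_REGISTRY)
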