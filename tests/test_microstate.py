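"""Microstate stage: GFP, peak picking, T-AAHC, CV selection, back-fitting."""

import numpy as np
import pandas as pd
import pytest

from eegdecide.microstate import (GFPSeries, TAAHC, backfit, cv_criterion,
                                  gfp, gfp_peaks, match_across_conditions,
                                  residual_variance, select_k,
                                  spatial_correlation, taahc)


def _orthonormal_maps(rng, n_channels, k):
    T = np.linalg.qr(rng.standard_normal((n_channels, k)))[0].T
    T = T - T.mean(axis=1, keepdims=True)
    return T / np.linalg.norm(T, axis=1, keepdims=True)


class TestGFP:
    @pytest.mark.parametrize("erp_map, expected", [
        ([1.0, -1.0], 1.0),
        ([2.0, -1.0, -1.0], np.sqrt(2.0)),
    ])
    def test_closed_form(self, erp_map, expected):
        """GFP is the RMS of average-referenced electrode values."""
        out = gfp(np.asarray(erp_map)[:, None])
        assert out.values[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_map_is_zero_field(self):
        out = gfp(np.full((5, 3), 7.0))
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_matches_direct_rms_oracle(self, rng):
        erp = rng.standard_normal((16, 40))
        erp -= erp.mean(axis=0)
        expected = np.sqrt((erp**2).mean(axis=0))  # direct formula
        np.testing.assert_allclose(gfp(erp).values, expected, atol=1e-12)

    def test_rereferences_with_warning(self, rng):
        erp = rng.standard_normal((8, 10)) + 5.0
        with pytest.warns(UserWarning, match="re-referencing"):
            out = gfp(erp)
        np.testing.assert_allclose(
            out.values, np.sqrt(((erp - erp.mean(0))**2).mean(0)), atol=1e-12)


class TestGFPPeaks:
    def test_strict_local_maxima(self):
        s = GFPSeries(np.array([0.0, 1.0, 0.0, 2.0, 0.0]), fs=1000.0)
        np.testing.assert_array_equal(gfp_peaks(s), [1, 3])

    def test_thinning_keeps_larger(self):
        fs = 1000.0  # 1 sample = 1 ms
        v = np.array([0, 1, 0, 0, 2, 0], dtype=float)
        s = GFPSeries(v, fs)
        np.testing.assert_array_equal(gfp_peaks(s, min_separation_ms=10), [4])

    def test_monotone_series_empty(self):
        s = GFPSeries(np.arange(10.0), fs=250.0)
        assert gfp_peaks(s).size == 0


class TestTAAHC:
    def test_template_recovery_from_noisy_maps(self):
        """60 noisy copies of 3 orthogonal templates recovered with
        |spatial correlation| >= 0.95 at K=3 (20 seeds)."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            T = _orthonormal_maps(rng, 32, 3)
            idx = rng.integers(0, 3, 60)
            maps = T[idx] + 0.1 * rng.standard_normal((60, 32)) / np.sqrt(32)
            sol = taahc(maps, 3, 3)[3]
            best = np.array([
                max(abs(spatial_correlation(t, u)) for u in sol.templates)
                for t in T])
            ok += bool((best >= 0.95).all())
        assert ok == 20

    def test_gev_one_when_every_map_its_own_cluster(self, rng):
        maps = rng.standard_normal((10, 8))
        sols = taahc(maps, 2, 10)
        assert sols[10].gev == pytest.approx(1.0, abs=1e-12)

    def test_identical_maps_single_cluster(self, rng):
        maps = np.tile(rng.standard_normal(8), (6, 1))
        sol = taahc(maps, 1, 1)[1]
        assert sol.gev == pytest.approx(1.0, abs=1e-12)

    def test_gev_nondecreasing_in_k(self, rng):
        maps = rng.standard_normal((30, 16))
        sols = taahc(maps, 2, 12)
        gevs = [sols[k].gev for k in sorted(sols)]
        assert all(np.diff(gevs) >= -1e-12)

    def test_k_max_exceeding_maps_rejected(self, rng):
        with pytest.raises(ValueError, match="k_max"):
            taahc(rng.standard_normal((5, 8)), 2, 6)

    def test_sklearn_protocol(self, rng):
        maps = rng.standard_normal((20, 8))
        est = TAAHC(k_min=3, k_max=5).set_params(k_min=2)
        assert est.get_params()["k_min"] == 2
        labels = est.fit_predict(maps)
        assert labels.shape == (20,)
        assert est.templates_.shape == (2, 8)
        np.testing.assert_allclose(
            np.linalg.norm(est.templates_, axis=1), 1.0, atol=1e-12)


class TestModelSelection:
    def test_cv_closed_form(self):
        assert cv_criterion(1.0, 32, 4) == pytest.approx((31 / 27) ** 2,
                                                         abs=1e-12)

    def test_perfect_fit_gives_zero_cv(self):
        for k in range(1, 6):
            assert cv_criterion(0.0, 32, k) == 0.0

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError):
            cv_criterion(1.0, 5, 4)

    def test_selects_planted_k(self):
        """CV picks K=3 for 3-template synthetic maps in >=18/20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            T = _orthonormal_maps(rng, 32, 3)
            maps = T[rng.integers(0, 3, 60)] \
                + 0.1 * rng.standard_normal((60, 32)) / np.sqrt(32)
            sols = taahc(maps, 2, 8)
            hits += select_k(sols, maps) == 3
        assert hits >= 18

    def test_residual_variance_zero_for_exact_fit(self, rng):
        T = _orthonormal_maps(rng, 8, 2)
        maps = np.vstack([3 * T[0], -2 * T[1], T[0]])
        assert residual_variance(maps, T, np.array([0, 1, 0])) == \
            pytest.approx(0.0, abs=1e-12)


class TestBackfit:
    def test_planted_two_segment_sequence(self, rng):
        T = _orthonormal_maps(rng, 16, 2)
        erp = np.hstack([np.outer(T[0], np.ones(50) * 3),
                         np.outer(T[1], np.ones(30) * 2)])
        labels, seg = backfit(erp, T, fs=1000.0)
        assert len(seg) == 2
        assert list(seg["template"]) == [0, 1]
        assert seg["end_ms"].iloc[-1] == pytest.approx(80.0)

    def test_single_scaled_template_one_segment(self, rng):
        T = _orthonormal_maps(rng, 16, 2)
        erp = np.outer(T[0], np.linspace(1, 5, 40))
        _, seg = backfit(erp, T, fs=250.0)
        assert len(seg) == 1 and seg["template"].iloc[0] == 0

    def test_noisy_sequence_label_accuracy(self):
        """Planted 3-state sequence at sigma=0.2 relabeled >=90% correctly."""
        rng = np.random.default_rng(4)
        T = _orthonormal_maps(rng, 32, 3)
        truth = np.repeat([0, 1, 2, 0, 1], 40)
        erp = T[truth].T * 2.0 + 0.2 * rng.standard_normal((32, truth.size))
        labels, _ = backfit(erp, T, fs=250.0)
        assert (labels == truth).mean() >= 0.90

    def test_labels_invariant_to_global_scaling(self, rng):
        T = _orthonormal_maps(rng, 16, 3)
        erp = rng.standard_normal((16, 60))
        l1, _ = backfit(erp, T, fs=250.0)
        l2, _ = backfit(erp * 37.5, T, fs=250.0)
        np.testing.assert_array_equal(l1, l2)

    def test_segments_tile_window(self, rng):
        T = _orthonormal_maps(rng, 16, 3)
        erp = rng.standard_normal((16, 100))
        _, seg = backfit(erp, T, fs=250.0, tmin=0.0)
        assert seg["start_ms"].iloc[0] == 0.0
        np.testing.assert_allclose(seg["end_ms"].iloc[:-1],
                                   seg["start_ms"].iloc[1:])
        assert seg["end_ms"].iloc[-1] == pytest.approx(100 / 250 * 1000)


class TestMatching:
    def test_identical_sets_identity(self, rng):
        T = _orthonormal_maps(rng, 16, 4)
        out = match_across_conditions({"a": T, "b": T.copy()})
        assert list(out["template"]) == list(out["ref_template"])
        np.testing.assert_allclose(out["abs_corr"], 1.0, atol=1e-9)

    def test_permutation_recovered(self, rng):
        T = _orthonormal_maps(rng, 16, 4)
        perm = np.array([2, 0, 3, 1])
        out = match_across_conditions({"a": T, "b": T[perm]})
        mapping = dict(zip(out["ref_template"], out["template"]))
        for ref_idx, b_idx in mapping.items():
            assert perm[b_idx] == ref_idx

    def test_shared_templates_rank_highest(self):
        """When two sets share 3 of 6 templates, the shared pairs are the
        three highest-correlation matches (20 seeds)."""
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            shared = _orthonormal_maps(rng, 32, 3)
            a = np.vstack([shared, _orthonormal_maps(rng, 32, 3)])
            b = np.vstack([shared, _orthonormal_maps(rng, 32, 3)])
            out = match_across_conditions({"a": a, "b": b})
            top3 = out.sort_values("abs_corr", ascending=False).head(3)
            ok += set(zip(top3["ref_template"], top3["template"])) == \
                {(0, 0), (1, 1), (2, 2)}
        assert ok == 20

    def test_needs_two_conditions(self, rng):
        with pytest.raises(ValueError):
            match_across_conditions({"a": rng.standard_normal((3, 8))})
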