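"""Cosinor regression exactness, umbrella-test oracles and calibration,
and the BH step-up against a brute-force implementation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from splicerhythm.rhythm import (
    _UmbrellaDesign,
    bh_adjust,
    detect_rhythms,
    harmonic_fit,
    harmonic_fit_matrix,
    umbrella_rank_test,
    umbrella_rank_test_matrix,
)

from conftest import make_matrix


class TestHarmonicFit:
    @pytest.mark.parametrize("grid", [
        np.arange(0.0, 48.0, 2.0),
        np.arange(0.0, 25.0, 2.0),
        np.arange(12.0, 43.0, 3.0),
    ])
    @pytest.mark.parametrize("period", [24.0, 12.0])
    @pytest.mark.parametrize("robust", [False, True])
    def test_noise_free_recovery_exact(self, grid, period, robust):
        m, A, phi = 5.0, 2.0, 7.25
        y = m + A * np.cos(2 * np.pi * (grid - phi) / period)
        fit = harmonic_fit(y, grid, period, robust=robust)
        assert fit.mesor == pytest.approx(m, abs=1e-8)
        assert fit.amplitude == pytest.approx(A, abs=1e-8)
        assert fit.peak_phase == pytest.approx(phi % period, abs=1e-8)
        assert fit.rel_amp == pytest.approx(A / m, abs=1e-8)

    def test_sine_phase_is_quarter_period(self):
        t = np.arange(0.0, 24.0, 2.0)
        y = 3.0 + np.sin(2 * np.pi * t / 24.0)
        fit = harmonic_fit(y, t, 24.0)
        assert fit.peak_phase == pytest.approx(6.0, abs=1e-8)

    def test_constant_series_has_no_phase(self):
        t = np.arange(0.0, 24.0, 2.0)
        fit = harmonic_fit(np.full_like(t, 4.0), t, 24.0)
        assert fit.amplitude == pytest.approx(0.0, abs=1e-10)
        assert math.isnan(fit.peak_phase)
        assert fit.rel_amp == pytest.approx(0.0, abs=1e-10)

    def test_phase_equivariance_under_time_shift(self, rng):
        t = np.arange(0.0, 48.0, 2.0)
        y = 2 + np.cos(2 * np.pi * (t - 5) / 24) + 0.1 * rng.standard_normal(t.size)
        base = harmonic_fit(y, t, 24.0).peak_phase
        for delta in (3.0, 11.5, 23.0):
            shifted = harmonic_fit(y, t + delta, 24.0).peak_phase
            assert shifted == pytest.approx((base + delta) % 24.0, abs=1e-6)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError):
            harmonic_fit([1.0, 2.0, 3.0], [0.0, 8.0, 16.0], 24.0)

    def test_degenerate_design_rejected(self):
        t = np.array([0.0, 24.0, 48.0, 72.0, 96.0, 120.0])
        with pytest.raises(ValueError, match="degenerate"):
            harmonic_fit(np.arange(6.0), t, 24.0)

    def test_matrix_and_scalar_agree(self, rng):
        t = np.arange(0.0, 25.0, 2.0)
        Y = rng.standard_normal((5, t.size)) + \
            np.cos(2 * np.pi * t / 24)[None, :]
        tab = harmonic_fit_matrix(Y, t, 24.0, robust=True)
        for i in range(5):
            fit = harmonic_fit(Y[i], t, 24.0, robust=True)
            # IRLS stopping is joint in matrix mode, so agreement is to the
            # convergence tolerance rather than machine precision
            assert tab.loc[i, "mesor"] == pytest.approx(fit.mesor, abs=1e-6)
            assert tab.loc[i, "phase_h"] == pytest.approx(fit.peak_phase, abs=1e-6)

    def test_robust_matches_reference_irls(self, rng):
        # statsmodels RLM with the same Huber constant is the independent
        # cross-check for the hand-rolled vectorised IRLS
        import statsmodels.api as sm

        t = np.arange(0.0, 48.0, 2.0)
        y = 3 + 1.2 * np.cos(2 * np.pi * (t - 4) / 24) + \
            0.3 * rng.standard_normal(t.size)
        y[5] += 5.0
        X = np.column_stack([np.ones_like(t), np.cos(2 * np.pi * t / 24),
                             np.sin(2 * np.pi * t / 24)])
        ref = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
            maxiter=100, tol=1e-10, scale_est="mad")
        fit = harmonic_fit(y, t, 24.0, robust=True)
        # the scale estimators differ slightly (median-centred MAD here,
        # zero-centred in the reference), so agreement is approximate
        assert fit.mesor == pytest.approx(ref.params[0], abs=0.02)
        assert fit.a == pytest.approx(ref.params[1], abs=0.02)
        assert fit.b == pytest.approx(ref.params[2], abs=0.02)


def brute_force_umbrella_p(values, times, period):
    """Independent enumeration oracle: per-shape exact p over all value
    permutations, min over shapes, referred to the permutation null of
    that minimum.  Pure-python double loops, no shared code path."""
    values = np.asarray(values, dtype=float)
    design = _UmbrellaDesign(times, period)
    pairs_per_shape = [list(zip(*np.nonzero(M))) for M in design.masks]

    def stat(v, pairs):
        s = 0.0
        for i, j in pairs:
            if v[i] < v[j]:
                s += 1.0
            elif v[i] == v[j]:
                s += 0.5
        return s

    perms = list(itertools.permutations(values))
    per_shape_stats = [[stat(p, pairs) for p in perms] for pairs in pairs_per_shape]
    n = len(perms)
    minp = []
    for pi in range(n):
        best = 1.0
        for k in range(len(pairs_per_shape)):
            obs = per_shape_stats[k][pi]
            tail = sum(1 for s in per_shape_stats[k] if s >= obs - 1e-9) / n
            best = min(best, tail)
        minp.append(best)
    obs_minp = minp[0]
    return sum(1 for m in minp if m <= obs_minp + 1e-12) / n


class TestUmbrellaRankTest:
    def test_constant_series_p_one(self):
        t = np.arange(0.0, 24.0, 2.0)
        assert umbrella_rank_test(np.full(12, 3.0), t, 24.0) == 1.0

    def test_exact_small_sample_matches_enumeration(self):
        t = np.arange(0.0, 24.0, 4.0)
        v = np.array([1.0, 2.0, 3.0, 3.0, 2.0, 1.0])
        expected = brute_force_umbrella_p(v, t, 24.0)
        assert umbrella_rank_test(v, t, 24.0) == pytest.approx(expected, abs=1e-12)
        assert expected < 0.2  # a perfect umbrella is among the most extreme

    def test_exact_oracle_on_random_small_series(self, rng):
        t = np.arange(0.0, 24.0, 4.0)
        for _ in range(3):
            v = rng.standard_normal(6)
            assert umbrella_rank_test(v, t, 24.0) == pytest.approx(
                brute_force_umbrella_p(v, t, 24.0), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        t = np.arange(0.0, 25.0, 2.0)
        v = rng.standard_normal(13)
        p1 = umbrella_rank_test(v, t, 24.0)
        p2 = umbrella_rank_test(np.exp(v), t, 24.0)
        p3 = umbrella_rank_test(3 * v - 7, t, 24.0)
        assert p1 == p2 == p3

    def test_null_calibration_and_uniformity(self, rng):
        t = np.arange(0.0, 25.0, 2.0)
        V = rng.standard_normal((1000, 13))
        p = umbrella_rank_test_matrix(V, t, 24.0)
        frac = np.mean(p < 0.05)
        assert 0.03 <= frac <= 0.07
        assert kstest(p, "uniform").pvalue > 0.01

    def test_strong_rhythm_detected(self, rng):
        t = np.arange(0.0, 48.0, 2.0)
        v = 5 + 2 * np.cos(2 * np.pi * (t - 9) / 24) + 0.2 * rng.standard_normal(24)
        assert umbrella_rank_test(v, t, 24.0) < 0.001

    def test_insufficient_samples_rejected(self):
        with pytest.raises(ValueError):
            umbrella_rank_test([1.0, 2.0, 3.0], [0.0, 8.0, 16.0], 24.0)


def brute_force_bh(p):
    p = np.asarray(p, dtype=float)
    n = p.size
    q = np.empty(n)
    for i in range(n):
        rank = np.sum(p <= p[i])
        candidates = []
        for j in range(n):
            rj = np.sum(p <= p[j])
            if rj >= rank:
                candidates.append(min(1.0, p[j] * n / rj))
        q[i] = min(candidates)
    return q


class TestBHAdjust:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.all(bh_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(100):
            p = rng.random(rng.integers(1, 12))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_range_and_order_preserved(self, ps):
        q = bh_adjust(ps)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(ps, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestDetectRhythms:
    def test_planted_features_recovered(self, rng):
        t = np.arange(0.0, 48.0, 2.0)
        n_sig, n_null = 30, 70
        phases = rng.uniform(0, 24, n_sig)
        Y = np.vstack([
            5 + 1.0 * np.cos(2 * np.pi * (t - ph) / 24) + 0.25 * rng.standard_normal(24)
            for ph in phases
        ] + [5 + 0.25 * rng.standard_normal(24) for _ in range(n_null)])
        tab = detect_rhythms(make_matrix(Y, t), 24.0, sig_mode=("q", 0.05))
        sig = tab["sig_pass"].to_numpy()
        assert sig[:n_sig].mean() >= 0.95
        assert sig[n_sig:].mean() <= 0.05
        err = np.abs(tab["phase_h"].to_numpy()[:n_sig] - phases)
        err = np.minimum(err, 24 - err)
        assert np.nanmean(err[sig[:n_sig]]) <= 1.0

    def test_amplitude_prefilter_applied_before_fdr(self, rng):
        t = np.arange(0.0, 48.0, 2.0)
        # strong rhythm but tiny relative amplitude: must never be significant
        Y = np.vstack([
            100 + 0.5 * np.cos(2 * np.pi * t / 24) + 0.01 * rng.standard_normal(24),
            5 + 2.0 * np.cos(2 * np.pi * t / 24) + 0.1 * rng.standard_normal(24),
        ])
        tab = detect_rhythms(make_matrix(Y, t), 24.0, sig_mode=("q", 0.05))
        assert not tab.loc[0, "amp_pass"]
        assert not tab.loc[0, "sig_pass"]
        assert np.isnan(tab.loc[0, "q_value"])
        assert tab.loc[1, "sig_pass"]

    def test_flat_matrix_mostly_unflagged(self, rng):
        t = np.arange(0.0, 25.0, 2.0)
        Y = 3 + 0.5 * rng.standard_normal((200, 13))
        tab = detect_rhythms(make_matrix(Y, t), 24.0, sig_mode=("q", 0.05))
        assert tab["sig_pass"].mean() <= 0.05

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            detect_rhythms(make_matrix(np.empty((0, 13)), np.arange(0, 25, 2.0),
                                       ids=[]), 24.0)
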