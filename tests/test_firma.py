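"""Probe-level decomposition and the residual-persistence splicing score."""

import numpy as np
import pandas as pd
import pytest

from splicerhythm.firma import (
    firma_score,
    median_polish,
    quantile_normalize,
    rhythmic_splicing_scan,
    splicing_scores,
)
from splicerhythm.synthio import ProbeDesign, ProbeEvent, gen_probe_matrix, \
    mouse_array_times

from conftest import make_matrix


class TestQuantileNormalize:
    def test_two_column_example(self):
        mat = make_matrix(np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]]),
                          [0.0, 2.0], units="log2intensity")
        out = quantile_normalize(mat)
        assert np.allclose(out.values.to_numpy(),
                           [[2.5, 2.5], [3.5, 3.5], [4.5, 4.5]])

    def test_identical_columns_unchanged(self):
        col = np.array([3.0, 1.0, 7.0, 2.0])
        mat = make_matrix(np.tile(col[:, None], (1, 3)), [0, 2, 4],
                          units="log2intensity")
        out = quantile_normalize(mat)
        assert np.allclose(out.values.to_numpy(), mat.values.to_numpy())

    def test_row_permutation_preserves_multiset(self, rng):
        X = rng.standard_normal((20, 4))
        Xp = X.copy()
        Xp[:, 2] = rng.permutation(Xp[:, 2])
        a = quantile_normalize(make_matrix(X, [0, 2, 4, 6], "log2intensity"))
        b = quantile_normalize(make_matrix(Xp, [0, 2, 4, 6], "log2intensity"))
        assert np.allclose(np.sort(a.values.to_numpy()[:, 2]),
                           np.sort(b.values.to_numpy()[:, 2]))

    def test_idempotent(self, rng):
        X = rng.standard_normal((30, 5))
        mat = make_matrix(X, np.arange(5) * 2.0, "log2intensity")
        once = quantile_normalize(mat)
        twice = quantile_normalize(once)
        assert np.allclose(once.values.to_numpy(), twice.values.to_numpy(),
                           atol=1e-12)

    def test_column_distributions_identical(self, rng):
        X = rng.standard_normal((50, 4)) * [1, 2, 3, 4]
        out = quantile_normalize(make_matrix(X, np.arange(4) * 2.0,
                                             "log2intensity"))
        V = out.values.to_numpy()
        for j in range(1, 4):
            assert np.allclose(np.sort(V[:, 0]), np.sort(V[:, j]))


class TestMedianPolish:
    def test_exactly_additive_block(self, rng):
        row = rng.standard_normal(6)
        col = rng.standard_normal(8)
        block = 3.0 + row[:, None] + col[None, :]
        _, _, _, resid = median_polish(block)
        assert np.max(np.abs(resid)) < 1e-10

    def test_reconstruction_identity(self, rng):
        block = rng.standard_normal((5, 7))
        overall, row, col, resid = median_polish(block)
        approx = overall + row[:, None] + col[None, :] + resid
        assert np.allclose(approx, block, atol=1e-12)

    def test_sample_permutation_equivariance(self, rng):
        block = rng.standard_normal((6, 8))
        perm = rng.permutation(8)
        o1, r1, c1, res1 = median_polish(block)
        o2, r2, c2, res2 = median_polish(block[:, perm])
        assert np.allclose(c2, c1[perm])
        assert np.allclose(np.sort(res1.ravel()), np.sort(res2.ravel()))

    def test_single_perturbed_cell_concentrates_residual(self):
        block = np.zeros((3, 3))
        block[1, 1] += 1.0
        _, _, _, resid = median_polish(block)
        # hand-run: all row/column medians stay zero, the perturbation
        # remains untouched in its cell
        expected = np.zeros((3, 3))
        expected[1, 1] = 1.0
        assert np.allclose(resid, expected, atol=1e-12)

    def test_degenerate_block_rejected(self):
        with pytest.raises(ValueError):
            median_polish(np.ones((1, 5)))


def residuals_with_unit_mad(z_entries, shape=(8, 6)):
    """Build a residual matrix whose scaled MAD is exactly 1, then add
    the requested standardised entries."""
    P, S = shape
    base = np.zeros((P, S))
    # half the cells at +1/1.4826, half at -1/1.4826 -> median 0, MAD 1
    fill = 1.0 / 1.4826
    flat = base.ravel()
    flat[: flat.size // 2] = fill
    flat[flat.size // 2:] = -fill
    base = flat.reshape(P, S)
    # interleave so no long same-sign probe runs build up in any column
    base[::2] *= -1
    for (i, j), z in z_entries.items():
        base[i, j] = z
    return base


class TestFirmaScore:
    def test_all_zero_residuals(self):
        scores, degenerate = firma_score(np.zeros((6, 4)))
        assert degenerate and np.all(scores == 0)

    def test_single_spike_scores_its_z(self):
        R = residuals_with_unit_mad({(3, 2): 3.0})
        scores, degenerate = firma_score(R)
        assert not degenerate
        assert scores[2] == pytest.approx(3.0)

    def test_run_of_four_scores_two(self):
        fill = 1.0 / 1.4826
        # negative flanks so no extension of the z=1 run can beat 4/sqrt(4)
        R = residuals_with_unit_mad({(2, 1): 1.0, (3, 1): 1.0,
                                     (4, 1): 1.0, (5, 1): 1.0,
                                     (1, 1): -fill, (6, 1): -fill})
        scores, _ = firma_score(R)
        assert scores[1] == pytest.approx(2.0)

    def test_probe_order_applied(self):
        # spread entries that only form a run under the stated order
        R = residuals_with_unit_mad({(0, 0): 2.0, (7, 0): 2.0})
        order = [0, 7, 1, 2, 3, 4, 5, 6]  # probes 0 and 7 are adjacent
        s_ordered, _ = firma_score(R, probe_order=np.argsort(order))
        s_plain, _ = firma_score(R)
        assert s_ordered[0] >= 4.0 / np.sqrt(2) - 1e-9
        assert s_ordered[0] > s_plain[0] - 1e-9

    def test_shift_invariance_via_polish(self, rng):
        d = ProbeDesign(n_genes=1, probes_per_gene=8,
                        sampling_times=mouse_array_times(),
                        events=[ProbeEvent("G00001", 2, 4, 24.0, 3.0, 0.8)],
                        noise_sd=0.1, seed=6)
        mat, ann, _ = gen_probe_matrix(d)
        base = splicing_scores(mat, ann, normalize=False)
        shifted = mat.values + 5.0  # constant per-cell shift
        shifted.iloc[:, 0] += 2.0   # plus a per-sample shift
        mat2 = make_matrix(shifted.to_numpy(), mat.times, "log2intensity",
                           ids=list(mat.values.index))
        out2 = splicing_scores(mat2, ann, normalize=False)
        # invariance holds up to the polish's 0.01 sweep tolerance
        assert np.allclose(base.values.to_numpy(), out2.values.to_numpy(),
                           atol=0.05)

    def test_score_monotone_in_event_depth(self):
        times = mouse_array_times()
        means = []
        for depth in (0.25, 0.5, 1.0, 2.0):
            d = ProbeDesign(n_genes=1, probes_per_gene=10, sampling_times=times,
                            events=[ProbeEvent("G00001", 3, 6, 24.0, 6.0, depth)],
                            noise_sd=0.15, seed=13)
            mat, ann, _ = gen_probe_matrix(d)
            scores = splicing_scores(mat, ann, normalize=False)
            means.append(scores.values.to_numpy().mean())
        assert np.all(np.diff(means) > 0)


class TestRhythmicSplicingScan:
    def test_planted_event_recovered_with_phase(self):
        times = mouse_array_times()
        events = [ProbeEvent(f"G{g + 1:05d}", 3, 6, 24.0, float((5 * g) % 24), 1.0)
                  for g in range(8)]
        d = ProbeDesign(n_genes=30, probes_per_gene=10, sampling_times=times,
                        events=events, noise_sd=0.15, gene_rhythm_frac=0.5,
                        gene_rhythm_amp=1.0, seed=3)
        mat, ann, truth = gen_probe_matrix(d)
        tab = rhythmic_splicing_scan(mat, ann)
        sig = tab[tab["sig_pass"]]
        hit = set(sig["gene_id"])
        assert all(g in hit for g in truth["gene_id"])
        # an event modulated at 24 h drives a |cos|-shaped score series,
        # so it surfaces at the 12-h harmonic with phase = event phase mod 12
        s12 = sig[sig["period_h"] == 12.0].set_index("gene_id")
        for g, ph in zip(truth["gene_id"], truth["phase_h"]):
            if g in s12.index:
                d_ = abs(s12.loc[g, "phase_h"] - ph % 12)
                assert min(d_, 12 - d_) <= 1.0

    def test_whole_gene_rhythm_not_flagged(self):
        # quantile normalisation presumes a representative feature count;
        # the scene uses 120 genes so the cross-sample target is stable
        times = mouse_array_times()
        d = ProbeDesign(n_genes=120, probes_per_gene=10, sampling_times=times,
                        events=[], noise_sd=0.15, gene_rhythm_frac=1.0,
                        gene_rhythm_amp=1.0, seed=17)
        mat, ann, _ = gen_probe_matrix(d)
        tab = rhythmic_splicing_scan(mat, ann)
        flagged = tab.groupby("gene_id")["sig_pass"].any()
        assert flagged.mean() <= 0.1

    def test_noise_free_eventless_zero_flags(self):
        times = mouse_array_times()
        d = ProbeDesign(n_genes=5, probes_per_gene=6, sampling_times=times,
                        events=[], noise_sd=0.0, seed=2)
        mat, ann, _ = gen_probe_matrix(d)
        tab = rhythmic_splicing_scan(mat, ann)
        assert not tab["sig_pass"].any()

    def test_small_genes_skipped_with_warning(self):
        times = mouse_array_times()
        d = ProbeDesign(n_genes=2, probes_per_gene=4, sampling_times=times,
                        noise_sd=0.1, seed=5)
        mat, ann, _ = gen_probe_matrix(d)
        ann2 = ann[~((ann["gene_id"] == "G00001") & (ann["probe_index"] > 2))]
        with pytest.warns(UserWarning, match="skipped"):
            tab = rhythmic_splicing_scan(mat, ann2)
        assert "G00001" not in set(tab["gene_id"])
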