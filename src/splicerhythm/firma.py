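"""Splicing-event scores from probe-level array data, and their rhythm scan.

Whole-transcript arrays cannot quantify individual isoforms, but a
candidate splicing event leaves a footprint in the probe-level residuals
of the additive chip/probe (RMA-style) model: several *adjacent* probes
covering the affected exon region deviate from the gene's overall
expression in the same direction.  The workflow is:

1. quantile normalisation across samples,
2. per-gene median polish into chip effects + probe effects + residuals,
3. a per-sample score: residuals are standardised by the gene's residual
   MAD (x 1.4826) and the score is the maximum over all contiguous probe
   runs of ``|sum of z| / sqrt(run length)`` — a CUSUM-style measure of
   residual persistence,
4. an umbrella rank test plus cosinor fit on each gene's score series for
   24-h and 12-h periods, amplitude filter, and BH correction.

Because the per-sample chip effect absorbs whole-gene expression changes,
a gene whose overall expression is rhythmic but whose probes behave
coherently scores near zero at all times: the scan reacts to *splicing*
rhythms, not expression rhythms.  Note that an event whose log2 depth
oscillates as ``depth*cos`` yields a score series proportional to
``|cos|``, so a 24-h event is typically detected at the 12-h harmonic of
the score series; the score phase matches the event phase modulo half the
event period.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import TimedMatrix
from .rhythm import bh_adjust, harmonic_fit_matrix, umbrella_rank_test_matrix

__all__ = [
    "quantile_normalize",
    "median_polish",
    "firma_score",
    "rhythmic_splicing_scan",
]


def quantile_normalize(mat: TimedMatrix) -> TimedMatrix:
    """Replace each column's sorted values by the cross-column mean of
    same-rank values; ties receive the mean of their would-be quantiles."""
    X = mat.values.to_numpy(dtype=float)
    if np.any(~np.isfinite(X)):
        raise ValueError("quantile normalisation requires complete data")
    order = np.argsort(X, axis=0, kind="mergesort")
    ranksorted = np.take_along_axis(X, order, axis=0)
    target = ranksorted.mean(axis=1)
    out = np.empty_like(X)
    n = X.shape[0]
    for j in range(X.shape[1]):
        col = np.empty(n)
        col[order[:, j]] = target
        # average target values over tied observations
        vals, inv, counts = np.unique(X[:, j], return_inverse=True, return_counts=True)
        if len(vals) < n:
            sums = np.zeros(len(vals))
            np.add.at(sums, inv, col)
            col = (sums / counts)[inv]
        out[:, j] = col
    df = pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns)
    return TimedMatrix(df, mat.times.copy(), units=mat.units, meta=dict(mat.meta))


def median_polish(block: np.ndarray, max_iter: int = 10, tol: float = 0.01):
    """Additive decomposition ``block = overall + row + col + residual``
    by alternating row/column median sweeps.

    Returns ``(overall, row_effects, col_effects, residuals)``; sweeps
    stop when the largest absolute change drops below ``tol`` (default
    0.01) or after ``max_iter`` sweeps.  Row effects play the role of
    probe affinities, ``overall + col`` the per-sample expression level.
    """
    X = np.asarray(block, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("median polish needs at least a 2 x 2 block")
    resid = X.copy()
    overall = 0.0
    row = np.zeros(X.shape[0])
    col = np.zeros(X.shape[1])
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        resid -= rmed[:, None]
        row += rmed
        cmed_of_row = np.median(row)
        row -= cmed_of_row
        overall += cmed_of_row
        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        col += cmed
        rmed_of_col = np.median(col)
        col -= rmed_of_col
        overall += rmed_of_col
        delta = max(np.max(np.abs(rmed)), np.max(np.abs(cmed)))
        if delta < tol:
            break
    return overall, row, col, resid


def firma_score(residuals: np.ndarray, probe_order=None) -> tuple[np.ndarray, bool]:
    """Per-sample residual-persistence score.

    Residuals (probes x samples, rows in within-gene probe order unless
    ``probe_order`` gives the ordering) are standardised by the gene's
    global residual MAD (x 1.4826); the score of sample ``j`` is
    ``max over contiguous runs [k..l] of |sum(z[k..l, j])| / sqrt(l-k+1)``.

    Returns ``(scores, degenerate)``; a zero MAD yields all-zero scores
    with ``degenerate=True``.
    """
    R = np.asarray(residuals, dtype=float)
    if probe_order is not None:
        order = np.argsort(np.asarray(probe_order))
        R = R[order]
    P, S = R.shape
    mad = 1.4826 * np.median(np.abs(R - np.median(R)))
    if mad < 1e-12:
        return np.zeros(S), True
    Z = R / mad
    # prefix sums over probes -> all contiguous run sums in O(P^2)
    csum = np.vstack([np.zeros(S), np.cumsum(Z, axis=0)])
    best = np.zeros(S)
    for k in range(P):
        for l in range(k + 1, P + 1):
            run = np.abs(csum[l] - csum[k]) / np.sqrt(l - k)
            best = np.maximum(best, run)
    return best, False


def splicing_scores(probe_mat: TimedMatrix, annotation: pd.DataFrame,
                    normalize: bool = True, min_probes: int = 4) -> TimedMatrix:
    """Gene-level score series for every adequately covered gene.

    ``annotation`` columns: probe_id, gene_id, probe_index.  Genes with
    fewer than ``min_probes`` probes are skipped with a warning.
    """
    mat = quantile_normalize(probe_mat) if normalize else probe_mat
    X = mat.values
    ann = annotation.set_index("probe_id")
    rows, ids = [], []
    skipped = []
    for gene, grp in ann.groupby("gene_id", sort=True):
        probes = [p for p in grp.index if p in X.index]
        if len(probes) < min_probes:
            skipped.append(gene)
            continue
        sub = grp.loc[probes].sort_values("probe_index")
        block = X.loc[sub.index].to_numpy(dtype=float)
        _, _, _, resid = median_polish(block)
        scores, _ = firma_score(resid)
        rows.append(scores)
        ids.append(gene)
    if skipped:
        import warnings

        warnings.warn(f"skipped {len(skipped)} genes with < {min_probes} probes",
                      stacklevel=2)
    df = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, mat.n_samples)),
                      index=ids, columns=X.columns)
    return TimedMatrix(df, mat.times.copy(), units="score")


def rhythmic_splicing_scan(probe_mat: TimedMatrix, annotation: pd.DataFrame,
                           periods=(24.0, 12.0), rel_amp_min: float = 0.1,
                           q_max: float = 0.1, min_probes: int = 4) -> pd.DataFrame:
    """Scan per-gene splicing-score series for rhythms.

    Per gene and period: umbrella rank test + robust cosinor on the score
    series, relative-amplitude filter (>= ``rel_amp_min``) *before* BH
    correction within each period, significance at ``q < q_max``.
    """
    score_mat = splicing_scores(probe_mat, annotation, min_probes=min_probes)
    out = []
    V = score_mat.values.to_numpy(dtype=float)
    for period in periods:
        p = umbrella_rank_test_matrix(V, score_mat.times, period)
        fits = harmonic_fit_matrix(V, score_mat.times, period, robust=True)
        rel = fits["rel_amp"].to_numpy()
        amp_pass = np.nan_to_num(rel, nan=np.inf) >= rel_amp_min
        q = np.full(p.shape, np.nan)
        if np.any(amp_pass):
            q[amp_pass] = bh_adjust(p[amp_pass])
        sig = amp_pass & (np.nan_to_num(q, nan=1.0) < q_max)
        out.append(pd.DataFrame(
            {
                "gene_id": score_mat.feature_ids,
                "period_h": period,
                "p_value": p,
                "q_value": q,
                "mesor": fits["mesor"].to_numpy(),
                "amplitude": fits["amplitude"].to_numpy(),
                "rel_amp": rel,
                "phase_h": fits["phase_h"].to_numpy(),
                "amp_pass": amp_pass,
                "sig_pass": sig,
            }
        ))
    return pd.concat(out, ignore_index=True)
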