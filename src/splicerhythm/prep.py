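"""Between-sample normalisation and expression filtering for count matrices.

Implements trimmed-mean-of-M-values (TMM) scale factors, log2 CPM
transformation, the mean-CPM expression filter with re-normalisation on the
retained features, and the per-gene collapsing of redundant transcript
clusters by best rhythm p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import TimedMatrix

__all__ = [
    "NormFactors",
    "tmm_factors",
    "log_cpm",
    "filter_expressed",
    "filter_and_renormalise",
    "collapse_transcript_clusters",
]


@dataclass
class NormFactors:
    """Per-sample TMM scale factors and raw library sizes.

    Factors are geometric-mean centred, so their product is 1 and the
    effective library size is ``lib_size * factor``.
    """

    factors: np.ndarray
    lib_sizes: np.ndarray

    def __post_init__(self):
        self.factors = np.asarray(self.factors, dtype=float)
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if np.any(self.factors <= 0) or np.any(self.lib_sizes <= 0):
            raise ValueError("factors and library sizes must be > 0")

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.factors * self.lib_sizes


def _tmm_pair(obs, ref, n_obs, n_ref, m_trim=0.3, a_trim=0.05):
    """Weighted trimmed mean of M-values of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M under binomial sampling
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(M)) < 1e-6:
        return 1.0
    n = M.size
    lo_m = np.floor(n * m_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * a_trim) + 1
    hi_a = n + 1 - lo_a
    r_m = rankdata(M)
    r_a = rankdata(A)
    keep = (r_m >= lo_m) & (r_m <= hi_m) & (r_a >= lo_a) & (r_a <= hi_a)
    if not np.any(keep):
        return 1.0
    f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    return float(2.0 ** f)


def tmm_factors(counts: TimedMatrix, m_trim: float = 0.3, a_trim: float = 0.05) -> NormFactors:
    """TMM scale factors for a raw count matrix.

    The reference sample is the one whose upper-quartile/library-size ratio
    is closest to the mean of that ratio across samples.  Per-sample
    factors are 2**(weighted trimmed mean of M-values) against the
    reference (30 % of M and 5 % of A trimmed, inverse-variance weights,
    features zero in either sample excluded) and are geometric-mean
    centred afterwards.
    """
    if counts.units != "counts":
        raise ValueError("tmm_factors expects a raw count matrix")
    X = counts.values.to_numpy(dtype=float)
    lib = X.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("all-zero sample in count matrix")
    uq = np.array([np.quantile(X[:, j][X[:, j] > 0] if np.any(X[:, j] > 0) else X[:, j], 0.75)
                   for j in range(X.shape[1])]) / lib
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        1.0 if j == ref else _tmm_pair(X[:, j], X[:, ref], lib[j], lib[ref], m_trim, a_trim)
        for j in range(X.shape[1])
    ])
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(factors, lib)


def log_cpm(counts: TimedMatrix, factors: NormFactors | None = None,
            prior: float = 0.5) -> TimedMatrix:
    """log2 counts-per-million with a pseudo-count.

    ``value = log2((count + prior) / (lib * factor + 2 * prior) * 1e6)``.
    """
    if counts.units != "counts":
        raise ValueError("log_cpm expects a raw count matrix")
    if prior <= 0:
        raise ValueError("prior pseudo-count must be > 0")
    if factors is None:
        factors = tmm_factors(counts)
    eff = factors.effective_lib_sizes
    X = counts.values.to_numpy(dtype=float)
    vals = np.log2((X + prior) / (eff + 2 * prior)[None, :] * 1e6)
    out = pd.DataFrame(vals, index=counts.values.index, columns=counts.values.columns)
    return TimedMatrix(out, counts.times.copy(), units="log2cpm",
                       meta={**counts.meta, "prior": prior})


def mean_cpm(counts: TimedMatrix, factors: NormFactors | None = None) -> pd.Series:
    """Per-feature mean CPM across all samples (no pseudo-count)."""
    if factors is None:
        try:
            factors = tmm_factors(counts)
        except ValueError:
            # all-zero samples make TMM undefined; fall back to plain
            # library-size scaling so the expression filter can still run
            lib = counts.values.to_numpy(dtype=float).sum(axis=0)
            factors = NormFactors(np.ones_like(lib), np.maximum(lib, 1.0))
    eff = factors.effective_lib_sizes
    X = counts.values.to_numpy(dtype=float)
    return pd.Series((X / eff[None, :] * 1e6).mean(axis=1), index=counts.values.index)


def filter_expressed(counts: TimedMatrix, factors: NormFactors | None = None,
                     min_avg_cpm: float = 0.5) -> list[str]:
    """Ids of features whose mean CPM over all samples is >= the threshold."""
    cpm = mean_cpm(counts, factors)
    return list(cpm.index[cpm >= min_avg_cpm])


def filter_and_renormalise(counts: TimedMatrix, min_avg_cpm: float = 0.5,
                           ) -> tuple[TimedMatrix, NormFactors, list[str]]:
    """Apply the expression filter, then recompute TMM factors on the kept set.

    Returns ``(filtered_counts, new_factors, kept_ids)``.  An empty result
    is reported with a warning rather than an error.
    """
    kept = filter_expressed(counts, None, min_avg_cpm)
    if not kept:
        import warnings

        warnings.warn("expression filter removed every feature", stacklevel=2)
        empty = counts.subset([])
        lib = counts.values.to_numpy(dtype=float).sum(axis=0)
        return empty, NormFactors(np.ones_like(lib), np.maximum(lib, 1.0)), []
    sub = counts.subset(kept)
    return sub, tmm_factors(sub), kept


def collapse_transcript_clusters(rhythm_table: pd.DataFrame,
                                 cluster2gene: pd.Series) -> pd.DataFrame:
    """Keep, per gene and period, only the transcript cluster with the
    smallest rhythm p-value.

    Ties are broken by larger relative amplitude, then lexicographically
    smaller feature id, for determinism.
    """
    tab = rhythm_table.copy()
    missing = [f for f in tab["feature_id"] if f not in cluster2gene.index]
    if missing:
        raise KeyError(f"clusters missing gene annotation: {missing[:5]}")
    tab["gene_id"] = cluster2gene.loc[tab["feature_id"]].values
    tab = tab.sort_values(
        by=["gene_id", "period_h", "p_value", "rel_amp", "feature_id"],
        ascending=[True, True, True, False, True],
        kind="mergesort",
    )
    out = tab.groupby(["gene_id", "period_h"], sort=True).head(1)
    return out.reset_index(drop=True)
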