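"""End-to-end pipeline orchestration with dataset profiles.

The three built-in profiles carry the threshold regimes of the three
study designs this pipeline reproduces:

=============  =======================  ==========================  =============
profile        design                   rhythm significance         pair rule
=============  =======================  ==========================  =============
array48h2h     2-h sampling, 48 h       q < 0.05                    (array: FIRMA
               (microarray)                                         scan, q < 0.1)
rnaseq24h2h    2-h sampling, 24 h       p < 0.005                   p<0.005 and
               (tissue RNA-seq)                                     p<0.05
rnaseq30h3h    3-h sampling, 30 h       p < 0.05                    both p<0.05
               (cell-line RNA-seq)
=============  =======================  ==========================  =============

All stages share: periods 24 h and 12 h, relative-amplitude filter 0.1
applied before FDR, pair BH pool = both periods within a tissue, pair
q < 0.05, amplitude ratio < 2, minimum phase shift period/6 at 24 h and
2 h (tissues) or 3 h (cell lines) at 12 h.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .containers import TimedMatrix
from .pairs import build_pairs, call_phase_shifted
from .phasestats import circular_dispersion, circular_mean, circular_median, phase_clusters
from .prep import filter_and_renormalise, log_cpm
from .rhythm import detect_rhythms
from .firma import rhythmic_splicing_scan
from .synthio import gen_gene_counts

__all__ = ["PipelineConfig", "run_rnaseq_pipeline", "run_array_pipeline"]

_PROFILES = {
    "array48h2h": dict(rhythm_sig=("q", 0.05), pair_p_strict=0.005, pair_p_loose=0.05,
                       shift_profile="baboon"),
    "rnaseq24h2h": dict(rhythm_sig=("p", 0.005), pair_p_strict=0.005, pair_p_loose=0.05,
                        shift_profile="baboon"),
    "rnaseq30h3h": dict(rhythm_sig=("p", 0.05), pair_p_strict=0.05, pair_p_loose=0.05,
                        shift_profile="cellline"),
}


@dataclass
class PipelineConfig:
    """Thresholds and switches for one pipeline run."""

    profile: str = "rnaseq24h2h"
    periods: tuple = (24.0, 12.0)
    rel_amp_min: float = 0.1
    rhythm_sig: tuple = ("p", 0.005)
    pair_p_strict: float = 0.005
    pair_p_loose: float = 0.05
    pair_q_max: float = 0.05
    pair_ratio_max: float = 2.0
    shift_profile: str = "baboon"
    firma_q_max: float = 0.1
    min_avg_cpm: float = 0.5
    cpm_prior: float = 0.5
    robust: bool = True
    seed: int = 0
    tissue: str = ""

    def __post_init__(self):
        if self.profile not in (*_PROFILES, "custom"):
            raise ValueError(f"unknown profile {self.profile!r}")
        for thr in (self.rhythm_sig[1], self.pair_q_max, self.firma_q_max):
            if not (0 < thr <= 1):
                raise ValueError("significance thresholds must lie in (0, 1]")

    @classmethod
    def from_profile(cls, profile: str, **overrides) -> "PipelineConfig":
        if profile not in _PROFILES:
            raise ValueError(f"unknown profile {profile!r}")
        kw = dict(_PROFILES[profile])
        kw.update(overrides)
        return cls(profile=profile, **kw)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        profile = raw.pop("profile", "custom")
        if "periods" in raw:
            raw["periods"] = tuple(float(p) for p in raw["periods"])
        if "rhythm_sig" in raw:
            raw["rhythm_sig"] = tuple(raw["rhythm_sig"])
        if profile in _PROFILES:
            return cls.from_profile(profile, **raw)
        return cls(profile="custom", **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["periods"] = list(self.periods)
        d["rhythm_sig"] = list(self.rhythm_sig)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format="%.10g")


def _manifest(out_dir: Path, config: PipelineConfig, tables: dict, log: list) -> dict:
    manifest = {
        "package": "splicerhythm",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "config": config.to_dict(),
        "stage_log": log,
        "outputs": {name: _sha256(out_dir / f"{name}.tsv") for name in tables},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True)
                                           + "\n")
    return manifest


def _phase_summary(rhythm_tx: pd.DataFrame, periods, seed: int) -> pd.DataFrame:
    rows = []
    for period in periods:
        sub = rhythm_tx[(rhythm_tx["period_h"] == period) & rhythm_tx["sig_pass"]]
        phases = sub["phase_h"].dropna().to_numpy()
        if phases.size == 0:
            continue
        mean, R = circular_mean(phases, period)
        row = {
            "period_h": period,
            "n": int(phases.size),
            "circ_mean_h": mean,
            "circ_median_h": circular_median(phases, period),
            "dispersion_h": circular_dispersion(phases, period),
            "resultant_R": R,
        }
        if phases.size >= 4:
            try:
                _, cents, sds, _ = phase_clusters(phases, period, k=2, seed=seed)
                order = np.argsort(cents)
                for j, o in enumerate(order):
                    row[f"cluster{j + 1}_mean_h"] = float(cents[o])
                    row[f"cluster{j + 1}_sd_h"] = float(sds[o])
            except RuntimeError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def run_rnaseq_pipeline(counts_tx: TimedMatrix, tx2gene: pd.Series,
                        config: PipelineConfig, out_dir) -> dict:
    """Full transcript + gene rhythm analysis and isoform-pair calling.

    Writes, under ``out_dir``: rhythm_transcripts.tsv, rhythm_genes.tsv,
    pairs.tsv, level_comparison.tsv (gene- vs transcript-level rhythmic
    gene sets per period), phase_summary.tsv, norm_report.tsv and
    manifest.json.  Returns the manifest dictionary.
    """
    if counts_tx.units != "counts":
        raise ValueError("pipeline expects raw transcript counts")
    missing = [t for t in counts_tx.feature_ids if t not in tx2gene.index]
    if missing:
        raise KeyError(f"transcripts missing from tx2gene: {missing[:5]}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log = []

    counts_gene = gen_gene_counts(counts_tx, tx2gene)
    levels = {}
    norm_rows = []
    for level, counts in (("transcript", counts_tx), ("gene", counts_gene)):
        filt, factors, kept = filter_and_renormalise(counts, config.min_avg_cpm)
        log.append({"stage": f"filter_{level}", "n_in": counts.n_features,
                    "n_out": len(kept)})
        lc = log_cpm(filt, factors, config.cpm_prior) if kept else None
        levels[level] = lc
        for j in range(counts.n_samples):
            norm_rows.append({"level": level, "sample": j,
                              "time_h": counts.times[j],
                              "lib_size": float(factors.lib_sizes[j]) if kept else np.nan,
                              "tmm_factor": float(factors.factors[j]) if kept else np.nan})

    tables: dict[str, pd.DataFrame] = {"norm_report": pd.DataFrame(norm_rows)}
    rhythm = {}
    for level, lc in levels.items():
        if lc is None or lc.n_features == 0:
            import warnings

            warnings.warn(f"no {level}-level features left after filtering",
                          stacklevel=2)
            rhythm[level] = pd.DataFrame(
                columns=["feature_id", "period_h", "p_value", "q_value", "mesor",
                         "amplitude", "rel_amp", "phase_h", "amp_pass", "sig_pass"])
            continue
        parts = [detect_rhythms(lc, period, config.rel_amp_min, config.rhythm_sig,
                                robust=config.robust)
                 for period in config.periods]
        rhythm[level] = pd.concat(parts, ignore_index=True)
        for period in config.periods:
            tab = rhythm[level]
            n_sig = int(tab.loc[tab["period_h"] == period, "sig_pass"].sum())
            log.append({"stage": f"rhythm_{level}_{period:g}h", "n_sig": n_sig})
    tables["rhythm_transcripts"] = rhythm["transcript"]
    tables["rhythm_genes"] = rhythm["gene"]

    # gene- vs transcript-level rhythmic gene sets
    comp_rows = []
    for period in config.periods:
        g_tab, t_tab = rhythm["gene"], rhythm["transcript"]
        g_sig = set(g_tab.loc[(g_tab["period_h"] == period)
                              & g_tab["sig_pass"].astype(bool), "feature_id"])
        t_sig = t_tab.loc[(t_tab["period_h"] == period)
                          & t_tab["sig_pass"].astype(bool), "feature_id"]
        t_genes = set(tx2gene.loc[list(t_sig)]) if len(t_sig) else set()
        union = g_sig | t_genes
        comp_rows.append({
            "period_h": period,
            "genes_gene_level": len(g_sig),
            "genes_transcript_level": len(t_genes),
            "intersection": len(g_sig & t_genes),
            "union": len(union),
            "gene_only": len(g_sig - t_genes),
            "transcript_only": len(t_genes - g_sig),
        })
    tables["level_comparison"] = pd.DataFrame(comp_rows)

    # isoform pairs on the transcript level
    lc_tx = levels["transcript"]
    if lc_tx is not None and lc_tx.n_features:
        cand = build_pairs(rhythm["transcript"], tx2gene,
                           config.pair_p_strict, config.pair_p_loose)
        lookup = {f: lc_tx.row(f) for f in
                  set(cand["tx_a"]).union(cand["tx_b"])} if len(cand) else {}
        called = call_phase_shifted(cand, lambda f: lookup[f], lc_tx.times,
                                    q_max=config.pair_q_max,
                                    ratio_max=config.pair_ratio_max,
                                    profile=config.shift_profile,
                                    robust=config.robust,
                                    tissue=config.tissue)
    else:
        called = call_phase_shifted(pd.DataFrame(), None, counts_tx.times)
    log.append({"stage": "pairs", "n_candidates": int(len(called)),
                "n_phase_shifted": int(called["phase_shifted"].sum())
                if len(called) else 0})
    tables["pairs"] = called
    tables["phase_summary"] = _phase_summary(rhythm["transcript"], config.periods,
                                             config.seed)

    for name, df in tables.items():
        _write_tsv(df, out_dir / f"{name}.tsv")
    return _manifest(out_dir, config, tables, log)


def run_array_pipeline(probe_mat: TimedMatrix, annotation: pd.DataFrame,
                       config: PipelineConfig, out_dir) -> dict:
    """Probe-level splicing-score rhythm scan (array profile)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scan = rhythmic_splicing_scan(probe_mat, annotation, periods=config.periods,
                                  rel_amp_min=config.rel_amp_min,
                                  q_max=config.firma_q_max)
    log = [{"stage": f"firma_{p:g}h",
            "n_sig": int(scan.loc[scan["period_h"] == p, "sig_pass"].sum())}
           for p in config.periods]
    tables = {"splicing_rhythms": scan}
    for name, df in tables.items():
        _write_tsv(df, out_dir / f"{name}.tsv")
    return _manifest(out_dir, config, tables, log)
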