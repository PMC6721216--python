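"""Synthetic time-course generators with machine-readable ground truth.

These generators emulate the three study designs the pipeline targets:

* a microarray-style design sampled every 2 h over 48 h (two full circadian
  cycles, 24 samples),
* an RNA-seq design sampled every 2 h over 24 h (13 samples, first and last
  time point one period apart),
* an RNA-seq cell-line design sampled every 3 h over 30 h starting 12 h
  after synchronisation (11 samples).

Rhythms are multiplicative on the linear scale,

    lambda(t) = baseline * (1 + rho * cos(2*pi*(t - peak_phase)/period)),

so two same-gene transcripts with equal baseline, equal relative amplitude
``rho`` and antiphasic peaks cancel *exactly* in the gene-level sum: the
gene appears flat although both isoforms oscillate.  This makes rhythm
masking by phase-shifted isoforms an exact, testable property of the
generator rather than a statistical accident.

Counts are drawn from a negative-binomial observation model with mean
proportional to library size (Poisson when ``dispersion == 0``).  Baselines
are expressed in counts-per-million units so that the expression filter of
the preparation stage acts on the generator's own scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import TimedMatrix

__all__ = [
    "RhythmTruth",
    "CountsDesign",
    "ProbeEvent",
    "ProbeDesign",
    "mouse_array_times",
    "baboon_times",
    "cellline_times",
    "gen_transcript_counts",
    "gen_gene_counts",
    "gen_probe_matrix",
    "gen_promoters",
]


# ---------------------------------------------------------------------------
# time grids of the three designs
# ---------------------------------------------------------------------------

def mouse_array_times() -> np.ndarray:
    """2-h sampling over 48 h (24 samples): two cycles, two replicates per phase."""
    return np.arange(0.0, 48.0, 2.0)


def baboon_times() -> np.ndarray:
    """2-h sampling over 24 h inclusive of both endpoints (13 samples)."""
    return np.arange(0.0, 25.0, 2.0)


def cellline_times() -> np.ndarray:
    """3-h sampling for 30 h starting 12 h post synchronisation (11 samples)."""
    return np.arange(12.0, 43.0, 3.0)


# ---------------------------------------------------------------------------
# ground truth and designs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RhythmTruth:
    """Ground-truth rhythm of one feature.

    ``period`` is ``None`` for an arrhythmic feature, in which case
    ``rel_amp`` must be 0.  ``baseline`` is the linear-scale mean in CPM
    units; ``peak_phase`` is the time of the cosine maximum in hours.
    """

    feature_id: str
    period: float | None
    peak_phase: float
    rel_amp: float
    baseline: float

    def __post_init__(self):
        if self.baseline <= 0:
            raise ValueError(f"{self.feature_id}: baseline must be > 0")
        if not (0 <= self.rel_amp < 1):
            raise ValueError(
                f"{self.feature_id}: rel_amp must be in [0, 1); the linear-scale "
                "mean would otherwise reach zero or below"
            )
        if (self.period is None) != (self.rel_amp == 0):
            raise ValueError(f"{self.feature_id}: rel_amp must be 0 iff period is None")
        if self.period is not None and not (0 <= self.peak_phase < self.period):
            raise ValueError(f"{self.feature_id}: peak_phase must lie in [0, period)")

    def mean_profile(self, times) -> np.ndarray:
        """Noise-free linear-scale mean (CPM units) at the given times."""
        times = np.asarray(times, dtype=float)
        if self.period is None or self.rel_amp == 0:
            return np.full(times.shape, float(self.baseline))
        mod = 1.0 + self.rel_amp * np.cos(2 * np.pi * (times - self.peak_phase) / self.period)
        return self.baseline * mod


@dataclass
class CountsDesign:
    """Layout of a synthetic transcript-level count experiment.

    ``transcripts_per_gene`` is either an explicit sequence of per-gene
    transcript counts or ``None``, in which case counts are drawn from a
    geometric distribution truncated to [1, 18] with success probability
    0.59 (mean about 1.7 expressed transcripts per gene, the typical ratio
    in mammalian tissue data).
    """

    n_genes: int
    sampling_times: Sequence[float]
    transcripts_per_gene: Sequence[int] | None = None
    dispersion: float = 0.05
    library_sizes: Sequence[float] | None = None
    n_background: int = 50
    seed: int = 0

    def __post_init__(self):
        self.sampling_times = np.asarray(self.sampling_times, dtype=float)
        if np.any(np.diff(self.sampling_times) <= 0):
            raise ValueError("sampling_times must be strictly increasing")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_sizes is None:
            # typical bulk RNA-seq depth; at 1e6 the Poisson floor would
            # dominate the biological dispersion for low-CPM transcripts
            self.library_sizes = np.full(len(self.sampling_times), 3e7)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if np.any(self.library_sizes <= 0):
            raise ValueError("library sizes must be > 0")
        if len(self.library_sizes) != len(self.sampling_times):
            raise ValueError("one library size per sample required")
        if self.transcripts_per_gene is not None:
            tpg = np.asarray(self.transcripts_per_gene, dtype=int)
            if len(tpg) != self.n_genes:
                raise ValueError("transcripts_per_gene must have one entry per gene")
            if tpg.min() < 1 or tpg.max() > 18:
                raise ValueError("transcripts per gene must lie in [1, 18]")
            self.transcripts_per_gene = tpg


def _draw_transcripts_per_gene(n_genes: int, rng: np.random.Generator) -> np.ndarray:
    # truncated geometric on [1, 18], p = 0.59 -> mean ~1.7
    draws = rng.geometric(0.59, size=n_genes)
    return np.clip(draws, 1, 18)


def design_ids(design: CountsDesign) -> tuple[list[str], pd.Series]:
    """Deterministic gene/transcript ids and the tx2gene map for a design."""
    rng = np.random.default_rng(design.seed)
    tpg = (design.transcripts_per_gene if design.transcripts_per_gene is not None
           else _draw_transcripts_per_gene(design.n_genes, rng))
    tx_ids, gene_of = [], []
    for g in range(design.n_genes):
        gid = f"G{g + 1:05d}"
        for k in range(int(tpg[g])):
            tx_ids.append(f"{gid}.T{k + 1}")
            gene_of.append(gid)
    return tx_ids, pd.Series(gene_of, index=tx_ids, name="gene_id")


def gen_transcript_counts(
    design: CountsDesign,
    truth_spec: Sequence[RhythmTruth] | None = None,
    default_baseline: str = "lognormal",
) -> tuple[TimedMatrix, pd.DataFrame, pd.Series]:
    """Generate a transcript-level count matrix plus its truth table.

    Transcripts named in ``truth_spec`` follow their stated rhythm; all
    other transcripts are flat with baselines drawn log-normally (median
    20 CPM, log-sd 0.8), the typical range of expressed transcripts.

    Baselines are CPM units, and in a real library CPM sums to 1e6 over
    the whole transcriptome.  So that a small scene behaves like a slice
    of a full library, ``design.n_background`` flat single-transcript
    filler genes (ids ``BG...``) absorb the residual library mass
    ``1e6 - sum(baselines)``; without them, counts-per-million computed
    from the scene's column sums would be inflated by orders of
    magnitude.  Set ``n_background=0`` for self-contained toy scenes.

    Returns ``(matrix, truth_table, tx2gene)``.  The truth table has one
    row per transcript (rhythmic or not, fillers flagged by
    ``is_background``) so truth and matrix are closed over each other.
    """
    tx_ids, tx2gene = design_ids(design)
    spec_map = {t.feature_id: t for t in (truth_spec or [])}
    unknown = set(spec_map) - set(tx_ids)
    if unknown:
        raise ValueError(f"truth features not in the design: {sorted(unknown)[:5]}")

    rng = np.random.default_rng(np.random.SeedSequence([int(design.seed), 1]))
    times = design.sampling_times
    n_tx, n_s = len(tx_ids), len(times)

    truths: list[RhythmTruth] = []
    for tid in tx_ids:
        if tid in spec_map:
            truths.append(spec_map[tid])
        else:
            base = 20.0 * np.exp(0.8 * rng.standard_normal()) if default_baseline == "lognormal" else 20.0
            truths.append(RhythmTruth(tid, None, 0.0, 0.0, base))

    n_bg = 0
    residual = 1e6 - sum(t.baseline for t in truths)
    if design.n_background > 0 and residual > 0:
        n_bg = int(design.n_background)
        share = residual / n_bg
        for k in range(n_bg):
            bid = f"BG{k + 1:03d}"
            truths.append(RhythmTruth(f"{bid}.T1", None, 0.0, 0.0, share))
            tx_ids.append(f"{bid}.T1")
        bg_map = pd.Series([f"BG{k + 1:03d}" for k in range(n_bg)],
                           index=[f"BG{k + 1:03d}.T1" for k in range(n_bg)])
        tx2gene = pd.concat([tx2gene, bg_map])
        tx2gene.name = "gene_id"

    mean_cpm = np.vstack([t.mean_profile(times) for t in truths])
    mu = mean_cpm * (np.asarray(design.library_sizes) / 1e6)[None, :]

    if design.dispersion == 0:
        counts = rng.poisson(mu)
    else:
        r = 1.0 / design.dispersion
        # NB as gamma-Poisson mixture: stable for any mean
        lam = rng.gamma(shape=r, scale=mu / r)
        counts = rng.poisson(lam)

    values = pd.DataFrame(counts.astype(np.int64), index=tx_ids)
    mat = TimedMatrix(values, times, units="counts")

    truth_table = pd.DataFrame(
        {
            "feature_id": [t.feature_id for t in truths],
            "gene_id": [tx2gene[t.feature_id] for t in truths],
            "period_h": [np.nan if t.period is None else t.period for t in truths],
            "peak_phase_h": [np.nan if t.period is None else t.peak_phase for t in truths],
            "rel_amp": [t.rel_amp for t in truths],
            "baseline_cpm": [t.baseline for t in truths],
            "is_background": [t.feature_id.startswith("BG") for t in truths],
        }
    ).set_index("feature_id")
    return mat, truth_table, tx2gene


def gen_gene_counts(tx_matrix: TimedMatrix, tx2gene: pd.Series) -> TimedMatrix:
    """Summarise transcript counts to gene level by per-sample summation."""
    missing = [t for t in tx_matrix.feature_ids if t not in tx2gene.index]
    if missing:
        raise KeyError(f"transcripts missing from tx2gene: {missing[:5]}")
    genes = tx2gene.loc[tx_matrix.feature_ids]
    summed = tx_matrix.values.groupby(genes.values, sort=True).sum()
    summed.index.name = "feature_id"
    return TimedMatrix(summed, tx_matrix.times.copy(), units=tx_matrix.units)


# ---------------------------------------------------------------------------
# probe-level array generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeEvent:
    """A planted splicing-like event: a contiguous probe run within a gene
    whose log2 intensity gains ``depth * cos(2*pi*(t - phase)/period)`` on
    top of the gene's additive chip + probe model."""

    gene_id: str
    run_start: int  # 1-based, inclusive
    run_end: int    # 1-based, inclusive
    period: float
    phase: float
    depth: float


@dataclass
class ProbeDesign:
    """Layout of a synthetic probe-level array experiment.

    The per-gene expression ("chip effect") over time can itself be
    rhythmic (``gene_rhythm_amp`` in log2 units applied to a seeded subset
    controlled by ``gene_rhythm_frac``), so that a splicing-score scan can
    be shown to ignore whole-gene expression rhythms.
    """

    n_genes: int
    probes_per_gene: int
    sampling_times: Sequence[float]
    events: Sequence[ProbeEvent] = field(default_factory=list)
    noise_sd: float = 0.1
    gene_rhythm_frac: float = 0.0
    gene_rhythm_amp: float = 1.0
    gene_rhythm_period: float = 24.0
    seed: int = 0

    def __post_init__(self):
        self.sampling_times = np.asarray(self.sampling_times, dtype=float)
        if self.probes_per_gene < 4:
            raise ValueError("probes_per_gene must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for ev in self.events:
            if not (1 <= ev.run_start <= ev.run_end <= self.probes_per_gene):
                raise ValueError(
                    f"event run [{ev.run_start}, {ev.run_end}] outside probes "
                    f"1..{self.probes_per_gene} for {ev.gene_id}"
                )


def gen_probe_matrix(design: ProbeDesign) -> tuple[TimedMatrix, pd.DataFrame, pd.DataFrame]:
    """Generate a probe x sample log2 intensity matrix.

    Returns ``(matrix, probe_annotation, event_truth)``; the annotation has
    columns ``probe_id, gene_id, probe_index`` (1-based within-gene order).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(design.seed), 2]))
    times = design.sampling_times
    P, n_s = design.probes_per_gene, len(times)
    gene_ids = [f"G{g + 1:05d}" for g in range(design.n_genes)]
    events_by_gene: dict[str, list[ProbeEvent]] = {}
    for ev in design.events:
        if ev.gene_id not in gene_ids:
            raise ValueError(f"event gene {ev.gene_id} not in design")
        events_by_gene.setdefault(ev.gene_id, []).append(ev)

    rhythmic_gene = rng.random(design.n_genes) < design.gene_rhythm_frac
    gene_phase = rng.uniform(0, design.gene_rhythm_period, size=design.n_genes)

    rows, probe_ids, ann_rows = [], [], []
    for gi, gid in enumerate(gene_ids):
        base = rng.normal(8.0, 1.0)
        chip = np.full(n_s, base) + rng.normal(0.0, 0.05, size=n_s)
        if rhythmic_gene[gi]:
            chip = chip + design.gene_rhythm_amp * np.cos(
                2 * np.pi * (times - gene_phase[gi]) / design.gene_rhythm_period
            )
        affinity = rng.normal(0.0, 1.0, size=P)
        block = chip[None, :] + affinity[:, None]
        for ev in events_by_gene.get(gid, []):
            term = ev.depth * np.cos(2 * np.pi * (times - ev.phase) / ev.period)
            block[ev.run_start - 1:ev.run_end, :] += term[None, :]
        if design.noise_sd > 0:
            block = block + rng.normal(0.0, design.noise_sd, size=block.shape)
        rows.append(block)
        for p in range(P):
            probe_ids.append(f"{gid}_p{p + 1:02d}")
            ann_rows.append((f"{gid}_p{p + 1:02d}", gid, p + 1))

    values = pd.DataFrame(np.vstack(rows), index=probe_ids)
    mat = TimedMatrix(values, times, units="log2intensity")
    annotation = pd.DataFrame(ann_rows, columns=["probe_id", "gene_id", "probe_index"])
    truth = pd.DataFrame(
        [
            (ev.gene_id, ev.run_start, ev.run_end, ev.period, ev.phase, ev.depth)
            for ev in design.events
        ],
        columns=["gene_id", "run_start", "run_end", "period_h", "phase_h", "depth_log2"],
    )
    truth["gene_is_rhythmic"] = [
        bool(rhythmic_gene[gene_ids.index(g)]) for g in truth["gene_id"]
    ] if len(truth) else pd.Series(dtype=bool)
    return mat, annotation, truth


# ---------------------------------------------------------------------------
# promoter generator
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _sample_motif(pssm, rng: np.random.Generator) -> str:
    out = []
    for col in pssm.matrix.T:  # matrix is 4 x W, rows A,C,G,T
        out.append(rng.choice(_BASES, p=col / col.sum()))
    return "".join(out)


def gen_promoters(
    n_pos: int,
    n_neg: int,
    length: int,
    gc_pos: float,
    gc_neg: float,
    motif=None,
    plant_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]], pd.DataFrame]:
    """Generate positive and control promoter sets with planted motifs.

    Returns ``(positives, negatives, truth)`` where each sequence set is a
    list of ``(seq_id, sequence)`` and the truth table records the planted
    motif position (0-based) or -1.
    """
    for gc in (gc_pos, gc_neg):
        if not (0 < gc <= 1):
            raise ValueError("gc fraction must lie in (0, 1]")
    if not (0 <= plant_rate <= 1):
        raise ValueError("plant_rate must lie in [0, 1]")
    if motif is not None and length < motif.width:
        raise ValueError("motif wider than sequence")

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    positives, truth_rows = [], []
    for i in range(n_pos):
        sid = f"pos{i + 1:04d}"
        seq = _random_seq(length, gc_pos, rng)
        pos = -1
        if motif is not None and rng.random() < plant_rate:
            site = _sample_motif(motif, rng)
            pos = int(rng.integers(0, length - motif.width + 1))
            seq = seq[:pos] + site + seq[pos + motif.width:]
        positives.append((sid, seq))
        truth_rows.append((sid, pos))
    negatives = [(f"neg{i + 1:04d}", _random_seq(length, gc_neg, rng)) for i in range(n_neg)]
    truth = pd.DataFrame(truth_rows, columns=["seq_id", "motif_pos"])
    return positives, negatives, truth


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in records:
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")
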