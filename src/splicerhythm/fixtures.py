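"""Registered, seeded demonstration scenes with digestable outputs.

Each scene writes a small set of deterministic text files plus a
``digests.json`` of SHA-256 hashes; regenerating a scene reproduces its
digests bit for bit.  The scenes double as tutorial material:

* ``masking_demo`` — a gene whose two equal-amplitude antiphasic
  isoforms oscillate while their summed gene-level profile is flat, and
  a gene whose transcripts each carry a sub-threshold rhythm in the same
  phase that only reaches significance after gene-level summation.
* ``phase_bimodal`` — transcript peak phases concentrated near ZT6 and
  ZT18, the day/night bimodality circular clustering should recover.
* ``probe_events`` — a probe-level array scene with planted splicing
  events on rhythmic and arrhythmic genes.
* ``promoter_motifs`` — positive/control promoter sets with a planted
  D-box-like motif, plus the motif in MEME format.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import write_tx2gene
from .promoter import PSSM, write_meme
from .synthio import (
    CountsDesign,
    ProbeDesign,
    ProbeEvent,
    RhythmTruth,
    baboon_times,
    gen_probe_matrix,
    gen_promoters,
    gen_transcript_counts,
    mouse_array_times,
    write_fasta,
)

__all__ = ["SCENES", "make_fixture", "dbox_like_pssm"]


def dbox_like_pssm() -> PSSM:
    """A synthetic high-information 8-mer motif with a D-box-like core
    (TTAxGTAA); a stand-in for clock TF matrices, not a published PSSM."""
    mat = np.full((4, 8), 0.02 / 3)
    for i, b in enumerate("TTATGTAA"):
        mat["ACGT".index(b), i] = 0.98
    mat[:, 3] = [0.4, 0.1, 0.1, 0.4]  # degenerate middle position
    return PSSM("Dbox_synthetic", mat)


def _masking_demo(out: Path) -> list[Path]:
    times = mouse_array_times()
    design = CountsDesign(n_genes=2, sampling_times=times,
                          transcripts_per_gene=[2, 3], dispersion=0.02, seed=11)
    truths = [
        # antiphasic pair: each transcript rhythmic, the sum exactly flat
        RhythmTruth("G00001.T1", 24.0, 6.0, 0.5, 60.0),
        RhythmTruth("G00001.T2", 24.0, 18.0, 0.5, 60.0),
        # coherent weak rhythms: each transcript sub-threshold, sum detectable
        RhythmTruth("G00002.T1", 24.0, 9.0, 0.12, 8.0),
        RhythmTruth("G00002.T2", 24.0, 9.0, 0.12, 8.0),
        RhythmTruth("G00002.T3", 24.0, 9.0, 0.12, 8.0),
    ]
    mat, truth, tx2gene = gen_transcript_counts(design, truths)
    mat.to_tsv(out / "transcript_counts.tsv")
    write_tx2gene(tx2gene, out / "tx2gene.tsv")
    truth.reset_index().to_csv(out / "truth.tsv", sep="\t", index=False,
                               lineterminator="\n")
    return [out / "transcript_counts.tsv", out / "tx2gene.tsv", out / "truth.tsv"]


def _phase_bimodal(out: Path) -> list[Path]:
    times = baboon_times()
    rng = np.random.default_rng(23)
    truths = []
    n_day, n_night = 40, 20
    for i in range(n_day + n_night):
        centre, sd = (6.0, 0.5) if i < n_day else (18.0, 0.5)
        phase = float(np.mod(rng.normal(centre, sd), 24.0))
        truths.append(RhythmTruth(f"G{i + 1:05d}.T1", 24.0, phase, 0.5,
                                  float(20 * np.exp(0.5 * rng.standard_normal()))))
    design = CountsDesign(n_genes=n_day + n_night, sampling_times=times,
                          transcripts_per_gene=[1] * (n_day + n_night),
                          dispersion=0.02, seed=23)
    mat, truth, tx2gene = gen_transcript_counts(design, truths)
    mat.to_tsv(out / "transcript_counts.tsv")
    write_tx2gene(tx2gene, out / "tx2gene.tsv")
    truth.reset_index().to_csv(out / "truth.tsv", sep="\t", index=False,
                               lineterminator="\n")
    return [out / "transcript_counts.tsv", out / "tx2gene.tsv", out / "truth.tsv"]


def _probe_events(out: Path) -> list[Path]:
    times = mouse_array_times()
    events = [ProbeEvent(f"G{g + 1:05d}", 4, 7, 24.0, float((3 * g) % 24), 1.0)
              for g in range(10)]
    design = ProbeDesign(n_genes=40, probes_per_gene=10, sampling_times=times,
                         events=events, noise_sd=0.15, gene_rhythm_frac=0.5,
                         gene_rhythm_amp=1.0, seed=31)
    mat, ann, truth = gen_probe_matrix(design)
    mat.to_tsv(out / "probe_intensities.tsv")
    ann.to_csv(out / "probe_annotation.tsv", sep="\t", index=False,
               lineterminator="\n")
    truth.to_csv(out / "event_truth.tsv", sep="\t", index=False, lineterminator="\n")
    return [out / "probe_intensities.tsv", out / "probe_annotation.tsv",
            out / "event_truth.tsv"]


def _promoter_motifs(out: Path) -> list[Path]:
    pssm = dbox_like_pssm()
    pos, neg, truth = gen_promoters(n_pos=40, n_neg=40, length=400,
                                    gc_pos=0.55, gc_neg=0.45, motif=pssm,
                                    plant_rate=0.9, seed=41)
    write_fasta(pos, out / "promoters_positive.fa")
    write_fasta(neg, out / "promoters_control.fa")
    write_meme([pssm], out / "motifs.meme")
    truth.to_csv(out / "plant_truth.tsv", sep="\t", index=False, lineterminator="\n")
    return [out / "promoters_positive.fa", out / "promoters_control.fa",
            out / "motifs.meme", out / "plant_truth.tsv"]


SCENES = {
    "masking_demo": _masking_demo,
    "phase_bimodal": _phase_bimodal,
    "probe_events": _probe_events,
    "promoter_motifs": _promoter_motifs,
}


def make_fixture(name: str, out_dir) -> dict:
    """Generate a registered scene under ``out_dir``; returns the digests."""
    if name not in SCENES:
        raise KeyError(f"unknown fixture scene {name!r}; "
                       f"available: {sorted(SCENES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = SCENES[name](out)
    digests = {f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in files}
    (out / "digests.json").write_text(json.dumps(digests, indent=2, sort_keys=True)
                                      + "\n")
    return digests
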