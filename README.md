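# splicerhythm

Detection of circadian (24-h) and ultradian (12-h) rhythms in gene,
transcript and splicing-event time courses, with phase statistics and
promoter motif enrichment — a tested, reusable implementation of the
transcript-level rhythmic alternative-splicing workflow, exercisable
end-to-end on synthetic data with known ground truth.

Most circadian transcriptome studies test rhythmicity at the whole-gene
level. That misses — and can actively mask — rhythms of individual
splice isoforms: two same-gene transcripts oscillating in antiphase with
equal amplitude sum to a flat gene profile, while a gene can score as
rhythmic although none of its transcripts does. `splicerhythm`
implements the full analysis chain needed to study this phenomenon:

* **prep** — TMM normalisation (matches edgeR's `calcNormFactors` to
  1e-6), log2 CPM, the mean-CPM ≥ 0.5 expression filter with
  re-normalisation, transcript-cluster collapsing;
* **rhythm** — a rank-based umbrella test for rise-then-fall patterns
  of arbitrary waveform (times folded mod T, Mack–Wolfe-style summed
  Mann–Whitney counts per candidate peak/trough shape, combined via a
  permutation-calibrated min-p), plus robust cosinor regression
  `y = m + a·cos(2πt/T) + b·sin(2πt/T)` giving mesor, amplitude A,
  relative amplitude A/|m| and peak phase; relative-amplitude ≥ 0.1
  pre-filter and Benjamini–Hochberg FDR;
* **pairs** — differential rhythmicity of same-gene isoform pairs via
  nested cosinor models (H0: shared amplitude/phase, free mesors), with
  a label-permutation-calibrated robust F; phase-shifted pair calling
  (q < 0.05, amplitude ratio < 2, phase difference ≥ period/6 at 24 h);
* **firma** — FIRMA-style splicing scores from probe-level array data:
  quantile normalisation, per-gene median polish, and the maximum over
  contiguous probe runs of |Σz|/√len per sample, scanned for 24-h/12-h
  rhythms (q < 0.1);
* **phasestats** — circular mean/median/dispersion and circular
  k-means for day/night phase clusters;
* **promoter** — promoter extraction (TSS ± 1000 bp), GC content,
  Wilcoxon comparisons, and clock-motif (D-box/E-box/E′-box/RRE-style)
  enrichment by average-odds PSSM scoring with one-tailed Fisher tests
  against shuffled controls;
* **synthio** — seeded generators for transcript counts (multiplicative
  rhythms on the linear scale, negative-binomial noise), gene-level
  sums, probe-level intensities with planted splicing events, and
  promoter sets with planted motifs — all with machine-readable ground
  truth.

Three dataset profiles carry the threshold regimes of the designs the
workflow targets: `array48h2h` (2-h sampling, 48 h; q < 0.05),
`rnaseq24h2h` (2-h sampling, 24 h; p < 0.005) and `rnaseq30h3h`
(3-h sampling, 30 h; p < 0.05).

## Worked example: isoform masking

Generate the bundled demonstration scene — one gene with two
equal-amplitude antiphasic isoforms, one gene with three weak coherent
isoforms — and run the full pipeline:

```bash
splicerhythm simulate masking_demo --out-dir scene
splicerhythm run scene/transcript_counts.tsv scene/tx2gene.tsv \
    --out-dir out --profile array48h2h --seed 1
```

`out/rhythm_transcripts.tsv` (24-h rows of the two demo genes):

```
feature_id  period_h  p_value   q_value   rel_amp   phase_h    sig_pass
G00001.T1   24        0.000025  0.000037  0.135504   5.965048  True
G00001.T2   24        0.000025  0.000037  0.132522  18.196729  True
G00002.T1   24        0.035373  NaN       0.064123   8.323944  False
G00002.T2   24        0.040798  NaN       0.070991   8.632967  False
G00002.T3   24        0.000825  0.000825  0.111717  10.298960  True
```

`out/rhythm_genes.tsv`:

```
feature_id  period_h  p_value   q_value  rel_amp   phase_h   sig_pass
G00001      24        0.246363  NaN      0.011513  6.397347  False
G00002      24        0.000025  NaN      0.058068  9.130931  False
```

Reading it: `G00001`'s isoforms are both strongly rhythmic
(p = 2.5×10⁻⁵, peaks ≈ 6 h and ≈ 18 h — antiphasic), yet their sum is
flat (gene p = 0.25, relative amplitude 0.01): transcript-level rhythms
masked at gene level. `G00002` is the converse: its three isoforms peak
coherently near 9 h but are individually weak (p = 0.035, 0.041,
0.0008), while the summed gene profile reaches p = 2.5×10⁻⁵ — the
rank test finds the gene-level rhythm far more convincing than any
single isoform (here the gene still fails the relative-amplitude ≥ 0.1
screen, which is amplitude-, not significance-based). The
`level_comparison.tsv` table tallies these gene- vs transcript-level
set differences per period, and `pairs.tsv` carries the differential-
rhythmicity calls for same-gene isoform pairs.

The `q_value` column is NaN for features removed by the
relative-amplitude pre-filter — they never enter the FDR pool.

## CLI

`splicerhythm` exposes `simulate`, `prep`, `rhythm`, `pairs`, `firma`,
`phases`, `motifs` and `run` (full pipeline: prep → rhythms at
transcript and gene level → isoform pairs → phase summary, with a
manifest recording config, seed and output digests; re-runs are
byte-identical). All inputs and outputs are plain TSV/FASTA/BED/MEME
text files; see `docs/methods.md` for the statistical details and
design decisions.
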