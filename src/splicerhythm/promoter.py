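"""Promoter sequence analysis: GC content, rank-sum comparisons, and
clock-motif (D-box / E-box / E'-box / RRE) enrichment.

Motifs are position probability matrices (PSSMs, MEME minimal format);
sequences are scored with the average-odds statistic — the mean over all
window positions on both strands of the likelihood ratio between the
motif model and a 0-order background.  Enrichment of a motif in a
positive set is assessed against per-sequence shuffled controls with a
one-tailed Fisher's exact test maximised over score thresholds
(Bonferroni-corrected for the number of thresholds tried).
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from scipy.stats import fisher_exact, mannwhitneyu

from .rhythm import bh_adjust

__all__ = [
    "PSSM",
    "read_meme",
    "write_meme",
    "extract_promoters",
    "gc_content",
    "ranksum_test",
    "avg_odds_score",
    "shuffle_sequence",
    "motif_enrichment",
]

_ALPHABET = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
_BASE_INDEX = {b: i for i, b in enumerate(_ALPHABET)}


@dataclass
class PSSM:
    """Position probability matrix over A, C, G, T (4 x width)."""

    motif_id: str
    matrix: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PSSM matrix must have 4 rows (A, C, G, T)")
        if self.pseudocount > 0:
            self.matrix = self.matrix + self.pseudocount
        self.matrix = self.matrix / self.matrix.sum(axis=0, keepdims=True)
        if np.any(self.matrix <= 0):
            raise ValueError(
                "PSSM contains zero probabilities; use a positive pseudocount")
        if np.any(np.abs(self.matrix.sum(axis=0) - 1) > 1e-9):
            raise ValueError("PSSM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    def reverse_complement(self) -> "PSSM":
        return PSSM(self.motif_id + "_rc", self.matrix[::-1, ::-1], 0.0)


def read_meme(path, pseudocount: float = 1e-4) -> list[PSSM]:
    """Read PSSMs from a MEME (minimal) motif file."""
    with open(path) as fh:
        records = motifs.parse(fh, "minimal")
    out = []
    for m in records:
        mat = np.array([[m.pwm[b][i] for i in range(m.length)] for b in _ALPHABET])
        out.append(PSSM(m.name or m.base_id, mat, pseudocount))
    return out


def write_meme(pssms, path, background=None) -> None:
    bg = background if background is not None else [0.25] * 4
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n")
        for p in pssms:
            fh.write(f"MOTIF {p.motif_id}\n")
            # large nsites so probability -> count -> probability round
            # trips through MEME parsers keep full precision
            fh.write(f"letter-probability matrix: alength= 4 w= {p.width} "
                     f"nsites= 1000000 E= 0\n")
            for col in p.matrix.T:
                fh.write(" " + "  ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# promoter extraction and GC content
# ---------------------------------------------------------------------------

@dataclass
class PromoterRecord:
    gene_id: str
    sequence: str
    chrom: str
    start: int  # 0-based, half-open genomic interval of the window
    end: int
    strand: str
    truncated: bool

    @property
    def gc(self) -> float:
        return gc_content(self.sequence)


def _read_bed6(path) -> list[tuple[str, int, int, str, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError("BED6 with strand required for TSS input")
            rows.append((f[0], int(f[1]), int(f[2]), f[3], f[5]))
    return rows


def extract_promoters(genome_fasta, tss_bed, flank: int = 1000) -> list[PromoterRecord]:
    """Promoter windows of ``2*flank + 1`` bases centred on each TSS.

    The TSS of a BED6 interval is its 5' end (``start`` on the + strand,
    ``end - 1`` on the - strand, 0-based).  Minus-strand windows are
    reverse-complemented; windows running off a contig end are truncated
    and flagged.  Exact duplicate sequences are removed keeping the first
    record in input order.
    """
    contigs = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    out, seen = [], set()
    for chrom, start, end, name, strand in _read_bed6(tss_bed):
        if chrom not in contigs:
            raise KeyError(f"contig {chrom!r} absent from the genome FASTA")
        seq = contigs[chrom]
        tss = start if strand != "-" else end - 1
        lo, hi = tss - flank, tss + flank + 1
        truncated = lo < 0 or hi > len(seq)
        lo_c, hi_c = max(lo, 0), min(hi, len(seq))
        window = seq[lo_c:hi_c]
        if strand == "-":
            window = window.translate(_COMPLEMENT)[::-1]
        if window in seen:
            continue
        seen.add(window)
        out.append(PromoterRecord(name, window, chrom, lo_c, hi_c, strand, truncated))
    return out


def gc_content(sequence: str) -> float:
    """(G+C) / (A+C+G+T), case-insensitive; ambiguity codes excluded."""
    s = sequence.upper()
    counts = {b: s.count(b) for b in _ALPHABET}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / total


def ranksum_test(x, y, alternative: str = "two-sided") -> float:
    """Wilcoxon rank-sum p-value: exact for small tie-free samples (total
    size <= 12), otherwise normal approximation with midranks, tie
    correction and continuity correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([x, y]))) == x.size + y.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    return float(mannwhitneyu(x, y, alternative=alternative, method=method).pvalue)


# ---------------------------------------------------------------------------
# motif scoring and enrichment
# ---------------------------------------------------------------------------

def _seq_to_indices(sequence: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, -1) for b in sequence.upper()], dtype=int)


def avg_odds_score(sequence: str, pssm: PSSM, background=None) -> float:
    """Mean over all start positions on both strands of the odds
    ``prod_w p_motif(base_w) / p_bg(base_w)``; window positions holding
    an ambiguous base contribute odds 1 for that position."""
    W = pssm.width
    if len(sequence) < W:
        raise ValueError("sequence shorter than the motif")
    bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
    bg = bg / bg.sum()
    idx = _seq_to_indices(sequence)
    L = idx.size
    n_win = L - W + 1
    total = 0.0
    for mat in (pssm.matrix, pssm.matrix[::-1, ::-1]):
        odds = mat / bg[:, None]               # 4 x W
        odds_ext = np.vstack([odds, np.ones((1, W))])  # ambiguous -> odds 1
        safe = np.where(idx < 0, 4, idx)
        # windows x W gather
        win = np.lib.stride_tricks.sliding_window_view(safe, W)
        vals = odds_ext[win, np.arange(W)[None, :]]
        total += float(np.prod(vals, axis=1).sum())
    return total / (2 * n_win)


def shuffle_sequence(sequence: str, rng: np.random.Generator,
                     kind: str = "mono") -> str:
    """Per-sequence shuffle preserving mononucleotide (default) or
    dinucleotide composition (random Eulerian-walk heuristic)."""
    if kind == "mono":
        arr = np.array(list(sequence))
        rng.shuffle(arr)
        return "".join(arr)
    if kind != "di":
        raise ValueError("kind must be 'mono' or 'di'")
    # dinucleotide-preserving shuffle via random edge ordering with
    # last-edge fixup (Altschul-Erickson style walk, heuristic retry)
    s = sequence
    for _ in range(10):
        edges: dict[str, list[str]] = {}
        for i in range(len(s) - 1):
            edges.setdefault(s[i], []).append(s[i + 1])
        for v in edges.values():
            rng.shuffle(v)
        out = [s[0]]
        cur = s[0]
        ok = True
        for _i in range(len(s) - 1):
            nxt_list = edges.get(cur)
            if not nxt_list:
                ok = False
                break
            cur = nxt_list.pop()
            out.append(cur)
        if ok:
            return "".join(out)
    arr = np.array(list(sequence))
    rng.shuffle(arr)
    return "".join(arr)


def _base_frequencies(sequences) -> np.ndarray:
    counts = np.zeros(4)
    for s in sequences:
        idx = _seq_to_indices(s)
        for b in range(4):
            counts[b] += int(np.sum(idx == b))
    if counts.sum() == 0:
        raise ValueError("no unambiguous bases in the positive set")
    return counts / counts.sum()


def motif_enrichment(positives, pssm: PSSM, seed: int = 0,
                     background=None, shuffle_kind: str = "mono"):
    """One-tailed Fisher enrichment of a motif in a positive sequence set.

    ``positives`` is a list of ``(seq_id, sequence)``.  One shuffled
    control is generated per positive (seeded).  All sequences are scored
    by :func:`avg_odds_score` (background defaults to the 0-order base
    frequencies of the positive set); for every threshold at an observed
    score value a one-tailed Fisher's exact test is run on the
    above/below x positive/control table, and the reported p-value is the
    Bonferroni-corrected minimum over thresholds, capped at 1.

    Returns ``(p_value, details_dict)``.
    """
    if len(positives) < 5:
        raise ValueError("need at least 5 positive sequences")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    seqs = [s for _, s in positives]
    bg = np.asarray(background, dtype=float) if background is not None \
        else _base_frequencies(seqs)
    controls = [shuffle_sequence(s, rng, shuffle_kind) for s in seqs]
    pos_scores = np.array([avg_odds_score(s, pssm, bg) for s in seqs])
    ctl_scores = np.array([avg_odds_score(s, pssm, bg) for s in controls])
    thresholds = np.unique(np.concatenate([pos_scores, ctl_scores]))
    if thresholds.size == 1:
        return 1.0, {"n_thresholds": 0, "pos_scores": pos_scores,
                     "ctl_scores": ctl_scores}
    # drop the lowest value: everything is "above or equal" there
    thresholds = thresholds[1:]
    best = 1.0
    for thr in thresholds:
        a = int(np.sum(pos_scores >= thr))
        b = int(np.sum(ctl_scores >= thr))
        table = [[a, len(pos_scores) - a], [b, len(ctl_scores) - b]]
        p = fisher_exact(table, alternative="greater")[1]
        best = min(best, p)
    p_final = min(1.0, best * thresholds.size)
    return float(p_final), {
        "n_thresholds": int(thresholds.size),
        "pos_scores": pos_scores,
        "ctl_scores": ctl_scores,
    }


def motif_set_enrichment(positives, pssms, seed: int = 0, **kwargs) -> pd.DataFrame:
    """Enrichment of several motifs with BH adjustment across the set."""
    rows = []
    for i, p in enumerate(pssms):
        pv, det = motif_enrichment(positives, p, seed=seed + i, **kwargs)
        rows.append({"motif_id": p.motif_id, "p_value": pv,
                     "n_pos": len(positives), "n_ctrl": len(positives)})
    df = pd.DataFrame(rows)
    df["adj_p"] = bh_adjust(df["p_value"].to_numpy())
    return df
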