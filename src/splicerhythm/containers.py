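"""Core in-memory containers and the TSV matrix dialect shared by all modules.

The central object is :class:`TimedMatrix`: a features x samples expression
grid where every sample carries a time stamp in hours and the grid carries a
units tag (raw counts, log2 CPM, log2 array intensity, or a dimensionless
score).  Sample ids encode the time stamp (``ZT00``, ``ZT02`` ... with an
optional ``_rN`` replicate suffix), so a written TSV is self-describing.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VALID_UNITS = ("counts", "log2cpm", "log2intensity", "score")

_SAMPLE_RE = re.compile(r"^ZT(?P<time>\d+(?:\.\d+)?)(?:_r(?P<rep>\d+))?$")


def sample_ids_for_times(times) -> list[str]:
    """Deterministic sample ids encoding the time stamps.

    Integral hours render as ``ZT06``; replicate time points get an ``_rN``
    suffix in input order (``ZT06_r1``, ``ZT06_r2``).
    """
    times = np.asarray(times, dtype=float)
    seen: dict[float, int] = {}
    counts: dict[float, int] = {}
    for t in times:
        counts[t] = counts.get(t, 0) + 1
    ids = []
    for t in times:
        base = f"ZT{int(round(t)):02d}" if float(t).is_integer() else f"ZT{t:g}"
        if counts[t] > 1:
            seen[t] = seen.get(t, 0) + 1
            ids.append(f"{base}_r{seen[t]}")
        else:
            ids.append(base)
    return ids


def times_from_sample_ids(ids) -> np.ndarray:
    times = []
    for s in ids:
        m = _SAMPLE_RE.match(str(s))
        if m is None:
            raise ValueError(f"sample id {s!r} does not encode a time stamp")
        times.append(float(m.group("time")))
    return np.asarray(times, dtype=float)


@dataclass
class TimedMatrix:
    """Features x timed samples expression grid.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by feature id, one column per sample.
    times : array of float
        Sampling time (hours) per column, same order as the columns.
    units : str
        One of ``counts``, ``log2cpm``, ``log2intensity``, ``score``.
    """

    values: pd.DataFrame
    times: np.ndarray
    units: str = "counts"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[1] != self.times.shape[0]:
            raise ValueError(
                f"{self.values.shape[1]} columns but {self.times.shape[0]} time stamps"
            )
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")
        if self.values.index.hasnans or not self.values.index.is_unique:
            raise ValueError("feature ids must be unique and non-missing")

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, feature_id: str) -> np.ndarray:
        return self.values.loc[feature_id].to_numpy(dtype=float)

    def subset(self, feature_ids) -> "TimedMatrix":
        return TimedMatrix(self.values.loc[list(feature_ids)].copy(), self.times.copy(),
                           self.units, dict(self.meta))

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path) -> None:
        """Write the matrix as TSV with a ``# units:`` comment header."""
        df = self.values.copy()
        df.columns = sample_ids_for_times(self.times)
        df.index.name = "feature_id"
        with open(path, "w") as fh:
            fh.write(f"# units: {self.units}\n")
            df.to_csv(fh, sep="\t", lineterminator="\n")

    @classmethod
    def from_tsv(cls, path) -> "TimedMatrix":
        with open(path) as fh:
            first = fh.readline()
            units = "counts"
            if first.startswith("# units:"):
                units = first.split(":", 1)[1].strip()
                body = fh.read()
            else:
                body = first + fh.read()
        df = pd.read_csv(io.StringIO(body), sep="\t", index_col=0)
        times = times_from_sample_ids(df.columns)
        return cls(df, times, units)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, TimedMatrix):
            return NotImplemented
        return (
            self.units == other.units
            and np.array_equal(self.times, other.times)
            and self.values.equals(other.values)
        )


def read_tx2gene(path) -> pd.Series:
    """Read a two-column transcript -> gene TSV into a Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("tx2gene file needs two columns: transcript_id, gene_id")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="gene_id")


def write_tx2gene(tx2gene: pd.Series, path) -> None:
    df = pd.DataFrame({"transcript_id": tx2gene.index, "gene_id": tx2gene.values})
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
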