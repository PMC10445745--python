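"""Readers and writers for every external format the pipeline touches.

Conventions: all genomic intervals are 0-based half-open (BED convention),
so ``length == end - start`` everywhere.  Every reader has a matching writer
and ``read(write(x)) == x`` on valid inputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .config import SampleMeta

logger = logging.getLogger(__name__)

__all__ = [
    "CountMatrix",
    "read_counts",
    "write_counts",
    "read_bed_like",
    "write_bed",
    "Motif",
    "MotifSet",
    "read_pfm",
    "write_pfm",
    "FootprintTrack",
    "read_track",
    "write_track",
    "read_fasta",
    "write_fasta",
]


# ---------------------------------------------------------------------------
# count matrices


@dataclass
class CountMatrix:
    """Gene x sample integer read counts plus parsed sample metadata."""

    counts: pd.DataFrame  # index: gene id, columns: sample id
    samples: list[SampleMeta]

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicated gene IDs: {list(dups)[:5]}")
        ids = [s.sample_id for s in self.samples]
        if ids != list(self.counts.columns):
            raise ValueError("sample metadata does not match count columns")
        keys = {(s.day, s.replicate, s.gfp) for s in self.samples}
        if len(keys) != len(self.samples):
            raise ValueError("(day, replicate, gfp) combinations must be unique")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def samples_where(self, day=None, gfp=None) -> list[str]:
        """Sample ids matching a day and/or GFP status."""
        out = []
        for s in self.samples:
            if day is not None and s.day != day:
                continue
            if gfp is not None and s.gfp != gfp:
                continue
            out.append(s.sample_id)
        return out


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count matrix (first column gene IDs, header = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    samples = []
    for col in df.columns:
        try:
            samples.append(SampleMeta.parse(col))
        except ValueError as exc:
            raise ValueError(f"malformed sample column {col!r}: {exc}") from exc
    for col in df.columns:
        vals = df[col]
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError(f"non-numeric counts in column {col!r}")
        if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
            raise ValueError(f"negative or non-integer count in column {col!r}")
    return CountMatrix(counts=df.astype(np.int64), samples=samples)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# BED / narrowPeak


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]
_NARROWPEAK_EXTRA = ["signal", "pvalue", "qvalue", "summit"]


def read_bed_like(path: str | Path, *, assign_ids: bool = True) -> pd.DataFrame:
    """Read BED3-6 or 10-column narrowPeak into a sorted interval table.

    Intervals are validated (``start < end``), sorted by (chrom, start, end),
    exact duplicates dropped with a warning, and stable integer ``peak_id``s
    assigned in sorted order.
    """
    rows = pd.read_csv(path, sep="\t", header=None, comment="#")
    ncol = rows.shape[1]
    names = _BED_COLS[: min(ncol, 6)] + _NARROWPEAK_EXTRA[: max(0, ncol - 6)]
    rows.columns = names[:ncol] + [f"extra{i}" for i in range(ncol - len(names))]
    rows["start"] = rows["start"].astype(np.int64)
    rows["end"] = rows["end"].astype(np.int64)
    bad = rows["start"] >= rows["end"]
    if bad.any():
        r = rows[bad].iloc[0]
        raise ValueError(f"start >= end at {r['chrom']}:{r['start']}-{r['end']}")
    before = len(rows)
    rows = rows.drop_duplicates(subset=["chrom", "start", "end"])
    if len(rows) < before:
        logger.warning("dropped %d duplicate intervals from %s", before - len(rows), path)
    rows = rows.sort_values(["chrom", "start", "end"], kind="mergesort").reset_index(drop=True)
    if assign_ids:
        rows.insert(0, "peak_id", np.arange(len(rows), dtype=np.int64))
    return rows


def write_bed(df: pd.DataFrame, path: str | Path, *, cols: list[str] | None = None) -> None:
    cols = cols or [c for c in _BED_COLS if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# JASPAR-style PFMs


@dataclass
class Motif:
    """One position frequency matrix and its TF name."""

    motif_id: str
    tf: str
    pfm: np.ndarray  # shape (4, width), rows A,C,G,T, non-negative counts

    @property
    def width(self) -> int:
        return self.pfm.shape[1]

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pfm.argmax(axis=0))


@dataclass
class MotifSet:
    """Motif collection; multiple motifs may map to one TF."""

    motifs: list[Motif]

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self):
        return len(self.motifs)

    def by_tf(self) -> dict[str, list[Motif]]:
        out: dict[str, list[Motif]] = {}
        for m in self.motifs:
            out.setdefault(m.tf, []).append(m)
        return out

    def get(self, motif_id: str) -> Motif:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(motif_id)


def read_pfm(path: str | Path) -> MotifSet:
    """Read JASPAR-style PFM text: ``>motif_id tf_name`` then 4 count rows.

    Rows are A, C, G, T in order; bracketed JASPAR row labels
    (``A [ 1 2 3 ]``) are tolerated.
    """
    motifs: list[Motif] = []
    header: tuple[str, str] | None = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal rows, header
        if header is None:
            return
        if len(rows) != 4:
            raise ValueError(f"motif {header[0]}: expected 4 rows, got {len(rows)}")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise ValueError(f"motif {header[0]}: unequal row lengths {sorted(widths)}")
        pfm = np.asarray(rows, dtype=float)
        if (pfm < 0).any():
            raise ValueError(f"motif {header[0]}: negative counts")
        if (pfm.sum(axis=0) == 0).any():
            raise ValueError(f"motif {header[0]}: zero total count at a column")
        motifs.append(Motif(motif_id=header[0], tf=header[1], pfm=pfm))
        rows = []
        header = None

    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            header = (parts[0], parts[1].strip() if len(parts) > 1 else parts[0])
        else:
            cleaned = line
            for ch in "ACGTacgt[]":
                cleaned = cleaned.replace(ch, " ")
            vals = [float(x) for x in cleaned.split()]
            if not vals:
                raise ValueError(f"unparseable PFM row: {line!r}")
            rows.append(vals)
    flush()
    if not motifs:
        raise ValueError(f"no motifs found in {path}")
    return MotifSet(motifs)


def write_pfm(ms: MotifSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in ms:
            fh.write(f">{m.motif_id} {m.tf}\n")
            for row in m.pfm:
                fh.write(" ".join(f"{v:g}" for v in row) + "\n")


# ---------------------------------------------------------------------------
# bedGraph per-bp tracks


class FootprintTrack:
    """Per-bp signal from a bedGraph; positions absent from the file read 0.

    Intervals must be non-overlapping within a chromosome.  Queries are
    strand-agnostic; callers reverse windows for minus-strand motifs.
    """

    def __init__(self, intervals: pd.DataFrame):
        # columns: chrom, start, end, value
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, grp in intervals.groupby("chrom", sort=True):
            grp = grp.sort_values("start")
            starts = grp["start"].to_numpy(np.int64)
            ends = grp["end"].to_numpy(np.int64)
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping bedGraph intervals on {chrom}")
            self._chrom[chrom] = (starts, ends, grp["value"].to_numpy(float))

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chrom)

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-bp signal over [start, end); gaps and unknown chroms read 0."""
        if end <= start:
            raise ValueError("empty query window")
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._chrom:
            return out
        starts, ends, vals = self._chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = vals[i]
        return out

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for chrom in self.chroms:
            starts, ends, vals = self._chrom[chrom]
            for s, e, v in zip(starts, ends, vals):
                recs.append((chrom, int(s), int(e), float(v)))
        return pd.DataFrame(recs, columns=["chrom", "start", "end", "value"])


def read_track(path: str | Path) -> FootprintTrack:
    df = pd.read_csv(
        path, sep="\t", header=None, names=["chrom", "start", "end", "value"], comment="#"
    )
    return FootprintTrack(df)


def write_track(track: FootprintTrack, path: str | Path) -> None:
    track.to_frame().to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")
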