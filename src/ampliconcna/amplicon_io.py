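"""Amplicon panels, read counting and count-table I/O.

A targeted amplicon panel is an ordered set of PCR-amplified genomic
intervals (typically one or a few per exon), each annotated with a gene
symbol, GC fraction and length.  Read counting assigns every primary mapped
read to at most one amplicon — the one with which its alignment shares the
maximum overlap — and duplicate reads are deliberately *kept*: at the
extreme depths of amplicon sequencing, most reads are PCR duplicates and
removing them would destroy the copy-number signal.

Amplicons that reciprocally overlap by more than 75% of their lengths are
merged before counting, because a read falling in the shared region could
not be attributed to either with confidence.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd

PANEL_COLUMNS = ["chrom", "start", "end", "gene", "gc", "length"]

_CHRX_NAMES = {"chrx", "x"}


class PanelError(ValueError):
    """Malformed panel definition (bad coordinates, missing GC source...)."""


def _chrom_key(chrom: str):
    """Natural sort key so that chr2 < chr10 and chrX sorts after autosomes."""
    c = chrom.lower().removeprefix("chr")
    if c.isdigit():
        return (0, int(c), "")
    return (1, 0, c)


def gc_fraction(seq: str) -> float:
    """Fraction of G/C bases among non-N bases of ``seq``."""
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return (s.count("G") + s.count("C")) / acgt


@dataclass(frozen=True)
class Amplicon:
    """One targeted interval; coordinates are 0-based half-open."""

    chrom: str
    start: int
    end: int
    gene: str
    gc: float
    id: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ReadAlignment:
    """Minimal view of an aligned single-end read (0-based half-open)."""

    chrom: str
    start: int
    end: int
    duplicate_flag: bool = False


class AmpliconPanel:
    """Ordered amplicon panel backed by a DataFrame.

    The frame has columns chrom, start, end, gene, gc, length, sorted by
    (chrom, start); the row position is the amplicon id.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        missing = [c for c in ("chrom", "start", "end", "gene", "gc") if c not in df]
        if missing:
            raise PanelError(f"panel missing columns: {missing}")
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise PanelError(f"amplicon with start >= end at row {bad}")
        if ((df["gc"] < 0) | (df["gc"] > 1)).any():
            raise PanelError("gc fraction outside [0, 1]")
        df["_key"] = [_chrom_key(c) for c in df["chrom"]]
        df = df.sort_values(["_key", "start"], kind="mergesort").drop(columns="_key")
        df = df.reset_index(drop=True)
        df["length"] = (df["end"] - df["start"]).astype(int)
        self._df = df[PANEL_COLUMNS]

    # -- basic accessors ---------------------------------------------------
    @property
    def df(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __getitem__(self, i: int) -> Amplicon:
        r = self._df.iloc[i]
        return Amplicon(r.chrom, int(r.start), int(r.end), r.gene, float(r.gc), int(i))

    def __iter__(self) -> Iterator[Amplicon]:
        for i in range(len(self)):
            yield self[i]

    @property
    def gc(self) -> np.ndarray:
        return self._df["gc"].to_numpy(float)

    @property
    def length(self) -> np.ndarray:
        return self._df["length"].to_numpy(float)

    @property
    def chroms(self) -> np.ndarray:
        return self._df["chrom"].to_numpy()

    @property
    def genes(self) -> np.ndarray:
        return self._df["gene"].to_numpy()

    def chrx_mask(self) -> np.ndarray:
        return np.array([c.lower() in _CHRX_NAMES for c in self._df["chrom"]])

    def gene_ranges(self) -> dict[str, np.ndarray]:
        """Gene symbol -> array of amplicon ids (panel order)."""
        out: dict[str, np.ndarray] = {}
        for gene, grp in self._df.groupby("gene", sort=False):
            out[str(gene)] = grp.index.to_numpy()
        return out

    def chrom_groups(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (chrom, amplicon ids) in panel order."""
        for chrom, grp in self._df.groupby("chrom", sort=False):
            yield str(chrom), grp.index.to_numpy()

    def panel_hash(self) -> str:
        h = hashlib.sha1()
        for r in self._df.itertuples():
            h.update(f"{r.chrom}:{r.start}-{r.end}".encode())
        return h.hexdigest()[:16]

    def to_bed(self, path) -> None:
        out = self._df[["chrom", "start", "end", "gene", "gc"]]
        out.to_csv(path, sep="\t", header=False, index=False)


def parse_panel(
    bed_path,
    reference: Optional[str] = None,
    gc_column: Optional[int] = None,
) -> AmpliconPanel:
    """Parse a BED panel (>=4 columns: chrom, start, end, name).

    The gene symbol is the name field up to the first underscore
    ("ERBB2_ex20" -> "ERBB2").  GC fractions come either from column index
    ``gc_column`` of the BED or are computed from a FASTA ``reference``;
    one of the two must be given.
    """
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = re.split(r"\t", line)
            if len(fields) < 4:
                raise PanelError(f"line {lineno}: expected >=4 BED columns")
            chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise PanelError(f"line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise PanelError(f"line {lineno}: start >= end ({start} >= {end})")
            gc = np.nan
            if gc_column is not None:
                if gc_column >= len(fields):
                    raise PanelError(f"line {lineno}: no column {gc_column}")
                gc = float(fields[gc_column])
            rows.append((chrom, start, end, name.split("_")[0], gc))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "gc"])
    if gc_column is not None:
        if df["gc"].max() > 1.0:  # tolerate percent-scale GC columns
            df["gc"] = df["gc"] / 100.0
    elif reference is not None:
        import pysam

        with pysam.FastaFile(str(reference)) as fa:
            df["gc"] = [
                gc_fraction(fa.fetch(r.chrom, r.start, r.end)) for r in df.itertuples()
            ]
    else:
        raise PanelError("no GC provenance: give gc_column or a reference FASTA")
    return AmpliconPanel(df)


def merge_overlapping(panel: AmpliconPanel, min_frac: float = 0.75) -> AmpliconPanel:
    """Merge amplicons that reciprocally overlap by more than ``min_frac``.

    Two amplicons are merged when the overlap exceeds ``min_frac`` of *both*
    lengths; merging is applied transitively until a fixed point.  Gene
    labels are kept when identical, otherwise comma-joined.
    """
    recs = panel.df.to_dict("records")
    changed = True
    while changed:
        changed = False
        for i in range(len(recs) - 1):
            a = recs[i]
            for j in range(i + 1, len(recs)):
                b = recs[j]
                if b["chrom"] != a["chrom"] or b["start"] >= a["end"]:
                    break
                ov = min(a["end"], b["end"]) - max(a["start"], b["start"])
                la, lb = a["end"] - a["start"], b["end"] - b["start"]
                if ov > min_frac * la and ov > min_frac * lb:
                    genes = [a["gene"]] + [
                        g for g in str(b["gene"]).split(",") if g not in str(a["gene"]).split(",")
                    ]
                    merged = {
                        "chrom": a["chrom"],
                        "start": min(a["start"], b["start"]),
                        "end": max(a["end"], b["end"]),
                        "gene": ",".join(genes),
                        "gc": np.average(
                            [a["gc"], b["gc"]], weights=[la, lb]
                        ),
                    }
                    recs[i] = merged
                    del recs[j]
                    changed = True
                    break
            if changed:
                break
    return AmpliconPanel(pd.DataFrame(recs))


class _ChromIndex:
    """Per-chromosome arrays for fast maximum-overlap lookup."""

    def __init__(self, panel: AmpliconPanel):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, int]] = {}
        for chrom, ids in panel.chrom_groups():
            sub = panel.df.loc[ids]
            starts = sub["start"].to_numpy(int)
            ends = sub["end"].to_numpy(int)
            self.by_chrom[chrom] = (starts, ends, ids, int((ends - starts).max()))

    def best(self, chrom: str, start: int, end: int) -> Optional[int]:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        starts, ends, ids, maxlen = entry
        lo = np.searchsorted(starts, start - maxlen)
        hi = np.searchsorted(starts, end)
        if hi <= lo:
            return None
        ov = np.minimum(ends[lo:hi], end) - np.maximum(starts[lo:hi], start)
        k = int(np.argmax(ov))  # first max = smaller start, then smaller id
        if ov[k] <= 0:
            return None
        return int(ids[lo + k])


def assign_read(read: ReadAlignment, panel: AmpliconPanel,
                _index: Optional[_ChromIndex] = None) -> Optional[int]:
    """Amplicon id with maximum overlap with the read, or None.

    Ties go to the amplicon with the smaller start (then smaller id).
    """
    idx = _index if _index is not None else _ChromIndex(panel)
    return idx.best(read.chrom, read.start, read.end)


def count_reads(
    alignments: Iterable[ReadAlignment], panel: AmpliconPanel
) -> tuple[np.ndarray, int]:
    """Count reads per amplicon for one sample.

    Returns (counts, n_reads) where n_reads is the total number of reads in
    the stream (assignable or not).  Duplicate-flagged reads are counted —
    at amplicon-sequencing depth nearly all reads are duplicates.
    """
    idx = _ChromIndex(panel)
    counts = np.zeros(len(panel), dtype=np.int64)
    n = 0
    for read in alignments:
        n += 1
        a = idx.best(read.chrom, read.start, read.end)
        if a is not None:
            counts[a] += 1
    if n == 0:
        warnings.warn("empty alignment stream: all-zero count column")
    return counts, n


def count_reads_sam(path, panel: AmpliconPanel) -> tuple[np.ndarray, int]:
    """Count primary mapped reads per amplicon from a SAM/BAM file."""
    import pysam

    def reads():
        with pysam.AlignmentFile(str(path)) as sam:
            for rec in sam:
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                yield ReadAlignment(
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end or rec.reference_start + 1,
                    rec.is_duplicate,
                )

    return count_reads(reads(), panel)


@dataclass
class CountMatrix:
    """Raw read counts (amplicons x samples) plus per-sample totals."""

    panel: AmpliconPanel
    counts: pd.DataFrame  # index: amplicon id, columns: sample names, int
    total_reads: dict[str, int]

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read counts")
        for s in self.counts.columns:
            self.total_reads.setdefault(s, int(self.counts[s].sum()))

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def column(self, sample: str) -> np.ndarray:
        return self.counts[sample].to_numpy(np.int64)

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.samples:
                fh.write(f"#total_reads\t{s}\t{self.total_reads[s]}\n")
            out = pd.concat([self.panel.df, self.counts], axis=1)
            out.to_csv(fh, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "CountMatrix":
        totals: dict[str, int] = {}
        with open(path) as fh:
            lines = fh.readlines()
        body = 0
        for line in lines:
            if line.startswith("#total_reads"):
                _, s, n = line.rstrip("\n").split("\t")
                totals[s] = int(n)
                body += 1
            else:
                break
        from io import StringIO

        df = pd.read_csv(StringIO("".join(lines[body:])), sep="\t")
        panel = AmpliconPanel(df[["chrom", "start", "end", "gene", "gc"]])
        samples = [c for c in df.columns if c not in PANEL_COLUMNS]
        counts = df[samples].astype(np.int64)
        counts.index = pd.RangeIndex(len(counts))
        return cls(panel, counts, totals)
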