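"""Genome coordinate model and readers/writers for the formats the pipeline touches.

All coordinates are 0-based half-open internally.  GFF3 (1-based closed) is
converted on read.  Chromosome order is fixed by the order of the chromosome
table; bin ids are global and consecutive in (chrom, start) order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ChromTable",
    "BinTable",
    "read_chrom_sizes",
    "make_bins",
    "read_intervals",
    "write_bed",
    "assign_to_bins",
]


@dataclass(frozen=True)
class ChromTable:
    """Ordered chromosome name -> length (bp) table."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]

    def __post_init__(self):
        if len(self.names) == 0:
            raise ValueError("chromosome table is empty")
        if len(self.names) != len(set(self.names)):
            raise ValueError("chromosome names are not unique")
        if any(l < 1 for l in self.lengths):
            raise ValueError("chromosome lengths must be >= 1")
        if len(self.names) != len(self.lengths):
            raise ValueError("names and lengths differ in length")

    @classmethod
    def from_dict(cls, d: dict[str, int]) -> "ChromTable":
        return cls(tuple(d.keys()), tuple(int(v) for v in d.values()))

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def length(self, name: str) -> int:
        try:
            return self.lengths[self.names.index(name)]
        except ValueError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def items(self):
        return zip(self.names, self.lengths)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.names, "length": self.lengths})

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", header=False, index=False)


def read_chrom_sizes(path) -> ChromTable:
    """Read a two-column (name, length) chromosome-sizes TSV."""
    df = pd.read_csv(
        path, sep="\t", header=None, usecols=[0, 1], names=["chrom", "length"],
        dtype={"chrom": str}, comment="#",
    )
    return ChromTable(tuple(df["chrom"]), tuple(int(x) for x in df["length"]))


@dataclass(frozen=True)
class BinTable:
    """Non-overlapping genomic bins tiling every chromosome.

    The last bin of a chromosome may be shorter than ``bin_size``.  ``frame``
    holds columns chrom/start/end indexed by the global bin id.
    """

    chroms: ChromTable
    bin_size: int
    frame: pd.DataFrame = field(repr=False)
    # global bin-id offset of the first bin of each chromosome
    offsets: dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_bins(self) -> int:
        return len(self.frame)

    def chrom_range(self, name: str) -> tuple[int, int]:
        """(lo, hi) global bin-id slice bounds for one chromosome."""
        lo = self.offsets[name]
        n = -(-self.chroms.length(name) // self.bin_size)
        return lo, lo + n

    def chrom_of(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    def bin_id(self, chrom: str, pos) -> np.ndarray:
        """Global bin id(s) of positions on one chromosome."""
        pos = np.asarray(pos)
        length = self.chroms.length(chrom)
        if np.any((pos < 0) | (pos >= length)):
            raise ValueError(f"position outside {chrom} (length {length})")
        return self.offsets[chrom] + pos // self.bin_size

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def make_bins(chroms: ChromTable, bin_size: int) -> BinTable:
    """Tile each chromosome with non-overlapping ``bin_size`` bins.

    Total bin count is sum(ceil(length / bin_size)); the remainder bin at a
    chromosome end is kept short rather than extended past the chromosome.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    records, offsets, off = [], {}, 0
    for name, length in chroms.items():
        starts = np.arange(0, length, bin_size, dtype=np.int64)
        ends = np.minimum(starts + bin_size, length)
        records.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        offsets[name] = off
        off += len(starts)
    frame = pd.concat(records, ignore_index=True)
    return BinTable(chroms=chroms, bin_size=int(bin_size), frame=frame, offsets=offsets)


_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_intervals(path, format: str = "BED", chroms: ChromTable | None = None,
                   feature_type: str | None = None) -> pd.DataFrame:
    """Read BED3/BED6 or GFF3 into a chrom/start/end/name/strand frame.

    GFF3 records are converted from 1-based closed to 0-based half-open, and
    optionally restricted to one ``feature_type`` (e.g. "gene"); the name is
    taken from the ID= attribute when present.  Malformed lines raise with
    the offending line number; intervals on chromosomes absent from
    ``chroms`` (when given) raise as well.
    """
    fmt = format.upper()
    if fmt == "BED":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
        except pd.errors.EmptyDataError:
            df = pd.DataFrame()
        if df.empty:
            logger.warning("empty interval file: %s", path)
            return pd.DataFrame(columns=["chrom", "start", "end", "name", "strand"])
        if df.shape[1] < 3:
            raise ValueError(f"{path}: BED needs at least 3 columns")
        df.columns = _BED_COLS[: df.shape[1]] + list(df.columns[6:])
        for col in ("name", "score", "strand"):
            if col not in df.columns:
                df[col] = None
        out = df[["chrom", "start", "end", "name", "strand"]].copy()
    elif fmt == "GFF3":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#",
                             names=["chrom", "source", "type", "start", "end",
                                    "score", "strand", "phase", "attributes"],
                             dtype={"chrom": str})
        except pd.errors.EmptyDataError:
            df = pd.DataFrame()
        if df.empty:
            logger.warning("empty interval file: %s", path)
            return pd.DataFrame(columns=["chrom", "start", "end", "name", "strand"])
        if feature_type is not None:
            df = df[df["type"] == feature_type].reset_index(drop=True)
        name = df["attributes"].str.extract(r"ID=([^;]+)", expand=False)
        out = pd.DataFrame({
            "chrom": df["chrom"],
            "start": pd.to_numeric(df["start"], errors="coerce") - 1,
            "end": pd.to_numeric(df["end"], errors="coerce"),
            "name": name,
            "strand": df["strand"].where(df["strand"].isin(["+", "-"]), None),
        })
    else:
        raise ValueError(f"unknown interval format {format!r}")

    start = pd.to_numeric(out["start"], errors="coerce")
    end = pd.to_numeric(out["end"], errors="coerce")
    bad = start.isna() | end.isna() | (start < 0) | (start >= end)
    if bad.any():
        # report 1-based data-line number of the first offender
        lineno = int(np.flatnonzero(bad.to_numpy())[0]) + 1
        raise ValueError(f"malformed interval at data line {lineno} of {path}")
    out["start"] = start.astype(np.int64)
    out["end"] = end.astype(np.int64)
    if chroms is not None:
        unknown = set(out["chrom"]) - set(chroms.names)
        if unknown:
            raise ValueError(f"unknown chromosome(s) in {path}: {sorted(unknown)}")
        over = out["end"] > out["chrom"].map(dict(chroms.items()))
        if over.any():
            lineno = int(np.flatnonzero(over.to_numpy())[0]) + 1
            raise ValueError(f"interval past chromosome end at data line {lineno}")
    return out.reset_index(drop=True)


def write_bed(df: pd.DataFrame, path, cols: list[str] | None = None) -> None:
    """Write chrom/start/end(+extra) columns as a headerless BED."""
    cols = cols or [c for c in ["chrom", "start", "end", "name", "score", "strand"]
                    if c in df.columns]
    df[cols].to_csv(path, sep="\t", header=False, index=False)


def assign_to_bins(intervals: pd.DataFrame, bins: BinTable,
                   rule: str = "majority") -> np.ndarray:
    """Map each interval to exactly one global bin id.

    rule="midpoint": the bin containing the interval midpoint (integer
    division).  rule="majority": the bin with maximal bp overlap, leftmost on
    ties.  Total and deterministic for valid input.
    """
    if rule not in ("midpoint", "majority"):
        raise ValueError(f"unknown assignment rule {rule!r}")
    out = np.empty(len(intervals), dtype=np.int64)
    bs = bins.bin_size
    for k, (chrom, start, end) in enumerate(
            zip(intervals["chrom"], intervals["start"], intervals["end"])):
        if chrom not in bins.offsets:
            raise ValueError(f"interval on unknown chromosome {chrom!r}")
        if rule == "midpoint":
            mid = (int(start) + int(end)) // 2
            out[k] = bins.bin_id(chrom, mid)
        else:
            first = int(start) // bs
            last = (int(end) - 1) // bs
            best_bin, best_ov = first, -1
            for b in range(first, last + 1):
                ov = min(int(end), (b + 1) * bs) - max(int(start), b * bs)
                if ov > best_ov:  # strict: leftmost wins ties
                    best_bin, best_ov = b, ov
            out[k] = bins.offsets[chrom] + best_bin
    return out
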