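"""Shared genomic coordinate model: genomes, bin tables, interval sets,
per-bin tracks, categorical bin labels, and BED/bedGraph/BEDPE I/O.

All coordinates are 0-based, half-open (BED convention). Bins tile each
chromosome in the genome's declared order; the last bin of a chromosome may
be shorter than the nominal bin size and is treated like any other bin.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GenomeSpec",
    "BinTable",
    "IntervalSet",
    "ProfileTrack",
    "AnnotationLabels",
    "make_bins",
    "intersect_bins",
    "label_bins",
    "read_bed",
    "write_bed",
    "read_bedgraph",
    "write_bedgraph",
    "read_bedpe",
    "write_bedpe",
    "read_chromsizes",
]


class FileFormatError(ValueError):
    """Malformed genomic text file; message carries the offending line number."""


@dataclasses.dataclass(frozen=True)
class GenomeSpec:
    """An ordered set of chromosomes with lengths in base pairs.

    The declared order is the canonical matrix order used by every
    genome-wide structure (bin tables, contact matrices, trans O/E tables).
    Arbitrary orders and names are accepted verbatim.
    """

    names: tuple
    lengths: tuple

    def __init__(self, names: Sequence[str], lengths: Sequence[int]):
        names = tuple(str(n) for n in names)
        lengths = tuple(int(x) for x in lengths)
        if len(names) != len(lengths):
            raise ValueError("names and lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(x <= 0 for x in lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "lengths", lengths)

    def __len__(self) -> int:
        return len(self.names)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.names.index(chrom)]
        except ValueError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    @property
    def total_length(self) -> int:
        return sum(self.lengths)


def read_chromsizes(path) -> GenomeSpec:
    """Read a two-column chromosome-sizes file (name, length)."""
    names, lengths = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise FileFormatError(f"{path}:{lineno}: expected 2 columns")
            try:
                names.append(parts[0])
                lengths.append(int(parts[1]))
            except ValueError:
                raise FileFormatError(f"{path}:{lineno}: bad length {parts[1]!r}")
    return GenomeSpec(names, lengths)


class BinTable:
    """Regular tiling of a genome into fixed-size bins.

    Bins are globally indexed, dense and strictly increasing, contiguous
    across chromosomes in genome order.
    """

    def __init__(self, genome: GenomeSpec, bin_size: int):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.genome = genome
        self.bin_size = int(bin_size)
        chroms, starts, ends = [], [], []
        offsets = {}
        n = 0
        for name, length in zip(genome.names, genome.lengths):
            offsets[name] = n
            nb = -(-length // bin_size)  # ceil
            s = np.arange(nb, dtype=np.int64) * bin_size
            e = np.minimum(s + bin_size, length)
            chroms.extend([name] * nb)
            starts.append(s)
            ends.append(e)
            n += nb
        self._chroms = np.array(chroms, dtype=object)
        self._starts = np.concatenate(starts)
        self._ends = np.concatenate(ends)
        self._offsets = offsets
        self.n_bins = n

    def __len__(self) -> int:
        return self.n_bins

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, BinTable)
            and self.bin_size == other.bin_size
            and self.genome == other.genome
        )

    @property
    def chroms(self) -> np.ndarray:
        return self._chroms

    @property
    def starts(self) -> np.ndarray:
        return self._starts

    @property
    def ends(self) -> np.ndarray:
        return self._ends

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chrom": self._chroms, "start": self._starts, "end": self._ends}
        )

    def chrom_slice(self, chrom: str) -> slice:
        """Global-index slice covering one chromosome."""
        off = self._offsets[chrom]
        nb = -(-self.genome.length_of(chrom) // self.bin_size)
        return slice(off, off + nb)

    def n_bins_of(self, chrom: str) -> int:
        s = self.chrom_slice(chrom)
        return s.stop - s.start

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing base-pair ``pos``."""
        if not 0 <= pos < self.genome.length_of(chrom):
            raise ValueError(f"position {pos} outside {chrom}")
        return self._offsets[chrom] + pos // self.bin_size

    def bin_interval_frame(self) -> pd.DataFrame:
        df = self.to_frame()
        df["index"] = np.arange(self.n_bins)
        return df


def make_bins(genome: GenomeSpec, bin_size: int) -> BinTable:
    """Tile ``genome`` into half-open bins of ``bin_size`` bp."""
    return BinTable(genome, bin_size)


class IntervalSet:
    """A set of genomic intervals (chrom, start, end[, name]), half-open.

    Backed by a DataFrame; ``name`` holds an optional per-interval label.
    """

    COLUMNS = ["chrom", "start", "end", "name"]

    def __init__(self, df: pd.DataFrame, genome: GenomeSpec | None = None):
        df = df.copy()
        if "name" not in df.columns:
            df["name"] = "."
        df = df[["chrom", "start", "end", "name"]]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise ValueError(f"interval {bad}: start >= end")
        if genome is not None:
            for chrom, grp in df.groupby("chrom", sort=False):
                L = genome.length_of(str(chrom))  # KeyError if absent
                if (grp["end"] > L).any():
                    raise ValueError(f"interval beyond end of {chrom}")
        self.df = df.reset_index(drop=True)
        self.genome = genome

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.df.equals(other.df)

    @classmethod
    def from_records(cls, records: Iterable[tuple], genome: GenomeSpec | None = None):
        rows = list(records)
        df = pd.DataFrame(
            [r[:4] if len(r) >= 4 else (*r, ".") for r in rows],
            columns=cls.COLUMNS,
        )
        return cls(df, genome)

    def trees(self) -> dict:
        """Per-chromosome interval trees (data = row index)."""
        out: dict[str, IntervalTree] = {}
        for chrom, grp in self.df.groupby("chrom", sort=False):
            out[str(chrom)] = IntervalTree.from_tuples(
                zip(grp["start"], grp["end"], grp.index)
            )
        return out


def intersect_bins(items: IntervalSet, regions: IntervalSet) -> IntervalSet:
    """Subset of ``items`` overlapping >=1 bp of any region (half-open test)."""
    if items.genome is not None and regions.genome is not None:
        for chrom in regions.df["chrom"].unique():
            items.genome.length_of(str(chrom))  # raises on unknown chromosome
    trees = regions.trees()
    keep = []
    for idx, row in items.df.iterrows():
        tree = trees.get(row["chrom"])
        if tree is not None and tree.overlap(row["start"], row["end"]):
            keep.append(idx)
    return IntervalSet(items.df.loc[keep], items.genome)


UNLABELED = "unlabeled"


class AnnotationLabels:
    """One categorical label per bin from a closed vocabulary.

    ``unlabeled`` marks uncovered bins and majority ties.
    """

    def __init__(self, bins: BinTable, labels: Sequence[str], vocabulary: Sequence[str]):
        labels = np.asarray(labels, dtype=object)
        if len(labels) != len(bins):
            raise ValueError("one label per bin required")
        vocab = set(vocabulary)
        bad = set(labels) - vocab - {UNLABELED}
        if bad:
            raise ValueError(f"labels outside vocabulary: {sorted(bad)}")
        self.bins = bins
        self.labels = labels
        self.vocabulary = tuple(vocabulary)

    def __len__(self) -> int:
        return len(self.labels)

    def mask_of(self, label: str) -> np.ndarray:
        return self.labels == label

    def counts(self) -> pd.Series:
        return pd.Series(self.labels).value_counts()


def label_bins(
    bins: BinTable,
    annotation: IntervalSet,
    vocabulary: Sequence[str],
    rule: str = "majority",
) -> AnnotationLabels:
    """Assign each bin a label from overlapping annotation intervals.

    rule="majority": label with the largest overlapping bp count wins; exact
    ties and uncovered bins are "unlabeled". rule="any": any overlap assigns;
    conflicting labels on one bin raise.
    """
    if rule not in ("majority", "any"):
        raise ValueError(f"unknown rule {rule!r}")
    vocab = set(vocabulary)
    bad = set(annotation.df["name"]) - vocab
    if bad:
        raise ValueError(f"annotation labels outside vocabulary: {sorted(bad)}")
    labels = np.full(len(bins), UNLABELED, dtype=object)
    trees = annotation.trees()
    ann = annotation.df
    for i in range(len(bins)):
        tree = trees.get(bins.chroms[i])
        if tree is None:
            continue
        hits = tree.overlap(bins.starts[i], bins.ends[i])
        if not hits:
            continue
        cover: dict[str, int] = {}
        for iv in hits:
            lab = ann.at[iv.data, "name"]
            bp = min(iv.end, bins.ends[i]) - max(iv.begin, bins.starts[i])
            cover[lab] = cover.get(lab, 0) + bp
        if rule == "any":
            if len(cover) > 1:
                raise ValueError(
                    f"bin {i} overlaps conflicting labels {sorted(cover)} under rule='any'"
                )
            labels[i] = next(iter(cover))
        else:
            best = max(cover.values())
            winners = sorted(k for k, v in cover.items() if v == best)
            labels[i] = winners[0] if len(winners) == 1 else UNLABELED
    return AnnotationLabels(bins, labels, vocabulary)


class ProfileTrack:
    """Per-bin numeric signal aligned to a BinTable; NaN marks missing bins."""

    def __init__(self, bins: BinTable, values: Sequence[float]):
        values = np.asarray(values, dtype=float)
        if len(values) != len(bins):
            raise ValueError("track length must equal number of bins")
        self.bins = bins
        self.values = values

    def __len__(self) -> int:
        return len(self.values)

    def copy(self) -> "ProfileTrack":
        return ProfileTrack(self.bins, self.values.copy())

    @property
    def missing(self) -> np.ndarray:
        return np.isnan(self.values)

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.bins.chrom_slice(chrom)]


# ---------------------------------------------------------------------------
# Text-format I/O. Readers tolerate comment/track/browser header lines and
# report malformed rows with their line number.
# ---------------------------------------------------------------------------


def _data_lines(path):
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            yield lineno, line.split()


def read_bed(path, genome: GenomeSpec | None = None) -> IntervalSet:
    rows = []
    for lineno, parts in _data_lines(path):
        if len(parts) < 3:
            raise FileFormatError(f"{path}:{lineno}: BED needs >=3 columns")
        try:
            rows.append(
                (parts[0], int(parts[1]), int(parts[2]), parts[3] if len(parts) > 3 else ".")
            )
        except ValueError:
            raise FileFormatError(f"{path}:{lineno}: non-integer coordinate")
    return IntervalSet(pd.DataFrame(rows, columns=IntervalSet.COLUMNS), genome)


def write_bed(intervals: IntervalSet, path, score: Sequence | None = None) -> None:
    df = intervals.df
    with open(path, "w") as fh:
        for i, row in df.iterrows():
            cols = [row["chrom"], row["start"], row["end"], row["name"]]
            if score is not None:
                cols.append(score[i])
            fh.write("\t".join(str(c) for c in cols) + "\n")


def write_bedgraph(track: ProfileTrack, path) -> None:
    """Write a per-bin track; missing (NaN) bins are simply absent."""
    b = track.bins
    with open(path, "w") as fh:
        for i, v in enumerate(track.values):
            if np.isnan(v):
                continue
            fh.write(f"{b.chroms[i]}\t{b.starts[i]}\t{b.ends[i]}\t{v:.10g}\n")


def read_bedgraph(path, bins: BinTable) -> ProfileTrack:
    """Read a bedGraph onto ``bins``; absent bins come back as NaN.

    Each record must coincide with exactly one bin of the table.
    """
    values = np.full(len(bins), np.nan)
    for lineno, parts in _data_lines(path):
        if len(parts) < 4:
            raise FileFormatError(f"{path}:{lineno}: bedGraph needs 4 columns")
        chrom, start, end, val = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
        try:
            idx = bins.bin_index(chrom, start)
        except (KeyError, ValueError):
            raise FileFormatError(f"{path}:{lineno}: interval not on bin grid")
        if bins.starts[idx] != start or bins.ends[idx] != end:
            raise FileFormatError(f"{path}:{lineno}: interval not aligned to a bin")
        values[idx] = val
    return ProfileTrack(bins, values)


def read_bedpe(path, genome: GenomeSpec | None = None) -> pd.DataFrame:
    """Read anchor pairs; anchors are normalized so anchor1 <= anchor2.

    Returns columns chrom1,start1,end1,chrom2,start2,end2,name plus any
    extra columns verbatim (as strings).
    """
    rows = []
    extra_max = 0
    for lineno, parts in _data_lines(path):
        if len(parts) < 6:
            raise FileFormatError(f"{path}:{lineno}: BEDPE needs >=6 columns")
        try:
            c1, s1, e1 = parts[0], int(parts[1]), int(parts[2])
            c2, s2, e2 = parts[3], int(parts[4]), int(parts[5])
        except ValueError:
            raise FileFormatError(f"{path}:{lineno}: non-integer coordinate")
        if (c1, s1, e1) > (c2, s2, e2):
            (c1, s1, e1), (c2, s2, e2) = (c2, s2, e2), (c1, s1, e1)
        name = parts[6] if len(parts) > 6 else "."
        extras = parts[7:]
        extra_max = max(extra_max, len(extras))
        rows.append([c1, s1, e1, c2, s2, e2, name, extras])
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2", "name"]
    df = pd.DataFrame([r[:7] for r in rows], columns=cols)
    for k in range(extra_max):
        df[f"extra{k + 1}"] = [r[7][k] if k < len(r[7]) else "." for r in rows]
    if genome is not None:
        for c in pd.concat([df["chrom1"], df["chrom2"]]).unique():
            genome.length_of(str(c))
    return df


def write_bedpe(df: pd.DataFrame, path) -> None:
    cols = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"]
    rest = [c for c in df.columns if c not in cols]
    with open(path, "w") as fh:
        for _, row in df.iterrows():
            fields = [str(row[c]) for c in cols] + [str(row[c]) for c in rest]
            fh.write("\t".join(fields) + "\n")
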