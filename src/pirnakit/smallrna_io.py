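"""Readers and writers for small-RNA sequence data and feature annotations.

Small-RNA libraries are handled as *collapsed* read sets: every distinct
sequence appears once, carrying the number of times it was cloned.  Reference
panels (transposon consensus sequences, piRNA cluster sequences, miRNA
hairpin-derived mature sequences) are handled as :class:`ReferenceSet`
objects with an explicit feature class per sequence and optional sub-feature
intervals loaded from BED.

Conventions used throughout the package:

* U is normalized to T on input, so all sequences are DNA-alphabet.
* Coordinates are 0-based, half-open.
* BED strand (column 6) is authoritative for fragment orientation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: hard length bounds for small-RNA reads kept by default
DEFAULT_LENGTH_WINDOW = (18, 35)

FEATURE_CLASSES = ("TE", "cluster", "miRNA", "other")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and convert U to T."""
    return seq.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# ReadSet
# ---------------------------------------------------------------------------


class ReadSet:
    """Collapsed unique small-RNA sequences with clone counts.

    Backed by a DataFrame with columns ``read_id``, ``sequence``, ``count``.
    Sequences are unique within a set and counts are positive integers.
    """

    COLUMNS = ["read_id", "sequence", "count"]

    def __init__(self, df: pd.DataFrame):
        if list(df.columns) != self.COLUMNS:
            df = df.loc[:, self.COLUMNS]
        if df["sequence"].duplicated().any():
            raise ValueError("ReadSet sequences must be unique after collapsing")
        if len(df) and (df["count"] < 1).any():
            raise ValueError("ReadSet counts must be >= 1")
        self.df = df.reset_index(drop=True)

    # -- constructors --------------------------------------------------

    @classmethod
    def empty(cls) -> "ReadSet":
        return cls(pd.DataFrame({c: [] for c in cls.COLUMNS}).astype(
            {"read_id": str, "sequence": str, "count": int}))

    @classmethod
    def from_counts(cls, counts: Mapping[str, int] | Iterable[tuple[str, int]]) -> "ReadSet":
        """Build a collapsed set from (sequence, count) pairs, summing duplicates."""
        if isinstance(counts, Mapping):
            counts = counts.items()
        agg: dict[str, int] = {}
        for seq, n in counts:
            seq = normalize_sequence(seq)
            agg[seq] = agg.get(seq, 0) + int(n)
        return cls._from_dict(agg)

    @classmethod
    def from_sequences(cls, seqs: Iterable[str]) -> "ReadSet":
        """Collapse an iterable of raw read sequences (each counted once)."""
        agg: dict[str, int] = {}
        for seq in seqs:
            seq = normalize_sequence(seq)
            agg[seq] = agg.get(seq, 0) + 1
        return cls._from_dict(agg)

    @classmethod
    def _from_dict(cls, agg: dict[str, int]) -> "ReadSet":
        if not agg:
            return cls.empty()
        # deterministic id assignment: most abundant first, ties by sequence
        items = sorted(agg.items(), key=lambda kv: (-kv[1], kv[0]))
        df = pd.DataFrame(
            {
                "read_id": [f"r{i + 1:06d}" for i in range(len(items))],
                "sequence": [s for s, _ in items],
                "count": [n for _, n in items],
            }
        )
        return cls(df)

    # -- basic queries -------------------------------------------------

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_count(self) -> int:
        return int(self.df["count"].sum())

    def scaled(self, k: int) -> "ReadSet":
        """Return a copy with every count multiplied by integer ``k``."""
        df = self.df.copy()
        df["count"] = df["count"] * int(k)
        return ReadSet(df)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReadSet):
            return NotImplemented
        a = self.df.sort_values("sequence").reset_index(drop=True)
        b = other.df.sort_values("sequence").reset_index(drop=True)
        return a[["sequence", "count"]].equals(b[["sequence", "count"]])

    # -- serialization -------------------------------------------------

    def write_fasta(self, path, expand: bool = False) -> None:
        """Write reads as FASTA.

        With ``expand=False`` each unique sequence is one record whose header
        carries the count (``>read_id_xN``); with ``expand=True`` every clone
        is written as its own record.
        """
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                if expand:
                    for i in range(row.count):
                        fh.write(f">{row.read_id}.{i + 1}\n{row.sequence}\n")
                else:
                    fh.write(f">{row.read_id}_x{row.count}\n{row.sequence}\n")

    def write_fastq(self, path) -> None:
        """Write every clone as a FASTQ record with constant quality 'I'."""
        with open(path, "w") as fh:
            for row in self.df.itertuples(index=False):
                q = "I" * len(row.sequence)
                for i in range(row.count):
                    fh.write(f"@{row.read_id}.{i + 1}\n{row.sequence}\n+\n{q}\n")


def _header_count(record_id: str) -> int:
    """Parse a trailing ``_xN`` collapsed-count suffix; default 1."""
    if "_x" in record_id:
        tail = record_id.rsplit("_x", 1)[1]
        if tail.isdigit():
            return int(tail)
    return 1


def read_sequences(path, format: str = "fastq",
                   length_window: tuple[int, int] = DEFAULT_LENGTH_WINDOW) -> ReadSet:
    """Load adapter-trimmed reads, collapse identical sequences, length-filter.

    Parameters
    ----------
    path
        FASTA or FASTQ file.
    format
        ``"fasta"`` or ``"fastq"``.
    length_window
        Inclusive [min, max] read length kept; reads outside are dropped and
        the drop count is logged.  FASTA headers ending in ``_xN`` are taken
        as pre-collapsed counts.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format: {format!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lo, hi = length_window
    agg: dict[str, int] = {}
    dropped = 0
    bad_alpha = 0
    n_records = 0
    try:
        with open(path) as handle:
            for n_records, rec in enumerate(SeqIO.parse(handle, format), start=1):
                seq = normalize_sequence(str(rec.seq))
                count = _header_count(rec.id) if format == "fasta" else 1
                if not (lo <= len(seq) <= hi):
                    dropped += count
                    continue
                if set(seq) - set("ACGT"):
                    bad_alpha += count
                    continue
                agg[seq] = agg.get(seq, 0) + count
    except ValueError as exc:
        raise ValueError(
            f"malformed {format} record near record {n_records + 1} in {path}: {exc}"
        ) from exc
    if n_records == 0:
        warnings.warn(f"empty input file: {path}")
    if dropped:
        logger.info("dropped %d reads outside length window %s", dropped, length_window)
    if bad_alpha:
        logger.info("dropped %d reads with non-ACGT characters", bad_alpha)
    return ReadSet._from_dict(agg)


# ---------------------------------------------------------------------------
# ReferenceSet
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Feature:
    """A reference sequence with a class label (TE, cluster, miRNA, other)."""

    id: str
    feature_class: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """A BED-style sub-feature interval (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "+"


class ReferenceSet:
    """Panel of reference features plus optional sub-feature intervals."""

    def __init__(self, features: Iterable[Feature], intervals: Iterable[Interval] = ()):
        self._features: dict[str, Feature] = {}
        for feat in features:
            if feat.id in self._features:
                raise ValueError(f"duplicate feature id: {feat.id}")
            if feat.feature_class not in FEATURE_CLASSES:
                raise ValueError(f"unknown feature class: {feat.feature_class!r}")
            self._features[feat.id] = feat
        self.intervals = list(intervals)
        for iv in self.intervals:
            if iv.chrom not in self._features:
                raise ValueError(f"BED interval on unknown contig {iv.chrom!r}")
            L = self._features[iv.chrom].length
            if not (0 <= iv.start < iv.end <= L):
                raise ValueError(
                    f"BED interval {iv.chrom}:{iv.start}-{iv.end} outside contig of length {L}"
                )
        self._index_cache: dict = {}

    # -- queries -------------------------------------------------------

    def ids(self) -> list[str]:
        return list(self._features)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self._features

    def __len__(self) -> int:
        return len(self._features)

    def feature(self, feature_id: str) -> Feature:
        return self._features[feature_id]

    def sequence(self, feature_id: str) -> str:
        return self._features[feature_id].sequence

    def feature_class(self, feature_id: str) -> str:
        return self._features[feature_id].feature_class

    def length(self, feature_id: str) -> int:
        return self._features[feature_id].length

    def by_class(self, feature_class: str) -> list[str]:
        return [f.id for f in self._features.values() if f.feature_class == feature_class]

    @property
    def class_map(self) -> dict[str, str]:
        return {f.id: f.feature_class for f in self._features.values()}

    def __eq__(self, other) -> bool:
        if not isinstance(other, ReferenceSet):
            return NotImplemented
        mine = [(f.id, f.feature_class, f.sequence) for f in self._features.values()]
        theirs = [(f.id, f.feature_class, f.sequence) for f in other._features.values()]
        return sorted(mine) == sorted(theirs) and sorted(
            map(_iv_key, self.intervals)
        ) == sorted(map(_iv_key, other.intervals))

    # -- serialization -------------------------------------------------

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for feat in self._features.values():
                fh.write(f">{feat.id}\n{feat.sequence}\n")

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for iv in self.intervals:
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score:g}\t{iv.strand}\n"
                )

    def write_class_map(self, path) -> None:
        with open(path, "w") as fh:
            for feat in self._features.values():
                fh.write(f"{feat.id}\t{feat.feature_class}\n")


def _iv_key(iv: Interval):
    return (iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)


def read_class_map(path) -> dict[str, str]:
    """Read a 2-column TSV mapping feature id to class."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "feature_class"],
                     dtype=str, comment="#")
    return dict(zip(df["id"], df["feature_class"]))


def _read_bed(path) -> list[Interval]:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str, "strand": str},
    )
    if df[["chrom", "start", "end"]].isna().any().any():
        raise ValueError(f"malformed BED file: {path}")
    return [
        Interval(r.chrom, int(r.start), int(r.end),
                 "." if pd.isna(r.name) else str(r.name),
                 0.0 if pd.isna(r.score) else float(r.score),
                 "+" if pd.isna(r.strand) else str(r.strand))
        for r in df.itertuples(index=False)
    ]


def load_annotations(fasta_path, bed_path=None,
                     class_map: Mapping[str, str] | str | Path | None = None) -> ReferenceSet:
    """Load a reference panel from FASTA (+ optional BED sub-features).

    ``class_map`` assigns a feature class per FASTA contig, either as a
    mapping or a path to a 2-column TSV.  Contigs without an assignment fall
    back to class ``"other"`` with a warning.
    """
    if class_map is None:
        cmap: Mapping[str, str] = {}
    elif isinstance(class_map, (str, Path)):
        cmap = read_class_map(class_map)
    else:
        cmap = class_map
    features = []
    unclassed = []
    with open(fasta_path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            cls = cmap.get(rec.id)
            if cls is None:
                cls = "other"
                unclassed.append(rec.id)
            features.append(Feature(rec.id, cls, normalize_sequence(str(rec.seq))))
    if unclassed:
        warnings.warn(f"{len(unclassed)} features without class assignment set to 'other'")
    intervals = _read_bed(bed_path) if bed_path is not None else []
    return ReferenceSet(features, intervals)
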