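"""Exact, strand-aware placement of collapsed reads on reference features.

Matching is exact (0 mismatches) against consensus-scale references, which
keeps the mapper equivalent to a brute-force all-substrings scan.  Reads may
hit several features and several positions; a read's count is split evenly
over all retained hits (``weight = count / n_hits``) and a hit is flagged
``unique`` when the read has exactly one placement anywhere in the panel.

Strand convention: ``five_prime`` is always the feature coordinate of the
read's biological 5' nucleotide.  For a minus-strand hit that is the *right*
end of the matched span — the convention the ping-pong 5'–5' overlap
arithmetic relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .smallrna_io import ReadSet, ReferenceSet, revcomp

logger = logging.getLogger(__name__)

DEFAULT_MAX_HITS = 100

ALIGNMENT_COLUMNS = [
    "read_id", "sequence", "feature_id", "strand",
    "five_prime", "length", "count", "weight", "unique",
]


@dataclass
class AlignmentTable:
    """Weighted read placements plus the reads that produced none.

    ``df`` has one row per hit with columns :data:`ALIGNMENT_COLUMNS`.
    ``unmapped`` and ``discarded`` record reads with zero hits and reads
    dropped for exceeding ``max_hits``, respectively.
    """

    df: pd.DataFrame
    unmapped: pd.DataFrame = field(default_factory=pd.DataFrame)
    discarded: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.df)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlignmentTable":
        return cls(pd.read_csv(path, sep="\t"))


def _substring_index(ref: ReferenceSet, lengths: frozenset[int]) -> dict:
    """Map every reference substring of the given lengths to its placements.

    Each entry maps a sequence to a list of ``(feature_id, strand,
    five_prime)`` tuples.  The index is cached on the ReferenceSet, so
    repeated mapping against the same panel (control/knockdown pairs) pays
    the construction cost once.
    """
    key = ("substring_index", lengths)
    cached = ref._index_cache.get(key)
    if cached is not None:
        return cached
    index: dict[str, list[tuple[str, str, int]]] = {}
    for fid in ref.ids():
        seq = ref.sequence(fid)
        L = len(seq)
        rc = revcomp(seq)
        for l in lengths:
            if l > L:
                continue
            for start in range(L - l + 1):
                sub = seq[start:start + l]
                index.setdefault(sub, []).append((fid, "+", start))
            for rp in range(L - l + 1):
                sub = rc[rp:rp + l]
                # a read equal to rc[rp:rp+l] matches antisense with its 5'
                # nucleotide at feature coordinate L-1-rp
                index.setdefault(sub, []).append((fid, "-", L - 1 - rp))
    ref._index_cache[key] = index
    return index


def map_reads(reads: ReadSet, ref: ReferenceSet,
              max_hits: int = DEFAULT_MAX_HITS) -> AlignmentTable:
    """Report every exact occurrence of every read on both strands.

    Reads with zero hits are returned in ``unmapped``; reads with more than
    ``max_hits`` placements are dropped (and logged) as ``discarded``.
    """
    if len(reads) == 0:
        empty = pd.DataFrame({c: [] for c in ALIGNMENT_COLUMNS})
        return AlignmentTable(empty, reads.df.copy(), reads.df.iloc[0:0].copy())
    lengths = frozenset(int(l) for l in reads.df["sequence"].str.len().unique())
    index = _substring_index(ref, lengths)

    rows = []
    unmapped_idx = []
    discarded_idx = []
    for i, row in enumerate(reads.df.itertuples(index=False)):
        hits = index.get(row.sequence)
        if not hits:
            unmapped_idx.append(i)
            continue
        n_hits = len(hits)
        if n_hits > max_hits:
            discarded_idx.append(i)
            continue
        w = row.count / n_hits
        uniq = n_hits == 1
        for fid, strand, fp in hits:
            rows.append((row.read_id, row.sequence, fid, strand, fp,
                         len(row.sequence), row.count, w, uniq))
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    unmapped = reads.df.iloc[unmapped_idx].reset_index(drop=True)
    discarded = reads.df.iloc[discarded_idx].reset_index(drop=True)
    if len(discarded):
        logger.info("discarded %d reads with more than %d hits", len(discarded), max_hits)
    return AlignmentTable(df, unmapped, discarded)


def map_reads_bruteforce(reads: ReadSet, ref: ReferenceSet,
                         max_hits: int = DEFAULT_MAX_HITS) -> AlignmentTable:
    """Reference implementation: scan every feature with ``str.find``.

    Independent of the indexed mapper; used as its oracle in tests.
    """
    rows = []
    unmapped_idx = []
    discarded_idx = []
    for i, row in enumerate(reads.df.itertuples(index=False)):
        hits = []
        l = len(row.sequence)
        rc_read = revcomp(row.sequence)
        for fid in ref.ids():
            seq = ref.sequence(fid)
            start = seq.find(row.sequence)
            while start != -1:
                hits.append((fid, "+", start))
                start = seq.find(row.sequence, start + 1)
            start = seq.find(rc_read)
            while start != -1:
                hits.append((fid, "-", start + l - 1))
                start = seq.find(rc_read, start + 1)
        if not hits:
            unmapped_idx.append(i)
            continue
        if len(hits) > max_hits:
            discarded_idx.append(i)
            continue
        w = row.count / len(hits)
        uniq = len(hits) == 1
        for fid, strand, fp in hits:
            rows.append((row.read_id, row.sequence, fid, strand, fp,
                         l, row.count, w, uniq))
    df = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    return AlignmentTable(df,
                          reads.df.iloc[unmapped_idx].reset_index(drop=True),
                          reads.df.iloc[discarded_idx].reset_index(drop=True))


def class_counts(alignments: AlignmentTable, ref: ReferenceSet
                 ) -> tuple[pd.Series, pd.DataFrame]:
    """Weighted read mass per feature class, and per length within classes.

    A read hitting features of several classes contributes to each class in
    proportion to its per-hit weights.  Returns ``(per_class, per_class_length)``
    where the second frame covers the non-miRNA classes.
    """
    df = alignments.df
    if len(df) == 0:
        per_class = pd.Series(0.0, index=list(dict.fromkeys(ref.class_map.values())))
        return per_class, pd.DataFrame(columns=["feature_class", "length", "weight"])
    classes = df["feature_id"].map(ref.class_map)
    work = df.assign(feature_class=classes)
    per_class = work.groupby("feature_class")["weight"].sum()
    non_mirna = work[work["feature_class"] != "miRNA"]
    per_len = (non_mirna.groupby(["feature_class", "length"])["weight"]
               .sum().reset_index())
    return per_class, per_len
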