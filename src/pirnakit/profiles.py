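"""Library normalization, coverage profiles, length histograms, RPKM.

Small-RNA libraries cannot be compared on raw depth because a piRNA-pathway
knockdown changes the piRNA share of the library itself.  miRNAs are
unaffected by the pathway, so all quantities are expressed in **RPMM** —
reads per million miRNA-mapped reads: ``factor = 1e6 / mirna_total`` and
every weighted count is multiplied by ``factor``.

Coverage profiles record 5'-end mass only (the quantity that enters the
ping-pong overlap statistic), signed by strand: sense positive, antisense
negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .mapping import AlignmentTable
from .smallrna_io import ReferenceSet

#: default piRNA length window (nt, inclusive)
PIRNA_WINDOW = (23, 30)


@dataclass
class NormalizedLibrary:
    """An alignment table with its miRNA-anchored normalization factor."""

    alignments: AlignmentTable
    ref: ReferenceSet
    mirna_total: float
    normalization_factor: float
    pirna_window: tuple[int, int] = PIRNA_WINDOW

    @property
    def df(self) -> pd.DataFrame:
        return self.alignments.df


def normalize_library(alignments: AlignmentTable, ref: ReferenceSet,
                      pirna_window: tuple[int, int] = PIRNA_WINDOW) -> NormalizedLibrary:
    """Anchor a library on its weighted miRNA-mapped read mass.

    Raises if no miRNA-mapped reads exist: without the invariant anchor no
    cross-library statement is meaningful (check that the reference panel
    contains miRNA-class features and that reads were not over-filtered).
    """
    df = alignments.df
    classes = df["feature_id"].map(ref.class_map) if len(df) else pd.Series(dtype=object)
    mirna_total = float(df.loc[classes == "miRNA", "weight"].sum()) if len(df) else 0.0
    if mirna_total <= 0:
        raise ValueError(
            "no miRNA-mapped reads: the normalization anchor is missing. "
            "Check that the reference panel includes miRNA-class features."
        )
    return NormalizedLibrary(alignments, ref, mirna_total, 1e6 / mirna_total,
                             tuple(pirna_window))


def _window_mask(df: pd.DataFrame, window: tuple[int, int]) -> pd.Series:
    return (df["length"] >= window[0]) & (df["length"] <= window[1])


def pirna_alignments(lib: NormalizedLibrary, classes: Iterable[str] | None = None,
                     orientation: str = "both") -> pd.DataFrame:
    """Alignment rows restricted to the piRNA window (and class/strand)."""
    df = lib.df
    mask = _window_mask(df, lib.pirna_window)
    if classes is not None:
        feat_cls = df["feature_id"].map(lib.ref.class_map)
        mask &= feat_cls.isin(list(classes))
    if orientation == "sense":
        mask &= df["strand"] == "+"
    elif orientation == "antisense":
        mask &= df["strand"] == "-"
    elif orientation != "both":
        raise ValueError(f"unknown orientation {orientation!r}")
    return df[mask]


def coverage_profile(lib: NormalizedLibrary, feature_id: str,
                     unique_only: bool = False) -> pd.DataFrame:
    """Signed per-position 5'-end profile of a feature, in RPMM.

    Returns a frame indexed by feature position with a non-negative
    ``sense`` column and a non-positive ``antisense`` column (the plotting
    convention: sense up, antisense down).  The two strands are kept
    separate so positions carrying mass on both strands are not cancelled.
    Only reads inside the piRNA length window contribute; ``unique_only``
    keeps single-placement hits, mirroring genome-unique mapping displays.
    """
    if feature_id not in lib.ref:
        raise KeyError(f"unknown feature: {feature_id}")
    L = lib.ref.length(feature_id)
    out = {"sense": np.zeros(L), "antisense": np.zeros(L)}
    df = lib.df
    mask = (df["feature_id"] == feature_id) & _window_mask(df, lib.pirna_window)
    if unique_only:
        mask &= df["unique"]
    sub = df[mask]
    for strand, sign, col in (("+", 1.0, "sense"), ("-", -1.0, "antisense")):
        rows = sub[sub["strand"] == strand]
        np.add.at(out[col], rows["five_prime"].to_numpy(dtype=int),
                  sign * rows["weight"].to_numpy() * lib.normalization_factor)
    return pd.DataFrame(out, index=pd.RangeIndex(L, name="position"))


def length_histogram(lib: NormalizedLibrary, classes: Iterable[str] | None = None,
                     length_range: tuple[int, int] = (18, 35)) -> pd.DataFrame:
    """Weighted, normalized counts per length, split sense/antisense.

    Returns a long frame with columns ``feature_class``, ``orientation``,
    ``length``, ``rpmm`` covering every length in ``length_range`` (zeros
    included so profiles plot with a stable x axis).
    """
    df = lib.df
    feat_cls = df["feature_id"].map(lib.ref.class_map)
    work = df.assign(feature_class=feat_cls,
                     orientation=np.where(df["strand"] == "+", "sense", "antisense"))
    if classes is not None:
        work = work[work["feature_class"].isin(list(classes))]
    grouped = (work.groupby(["feature_class", "orientation", "length"])["weight"]
               .sum() * lib.normalization_factor)
    lengths = range(length_range[0], length_range[1] + 1)
    all_classes = sorted(work["feature_class"].unique()) if classes is None else sorted(set(classes))
    idx = pd.MultiIndex.from_product([all_classes, ["sense", "antisense"], lengths],
                                     names=["feature_class", "orientation", "length"])
    out = grouped.reindex(idx, fill_value=0.0).rename("rpmm").reset_index()
    return out


# ---------------------------------------------------------------------------
# RPKM expression filtering
# ---------------------------------------------------------------------------


def rpkm_table(counts: Mapping[str, float] | pd.Series,
               lengths: Mapping[str, float] | pd.Series,
               total_mapped: float) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads for a count table.

    RPKM = count / (length / 1000) / (total_mapped / 1e6).
    """
    counts = pd.Series(counts, dtype=float)
    lengths = pd.Series(lengths, dtype=float).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()].tolist()
        raise ValueError(f"missing lengths for genes: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be > 0")
    if total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    rpkm = counts / (lengths / 1e3) / (total_mapped / 1e6)
    return pd.DataFrame({
        "gene_id": counts.index,
        "count": counts.to_numpy(),
        "length": lengths.to_numpy(),
        "rpkm": rpkm.to_numpy(),
    })


def filter_expressed(table: pd.DataFrame, cutoff: float = 1.0) -> pd.Index:
    """Genes whose RPKM reaches the cutoff (>= comparison)."""
    return pd.Index(table.loc[table["rpkm"] >= cutoff, "gene_id"])
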