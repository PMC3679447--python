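"""Ping-pong 5'-overlap statistics and positional nucleotide bias.

The ping-pong amplification loop leaves two fingerprints in a piRNA
population.  First, secondary piRNAs are cleaved so that the 5' ends of a
sense/antisense pair overlap by exactly 10 nt; a histogram of pair mass per
5'–5' overlap length therefore peaks at 10, and the peak's excess over the
other overlap bins is summarized as a z-score.  Second, because primary
piRNAs start with U, their ping-pong partners carry A at position 10; the
10A fraction of sense TE piRNAs above its positional background measures
ping-pong throughput.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .profiles import NormalizedLibrary, pirna_alignments

DEFAULT_MAX_OVERLAP = 25
DEFAULT_Z_THRESHOLD = 3.0

#: positions used as the 10A background: 2–9 and 11–23 (1-based in the read)
DEFAULT_BACKGROUND_POSITIONS = tuple(range(2, 10)) + tuple(range(11, 24))


@dataclass
class OverlapHistogram:
    """Weighted pair mass per 5'–5' overlap length, with a bin-10 z-score."""

    mass: np.ndarray          # index 0 == overlap 1
    z_threshold: float = DEFAULT_Z_THRESHOLD

    @property
    def overlaps(self) -> np.ndarray:
        return np.arange(1, len(self.mass) + 1)

    @property
    def fractions(self) -> np.ndarray:
        total = self.mass.sum()
        return self.mass / total if total > 0 else np.zeros_like(self.mass)

    @property
    def z10(self) -> float:
        return pingpong_z(self.fractions)[0]

    @property
    def significant(self) -> bool:
        total = self.mass.sum()
        if total <= 0:
            return False
        return self.z10 >= self.z_threshold

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"overlap": self.overlaps, "mass": self.mass,
                             "fraction": self.fractions})


def pingpong_z(fractions: Sequence[float], bin10: int = 10) -> tuple[float, bool]:
    """z-score of the 10 nt bin against all other overlap bins.

    ``z = (f10 - mean(f_o, o != 10)) / sd(f_o, o != 10)`` with the n-1
    denominator.  A zero-variance background yields 0 when the 10 nt bin
    equals the mean and +inf when it exceeds it.
    """
    f = np.asarray(fractions, dtype=float)
    i = bin10 - 1
    others = np.delete(f, i)
    mean = others.mean()
    sd = others.std(ddof=1)
    if sd == 0:
        if f[i] > mean:
            return math.inf, True
        return 0.0, False
    z = (f[i] - mean) / sd
    return float(z), bool(z >= DEFAULT_Z_THRESHOLD)


def _five_prime_mass(df: pd.DataFrame, strand: str, length: int) -> np.ndarray:
    out = np.zeros(length)
    rows = df[df["strand"] == strand]
    np.add.at(out, rows["five_prime"].to_numpy(dtype=int), rows["weight"].to_numpy())
    return out


def overlap_histogram(lib: NormalizedLibrary,
                      features: Iterable[str] | None = None,
                      max_overlap: int = DEFAULT_MAX_OVERLAP,
                      z_threshold: float = DEFAULT_Z_THRESHOLD) -> OverlapHistogram:
    """Histogram of sense/antisense 5'–5' overlap pair mass.

    For every feature and every (sense s, antisense a) alignment pair on it,
    the overlap is ``o = a.five_prime - s.five_prime + 1``; pairs with
    ``1 <= o <= max_overlap`` add ``weight(s) * weight(a)`` to bin ``o``.
    Only piRNA-window alignments participate and features are treated
    independently (no inter-feature pairs).  By default all non-miRNA
    features are used.
    """
    if features is None:
        features = [f for f in lib.ref.ids() if lib.ref.feature_class(f) != "miRNA"]
    df = pirna_alignments(lib)
    mass = np.zeros(max_overlap)
    for fid in features:
        sub = df[df["feature_id"] == fid]
        if not len(sub):
            continue
        L = lib.ref.length(fid)
        sense = _five_prime_mass(sub, "+", L)
        anti = _five_prime_mass(sub, "-", L)
        if sense.sum() == 0 or anti.sum() == 0:
            continue
        for o in range(1, max_overlap + 1):
            # sum_p sense[p] * anti[p + o - 1]
            if o - 1 < L:
                mass[o - 1] += float(sense[:L - o + 1] @ anti[o - 1:])
    return OverlapHistogram(mass, z_threshold)


def overlap_histogram_bruteforce(lib: NormalizedLibrary,
                                 features: Iterable[str] | None = None,
                                 max_overlap: int = DEFAULT_MAX_OVERLAP) -> np.ndarray:
    """All-pairs double loop over alignments; oracle for the histogram."""
    if features is None:
        features = [f for f in lib.ref.ids() if lib.ref.feature_class(f) != "miRNA"]
    features = set(features)
    df = pirna_alignments(lib)
    mass = np.zeros(max_overlap)
    rows = list(df.itertuples(index=False))
    for s in rows:
        if s.strand != "+" or s.feature_id not in features:
            continue
        for a in rows:
            if a.strand != "-" or a.feature_id != s.feature_id:
                continue
            o = a.five_prime - s.five_prime + 1
            if 1 <= o <= max_overlap:
                mass[o - 1] += s.weight * a.weight
    return mass


def per_feature_overlap(lib: NormalizedLibrary,
                        features: Iterable[str] | None = None,
                        max_overlap: int = DEFAULT_MAX_OVERLAP,
                        z_threshold: float = DEFAULT_Z_THRESHOLD
                        ) -> dict[str, OverlapHistogram]:
    """One overlap histogram per feature (TEs by default)."""
    if features is None:
        features = lib.ref.by_class("TE")
    return {fid: overlap_histogram(lib, [fid], max_overlap, z_threshold)
            for fid in features}


# ---------------------------------------------------------------------------
# positional nucleotide bias
# ---------------------------------------------------------------------------


@dataclass
class BiasResult:
    """Observed vs expected weighted fraction of a nucleotide at a position.

    ``expected`` is the mean of the same fraction over the background
    positions; ``defined`` is False when no read reaches the query position.
    """

    position: int
    nucleotide: str
    observed: float
    expected: float
    n_weighted: float
    defined: bool = True

    @property
    def delta(self) -> float:
        return self.observed - self.expected


def _weighted_fraction(df: pd.DataFrame, position: int, nucleotide: str
                       ) -> tuple[float, float]:
    """(fraction, total weight) of reads carrying ``nucleotide`` at 1-based
    ``position``, among reads long enough to have that position."""
    sel = df[df["length"] >= position]
    total = float(sel["weight"].sum())
    if total == 0:
        return float("nan"), 0.0
    hit = sel["sequence"].str[position - 1] == nucleotide
    return float(sel.loc[hit, "weight"].sum()) / total, total


def positional_bias(lib: NormalizedLibrary,
                    orientation: str = "sense",
                    position: int = 10,
                    nucleotide: str = "A",
                    background_positions: Sequence[int] = DEFAULT_BACKGROUND_POSITIONS,
                    classes: Iterable[str] = ("TE",)) -> BiasResult:
    """Positional nucleotide bias of piRNA-window reads on selected features.

    The default call measures the adenosine fraction at position 10 of sense
    TE piRNAs against the average A content at positions 2–9 and 11–23 — the
    ping-pong responder signature.  Reads shorter than a position are
    excluded from that position's tally.
    """
    df = pirna_alignments(lib, classes=classes, orientation=orientation)
    observed, n_weighted = _weighted_fraction(df, position, nucleotide)
    if n_weighted == 0:
        return BiasResult(position, nucleotide, float("nan"), float("nan"), 0.0,
                          defined=False)
    bg = [f for f, w in (_weighted_fraction(df, p, nucleotide)
                         for p in background_positions) if w > 0]
    expected = float(np.mean(bg)) if bg else float("nan")
    return BiasResult(position, nucleotide, observed, expected, n_weighted)
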