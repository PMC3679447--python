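"""Control-vs-knockdown library comparison.

Quantifies what loss of a piRNA biogenesis factor does to the piRNA
population: per-TE antisense piRNA levels (RPMM), log2 fold changes and
their scatter correlation across all TEs, the global miRNA-normalized
reduction of the 23–30 nt non-miRNA population, and the type-I biogenesis
factor fingerprint — most TEs collapse, while a handful of ping-pong-driven
TEs keep their piRNA levels with a sharpened 10 nt overlap signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import NormalizedLibrary, pirna_alignments
from .signatures import per_feature_overlap

DEFAULT_PSEUDOCOUNT = 1.0  # RPMM floor for log2 transforms
DEFAULT_FC_THRESHOLD = 2.0
DEFAULT_DZ_THRESHOLD = 2.0

TE_ORIGIN_CLASSES = ("soma-dominant", "intermediate", "germline-dominant", "unclassified")
TYPEI_CLASSES = ("collapsed", "pingpong-rescued", "unchanged")


def te_levels(lib: NormalizedLibrary, orientation: str = "antisense") -> pd.Series:
    """Weighted piRNA-window mass per TE in RPMM, zeros for silent TEs."""
    te_ids = lib.ref.by_class("TE")
    df = pirna_alignments(lib, classes=("TE",), orientation=orientation)
    mass = df.groupby("feature_id")["weight"].sum() * lib.normalization_factor
    return mass.reindex(te_ids, fill_value=0.0).rename("rpmm")


def nonmirna_window_mass(lib: NormalizedLibrary) -> float:
    """Total 23–30 nt non-miRNA weighted mass, in RPMM."""
    df = pirna_alignments(lib, classes=("TE", "cluster", "other"))
    return float(df["weight"].sum()) * lib.normalization_factor


def log2_fold_changes(control_levels: pd.Series, kd_levels: pd.Series,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.Series:
    """Per-TE log2((kd + c) / (control + c))."""
    kd_levels = kd_levels.reindex(control_levels.index, fill_value=0.0)
    return np.log2((kd_levels + pseudocount) / (control_levels + pseudocount)).rename("log2_fc")


def pearson_log2(control_levels: pd.Series, kd_levels: pd.Series,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """Pearson r of log2(level + c) vectors across all TEs.

    Returns NaN (flagged) when fewer than two TEs have nonzero level in
    either library, or when a vector is constant.
    """
    kd_levels = kd_levels.reindex(control_levels.index, fill_value=0.0)
    nonzero = ((control_levels > 0) | (kd_levels > 0)).sum()
    if nonzero < 2:
        return float("nan")
    x = np.log2(control_levels + pseudocount)
    y = np.log2(kd_levels + pseudocount)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


@dataclass
class ComparisonResult:
    """Per-TE and global statistics of a control/knockdown pair."""

    per_te: pd.DataFrame          # control_rpmm, kd_rpmm, log2_fc, z10_*, dz10
    pearson_r: float
    global_ratio: float           # kd / control 23-30 nt non-miRNA RPMM
    pseudocount: float

    def to_tsv(self, path) -> None:
        self.per_te.to_csv(path, sep="\t")


def compare_libraries(control: NormalizedLibrary, kd: NormalizedLibrary,
                      pseudocount: float = DEFAULT_PSEUDOCOUNT) -> ComparisonResult:
    """Compare a knockdown library against its control.

    Both libraries must share the reference panel.  Per-TE levels are
    antisense piRNA RPMM; z-scores come from per-TE overlap histograms so
    the type-I classification can use their knockdown-minus-control shift.
    """
    if control.ref is not kd.ref and control.ref != kd.ref:
        raise ValueError("control and knockdown must share the reference panel")
    levels_c = te_levels(control)
    levels_k = te_levels(kd)
    fc = log2_fold_changes(levels_c, levels_k, pseudocount)
    r = pearson_log2(levels_c, levels_k, pseudocount)
    hists_c = per_feature_overlap(control)
    hists_k = per_feature_overlap(kd)
    z_c = pd.Series({t: hists_c[t].z10 for t in levels_c.index}, name="z10_control")
    z_k = pd.Series({t: hists_k[t].z10 for t in levels_c.index}, name="z10_kd")
    dz = z_k - z_c
    dz[np.isinf(z_c) & np.isinf(z_k)] = 0.0  # both saturated: no shift
    per_te = pd.DataFrame({
        "control_rpmm": levels_c,
        "kd_rpmm": levels_k.reindex(levels_c.index, fill_value=0.0),
        "log2_fc": fc,
        "z10_control": z_c,
        "z10_kd": z_k,
        "dz10": dz,
    })
    mass_c = nonmirna_window_mass(control)
    ratio = nonmirna_window_mass(kd) / mass_c if mass_c > 0 else float("nan")
    return ComparisonResult(per_te, r, ratio, pseudocount)


def classify_te_origin(soma_levels: pd.Series, germline_levels: pd.Series,
                       log2_margin: float = 1.0) -> pd.Series:
    """Label TEs soma-dominant / intermediate / germline-dominant.

    The label follows log2(soma / germline): at or above the margin the TE
    is soma-dominant, at or below its negation germline-dominant, otherwise
    intermediate.  TEs silent in both compartments are 'unclassified'.
    """
    germline_levels = germline_levels.reindex(soma_levels.index, fill_value=0.0)
    out = {}
    for te in soma_levels.index:
        s, g = float(soma_levels[te]), float(germline_levels[te])
        if s == 0 and g == 0:
            out[te] = "unclassified"
            continue
        if g == 0:
            ratio = np.inf
        elif s == 0:
            ratio = -np.inf
        else:
            ratio = np.log2(s / g)
        if ratio >= log2_margin:
            out[te] = "soma-dominant"
        elif ratio <= -log2_margin:
            out[te] = "germline-dominant"
        else:
            out[te] = "intermediate"
    return pd.Series(out, name="origin")


def typeI_signature(comparison: ComparisonResult,
                    fc_threshold: float = DEFAULT_FC_THRESHOLD,
                    dz_threshold: float = DEFAULT_DZ_THRESHOLD) -> pd.Series:
    """Classify each TE's response to a primary-pathway knockdown.

    ``collapsed``: piRNA level fell at least ``fc_threshold`` log2 units.
    ``pingpong-rescued``: level held up and the 10 nt overlap z-score rose
    by at least ``dz_threshold`` — the mark of a TE whose piRNAs are made
    almost exclusively by ping-pong once primary biogenesis is gone.
    ``unchanged`` otherwise.  TEs with no piRNAs in either library are
    skipped.
    """
    out = {}
    for te, row in comparison.per_te.iterrows():
        if row["control_rpmm"] == 0 and row["kd_rpmm"] == 0:
            continue
        if row["log2_fc"] <= -fc_threshold:
            out[te] = "collapsed"
        elif row["dz10"] >= dz_threshold:
            out[te] = "pingpong-rescued"
        else:
            out[te] = "unchanged"
    return pd.Series(out, name="typeI", dtype=object)
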