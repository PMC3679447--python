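"""Statistics for transgenic RNAi screens scored with an ordinal reporter.

Models the analytics of a reporter-based ovary screen: per-line knockdown
efficiency and the resulting gene-level false-negative rate, hit-rate
summaries, phenotype rates across expression bins, fold-change group
comparisons, and the soma/germline two-reporter specificity classes.

Staining is scored on a six-level ordinal scale (0 = none .. 5 = strong);
ovarian morphology is one of wild_type / distorted / rudimentary.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

STAINING_LABELS = ("none", "weak", "weak-intermediate", "intermediate",
                   "intermediate-strong", "strong")
MORPHOLOGY_LABELS = ("wild_type", "distorted", "rudimentary")

#: staining levels counted as "strong-range" hits by default
DEFAULT_STRONG_RANGE = (4, 5)

RECORD_COLUMNS = ["gene_id", "line_id", "staining", "morphology"]


@dataclass(frozen=True)
class ScreenRecord:
    """One (gene, RNAi line) observation."""

    gene_id: str
    line_id: str
    staining: int
    morphology: str

    def __post_init__(self):
        if not 0 <= self.staining <= 5:
            raise ValueError("staining must be an ordinal in 0..5")
        if self.morphology not in MORPHOLOGY_LABELS:
            raise ValueError(f"unknown morphology {self.morphology!r}")


def records_frame(records) -> pd.DataFrame:
    """Normalize records (dataclasses or a DataFrame) to a validated frame."""
    if isinstance(records, pd.DataFrame):
        df = records.loc[:, RECORD_COLUMNS].copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records], columns=RECORD_COLUMNS)
    if len(df):
        if df.duplicated(["gene_id", "line_id"]).any():
            raise ValueError("one record per (gene, line) required")
        if not df["staining"].between(0, 5).all():
            raise ValueError("staining must be in 0..5")
        if not df["morphology"].isin(MORPHOLOGY_LABELS).all():
            raise ValueError("invalid morphology label")
    return df


def summarize_screen(records, tested_gene_total: int, expressed_gene_total: int,
                     strong_range: Sequence[int] = DEFAULT_STRONG_RANGE) -> dict:
    """Gene-level hit counts and percentages for a screen.

    A gene scores when any of its lines shows staining above none; the
    strong-range set (intermediate-strong or stronger by default) captures
    hits in the range of known pathway members.  Percentages are relative
    to ``tested_gene_total``; coverage is tested / expressed.
    """
    if tested_gene_total <= 0 or expressed_gene_total <= 0:
        raise ValueError("gene totals must be positive")
    df = records_frame(records)
    if len(df):
        per_gene = df.groupby("gene_id")["staining"].max()
        n_any = int((per_gene > 0).sum())
        n_strong = int(per_gene.isin(list(strong_range)).sum())
        morph = df.groupby("gene_id")["morphology"].agg(
            lambda m: ("rudimentary" if (m == "rudimentary").any()
                       else "distorted" if (m == "distorted").any()
                       else "wild_type"))
        morph_counts = morph.value_counts().reindex(MORPHOLOGY_LABELS, fill_value=0)
    else:
        n_any = n_strong = 0
        morph_counts = pd.Series(0, index=list(MORPHOLOGY_LABELS))
    return {
        "n_any_staining": n_any,
        "pct_any_staining": 100.0 * n_any / tested_gene_total,
        "n_strong_range": n_strong,
        "pct_strong_range": 100.0 * n_strong / tested_gene_total,
        "morphology_gene_counts": morph_counts.to_dict(),
        "coverage_pct": 100.0 * tested_gene_total / expressed_gene_total,
    }


# ---------------------------------------------------------------------------
# detection model
# ---------------------------------------------------------------------------


@dataclass
class DetectionModel:
    """Per-line efficiency p and the gene-level miss model fn(n) = (1-p)^n."""

    p: float
    n_lines_default: int = 2
    empirical_gene_miss_rate: float | None = None

    def fn(self, n: int | None = None) -> float:
        if n is None:
            n = self.n_lines_default
        if n < 0:
            raise ValueError("n must be >= 0")
        return (1.0 - self.p) ** n


def estimate_detection(control_records, n_lines: int = 2,
                       effective_morphology: str = "rudimentary") -> DetectionModel:
    """Estimate per-line knockdown efficiency from a positive-control set.

    Control genes (e.g. ribosomal proteins) have an obligatory per-line
    phenotype when the knockdown works, so the fraction of lines showing
    ``effective_morphology`` estimates the per-line efficiency p.  The
    false-negative model assumes line independence: fn(n) = (1-p)^n.  The
    empirical gene-level miss rate (control genes where no line worked) is
    reported alongside, since real lines are not fully independent.
    """
    df = records_frame(control_records)
    if not len(df):
        raise ValueError("empty control record set")
    effective = df["morphology"] == effective_morphology
    p = float(effective.mean())
    gene_missed = df.assign(eff=effective).groupby("gene_id")["eff"].any()
    miss_rate = float(1.0 - gene_missed.mean())
    return DetectionModel(p, n_lines, miss_rate)


def fn_bruteforce(p: float, n: int) -> float:
    """Gene-level miss probability by enumerating all 2^n line outcomes."""
    total = 0.0
    for outcome in product([0, 1], repeat=n):
        prob = 1.0
        for eff in outcome:
            prob *= p if eff else (1.0 - p)
        if not any(outcome):
            total += prob
    return total


# ---------------------------------------------------------------------------
# expression-bin phenotype rates
# ---------------------------------------------------------------------------


def phenotype_by_bin(gene_flags: pd.Series, expression: pd.Series,
                     n_bins: int = 10, cutoff: float = 1.0) -> pd.DataFrame:
    """Phenotype rate per expression bin.

    Genes at or above the expression ``cutoff`` are ranked by expression and
    cut into ``n_bins`` equal-size bins (bin 1 lowest, bin ``n_bins``
    highest; the division remainder goes to the top bin).  Genes below the
    cutoff form bin 0.  ``gene_flags`` is a boolean per-gene phenotype call.
    """
    expression = expression.reindex(gene_flags.index)
    if expression.isna().any():
        raise ValueError("every gene needs an expression value")
    expressed = expression[expression >= cutoff]
    if n_bins > len(expressed):
        raise ValueError("n_bins exceeds expressed gene count")
    order = expressed.sort_values(kind="mergesort").index
    size = len(order) // n_bins
    bins = pd.Series(0, index=gene_flags.index, dtype=int)
    for b in range(n_bins):
        hi = (b + 1) * size if b < n_bins - 1 else len(order)
        bins[order[b * size:hi]] = b + 1
    work = pd.DataFrame({"bin": bins, "flag": gene_flags.astype(bool)})
    out = work.groupby("bin").agg(n_genes=("flag", "size"), n_flagged=("flag", "sum"))
    out["pct"] = 100.0 * out["n_flagged"] / out["n_genes"]
    return out.reset_index()


# ---------------------------------------------------------------------------
# fold-change group comparisons
# ---------------------------------------------------------------------------


def group_fold_changes(values: pd.Series, labels: pd.Series,
                       reference_group: str) -> pd.DataFrame:
    """Box-plot summaries per group plus a rank test against the reference.

    Per group: median, quartiles, whiskers at 1.5 * IQR, outliers beyond the
    whiskers, and a two-sided rank-sum (Mann-Whitney U) p-value versus the
    reference group.  The reference row carries p = NaN.
    """
    labels = labels.reindex(values.index)
    groups = labels.dropna().unique().tolist()
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} missing")
    ref_vals = values[labels == reference_group].to_numpy(dtype=float)
    rows = []
    for g in groups:
        v = values[labels == g].to_numpy(dtype=float)
        if len(v) == 0:
            raise ValueError(f"group {g!r} has no values")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        outliers = v[(v < lo) | (v > hi)]
        if g == reference_group:
            p = float("nan")
        else:
            p = float(stats.mannwhitneyu(v, ref_vals, alternative="two-sided").pvalue)
        rows.append({
            "group": g, "n": len(v), "median": med, "q1": q1, "q3": q3,
            "whisker_low": lo, "whisker_high": hi,
            "n_outliers": len(outliers), "p_vs_reference": p,
        })
    return pd.DataFrame(rows)


def box_outliers(values: Sequence[float]) -> np.ndarray:
    """Values outside the 25th-75th percentile box +- 1.5 IQR."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return v[(v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)]


# ---------------------------------------------------------------------------
# two-reporter specificity
# ---------------------------------------------------------------------------

NOT_ASSAYABLE = "not-assayable"

SPECIFICITY_CLASSES = ("soma-specific", "common", "germline-specific",
                       "not-interpretable")


def classify_pathway_specificity(soma_score: int,
                                 germline_score: int | str | None,
                                 threshold: int = 2) -> str:
    """Assign a gene to soma-specific / common / germline-specific.

    Scores are on the ordinal staining scale; the default inclusion
    threshold is weak-intermediate (2).  A germline score that could not be
    assayed (``None`` or ``"not-assayable"``) makes the gene
    not-interpretable, as does a gene reaching the threshold in neither
    compartment.
    """
    if not 0 <= int(soma_score) <= 5:
        raise ValueError("soma_score must be an ordinal in 0..5")
    if germline_score is None or germline_score == NOT_ASSAYABLE:
        return "not-interpretable"
    if not 0 <= int(germline_score) <= 5:
        raise ValueError("germline_score must be an ordinal in 0..5")
    soma = int(soma_score) >= threshold
    germ = int(germline_score) >= threshold
    if soma and germ:
        return "common"
    if soma:
        return "soma-specific"
    if germ:
        return "germline-specific"
    return "not-interpretable"
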