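"""End-to-end simulate → map → normalize → compare workflows.

The flagship workflow emulates, on a simulated control/knockdown pair, the
panel of statistics used to characterize a type-I biogenesis-factor
knockdown: length histograms, cluster coverage profiles, the per-TE log2
scatter with its Pearson correlation, the 10A bias with its positional
background, per-TE ping-pong z-scores, and the global miRNA-normalized
piRNA reduction.  The machine-readable JSON report is the tested contract;
TSV side files carry the larger tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import knockdown as kd_mod
from . import signatures
from .mapping import map_reads
from .profiles import length_histogram, coverage_profile, normalize_library
from .simlib import SimConfig, build_reference, simulate_knockdown_pair

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full simulation-to-report run."""

    sim: SimConfig = field(default_factory=SimConfig)
    z_threshold: float = signatures.DEFAULT_Z_THRESHOLD
    fc_threshold: float = kd_mod.DEFAULT_FC_THRESHOLD
    dz_threshold: float = kd_mod.DEFAULT_DZ_THRESHOLD
    pseudocount: float = kd_mod.DEFAULT_PSEUDOCOUNT
    max_hits: int = 100

    def validate(self) -> None:
        self.sim.validate()
        if self.pseudocount < 0 or self.fc_threshold < 0 or self.dz_threshold < 0:
            raise ValueError("thresholds must be >= 0")


def _jsonable(x):
    if isinstance(x, float) and not np.isfinite(x):
        return None if np.isnan(x) else ("inf" if x > 0 else "-inf")
    if isinstance(x, (np.floating, np.integer)):
        return _jsonable(x.item())
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    return x


def run_fig6_workflow(config: RunConfig, outdir=None) -> dict:
    """Simulate a knockdown pair and compute the full comparison report.

    Deterministic for a fixed config seed: running twice yields
    byte-identical JSON.  Each stage failure is re-raised with a
    stage-labeled message.
    """
    config.validate()
    report: dict = {"seed": config.sim.seed,
                    "primary_reduction": config.sim.primary_reduction}
    stage = "simulate"
    try:
        ref = build_reference(config.sim)
        control_reads, kd_reads, truth = simulate_knockdown_pair(ref, config.sim)

        stage = "map"
        aln_c = map_reads(control_reads, ref, config.max_hits)
        aln_k = map_reads(kd_reads, ref, config.max_hits)

        stage = "normalize"
        lib_c = normalize_library(aln_c, ref)
        lib_k = normalize_library(aln_k, ref)

        stage = "compare"
        comparison = kd_mod.compare_libraries(lib_c, lib_k, config.pseudocount)
        labels = kd_mod.typeI_signature(comparison, config.fc_threshold,
                                        config.dz_threshold)

        stage = "signatures"
        bias_c = signatures.positional_bias(lib_c)
        bias_k = signatures.positional_bias(lib_k)
        hist_c = signatures.overlap_histogram(lib_c, z_threshold=config.z_threshold)
        hist_k = signatures.overlap_histogram(lib_k, z_threshold=config.z_threshold)

        stage = "report"
        per_te = comparison.per_te.copy()
        per_te["typeI"] = labels.reindex(per_te.index, fill_value="skipped")
        report.update({
            "global_ratio": comparison.global_ratio,
            "pearson_r": comparison.pearson_r,
            "z10": {"control": hist_c.z10, "knockdown": hist_k.z10},
            "bias_10a": {
                "control": {"observed": bias_c.observed, "expected": bias_c.expected},
                "knockdown": {"observed": bias_k.observed, "expected": bias_k.expected},
            },
            "per_te": {te: {k: _jsonable(v) for k, v in row.items()}
                       for te, row in per_te.to_dict("index").items()},
            "truth": {
                "reduction": truth.reduction,
                "control_total_reads": truth.control.total_reads,
                "knockdown_total_reads": truth.knockdown.total_reads,
            },
        })
        report = _jsonable(report)

        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            with open(outdir / "report.json", "w") as fh:
                fh.write(json.dumps(report, sort_keys=True, indent=2) + "\n")
            truth.to_json(outdir / "truth.json")
            per_te.to_csv(outdir / "per_te.tsv", sep="\t")
            for name, lib in (("control", lib_c), ("knockdown", lib_k)):
                length_histogram(lib).to_csv(outdir / f"lenhist_{name}.tsv",
                                             sep="\t", index=False)
                hist = signatures.overlap_histogram(lib)
                hist.to_frame().to_csv(outdir / f"pingpong_{name}.tsv",
                                       sep="\t", index=False)
                for cid in ref.by_class("cluster"):
                    prof = coverage_profile(lib, cid)
                    prof.to_csv(outdir / f"profile_{name}_{cid}.tsv", sep="\t")
    except Exception as exc:
        raise RuntimeError(f"workflow failed at stage '{stage}': {exc}") from exc
    return report


def report_json(report: dict) -> str:
    """Canonical JSON text of a workflow report."""
    return json.dumps(report, sort_keys=True, indent=2)
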