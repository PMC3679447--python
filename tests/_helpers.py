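"""Shared helpers for the test suite: scaled simulation configs and the
simulate → map → normalize shorthand used by many tests."""

from pirnakit.mapping import map_reads
from pirnakit.profiles import normalize_library
from pirnakit.simlib import (ClusterSpec, SimConfig, build_reference,
                             simulate_knockdown_pair, simulate_library)


def small_sim_config(seed=0, **overrides) -> SimConfig:
    """A scaled-down library: 4 TEs, two small clusters, 10k reads.

    Keeps Monte-Carlo tests fast while preserving every structural feature
    of the default generator (uni + dual clusters, miRNA anchor, piRNA
    length window).
    """
    base = dict(
        n_te=4,
        te_length_range=(600, 900),
        clusters=[ClusterSpec("cluster_uni", "uni", 4),
                  ClusterSpec("cluster_dual", "dual", 4)],
        fragment_length_range=(120, 250),
        n_mirna=20,
        library_depth=10_000,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def simulate_normalized(cfg):
    """build_reference + simulate_library + map + normalize."""
    ref = build_reference(cfg)
    reads, truth = simulate_library(ref, cfg)
    lib = normalize_library(map_reads(reads, ref), ref)
    return ref, reads, truth, lib


def simulate_pair_normalized(cfg):
    """Same for a control/knockdown pair."""
    ref = build_reference(cfg)
    control, kd, truth = simulate_knockdown_pair(ref, cfg)
    lib_c = normalize_library(map_reads(control, ref), ref)
    lib_k = normalize_library(map_reads(kd, ref), ref)
    return ref, truth, lib_c, lib_k
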