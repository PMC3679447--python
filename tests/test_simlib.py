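"""Generator contracts: reference geometry, read classes, determinism,
conservation, the 1U/10A forcing, and knockdown thinning."""

import numpy as np
import pytest

from pirnakit.mapping import map_reads
from pirnakit.profiles import normalize_library, pirna_alignments
from pirnakit.simlib import (ClusterSpec, SimConfig, build_reference,
                             simulate_knockdown_pair, simulate_library)

from _helpers import small_sim_config


class TestBuildReference:
    def test_uni_cluster_fragments_all_antisense(self):
        cfg = small_sim_config(seed=7, n_te=2,
                               clusters=[ClusterSpec("flam_like", "uni", 4)])
        ref = build_reference(cfg)
        ivs = [iv for iv in ref.intervals if iv.chrom == "flam_like"]
        assert len(ivs) == 4
        assert all(iv.strand == "-" for iv in ivs)

    def test_fragment_provenance_reconstructs_cluster(self):
        """Each fragment interval names its source TE slice; stitching the
        (reverse-complemented) slices back reproduces the cluster sequence."""
        from pirnakit.smallrna_io import revcomp
        cfg = small_sim_config(seed=3)
        ref = build_reference(cfg)
        for cid in ref.by_class("cluster"):
            rebuilt = []
            for iv in (iv for iv in ref.intervals if iv.chrom == cid):
                te, span = iv.name.split(":")
                lo, hi = map(int, span.split("-"))
                piece = ref.sequence(te)[lo:hi]
                rebuilt.append(revcomp(piece) if iv.strand == "-" else piece)
            assert "".join(rebuilt) == ref.sequence(cid)

    def test_deterministic(self):
        cfg = small_sim_config(seed=11)
        assert build_reference(cfg) == build_reference(cfg)

    def test_impossible_fragment_rejected(self):
        cfg = small_sim_config(n_te=1, te_length_range=(100, 100),
                               fragment_length_range=(150, 150))
        with pytest.raises(ValueError, match="exceeds source TE"):
            build_reference(cfg)

    def test_degenerate_te_length_range_rejected(self):
        cfg = small_sim_config(te_length_range=(900, 600))
        with pytest.raises(ValueError, match="degenerate"):
            build_reference(cfg)


class TestSimulateLibrary:
    def test_phi_zero_disables_pingpong(self):
        cfg = small_sim_config(seed=1, pingpong_fraction=0.0)
        ref = build_reference(cfg)
        _, truth = simulate_library(ref, cfg)
        assert sum(truth.control.pingpong_mass.values()) == 0

    def test_phi_for_unknown_te_rejected(self):
        cfg = small_sim_config(pingpong_fraction={"TE99": 0.5})
        ref = build_reference(small_sim_config())
        with pytest.raises(ValueError, match="absent from the reference"):
            simulate_library(ref, cfg)

    def test_beta_one_forces_all_primary_reads_to_start_with_u(self):
        """With a 1U bias of 1 and no ping-pong, every piRNA-length read is a
        primary read and must begin with U (T after normalization)."""
        cfg = small_sim_config(seed=2, u1_bias=1.0, pingpong_fraction=0.0)
        ref = build_reference(cfg)
        reads, _ = simulate_library(ref, cfg)
        pirna = reads.df[reads.df["sequence"].str.len() >= 23]
        assert len(pirna) > 100
        assert (pirna["sequence"].str[0] == "T").all()

    def test_mass_conservation(self):
        cfg = small_sim_config(seed=5, pingpong_fraction=0.4)
        ref = build_reference(cfg)
        reads, truth = simulate_library(ref, cfg)
        assert reads.total_count == truth.control.total_reads

    def test_depth_zero_yields_empty_library(self):
        cfg = small_sim_config(library_depth=0)
        ref = build_reference(cfg)
        reads, truth = simulate_library(ref, cfg)
        assert reads.total_count == 0
        assert truth.control.total_reads == 0

    def test_determinism_bytes(self, tmp_path):
        cfg = small_sim_config(seed=9, pingpong_fraction=0.3)
        ref = build_reference(cfg)
        out = []
        for i in range(2):
            reads, truth = simulate_library(ref, cfg)
            p = tmp_path / f"lib{i}.fastq"
            reads.write_fastq(p)
            out.append((p.read_bytes(), truth.to_json()))
        assert out[0] == out[1]

    def test_u1_bias_law(self):
        """Observed 1U fraction of primary piRNAs approaches the configured
        bias within 3 binomial standard errors at 30k depth."""
        beta = 0.7
        cfg = small_sim_config(seed=4, u1_bias=beta, pingpong_fraction=0.0,
                               clusters=[], library_depth=30_000)
        ref = build_reference(cfg)
        reads, truth = simulate_library(ref, cfg)
        pirna = reads.df[reads.df["sequence"].str.len() >= 23]
        n = pirna["count"].sum()
        frac_u = pirna.loc[pirna["sequence"].str[0] == "T", "count"].sum() / n
        se = np.sqrt(beta * (1 - beta) / n)
        assert abs(frac_u - beta) <= 3 * se

    def test_responder_10a_equals_initiator_1u_by_complementarity(self):
        """With the 1U bias forced to 1 and no primary templates, every sense
        TE piRNA is a ping-pong responder and must carry A at position 10."""
        cfg = small_sim_config(seed=6, u1_bias=1.0, pingpong_fraction=0.8,
                               clusters=[], library_depth=20_000)
        ref = build_reference(cfg)
        reads, _ = simulate_library(ref, cfg)
        lib = normalize_library(map_reads(reads, ref), ref)
        sense_te = pirna_alignments(lib, classes=("TE",), orientation="sense")
        anti_te = pirna_alignments(lib, classes=("TE",), orientation="antisense")
        assert len(sense_te) > 10
        assert (sense_te["sequence"].str[9] == "A").all()
        # initiators are the forced-1U antisense partners
        assert (anti_te[anti_te["sequence"].str.len() >= 23]["sequence"].str[0] == "T").mean() > 0.99


class TestKnockdownPair:
    def test_r_one_keeps_primary_draw_identical(self):
        cfg = small_sim_config(seed=3, primary_reduction=1.0)
        ref = build_reference(cfg)
        control, kd, truth = simulate_knockdown_pair(ref, cfg)
        assert truth.knockdown.primary_mass == truth.control.primary_mass

    def test_r_zero_removes_primary_but_keeps_pingpong(self):
        cfg = small_sim_config(seed=3, primary_reduction=0.0,
                               pingpong_fraction={"TE01": 0.8})
        ref = build_reference(cfg)
        _, kd, truth = simulate_knockdown_pair(ref, cfg)
        assert sum(truth.knockdown.primary_mass.values()) == 0
        assert truth.knockdown.pingpong_mass["TE01"] > 0
        assert truth.knockdown.pingpong_mass == truth.control.pingpong_mass

    def test_control_matches_standalone_library(self):
        cfg = small_sim_config(seed=8, primary_reduction=0.25)
        ref = build_reference(cfg)
        control, _, pair_truth = simulate_knockdown_pair(ref, cfg)
        solo, solo_truth = simulate_library(ref, cfg)
        assert control == solo
        assert pair_truth.control.as_dict() == solo_truth.control.as_dict()

    def test_invalid_reduction_rejected(self):
        cfg = small_sim_config(primary_reduction=1.5)
        with pytest.raises(ValueError, match="primary_reduction"):
            build_reference(cfg)
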