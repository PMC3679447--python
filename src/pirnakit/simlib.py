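"""Generative model of ovarian small-RNA libraries with ground truth.

The simulator emulates the read populations that piRNA biogenesis in the
fly ovary produces:

* **miRNA reads** — exact copies of miRNA species with heavy-tailed
  abundances.  miRNAs are unaffected by piRNA-pathway perturbations and
  anchor cross-library normalization.
* **primary piRNAs** — 23–30 nt substrings of piRNA-cluster transcripts or
  of antisense transposon (TE) transcripts, with a 1U bias at the 5' end.
  Uni-strand clusters (flamenco-like) are built entirely from antisense TE
  fragments; dual-strand clusters (42AB-like) carry fragments in random
  orientation.
* **ping-pong pairs** — an antisense *initiator* piRNA and a sense
  *responder* piRNA on a TE whose 5' ends sit on opposite strands with an
  exact 10 nt overlap.  Because the responder's position 10 is the
  complement of the initiator's position 1, a 1U initiator forces a 10A
  responder; the simulator enforces this by sampling pair sites, never by
  mutating sequences.

A knockdown of a primary biogenesis factor is modelled as a multiplicative
factor ``r`` on the primary pathway's expected read counts (binomial
thinning of the control draw); ping-pong output and miRNA expectations are
untouched.

All randomness flows from the config seed; identical (config, seed) pairs
produce byte-identical libraries and truth records.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .smallrna_io import Feature, Interval, ReadSet, ReferenceSet, revcomp

_BASES = np.array(list("ACGT"))

#: hard bounds the piRNA length window must stay inside
LENGTH_HARD_BOUNDS = (18, 35)

# fixed stream labels so library and knockdown-pair generation share draws
_STREAM_REF = 1
_STREAM_LIB = 2


@dataclass(frozen=True)
class ClusterSpec:
    """One piRNA cluster to assemble from TE fragments."""

    cluster_id: str
    strand_mode: str  # "uni" (all fragments antisense) or "dual" (random)
    fragment_count: int


def _default_clusters() -> list[ClusterSpec]:
    return [ClusterSpec("cluster_uni", "uni", 6),
            ClusterSpec("cluster_dual", "dual", 6)]


@dataclass
class SimConfig:
    """Parameters of the generative model.

    The defaults describe a desk-scale ovary-like library: a panel of TE
    consensus sequences, one uni-strand and one dual-strand cluster, an
    invariant miRNA population taking ~25% of the library, piRNAs of
    23–30 nt centred at 26 nt, and a strong (90%) 1U bias.
    """

    n_te: int = 8
    te_length_range: tuple[int, int] = (800, 1400)
    clusters: list[ClusterSpec] = field(default_factory=_default_clusters)
    fragment_length_range: tuple[int, int] = (150, 400)
    n_mirna: int = 30
    mirna_length: int = 22
    mirna_fraction: float = 0.25
    pirna_length_mean: float = 26.0
    pirna_length_sd: float = 1.5
    pirna_length_bounds: tuple[int, int] = (23, 30)
    u1_bias: float = 0.9
    pingpong_fraction: float | Mapping[str, float] = 0.0
    primary_reduction: float = 1.0
    library_depth: int = 50_000
    pingpong_site_reads: float = 40.0  # mean reads per ping-pong pair site
    te_abundance_sigma: float = 1.0    # log-normal spread of per-template output
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.pirna_length_bounds
        if not (LENGTH_HARD_BOUNDS[0] <= lo <= hi <= LENGTH_HARD_BOUNDS[1]):
            raise ValueError(f"pirna_length_bounds must lie within {LENGTH_HARD_BOUNDS}")
        if not 0.0 <= self.u1_bias <= 1.0:
            raise ValueError("u1_bias must be in [0, 1]")
        if not 0.0 <= self.primary_reduction <= 1.0:
            raise ValueError("primary_reduction must be in [0, 1]")
        if not 0.0 < self.mirna_fraction < 1.0:
            raise ValueError("mirna_fraction must be in (0, 1)")
        if self.n_te < 1 or self.n_mirna < 1:
            raise ValueError("n_te and n_mirna must be >= 1")
        if self.te_length_range[0] > self.te_length_range[1]:
            raise ValueError("degenerate te_length_range: min > max")
        if self.fragment_length_range[0] > self.fragment_length_range[1]:
            raise ValueError("degenerate fragment_length_range: min > max")
        for spec in self.clusters:
            if spec.strand_mode not in ("uni", "dual"):
                raise ValueError(f"unknown strand_mode {spec.strand_mode!r}")
            if spec.fragment_count < 1:
                raise ValueError("cluster fragment_count must be >= 1")
        if self.library_depth < 0:
            raise ValueError("library_depth must be >= 0")
        phis = (self.pingpong_fraction.values()
                if isinstance(self.pingpong_fraction, Mapping)
                else [self.pingpong_fraction])
        for phi in phis:
            if not 0.0 <= phi <= 1.0:
                raise ValueError("pingpong_fraction values must be in [0, 1]")

    def phi_for(self, te_ids: list[str]) -> np.ndarray:
        """Resolve the per-TE ping-pong fraction vector."""
        if isinstance(self.pingpong_fraction, Mapping):
            unknown = set(self.pingpong_fraction) - set(te_ids)
            if unknown:
                raise ValueError(
                    f"pingpong_fraction given for TEs absent from the reference: {sorted(unknown)}"
                )
            return np.array([float(self.pingpong_fraction.get(t, 0.0)) for t in te_ids])
        return np.full(len(te_ids), float(self.pingpong_fraction))


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------


@dataclass
class LibraryTruth:
    """Per-class generated read masses for one library."""

    mirna_counts: dict[str, int]
    primary_mass: dict[str, int]   # per template feature (cluster or TE-antisense)
    pingpong_mass: dict[str, int]  # per TE, total reads (initiators + responders)

    @property
    def total_reads(self) -> int:
        return (sum(self.mirna_counts.values())
                + sum(self.primary_mass.values())
                + sum(self.pingpong_mass.values()))

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimTruth:
    """Ground truth of a simulated library (or control/knockdown pair)."""

    seed: int
    reduction: float
    fragments: list[dict]
    control: LibraryTruth
    knockdown: LibraryTruth | None = None

    def to_json(self, path=None) -> str:
        payload = {
            "seed": self.seed,
            "reduction": self.reduction,
            "fragments": self.fragments,
            "control": self.control.as_dict(),
            "knockdown": None if self.knockdown is None else self.knockdown.as_dict(),
        }
        text = json.dumps(payload, sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, path) -> "SimTruth":
        with open(path) as fh:
            payload = json.load(fh)
        kd = payload["knockdown"]
        return cls(
            seed=payload["seed"],
            reduction=payload["reduction"],
            fragments=payload["fragments"],
            control=LibraryTruth(**payload["control"]),
            knockdown=None if kd is None else LibraryTruth(**kd),
        )


# ---------------------------------------------------------------------------
# reference construction
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def build_reference(config: SimConfig) -> ReferenceSet:
    """Generate TE consensus, cluster, and miRNA sequences.

    Clusters are assembled by concatenating fragments copied from the TE
    panel.  In ``uni`` mode every fragment is reverse-complemented (the
    cluster transcript is antisense to its source TEs, as for flamenco); in
    ``dual`` mode orientation is random.  Fragment provenance is recorded as
    BED-style intervals on the cluster (0-based, half-open; strand gives the
    fragment's orientation relative to its source TE).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _STREAM_REF]))
    features: list[Feature] = []
    intervals: list[Interval] = []

    te_ids = [f"TE{i + 1:02d}" for i in range(config.n_te)]
    te_seqs: dict[str, str] = {}
    for te_id in te_ids:
        L = int(rng.integers(config.te_length_range[0], config.te_length_range[1] + 1))
        te_seqs[te_id] = _random_seq(rng, L)
        features.append(Feature(te_id, "TE", te_seqs[te_id]))

    for spec in config.clusters:
        parts: list[str] = []
        offset = 0
        for _ in range(spec.fragment_count):
            src = te_ids[int(rng.integers(0, len(te_ids)))]
            src_seq = te_seqs[src]
            frag_len = int(rng.integers(config.fragment_length_range[0],
                                        config.fragment_length_range[1] + 1))
            if frag_len > len(src_seq):
                raise ValueError(
                    f"fragment of length {frag_len} exceeds source TE {src} "
                    f"({len(src_seq)} nt)"
                )
            start = int(rng.integers(0, len(src_seq) - frag_len + 1))
            piece = src_seq[start:start + frag_len]
            if spec.strand_mode == "uni":
                strand = "-"
            else:
                strand = "-" if rng.random() < 0.5 else "+"
            if strand == "-":
                piece = revcomp(piece)
            intervals.append(Interval(
                spec.cluster_id, offset, offset + frag_len,
                name=f"{src}:{start}-{start + frag_len}", score=0.0, strand=strand,
            ))
            parts.append(piece)
            offset += frag_len
        features.append(Feature(spec.cluster_id, "cluster", "".join(parts)))

    for i in range(config.n_mirna):
        features.append(Feature(f"mir{i + 1:03d}", "miRNA",
                                _random_seq(rng, config.mirna_length)))

    return ReferenceSet(features, intervals)


def fragments_as_dicts(ref: ReferenceSet) -> list[dict]:
    return [dataclasses.asdict(iv) for iv in ref.intervals]


# ---------------------------------------------------------------------------
# library generation
# ---------------------------------------------------------------------------


def _sample_lengths(rng: np.random.Generator, n: int, config: SimConfig) -> np.ndarray:
    """Truncated-normal integer lengths inside the piRNA bounds."""
    lo, hi = config.pirna_length_bounds
    out = np.rint(rng.normal(config.pirna_length_mean, config.pirna_length_sd, size=n))
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = np.rint(rng.normal(config.pirna_length_mean, config.pirna_length_sd,
                                      size=int(bad.sum())))
        bad = (out < lo) | (out > hi)
    return out.astype(int)


def _positions_with_first_base(template: np.ndarray, want_t: bool) -> np.ndarray:
    """Start positions whose base is (or is not) T, ascending."""
    mask = template == "T"
    return np.flatnonzero(mask if want_t else ~mask)


def _sample_primary_reads(rng: np.random.Generator, template: str, n: int,
                          config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Sample (pos, length) for n primary reads on one template string.

    The 1U bias is applied by choosing, with probability ``u1_bias``, a start
    position carrying T and otherwise a start position carrying a non-T base,
    so the realized 1U fraction converges to ``u1_bias`` and reads stay exact
    template substrings.
    """
    arr = np.frombuffer(template.encode(), dtype="S1").astype("U1")
    L = len(arr)
    lengths = _sample_lengths(rng, n, config)
    forced = rng.random(n) < config.u1_bias
    pos = np.empty(n, dtype=int)
    t_pos = _positions_with_first_base(arr, True)
    v_pos = _positions_with_first_base(arr, False)
    for l in np.unique(lengths):
        sel = lengths == l
        limit = L - int(l)
        if limit < 0:
            raise ValueError(f"template shorter than read length {l}")
        tp = t_pos[t_pos <= limit]
        vp = v_pos[v_pos <= limit]
        for want, pool in ((True, tp), (False, vp)):
            m = sel & (forced == want)
            k = int(m.sum())
            if k == 0:
                continue
            if len(pool) == 0:
                # degenerate template composition: fall back to any position
                pool = np.arange(limit + 1)
            pos[m] = pool[rng.integers(0, len(pool), size=k)]
    return pos, lengths


@dataclass
class _PrimaryDraw:
    feature_id: str
    template: str          # cluster sense sequence, or revcomp(TE) for TEs
    pos: np.ndarray
    lengths: np.ndarray

    @property
    def n(self) -> int:
        return len(self.pos)

    def sequences(self, mask: np.ndarray | None = None) -> list[str]:
        idx = range(self.n) if mask is None else np.flatnonzero(mask)
        return [self.template[self.pos[i]:self.pos[i] + self.lengths[i]] for i in idx]


@dataclass
class _PingpongDraw:
    te_id: str
    initiator_seqs: list[str]
    responder_seqs: list[str]
    counts: np.ndarray  # per pair site; initiator and responder share it

    @property
    def total_reads(self) -> int:
        return int(2 * self.counts.sum())


def _sample_pingpong(rng: np.random.Generator, te_id: str, te_seq: str,
                     lam: float, config: SimConfig) -> _PingpongDraw:
    """Sample ping-pong pair sites on one TE with shared per-pair rates.

    Each site fixes the initiator 5' coordinate ``a`` on the TE sense
    strand: the responder is the sense read starting at ``a - 9`` and the
    initiator is the antisense read whose 5' nucleotide sits at ``a``
    (exact 10 nt 5' overlap).  With probability ``u1_bias`` the site is
    drawn from positions where the TE carries A, which makes the initiator
    1U and the responder 10A by complementarity.
    """
    if lam <= 0:
        return _PingpongDraw(te_id, [], [], np.zeros(0, dtype=int))
    n_sites = 1 + int(rng.poisson(lam / config.pingpong_site_reads))
    rates = rng.dirichlet(np.ones(n_sites)) * lam
    counts = rng.poisson(rates / 2.0)
    arr = np.frombuffer(te_seq.encode(), dtype="S1").astype("U1")
    L = len(arr)
    lo, hi = config.pirna_length_bounds
    a_min, a_max = hi - 1, L - hi + 9  # valid for any in-bounds length pair
    if a_max < a_min:
        raise ValueError(f"TE {te_id} too short for ping-pong pairs")
    valid = np.arange(a_min, a_max + 1)
    a_sites = valid[arr[valid] == "A"]
    non_a_sites = valid[arr[valid] != "A"]
    init_seqs, resp_seqs = [], []
    keep = counts > 0
    counts = counts[keep]
    n_sites = len(counts)
    forced = rng.random(n_sites) < config.u1_bias
    l_init = _sample_lengths(rng, n_sites, config)
    l_resp = _sample_lengths(rng, n_sites, config)
    # hotspots are kept >= min_sep apart so that 5' products between
    # distinct hotspots cannot fall inside the overlap histogram window
    min_sep = 26
    taken: list[int] = []
    for i in range(n_sites):
        pool = a_sites if forced[i] else non_a_sites
        if len(pool) == 0:
            pool = valid
        a = int(pool[rng.integers(0, len(pool))])
        for _ in range(60):
            if all(abs(a - t) >= min_sep for t in taken):
                break
            a = int(pool[rng.integers(0, len(pool))])
        taken.append(a)
        s = a - 9
        resp_seqs.append(te_seq[s:s + int(l_resp[i])])
        init_seqs.append(revcomp(te_seq[a - int(l_init[i]) + 1:a + 1]))
    return _PingpongDraw(te_id, init_seqs, resp_seqs, counts.astype(int))


def _library_expectations(ref: ReferenceSet, config: SimConfig,
                          rng_weights: np.random.Generator):
    """Expected read counts per miRNA species and per piRNA template.

    Per-template output is proportional to template length times a
    log-normal abundance factor, so TE piRNA levels span orders of
    magnitude as they do in real libraries.
    """
    te_ids = ref.by_class("TE")
    cluster_ids = ref.by_class("cluster")
    mirna_ids = ref.by_class("miRNA")
    phi = config.phi_for(te_ids)

    depth = config.library_depth
    lam_mirna_total = depth * config.mirna_fraction
    lam_pirna_total = depth - lam_mirna_total

    templates = cluster_ids + te_ids
    lengths = np.array([ref.length(f) for f in templates], dtype=float)
    abundance = rng_weights.lognormal(0.0, config.te_abundance_sigma, size=len(templates))
    raw = lengths * abundance
    shares = raw / raw.sum() if raw.sum() > 0 else raw
    lam_templates = lam_pirna_total * shares
    lam_primary: dict[str, float] = {}
    lam_pingpong: dict[str, float] = {}
    for fid, lam in zip(templates, lam_templates):
        if fid in te_ids:
            p = phi[te_ids.index(fid)]
            lam_primary[fid] = lam * (1.0 - p)
            lam_pingpong[fid] = lam * p
        else:
            lam_primary[fid] = lam
    return mirna_ids, lam_mirna_total, lam_primary, lam_pingpong


def _mirna_weights(rng: np.random.Generator, n: int) -> np.ndarray:
    """Heavy-tailed (log-normal) species abundance weights, normalized."""
    w = rng.lognormal(mean=0.0, sigma=1.5, size=n)
    return w / w.sum()


def _draw_library(ref: ReferenceSet, config: SimConfig, streams: dict):
    """Draw all three read classes for one control-condition library."""
    mirna_ids, lam_mirna_total, lam_primary, lam_pingpong = _library_expectations(
        ref, config, streams["weights"])
    weights = _mirna_weights(streams["weights"], len(mirna_ids))
    mirna_counts = streams["mirna"].poisson(lam_mirna_total * weights).astype(int)

    primaries: list[_PrimaryDraw] = []
    rng_p = streams["primary"]
    for fid, lam in lam_primary.items():
        n = int(rng_p.poisson(lam))
        feat = ref.feature(fid)
        template = feat.sequence if feat.feature_class == "cluster" else revcomp(feat.sequence)
        if n > 0:
            pos, lens = _sample_primary_reads(rng_p, template, n, config)
        else:
            pos = np.zeros(0, dtype=int)
            lens = np.zeros(0, dtype=int)
        primaries.append(_PrimaryDraw(fid, template, pos, lens))

    rng_pp = streams["pingpong"]
    pingpongs = [
        _sample_pingpong(rng_pp, te_id, ref.sequence(te_id), lam, config)
        for te_id, lam in lam_pingpong.items()
    ]
    return mirna_ids, weights, lam_mirna_total, mirna_counts, primaries, pingpongs


def _assemble(mirna_ids, mirna_counts, ref, primaries, pingpongs,
              primary_masks=None) -> tuple[ReadSet, LibraryTruth]:
    pairs: list[tuple[str, int]] = []
    mirna_truth = {}
    for mid, n in zip(mirna_ids, mirna_counts):
        mirna_truth[mid] = int(n)
        if n > 0:
            pairs.append((ref.sequence(mid), int(n)))
    primary_truth = {}
    for i, draw in enumerate(primaries):
        mask = None if primary_masks is None else primary_masks[i]
        seqs = draw.sequences(mask)
        primary_truth[draw.feature_id] = len(seqs)
        pairs.extend((s, 1) for s in seqs)
    pingpong_truth = {}
    for pp in pingpongs:
        pingpong_truth[pp.te_id] = pp.total_reads
        for seq_i, seq_r, n in zip(pp.initiator_seqs, pp.responder_seqs, pp.counts):
            pairs.append((seq_i, int(n)))
            pairs.append((seq_r, int(n)))
    reads = ReadSet.from_counts(pairs)
    truth = LibraryTruth(mirna_truth, primary_truth, pingpong_truth)
    if reads.total_count != truth.total_reads:
        raise AssertionError("read/truth mass conservation violated")
    return reads, truth


def _streams(config: SimConfig) -> dict[str, np.random.Generator]:
    ss = np.random.SeedSequence([config.seed, _STREAM_LIB])
    children = ss.spawn(6)
    names = ["weights", "mirna", "primary", "pingpong", "mirna_kd", "thin"]
    return {name: np.random.default_rng(child) for name, child in zip(names, children)}


def simulate_library(ref: ReferenceSet, config: SimConfig) -> tuple[ReadSet, SimTruth]:
    """Simulate one small-RNA library under control conditions.

    ``primary_reduction`` is ignored here; use :func:`simulate_knockdown_pair`
    for perturbed libraries.  Depth 0 yields an empty read set with zeroed
    truth.
    """
    config.validate()
    streams = _streams(config)
    mirna_ids, _, _, mirna_counts, primaries, pingpongs = _draw_library(ref, config, streams)
    reads, truth = _assemble(mirna_ids, mirna_counts, ref, primaries, pingpongs)
    return reads, SimTruth(config.seed, 1.0, fragments_as_dicts(ref), truth)


def simulate_knockdown_pair(ref: ReferenceSet, config: SimConfig
                            ) -> tuple[ReadSet, ReadSet, SimTruth]:
    """Simulate a control/knockdown library pair.

    The control library equals :func:`simulate_library` output for the same
    (config, seed).  The knockdown shares the control's generative draw:
    every primary-pathway read is kept with probability ``primary_reduction``
    (binomial thinning, i.e. expected primary counts multiplied by ``r``),
    ping-pong pairs are emitted unchanged, and miRNA counts are re-drawn
    around the identical expectations.
    """
    config.validate()
    r = config.primary_reduction
    streams = _streams(config)
    (mirna_ids, weights, lam_mirna_total, mirna_counts,
     primaries, pingpongs) = _draw_library(ref, config, streams)

    control, truth_c = _assemble(mirna_ids, mirna_counts, ref, primaries, pingpongs)

    mirna_kd = streams["mirna_kd"].poisson(lam_mirna_total * weights).astype(int)
    rng_thin = streams["thin"]
    masks = [rng_thin.random(d.n) < r for d in primaries]
    kd, truth_k = _assemble(mirna_ids, mirna_kd, ref, primaries, pingpongs,
                            primary_masks=masks)

    truth = SimTruth(config.seed, r, fragments_as_dicts(ref), truth_c, truth_k)
    return control, kd, truth
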