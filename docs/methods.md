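# Methods

## The generative model

`simlib` simulates the small-RNA output of an ovary-like tissue as three
read classes drawn around Poisson expectations that sum to
`library_depth`:

1. **miRNA reads.**  Exact copies of `n_mirna` miRNA species.  Species
   abundances are log-normal (σ = 1.5), giving the heavy-tailed species
   distribution typical of miRNA populations.  miRNAs take
   `mirna_fraction` (default 0.25) of the library and their expectations
   are identical between a control and its knockdown, which is what makes
   them usable as a normalization anchor.
2. **Primary piRNAs.**  Substrings of piRNA-cluster transcripts or of
   antisense TE transcripts.  5′ positions are uniform over the eligible
   template — the underlying profiles are dispersed and no positional
   model is imposed.  Lengths are a truncated normal (mean 26 nt,
   sd 1.5 nt) inside the 23–30 nt piRNA window.  The 1U bias β (default
   0.9) is applied by drawing, with probability β, a start position whose
   template base is U/T and otherwise a start with a non-T base.  Reads
   therefore remain exact reference substrings (mappable with zero
   mismatches) and the realized 1U fraction converges to β exactly, which
   the suite verifies against a binomial error bound.
3. **Ping-pong pairs.**  For TEs with ping-pong fraction φ_t > 0, pair
   *hotspots* are sampled on the TE: the responder is a sense read with 5′
   at `a − 9` and the initiator an antisense read with its 5′ nucleotide at
   `a`, an exact 10 nt 5′ overlap.  With probability β the hotspot is drawn
   from positions where the TE carries A, which makes the initiator 1U and
   the responder 10A *by complementarity* — the sequence is never mutated,
   so responder-10A and initiator-1U fractions are equal by construction.
   Hotspot abundances share one rate per pair (Dirichlet split of the
   TE's ping-pong expectation, ~`pingpong_site_reads` = 40 reads per
   hotspot), and initiator and responder of a hotspot carry the same
   count, so pair mass is well defined.  Hotspots are kept ≥ 26 nt apart
   so that 5′ products between *different* hotspots cannot fall inside the
   25-bin overlap histogram window; without this, a handful of large
   cross-hotspot products dominates the off-bin variance and the z-score
   becomes erratic at small scale (see Limitations).

**References.**  TE consensus sequences are uniform-random ACGT (800–1400
nt).  Clusters are concatenations of TE fragments (150–400 nt): a
*uni-strand* cluster reverse-complements every fragment (its transcript is
antisense to the source TEs, the flamenco geometry), a *dual-strand*
cluster orients fragments randomly.  Fragment provenance is recorded as
BED intervals on the cluster.  Per-template output is proportional to
length times a log-normal abundance factor (`te_abundance_sigma` = 1.0),
so TE piRNA levels span roughly two orders of magnitude as real TE
families do — without this, per-TE scatter correlations would be
meaningless.

**Knockdowns.**  A primary-biogenesis knockdown multiplies the primary
pathway's expected counts by `primary_reduction` = r ∈ [0, 1].  It is
implemented as binomial thinning of the control draw: control and
knockdown share one generative draw, every primary read survives with
probability r, ping-pong pairs are emitted unchanged, and miRNA counts
are re-drawn around identical expectations.  r = 1 reproduces the control
exactly; r = 0 removes the primary class entirely while ping-pong TEs
persist.  Sampling around a shared draw makes the miRNA-normalized global
23–30 nt ratio an unbiased estimator of r, which the suite checks over
seeds for r ∈ {0.1, 0.25, 0.5, 1.0}.

**Determinism.**  All randomness flows from the config seed through named
`numpy` `SeedSequence` streams (reference, miRNA weights, miRNA counts,
primary, ping-pong, thinning); identical (config, seed) pairs give
byte-identical FASTQ and truth JSON, and the control of a knockdown pair
equals the standalone library for the same seed.

## Mapping

Matching is exact (0 mismatches) on consensus-scale panels; this keeps
the mapper equivalent to a brute-force all-substrings scan, which the
suite asserts on random references.  The implementation builds a
substring index per (panel, read-length set) and caches it on the
reference, so mapping a control/knockdown pair pays the indexing cost
once.  Multi-mappers are weighted `count / n_hits`; reads with more than
`max_hits` (default 100) placements are discarded and logged.  The 5′
coordinate of a minus-strand hit is the right end of its matched span —
the biological 5′ nucleotide — which is what makes the overlap arithmetic
`o = a.five_prime − s.five_prime + 1` correct on plus-strand coordinates.

## Normalization and statistics

* **RPMM.**  `factor = 10^6 / mirna_total` with `mirna_total` the weighted
  miRNA-mapped mass.  A library without miRNA-mapped reads is rejected:
  no cross-library statement is meaningful without the anchor.
* **Overlap histogram.**  Pair mass is the product of alignment weights
  (the bilinear choice; oracle-checkable against the all-pairs double
  loop), accumulated per feature — inter-feature pairs are ignored.  The
  z-score background is bins 1–25 excluding 10, sd with n − 1;
  significance is `z10 ≥ 3`.  A zero-variance background yields z = 0
  when bin 10 equals the mean and +inf when it exceeds it.
* **10A bias.**  Weighted fraction of sense TE piRNAs carrying A at
  position 10, against the mean A fraction over positions 2–9 and 11–23
  of the same weighted reads; reads shorter than a position are excluded
  from that position's tally, and positions with no qualifying reads drop
  out of the background mean.
* **Knockdown comparison.**  Per-TE antisense RPMM levels; log2 fold
  changes with a pseudocount of 1 RPMM; Pearson r on log2(level + 1)
  across all TEs (flagged undefined below two nonzero TEs); the global
  ratio is knockdown/control 23–30 nt non-miRNA RPMM mass.  Type-I
  labels: *collapsed* if log2 FC ≤ −2; *pingpong-rescued* if the level
  held up and the per-TE z10 rose by ≥ 2; *unchanged* otherwise.  The
  fold-change and Δz thresholds (and the ±1 log2 soma/germline dominance
  margin) are exposed defaults — the categories are biologically defined,
  the cutoffs are not.
* **Screen statistics.**  Staining is a six-level ordinal
  (none … strong); the "strong range" defaults to the top two levels.
  Per-line efficiency p is the fraction of effective control lines
  (ribosomal-protein knockdowns scored by the rudimentary-ovary
  phenotype), and the gene-level false-negative model `fn(n) = (1 − p)^n`
  assumes line independence; because real lines are not independent, the
  empirical per-gene miss rate is reported alongside the model value
  rather than asserted equal to it.  Group fold-change comparisons report
  median/quartiles with 1.5·IQR whiskers and a two-sided Mann-Whitney
  rank-sum p versus the reference group — the groups being compared
  (staining categories vs control lines) are independent samples of
  different sizes, so an unpaired rank test is the applicable one.
* **Expression binning.**  Genes at or above the RPKM cutoff (inclusive
  ≥, default 1) are ranked and cut into equal-size bins, remainder to the
  top bin; below-cutoff genes form bin 0.

## What the simulator does and does not emulate

It reproduces the features the statistics consume: the piRNA length
window, the 1U/10A complementarity coupling, exact 10 nt 5′ overlaps,
cluster strandedness, heavy-tailed TE and miRNA abundances, and
knockdowns as proportional primary-pathway reduction.  It does **not**
model sequence mismatches or polymorphism, piRNA phasing or trailing-U
trimming, 2′-O-methylation, secondary structure, genomic background
outside the panel, or position-dependent biogenesis preferences.  Passing
tests therefore demonstrate correctness of the statistics under the
model's assumptions, not robustness to mismatch-tolerant mapping or to
genome-scale multi-mapping.

## Numerical and design choices

* U→T normalization on input; 0-based, half-open coordinates everywhere;
  BED strand is authoritative for fragment orientation.
* Coverage profiles record 5′-end mass only (the quantity entering the
  overlap statistic) and keep sense/antisense columns separate so
  coincident 5′ ends on opposite strands do not cancel.
* The expression cutoff is inclusive (≥).
* Truth JSON is a side-car next to the reads; seeds are mandatory and no
  wall-clock entropy is used.
* Degenerate inputs: empty libraries yield empty read sets (not errors);
  a fragment longer than its source TE, a reversed length range, a
  ping-pong fraction for an unknown TE, and r outside [0, 1] are rejected
  with explicit messages.
* Monte-Carlo tests run on a scaled-down panel (4 TEs, two 4-fragment
  clusters, 20 miRNAs, 10k–20k reads) chosen so each property is measured
  at comfortable statistical resolution; the signal-detection check uses
  the full default depth of 50k reads.

## Known limitations

* **TE vs cluster class ambiguity.**  Cluster fragments are exact TE
  copies, so reads from fragment regions multi-map between the cluster
  and its source TE and the per-class weighted split is intrinsically
  ambiguous.  miRNA and aggregate non-miRNA masses match the generative
  truth to < 1%; the TE/cluster split individually does not, and tests
  assert the former.
* **z-score saturation at extreme ping-pong fractions.**  When φ ≳ 0.8
  the control histogram is already almost pure bin-10 mass; the
  knockdown-minus-control z shift (Δz10) becomes small and noisy, so
  ping-pong rescue detection is exercised and validated at moderate
  fractions (φ ≈ 0.5–0.6), where it is reliable across seeds.  Real
  libraries, with far more distinct piRNA 5′ positions, are less prone to
  this small-sample saturation.
* The per-line detection model treats RNAi lines as independent; the
  empirical gene-level miss rate in real screens sits above `(1 − p)^n`.
* Exact matching only: no mismatch policy toward consensus sequences is
  modelled or recoverable here.
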