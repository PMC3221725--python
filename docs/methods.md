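# Methods

`hicfmap` models the complete computational pathway of a BAC-library
physical-mapping project based on four-color high-information-content
fingerprinting (HICF): in-silico restriction digestion and band calling,
fingerprint quality control, Sulston-score overlap statistics, FPC-style
contig assembly with a consensus-band (CB) map, whole-map summary
statistics, and validation of assemblies against simulated ground truth.

## The simulator

### Digestion model

The generator works at the coordinate level, not the sequence level.
Restriction sites of the four labeled 6-bp cutters (EcoRI, XbaI, BamHI,
XhoI — channels 0..3) and of the unlabeled 4-bp cutter HaeIII are drawn
as independent homogeneous Poisson processes along each replicon. A
clone is an interval; its fingerprint is derived from the union of all
five enzymes' sites inside the interval plus the interval boundaries:

- every fragment between consecutive cuts contributes one band per
  fragment end that is a labeled-enzyme site (a fragment cut by 6-bp
  cutters at both ends emits **two** single-channel bands, matching
  channel-wise peak calling on a capillary sequencer);
- fragments touching the interval boundaries stand in for
  vector-junction fragments and are excluded;
- only fragments inside the sizing window (default 50–500 bp, the
  usable range of a 500-marker size ladder) are retained;
- sizes are quantized to 0.1 bp — the precision at which fragment sizes
  are reported and stored, which makes in-memory and on-disk pipelines
  identical — and peak heights are lognormal.

### Parameter defaults and their rationale

| parameter | default | rationale |
|---|---|---|
| genome_length | 10 Mb | two 5-Mb replicons; desk-scale stand-in for a ~1.7 Gb genome |
| n_clones | 710 | ~10× clone coverage at the default insert size |
| insert_mean | 141 kb | the BAC library's mean insert size |
| insert_cv | 0.15 | typical spread of a size-selected BAC library |
| six_cutter_rate | 1.265e-4 /bp/enzyme | see below |
| four_cutter_rate | 4⁻⁴ /bp | naive expectation for a 4-bp site |
| sizing window | 50–500 bp | GeneScan-500-class ladder range |
| size_noise_sd | 0.15 bp | capillary sizing repeatability |
| dropout_prob | 0.05 | weak peaks lost in calling |
| spurious_per_clone | 2 | stray peaks per well |
| artifact fractions | 0.5% each | empty, contaminated, off-scale, vector-only wells (2% total) |
| repeat_fraction | 0.50 | a strong dispersed repeat family present in half the clones |

The six-cutter site density deserves a note. The naive expectation for
a 6-bp palindrome is 4⁻⁶ ≈ 2.44e-4 per bp, but three of the four
enzymes' sites contain CG dinucleotides, which are strongly
under-represented in AT-rich vertebrate genomes; observed HICF band
yields correspond to a much lower effective density. The default is
calibrated so that the closed-form expectation of the band count
(`expected_bands_per_clone`) is ≈ 98.5 bands for a 141-kb insert:

    E[bands] = 2 · (4·r₆) · L · (e^{−λ·50} − e^{−λ·500}),   λ = 4·r₆ + r₄

Every fragment end at a labeled site is a potential band (factor 2·4·r₆·L)
and survives if the Exponential(λ) fragment length falls in the window.
With this default, most clones carry 60–120 bands (≈ 94%; local site
density varies along the genome, so the distribution is wider than
Poisson) and one band represents ≈ 1.4 kb.

### Planted artifacts

After sizing noise, dropout and spurious-band injection, clone-level
artifacts are planted and recorded in the truth labels: empty wells;
**contaminated** wells, whose band set is unioned with a clone drawn
from the *same plate* (well-to-well cross-contamination is a liquid
handling phenomenon, which is also what makes a plate-local QC check
meaningful); off-scale wells (all peak heights above the saturation
threshold); vector-only wells (no insert); a constant vector band
family added to every clone; and a repeat band family added to half the
clones. The generator is fully reproducible from its seed.

### What the simulator does not model

Electrophoretic mobility artifacts, dye-dependent shifts, +A addition,
partial digestion, GC-gradient site densities, and sequence-level
effects (the coordinate model has no sequence). Passing tests therefore
certify the pipeline's statistical and algorithmic behavior on an
idealized but structurally faithful library — not instrument-specific
behavior on real chromatograms.

## Quality control

The cascade runs in a fixed order:

1. **Frequent-band removal.** Fragment-frequency analysis per channel:
   a sliding window of width 2 × tolerance is scanned over the sorted
   band values; while the most frequent window contains bands from more
   than `frequent_band_fraction` (default 30%) of clones, that window's
   bands are removed everywhere and the scan repeats. Iterative window
   removal is required at realistic coverage: pooled band values of a
   few hundred clones chain into one cluster under single-linkage at
   any usable tolerance, and per-window clone counts fluctuate to ~20%
   by chance (each genomic fragment is carried by ~coverage clones at
   once), so the threshold must sit above that ceiling and below the
   ≥50% frequencies of vector/repeat families. Removal runs first so
   that vector bands can neither rescue nor doom clones near the
   band-count thresholds.
2. **Per-clone screening**, in order: empty wells dropped; off-scale
   bands (height > 6,000 RFU, strict) removed individually; clones with
   fewer than 50 or more than 250 remaining bands dropped; clones with
   more than 60 bands in any single channel dropped. All thresholds are
   strict inequalities.
3. **Cross-contamination.** For same-plate pairs, similarity = shared
   bands / smaller band count (channel-aware, at the size tolerance).
   A pair is flagged when similarity ≥ 0.8 **and** either the larger
   fingerprint has ≥ 1.5 × the smaller's bands (the union signature of
   a well that received foreign DNA on top of its own insert) or the
   shared bands also cover ≥ 0.8 of the larger (a duplicate/full
   replacement). The second condition is what distinguishes
   contamination from genuine deep overlaps, which are common between
   same-plate clones in a deeply covered library; without it, at
   desk-scale genome sizes the bare similarity rule removes a third of
   all clones. Both members of a flagged pair are removed — the source
   well cannot be identified with certainty. Measured on simulation,
   recall of planted contamination is 100%; the precision cost is a few
   genuine near-duplicate placements per plate.

The report reconciles exactly (input = survivors + per-rule drops) and
the cascade is idempotent.

## Overlap statistics

Shared bands are counted per channel by a greedy two-pointer sweep over
the sorted size lists (match when within tolerance, each band used
once). For threshold matching of points on a line this greedy attains
the maximum bipartite matching (exchange argument on the two least
heads); the test suite cross-checks against an independent maximum
matching oracle.

The Sulston score — the probability that two unrelated clones share at
least the observed number of bands by chance — is the binomial tail

    p = 1 − (1 − 2t/G)^{n_H},    S = Σ_{k=m}^{n_L} C(n_L,k) p^k (1−p)^{n_L−k}

with tolerance t = 0.4 bp and G = 1800 effective band positions
(4 channels × 450 bp window). G is a model constant of the chance-match
probability, exposed as configuration. The tail is accumulated in log
space (`gammaln` + `logsumexp`), exact down to 1e-300 (smaller values
report as 0.0); a Monte-Carlo simulation of the uniform null and
scipy's binomial survival function serve as independent cross-checks in
the tests. Note the score is capped by the smaller clone's band count:
a 35-band fingerprint can never reach 1e-40 against any partner, and
~60% overlap of typical 100-band clones is needed to cross 1e-40.

All-pairs scoring buckets band values at tolerance granularity per
channel, so two bands within tolerance always fall in the same or
adjacent buckets; candidate generation is lossless with respect to the
brute-force scan (asserted in tests).

## Assembly

The schedule follows fingerprint-contig practice:

1. initial contigs = single-linkage connected components at the
   stringent cutoff 1e-40;
2. seriation and CB map per contig (below), Q-clone flagging;
3. DQer: contigs with > 15% Q-clones are dissolved and re-clustered at
   cutoff × 1e-5 per round, up to 3 rounds; still-unplaced clones
   become singletons;
4. end-to-end merging over the relaxing schedule 1e-35 … 1e-15: the
   best-scoring pair of contig ends (best score among the 2 terminal
   clones of each end) merges while at or below the current cutoff; a
   merge whose re-seriated result would exceed the 15% Q fraction is
   rejected;
5. single-to-end attachment of singletons at the final cutoff 1e-15.

Every tie-break is total (score, then lexicographic ids), so identical
inputs yield byte-identical assemblies.

### Seriation and the consensus-band map

Ordering the clones of a deep-coverage contig from band content alone
is the hard part of fingerprint mapping. Two design facts drive the
implementation:

- Raw pairwise similarity is **not** monotone in start-coordinate
  distance when insert lengths vary (a longer clone starting farther
  away can share more bands than a shorter nearer one), so similarity-
  based orderings are systematically confounded. The quantity
  d = (n_A + n_B)/2 − m is, up to band-density fluctuations, the
  distance between clone **midpoints** in band units. A Gaussian
  affinity on d restores the banded (Robinson) structure, and the
  Fiedler vector of the affinity Laplacian gives a robust global 1-D
  order. Affinities are kept only for genuinely scored pairs: adding
  chance-level pairs would swamp the tiny Fiedler eigenvalue
  (~(π/n)²) of a long clone chain with weak long-range links.
- The same band size recurring in two separated regions is two
  different restriction fragments. CB classes are therefore built by
  single-linkage clustering of band values per channel at the
  tolerance, then **split into positional runs** wherever the ranks of
  consecutive carrying clones jump by more than `cb_split_gap`
  (default 3) positions. Each run is one consensus band, positioned at
  the median rank of its carriers.

The order is then refined to a fixed point: clones re-sort by robust
order statistics of their runs' positions (the `key_order_stat`-th
smallest/largest, default 4th — the extreme statistics are corrupted by
residual band-size collisions, which occur at ~0.27 per fragment at
0.4-bp tolerance over 1800 positions), and runs/keys recompute, up to
15 iterations. The final CB count is the number of runs; a clone's CB
interval is the rank span of its runs; the final (left, right) keys are
stored as the contig's `order_keys`.

**Resolution limit.** Clones sharing their leftmost consensus band
(equal left key) start within the same inter-cut gap and cannot be
ordered from band content by any method; ~1.6% of adjacent clone pairs
at 10× coverage are in this class. Together with collision-corrupted
ranks this bounds achievable ordering: on noiseless 10× simulations the
mean |Spearman| between clone order and true position is ≥ 0.999, but
zero-discordance ("perfect") order over a few-hundred-clone contig is
only achieved for a minority of contigs. This mirrors real fingerprint
maps, where clone order inside contigs is treated as approximate and
verified externally (PCR, linkage anchors) — which is exactly what the
evaluation module's junction and marker checks model.

### Q-clones

A clone is flagged Q when fewer than half its bands match the pooled
bands of its immediate neighbors in the contig order (in a 2-clone
contig, the other clone). Q fractions drive the DQer and merge
rejection as above.

## Map statistics

`report` computes the standard summary table: clone/contig counts,
mean clones and CB per contig, kb-per-band = mean insert size / mean
band count, contig physical lengths = CB × kb-per-band, N50 (length at
which the descending cumulative sum first reaches half the total, plus
the count of strictly longer contigs), total assembled length, per-
assembled-clone CB and kb, and the distribution of Q-clones per contig
(buckets 0, 1, …, 5, >5).

Rounding conventions are fixed per field: kb-per-band truncated (not
rounded) to 3 decimals; per-contig means half-up to 2 decimals; CB
means to the nearest integer; percentages of contigs half-up to 1
decimal; pass rate to the nearest integer percent; total length to 3
significant figures in Gb; per-assembled-clone CB truncated to 1
decimal. These conventions reproduce a published statistics table
exactly from its aggregates and are kept stable so the same inputs
always print the same table. Genome coverage requires an external
genome-size constant and is reported, never asserted.

## Evaluation against truth

- **Chimera label**: a contig is non-chimeric iff all member clones lie
  on one replicon and the union of their true intervals is one
  connected block (inter-clone gaps ≤ `gap_kb`, default 0).
- **Junction validation** (the in-silico analog of PCR across a merge
  junction): every end-to-end merge in the provenance log is true iff
  the two joined end clones' true intervals intersect.
- **Order accuracy**: a non-chimeric contig is perfectly ordered up to
  reflection iff it has no discordant pair in one of two readings —
  forward, pairs with distinct left `order_keys` must ascend in true
  start; reflected, the same pairs must descend in true **end** (a
  reflected map's coordinate is an affine image of the genome end, so
  that is what its order sorts by; with varying insert lengths the two
  readings differ). Clones tied on the left key are mutually unordered
  by the data and excused. Mean |Spearman| is reported alongside.
- **Marker consistency** (the analog of linkage-group anchoring):
  uniform marker points are dropped on the genome; a contig holding ≥ 2
  markers is consistent iff they lie on one replicon within 1.5 × the
  contig's true span.
- **Clone-assignment recall**: fraction of clones having a ≥ 40%
  (of the smaller insert) true overlap partner that are co-assembled
  with at least one such partner.

All metrics are invariant under contig relabeling and reflection.

## Problem sizes used by the test suite

The end-to-end fixtures use a 10 Mb genome (two 5 Mb replicons) at ~10×
clone coverage (710 clones), once noiseless and once with default noise
plus 2% planted artifacts; module tests use 1.5–3 Mb genomes at 5–10×.
These sizes exercise every stage — multi-hundred-clone contigs,
coverage gaps, merging, DQer — while keeping the full suite fast.

## Known limitations

- Coordinate-level simulation cannot express sequence-dependent biases
  (site clustering, partial digestion, GC gradients).
- The seriation resolution limit above: contig-internal clone order is
  near-perfect by rank correlation but not guaranteed discordance-free
  on deep-coverage contigs.
- The contamination check trades a small precision loss (genuine
  near-duplicate same-plate placements) for full recall.
- CB counts undercount distinct fragments slightly when distinct
  fragments collide in size within one region (no positional split
  possible); at moderate coverage the CB count tracks the true span to
  within ~15%.
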