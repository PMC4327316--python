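# Methods

This note documents the models behind `clonemap`, the defaults and why they
were chosen, what the synthetic-data generator does and does not emulate,
and the numerical conventions that affect results.

## Substrate geometry

The substrate is a rows × cols grid of microwells.  The `hex` layout
emulates an etched fibre-optic bundle: odd rows offset by pitch/2, row
spacing pitch·√3/2, so every pair of neighbouring centres is exactly one
pitch apart.  World coordinates are micrometres, 0-based, y increasing
downward (the image-raster convention; using the same handedness in world
and pixel space means registration transforms never need a reflection).
The default pitch of 50 µm is a placeholder consistent with a ~30 µm bead
in its own well; the true substrate pitch is instrument-specific and every
entry point takes it as a parameter.  `nearest_well` queries are backed by
a k-d tree with exact ties broken toward the smallest row-major well id,
making assignment deterministic.

## Registration

**Transform family.**  Each fit is a 4-DOF similarity — uniform scale s,
rotation θ, translation — which two point correspondences determine
exactly: s is the ratio of segment lengths, θ the angle between the
segments, the translation pins the first point.  Reflections are excluded:
the chip cannot flip in the instrument.

**Global baseline.**  One two-point fit applied to every read, each mapped
point snapped to its nearest well.  Residuals are measured in the well-map
frame and divided by the fitted scale, so the assignment threshold
(default 13.5 px) is expressed in pixels regardless of camera
magnification.  Reads over threshold stay unassigned; when two reads claim
one well the smaller residual wins and the loser is flagged `collision`
(the platform is one bead per well, so collisions mean mapping stress, not
biology).

**Local algorithm.**  The pixel bounding box is partitioned into nx × ny
subdomains whose extended bounds overlap; a full-density chip uses the
classic 20 × 15 = 300 partition, and the desk-scale default is 8 × 6 so
each cell still holds tens of beads.  Starting from the subdomain holding
the two externally verified seed beads, a breadth-first wave crosses the
4-connected subdomain lattice.  BFS (rather than any scan order) minimises
the reference-chain length from the verified seed, limiting accumulation of
hand-off error.  Each subdomain fits its own two-point similarity from the
pair handed to it, assigns the reads in its core cell, and for every
unvisited neighbour selects a new reference pair from the shared overlap:
candidates must be ok-assigned with residual below 0.25 × threshold (only
confident assignments may anchor a neighbour), and among candidates the
most widely separated pixel pair wins (the widest lever arm minimises
extrapolation error of the neighbour's fit), with exact ties broken by read
id.  Subdomains that never receive a trusted pair are flagged `failed` and
their reads left unassigned — mark-and-continue, so one bald region cannot
abort a whole-chip run.  The algorithm contains no randomness: identical
inputs give identical output.

**Overlap fraction.**  Adjacent extended bounds must share enough beads to
yield two trusted references.  At full chip density (~300 beads per
subdomain) a 0.10 overlap suffices; the desk-scale defaults and benchmark
scenarios use 0.20 because ~12 beads per subdomain would otherwise leave
overlap strips with fewer than two candidates too often.

## Synthetic runs

The generator emulates, with full ground truth:

* **Design pools** — uniform-random ACGT sequences, default 120 nt.
* **Abundance bias** — weights with an exact max/min ratio B (default 10),
  log-uniform between pinned endpoints (or a two-class mixture); the
  realised bias equals B exactly by construction.
* **Synthesis errors** — independent per-base substitution / insertion /
  deletion, totalling 1/70 per base by default (split 60/20/20), matching
  typical microarray-pool quality.  Every injected edit is recorded, so the
  expected error-free fraction (1 − 1/70)^120 ≈ 0.178 and the per-base rate
  are testable against truth.
* **Sequencing errors** — substitutions at 0.001 per base and
  homopolymer-driven indels: a run of length L suffers an indel with
  probability min(1, 0.004 · 2^(L−1)), the geometric escalation standing in
  for flow-signal saturation on long runs.  A per-read lognormal rate
  multiplier (σ = 0.6) produces the read-quality spread of a real run, and
  per-base qualities Phred-encode the realised per-base error probability
  (integer 0–40, Phred+33 in FASTQ), with small Gaussian jitter.  The
  defaults give ~1% total error dominated ~4:1 by indels, the familiar
  profile of flow-based pyrosequencing.
* **Distortion** — pixel = S(world) + radial + warp(world): a global
  similarity (camera scale/rotation/offset), an optional radial term
  k1·r² + k2·r⁴ about a stated centre (normalised radius), and a random
  smooth warp: i.i.d. N(0,1) node vectors on a grid of spacing one
  correlation length, cubic-spline interpolated, rescaled so the maximum
  displacement equals the stated amplitude (realised to <0.5%, the spline
  overshoot between dense normalisation probes).  Deterministic per seed.
* **Chip images** — a Gaussian spot at every well's distorted pixel
  position (the raw image shows the substrate, occupied or not), additive
  Gaussian noise, 16-bit range; the renderer can also cut overlapping
  tiles with small integer offset jitter for stitching tests.

Not emulated (out of scope by design): flowgram signals, emulsion-PCR
duplication statistics, polyclonal (mixed-template) wells, optical
crosstalk between wells, illumination gradients.  Passing tests on this
generator therefore demonstrate the algorithms' behaviour under smooth
distortion and the stated error models, not instrument-level fidelity — no
claim is made that the simulated distortion field matches any particular
sequencer.

## Benchmark scenarios

`clonemap.scenarios` freezes the study conditions the claims are tested
under.

* **Similarity scenario** — 100 × 100 wells, 10% occupancy, camera = pure
  similarity (scale 1.1, rotation 3°).  Two-point fits interpolate a
  similarity exactly, so both algorithms must assign 100% of reads
  correctly; anything less is a defect.
* **Warp scenario** — 120 × 120 wells, 10% occupancy (1,440 beads), camera
  scale 0.25 px/µm (12.5 px well pitch), plus a fixed radial term
  k1 = 0.016 and a random smooth warp of amplitude 2 px (correlation
  1,000 µm).  The radial term is the systematic part of the distortion and
  gives the global baseline a seed-independent failure floor (chip corners
  displace by about one pitch); the random warp varies chip to chip.  The
  two components were calibrated once so that the one-step global fit
  typically misassigns 10–30% of reads (mean ≈ 16% over 20 seeds, range
  1–34%) — the regime the local algorithm exists for.  A purely random
  warp cannot be calibrated into that band per-seed: the global fit's error
  is dominated by the warp value at the two reference beads, a single
  random draw that swings the per-seed fraction between ~0 and ~80%.
  Under the frozen conditions the local algorithm beat the global one in
  20/20 seeds and stayed at ≤1% misassignment in 20/20.
* **Quality scenario** — substitution-only synthesis errors at 1/70 with
  the default sequencing-error model, 1,000 reads.  This is the regime the
  substitution-vs-indel analysis addresses: synthesis errors surface as
  substitutions, sequencing errors mostly as homopolymer indels.  The
  substitution-only ("red") correct fraction then tracks molecule quality
  while the strict ("blue") fraction additionally loses reads to
  sequencing indels, so the red−blue gap shrinks as read quality rises.

"Misassignment" throughout is the fraction of reads *not* ok-assigned to
their true well: wrong-well, over-threshold and failed-subdomain reads all
count as losses.

## Selection and analytics

Reads are matched to designs by exact hash lookup first, then global
alignment (unit edit costs) against candidates sharing a 12-mer seed with
the read (falling back to the whole pool when no seed hits); distance ties
break toward the smaller design id.  Reads beyond edit distance 15
(~12.5% of a 120-nt insert) are `unmatched` rather than force-assigned.
Alignment decomposition into substitutions/insertions/deletions follows
the aligner's deterministic traceback; on simulated truth it reproduces
the injected decomposition for ≥99% of reads, with the remainder differing
only in decomposition (never total distance) on ambiguity.  Adapter
trimming removes a full adaptor occurrence with ≤1 mismatch from each end;
indel-containing adaptors are not modelled.

Quality groups are equal-count terciles (configurable) of matched reads by
mean Phred quality.  The per-base error rate is total edits over aligned
bases, rendered "1 in ⌊1/rate⌉ bp"; fold improvement is the ratio of two
such rates (infinite, flagged, when the denominator rate is zero — the
desk-scale pipeline reaches this state because selected perfect reads
almost always sit on perfect molecules).

Target selection keeps, per design, up to k wells among perfect ok-mapped
beads, ordered by ascending mapping residual; designs with fewer than k
such beads are kept and flagged `under_replicated`, designs with none are
listed `missing`.

## Picking statistics

All probability arithmetic is in log space (`expm1`/`log1p`), so regimes
like n = 10³, N = 10⁴ are exact.  `min_pickings` inverts the analytic
formula and then scans integers locally, so floating-point boundary cases
cannot shift the returned N.  The independence treatment `P^n` upper-bounds
the exact inclusion–exclusion probability (missing events are negatively
correlated); the Monte Carlo simulator draws multinomial colony counts
(optionally biased) and thins picks by the correct-colony fraction f, and
converges to the exact value, not the bound.  The inclusion–exclusion
oracle is guarded to n ≤ 10⁴, where its alternating sum is numerically
tame.  The bias-and-error regime (B > 1, f < 1) is reported as simulation
output only; its answer depends on the assumed abundance distribution,
which the simulator exposes as a parameter.

## Retrieval planning

Stage calibration is a closed-form least-squares similarity (≥2 fiducials)
or affine (≥3, non-collinear) fit with its RMS residual reported.  Shot
ordering is boustrophedon by well row (default) or greedy nearest
neighbour; destinations fill 96-well plates row-major A1→H12 with
rollover.  The duration estimate divides shot count by the instrument rate
(default 2 wells/s).  The radiation-force utility computes
F = (1+R)·η·E/(c·τ) and J = F·τ; published instrument-scale force/impulse
pairs imply an effective coupling η ≈ 0.01 at 50 µJ / 7 ns, so η is an
explicit parameter with default 1 and no acceptance claim is attached to
these numbers.

## Reporting conventions

Percentages are 100·a/b rounded **half-up** to the stated decimals (the
convention under which 1060/1108 prints as 95.67 and 5188/10634 as 48.8).
Every run is a pure function of (config, seed): child seeds are drawn once
from the master seed, artifacts are written with fixed float formats, and
repeat runs are byte-identical except the timing block of the report.

## Problem sizes

The shipped defaults are desk-scale, chosen so the whole pipeline and the
full test suite run in seconds on one core: 10⁴ wells / 10³ designs / 10³
beads for the end-to-end run, 1.4–2.2 × 10³ beads for the registration
benchmarks, 10⁵ Monte Carlo replicates for picking-statistics checks at
n ≤ 10.  A full-scale chip (10⁶ wells, 10⁵ reads, 300 subdomains) uses the
same code paths with larger configuration values.

## Known limitations

* The local algorithm needs two trusted beads per overlap strip; extremely
  sparse plates or very fine subdomain grids starve the propagation (the
  failed-subdomain diagnostics make this visible).
* Classification assumes one design per read; chimeras and mixed-template
  wells are not modelled or detected.
* The greedy shot ordering is a heuristic, not a TSP solution.
* The simulator's distortion field is a stand-in with convenient knobs, not
  a fitted model of any real imaging train.
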