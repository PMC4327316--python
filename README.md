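# clonemap

Registration, perfect-clone selection and retrieval planning for clonal-bead
sequencing substrates.

## The problem

Microarray-synthesised oligonucleotide pools are cheap and massively
parallel, but each ~120-nt oligo carries synthesis errors at roughly one per
70 bases, so only a minority of molecules are perfect.  A bead-based
sequencer (PicoTiterPlate-style: one clonal bead per etched microwell) reads
every molecule in the pool *and* reports the CCD pixel position each read
came from.  If the pixel positions can be registered onto the physical well
map, the sequence-perfect beads can be picked out individually — for
example with a focused laser pulse that ejects a chosen bead from its well —
turning a sequencer into a molecular sorting machine and replacing random
colony picking entirely.

The obstacle is the sequencer's imaging train: its distortion is smooth but
non-linear, so a single similarity transform fitted from two reference
beads places a substantial minority of reads in the wrong well.  `clonemap`
implements the fix: a **diffusion-like local mapping algorithm** that
partitions the chip into overlapping subdomains (the distortion is
approximately linear at subdomain scale), anchors one subdomain with two
externally verified reference beads, and propagates two-point similarity
fits breadth-first across the subdomain lattice, each subdomain handing a
fresh pair of confidently mapped beads to its neighbours.

The package also quantifies why this beats the conventional route.  For a
library of `n` equally abundant species, the probability that one given
species appears among `N` random colony picks is

    P = 1 − (1 − 1/n)^N

and the whole-library recovery probability is `P^n` (treated as
independent; the exact inclusion–exclusion value
`Σₖ (−1)^k C(n,k)(1−k/n)^N` is provided as an oracle, and a Monte Carlo
simulator adds abundance bias and synthesis error).  For `n = 1000`,
reaching 95.6% recovery requires `N = 10,004` pickings — while a single
sequencing run enumerates every bead on the plate.

## What is in the package

| module | contents |
| --- | --- |
| `clonemap.plate` | microwell-grid geometry (hex/square), nearest-well queries, well-map TSV |
| `clonemap.simulate` | synthetic runs with full ground truth: design pools, abundance bias, synthesis errors (1/70 per base), homopolymer-biased pyrosequencing reads with Phred qualities, smooth non-linear pixel distortion, rendered chip images |
| `clonemap.imaging` | tile stitching (phase correlation) and sub-pixel well-centre detection |
| `clonemap.mapping` | two-point similarity fits, the global one-step baseline, the subdomain-propagated local algorithm, diagnostics |
| `clonemap.seqselect` | adapter trimming, read-vs-design classification (substitution vs indel), perfect-target selection with replication policy, error-rate and quality-group analytics |
| `clonemap.pickstats` | colony-picking recovery: analytic model, exact oracle, inverse solver, Monte Carlo |
| `clonemap.planner` | stage calibration, shot-list ordering, 96-well destination layout, retrieval-duration estimate, radiation-force utility |
| `clonemap.pipeline` / `clonemap.cli` | end-to-end orchestration and the `clonemap` command |

## Worked example

A full desk-scale run (10,000 wells, 1,000 designs, 1,000 beads):

```
$ clonemap run --seed 7 --out out/
designs: 1000  with perfect bead: 87 (8.7%)
beads selected: 87  error rate: 1 in 48 bp
report: out/report.json
```

The report shows what the run did: the one-step global registration
misassigned 8.1% of reads under the configured non-linear distortion while
the local algorithm misassigned 0.0%; of 1,000 sequenced beads, 92 reads
were sequence-perfect, covering 87 distinct designs, and those 87 wells
became an ordered shot list (estimated 43.5 s at 2 wells/s).  The observed
per-read error rate of "1 in 48 bp" combines the 1/70 synthesis rate with
the simulated sequencing errors; the selected beads' molecules carry zero
synthesis errors in this run, so the truth-based fold improvement is
reported as infinite.

The picking-statistics comparison as a standalone command:

```
$ clonemap stats -n 1000 -N 10004 --reps 2000 --seed 1
{
  "recovery_analytic": 0.9560032793400927,
  "recovery_exact": 0.9559936328469183,
  "recovery_simulated": 0.958,
  ...
}
```

The analytic independence treatment (0.95600) and the exact
inclusion–exclusion value (0.95599) agree to four decimals at this n/N, and
the simulation's 95% CI covers both.

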