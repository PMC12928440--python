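# Methods

## Scope and model

`wgdkit` reconstructs the duplication and rearrangement history of a
polyploid grass genome from gene-level evidence. The underlying model
is the standard one for grass comparative genomics: all extant grass
karyotypes descend from a 12-chromosome ancestor (chromosomes A1–A12);
whole-genome duplications (WGDs) leave peaks in the distribution of
synonymous divergence (Ks) between paralog pairs; descending dysploidy
proceeds mainly by nested chromosome insertion (NCI), which fuses two
chromosomes into one and leaves a diagnostic outer–inner–outer ancestry
pattern; and synteny with diploid relatives exposes cumulative ploidy as
a depth ratio (one diploid chromosome ↔ 2^w chromosomes of a genome
with w subsequent WGDs, before fractionation).

## Homolog detection

Similarity hits are consumed as BLAST tabular (outfmt 6), parsed
positionally with extra columns ignored. Filters, applied per hit:
e-value strictly below 1e-5, percent identity ≥ 70, HSP length ≥ 60 bp.
The repeat rule is per gene: a CDS whose soft-masked (lowercase)
fraction strictly exceeds 0.25 removes every hit touching it. "Length"
is HSP length, not summed aligned length; multiple HSPs per gene pair
collapse to the max-bitscore HSP before any best-hit logic. Strict
reciprocal best hits (max bitscore; ties broken by lower e-value, higher
identity, lexicographic subject id) serve ortholog tables. The synteny
stage instead consumes *reciprocal hit pairs* — every gene pair
supported by a filtered hit in both directions — because strict 1:1
best hits cannot express the 1:4 homeolog multiplicity that WGDs create;
the same-chromosome multicopy filter (below) then removes tandem-array
noise from that larger set.

## Divergence estimation (ks_clock)

Pairs are aligned at the protein level (global Needleman–Wunsch,
BLOSUM62, gap open −10, extend −0.5, via Biopython's PairwiseAligner)
and the alignment is threaded back onto codons, so gaps are whole
codons and removing gap columns restores the inputs. Internal stops are
tolerated but flagged; stop-containing and ambiguous columns are
excluded from counting.

The Nei–Gojobori (1986) estimator is implemented from first principles
on integer codon indices with precomputed 64×64 tables:

* synonymous sites per codon = Σ over the three positions of the
  fraction of single-base changes preserving the amino acid. Changes
  creating a stop codon count as nonsynonymous, which keeps the
  identity S + N = 3 per compared codon exact.
* differences between codons are averaged over all orderings of the
  separating single-base steps; steps into or out of a stop
  intermediate count as nonsynonymous, and pathways through stops are
  *not* pruned. (codeml's NG86 drops stop-mutations from the site
  denominator; the resulting discrepancies are small and documented
  here rather than chased.)
* Jukes–Cantor correction d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 is reported
  as a saturation flag, never a number.

Ks values outside [0.01, 3) are filtered before distribution modeling:
the lower bound removes allelic/near-identical copies, the upper bound
saturated estimates.

## Mixture dating and the clock

The filtered Ks vector is modeled as a 1-D Gaussian mixture fitted by
EM (sklearn GaussianMixture, full covariance, 5 initializations). The
convergence criterion 0.001 applies to the change in *total*
log-likelihood between iterations (the mixtools convention); since
sklearn's `tol` is per-sample, the implementation passes `0.001/n`.
This matters: with the raw value, EM on a 3000-point three-peak profile
stops about nine iterations in and the wide ancient-WGD component is
biased ≈ +0.02. The number of components is chosen by BIC over k ∈
[1, 5]; the paper-trail default range can be restricted. Uncertainty
comes from refitting bootstrap resamples (with replacement, k fixed,
warm-started at the point estimate; default 1000 replicates) and is
reported as the per-component standard deviation of means.

A peak (mean m, stdev s) converts to a divergence window by the strict
molecular clock T = Ks/(2µ), µ = 6.5e-9 substitutions/site/year (the
standard monocot synonymous rate), evaluated at m − s, m and m + s,
rounded half-up to 0.1 My. A negative lower bound is floored at zero
and flagged. "Mode" of a peak is the fitted component mean, not a
kernel-density mode.

## Synteny

Gene positions are ranks along chromosomes (BED input is ranked by
start coordinate). Pairs where a gene has ≥ 2 homologs on a single
partner chromosome are removed (both directions). Chaining runs per
(chromosome pair, orientation): ascending and descending partner-rank
progressions are chained separately, so inverted blocks are distinct.
A chain requires strictly monotone ranks on both genomes and at most
`max_gap` intervening genes (rank difference − 1) on *each* genome —
the stricter both-genomes reading, switchable in principle but fixed
here. The chain extractor is an exact O(n²) longest-chain DP with
canonical tie-breaks (first index among maxima), peeled iteratively
until no chain of ≥ `min_pairs` (default 5) remains; this objective
("maximize chained pairs, sparse DP") was chosen over greedy extension
because it is exactly reproducible by an independent brute-force
oracle. Defaults: min_pairs 5, max_gap 100 for discovery, 20 for
painting-grade blocks.

A caveat the test suite makes explicit: iterated longest-chain peeling
is not globally optimal, so the total chained-pair count is not
*guaranteed* monotone as `max_gap` tightens — on adversarial uniform
noise a loose-gap chain occasionally bridges two local runs and
fragments the remainder (≈ 1–3% of random tables). On genome-like
inputs (simulated WGD + fractionation histories) no violation was
observed in 150 varied runs, and the stringency-sweep property is
asserted on such inputs.

Syntenic depth counts, per reference chromosome, the distinct partner
chromosomes covered by ≥ 1 block (self-pairs excluded in
self-comparisons); the modal depth summarizes the genome (ties resolve
to the smaller depth). Pseudochromosome assembly assigns each scaffold
to the reference chromosome holding the plurality of its chained pairs,
ties toward the lower-numbered chromosome and flagged; scaffolds with
no blocks are listed unplaced. The dotplot exporter emits both rank
coordinates and a closed-open Ks-band label per pair.

## Karyotype painting

A chromosome homology table in ancestral layout (one row per A1–A12,
one comma-separated chromosome list per species) is inverted into
per-species chromosome → origin-set maps; the Poaceae table for
O. sativa, S. bicolor, E. tef, O. thomaeum, Z. japonica and
S. alterniflorus ships as package data. Every comparator hit of a focal
gene contributes its bitscore to the implied origins — split equally
when a chromosome maps to several ancestral chromosomes — and the
masses are normalized by total bitscore into an empirical origin
distribution.

Bootstrap: each of 1000 replicates draws m labels (m = number of
contributing hits, preserving the gene's evidence weight) from that
distribution; an origin's support is the fraction of replicates where
it is the *strict* plurality (ties support no origin). A gene is
painted uniquely iff best support ≥ 0.5 and the margin over the
runner-up ≥ 0.05; otherwise it is ambiguous and all supported origins
are retained as candidates. The estimator is exactly the multinomial
strict-plurality probability, verified by enumeration for small m;
note a single 1000-replicate bootstrap has binomial noise ≈ 0.015, so
point comparisons tighter than that need averaging over runs.

Block validation paints along syntenic blocks rebuilt at gap ≤ 20: the
block origin is the shared origin of unambiguous members; ambiguous
members inherit it when it is among their candidates; disagreement
among unambiguous members splits the block at the disagreement point.
Sliding windows (10 genes) with ambiguous fraction > 0.5 are excised as
transition zones (both parameters configurable). Gene-level origins are
then collapsed into painted segments per chromosome; runs shorter than
5 genes are dropped as noise and flanking same-origin runs merged.

Event calling reduces each chromosome's segment pattern: X…Y…X triples
emit NCI(Y into X) and collapse, innermost first (A2-A10-A12-A10-A2
yields NCI(A12→A10) then NCI(A10→A2)); residual multi-origin junctions
are end fusions, upgraded to translocations when the reciprocal
truncation appears on another chromosome, and flagged unresolved when
one-sided. Stage karyotypes follow from event multiplicities across
homeologous copies: events in ≥ 3 of the four copies predate WGD1
(n_pre-WGD1 = 12 − #shared), the rest fall between the WGDs
(n_pre-WGD2 = 2·n_pre-WGD1 − #specific); translocations leave counts
unchanged. The ≥ 3 threshold tolerates one fractionated-away copy.

## The simulator

`simulate_scenario` applies an ordered event script (WGD, NCI,
translocation, fractionation, divergence, speciation) to a single
evolving lineage; speciation snapshots the genome and applies terminal
divergence to the snapshot. The packaged scenario
(`sect_spartina_scenario`) replays the cordgrass history: two ancestral
NCIs (A10→A2, A9→A6) → n = 10; WGD1 → n = 20; five NCIs (A12 into the
A10 arm of the fused A2 chromosome, giving the nested pattern; A12→A7;
A5→A3; A11→A3; A11→A8) plus a distal A6/9↔A1 translocation → n = 15;
WGD2 → n = 30. Four additional species provide evidence: two
pre-fusion diploids (n = 12), a post-fusion diploid (n = 10) and a
post-WGD2 sister genome.

Sequence divergence is a per-codon jump process: each codon receives a
Poisson number of synonymous and, separately, nonsynonymous
single-codon replacement events (drawn uniformly from the codon's
synonymous set / nonsynonymous single-step non-stop neighbours). The
two rates are calibrated *jointly* by fixed-point iteration against
the package's own NG86 estimator on a 30,000-codon pre-run (the
processes interact: a nonsynonymous replacement can overwrite a
synonymous difference), cached per target, with a fixed internal
calibration seed so the rate map is a property of the model, not of the
scenario seed. Realized mean Ks over ≥ 500 genes lands within ±0.05 of
targets 0.06, 0.28 and 0.9. Branch increments in the packaged scenario
approximate the published peak structure within a consistent strict
clock (WGD1 pairs ≈ 0.28–0.3, WGD2 pairs ≈ 0.08, sister species ≈
0.06, post-fusion diploid ≈ 0.33, pre-fusion diploids ≈ 0.6–0.7); the
published WGD2-peak/sister-divergence values themselves are mutually
inconsistent under a strict clock, so exact replication is not
attempted. A Ka:Ks ratio of 0.2 applies throughout — typical purifying
selection strength for conserved plant genes.

Similarity hits are synthesized from truth (gene families =
descendants of one ancestral gene) with identity from exact codon
comparison, blastn-like bitscores (match +2 / mismatch −3, λ = 0.625,
K = 0.41) and derived e-values; pairs under 60% identity are treated as
undetectable. The simulator introduces no indels, inversions,
transposable elements or intergenic sequence; gene coordinates are
emitted 0-based half-open, rank-spaced. Soft-masking can lowercase a
fraction of genes (default 30% of their length over 5% of genes in the
CLI fixture writer) to exercise the repeat filter. Defaults for
desk-scale study: 12 chromosomes × 50 genes × 60 codons,
fractionation 0.

What passing the replay shows — and does not: with fractionation 0,
indel-free genes and noise-free positions, painting accuracy ≈ 1 and
event recovery is exact; real genomes add fractionation holes,
tandem arrays, assembly errors and rate heterogeneity that this replay
does not emulate, so the tests validate the *machinery*, not
genome-scale error rates.

## Problem sizes and numerical choices

The full replay (4 comparator genomes, 2400-gene focal genome, 1000
bootstrap replicates) runs in a few seconds; tests use 12–50 genes per
chromosome. Chain-DP tie-breaks, bitscore tie-breaks and bootstrap
seeding are all deterministic under a fixed seed; every source of
randomness in the acceptance script derives from `--seed`. Mixture
fitting requires ≥ 50 values; degenerate inputs (empty gene sets,
empty sequences, unmapped chromosomes, events referencing absent
chromosomes) raise named errors rather than propagating silently.

## Known limitations

* NG86 only — no ML codon models (GY94), no among-site rate variation,
  no lineage rate heterogeneity; the strict clock inherits all the
  usual caveats, and divergence windows are mode ± one σ of a mixture
  component, not confidence intervals.
* Chaining is per chromosome pair; blocks spanning assembly breaks are
  not merged, and breakpoints are rank-resolution only.
* Whether the original block-validation intersected origins across all
  comparator species or required per-species agreement is
  unknowable from the description; intersection semantics are used.
* The exact bootstrap replicate size in the original painting pipeline
  is unstated; m = number of evidence hits is this package's choice.
* The translocation/end-fusion disambiguation needs reciprocal
  evidence; one-sided cases stay flagged "unresolved".
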