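# Methods

## Overview

`sexmark` implements an alignment-free, pooled-sequencing route to
male-specific markers in an XX/XY dioecious species, plus the in-silico PCR
machinery to validate candidate markers on known-sex panels. The pipeline is
a chain of simple, auditable primitives: orientation-specific k-mer counting,
count-band filtering, female-zero selection, unitig assembly, zero-mismatch
map-back with depth rules, and 3′-anchored primer matching. This note records
the model each stage assumes, the defaults and why, the numerical choices,
and what the synthetic data can and cannot show.

## The k-mer screen

K-mers of length *k* = 35 are taken from reads **exactly as sequenced** —
no reverse-complement canonicalization — and only those starting with the
dinucleotide `AG` are counted. The prefix filter is an orientation-specific
1/16 subsample of k-mer space: because both strands of every locus are
sequenced across a pool, any Y-restricted locus still contributes
`AG`-anchored k-mers from one strand or the other, so sensitivity at the
locus level is preserved while table size and runtime drop 16-fold.
Canonicalization would break this: the canonical form of an `AG`-anchored
k-mer usually does not start with `AG`.

Retention band: a k-mer is kept iff `2 ≤ male + female ≤ 200`. Totals of one
are dominated by sequencing error; totals above 200 are repetitive sequence
that cannot yield a locus-specific marker. Survivors with `female == 0` are
the male-specific k-mers (MSKs). Counting is multiplicity-aware within a read
(switchable to per-read presence with `count_multiplicity=False`). K-mers
containing `N` are skipped. A `partitions` argument (4 or 16) re-traverses
the input once per prefix-extension partition, bounding peak memory to
roughly 1/partitions of the table for large pools; the result is identical
to single-pass counting and is tested to be.

Candidate extraction keeps a read pair iff either mate contains at least one
MSK as a literal substring. Since every MSK is itself an `AG`-anchored
35-mer, containment is decided by intersecting the mate's own anchored
k-mers with the MSK set — an exact, index-free test.

### Quality trimming

The trimmer removes only 3′ bases: while the trailing 4-base window's mean
Phred score is below 20, the last base is dropped; remaining trailing bases
below 20 are then dropped; finally a pair is discarded if either mate is
shorter than 50 bases. Window 4 / Q20 / length 50 are conventional
short-read defaults, fully parameterized in `TrimParams`. On the simulator's
default constant-Q37 reads the stage is a no-op; the simulator's
`degrade_three_prime` option writes a falling 3′ quality ramp to exercise it.

## Unitig assembly

Nodes are canonical 31-mers (lexicographic minimum of the k-mer and its
reverse complement; *k* odd so no k-mer is its own reverse complement) with
occurrence counts; edges are the observed 32-mers. Nodes seen fewer than
`min_kmer_count = 2` times are dropped. Unitigs are maximal non-branching
paths; the only other cleaning is tip clipping (dead-end, all-count-1 chains
shorter than 2*k* attached to the graph at one end). There is no bubble
popping, scaffolding or repeat resolution: the candidate regions are small
and determinism matters more than contiguity. Output is deterministic —
unitigs are reported in canonical orientation, sorted by descending length
then sequence, and identical inputs yield byte-identical FASTA. Unlike the
screen, assembly **must** merge strands, hence canonical k-mers here and not
there. Unitigs shorter than 100 bases are discarded.

## Map-back and depth classification

Reads map to scaffolds wherever the read or its reverse complement is an
exact substring — no mismatches, all placements reported. The production
path is a seed-and-verify index (every 20-mer position of every scaffold;
candidates verified by full comparison), contractually identical to a naive
all-positions scan and tested for equivalence against it.

Per scaffold and pool: mapped-read count (a read counts once per scaffold it
hits, and toward **every** scaffold it hits — conservative, since any female
evidence should disqualify a scaffold) and mean depth = mapped read bases /
scaffold length. Labels:

- `MALE_SPECIFIC` — at least one male read, zero female reads;
- `RESCUED_MALE_SPECIFIC` — nonzero female depth, and male mean depth ≥
  `rescue_ratio` (default 2.0, comparison inclusive) × female mean depth —
  the expected signature of a hemizygous locus whose diverged X or autosomal
  paralog attracts some female reads;
- `PENDING` — everything else.

The rescue rule is driven by mean per-base depth; read counts are reported
alongside in `scaffold_report.tsv` so the choice is auditable. Candidate
selection keeps male-specific and rescued scaffolds of ≥ 100 bases, longest
first — a deliberate simplification that stands in for gene-level
prioritization of candidates.

Scaffolds shorter than the read length can receive no exact read placements
and therefore always come out `PENDING`; with 150 bp reads and a 100 bp
unitig floor, scaffolds of 100–149 bases are effectively unclassifiable by
design.

## In-silico PCR and panel scoring

A primer binds where it matches a template window with at most
`max_mismatches` substitutions (default 0) **and** its 3′-terminal base
matches exactly — a 3′ mismatch abolishes polymerase extension, the standard
in-silico PCR rule. Both strands are searched; amplicons are formed from
every productive forward/reverse site combination with product length in
[50, 5000] and reported forward-primer-first with 0-based half-open template
coordinates internally, 1-based inclusive in report tables. Annealing
temperature is carried as primer metadata and never enters matching;
empirical temperature-dependent specificity is out of computational scope.

A dominant marker is scored per individual: ≥ 1 predicted amplicon on any of
the individual's templates → "presence" → male call; otherwise "absence" →
female call. Panel accuracy is
`100 × (males with presence + females with absence) / n`, rounded **half-up**
to two decimals (124/128 prints 96.88, 123/128 prints 96.09).

## The synthetic data model

`simulate_genomes` builds a female set {autosome, X region} and a male set
{autosome, X region, Y-MSR}, all uniform i.i.d. A/C/G/T. Independent
generation makes a shared 35-mer between the MSR and the 120 kb female
genome a ~10⁻¹³ event, so MSK soundness is checkable by brute-force scan.
With `divergence_xy > 0` the male set additionally carries a Y gametolog of
the X region with that fraction of sites substituted (default 0.0: the male
set is then exactly the female set plus the MSR). Hemizygous sequences
(Y-MSR, Y gametolog) carry dosage weight 0.5, so the male pool shows the
biologically expected half depth over the MSR.

`simulate_pool_reads` draws
`round(coverage × Σ weightᵢ·lengthᵢ / (2 × read_length))` fragment
positions with per-sequence probability ∝ weight × length, fragment lengths
Normal(350, 50) truncated below at the read length, either strand with
probability ½, constant Q37 qualities, and optional per-base substitution
errors. Read names encode the true source sequence, fragment coordinates and
strand, giving downstream tests a ground-truth oracle.

**Circular sampling.** By default fragments are drawn as if each template
were circular (`ReadSimConfig.circular=True`). The toy contigs stand in for
the interior of a chromosome-scale genome; linear sampling of a 100 kb
contig leaves orientation-specific 35-mer coverage ramping to zero over the
last ~115–350 bases of each end (an as-sequenced + strand k-mer is only ever
covered by read windows anchored at fragment starts), which floods the
screen with end-artifact false MSKs that the emulated data would not
contain. Circular sampling restores uniform coverage; the price is that a
fragment-length fraction of reads (~0.3% at these sizes) spans the wrap
junction and is a substring of the circularized rather than the linear
template. `circular=False` gives strict linear behavior.

`simulate_panel` gives every individual a shared background template and
gives the marker template to males with probability 1 − `male_dropout` and
to females with probability `female_leakage`, mirroring the two error modes
a dominant marker shows on real panels (null Y haplotypes / failed
reactions, and amplifiable female paralogs). Defaults are a 45-male,
52-female panel at zero noise.

### What the simulation does not model

No indels or structural variants, no polyploidy, no diploid heterozygosity
(pools are haploid reference sets with dosage weights), no positional or
GC-dependent error profile, no quality-model calibration. Passing synthetic
tests therefore demonstrates the pipeline's logic — selection thresholds,
assembly correctness, depth rules, scoring arithmetic — not robustness to
real-instrument noise or genome complexity.

## Sampling limits of MSK soundness

At pool coverage *C* = 30× and read length 150, a specific oriented 35-mer
window is covered by Poisson(λ), λ = C/(2·150) × (150 − 34) ≈ 11.6 reads.
P(count = 0) ≈ 9×10⁻⁶, and a 120 kb female genome exposes ~15,000
`AG`-anchored oriented 35-mers, so the expected number of shared k-mers that
the female pool misses entirely — which then surface as false MSKs — is
~0.14 per simulated study, arriving in bursts when a single ≥ 116 bp gap in
fragment starts silences a run of adjacent k-mers in one orientation
(expected ~1 such gap per pool). Measured over 20 fixed seeds at the default
study conditions, 18/20 runs had zero false MSKs and two had 1 and 3. This
is intrinsic to finite-depth pooled screens, scales as e^(−λ), and is
precisely the failure mode the map-back classification stage corrects: in
the same 20 runs, male-specific/rescued scaffolds covered 100% of the
planted MSR in 20/20 seeds and no purely-background scaffold was ever
labeled `MALE_SPECIFIC`.

## Determinism and problem sizes

Every simulator and every stage is deterministic for a fixed seed; the
pipeline fans one global seed out to per-stage seeds through a fixed
blake2s hash of the stage name, so stages can be rerun in isolation.
Reruns with identical config produce byte-identical outputs (checksummed in
`manifest.json`).

Problem sizes used by the shipped tests and the acceptance script, chosen to
exercise every stage while keeping a full run in seconds: the reference
synthetic study is a 100 kb autosome + 20 kb X + 10 kb MSR at 30× per pool
(error-free 150 bp pairs), evaluated over 20 seeds; integration and
demonstration runs use 40 kb + 8 kb + 6 kb at 25×; unit tests use 0.5–20 kb
sequences. Oracle-equivalence checks run 50 randomized instances per
primitive against naive full scans.

## Known limitations

- Exact-match mapping means any sequencing error in a real read unmaps it;
  on real data the depth rules would need a mismatch-tolerant mapper (the
  `classify` stage accepts externally assembled scaffolds, but not external
  alignments).
- The unitig assembler resolves no repeats; real MSR haplotypes with
  internal repeats longer than the graph k would fragment.
- In-silico PCR knows nothing of thermodynamics: a primer pair that matches
  perfectly but anneals poorly in practice is invisible to it, as is the
  empirical annealing-temperature tuning that real dominant markers need.
- The in-memory k-mer table is practical to a few tens of millions of
  distinct k-mers; the partitioned mode extends this ~16-fold but still
  assumes re-iterable inputs.
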