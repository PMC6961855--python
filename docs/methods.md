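# Methods

## Model

A query motif of length *k* (default 15 bp) is compared against every
plus-strand window of a landscape through its reverse complement. A
candidate alignment is either ungapped or carries exactly one 1-bp gap
(one unaligned query base against a (k−1)-bp window, or one unaligned
target base against a (k+1)-bp window). A gapped alignment pays a fixed
penalty of 2 effective mismatches on top of its substitutions — the
strained fold-back geometry of a bulged ectopic pairing is treated as
costly as two substitutions — while *reported homology* counts matched
bases only over *k* (a 14/15 gapped match: 93% homology, 2 effective
mismatches). Hits above 6 effective mismatches (below 60% homology) are
discarded: at one decade of reactivity lost per 10% homology (see below)
such loci contribute negligibly. Multi-gap alignments are not considered;
at this homology floor a second gap costs 4 of the 6 allowed mismatches
and adds essentially no hits. Non-ACGT characters (ambiguity codes, N
fill-in) always score as substitution mismatches on either side, and
windows containing an N-run longer than 1 bp are skipped entirely.

Overlapping candidate alignments describe the same physical locus and are
merged to the best-scoring one (fewest effective mismatches; ties prefer
ungapped, then the smallest start). Hit separation is the nearest-edge
distance in bp between the hit and query intervals.

Each hit within the reactive distance *R* = 421,000 bp (the separation
out to which inverted *Alu* pairs are statistically depleted) contributes

    w = A · D^(−(m − m₀)·(100/k)/10) · f(d)

- `D = 10` — reactivity drops one order of magnitude per 10-point homology
  loss, as measured for inverted *Alu* recombination in yeast. With k = 15
  each mismatch is 100/15 ≈ 6.7 points, so adjacent mismatch classes
  differ by 10^(2/3) ≈ 4.64× and a 2- vs 5-mismatch pair by exactly 100×.
- `m₀ = 2` — the reference class; `A` is the weight of an m₀ hit at
  distance 0 (default 5×10⁻⁴).
- `f(d)` — a pluggable distance kernel: `uniform` (1), `linear`
  (max(0, 1 − d/R)), or the default `hyperbolic` c/(c + d) with
  c = 10,000 bp. All kernels are 0 beyond R.

Stability is additive: I = Σw, S = 1 − I, exactly 1.0 with no hits.
Additivity makes the leave-one-out arithmetic exact (I_total − I_excl is
precisely the excluded hit's weight) and makes a tandem duplication of a
hit-bearing block double that locus's contribution, which is what the
comparison-table footnote arithmetic and the SV-perturbation results
require. Relative stability across haplotypes is
100·(1 − (I − I_min)/I_min); this formula reproduces, to the printed two
decimals, all ten published percentages from the ten published raw
scores, which is the evidence for it. Reported S is rounded to 8
decimals; all internal arithmetic is full precision.

The published account does not specify the absolute scale or distance
dependence of the underlying *Alu*-pair model, so `A` and the kernel are
configuration, not claims: with the defaults, a Table-1-like landscape
(one 2-mismatch hit at 1.4 kb plus 89 weaker hits spread over ±421 kb)
has I ≈ 5×10⁻⁴ with ~90% carried by the near hit, matching the published
orders of magnitude, and `calibrate_kernel` fits (A, c) to observed
scores by least squares when data are available. Raw stability scores on
real sequence are therefore reproduced in structure, not digit-for-digit.

## Scanning modes

`exhaustive` scores every alignment start in the ±500 kb reporting window
(vectorised mismatch cumsums over all gap placements; ~1 s per 1 Mb
landscape). `seeded` (the default) additionally requires the winning
alignment to contain a contiguous exact-match run of ≥ 8 bp, emulating
the word-seeded behaviour of the BLAST-style search such catalogues are
built with, whose exact parameters are not published. Seeding is applied
as a filter on the merged exhaustive hits, so seeded output is by
construction a subset of exhaustive output with identical scores. On
i.i.d. random sequence the exhaustive mode reports ~4×10⁻³ loci/bp
(≈3,500 per ±421 kb) while the seeded mode reports ~10⁻⁴ loci/bp (≈90 per
±421 kb — the density actually observed in real landscapes); the exact
per-position probability is computable by enumerating all 2^15
match/mismatch patterns and is used as the oracle in the tests.

Only the plus strand is scanned for the reverse complement of the query:
a minus-strand occurrence is a direct repeat, which does not form the
fold-back geometry this model scores.

## Enrichment statistics

The likelihood of a ≥(k−1)-match reverse complement follows the published
three-term enumeration: P = p^k + k(1−p)p^(k−1) + k·p^(k−1) with
p = 0.25, i.e. each single-gap pattern is weighted p^(k−1) with no (1−p)
factor for the gapped base. That gap term is not a conventional binomial
quantity, but it is implemented verbatim because the printed numbers
(9.87×10⁻⁸; 2,734 opportunities = 2(d+1) at d = 1,366; landscape
p = 2.70×10⁻⁴) follow from it; a substitution-only binomial tail is
available behind `conventional=True`. The landscape p-value is capped at 1.

## Synthetic landscapes

The generator emulates the study conditions for a phased landscape set:

- 1,000,001 bp of i.i.d. 50%-GC background with the query at the centre,
  its reference coordinates matching the canonical locus;
- 90 planted inverted approximate copies with mismatch classes
  1/3/11/20/55 at 2–6 effective mismatches; the single 2-mismatch copy is
  a gapped 14/15 match planted 1,366 bp downstream; the rest are uniform
  over ±[5, 420] kb (the real inter-hit distance distribution is not
  published; uniform is the neutral choice and is configurable);
- per-haplotype phase structure: low-coverage discontinuities drawn as
  18 + Binomial(12, 2/3) (mean 26, range 18–30), total gap length tuned
  to a 97.6% covered fraction, covered blocks phased with probability
  0.85, and the block containing the query forced covered and phased
  (the near hit and the query co-reside in one phase block);
- across n haplotypes, a configurable number of non-anchor plant loci
  (default 21) each dropped from 1..n−1 randomly chosen haplotypes, so
  every union locus survives somewhere.

A random megabase unavoidably contains chance reverse complements at
these thresholds (~3,500 exhaustive-mode, ~90 seeded-mode loci), so truth
labels are made unambiguous by *scrubbing*: after planting, the generator
repeatedly rescans and makes single-base edits (a matched alignment
position near the offending hit's centre) that break every spurious
seeded-mode locus landscape-wide and every spurious exhaustive-mode locus
within 2 kb of a plant, never touching a planted segment or the query.
Re-rolling the whole background instead cannot converge — the expected
number of chance loci near 90 plants is in the hundreds. After scrubbing,
a seeded scan returns exactly the planted hits and an exhaustive scan
recovers every plant with exactly its intended score; both properties are
asserted in the tests. Plants keep an exact-match run ≥ the seed word so
both modes see them; each plant is re-scored in context after writing and
its mutation layout re-drawn (or its position re-sampled) if the local
background admits a better-scoring alternative alignment, so the realised
score always equals the intended one. Gap positions in gapped plants stay
≥2 columns from the motif ends, and the flanking bases are pinned away
from the motif's end bases, because otherwise an equal-scoring ungapped
or shifted framing of the same locus wins the merge tie-break.

All randomness flows from one top-level seed through named substreams
(background, planting, scrubbing, absences, per-haplotype phase), so any
stage is reproducible in isolation and identical spec + seed yields
byte-identical FASTA/BED/truth outputs.

What the generator does **not** emulate: repeat elements (*Alu*/LINE
content), GC isochores, realistic indel spectra, or read-level artefacts.
Passing tests on synthetic data therefore validate the arithmetic and the
scanning contracts, not the biological hit densities of real genomes;
the one real-sequence check (the hg38 nearest-hit geometry) runs only
when a local reference slice is provided.

## Structural-variant perturbation

Edits (deletion, tandem duplication, inversion; the default interval is
the 1-kb block 1 kb downstream of the exon that holds the near-perfect
hit) are each applied independently to the pristine landscape. Phase
blocks and fill-in intervals are remapped through the edit; hit distances
are recomputed on the edited coordinates, so a duplication pushes
downstream hits 1 kb farther. Deleting or inverting the block removes the
contained hit's contribution (exactly, under a distance-free kernel;
to within the distance-kernel shift otherwise); duplication adds a second
copy at +1 kb, nearly doubling the locus's contribution under the default
kernel (ratio ≈ 1.8 at c = 10 kb).

## Window profiles

Exon profiles score every k-bp window as its own query (85 fully-exonic
15-bp windows for a 99-bp exon, indexed 1-based from the exon 5′ end so
the canonical deletion is window 52; k = 20 mode extends into the
flanking introns to cover every exon base, 118 windows). Percentile ranks
use midranks for ties.

## Numerical and interface choices

- Coordinates: 0-based half-open internally; 1-based inclusive in all
  user-facing strings and TSV reports; standard 0-based BED on disk.
  Phase-block BED: column 4 block label, column 5 phased flag (1/0);
  covered blocks are listed, gaps between them are the discontinuities.
- Landscape FASTA headers carry `origin=chrom:start-end` so slices
  round-trip with their reference coordinates.
- Haplotype labels are arbitrary; nothing assumes parental identity
  across phase blocks.
- Reference fill-in of low-coverage gaps replaces gap sequence with the
  reference's bases at homologous coordinates; hits inside filled
  intervals are flagged (`in_filled_region`), never silently mixed.
- `calibrate_kernel` fits log-parameters with Levenberg–Marquardt
  (positivity by construction); uniform/linear kernels reduce to a
  closed-form linear solve. Degenerate systems (fewer observations than
  unknowns, all-empty hit sets) raise.
- The acceptance script's problem sizes (the ten printed raw scores) are
  in-paper inputs; the package-level simulations in the test suite use a
  1 Mb landscape at study scale and an 80 kb landscape for unit-level
  checks, sizes chosen to exercise the same code paths at interactive
  speed.

## Known limitations

- Absolute raw stability scores depend on the unpublished scale and
  kernel of the upstream *Alu*-pair model; only their structure (order of
  magnitude, top-hit dominance, relative comparisons) is reproduced.
- The scanner is exact for ≤1-gap alignments only; hits whose best
  alignment needs two gaps at ≤6 effective mismatches are missed (rare at
  this floor, see above).
- The seeded mode filters merged exhaustive hits rather than seeding the
  candidate generation; results are identical except in rare tie cases
  where a locus's best alignment lacks a seed word but a worse overlapping
  alignment has one (such loci are dropped, mirroring what a word-seeded
  search would never have scored).
- In-silico inversions re-scan the edited sequence, so an inversion can in
  principle create new chance hits at its junctions; at seeded thresholds
  this is a ~10⁻⁴ probability per junction.
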