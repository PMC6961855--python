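# invstab

Inverted-repeat instability scoring of haplotype-resolved gene landscapes.

## The problem

Widely spaced inverted repeats — a sequence and an approximate reverse
complement of it elsewhere on the same strand — can transiently align
through DNA looping and single-stranded intermediates, and such ectopic
pairings are implicated in the formation of deletions. Genome-wide counts
of inverted vs direct-oriented *Alu* element pairs show a measurable
depletion of inverted pairs out to separations of 421 kb, which motivates
treating every sufficiently homologous reverse complement within that
"reactive distance" as a small, additive threat to the stability of a
locus.

`invstab` applies that model to a single query motif — by default the
15-bp *EGFR* exon 19 canonical deletion sequence (hg38
chr7:55,174,773–55,174,787, the ELREA deletion that is the most common
*EGFR* driver mutation in lung adenocarcinoma) — across megabase-scale,
haplotype-resolved landscapes. It is aimed at people studying how
structural variation in "normal" genomic architecture changes the
propensity of a locus to generate a recurrent driver mutation.

## The model

For a query of length *k* (default 15), every locus within ±500 kb whose
best alignment to the reverse complement of the query has at most 6
effective mismatches (≥60% homology) is catalogued. Alignments may carry
at most one 1-bp gap; a gap counts as **2 effective mismatches** on top of
the substitutions, while reported homology counts matched bases only (a
14/15 gapped match is 93% homologous with 2 effective mismatches).

Each hit within the 421 kb reactive distance contributes a reactivity
weight

```
w = A · D^(−(m − m₀)·(100/k)/10) · f(d)
```

where `m` is the hit's effective mismatch count, `D = 10` encodes the
observation that inverted-repeat reactivity drops one order of magnitude
per 10-percentage-point loss of homology, and `f(d)` is a non-increasing
distance kernel (default hyperbolic, `f = c/(c+d)` with `c = 10` kb). The
landscape's **raw stability score** is

```
S = 1 − Σ w          (S = 1.0 for a landscape with no reactive hits)
```

and a set of haplotypes is compared through relative stabilities
`100·(1 − (Iᵢ − I_min)/I_min)` with `I = 1 − S`, so the most stable
haplotype scores exactly 100.00%. Additivity is deliberate: leave-one-out
contributions are exact, and a duplicated hit contributes exactly twice.

The package also provides sliding-window stability profiles across an
exon, in-silico structural-variant perturbation (1-kb deletion /
tandem duplication / inversion with coordinate remapping), the binomial
enrichment calculation for finding a ≥14/15 reverse complement within a
given distance, and a ground-truth synthetic landscape generator so the
whole pipeline is testable without any sequence download.

## Worked example

```bash
invstab simulate --seed 42 --length 1000001 --n-haplotypes 2 --absence 5 --out demo
invstab scan  --landscape demo/hap1.fa --query chr7:55174773-55174787 --out demo/hits.tsv
invstab score --hits demo/hits.tsv
```

```
{
  "n_hits": 87,
  "instability": 0.0004880152543853544,
  "raw_stability": 0.99951198,
  "top_contribution": {
    "locus": "chr7:55176154-55176167",
    "weight": 0.00043990849903220134,
    "fraction": 0.9014236646890421
  }
}
```

The simulated landscape carries 90 planted inverted copies of the query
with the mismatch-class profile of a real reference landscape
(1/3/11/20/55 at 2–6 mismatches), five of which were dropped from one of
the two haplotypes; 87 survive in `hap1`. The single 2-mismatch hit — a
gapped 14/15 match planted 1,366 bp downstream, mirroring the real
geometry — carries 90% of the predicted instability, so `S` sits just
below 1 in the fourth decimal.

```bash
invstab compare --landscape demo/hap1.fa --landscape demo/hap2.fa \
                --query chr7:55174773-55174787 --out demo/compare.tsv
# variation 0.0% (excluding top hit 0.6%) -> demo/compare.tsv
```

| haplotype | mm2 | mm3 | mm4 | mm5 | mm6 | total | raw_stability | relative_pct | raw_stability_excl | relative_excl_pct |
|-----------|-----|-----|-----|-----|-----|-------|---------------|--------------|--------------------|-------------------|
| hap1      | 1   | 3   | 11  | 20  | 52  | 87    | 0.99951198    | 99.95        | 0.999951893        | 99.44             |
| hap2      | 1   | 3   | 11  | 19  | 54  | 88    | 0.99951225    | 100.0        | 0.999952161        | 100.0             |

Because both haplotypes share the dominant 2-mismatch hit, their relative
stabilities differ by far less than 1%; removing that shared hit
(`relative_excl_pct`) amplifies the haplotype-specific differences — the
same effect the model predicts for real phased landscapes.

`invstab enrich` prints the binomial likelihood chain for the near-perfect
hit: 32,768 match/mismatch patterns over 15 bp, 31 of them with ≥14
matches, a per-sequence probability of 9.87×10⁻⁸, 2,734 placement
opportunities within ±1,366 bp, and a landscape-level p of 2.70×10⁻⁴.

Other subcommands: `profile` (per-window exon stability), `perturb`
(independent SV edits with re-scanning), `run` (YAML-configured
end-to-end run writing a reproducible artifact bundle keyed by a config
hash).

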