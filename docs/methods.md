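# Methods

## The model

`igcsim` simulates the population genetics of a small multigene family —
three paralogous copies of a gene on one chromosome — whose members
exchange sequence by interlocus gene conversion (IGC) while the population
reproduces, recombines, selfs, and (optionally) maintains a copy-number
polymorphism under balancing selection.  The motivating system is a plant
NLR immune-receptor family in a highly selfing species: a tandem pair of
copies a few kb apart plus a third copy ~2 Mb away, with a segregating
presence/absence polymorphism at the middle copy.

### Chromosome and population

A diploid Wright-Fisher population of `N` individuals is represented as
`2N` chromosomes.  Each chromosome carries five blocks of `L` binary sites
(0 ancestral, 1 derived), laid out as

    copy1 | spacer1 | copy2 | spacer2 | copy3

The copies are homologous to one another (IGC and cross-copy comparisons
use the same site coordinates in every copy block); the spacers are
unrelated single-copy sequence.  Copy2 and copy3 are absent at the start
and carry per-chromosome presence flags once introduced.

### Phases

| phase | default generations | events |
|---|---|---|
| I   | 0 – 3000      | burn-in of copy1 + spacers |
| II  | from 3000     | copy2 seeded from a random copy1 haplotype; conditioned to fixation |
| III | … – 8000      | neutral two-copy evolution |
| IV  | from 8000     | copy3 seeded likewise beyond spacer2; conditioned to fixation |
| V   | … – 16000     | neutral three-copy evolution |
| VI  | 16000 – 26000 | one chromosome loses copy2; balancing selection holds both CNV classes near 50% |

Conditioning to fixation is by rejection: if the seeded copy is lost, the
population is restored to its state at the seeding event and reseeded with
fresh randomness, so accepted trajectories follow the neutral fixation
path.  Expected restarts per fixation are ~2N (the neutral fixation
probability of a new variant is 1/2N).

Equilibrium summaries use fixed measurement windows — two-copy diversity
in generations 4300–6500, three-copy in 11,000–16,000, CNV-phase in
21,000–26,000, and the single-copy spacer1 reference in 3000–15,000.  The
windows are stored as fractions of the phase spans, so a rescaled schedule
rescales its windows proportionally.

### Per-generation events

1. **Reproduction.**  Each offspring chromosome picks a parent chromosome
   (uniformly; weighted in phase VI) and, per block, suffers at most one
   crossover with probability `min(1, R_b_eff / 2N)`, where `R_b` is the
   population crossover rate of that block and `R_b_eff = R_b (1 - s)`.
   A crossover draws a partner chromosome and a uniform breakpoint; the
   offspring switches source at each breakpoint walking left to right.
   `R_s2` is large (1600, a ~2 Mb spacer), so copy3 is effectively
   unlinked from the copy1/copy2 cluster.
2. **Mutation.**  Poisson with mean `mu × (carriers of the block)` events
   per block per generation; each event sets a uniformly chosen site of a
   uniformly chosen carrier to derived.  Mutation is idempotent on
   already-derived sites; with the defaults (`mu = 0.001` per block per
   chromosome per generation, `L = 1000`) the per-site scaled diversity is
   4Nmu/L = 4×10⁻⁴ and recurrent hits are negligible.
3. **IGC.**  Poisson(`C_eff`) events, `C_eff = C_total (1 - s)`.  Each
   event picks one of the six directed donor→acceptor copy channels by the
   `igc_fractions`, a uniform donor chromosome carrying the donor copy, a
   uniform acceptor chromosome carrying the acceptor copy, and a uniform
   tract start; `tract_len` sites (default 100) are copied, truncating at
   the block end.  An event whose donor or acceptor copy currently has no
   carrier is skipped and counted.

### Selfing

Selfing at fraction `s` is folded into the rates: every crossover and IGC
rate is multiplied by `(1 - s)` ("effective rates"), rather than modelling
explicit self-mating.  This is exact for the rate at which exchanges occur
between distinct haplotypes, which is what shapes diversity here; it does
not model the reduced effective population size of a partially selfing
species, so single-copy diversity is independent of `s` by construction.
The same scaling is applied to `C` even though some IGC is
intra-chromosomal; with the default unequal fractions the bias is small,
and the alternative (not scaling the intra-chromosomal share) is a
one-line change in `SimParams.C_eff`.

### Crossover in structurally heterozygous pairings

When the two chromosomes of a pairing disagree on copy2 presence, the
copy1–spacer1–copy2 cluster is structurally mispaired; such pairings do
not recombine within that cluster (crossovers drawn there are discarded).
Likewise a pairing discordant for copy3 cannot recombine inside copy3.
This mirrors the well-documented suppression of crossing over across
heterozygous structural variants, and it is load-bearing: with free
crossover in the cluster, copy1 lineages would migrate between the two
CNV haplotype classes every ~1/m ≈ 1700 generations (at the default
rates), eroding the balanced divergence that the CNV phase is designed to
study.  Presence-flag counts still follow an exchangeable Wright-Fisher
chain, so fixation conditioning is unaffected.

### Balancing selection on the copy2 CNV

Phase VI applies frequency-dependent offspring weights to the two
presence/absence classes,

    w(h) = max(0, 1 + sigma (1/2 - f_h)),

with `sigma = sel_strength`.  The expected next-generation frequency is
`f' = f w1 / (f w1 + (1-f) w0)`; at `sigma = 2` this equals 1/2 exactly
from any interior frequency, so the polymorphism is held at 50% with
binomial fluctuation (sd ≈ 0.035 at N=100) and essentially no extinction
risk, matching the intended "constrained to ~50%" behaviour.  `sigma = 2`
is the default: the linearized map has slope `1 - sigma/2`, so values
above 4 are dynamically unstable (overshooting oscillation), and large
values clamp one class's weight to zero at the seeding frequency 1/2N,
killing the phase deterministically.  If either class is nonetheless lost,
the phase restarts from the deletion event.

## Statistics and inference

* **pi** is average pairwise difference per site, gaps excluded pairwise
  (each allele pair normalized by its own co-called sites plus the
  invariant sites of the source alignment); a brute-force all-pairs oracle
  reproduces it to 1e-12 in the tests.  **Tajima's D** uses the canonical
  variance constants and is reported as missing (NaN) when S = 0.
  **Sliding windows** default to 300 bp width and 25 bp step.
  **r²** is D²/(p₁q₁p₂q₂) over phased alleles, pairs with a monomorphic
  member skipped.
* **Pairwise SFS**: sites with the derived allele present in the acceptor
  sample are classed shared (also present in the donor sample) or
  specific, binned by derived count 1..n−1; acceptor-fixed sites (count n)
  are tabulated separately, mirroring the separation of fixed differences
  from shared polymorphism.  The **three-copy SFS** partitions
  derived-bearing sites into 7 categories (3 private, 3 two-way shared,
  shared-all); pairwise shared counts are recoverable by marginalization.
* **Gamma bootstrap**: per SNP with derived frequency p, a replicate draws
  Gamma(shape = n_target·p, scale = 1) and assigns class round(g),
  discarding draws outside [1, n_target−1] (the SNP is unsampled or fixed
  in that replicate).  The "size parameter" of the recipe is read as the
  gamma shape, the scale being stated separately as 1.
* **KS classification**: each of the (default 1000) resampled spectra is
  assigned to the candidate theoretical spectrum with minimum KS distance,
  computed on the concatenated specific-then-shared normalized spectrum
  (per-category KS summed is available by flag); ties break to the lowest
  C.  A chi-squared goodness-of-fit against a uniform split over the k
  candidates (df = k−1) measures how decisive the assignment is.
* **Theoretical spectra** for candidate rates C ∈ {0.2, 1, 5} (n = 10,
  R = 1) are regenerated by running the two-copy configuration of the
  simulator to equilibrium and averaging pairwise SFS over replicates,
  rather than transcribing published tables; the generating reps and seed
  travel in the spectrum metadata.  Under neutrality the SFS shape is
  invariant to the mutation rate (mutations Poisson-mark the genealogy),
  so spectrum regeneration uses a per-block µ high enough to populate all
  frequency classes.
* **Parameter recovery** is assessed on datasets that pool the SFS of
  several (default 6) independent duplicate families.  A single simulated
  family contributes only a handful of correlated genealogical segments
  (R = 1 crossover per block per generation population-wide), which is
  not enough information to discriminate neighbouring candidate rates;
  pooling gives a dataset the several-hundred-SNP,
  many-independent-segments regime the classifier is designed for, at
  which it recovers the generating C in ≥80% of datasets per rate.

## Synthetic data and what it does not capture

The simulator is the data generator for all tests: binary sites, a single
pair of homologous chromosomes per individual, no codon structure, no
indels, no fitness effects of point mutations, no crossover interference,
and selfing only through effective rates (no inbreeding-reduced Ne, no
homozygosity tracking).  Passing tests therefore validate the
population-genetic machinery — frequency dynamics, exchange processes,
spectra, classification — not sequence-level realism.  The planted
fixtures (`igcsim.fixtures`) give the tabulators exact ground truth
without simulation; the "rpp8" preset mimics only the shape of the real
data (sample sizes, 470 sites, 234/51/15 two-way sharing), not its
sequences.

## Numerical choices

* Sites are stored one byte each, packed 8-per-uint64 word; `L` must be a
  multiple of 8 so blocks stay word-aligned.  The generation loop is
  numba-compiled; every generation g reseeds the kernel RNG from
  (run seed, g, restart attempt), so any generation is replayable in
  isolation, stepping equals batch running bit-for-bit, and replicate r of
  an experiment uses seed+r.
* `L` defaults to 1000 sites per block with a 100-site conversion tract.
  The tract:block ratio shapes how strongly one conversion event
  homogenizes a pair of copies; 10% keeps per-site conversion slower than
  drift at moderate C, which reproduces the neutral diversity ceiling
  (each copy's diversity approaches 3× the single-copy level only when C
  reaches ~200, the merged six-chromosome pool limit).
* Experiment problem sizes: 20 replicates per condition and per-generation
  trajectories thinned 10–20× (windows several thousand generations wide
  retain hundreds of samples).  The neutral sweep runs a proportionally
  rescaled schedule with rescaled windows; the CNV-phase experiments keep
  the full default schedule because the balanced divergence grows with
  absolute CNV age and does not rescale.

## Known limitations

* One-way binary mutation lets sites fix derived permanently;
  at the defaults ~2.6% of a block saturates over a full run, a negligible
  downward drift in mutational input.
* Under the verbatim (1−s) effective-rate treatment, extreme selfing
  (s = 0.999) leaves C_eff ≈ 0.008 at C = 8.4, which cannot sustain any
  between-copy homogenization: copy diversities fall to the single-copy
  level rather than to the intermediate (~2×) plateau reported for the
  original implementation of this scenario.  Relatedly, with the 10%
  tract:block ratio, strongly unequal exchange at high C behaves as a
  source–sink flow that depresses rather than raises the acceptor's
  diversity, and conversion between long-diverged paralogs at intermediate
  C *inflates* diversity of the linked copy under CNV balancing (imported
  tracts carry paralog divergence — the allele-factory effect) instead of
  eroding it.  These regimes are where this implementation's equilibria
  visibly differ from the original study's figures; the acceptance checks
  report the measured values as they are.
* LD between paralogs sampled in different (unphased, unpaired) allele
  sets is not defined here; r² is computed within an allele set.
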