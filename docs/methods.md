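# Methods

## The phasing problem

A patient carrying two heterozygous mutations in a recessive-disease gene is
affected only if the mutations sit on opposite chromosome copies (*trans*);
if both sit on one copy (*cis*) the other allele is intact. Sanger sequencing
cannot separate the two configurations. `matephase` resolves them from
standard paired sequencing data: the two reads of one sequenced fragment come
from one physical DNA molecule, so any variant bases they observe are in cis
on that molecule. Short paired-end (PE) fragments link positions up to a few
hundred bp apart; mate-pair (MP) libraries, in which multi-kilobase fragments
are circularized and re-sequenced across the junction, link positions
kilobases apart. Pooling many such linked observations over a deeply covered
amplicon yields a statistical phase call with an explicit confidence
statement.

## Association matrices

For an ordered pair of heterozygous SNV positions (upstream h_i, downstream
h_j), the association matrix A is the 4×4 table

    A[b1, b2] = #{fragments calling base b1 at h_i and b2 at h_j},

rows and columns in the fixed order A, C, G, T. For a true biallelic pair all
mass should fall in two cells — the diagonal pair of allele combinations for
cis, the anti-diagonal pair for trans. The off-allele cells are retained
because they are exactly what the error decomposition measures.

Fragments are identified by read name; secondary, supplementary and
duplicate-flagged alignments are ignored. If a fragment's two reads both
cover a site and disagree, the call is dropped for that fragment
(conservative: no majority vote, no N). Base calls outside A/C/G/T or below
the quality floors (defaults: base quality ≥ 20, mapping quality ≥ 20,
conventional clinical-NGS floors) are not observations.

## Row bootstrap with injected error mass

Each matrix row (one upstream allele) with counts c and total n is converted
to adjusted probabilities

    p_b = (1 − ε) · c_b / n + ε / 4,        ε = 0.01 by default,

i.e. one percent of probability mass is spread uniformly over the four
downstream bases to model random sequencing error, and the observed mass is
rescaled so the row still sums to 1 (the minimal reading of "spread 1% across
the row"; the split and renormalization are this package's choice). Then
`n_iter = 1000` multinomial resamples of size n are drawn from p, converted
to proportions, and per-base confidence intervals are taken as the 1st and
99th percentiles of the resampled proportions using the nearest-rank rule.
Following the method's convention these are labelled "99% CI"; note that the
1st-to-99th percentile band is a literal percentile interval, not a
calibrated 99%-coverage interval — we keep the literal rule and the label
rather than silently substituting a different estimator. A row with n = 0 is
a zero-coverage signal, never an interval.

## Pair calls and chained extension

For a single pair, both upstream-allele rows are bootstrapped independently;
each selects its argmax downstream base. The configuration is cis if ref
selects ref and alt selects alt, trans for the opposite pattern, and
ambiguous if the rows agree on one base, an argmax ties, or any selected
base's CI lower bound fails to exceed every rejected base's CI upper bound in
its row.

For sites further apart than any fragment spans, matrices A_1 = (h_0, h_1),
A_2 = (h_1, h_2), … are chained under a Markov assumption (each step's
linkage is independent of earlier steps, reflecting the physical independence
of the fragment sets). One base is chosen at h_0 (default: the REF allele;
configurable), the corresponding row of A_1 selects the base at h_1, whose
row of A_2 selects the base at h_2, and so on. The opposite allele is phased
by starting from the alternate base at h_0; the two chains are cross-checked
and must select complementary bases everywhere.

Confidence across a chain uses two cumulative quantities:

* cumulative probability: the running product of step probabilities,
  Π_{j≤k} p_j — exact, tested to 1e-12;
* cumulative CI: per bootstrap iteration b, the product Π_{j≤k} draw_j[b] of
  the selected-base draws, iterations paired by index across steps (each
  matrix is resampled independently; index pairing of independent streams is
  this package's choice where the procedure is underdetermined), with
  nearest-rank 1st/99th percentiles per step.

A step is *confident* while its cumulative CI lower bound exceeds the CI
upper bound of every rejected base at that step; once a step is ambiguous,
later steps are still reported but flagged as downstream-of-ambiguity.
Argmax ties break to the lowest base in A < C < G < T order and flag the
step ambiguous.

Chain plumbing around coverage holes: if an adjacent pair has fewer than
`min_total = 20` linked fragments (below which the bootstrap percentiles are
too coarse to mean much), the junction is bridged by skipping to the next
site that restores coverage, and the skipped site is later phased from its
nearest anchored neighbor's pairwise matrix; if no bridge exists, the chain
breaks and phasing restarts downstream with a fresh phase set (and a fresh
cumulative product). In the phased VCF, GT is pipe-phased with a PS tag equal
to the first position of the segment; segments split at broken or ambiguous
junctions, and singleton segments stay unphased.

## The simulator

The generator emulates the study conditions the method was designed for: a
10 kb diploid amplicon with K heterozygous SNVs of known phase, sequenced as
101 bp reads from both ends of each fragment, with

* a PE+MP size mixture: PE ~ uniform on [100, 600] bp (clamped below at the
  read length, since a fragment cannot be shorter than one read); MP ~
  truncated log-normal on [500, 5000] bp with mean 2000 bp. The log-normal σ
  is fixed by reading the stated range as the central 95% of the untruncated
  law (σ = ln 10 / (2·1.96) ≈ 0.587) and μ is solved numerically for the
  truncated mean — the only two published facts about the law are its range
  and mean, and this is a one-parameter-free way to honor both. A uniform MP
  law is available for analytic tests. Default PE fraction 0.2 (the PE reads
  of an MP protocol are a co-purified minority subpopulation);
* fragment-level recombination chimeras at rate 0.07: the template switches
  to the other haplotype at a uniformly placed internal breakpoint, the
  dominant artifact of long-range-PCR-amplified libraries;
* random base-call error 0.02 per het-site call (uniform over the three other
  bases). Quality strings are constant Q37; per-base quality modelling is out
  of scope, so the error knob applies per het-site call, which is how the
  error is measured downstream.

All randomness derives from a single seed through named sub-streams, so
reruns are byte-identical and individual components can be varied
reproducibly. A truth table records per fragment the source haplotype,
chimera breakpoint, and per-site emitted base and error flag, enabling exact
parameter-recovery oracles.

### Coverage semantics in the evaluation scenarios

`SimulationConfig.coverage` is mean read depth (each fragment contributes
2 × 101 read bases). But the statistic that drives phasing quality is the
*linked* coverage of a site pair — the association-matrix total — and with
101 bp reads at the ends of long fragments only ~2% of raw depth links any
given pair (which is why the original experimental runs needed raw coverages
in the tens of thousands). The evaluation scenarios therefore state their
conditions on the linked-coverage axis and size the library with
`fragments_for_linked_coverage`, which inverts an analytic expectation: the
probability that a random fragment's two read windows cover both sites,
integrated over the size law. Scenario sizes used by the tests and the
acceptance script, chosen to exercise the method at the scale where its
confidence machinery is informative while keeping desk-scale runtimes:

* pair recovery: 2 sites 2 kb apart in a 2.5 kb amplicon, 500× linked
  coverage, 200 replicates;
* chained phasing: 12 evenly spaced sites over 10 kb, 1000× linked coverage
  at the least-covered adjacent pair (~2.7 M fragments, simulated in
  vectorized form without SAM materialization);
* error decomposition: 400× linked coverage (large enough to see a ~7%
  effect, small enough that the ±3-SE recovery band stays wider than the
  small bias random call error adds to the recombinant class).

## Diagnostics

* **Linked coverage vs distance**: for each Δ, the mean over positions x of
  the number of fragments with one read covering x and a read covering x+Δ
  (default grid 101–3000 bp). Intra-read pairs count when Δ is below the
  read length; the default grid starts above it. PE-only support ends at the
  maximum PE fragment size (a fragment of size S links distances up to
  S − 1); MP fragments extend support into the kilobase range.
* **CI width vs coverage**: per coverage N, multinomial(N, p) counts are
  drawn from a fixed row probability vector, bootstrapped, and the CI width
  averaged over all four bases and over replicates. Width falls as 1/√N —
  halving between N = 500 and N = 2000 in relative terms, but by then the
  absolute width is a few percent, the diminishing-returns regime: the drop
  from 500× to 2000× is under 20% of the width at 50×.
* **Error decomposition**: against a known phase, each linked observation
  pair is concordant (both bases from one haplotype), recombinant (both
  bases valid alleles, one from each haplotype — the chimera signature), or
  other (any non-allele base). Categories are disjoint (a recombinant-looking
  pair containing an invalid base counts as other), fractions are reported
  per linked observation pair, and the classification is symmetric under
  swapping haplotype labels.

## What the synthetic data does and does not show

The simulator reproduces the *structure* of the real libraries — fragment
size mixture, linked-coverage geometry, chimera and random-error processes —
so passing tests demonstrate that the statistics recover known truth under
those processes at the stated rates. It does not model alignment error,
reference bias, pseudogene cross-mapping, indels, quality-score variation,
duplicate fragments, or coverage non-uniformity along the amplicon; real-data
performance additionally depends on all of these, and on the mapper excluded
from scope here (het sites are given, never discovered; reads arrive already
aligned).

## Numerical choices and degenerate inputs

* Nearest-rank percentiles (the ceil(q·n)-th order statistic); no
  interpolation, so CI endpoints are exact lattice values k/n.
* Seeds are mandatory; all generators are spawned from `SeedSequence`
  children in a fixed layout. Identical seed + inputs ⇒ bit-identical output.
* Zero het SNVs in a VCF is an empty result, not an error; fewer than two
  sites is a distinct "nothing to phase" exit path (code 3) in the CLI.
* A site phased to a base that is neither ref nor alt raises a consistency
  error rather than writing a malformed genotype.
* Floating-point TSV output is printed at 6 significant digits; counts are
  bit-exact integers.

## Known limitations

* The percentile band labelled "99% CI" is not calibrated coverage
  (documented above, kept for fidelity to the method).
* Chaining is strictly sequential; no joint likelihood over all pairs, no
  MEC-style haplotype assembly, no population reference panel.
* Copy-number changes and highly homologous paralogs violate the two-allele
  assumption and are out of scope.
* The cumulative-CI pairing of bootstrap iterations across matrices is one
  of several defensible constructions (sorted-quantile pairing would give
  narrower products); the index-paired independent version matches the
  physical independence of the fragment sets.
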