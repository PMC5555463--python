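# Methods

## Model

The package models a biallelic cross between a recurrent parent
(allele `A`, state code 0/1/2 = copies of the donor allele) and a
donor parent (allele `B`).  Meiosis in a parent of known phase is
enumerated exactly: an inheritance vector over the ordered locus set
is drawn with probability ½ for the starting chromatid and a switch
probability equal to the adjacent recombination fraction `r` between
consecutive loci.  Adjacent loci on different chromosomes get `r = ½`
exactly; within chromosomes `r` derives from cM positions through a
map function (Kosambi by default,
`d = 25·ln((1+2r)/(1−2r))`; Haldane and Morgan available).  Crossovers
in disjoint intervals are independent — no interference beyond what
the map function implies — which is adequate for the two-point
analyses the package performs.

Gametophytic selection is a set of rules `(pattern, sex, penetrance)`:
a gamete whose haplotype matches the pattern (wildcards allowed) is
inviable with probability `penetrance` when transmitted through the
stated sex.  Penetrance defaults to 1 (complete sterility): the
motivating data show a complete absence of the double-null homozygote
class, which is consistent with full penetrance although it only
bounds it loosely; partial penetrance is configurable but never
estimated here.  The surviving-gamete mass (the renormalisation
constant) is reported alongside the renormalised distribution; on the
male side it *is* the plant's expected pollen fertility, which is why
the same computation predicts both genotype ratios and the
50/75/100 % fertility classes.

Offspring distributions are the outer product of the two sex-specific
gamete distributions, aggregated to unphased genotype classes in a
fixed locus-major order (AA < AB < BB, first locus slowest).  All
probability arithmetic is polymorphic: exact `Fraction` inputs give
exact rational outputs (this is how the canonical 1:2:1:1:3:2:0:1:1
and 2:3:7 ratios are derived, and how the test suite asserts them as
identities rather than approximations); float inputs flow through
unchanged for likelihood work.

Unphased genotypes heterozygous at more than one linked locus are
rejected rather than guessed: gamete frequencies depend on coupling
versus repulsion, and a silent wrong answer is worse than an error.
For unlinked loci phase is irrelevant and resolved canonically.

## Transgene rescue

The complementation design is modelled as `c` independent, unlinked,
hemizygous insertions of a functional gene copy in the selfed
transformant.  A gamete inherits at least one insertion with
probability `q = 1 − (1/2)^c` and is then viable even if it matches a
sterile pattern; rescue applies to male gametes only by default, since
the sterile patterns are male-specific.  Closed forms under selfing of
a single-locus semisterile transformant: marker classes 1:1:0 at
`c = 0`, 2:3:1 at `c = 1`, approaching 1:2:1 as `c → ∞`, with the
heterozygote class pinned at ½ for every `c ≥ 1`.

Copy-number estimation maximises the multinomial likelihood of the
observed (AA, AB, BB) marker counts over integer `c`.  Two deliberate
choices:

- **Marker–gene recombination** is part of the model (default
  `r = 0.01`): the assayed marker is linked to, not identical with,
  the rescued gene, so the class that is impossible at `c = 0` can
  still appear through a recombinant gamete.  Without this term a
  single such plant — the motivating vector-control family contains
  exactly one — would force a spurious `c ≥ 1`.  Counts in classes
  impossible at `r = 0` under the estimated `c` are reported as
  recombination-attributed.
- **Boundary flagging**: the expected ratios converge geometrically in
  `c`, so a maximum at the top of the candidate range with the profile
  still rising is reported as `c ≥ max_c` rather than a point estimate.

That geometric convergence is also an intrinsic limit: adjacent copy
numbers beyond 1 differ by a few thousandths of a nat per plant
(KL(c=2‖c=3) ≈ 0.0015), so families of ~80 plants cannot reliably
distinguish them — the acceptance suite measures this recovery rate
honestly and the corresponding check documents the limitation.  Real
studies measure copy number by qPCR for exactly this reason; the
segregation-based estimate is a consistency check, not a substitute.

## Statistics

*Goodness of fit.* Expected counts are `N·ratio_i/Σratio`.  Classes
with expected ratio 0 are dropped (the Pearson term is undefined) and
`df = retained − 1`; an observed count in such a class is a model
violation and raises with the offending class named.  This convention
reproduces `P ≈ 0.93` for the canonical 90-plant family.

*Fisher's exact test* sums hypergeometric point probabilities in log
space.  One-sided tails sum tables at least as extreme in the stated
direction; the two-sided tail uses the minimum-likelihood convention
(all tables no more probable than the observed one), which is the
convention behind the published p-values this package reproduces.

*Model selection* scores each candidate sterile-haplotype model by the
multinomial log-likelihood of genotype class counts plus per-plant
binomial log-likelihoods of fertile-grain counts given model-implied
fertility.  The pollen term is essential: male- and female-side
selection with the same pattern give *identical* genotype
distributions (an exact symmetry, asserted in the tests), so genotype
counts alone tie them; only pollen phenotypes attribute the selection
to a sex.  All candidates have equal parameter count, so ranking uses
raw log-likelihood with no information criterion; a candidate giving
probability zero to an observation scores −∞ and ranks last rather
than raising.

*Fertility classing* compares beta-binomial likelihoods around the
candidate class means with intra-class correlation `rho`
(default 0.01, chosen to mirror the visible spread of per-plant
fertilities within a class in real families; `rho = 0` collapses to
binomial and degenerate means 0/1 are handled as point masses).  Exact
ties break toward the lower class and are flagged.

## Linkage

Two-point estimation maximises the multinomial likelihood of the
joint marker × gene class counts, with expected frequencies computed
by the transmission engine as a function of `r` — i.e. *including* the
selection distortion, which would bias a naive recombinant-fraction
count.  Maximisation scans a 0.001 grid over `[0, ½]` and refines the
bracketing interval by bounded scalar minimisation (deterministic and
derivative-free; the coarse-grid-plus-refinement reaches the same
optimum as a fine grid at a fraction of the evaluations).  The 95 %
interval is the profile-likelihood region within a 1.92 log-likelihood
drop, found by bisection; in a neutral backcross the estimator reduces
exactly to the closed-form recombinant fraction, which the tests
assert.  Estimated distances are conventionally reported to one
decimal in cM.

Fine-mapping interval delimitation takes per-marker recombinant counts
ordered along the chromosome: markers with zero recombinants
cosegregate with the gene, and the reported interval is bounded by the
nearest markers with recombinants on each side (the lightest adjacent
pair when no marker cosegregates).  All-zero counts return a
`cosegregating` status, not an error.  When recombinants are counted
from unphased plant tables, each plant contributes
`|marker_state − gene_state|` recombinant chromosomes — a lower bound,
since a double recombinant in repulsion is invisible.

## Simulator

`simulate_population` draws each plant gamete by gamete: inheritance
vectors with Bernoulli(`r`) switches, rejection of inviable gametes
with probability `penetrance·(1 − q)`, beta-binomial pollen counts
around the plant's model fertility, and uniform random missingness.
One seed expands into separate substreams (genotypes, pollen,
missingness) so adding a stream never perturbs another; outputs are
bit-reproducible from the configuration.

Defaults mirror the segregating-family design the analysis targets:
90 plants per family, 200 pollen grains scored per plant, two unlinked
loci with male `B|A` gametes sterile, `rho = 0.01`, no missing data.
Problem sizes used by the calibration tests — 200 families for model
recovery, ~1900-plant fine-mapping families, 900 replicates of
1000-plant backcrosses for interval coverage — were chosen as the
smallest sizes at which the measured rates are stable against their
asserted margins.

What the simulator does *not* emulate: genotyping error (only
missingness), crossover interference, pollen competition, variation in
grains scored per plant, or whole-genome background segregation.
Passing calibration tests therefore demonstrate correctness of the
inference machinery under the stated model, not robustness to these
real-data complications.

## Known limitations

- Two alleles per locus, diploids only; no mutation or de novo marker
  discovery.
- Multi-generation `propagate` tracks unphased class distributions, so
  it is restricted to designs where phase is irrelevant (unlinked
  loci, or one heterozygous locus per linked block).
- Two-point only: no multipoint/interval mapping or marker ordering.
- Copy-number estimates above `c = 1` are weakly identified from
  segregation data alone (see above).
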