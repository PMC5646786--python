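# Methods

## The model

The question the package answers is: do two candidate-gene lists, produced
by independent selective-sweep screens in different species, share more
genes than chance allows? The null model treats each list as a uniform draw
without replacement from a common universe of `n` distinct protein-coding
genes — sizes `a` and `b` — and asks for the distribution of the
intersection size `V = |A ∩ B|`.

Although both sets are random, the identity of the first set is irrelevant
by exchangeability: conditioning on `A` reduces `V` to the standard
hypergeometric law

    P(V = v) = C(a, v) · C(n − a, b − v) / C(n, b),

with support `max(0, a + b − n) ≤ v ≤ min(a, b)`, mean `ab/n`, and variance
`(ab/n)(1 − a/n)(n − b)/(n − 1)`. The package implements the reduced form
and verifies the reduction two independent ways: a full subset-pair
enumeration oracle at small `n` (exact rationals, every `C(n,a)·C(n,b)`
pair visited), and a two-sample Kolmogorov–Smirnov comparison between the
literal two-subset Monte Carlo sampler and the fixed-first-set sampler.

Significance is always the upper tail `P(V ≥ v)` — the probability of an
overlap at least as large as observed. The strict tail `P(V > v)` is
deliberately not exposed: the ≥/> off-by-one is the most common misuse of
this statistic.

### Model assumptions

- All `n` genes are equally likely candidates in every screen (no
  length/GC/annotation-density bias), and the two screens are independent.
- Categories are distinct: a gene appears at most once per list.
  Harmonization and deduplication enforce this before any test runs.
- `n` is a single effective universe shared by both species. The default
  configs use `n = 19,500`, a round figure for the protein-coding gene
  count common to the mammalian genomes compared; the tail at `v ≈ 41`
  changes only in the third significant digit for `n` within ±1,000 of
  that, so the conclusion is robust to the exact choice.

## Numerical choices

- Binomial coefficients are computed as log-gamma differences; the pmf is
  exponentiated only at the end. Tails sum the smaller side of the support
  directly (the other side as `1 − lower sum`) with exact-rounded float
  summation (`math.fsum`), then clamp to `[0, 1]`.
- The pmf is evaluated with `(a, b)` in canonical (sorted) order so the
  mathematical symmetry `pmf(n, a, b, v) = pmf(n, b, a, v)` holds exactly
  in floating point, not just approximately.
- Agreement budgets: analytic vs pmf-summed moments to 1e−10 relative
  (checked at `n = 19,500`); our tail vs `scipy.stats.hypergeom.sf` (an
  independent implementation path) to 1e−8 relative.
- The brute-force oracle refuses `n > 14` — beyond that, full enumeration
  is no longer interactive and the oracle's purpose (an independent check
  at toy scale) is better served by refusing than by silently sampling.

## Monte Carlo null

The simulation draws two sets without replacement and records
`|A ∩ B| ≥ v` across trials. The default sampler fixes `A = {0..a−1}` and
simulates the second draw as a sequential urn: at step `j` the probability
that the next gene is a hit is `(a − h)/(n − j)` given `h` hits so far.
This is an exact draw-by-draw simulation of sampling without replacement
(not a shortcut through the hypergeometric formula being tested), and it
vectorizes across trials: 10^6 paper-scale trials take a few seconds. The
literal two-subset draw is available as `method="two_subset"` and backs the
reduction-validation test.

Estimates report the trial fraction, the seed, and a normal-approximation
95% binomial CI — descriptive at the default 10^6 replicates, where the
approximation error is negligible for fractions above ~10^−4. Identical
seeds give bit-identical results (numpy `default_rng` bit-stream contract).

## Synteny verdicts

A shared symbol only evidences convergent selection if it names orthologous
loci. The check compares the ordered protein-coding genes flanking the
focal gene in two species:

- `shared_flanks` counts symbols common to both neighborhoods (union of
  both sides);
- order consistency requires the shared symbols plus the focal to appear
  as the same sequence in both species, in the given orientation or after
  full reversal of one block (assembly orientation is arbitrary), with at
  most `max_insertions` non-shared genes interleaved between consecutive
  shared ones;
- `conserved = shared_flanks ≥ min_shared AND order-consistent`.

Defaults: 4 flanks per side where available, `min_shared = 4` (half the
flank budget), `max_insertions = 1`. The sources this kind of curation
works from give worked examples but no numeric criterion, so the threshold
is an explicit, documented parameter rather than a buried constant; all
three are CLI-tunable. Strand is ignored — only gene order matters.
Neighborhoods come from TSV fixtures or, via the `gffutils`-based helper,
from a GFF3 annotation (protein-coding gene features sorted by start
coordinate per sequence region; 0-based half-open internally).

## Synthetic data

The generator emulates exactly the level at which the statistics operate:
gene-list membership. It draws pools uniformly without replacement from a
synthetic universe (`G00000…`, disjoint from real gene nomenclature), with:

- a **planted overlap**: a fixed set of symbols deterministically inserted
  into designated pools (exact planting keeps power statements crisp);
- **alias noise**: records emitted under a variant spelling (`SYMBOL-V1`)
  together with the alias table that resolves them;
- **non-coding contaminants**: extra records classed miRNA/antisense/other,
  in a binomial number per pool at the configured rate.

Memberships are fixed before any noise randomness is consumed, so the same
seed yields identical memberships at any noise setting, and a truth table
(pool, symbol, planted) is emitted alongside the data. Neighborhood
generation replicates one block across species and applies a named
rearrangement (insertion, inversion, shuffle, translocation) to one
species, returning the expected verdict under default thresholds.

What the generator does **not** model: sweep detection itself (linkage,
allele frequencies, sweep-calling error), per-gene ascertainment bias,
correlated screens, or realistic gene-name pathology beyond one variant
spelling per symbol. Passing tests therefore show that the statistics and
plumbing behave correctly under the stated null and alternatives — not
that any real screen satisfies the null's uniformity assumptions.

## Calibration of a discrete test

Because `V` is discrete, the upper-tail p-value is *super-uniform*: its
null CDF satisfies `P(P ≤ u) = u` exactly at achievable levels
`u = P(V ≥ v)` and `P(P ≤ u) < u` between them. A continuous-uniform
goodness-of-fit test on simulated p-values would therefore reject given
enough replicates even for a perfectly calibrated test (at
`n = 19,500, a = 691, b = 742` the largest pmf value is ≈ 0.078, which is
the size of the largest CDF step). The calibration suite consequently
checks the two statements that are actually true of a correct
implementation: simulated null overlaps follow the exact pmf (chi-square
with tail bins pooled to expected counts ≥ 5), and the empirical p-value
CDF never exceeds the uniform beyond binomial noise at conventional
thresholds — i.e., the test is never anti-conservative. Power is verified
separately: planting 25 shared genes (pushing the expected overlap to
≈ 51) yields `p < 0.01` in ≥ 95% of seeds.

## Battery defaults

The shipped `configs/paper_battery.yaml` encodes the published comparison
sizes: the domesticate pool (a = 691) against the AMH pool (b = 742,
v = 41) and its per-source subsets (108/9 and 419/24), the great-ape
controls (chimpanzee 415/16, orangutan 500/20, gorilla 426/12), and the
wolf/wisent controls against the AMH pool (a = 742; b = 32/70/33/32/425/72
with v = 3/0/1/1/11/3). Wolf and wisent rows are size-driven because the
underlying lists are not machine-readably published; pool-driven rows
(TSV files) are supported and used for the packaged 41-gene fixture.
Significance is reported at both 0.05 and 0.01. Reports render floats to 4
significant digits and are byte-identical across reruns of the same config
and seed.

## Problem sizes used in the checked examples

The test suite runs the exact test at full published scale (desk-cheap),
Monte Carlo confirmations at the published 10^6 trials, pipeline
calibration on 500 seeded synthetic replicates at full scale
(n = 19,500, pools 691/742), and power on 200 replicates — the whole
suite completes in well under a minute on one core.

## Known limitations

- Harmonization is only as good as the alias table; the packaged fixture
  covers a handful of common legacy renames, not the full HGNC history.
- The universe size `n` is a modeling choice, not an estimate with
  uncertainty; sensitivity should be checked by rerunning with plausible
  alternatives.
- Multi-pool significance is handled pairwise; no joint distribution for
  the intersection of three or more random draws is provided.
- The synteny verdict is symbol-based; it cannot detect paralogy when the
  flanking genes were themselves misassigned the same names.
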