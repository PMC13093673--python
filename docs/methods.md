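# Methods

## Problem setting

A resurrection experiment estimates evolutionary change as the
difference between descendants and revived ancestors grown in a common
environment. Two distortions threaten the ancestral baseline: a
*storage effect* (a plastic response to storage stress, removable by a
refresher generation) and the *invisible-fraction bias* (genotype-
correlated mortality in storage, not removable by design). This package
implements a mechanistic model of the second: seed "birth order" on the
maternal plant links provisioning (hence storage survival) to the sire's
flowering-time alleles (through temporally assortative mating), so a
sieve on birth order becomes a sieve on flowering-time genotype.

## Deterministic single-locus model (`toy_model`)

Two homozygous lines EE (early) and LL (late) with genetic values 10 and
30 days and a partially dominant heterozygote EL at 20 days. Four seed
batches (dam line × priority) get sire pools ordered by the season:
(EE, first) pure early, (EE, last) mixed, (LL, first) mixed, (LL, last)
pure late. The mixed pools default to 50:50 — the unique symmetric
choice; both are exposed as parameters, as are batch weights (default
equal). Offspring distributions follow the Mendelian cross of a
homozygous dam with a two-class sire pool. Survivor-weighted means are
computed in double precision (the quantities are small rational numbers;
round-off is far below reporting precision) and printed at one decimal.
Degenerate inputs (all effective weights zero) raise rather than return
NaN.

Two exact invariants are tested: priority-independent survival cancels
from the weighted mean (zero bias for any batches), and identical sire
pools across batches give zero bias under any survival asymmetry — the
bias requires *both* assortative mating and a priority-dependent sieve.

## Flowering-season simulator (`phenology`)

Each plant has a flower-deployment density over time: `uniform` on
[onset, onset + duration] or `triangular` peaking mid-season, both unit
area. Defaults: 30-day duration, late line onset 14 days after the
early line. A flower contributes pollen and ovules at its deployment
instant; flower lifespan is folded into the density, which keeps the
pollen-pool fraction analytic. The late-line share of the pollen pool
at time *t* is the density-weighted share of open late-line flowers,
with the dam's own flowers excluded (obligate outcrosser). Seeds whose
birth time finds no compatible sire are dropped and counted, never
selfed.

Per dam, birth times are i.i.d. draws from its density, sorted to give
birth ranks; priority labels take the lowest `ceil(n·first_fraction)`
ranks as *first* and the highest `ceil(n·last_fraction)` as *last*
(count-event windows from the original calendar are not reproducible, so
rank quantiles stand in). Storage survival is an independent Bernoulli
draw per seed at `s(treatment, priority)`; middle seeds use the mean of
the first/last probabilities. Default survival probabilities are
control 0.99 and aged 0.78 / 0.68 (first / last): the aged mean sits 26
points below control with a 10-point priority gap. Phenotypes are
genotype value + N(0, env_sd²); `env_sd = 0` reduces exactly to the
deterministic model.

Randomness: one integer seed per simulation; each dam derives a
sub-stream from (seed, dam index), so cohorts are bit-reproducible and
adding dams never perturbs earlier streams.

### Simulator/closed-form concordance

With an early plant flowering on [0, 20] and a late plant on [10, 30],
first-half seeds of each dam see a pure pool and the overlap window is
50:50, matching the deterministic batch structure. Self-exclusion is
disabled for this check (`exclude_self=False`): removing the dam's own
flowers is a finite-population correction of order 1/(2N) that is
orthogonal to the sieve mechanism under test. The rank-median boundary
wobbles by O(√n) seeds, contributing a systematic offset of roughly
2/√(seeds per dam) days (≈ 0.03 d at 5,000 seeds); the concordance test
runs 8 independent replays of 10⁴ seeds and checks the mean bias against
2.5 days within 3 Monte-Carlo SEs.

## Survival statistics (`survstats`)

Flowering onset is right-censored time-to-event data (plants not yet
flowering at study end). The product-limit estimator and the log-rank
test are delegated to `lifelines`; Wilson intervals for germination
rates to `statsmodels`. Ties between an event and a censoring at the
same time follow the standard convention (event first). Comparisons are
pairwise log-rank tests with no multiplicity correction — the reporting
style being emulated; mixed models controlling maternal ID and block are
deliberately out of scope. The median is the smallest event time with
S ≤ 0.5, `inf` when never reached. Tests pin hand-computed oracles (the
3-observation censored product-limit; the two-sample statistic 49/17)
and a 1,000-replicate null simulation of the log-rank type-I error.

## Resampling simulations (`bias`)

Bias statistic: control (descendant) cohort mean minus aged (ancestral)
cohort mean, in days, with cohort means taken *as if priority were
unknown* — exactly what a resurrection study without priority records
would estimate. Censored observations are excluded before pooling.

* **Simulation one** draws both cohorts from the first/last flowering
  pools with priority mixes proportional to germination (survival) rates
  per treatment: each seed's priority is a Bernoulli draw at the
  normalised rate, so the mix itself varies binomially as it would in a
  real germination batch. By default both cohorts draw from the control
  pools (the descendant data, free of storage effects); a toggle sources
  the aged cohort from its own treatment's pools.
* **Simulation two** fixes the control mix at 50:50 and sweeps the aged
  first-fraction over 0.50…0.95 (step 0.05) with *fixed* counts
  (`round(n·f)`), because here the ratio is the independent variable.
  Equal cohort sizes remove mortality effects that are independent of
  priority. The analytic expectation is (f − 0.5)·Δ for pools whose
  means differ by Δ; the suite checks recovery to 0.01 days at 10⁵
  iterations with an even cohort size (200) so that rounding the split
  is exact.

Sampling is with replacement by default (cohort size 245, one
experimental group; 10,000 iterations), all configurable; iterations are
vectorised in blocks of 10,000 to bound memory. `end_to_end_replay`
chains simulator → priority → sieve → survivor mean against an
independent unselected cohort from the same population.

## Synthetic experiment generator (`synth`)

Emulates a balanced three-generation design: F1 with 44 plants per
treatment × priority × line × block cell (704 rows), F2 with 245 per
treatment × priority group (980 rows). Germination is Bernoulli at the
survival-model rates (F2 at 0.98 — storage effects do not recur);
flowering day is a rounded Gaussian around group means; censoring is
Bernoulli at 3/695 (F1) and 20/941 (F2), censored plants carrying the
study-end day (60) as their observation time. Group means: F1 control
21 d with a +1-day aged shift (the plastic storage effect); F2 has no
treatment main effect, but the aged group carries a 2-day first/last gap
centred on the baseline (first 20, last 22) — the genetic signature the
sieve mechanism predicts. The 21-day baseline and 3-day SD are
placeholders, not measured values. Germination failures are kept as
rows (`germinated=0`), mirroring a thinned design rather than dropping
positions.

What the generator does *not* emulate: maternal-family structure and
maternal-ID random effects, block effects on flowering, seed mass,
dormancy, and any non-Gaussian or skewed onset distribution. Parameter-
recovery tests on these tables therefore validate the pipeline's
bookkeeping and statistical machinery, not the field realism of the
distributions.

Tables are long-format CSV (`plant_id, generation, line, block,
treatment, priority, germinated, flowering_day, censored`); missing days
are `NA` (allowed only for non-germinated or censored rows), `#` lines
are provenance comments, unknown extra columns round-trip untouched, and
schema violations name the column and row.

## Command-line interface (`cli`)

One `seedsieve` entry point with subcommands `toy`, `simulate`, `km`,
`resample1`, `resample2`, `synth`, `replay`; a YAML config file can
supply any flag (one section per subcommand, unknown keys rejected by
name), explicit flags win, and every output file starts with provenance
comments (version, global seed, config hash). One global seed feeds all
module sub-streams.

## Problem sizes in the test suite

The suite favours exact oracles where they exist and scales Monte-Carlo
checks to sizes where 3·MC-SE bands are decisive: 8 × 10⁴ seeds for the
concordance replay, 10⁴ grid iterations and 10⁵ closed-form iterations
for the bias surface, 10³ null replicates for the log-rank type-I error,
and the full 704 + 980-row synthetic design for parameter recovery.

## Known limitations

* Single-locus inheritance in the deterministic model; the simulator
  generalises the mating mechanism but still uses line-homozygous
  parents, not a quantitative trait.
* No pollinator behaviour, pollen competition, provisioning dynamics or
  seed dormancy; survival depends on priority only through the supplied
  probability table.
* Flower lifespan is collapsed into the deployment density.
* Log-rank p-values for the experiment-style comparisons are pairwise
  and uncorrected by design.
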