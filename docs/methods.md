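# Methods

## The statistical model

A tumor pair yields *n* distinct genomic loci with a high-confidence (HC)
somatic SNV called in at least one tumor; *X* of them are shared. Treating
*n* as fixed, the shared count is modeled as X ~ Binomial(n, p), with p the
pair's shared-mutation rate. Two regimes are distinguished:

- **independent pairs**: p ≤ p0, the background rate of apparent sharing —
  recurrent driver mutations (PIK3CA- and TP53-like hotspots dominate in
  breast cohorts), chance passenger overlap, and technical artifacts. The
  artifact component is larger for two tumors sequenced in the same batch
  than for cross-patient pairings, which is why the recommended p0 (3–4%)
  sits well above empirically observed cross-patient maxima (~2.8%).
- **clonal pairs**: p ≥ pa, the sharing rate inherited from the founding
  clone; observed clonal pairs in public data sit in the 13–100% range, so
  pa = 15% (default) or 20% is a conservative lower bound.

The test of H0: p ≤ p0 vs p > p0 is exact and one-sided: reject when
X ≥ c(n, p0, α), where c is the smallest integer with
P(X ≥ c | n, p0) ≤ α. The ≤-boundary convention is the standard exact-test
one; at the recommended operating points it is verified against exact
rational arithmetic (e.g. n = 21, p0 = 0.04 has P(X ≥ 3) = 0.0497 ≤ 0.05,
giving c = 3). The rejection rule "X ≥ c" and the reported p-value
P(X ≥ x_obs) are dual by construction: X ≥ c exactly when the p-value is at
most the achieved α of c. Exact two-sided Clopper–Pearson intervals
(beta-quantile form) are reported for the CLS alongside the p-value.

Binomial tails are computed through the regularized incomplete beta
function (`scipy.stats.binom.sf`), accurate to machine precision far into
the tails; the test suite cross-checks every tail for n ≤ 200 against an
exact rational-arithmetic summation.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `p0` | 0.04 | null shared-call rate (fraction); assay-specific, calibrated from cohorts |
| `alpha` | 0.05 | one-sided significance level |
| `pa` | 0.15 | design alternative; drives the underpowered flag and design searches |
| `confidence` | 0.95 | Clopper–Pearson level |
| `germline_min_hq_depth` | 15 | minimum germline reads above Q20 for a homozygous-reference call |
| `germline_max_alt_reads` | 1 | maximum germline alternate reads |
| `germline_max_alt_fraction` | 0.05 | germline alternate fraction must be strictly below this |
| `tumor_min_depth` | 40 | minimum coverage in *both* tumors |
| `exclude_dbsnp` | true | reject known polymorphisms (likely germline) |

## HC filtering

A locus enters the shared/private profile when it passes, in fixed
precedence: (1) not in dbSNP; (2) germline homozygous-reference
(hq_depth ≥ 15, alt reads ≤ 1, alt fraction < 5% — strict inequality);
(3) both tumors covered at ≥ 40×; (4) a caller-emitted variant in at least
one tumor. The precedence order only determines which reason a doubly
failing locus is logged under; it cannot change X or n. A call in the other
tumor at the same allele-level key — at any confidence — makes a locus
shared: requiring high confidence in both tumors would systematically
undercount sharing, because shared mutations at low allelic fraction (low
cellularity) are the dominant false-negative mode.

Mutation identity is the full (chromosome, 1-based position, ref, alt) key,
so two different alternate alleles at one position are two mutations — the
stricter convention where only "loci" are specified. Indels and MNVs are
excluded with a logged tally: the method is defined on SNVs.

## Decisions and the underpowered flag

`fit()` reports one of three decisions. `clonal` when X ≥ c; otherwise
`underpowered` when n is below the minimum-n for 80% power at (p0, pa, α)
(44 under defaults), else `independence_not_rejected`. A rejection is
reported as `clonal` even when n is small — the exact test's level does not
depend on power — but the boolean `underpowered` field stays set so reports
never hide a thin evidence base.

When n = 0 the CLS is undefined; the API raises an explicit no-test error
rather than emitting a degenerate result.

## Design searches

`critical_value` inverts the exact tail; `min_n_for_power` scans n upward
and returns the **first** n whose own critical value reaches the target
power. Power as a function of n (with c recomputed at each n) is a sawtooth
— it can dip back below the target after first crossing it — and the
first-passing convention is the one that reproduces the published design
grid ((n, c) = (44, 5) at p0 = 4%, pa = 15%). The scan is capped at
n = 10⁶ and raises a search error beyond it.

## Display conventions

Underlying values are never rounded. For display, percentages at or above
2% are shown to the nearest integer and smaller values with one decimal;
this reproduces the conventional presentation of the worked examples (81%,
1.1%, interval 0.1% to 4%) — a single threshold anywhere in (1.1, 3.9)
yields the same strings, and 2% was chosen as the boundary between "round
number" and "vanishing" regimes. P-values display at full precision down to
1e-15 and as "<1e-15" below.

## Cohort calibration

`summarize_cohort` pairs tumors from different patients (all cross-patient
pairs, a cross-group product, or a seeded random subsample) and aggregates
the per-pair CLS distribution. Pairs are streamed one at a time; the CLS
distribution is accumulated into a fixed histogram of 0.1%-wide bins, so
memory does not grow with the number of pairs and 10⁴–10⁵-pair cohorts run
comfortably. `suggested_p0` is a reproducible stand-in for the judgment
call of setting p0 with headroom above the observed background: the
smallest value on the 1% grid starting at 3% strictly above the (binned,
upper-edge) 99.9th percentile of pair CLS. It is a default, not a mandate —
the field overrides it freely. With a user-supplied locus→gene mapping the
shared-mutation tally is per gene (surfacing recurrent drivers); otherwise
per locus.

## The simulator

Each simulated pair draws n from a configurable range, marks each locus
truly shared with probability `true_shared_rate`, and observes:

- a truly shared locus as **shared** only if detected in both tumors
  (independent Bernoulli sensitivities per tumor, modeling cellularity);
  detected in exactly one tumor it degrades to a **private** call;
  detected in neither it is dropped from the observed total (it is
  observed nowhere);
- an unshared locus as **shared** with probability `fp_shared_rate`
  (artifact sharing — the quantity p0 bounds).

This three-knob model maps one-to-one onto the calibrated quantities
(pa, sensitivity loss, p0); it does not model read-level noise, mutation
spectra, copy number, or clonal phylogenies. Passing operating-
characteristic tests therefore demonstrate that the *decision rule* has its
nominal error rates when the binomial sampling assumptions hold — they do
not validate upstream variant calling on real reads.

`generate_fixture_trio` emits full per-locus read-evidence tables that
realize requested shared/private/rejected counts under the default filter
(depths drawn uniformly: germline 25–60×, tumors 45–150×, rejected rows
violating exactly one requested rule); the realized profile is verified
internally before the table is returned. All randomness flows through one
seeded `numpy` generator; identical seeds give bit-identical outputs.

## Problem sizes and numerical choices

Operating-characteristic runs use 10,000 replicates at n = 44, giving a
Monte-Carlo standard error of about 0.4 percentage points on an 80% rate
(acceptance checks allow 3 SE). The parameter-recovery test uses 10⁵ draws.
The exact-rational oracle sweep covers all X ≤ n ≤ 200 at p0 = 4%.
Clopper–Pearson coverage is checked empirically at n = 62 with 10⁴ draws at
p ∈ {0.1, 0.5, 0.8}; exact intervals are conservative, so coverage sits at
or above 95%.

Degenerate inputs: c = n + 1 encodes "no achievable rejection region"
(power 0); X = 0 gives an upper tail of exactly 1 and a CI lower bound of
exactly 0; X = n gives a CI upper bound of exactly 1.

## Limitations

- The binomial model treats loci as exchangeable; recurrent hotspot loci
  mildly violate this and are absorbed into p0.
- p0 and pa are assay- and tumor-type-specific; defaults reflect stringent
  exome pipelines and should be recalibrated (`clstest calibrate`) for
  other assays.
- The VCF route expects single-sample files with DP/AD genotype fields; an
  optional HQD FORMAT field carries the Q>20 depth, which otherwise falls
  back to total depth with a warning.
- Cross-format equivalence holds for loci called in at least one tumor;
  loci called in neither (possible in hand-built evidence tables) cannot be
  represented as VCF variant calls and are dropped by the VCF route — the
  HC filter would reject them anyway.
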