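# Methods

## The measurement model

Input is a table of allele designations per clone and locus, as produced by
standard STR fragment analysis (GeneMapper-style binning is assumed done
upstream; the package never sees peak heights or raw sizes in bp). Alleles
are `repeats[.partial_nt]` with the microvariant part strictly smaller than
the repeat unit, so ordering by `(repeats, partial_nt)` equals ordering by
fragment length within a locus. The panel is 19 STR loci plus amelogenin;
all repeat units are 4 nt except D22S1045 (3 nt). The collective label
"tetranucleotide panel" is therefore not used in arithmetic — shift
calculations always use the per-locus unit.

Amelogenin is stored as X/Y presence flags. A single-allele locus is stored
as observed, with no homozygous-vs-hemizygous imputation: "homozygous" is
only ever evaluated on the designated parental profile, because that is the
profile that determines which loci are informative for LOH.

## Aberration calling

Each clone is compared to an explicitly designated parent, locus by locus
in panel order. With parental allele set `P` and child set `C`:

* novel alleles (`C − P`) and missing parental alleles (`P − C`) are paired
  by an exhaustive optimal matching: a pair is admissible when the length
  difference is a nonzero whole multiple of the repeat unit, at most the
  shift window (default ±2 repeat units); among admissible matchings the
  one with the most pairs wins, ties broken by smallest total |shift| and
  then by shorter parental allele. Each matched pair is a single **EMAST**
  event (the missing allele is the shift template) — not LOH plus gain.
* an unmatched novel allele is classified against the nearest surviving
  parental allele (ties to the shorter allele, flagged `ambiguous_ref`):
  EMAST if unit-multiple-shifted within the window, otherwise
  **UNCLASSIFIED** — reported but excluded from burden, since the event
  taxonomy has no third somatic class.
* an unmatched missing allele is **LOH** when the parent is heterozygous
  there. Parent-homozygous loci can never produce LOH; their lone allele
  can only be replaced (EMAST/UNCLASSIFIED) or drop out entirely, which
  raises a `NullProfileError` (amplification failure, not biology).
* parental Y present and child Y absent is one **Y_LOSS** event.

A child typing a locus the parent lacks is a structural mismatch error. A
locus missing from the child is skipped (treated as untyped). The optimal
matching replaces a per-novel greedy nearest rule because greedy can
mis-pair tri-allelic patterns; the matching key totally orders outcomes, so
the caller is deterministic and provably equivalent to a brute-force
enumeration of all pairings (tested against exactly that oracle).

Burden is `n_loh + n_emast + n_yloss`; a clone is stable iff burden is 0.
Whether Y losses pool into LOH-class tallies in downstream contingency
analyses is a visible switch (`count_y_as_loh`, default true): published
tallies group "loss Y and LOH" together in the step-one analysis, and the
step-two analysis simply excludes the loci already aberrant in the parent
via `exclude_parental_loci`.

## Contingency statistics

All group comparisons are 2×2 tables (a, b = events/non-events in group 1;
c, d in group 2).

* **Odds ratio** OR = ad/bc with the **Woolf CI**
  `exp(ln OR ± z₀.₉₇₅ √(1/a+1/b+1/c+1/d))`, z₀.₉₇₅ = 1.959963985. Any zero
  cell raises an error unless the Haldane–Anscombe +0.5 correction is
  requested explicitly; it is never applied silently.
* **Fisher exact, two-tailed**, point-probability convention: sum the
  hypergeometric probabilities of all margin-preserving tables whose point
  probability is at most the observed one (relative tie tolerance 1e-7,
  the common software convention). Implemented with log-gamma factorials,
  so it is overflow-safe and exact in practice for totals up to ~10⁴; it is
  tested against an exact integer enumeration over every table with n ≤ 40
  and against an independent library implementation.
* **Pearson chi-square** for 2×2, df = 1, **without** continuity
  correction: `χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`. The uncorrected
  statistic is deliberate: it is the dialect that reproduces the published
  p-values this package is validated against (0.0172, 0.0030, 0.0513,
  0.0384, 0.0618 at four decimals). A Yates-corrected variant exists
  behind `correction=True`. Zero margins are an error.
* **Rates** use exact Clopper–Pearson beta-quantile 95% CIs.

Reports always carry both p-values; `method_note` marks the surfaced one
(Fisher when any expected cell count is below 5, chi-square otherwise).
This is a reporting heuristic only — no published value depends on it.
CIs are printed at two decimals using half-even rounding.

### Growth-rank stratification

Clone serial numbers follow pick order, and wells are harvested as they
reach confluence, so serial rank is a growth-rate proxy. `split_by_rank`
cuts the serially ordered cohort into contiguous near-equal blocks (a
remainder of r goes to the first r blocks, giving 1–127/128–254/255–381
for n = 381 and 1–60/61–120/121–180 for n = 180). `merge_similar_groups`
then pools adjacent fast blocks while their pairwise uncorrected
chi-square p exceeds α (default 0.05), always keeping the slowest block
separate; the merge direction is fixed (fast side first) because the
slow tail is the group of interest. Burden analyses tabulate clones with
burden strictly above a threshold (default 3) in slow vs pooled-normal
groups.

## The cohort simulator

The generator emulates a limiting-dilution subcloning experiment: one
founder cell, `divisions` synchronous doublings (default D = 20, roughly a
single-cell well grown to a monolayer; the true division count between
cloning and harvest is not observable, so D stays a visible parameter),
and per-division, per-locus event probabilities:

| parameter | default | meaning |
|---|---|---|
| `mu_loh` | 0.008 | LOH per parent-heterozygous locus per division |
| `mu_emast` | 0.018 | EMAST per STR locus per division |
| `mu_yloss` | 0.005 | amelogenin-Y loss per division |
| `locus_weights` | none | per-locus EMAST multipliers (non-uniform spectra) |
| `theta` | 0.3 | minimum mutant-lineage fraction for a callable allele |
| `founder_aberrant_frac` | 0.02 | founder already carries one event |
| `fitness_cost` | 1.3 | multiplicative harvest-time delay per true event |
| `growth_noise_sd` | 0.2 | σ of log-normal harvest-time noise |
| `shift_probs` | (0.8, 0.2) | P(|shift| = 1 unit), P(|shift| = 2 units) |

An event arising at division d is carried by an expected lineage fraction
2⁻ᵈ and reaches the profile iff 2⁻ᵈ ≥ θ; with θ = 0.3 only
first-division and founder events are callable while later events
accumulate silently — this deterministic-depth rule replaces full lineage
tracking, preserving the "early events dominate the clone" biology at
desk-scale speed. Observable EMAST substitutes the template allele with
the shifted one (matching the caller's worked examples), LOH removes the
lost allele, and one callable event per locus is allowed (later callable
hits at an already-rewritten locus are masked). EMAST shift magnitudes are
1 or 2 repeat units with probabilities (0.8, 0.2) and a random sign,
flipped when the shifted allele would collide with an existing one.

Harvest time is `base_time · fitness_cost^(true events) · lognormal`, so
`fitness_cost > 1` produces the slow-growth/high-burden association as an
emergent, tunable property (the data motivating it show an association,
not a mechanism), and `fitness_cost = 1` switches it off for null
experiments. Identical sibling profiles emerge naturally whenever the
founder of a well was already aberrant. Randomness: clone i of a cohort
uses the counter-derived stream `default_rng([seed, i])`, making output
byte-identical across runs and independent of parallelisation.

Default rates were calibrated once so a Jurkat-like parent yields cohorts
in the regime the assay is designed for — roughly a third of subclones
with a callable aberration (≈10% LOH-class, ≈25–30% EMAST clones) against
a non-tumour-like configuration below 1 in 100 — and are not tuned per
experiment.

**What the generator does not emulate:** karyotype-level events
(translocations, ploidy shifts), cell death, selection during therapy,
stutter/pull-up artifacts, locus dropout, and realistic non-uniform locus
spectra unless `locus_weights` is supplied. Passing round-trip tests on
simulated cohorts therefore demonstrates internal consistency of caller
and generator under the stated observation model, not calling accuracy on
raw electropherograms.

### Rate estimation

Under the observation model, a clone is callable-aberrant with probability
`1 − (1 − μ)^(L·d)` where L is the number of informative loci and
`d = min(D, ⌊log₂(1/θ)⌋)` the number of detectable divisions (θ > 0.5
leaves none; founder events are assumed off when estimating).
`estimate_rates` inverts the observed aberrant fraction with the
method-of-moments form `μ̂ = −ln(1 − f_obs)/(L·d)` (equal to the exact
inversion to first order; the O(μ²/2) bias is far below sampling error at
realistic cohort sizes) and attaches a percentile bootstrap CI from
binomial resampling of the aberrant flags (B = 1000). A saturated cohort
(f_obs = 1) is not identifiable and raises an error. Calibration: across
100 simulated cohorts of 400 clones the true rate falls inside the 95% CI
at least 90 times (tested).

## Numerical and design notes

* Allele ties in EMAST attribution go to the shorter parental allele and
  are flagged on the event record.
* The Fisher tie tolerance (1e-7 relative) matters only for exact
  probability ties; the enumeration oracle uses the same rule in exact
  integer arithmetic.
* `split_by_rank` puts remainders in the leading (faster) groups, which
  reproduces the published block boundaries for both cohort sizes.
* Problem sizes in the test suite (cohorts of 90–4000 clones, 100 recovery
  trials at n = 400, 50 seeds for the coupling experiment, exhaustive
  Fisher families to n = 40) were chosen as the smallest sizes at which
  the statistical assertions have comfortable margins.
* Known limitations: the caller assumes at most three alleles per locus;
  no MSI-H/L mononucleotide classification; no multiple-testing
  correction (none is applied in the analyses this package reproduces);
  de novo calling without a designated parent is out of scope.
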