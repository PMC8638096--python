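# Methods

## Status model

Every cell of a mutation × sample matrix carries one of three statuses.
*Positive* is user-defined: any cell passing the caller's rule (here, a
minimum mutant-read count, optionally a minimum VAF).  The package's job is
the remaining two labels for non-positive cells:

* **MSN (mutation-specific negative).**  Under H₀, a non-positive sample
  contains mutant reads at the same frequency as a given positive sample of
  the same mutation; conditioning on the margins of the 2×2 mutant/wildtype
  table gives the hypergeometric null (Fisher's exact test).  A cell is
  negative iff it has zero mutant reads and H₀ is rejected (p < α, strict)
  against **every** positive sample of that mutation.  The all-positives
  quantifier makes the rule conservative: one compatible positive sample is
  enough to keep the status unknown.
* **UMC (universal minimum coverage).**  The baseline: negative iff total
  reads ≥ threshold (inclusive) and zero mutant reads.

Assumptions: read counts are exchangeable within a site (no base-quality or
strand modeling); a mutation's relative abundance is roughly shared across
related samples — the premise that makes a positive sample's VAF informative
about the coverage needed elsewhere.  Under strong CNV drift or extreme
inter-sample heterogeneity the test is only approximate, though still
abundance-aware where a fixed coverage cutoff is not.

## Numerical choices

* **Exact integer enumeration.**  P-values are computed from integer
  hypergeometric numerators over the common denominator C(N, column sum);
  the two-sided p sums tables whose numerator is ≤ the observed one, decided
  by integer comparison.  No floating-point tie tolerance exists, so results
  are bit-reproducible and match brute-force enumeration exactly (scipy's
  `fisher_exact` agrees up to its 1e-7 relative tie guard; it is used as an
  independent cross-check in the tests).
* **Sidedness.**  Default two-sided (the standard convention, and the one
  consistent with all worked-example significance bounds).  The one-sided
  option uses the smaller tail of the observed table — the lower tail of the
  zero-mutant sample in classifier use — which keeps the statistic symmetric
  in its two arguments.  One-sided rejects at least as often, so it can only
  move unknowns to negatives.
* **Degenerate tables.**  Either sample with zero total reads gives p = 1: no
  reads, no evidence.  Hence an unmeasured cell, encoded (0, 0), is always
  unknown under both methods without special-casing.
* **Sub-threshold mutant reads.**  A non-positive cell with mutant reads > 0
  (possible when the positive rule demands ≥ 2) is never negative — the
  negative definition requires absence of mutant reads.  By default such
  cells are labeled unknown untested (`always-unknown`); the
  `test-observed-counts` policy runs the tests anyway so the audit table is
  complete, without changing the label.
* **Mutations with no positive sample.**  The all-positives condition would
  be vacuously true; instead all their non-positive cells are labeled unknown
  with a warning, since well-formed input only lists mutations called
  somewhere.
* **No multiplicity adjustment.**  α applies per comparison; it is exposed so
  users can tighten it (e.g. 0.01) rather than silently corrected.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `PositiveRule.min_mutant_reads` | 2 | mutant reads needed to call positive (1 in the simulation study, where any detected read counts as called) |
| `PositiveRule.min_vaf` | unset | optional VAF floor for positives |
| `MsnConfig.alpha` | 0.05 | strict rejection cutoff, per test |
| `MsnConfig.sidedness` | two-sided | see above |
| `UmcConfig.min_coverage` | 20 | inclusive depth threshold (study grids: 20–300X simulated, 10–1000X dual-platform) |

## Simulation design

The simulator emulates repeated measurements (multisite or longitudinal
sampling) of one tumor at tumor-cell fraction f ∈ {0.90, 0.20, 0.05, 0.01},
spanning high-purity biopsies down to liquid-biopsy-like dilution.  Defaults:
200X coverage, 100 clonal mutations present in every measurement, 100
subclonal mutations present in each of 3 measurements independently with
probability 0.5, expected VAF = f/2 (diploid sites), mutant reads
Poisson(200·f/2) where present and 0 where absent.  Coverage is a fixed
per-site total (total = max(200, mutant)); a Poisson per-site coverage mode
exists as an option, as does an exactly-k-of-n subclonal assignment.
Mutations with zero mutant reads in every measurement are excluded before
scoring — no caller would have reported them.  Retained cells are scored
TP/FP (positive vs. truth), FN/TN (negative vs. truth) or unknown; the five
fractions partition the cells.

What the generator does **not** emulate: sequencing error (so FP ≡ 0
structurally), per-site coverage heterogeneity of real capture data, mappability
or allele bias, and CNVs.  Passing benchmarks therefore demonstrate the
methods' behavior under idealized counts, not end-to-end calling accuracy on
real BAMs.  In particular, at f = 0.01 the false-negative and negative rates
of shallow UMC thresholds depend on the (here fixed) coverage distribution,
so low-fraction results are directional rather than point targets.

Two checks anchor the simulator analytically.  At f = 0.90 virtually every
present cell is detected (P(Poisson(90) = 0) = e⁻⁹⁰), so false negatives
vanish for every method, and under UMC-300X (threshold above the 200X
coverage) the unknown fraction converges to the truly-absent share of
retained statuses: with Bernoulli-0.5 presence over 3 measurements,
(100·9/8)/((100 + 100·7/8)·3) = 20%.  Simulation means over ≥ 20 replicate
seeds are required to sit within 3 standard errors of this closed form.
Headline fractions are reported as means over 25 replicate seeds; one
replicate of the full 4-scenario × 6-method grid takes ~20 ms, so replication
is cheap.

## Dual-platform evaluation

When each unit (a single cell) is sequenced on two platforms, the paired runs
should agree on every mutation; cross-unit comparisons are excluded because
cell-to-cell heterogeneity makes disagreement biologically real.  A unit ×
mutation point is *informative* iff neither platform's status is unknown, and
*concordant* iff both match.  Concordance with zero informative points is
reported as NaN, never 0 or 100.  By default a mutation's MSN comparison
anchors are the positives in **all** related samples of the matrix (the
natural reading of "all known positive samples" when 24 samples of one
patient are pooled); a per-pair-only anchor mode is provided since a stricter
reading is defensible.  Conservative settings trade informative points for
concordance; the sweep (`sweep_thresholds`) traces that frontier across
UMC 10–1000X and MSN α ∈ {0.05, 0.01}.

## Open design choices taken

* "Randomly present in half of the samples" for subclonal mutations is read
  as independent Bernoulli(0.5) per measurement (this reproduces the 20%
  unknown share analytically); the exactly-half mode is an option.
* The test's sidedness is not dictated by the method definition; two-sided is
  the default with one-sided exposed, and both satisfy every documented
  worked-example bound.
* Input stores (mutant, total) rather than (mutant, wildtype): totals are
  what pileup tools report; wildtype is derived.
* Column order of matrices is order of first appearance and is never sorted,
  keeping count and status files aligned line by line.

## Limitations

Positives are trusted as given: a false positive among the anchors makes MSN
over-conservative for that mutation (more unknowns), never more permissive.
The method needs at least two related samples and NGS-style counts (it does
not apply to Sanger traces), and it models neither purity nor copy number
when translating a positive sample's VAF into an expected abundance
elsewhere.
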