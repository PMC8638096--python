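# msnstat

Adaptive classification of **negative vs. unknown** somatic-mutation statuses
in multi-sample NGS comparisons.

## The problem

Cancer genomics routinely compares mutation profiles across *related* samples
— multisite biopsies, serial liquid biopsies, or paired platform runs of the
same cell.  A mutation found in one sample may show **zero mutant reads** in
another.  That can mean the mutation is truly absent (*negative*) or that
coverage at the site was simply too shallow to detect it (a false negative,
better reported as *unknown*).  The common fix — a **universal minimum
coverage (UMC)** threshold, e.g. "call negative only if depth ≥ 20X" — ignores
that the coverage needed to rule a mutation out depends on that mutation's
relative abundance, its variant allele frequency (VAF): a 56%-VAF mutation is
detectable at 15X, while excluding a 5%-VAF mutation at 30X is hopeless.

## The method

The **mutation-specific negative (MSN)** rule makes the decision adaptive.
Positive calls are the user's own (any caller or rule such as ≥ 2 mutant
reads); MSN never creates or removes them.  For each mutation, every
non-positive sample *i* (mutant reads m_i, total reads n_i) is tested against
every positive sample *j* of that mutation with **Fisher's exact test** on the
2×2 table

|          | mutant | wildtype  |
|----------|--------|-----------|
| sample i | m_i    | n_i − m_i |
| sample j | m_j    | n_j − m_j |

under H₀: both samples contain the same frequency of mutant reads.  Sample
*i* is called **negative** iff m_i = 0 and p < α against **all** positive
samples; failing to reject against any one positive sample leaves it
**unknown** (more coverage would be needed).  The default is the two-sided
test with α = 0.05, user-adjustable and deliberately unadjusted for multiple
testing.

The package also provides the UMC baseline, a count-level simulator for
benchmarking both rules across tumor-cell fractions, and a paired-platform
(dual-capture single-cell) concordance evaluation.

## Worked example

Two serial biopsies of one patient carry two EGFR mutations; the follow-up
biopsy detects neither, at 15X and 30X depth:

```bash
msnstat fixture --kind table1 --out-dir .
msnstat classify --counts table1_counts.tsv --min-mut-reads 1 \
    --method msn --alpha 0.05 --out msn_status.tsv --audit msn_audit.tsv
```

`msn_status.tsv`:

```
chrom	pos	ref	alt	biopsy1	biopsy2
chr7	55249071	C	T	positive	negative
chr7	55249092	T	A	positive	unknown
```

The audit file shows why.  The first mutation was positive at 40/72 reads
(56% VAF), so observing 0/15 in the follow-up is already incompatible with
equal abundance (p = 3.0e-5 < 0.05): **negative**.  The second was positive
at only 5/100 reads (5% VAF), and 0/30 cannot exclude that frequency
(p = 0.59): **unknown**.  A UMC-20X rule (`--method umc --min-cov 20`) gets
both calls backwards — it labels the first mutation unknown (15X < 20X) and
the second negative (30X ≥ 20X) despite its low expected VAF.

The same applies matrix-wide from Python:

```python
import msnstat as ms

counts = ms.io.read_count_matrix("table1_counts.tsv")
positives = ms.define_positive(counts, ms.PositiveRule(min_mutant_reads=1))
statuses = ms.classify_msn(counts, positives, ms.MsnConfig(alpha=0.05))
print(statuses.to_frame())
```

## Simulation and dual-platform evaluation

`msnstat simulate` draws multi-measurement read counts at configurable
tumor-cell fractions (expected VAF = fraction/2 at diploid sites, mutant
reads Poisson at fixed 200X coverage, 100 clonal + 100 subclonal mutations)
and scores each method's statuses against ground truth (TP/FP/TN/FN/unknown
fractions).  `msnstat eval-dual` sweeps UMC and MSN thresholds on a paired
design (two platforms per unit), reporting informative data points (neither
platform unknown) and between-platform concordance.  See `docs/methods.md`
for the model, its assumptions, and all tunable parameters.

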