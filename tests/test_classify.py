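"""Positive-rule application and MSN/UMC classification, including the two
worked examples and the partition/preservation/monotonicity invariants."""

import numpy as np
import pytest

from msnstat import (
    NEGATIVE,
    POSITIVE,
    TBD,
    UNKNOWN,
    CountMatrix,
    MsnConfig,
    MutationKey,
    PositiveRule,
    StatusMatrix,
    UmcConfig,
    classify_msn,
    classify_umc,
    define_positive,
    validate_positives,
)
from msnstat.classify import TEST_OBSERVED

from conftest import random_count_matrix


# ---------------------------------------------------------------------------
# define_positive
# ---------------------------------------------------------------------------

def test_define_positive_five_sample_example(five_sample_counts):
    statuses = define_positive(five_sample_counts, PositiveRule(min_mutant_reads=1))
    assert statuses.values.tolist() == [[POSITIVE, TBD, POSITIVE, TBD, TBD]]


def test_define_positive_all_zero_matrix():
    counts = CountMatrix(
        [MutationKey("chr1", 1, "A", "T")], ["s1", "s2"], [[0, 0]], [[50, 0]]
    )
    statuses = define_positive(counts, PositiveRule(min_mutant_reads=1))
    assert (statuses.values == TBD).all()


def test_define_positive_thresholds():
    counts = CountMatrix(
        [MutationKey("chr1", 1, "A", "T")], ["s1", "s2"], [[1, 5]], [[100, 100]]
    )
    st = define_positive(counts, PositiveRule(min_mutant_reads=2))
    assert st.values.tolist() == [[TBD, POSITIVE]]
    # adding a VAF floor removes the 5% cell too
    st = define_positive(counts, PositiveRule(min_mutant_reads=2, min_vaf=0.10))
    assert st.values.tolist() == [[TBD, TBD]]


def test_supplied_positive_matrix_with_zero_mutants_rejected(five_sample_counts):
    bad = StatusMatrix(
        five_sample_counts.mutations,
        five_sample_counts.samples,
        [[POSITIVE, POSITIVE, POSITIVE, TBD, TBD]],  # B has 0 mutant reads
    )
    with pytest.raises(ValueError, match="zero mutant reads"):
        validate_positives(five_sample_counts, bad)
    with pytest.warns(UserWarning, match="zero mutant reads"):
        validate_positives(five_sample_counts, bad, on_zero_mutant="warn")


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

def test_msn_five_sample_example(five_sample_counts):
    """B is rejected against both positives (negative); D and E each fail to
    reject against at least one positive (unknown)."""
    positives = define_positive(five_sample_counts, PositiveRule(min_mutant_reads=1))
    statuses, audit = classify_msn(
        five_sample_counts, positives, MsnConfig(alpha=0.05), collect_audit=True
    )
    assert statuses.values.tolist() == [[POSITIVE, NEGATIVE, POSITIVE, UNKNOWN, UNKNOWN]]

    p = {(r.sample, r.positive_sample): r.p_value for r in audit.itertuples()}
    assert p[("B", "A")] < 0.01 and p[("B", "C")] < 0.01
    assert p[("D", "A")] < 0.05
    assert p[("D", "C")] >= 0.05
    assert p[("E", "A")] >= 0.05 and p[("E", "C")] >= 0.05


def test_msn_and_umc_biopsy_example(biopsy_counts):
    """High-VAF mutation: follow-up 0/15 is negative under MSN but unknown
    under UMC-20X; low-VAF mutation: 0/30 is unknown under MSN but negative
    under UMC-20X."""
    positives = define_positive(biopsy_counts, PositiveRule(min_mutant_reads=1))
    msn = classify_msn(biopsy_counts, positives, MsnConfig(alpha=0.05))
    umc = classify_umc(biopsy_counts, positives, UmcConfig(min_coverage=20))
    assert msn.values[:, 1].tolist() == [NEGATIVE, UNKNOWN]
    assert umc.values[:, 1].tolist() == [UNKNOWN, NEGATIVE]
    assert (msn.values[:, 0] == POSITIVE).all() and (umc.values[:, 0] == POSITIVE).all()


# ---------------------------------------------------------------------------
# edge cases
# ---------------------------------------------------------------------------

def test_msn_zero_coverage_cell_is_unknown():
    counts = CountMatrix(
        [MutationKey("chr1", 1, "A", "T")], ["pos", "none"], [[30, 0]], [[60, 0]]
    )
    positives = define_positive(counts, PositiveRule(min_mutant_reads=1))
    statuses = classify_msn(counts, positives)
    assert statuses.values[0, 1] == UNKNOWN


def test_umc_boundary_is_inclusive():
    counts = CountMatrix(
        [MutationKey("chr1", 1, "A", "T")],
        ["pos", "at", "below", "empty"],
        [[10, 0, 0, 0]],
        [[20, 300, 299, 0]],
    )
    positives = define_positive(counts, PositiveRule(min_mutant_reads=1))
    statuses = classify_umc(counts, positives, UmcConfig(min_coverage=300))
    assert statuses.values[0].tolist() == [POSITIVE, NEGATIVE, UNKNOWN, UNKNOWN]


def test_umc_never_calls_negative_with_mutant_reads():
    counts = CountMatrix(
        [MutationKey("chr1", 1, "A", "T")], ["pos", "sub"], [[10, 1]], [[20, 500]]
    )
    positives = define_positive(counts, PositiveRule(min_mutant_reads=2))
    statuses = classify_umc(counts, positives, UmcConfig(min_coverage=20))
    assert statuses.values[0, 1] == UNKNOWN


def test_msn_mutation_without_positives_warns_and_stays_unknown():
    counts = CountMatrix(
        [MutationKey("chr1", 1, "A", "T")], ["s1", "s2"], [[0, 0]], [[500, 500]]
    )
    positives = StatusMatrix(counts.mutations, counts.samples, [[TBD, TBD]])
    with pytest.warns(UserWarning, match="no positive sample"):
        statuses = classify_msn(counts, positives)
    assert (statuses.values == UNKNOWN).all()


@pytest.mark.parametrize("policy", ["always-unknown", TEST_OBSERVED])
def test_subthreshold_mutant_cell_never_negative(policy):
    """A non-positive cell with one mutant read stays unknown under both
    sub-threshold policies, however deep its coverage."""
    counts = CountMatrix(
        [MutationKey("chr1", 1, "A", "T")], ["pos", "sub"], [[50, 1]], [[100, 100000]]
    )
    positives = define_positive(counts, PositiveRule(min_mutant_reads=2))
    statuses, audit = classify_msn(
        counts, positives, MsnConfig(alpha=0.05, subthreshold_policy=policy), collect_audit=True
    )
    assert statuses.values[0, 1] == UNKNOWN
    tested = audit[audit["sample"] == "sub"]
    if policy == TEST_OBSERVED:
        assert len(tested) == 1 and tested.iloc[0].sample_mut == 1
    else:
        assert tested.empty


def test_axis_mismatch_rejected(five_sample_counts, biopsy_counts):
    positives = define_positive(biopsy_counts, PositiveRule(min_mutant_reads=1))
    with pytest.raises(ValueError, match="axes"):
        classify_msn(five_sample_counts, positives)
    with pytest.raises(ValueError, match="axes"):
        classify_umc(five_sample_counts, positives, UmcConfig(20))


# ---------------------------------------------------------------------------
# invariants on randomized matrices
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("seed", range(8))
def test_classification_invariants(seed):
    """Partition, positive preservation, negative⇒no-mutant-reads, MSN alpha
    monotonicity and UMC threshold monotonicity on random inputs."""
    counts = random_count_matrix(seed)
    positives = define_positive(counts, PositiveRule(min_mutant_reads=2))
    pos_mask = positives.values == POSITIVE

    msn_01 = classify_msn(counts, positives, MsnConfig(alpha=0.01))
    msn_05 = classify_msn(counts, positives, MsnConfig(alpha=0.05))
    umc_20 = classify_umc(counts, positives, UmcConfig(20))
    umc_100 = classify_umc(counts, positives, UmcConfig(100))

    for statuses in (msn_01, msn_05, umc_20, umc_100):
        # partition into exactly the three output labels
        assert set(np.unique(statuses.values)) <= {POSITIVE, NEGATIVE, UNKNOWN}
        # positives pass through untouched, and none are created
        assert ((statuses.values == POSITIVE) == pos_mask).all()
        # a negative cell never has mutant reads
        assert not (np.asarray(counts.mutant > 0) & (statuses.values == NEGATIVE)).any()

    # lowering alpha can only move negatives to unknown
    assert ((msn_01.values == NEGATIVE) <= (msn_05.values == NEGATIVE)).all()
    # raising the UMC threshold can only move negatives to unknown
    assert ((umc_100.values == NEGATIVE) <= (umc_20.values == NEGATIVE)).all()


@pytest.mark.parametrize("seed", range(4))
def test_one_sided_calls_at_least_as_many_negatives(seed):
    """The one-sided test is never less powerful than the two-sided test for
    zero-mutant cells, so its negative set contains the two-sided one."""
    counts = random_count_matrix(seed + 100)
    positives = define_positive(counts, PositiveRule(min_mutant_reads=2))
    two = classify_msn(counts, positives, MsnConfig(alpha=0.05, sidedness="two-sided"))
    one = classify_msn(counts, positives, MsnConfig(alpha=0.05, sidedness="one-sided"))
    assert ((two.values == NEGATIVE) <= (one.values == NEGATIVE)).all()
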