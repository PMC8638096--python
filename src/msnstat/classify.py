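"""Negative-vs-unknown status classification for non-positive samples.

Two methods are provided for the same task — deciding, for each mutation and
each sample in which it was *not* called positive, whether the absence of
mutant reads is trustworthy (``negative``) or possibly a coverage artifact
(``unknown``):

* **MSN** (mutation-specific negative): the non-positive sample is compared
  with *every* positive sample of the same mutation by Fisher's exact test on
  the mutant/wildtype read counts.  It is negative only if the null hypothesis
  of equal mutant-read frequency is rejected against all positive samples;
  failing to reject against any one of them leaves the status unknown.
* **UMC** (universal minimum coverage): the conventional baseline — negative
  iff the site's total coverage meets a fixed global threshold.

Neither method creates or removes positive statuses: the positive labels are
user-provided (any caller or ad-hoc rule) and pass through unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fisher import ONE_SIDED, SIDEDNESS, TWO_SIDED, fisher_exact_p
from .matrix import (
    NEGATIVE,
    POSITIVE,
    TBD,
    UNKNOWN,
    CountMatrix,
    StatusMatrix,
    check_same_axes,
)

logger = logging.getLogger(__name__)

ALWAYS_UNKNOWN = "always-unknown"
TEST_OBSERVED = "test-observed-counts"

AUDIT_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample",
    "positive_sample",
    "sample_mut",
    "sample_wt",
    "positive_mut",
    "positive_wt",
    "p_value",
]


@dataclass(frozen=True)
class PositiveRule:
    """User rule for calling a mutation positive in a sample.

    ``min_mutant_reads`` is the minimum number of mutant reads (default 2, the
    rule used for the single-cell evaluation; count-level simulations use 1);
    ``min_vaf``, when set, additionally requires mutant/total ≥ min_vaf.
    """

    min_mutant_reads: int = 2
    min_vaf: float | None = None

    def __post_init__(self) -> None:
        if self.min_mutant_reads < 1:
            raise ValueError("min_mutant_reads must be >= 1")
        if self.min_vaf is not None and not (0.0 <= self.min_vaf <= 1.0):
            raise ValueError("min_vaf must be in [0, 1]")


@dataclass(frozen=True)
class MsnConfig:
    """Settings for the mutation-specific negative classifier.

    alpha
        Rejection cutoff for Fisher's exact test; rejection is strict
        (p < alpha).  No multiple-testing adjustment is applied — the cutoff
        is deliberately user-settable instead.
    sidedness
        ``"two-sided"`` (default) or ``"one-sided"``.
    subthreshold_policy
        What to do with a non-positive cell that nevertheless has mutant
        reads (possible when the positive rule requires ≥2).  Such a cell can
        never be negative — a negative call requires zero mutant reads — but
        ``"test-observed-counts"`` still runs the tests (for the audit trail)
        whereas ``"always-unknown"`` (default) labels it unknown untested.
    """

    alpha: float = 0.05
    sidedness: str = TWO_SIDED
    subthreshold_policy: str = ALWAYS_UNKNOWN

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.sidedness not in SIDEDNESS:
            raise ValueError(f"sidedness must be one of {SIDEDNESS}")
        if self.subthreshold_policy not in (ALWAYS_UNKNOWN, TEST_OBSERVED):
            raise ValueError(
                f"subthreshold_policy must be {ALWAYS_UNKNOWN!r} or {TEST_OBSERVED!r}"
            )


@dataclass(frozen=True)
class UmcConfig:
    """Universal-minimum-coverage baseline: negative iff coverage ≥ min_coverage
    (inclusive) and no mutant reads were observed."""

    min_coverage: int = 20

    def __post_init__(self) -> None:
        if self.min_coverage < 1:
            raise ValueError("min_coverage must be >= 1")


def define_positive(counts: CountMatrix, rule: PositiveRule = PositiveRule()) -> StatusMatrix:
    """Label each cell ``positive`` per the rule, everything else ``TBD``.

    Users who called positives with their own tool can skip this and supply
    an explicit positive/TBD matrix instead (see :func:`validate_positives`).
    """
    pos = counts.mutant >= rule.min_mutant_reads
    if rule.min_vaf is not None:
        with np.errstate(invalid="ignore"):
            vaf_ok = (counts.mutant >= rule.min_vaf * counts.total) & (counts.total > 0)
        pos &= vaf_ok
    values = np.where(pos, POSITIVE, TBD)
    return StatusMatrix(counts.mutations, counts.samples, values)


def validate_positives(
    counts: CountMatrix, positives: StatusMatrix, *, on_zero_mutant: str = "error"
) -> StatusMatrix:
    """Check a user-supplied positive/TBD matrix against the counts.

    A cell marked positive with zero mutant reads is contradictory; with
    ``on_zero_mutant="error"`` (default) it raises, with ``"warn"`` it is
    accepted with a warning (the user's caller may have used evidence beyond
    these counts, e.g. a realigned BAM).
    """
    check_same_axes(counts, positives)
    bad = set(np.unique(positives.values)) - {POSITIVE, TBD} if positives.values.size else set()
    if bad:
        raise ValueError(f"positive matrix may only contain positive/TBD, found {sorted(bad)}")
    contradictory = (positives.values == POSITIVE) & (counts.mutant == 0)
    if contradictory.any():
        i, j = np.argwhere(contradictory)[0]
        msg = (
            f"{int(contradictory.sum())} cell(s) marked positive with zero mutant reads "
            f"(first: {counts.mutations[i]} in sample {counts.samples[j]!r})"
        )
        if on_zero_mutant == "warn":
            warnings.warn(msg, UserWarning, stacklevel=2)
        else:
            raise ValueError(msg)
    return positives


def classify_msn(
    counts: CountMatrix,
    positives: StatusMatrix,
    cfg: MsnConfig = MsnConfig(),
    *,
    collect_audit: bool = False,
):
    """Classify every TBD cell as negative or unknown by the MSN rule.

    For each mutation, each TBD cell is tested by Fisher's exact test against
    every positive cell of the same mutation; it is labeled ``negative`` iff
    p < alpha for *all* positive comparisons and the cell itself has zero
    mutant reads.  Otherwise it is ``unknown``.  A mutation with no positive
    sample at all would make the all-positives quantifier vacuously true, so
    its TBD cells are labeled unknown instead (with a warning: well-formed
    input lists only mutations that were called somewhere).

    Returns the :class:`StatusMatrix`, or ``(StatusMatrix, audit)`` when
    ``collect_audit`` is set, where *audit* is a long-format DataFrame with
    one row per (mutation, non-positive sample, positive sample) test showing
    the 2×2 table and p-value.
    """
    check_same_axes(counts, positives)
    out = positives.values.copy()
    audit_rows: list[tuple] = [] if collect_audit else None  # type: ignore[assignment]
    n_orphan = 0

    for i, key in enumerate(counts.mutations):
        pos_js = np.flatnonzero(positives.values[i] == POSITIVE)
        tbd_js = np.flatnonzero(positives.values[i] == TBD)
        if tbd_js.size == 0:
            continue
        if pos_js.size == 0:
            out[i, tbd_js] = UNKNOWN
            n_orphan += 1
            continue
        for j in tbd_js:
            mut = int(counts.mutant[i, j])
            tot = int(counts.total[i, j])
            if mut > 0 and cfg.subthreshold_policy == ALWAYS_UNKNOWN:
                out[i, j] = UNKNOWN
                continue
            # under "test-observed-counts" the observed mutant count enters the
            # tables; mutant > 0 still forbids a negative label below
            all_rejected = True
            for pj in pos_js:
                p = fisher_exact_p(
                    (mut, tot),
                    (int(counts.mutant[i, pj]), int(counts.total[i, pj])),
                    cfg.sidedness,
                )
                if collect_audit:
                    audit_rows.append(
                        (
                            key.chrom,
                            key.pos,
                            key.ref,
                            key.alt,
                            counts.samples[j],
                            counts.samples[pj],
                            mut,
                            tot - mut,
                            int(counts.mutant[i, pj]),
                            int(counts.total[i, pj]) - int(counts.mutant[i, pj]),
                            p,
                        )
                    )
                if not p < cfg.alpha:
                    all_rejected = False
                    if not collect_audit:
                        break
            out[i, j] = NEGATIVE if (all_rejected and mut == 0) else UNKNOWN

    if n_orphan:
        warnings.warn(
            f"{n_orphan} mutation(s) have no positive sample; their non-positive "
            "cells were labeled unknown",
            UserWarning,
            stacklevel=2,
        )
    result = StatusMatrix(counts.mutations, counts.samples, out)
    if collect_audit:
        return result, pd.DataFrame(audit_rows, columns=AUDIT_COLUMNS)
    return result


def classify_umc(
    counts: CountMatrix, positives: StatusMatrix, cfg: UmcConfig = UmcConfig()
) -> StatusMatrix:
    """Classify every TBD cell by the universal-minimum-coverage baseline.

    A TBD cell is ``negative`` iff its total coverage is at least
    ``min_coverage`` and it has zero mutant reads; otherwise ``unknown``.
    Positive cells pass through unchanged.
    """
    check_same_axes(counts, positives)
    tbd = positives.values == TBD
    negative = tbd & (counts.total >= cfg.min_coverage) & (counts.mutant == 0)
    out = positives.values.copy()
    out[tbd] = UNKNOWN
    out[negative] = NEGATIVE
    return StatusMatrix(counts.mutations, counts.samples, out)
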