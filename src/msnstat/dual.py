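"""Dual-platform (paired-sample) evaluation of negative-defining methods.

When the same unit (e.g. a single cell) is sequenced twice on independent
platforms, the two runs should agree on every mutation's status.  Treating
that as a gold standard, a method is scored by

* **informative data points** — unit × mutation pairs where *both* platform
  statuses are positive or negative (not unknown), and
* **concordance** — the percentage of informative points where the two
  statuses match.

A conservative method converts negatives to unknowns, buying concordance at
the cost of informative points; the sweep over thresholds traces that
trade-off.  Only within-unit comparisons are made — cross-unit comparisons
are meaningless under cell-to-cell heterogeneity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classify import MsnConfig, UmcConfig, classify_msn, classify_umc
from .matrix import CountMatrix, StatusMatrix, UNKNOWN

RESULT_COLUMNS = ["method", "threshold", "informative_points", "concordant_points", "concordance_pct"]


@dataclass(frozen=True)
class PairMap:
    """Mapping of units to their two platform samples."""

    pairs: tuple  # of (unit, sample_a, sample_b)

    def __init__(self, pairs):
        norm = tuple((str(u), str(a), str(b)) for u, a, b in pairs)
        for u, a, b in norm:
            if a == b:
                raise ValueError(f"unit {u!r} maps to the same sample twice: {a!r}")
        units = [u for u, _, _ in norm]
        if len(set(units)) != len(units):
            raise ValueError("duplicate unit names in pair map")
        object.__setattr__(self, "pairs", norm)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def validate_against(self, samples: Sequence[str]) -> None:
        known = set(samples)
        for u, a, b in self.pairs:
            for s in (a, b):
                if s not in known:
                    raise KeyError(f"pair map sample {s!r} (unit {u!r}) not in matrix")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["unit", "sample_A", "sample_B"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PairMap":
        need = ["unit", "sample_A", "sample_B"]
        missing = [c for c in need if c not in frame.columns]
        if missing:
            raise ValueError(f"pair map is missing columns: {missing}")
        return cls(list(frame[need].itertuples(index=False, name=None)))


@dataclass(frozen=True)
class PairedEvalResult:
    """Concordance and informative-point counts for one method setting.

    ``concordance`` is a percentage; it is NaN (undefined, not 0 or 100)
    when there are no informative points at all.
    """

    method: str
    threshold: float
    informative_points: int
    concordant_points: int

    @property
    def concordance(self) -> float:
        if self.informative_points == 0:
            return math.nan
        return 100.0 * self.concordant_points / self.informative_points


def evaluate_pairs(statuses: StatusMatrix, pairs: PairMap, *, method: str = "", threshold: float = math.nan) -> PairedEvalResult:
    """Count informative and concordant unit × mutation points.

    A point is informative iff neither platform status is unknown; it is
    concordant iff the two statuses are equal (both positive or both
    negative).  ``method``/``threshold`` are carried through as labels.
    """
    pairs.validate_against(statuses.samples)
    informative = 0
    concordant = 0
    for _, sa, sb in pairs:
        ja = statuses.samples.index(sa)
        jb = statuses.samples.index(sb)
        va = statuses.values[:, ja]
        vb = statuses.values[:, jb]
        info = (va != UNKNOWN) & (vb != UNKNOWN)
        informative += int(info.sum())
        concordant += int((info & (va == vb)).sum())
    return PairedEvalResult(method, threshold, informative, concordant)


def sweep_thresholds(
    counts: CountMatrix,
    positives: StatusMatrix,
    pairs: PairMap,
    *,
    umc_thresholds: Sequence[int] = (10, 20, 50, 100, 300, 1000),
    msn_alphas: Sequence[float] = (0.05, 0.01),
    sidedness: str = "two-sided",
    pooled_positives: bool = True,
) -> list[PairedEvalResult]:
    """Evaluate UMC and MSN over grids of thresholds on a paired design.

    By default all related samples of the matrix are eligible MSN comparison
    anchors for a mutation (``pooled_positives=True``); with
    ``pooled_positives=False`` each unit's non-positive status is tested only
    against positives within its own two samples.
    """
    pairs.validate_against(counts.samples)
    results: list[PairedEvalResult] = []
    for t in umc_thresholds:
        statuses = classify_umc(counts, positives, UmcConfig(min_coverage=int(t)))
        results.append(evaluate_pairs(statuses, pairs, method="umc", threshold=float(t)))
    for alpha in msn_alphas:
        cfg = MsnConfig(alpha=float(alpha), sidedness=sidedness)
        if pooled_positives:
            statuses = classify_msn(counts, positives, cfg)
            results.append(evaluate_pairs(statuses, pairs, method="msn", threshold=float(alpha)))
        else:
            informative = 0
            concordant = 0
            for unit, sa, sb in pairs:
                cols = [counts.sample_index(sa), counts.sample_index(sb)]
                sub_counts = CountMatrix(
                    counts.mutations, (sa, sb), counts.mutant[:, cols], counts.total[:, cols]
                )
                sub_pos = StatusMatrix(counts.mutations, (sa, sb), positives.values[:, cols])
                statuses = classify_msn(sub_counts, sub_pos, cfg)
                r = evaluate_pairs(statuses, PairMap([(unit, sa, sb)]))
                informative += r.informative_points
                concordant += r.concordant_points
            results.append(PairedEvalResult("msn", float(alpha), informative, concordant))
    return results


def results_to_frame(results: Sequence[PairedEvalResult]) -> pd.DataFrame:
    """Tabulate sweep results (one row per method setting)."""
    return pd.DataFrame(
        [
            (r.method, r.threshold, r.informative_points, r.concordant_points, r.concordance)
            for r in results
        ],
        columns=RESULT_COLUMNS,
    )
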