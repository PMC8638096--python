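"""Count-level simulation of multi-measurement tumor sequencing data.

The simulator emulates repeated NGS measurements (multisite biopsies, serial
liquid biopsies) of one tumor at a known tumor-cell fraction.  Mutations are
abstract loci split into *clonal* mutations present in every measurement and
*subclonal* mutations present in each measurement independently with
probability ``subclonal_presence_prob``.  Assuming diploid sites, a mutation's
expected VAF is half the tumor-cell fraction, so where a mutation is present
its mutant read count is drawn as Poisson(coverage × fraction / 2); where
absent, zero.  Coverage is a fixed per-site total by default (an optional
Poisson per-site coverage mode is available).

Mutations with no mutant reads in any measurement would never have been
reported by a variant caller and are excluded before scoring
(:func:`exclude_undetected`).  Scored categories per retained cell: TP/FP
(positive status vs. truth), FN/TN (negative status vs. truth), and unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .classify import MsnConfig, PositiveRule, UmcConfig, classify_msn, classify_umc, define_positive
from .matrix import NEGATIVE, POSITIVE, UNKNOWN, CountMatrix, MutationKey, StatusMatrix

FIXED_COVERAGE = "fixed"
POISSON_COVERAGE = "poisson"
BERNOULLI = "bernoulli"
EXACT_HALF = "exact-half"

SCORE_CATEGORIES = ("unknown", "fn", "tn", "fp", "tp")


@dataclass(frozen=True)
class Scenario:
    """One simulated study condition.

    Defaults are the reference conditions of the simulation study: 200X
    coverage, 100 clonal + 100 subclonal mutations, 3 measurements, subclonal
    mutations present per measurement with probability 0.5.  The tumor-cell
    fractions examined are 0.90, 0.20, 0.05 and 0.01.
    """

    tumor_fraction: float
    mean_coverage: int = 200
    n_clonal: int = 100
    n_subclonal: int = 100
    n_measurements: int = 3
    subclonal_presence_prob: float = 0.5
    seed: int = 0
    coverage_model: str = FIXED_COVERAGE
    subclonal_assignment: str = BERNOULLI

    def __post_init__(self) -> None:
        if not (0.0 < self.tumor_fraction <= 1.0):
            raise ValueError("tumor_fraction must be in (0, 1]")
        for name in ("mean_coverage", "n_clonal", "n_subclonal", "n_measurements"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0.0 <= self.subclonal_presence_prob <= 1.0):
            raise ValueError("subclonal_presence_prob must be in [0, 1]")
        if self.coverage_model not in (FIXED_COVERAGE, POISSON_COVERAGE):
            raise ValueError(f"coverage_model must be {FIXED_COVERAGE!r} or {POISSON_COVERAGE!r}")
        if self.subclonal_assignment not in (BERNOULLI, EXACT_HALF):
            raise ValueError(f"subclonal_assignment must be {BERNOULLI!r} or {EXACT_HALF!r}")

    @property
    def expected_vaf(self) -> float:
        """Expected VAF at a diploid site: half the tumor-cell fraction."""
        return self.tumor_fraction / 2.0


@dataclass(frozen=True)
class TruthMatrix:
    """Ground-truth presence per mutation × measurement."""

    mutations: tuple
    samples: tuple
    present: np.ndarray  # bool array

    def __init__(self, mutations: Iterable, samples: Iterable[str], present):
        mutations = tuple(MutationKey(*m) for m in mutations)
        samples = tuple(str(s) for s in samples)
        pres = np.asarray(present, dtype=bool)
        if pres.shape != (len(mutations), len(samples)):
            raise ValueError("truth array shape does not match axes")
        pres.setflags(write=False)
        object.__setattr__(self, "mutations", mutations)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "present", pres)

    def take_mutations(self, row_indices: Sequence[int]) -> "TruthMatrix":
        idx = np.asarray(row_indices, dtype=int)
        return TruthMatrix([self.mutations[i] for i in idx], self.samples, self.present[idx])


@dataclass(frozen=True)
class SimScore:
    """Fractions of retained mutation-status cells by category (sum to 1)."""

    unknown: float
    fn: float
    tn: float
    fp: float
    tp: float
    n_cells: int = 0

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in SCORE_CATEGORIES}


def simulate_counts(scenario: Scenario) -> tuple[CountMatrix, TruthMatrix]:
    """Draw one replicate of the scenario: read counts plus ground truth.

    Deterministic for a fixed ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    n_mut = scenario.n_clonal + scenario.n_subclonal
    n_meas = scenario.n_measurements

    present = np.ones((n_mut, n_meas), dtype=bool)
    if scenario.subclonal_assignment == BERNOULLI:
        present[scenario.n_clonal:] = (
            rng.random((scenario.n_subclonal, n_meas)) < scenario.subclonal_presence_prob
        )
    else:  # exact-half: a fixed number of measurements per subclonal mutation
        k = int(round(scenario.subclonal_presence_prob * n_meas))
        sub = np.zeros((scenario.n_subclonal, n_meas), dtype=bool)
        for r in range(scenario.n_subclonal):
            sub[r, rng.choice(n_meas, size=k, replace=False)] = True
        present[scenario.n_clonal:] = sub

    lam = scenario.mean_coverage * scenario.expected_vaf
    mutant = np.where(present, rng.poisson(lam, size=(n_mut, n_meas)), 0)

    if scenario.coverage_model == FIXED_COVERAGE:
        total = np.full((n_mut, n_meas), scenario.mean_coverage, dtype=np.int64)
    else:
        total = rng.poisson(scenario.mean_coverage, size=(n_mut, n_meas))
    total = np.maximum(total, mutant)  # a site cannot have fewer reads than its mutant reads

    mutations = [
        MutationKey("sim", i + 1, "A", "T") for i in range(n_mut)
    ]  # abstract loci: clonal rows first, then subclonal
    samples = [f"measurement{k + 1}" for k in range(n_meas)]
    return (
        CountMatrix(mutations, samples, mutant, total),
        TruthMatrix(mutations, samples, present),
    )


def exclude_undetected(
    counts: CountMatrix, truth: TruthMatrix
) -> tuple[CountMatrix, TruthMatrix]:
    """Drop mutations with zero mutant reads in every measurement.

    Such mutations would not have been captured by any somatic variant caller
    and are removed from both matrices before methods are scored.
    """
    if counts.mutations != truth.mutations or counts.samples != truth.samples:
        raise ValueError("count matrix and truth matrix axes do not match")
    keep = np.flatnonzero(counts.mutant.sum(axis=1) > 0)
    return counts.take_mutations(keep), truth.take_mutations(keep)


def score_statuses(statuses: StatusMatrix, truth: TruthMatrix) -> SimScore:
    """Score status calls against ground truth over all retained cells.

    positive+present → TP, positive+absent → FP, negative+present → FN,
    negative+absent → TN, unknown → unknown.
    """
    if statuses.mutations != truth.mutations or statuses.samples != truth.samples:
        raise ValueError("status matrix and truth matrix axes do not match")
    v, pres = statuses.values, truth.present
    n = v.size
    if n == 0:
        raise ValueError("cannot score an empty status matrix")
    return SimScore(
        unknown=float((v == UNKNOWN).sum()) / n,
        fn=float(((v == NEGATIVE) & pres).sum()) / n,
        tn=float(((v == NEGATIVE) & ~pres).sum()) / n,
        fp=float(((v == POSITIVE) & ~pres).sum()) / n,
        tp=float(((v == POSITIVE) & pres).sum()) / n,
        n_cells=int(n),
    )


def _apply_method(counts, positives, method: str, threshold: float, sidedness: str):
    if method == "msn":
        return classify_msn(counts, positives, MsnConfig(alpha=float(threshold), sidedness=sidedness))
    if method == "umc":
        return classify_umc(counts, positives, UmcConfig(min_coverage=int(threshold)))
    raise ValueError(f"unknown method {method!r}")


DEFAULT_METHODS: tuple[tuple[str, float], ...] = (
    ("msn", 0.01),
    ("msn", 0.05),
    ("umc", 20),
    ("umc", 50),
    ("umc", 200),
    ("umc", 300),
)


def run_scenarios(
    scenarios: Sequence[Scenario],
    methods: Sequence[tuple[str, float]] = DEFAULT_METHODS,
    *,
    n_replicates: int = 1,
    base_seed: int | None = None,
    positive_rule: PositiveRule = PositiveRule(min_mutant_reads=1),
    sidedness: str = "two-sided",
) -> pd.DataFrame:
    """Score every (scenario, method, threshold) combination.

    Each replicate re-simulates every scenario with a fresh seed derived from
    ``base_seed`` (or from each scenario's own seed when ``base_seed`` is
    None and ``n_replicates`` is 1).  In the simulation, any cell with at
    least one mutant read counts as positive, mirroring how a caller would
    flag any detected mutation.

    Returns a long-format DataFrame with columns
    ``scenario, tumor_fraction, method, threshold, replicate, category,
    fraction, n_cells`` — one row per score category.
    """
    if not scenarios or not methods:
        raise ValueError("scenarios and methods must be non-empty")
    if base_seed is not None:
        seeds = np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n_replicates)
    elif n_replicates == 1:
        seeds = [None]
    else:
        raise ValueError("base_seed is required when n_replicates > 1")

    rows = []
    for rep, rep_seed in enumerate(seeds):
        for s_idx, scen in enumerate(scenarios):
            if rep_seed is not None:
                # distinct stream per scenario within the replicate
                scen = replace(scen, seed=int((int(rep_seed) + 7919 * s_idx) % 2**31))
            counts, truth = simulate_counts(scen)
            counts, truth = exclude_undetected(counts, truth)
            positives = define_positive(counts, positive_rule)
            for method, threshold in methods:
                statuses = _apply_method(counts, positives, method, threshold, sidedness)
                score = score_statuses(statuses, truth)
                for cat, frac in score.as_dict().items():
                    rows.append(
                        (
                            f"fraction={scen.tumor_fraction:g}",
                            scen.tumor_fraction,
                            method,
                            threshold,
                            rep,
                            cat,
                            frac,
                            score.n_cells,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "scenario",
            "tumor_fraction",
            "method",
            "threshold",
            "replicate",
            "category",
            "fraction",
            "n_cells",
        ],
    )


def summarize_scenarios(table: pd.DataFrame) -> pd.DataFrame:
    """Average the long-format replicate table into one fraction per
    (scenario, method, threshold, category)."""
    out = (
        table.groupby(["scenario", "method", "threshold", "category"], sort=False)["fraction"]
        .mean()
        .reset_index()
    )
    return out
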