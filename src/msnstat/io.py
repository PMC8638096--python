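"""Readers and writers for the tab-separated interchange formats.

Formats (all UTF-8, tab-delimited, no quoting):

* count matrix — ``chrom pos ref alt <sample>:mut <sample>:tot ...`` with one
  mut/tot column pair per sample, pair order fixed;
* positive / status matrix — ``chrom pos ref alt <sample> ...`` with cell
  values in {positive, TBD} (input) or {positive, negative, unknown} (output);
* pair map — ``unit sample_A sample_B``;
* audit table — one row per Fisher test (2×2 table and p-value);
* result tables — long-format simulation fractions and dual-evaluation rows.

Column order is the order of first appearance and is never silently sorted,
so count and status matrices written from the same axes stay aligned.
Read → write round-trips are byte-stable for canonical column order.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .matrix import (
    INPUT_STATUSES,
    OUTPUT_STATUSES,
    CountMatrix,
    MutationKey,
    StatusMatrix,
)
from .dual import PairMap

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["chrom", "pos", "ref", "alt"]


class FormatError(ValueError):
    """A malformed input file; the message carries the offending line number."""


def _rows(path) -> list[list[str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        return list(csv.reader(fh, delimiter="\t"))


def _parse_int(text: str, what: str, line_no: int) -> int:
    # plain integers only: scientific notation or floats are rejected
    try:
        if not text.lstrip("-").isdigit():
            raise ValueError
        return int(text)
    except ValueError:
        raise FormatError(f"line {line_no}: {what} is not a plain integer: {text!r}") from None


def _parse_key(row: list[str], line_no: int) -> MutationKey:
    try:
        key = MutationKey(row[0], _parse_int(row[1], "position", line_no), row[2], row[3])
        return key.validate()
    except ValueError as exc:
        raise FormatError(f"line {line_no}: {exc}") from None


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

def read_count_matrix(path) -> CountMatrix:
    """Parse a count-matrix TSV, validating counts cell by cell.

    Raises :class:`FormatError` with a line number on a malformed header,
    non-integer counts, mutant > total, or a duplicate mutation key.  An
    empty data section yields an empty matrix with a logged warning.
    """
    rows = _rows(path)
    if not rows:
        raise FormatError("line 1: empty file (expected a header row)")
    header = rows[0]
    if header[:4] != KEY_COLUMNS:
        raise FormatError(
            f"line 1: header must start with {' '.join(KEY_COLUMNS)}, got {header[:4]}"
        )
    sample_cols = header[4:]
    if len(sample_cols) % 2:
        raise FormatError("line 1: sample columns must come in <sample>:mut/<sample>:tot pairs")
    samples = []
    for k in range(0, len(sample_cols), 2):
        mcol, tcol = sample_cols[k], sample_cols[k + 1]
        if not (mcol.endswith(":mut") and tcol.endswith(":tot")):
            raise FormatError(f"line 1: expected <sample>:mut/<sample>:tot pair, got {mcol!r}/{tcol!r}")
        name = mcol[:-4]
        if tcol[:-4] != name:
            raise FormatError(f"line 1: mismatched sample pair {mcol!r}/{tcol!r}")
        samples.append(name)

    mutations: list[MutationKey] = []
    seen: set[MutationKey] = set()
    mutant_rows, total_rows = [], []
    for offset, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and row[0] == ""):
            continue
        if len(row) != 4 + 2 * len(samples):
            raise FormatError(
                f"line {offset}: expected {4 + 2 * len(samples)} fields, got {len(row)}"
            )
        key = _parse_key(row, offset)
        if key in seen:
            raise FormatError(f"line {offset}: duplicate mutation {key}")
        seen.add(key)
        mut_row, tot_row = [], []
        for j, s in enumerate(samples):
            m = _parse_int(row[4 + 2 * j], f"{s} mutant count", offset)
            t = _parse_int(row[5 + 2 * j], f"{s} total count", offset)
            if m < 0 or t < 0:
                raise FormatError(f"line {offset}: negative read count for sample {s!r}")
            if m > t:
                raise FormatError(
                    f"line {offset}: mutant reads exceed total for sample {s!r} ({m} > {t})"
                )
            mut_row.append(m)
            tot_row.append(t)
        mutations.append(key)
        mutant_rows.append(mut_row)
        total_rows.append(tot_row)

    if not mutations:
        logger.warning("%s: no data rows; returning an empty matrix", path)
        shape = (0, len(samples))
        return CountMatrix([], samples, np.empty(shape, int), np.empty(shape, int))
    return CountMatrix(mutations, samples, np.array(mutant_rows), np.array(total_rows))


def write_count_matrix(counts: CountMatrix, path) -> None:
    counts.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# status / positive matrices
# ---------------------------------------------------------------------------

def _read_label_matrix(path, allowed: frozenset, what: str) -> StatusMatrix:
    rows = _rows(path)
    if not rows:
        raise FormatError("line 1: empty file (expected a header row)")
    header = rows[0]
    if header[:4] != KEY_COLUMNS:
        raise FormatError(f"line 1: header must start with {' '.join(KEY_COLUMNS)}")
    samples = header[4:]
    mutations, values = [], []
    seen: set[MutationKey] = set()
    for offset, row in enumerate(rows[1:], start=2):
        if not row or (len(row) == 1 and row[0] == ""):
            continue
        if len(row) != 4 + len(samples):
            raise FormatError(f"line {offset}: expected {4 + len(samples)} fields, got {len(row)}")
        key = _parse_key(row, offset)
        if key in seen:
            raise FormatError(f"line {offset}: duplicate mutation {key}")
        seen.add(key)
        labels = row[4:]
        bad = [v for v in labels if v not in allowed]
        if bad:
            raise FormatError(
                f"line {offset}: invalid {what} label(s) {bad!r}; allowed: {sorted(allowed)}"
            )
        mutations.append(key)
        values.append(labels)
    vals = np.array(values, dtype="<U8") if mutations else np.empty((0, len(samples)), dtype="<U8")
    return StatusMatrix(mutations, samples, vals)


def read_positive_matrix(path) -> StatusMatrix:
    """Read a user-supplied positive/TBD matrix."""
    return _read_label_matrix(path, INPUT_STATUSES, "positive-matrix")


def read_status_matrix(path) -> StatusMatrix:
    """Read a classified positive/negative/unknown matrix."""
    return _read_label_matrix(path, OUTPUT_STATUSES, "status")


def write_status_matrix(statuses: StatusMatrix, path) -> None:
    statuses.to_frame().to_csv(path, sep="\t", index=False)


write_positive_matrix = write_status_matrix


# ---------------------------------------------------------------------------
# pair map, audit, results
# ---------------------------------------------------------------------------

def read_pair_map(path) -> PairMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return PairMap.from_frame(frame)


def write_pair_map(pairs: PairMap, path) -> None:
    pairs.to_frame().to_csv(path, sep="\t", index=False)


def write_table(frame: pd.DataFrame, path) -> None:
    """Write any result/audit table as TSV (used for audit, sweep and
    simulation outputs)."""
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# simulation scenario configuration
# ---------------------------------------------------------------------------

def load_simulation_config(path) -> dict:
    """Load a YAML scenario configuration.

    Recognized keys (all optional, with the reference-study defaults):
    ``fractions`` (list), ``coverage``, ``n_clonal``, ``n_subclonal``,
    ``measurements``, ``presence_prob``, ``coverage_model``,
    ``subclonal_assignment``, ``methods`` (list of ``"msn:0.05"`` /
    ``"umc:300"`` strings), ``replicates``, ``seed``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("scenario configuration must be a mapping")
    cfg = default_simulation_config()
    unknown = set(raw) - set(cfg)
    if unknown:
        raise FormatError(f"unknown configuration keys: {sorted(unknown)}")
    cfg.update(raw)
    return cfg


def default_simulation_config() -> dict:
    """The reference study design (see load_simulation_config)."""
    return {
        "fractions": [0.90, 0.20, 0.05, 0.01],
        "coverage": 200,
        "n_clonal": 100,
        "n_subclonal": 100,
        "measurements": 3,
        "presence_prob": 0.5,
        "coverage_model": "fixed",
        "subclonal_assignment": "bernoulli",
        "methods": ["msn:0.01", "msn:0.05", "umc:20", "umc:50", "umc:200", "umc:300"],
        "replicates": 1,
        "seed": 0,
    }


def parse_method_grid(specs) -> list[tuple[str, float]]:
    """Parse ``"msn:0.05"`` / ``"umc:300"`` strings into (method, threshold)."""
    out = []
    for item in specs:
        if isinstance(item, (tuple, list)) and len(item) == 2:
            method, threshold = item
        else:
            try:
                method, threshold = str(item).split(":")
            except ValueError:
                raise FormatError(f"cannot parse method spec {item!r} (expected method:threshold)") from None
        method = method.strip().lower()
        if method not in ("msn", "umc"):
            raise FormatError(f"unknown method {method!r} (expected msn or umc)")
        value = float(threshold) if method == "msn" else int(threshold)
        out.append((method, value))
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _biopsy_example() -> CountMatrix:
    """Two EGFR mutations measured in two serial biopsies: a high-VAF T790M
    (40/72 then 0/15) and a low-VAF C797S (5/100 then 0/30)."""
    mutations = [
        MutationKey("chr7", 55249071, "C", "T"),  # EGFR T790M
        MutationKey("chr7", 55249092, "T", "A"),  # EGFR C797S
    ]
    samples = ["biopsy1", "biopsy2"]
    mutant = [[40, 0], [5, 0]]
    total = [[72, 15], [100, 30]]
    return CountMatrix(mutations, samples, mutant, total)


def _five_sample_example() -> CountMatrix:
    """One mutation across five samples A–E (10/20, 0/20, 4/9, 0/8, 0/5)."""
    mutations = [MutationKey("chr1", 100, "A", "T")]
    samples = ["A", "B", "C", "D", "E"]
    mutant = [[10, 0, 4, 0, 0]]
    total = [[20, 20, 9, 8, 5]]
    return CountMatrix(mutations, samples, mutant, total)


def _random_small(seed: int) -> CountMatrix:
    rng = np.random.default_rng(seed)
    n_mut, n_samp = 8, 4
    mutations = [MutationKey(f"chr{rng.integers(1, 5)}", int(p), "G", "C") for p in rng.choice(10_000, size=n_mut, replace=False) + 1]
    samples = [f"s{k + 1}" for k in range(n_samp)]
    total = rng.integers(0, 120, size=(n_mut, n_samp))
    mutant = rng.binomial(total, 0.15)
    return CountMatrix(mutations, samples, mutant, total)


def _paired_demo(seed: int) -> tuple[CountMatrix, PairMap]:
    rng = np.random.default_rng(seed)
    units = ["cell1", "cell2", "cell3"]
    samples = [f"{u}_{plat}" for u in units for plat in ("AGL", "NXT")]
    n_mut = 12
    mutations = [MutationKey("chr2", 1000 + 10 * i, "A", "G") for i in range(n_mut)]
    present = rng.random((n_mut, len(units))) < 0.6
    present = np.repeat(present, 2, axis=1)  # both platforms share the cell's truth
    total = rng.poisson(80, size=(n_mut, len(samples)))
    mutant = np.where(present, rng.binomial(total, 0.4), 0)
    pairs = PairMap([(u, f"{u}_AGL", f"{u}_NXT") for u in units])
    return CountMatrix(mutations, samples, mutant, np.maximum(total, mutant)), pairs


FIXTURE_KINDS = ("table1", "table2", "random-small", "paired-demo")


def make_fixture(kind: str, seed: int = 0, out_dir=".") -> list[Path]:
    """Write a named demo/test fixture to ``out_dir``; returns written paths.

    ``table1``/``table2`` are the two worked examples (serial-biopsy pair and
    five-sample single mutation); ``random-small`` is a seeded random matrix;
    ``paired-demo`` adds a pair map for the dual-platform evaluation.
    Deterministic per seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if kind == "table1":
        path = out_dir / "table1_counts.tsv"
        write_count_matrix(_biopsy_example(), path)
        return [path]
    if kind == "table2":
        path = out_dir / "table2_counts.tsv"
        write_count_matrix(_five_sample_example(), path)
        return [path]
    if kind == "random-small":
        path = out_dir / "random_small_counts.tsv"
        write_count_matrix(_random_small(seed), path)
        return [path]
    if kind == "paired-demo":
        counts, pairs = _paired_demo(seed)
        cpath = out_dir / "paired_demo_counts.tsv"
        ppath = out_dir / "paired_demo_pairs.tsv"
        write_count_matrix(counts, cpath)
        write_pair_map(pairs, ppath)
        return [cpath, ppath]
    raise ValueError(f"unknown fixture kind {kind!r}; expected one of {FIXTURE_KINDS}")
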