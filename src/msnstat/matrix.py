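"""Core containers: mutation keys, read-count matrices and status matrices.

A :class:`CountMatrix` holds, for every unique somatic mutation (chromosome,
position, reference allele, mutant allele) and every related sample, the
number of reads supporting the mutant allele and the total coverage at the
site.  Wildtype read counts are derived (``total - mutant``): totals are what
pileup tools report.  A missing measurement is encoded as ``(0, 0)``, which
deterministically classifies as *unknown* under every method — no separate
missing-data code path exists.

A :class:`StatusMatrix` shares the same axes and carries one label per cell:
``positive``/``TBD`` on input (after the user's positive-calling rule) and
``positive``/``negative``/``unknown`` on output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"
TBD = "TBD"

INPUT_STATUSES = frozenset({POSITIVE, TBD})
OUTPUT_STATUSES = frozenset({POSITIVE, NEGATIVE, UNKNOWN})


class MutationKey(NamedTuple):
    """Identity of a unique somatic mutation (VCF-style 1-based position)."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def validate(self) -> "MutationKey":
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt alleles are identical: {self!r}")
        return self

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def _as_2d_int(arr, name: str) -> np.ndarray:
    out = np.asarray(arr)
    if out.ndim != 2:
        raise ValueError(f"{name} must be 2-dimensional, got shape {out.shape}")
    if not np.issubdtype(out.dtype, np.integer):
        if not np.all(np.equal(np.mod(out, 1), 0)):
            raise ValueError(f"{name} must contain integers")
        out = out.astype(np.int64)
    return np.ascontiguousarray(out, dtype=np.int64)


@dataclass(frozen=True)
class CountMatrix:
    """Mutant / total read counts for every mutation × sample pair.

    Parameters
    ----------
    mutations
        Ordered, unique :class:`MutationKey` rows.
    samples
        Ordered, unique sample names (columns).
    mutant, total
        Integer arrays of shape ``(len(mutations), len(samples))`` with
        ``0 <= mutant <= total`` cell-wise.
    """

    mutations: tuple
    samples: tuple
    mutant: np.ndarray
    total: np.ndarray

    def __init__(self, mutations: Iterable, samples: Iterable[str], mutant, total):
        mutations = tuple(MutationKey(*m).validate() for m in mutations)
        samples = tuple(str(s) for s in samples)
        if len(set(mutations)) != len(mutations):
            raise ValueError("duplicate MutationKey in count matrix")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample names in count matrix")
        mut = _as_2d_int(mutant, "mutant")
        tot = _as_2d_int(total, "total")
        shape = (len(mutations), len(samples))
        if mut.shape != shape or tot.shape != shape:
            raise ValueError(
                f"count arrays must have shape {shape}; got mutant {mut.shape}, total {tot.shape}"
            )
        if (mut < 0).any() or (tot < 0).any():
            raise ValueError("read counts must be non-negative")
        if (mut > tot).any():
            i, j = np.argwhere(mut > tot)[0]
            raise ValueError(
                f"mutant reads exceed total reads for {mutations[i]} in sample "
                f"{samples[j]!r}: {mut[i, j]} > {tot[i, j]}"
            )
        mut.setflags(write=False)
        tot.setflags(write=False)
        object.__setattr__(self, "mutations", mutations)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "mutant", mut)
        object.__setattr__(self, "total", tot)

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.mutations), len(self.samples))

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"unknown sample name {name!r}") from None

    # -- derived quantities --------------------------------------------------
    @property
    def wildtype(self) -> np.ndarray:
        return self.total - self.mutant

    def vaf(self) -> np.ndarray:
        """Variant allele frequency per cell; NaN where total = 0."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.total > 0, self.mutant / np.maximum(self.total, 1), np.nan)

    # -- selection -----------------------------------------------------------
    def take_mutations(self, row_indices: Sequence[int]) -> "CountMatrix":
        idx = np.asarray(row_indices, dtype=int)
        return CountMatrix(
            [self.mutations[i] for i in idx],
            self.samples,
            self.mutant[idx],
            self.total[idx],
        )

    # -- interop -------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Wide frame: chrom/pos/ref/alt plus one ``<sample>:mut``/``:tot`` pair per sample."""
        data: dict = {
            "chrom": [m.chrom for m in self.mutations],
            "pos": [m.pos for m in self.mutations],
            "ref": [m.ref for m in self.mutations],
            "alt": [m.alt for m in self.mutations],
        }
        for j, s in enumerate(self.samples):
            data[f"{s}:mut"] = self.mutant[:, j]
            data[f"{s}:tot"] = self.total[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "CountMatrix":
        """Inverse of :meth:`to_frame` (column pair order defines sample order)."""
        key_cols = ["chrom", "pos", "ref", "alt"]
        missing = [c for c in key_cols if c not in frame.columns]
        if missing:
            raise ValueError(f"missing key columns: {missing}")
        samples = []
        for col in frame.columns:
            if col.endswith(":mut"):
                samples.append(col[: -len(":mut")])
        mutations = [
            MutationKey(str(c), int(p), str(r), str(a))
            for c, p, r, a in zip(frame["chrom"], frame["pos"], frame["ref"], frame["alt"])
        ]
        mut = np.column_stack([frame[f"{s}:mut"].to_numpy() for s in samples]) if samples else np.empty((len(frame), 0), dtype=int)
        tot = np.column_stack([frame[f"{s}:tot"].to_numpy() for s in samples]) if samples else np.empty((len(frame), 0), dtype=int)
        return cls(mutations, samples, mut, tot)


@dataclass(frozen=True)
class StatusMatrix:
    """Per mutation × sample status labels on the axes of a :class:`CountMatrix`."""

    mutations: tuple
    samples: tuple
    values: np.ndarray  # dtype <U8, same shape as the count matrix

    def __init__(self, mutations: Iterable, samples: Iterable[str], values):
        mutations = tuple(MutationKey(*m) for m in mutations)
        samples = tuple(str(s) for s in samples)
        vals = np.asarray(values, dtype="<U8")
        if vals.shape != (len(mutations), len(samples)):
            raise ValueError(
                f"status array shape {vals.shape} does not match axes "
                f"({len(mutations)}, {len(samples)})"
            )
        allowed = INPUT_STATUSES | OUTPUT_STATUSES
        bad = set(np.unique(vals)) - allowed if vals.size else set()
        if bad:
            raise ValueError(f"invalid status labels: {sorted(bad)}")
        vals.setflags(write=False)
        object.__setattr__(self, "mutations", mutations)
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "values", vals)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def counts(self) -> dict[str, int]:
        """Number of cells per status label."""
        labels, n = np.unique(self.values, return_counts=True)
        return dict(zip(labels.tolist(), n.tolist()))

    def with_values(self, values: np.ndarray) -> "StatusMatrix":
        return StatusMatrix(self.mutations, self.samples, values)

    def take_mutations(self, row_indices: Sequence[int]) -> "StatusMatrix":
        idx = np.asarray(row_indices, dtype=int)
        return StatusMatrix([self.mutations[i] for i in idx], self.samples, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        data: dict = {
            "chrom": [m.chrom for m in self.mutations],
            "pos": [m.pos for m in self.mutations],
            "ref": [m.ref for m in self.mutations],
            "alt": [m.alt for m in self.mutations],
        }
        for j, s in enumerate(self.samples):
            data[s] = self.values[:, j]
        return pd.DataFrame(data)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StatusMatrix":
        key_cols = ["chrom", "pos", "ref", "alt"]
        missing = [c for c in key_cols if c not in frame.columns]
        if missing:
            raise ValueError(f"missing key columns: {missing}")
        samples = [c for c in frame.columns if c not in key_cols]
        mutations = [
            MutationKey(str(c), int(p), str(r), str(a))
            for c, p, r, a in zip(frame["chrom"], frame["pos"], frame["ref"], frame["alt"])
        ]
        vals = frame[samples].to_numpy(dtype="<U8") if samples else np.empty((len(frame), 0), dtype="<U8")
        return cls(mutations, samples, vals)


def check_same_axes(counts: CountMatrix, statuses: StatusMatrix) -> None:
    """Raise if the two matrices do not share identical mutation/sample axes."""
    if counts.mutations != statuses.mutations or counts.samples != statuses.samples:
        raise ValueError("count matrix and status matrix axes do not match")
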