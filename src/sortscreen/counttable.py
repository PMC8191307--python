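"""Per-sgRNA read-count tables.

A :class:`CountTable` holds one row per library sgRNA (including zero-count
rows) and one column per sequenced sample, plus per-sample bookkeeping:
total reads processed and reads that could not be assigned to any guide.
The conservation invariant ``assigned + unassigned == total`` holds per
sample at all times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd


@dataclass
class SampleStats:
    total_reads: int
    unassigned: int


@dataclass
class CountTable:
    """sgRNA-by-sample count matrix with per-sample totals.

    ``counts`` is indexed by sgRNA id with a leading ``gene`` column followed
    by one integer (or, after normalization, float) column per sample.
    """

    counts: pd.DataFrame
    stats: dict[str, SampleStats] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if "gene" not in self.counts.columns:
            raise ValueError("counts frame must carry a 'gene' column")
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sgRNA ids in count table: {dups[:5]}")
        for sample in self.samples:
            col = self.counts[sample]
            if (col < 0).any():
                raise ValueError(f"negative counts in sample {sample!r}")

    @property
    def samples(self) -> list[str]:
        return [c for c in self.counts.columns if c != "gene"]

    @property
    def sgrna_ids(self) -> pd.Index:
        return self.counts.index

    def column(self, sample: str) -> pd.Series:
        if sample not in self.samples:
            raise KeyError(f"unknown sample {sample!r}; have {self.samples}")
        return self.counts[sample]

    def assigned(self, sample: str) -> int:
        return int(self.column(sample).sum())

    def check_conservation(self) -> None:
        """Assert assigned + unassigned == total for every tracked sample."""
        for sample, st in self.stats.items():
            assigned = self.assigned(sample)
            if assigned + st.unassigned != st.total_reads:
                raise AssertionError(
                    f"sample {sample!r}: assigned {assigned} + unassigned "
                    f"{st.unassigned} != total {st.total_reads}"
                )

    def to_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "sgrna_id", out.index)
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        frame = pd.read_csv(path, sep="\t", dtype={"sgrna_id": str, "gene": str})
        frame = frame.set_index("sgrna_id")
        frame.index.name = "sgrna_id"
        return cls(counts=frame)

    @classmethod
    def from_counts(
        cls,
        sgrna_ids: Sequence[str],
        genes: Sequence[str],
        columns: Mapping[str, Sequence[int]],
        stats: Mapping[str, SampleStats] | None = None,
    ) -> "CountTable":
        frame = pd.DataFrame({"gene": list(genes)}, index=pd.Index(sgrna_ids, name="sgrna_id"))
        for sample, values in columns.items():
            frame[sample] = list(values)
        return cls(counts=frame, stats=dict(stats or {}))


def merge_counts(tables: Sequence[CountTable]) -> CountTable:
    """Merge single- or multi-sample tables over an identical sgRNA key set.

    Sample order follows the input order. Mismatched sgRNA sets are an error
    listing the symmetric difference.
    """
    if not tables:
        raise ValueError("no tables to merge")
    base = tables[0]
    merged = base.counts[["gene"]].copy()
    stats: dict[str, SampleStats] = {}
    for tab in tables:
        if not tab.sgrna_ids.equals(base.sgrna_ids):
            diff = set(tab.sgrna_ids).symmetric_difference(base.sgrna_ids)
            raise ValueError(
                f"sgRNA sets differ between tables; symmetric difference "
                f"({len(diff)} ids): {sorted(diff)[:10]}"
            )
        for sample in tab.samples:
            if sample in merged.columns:
                raise ValueError(f"duplicate sample name {sample!r} in merge")
            merged[sample] = tab.counts[sample]
        stats.update(tab.stats)
    return CountTable(counts=merged, stats=stats)
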