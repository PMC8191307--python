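"""Pseudo-count fold-change candidate selection across replicates.

This is the scatterplot-based hit-calling procedure for sorting screens:
per replicate, each guide gets a log2 fold-change
``log2((sorted + pseudo) / (unsorted + pseudo))`` on raw counts (the
pseudo-count, 0.5 by default, keeps the value finite at zero counts).
Guides are retained only if, in *every* replicate, the unsorted (control)
count is at least ``min_unsorted_reads`` and the fold-change is strictly
above ``lfc_threshold``. After four rounds of sorting the bulk of a
library collapses to log2(pseudo / n_unsorted) — roughly −9 for a
well-covered guide — so a threshold of −5 separates guides that survived
the sorts from those washed out. Genes with at least ``min_sgrnas``
passing guides form the candidate set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .counttable import CountTable
from .library import NONTARGETING_GENE, SgRNALibrary

logger = logging.getLogger(__name__)

DEFAULT_PSEUDO = 0.5
DEFAULT_MIN_UNSORTED_READS = 30
DEFAULT_LFC_THRESHOLD = -5.0
DEFAULT_MIN_SGRNAS = 2


def log2_fold_change(
    counts: CountTable,
    pair: tuple[str, str],
    pseudo: float = DEFAULT_PSEUDO,
    rep_label: str | None = None,
) -> pd.DataFrame:
    """Per-guide log2 fold-change for one (unsorted, sorted) sample pair.

    Enrichment in the sorted pool is positive. Raw counts are used — no
    library-size normalization at this stage. Returns a frame with columns
    ``count_unsorted_<rep>``, ``count_sorted_<rep>``, ``lfc_<rep>``.
    """
    if pseudo <= 0:
        raise ValueError(f"pseudo-count must be positive, got {pseudo}")
    unsorted_name, sorted_name = pair
    u = counts.column(unsorted_name).to_numpy(dtype=float)
    s = counts.column(sorted_name).to_numpy(dtype=float)
    lfc = np.log2((s + pseudo) / (u + pseudo))
    rep = rep_label or sorted_name
    return pd.DataFrame(
        {
            f"count_unsorted_{rep}": u.astype(int),
            f"count_sorted_{rep}": s.astype(int),
            f"lfc_{rep}": lfc,
        },
        index=counts.sgrna_ids,
    )


def compute_enrichment(
    counts: CountTable,
    pairs: Sequence[tuple[str, str]],
    pseudo: float = DEFAULT_PSEUDO,
) -> pd.DataFrame:
    """Fold-changes for every replicate pair; replicates labelled rep1..repR."""
    if not pairs:
        raise ValueError("no replicate pairs given")
    frames = [
        log2_fold_change(counts, pair, pseudo=pseudo, rep_label=f"rep{i + 1}")
        for i, pair in enumerate(pairs)
    ]
    table = pd.concat(frames, axis=1)
    table.insert(0, "gene", counts.counts["gene"])
    table.attrs["pseudo"] = pseudo
    table.attrs["orientation"] = "log2(sorted/unsorted); enrichment positive"
    table.attrs["n_replicates"] = len(pairs)
    return table


def _rep_labels(tab: pd.DataFrame) -> list[str]:
    return [c[len("lfc_"):] for c in tab.columns if c.startswith("lfc_")]


def subset_filter(
    tab: pd.DataFrame,
    min_unsorted_reads: int = DEFAULT_MIN_UNSORTED_READS,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
) -> pd.DataFrame:
    """Flag guides passing the dual-replicate subset filter.

    Per replicate: ``pass`` requires unsorted count >= min_unsorted_reads
    AND lfc strictly > lfc_threshold. ``pass_all`` requires both conditions
    in every replicate. Returns a copy with pass columns added.
    """
    reps = _rep_labels(tab)
    if not reps:
        raise ValueError("table carries no lfc_<rep> columns; run compute_enrichment first")
    if len(reps) == 1:
        logger.warning("subset_filter applied to a single replicate")
    out = tab.copy()
    all_pass = np.ones(len(tab), dtype=bool)
    for rep in reps:
        min_ok = out[f"count_unsorted_{rep}"].to_numpy() >= min_unsorted_reads
        lfc_ok = out[f"lfc_{rep}"].to_numpy() > lfc_threshold  # strict, per the ">" rule
        out[f"pass_min_reads_{rep}"] = min_ok
        out[f"pass_lfc_{rep}"] = lfc_ok
        all_pass &= min_ok & lfc_ok
    out["pass_all"] = all_pass
    out.attrs.update(tab.attrs)
    out.attrs["min_unsorted_reads"] = min_unsorted_reads
    out.attrs["lfc_threshold"] = lfc_threshold
    return out


@dataclass
class CandidateSet:
    """Gene-level candidates with per-gene passing-guide counts."""

    genes: list[tuple[str, int]]           # (gene, n_passing_sgrnas), sorted
    threshold: int
    provenance: str = "subset_filter"      # or rank_aggregation / union
    params: dict = field(default_factory=dict)

    @property
    def gene_names(self) -> list[str]:
        return [g for g, _ in self.genes]

    def __len__(self) -> int:
        return len(self.genes)

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame(self.genes, columns=["gene", "n_passing"])
        frame["provenance"] = self.provenance
        frame.to_csv(path, sep="\t", index=False)


def call_candidates(
    tab: pd.DataFrame,
    lib: SgRNALibrary | None = None,
    min_sgrnas: int = DEFAULT_MIN_SGRNAS,
) -> CandidateSet:
    """Count passing guides per gene and keep genes with >= ``min_sgrnas``.

    Non-targeting controls are excluded. Output is sorted by descending
    passing-guide count, then gene name.
    """
    if "pass_all" not in tab.columns:
        raise ValueError("run subset_filter before call_candidates")
    passing = tab.loc[tab["pass_all"] & (tab["gene"] != NONTARGETING_GENE)]
    per_gene = passing.groupby("gene").size()
    kept = per_gene[per_gene >= min_sgrnas]
    genes = sorted(kept.items(), key=lambda kv: (-kv[1], kv[0]))
    return CandidateSet(
        genes=[(g, int(n)) for g, n in genes],
        threshold=min_sgrnas,
        provenance="subset_filter",
        params={k: tab.attrs.get(k) for k in ("min_unsorted_reads", "lfc_threshold", "pseudo")},
    )


def union_candidates(a: CandidateSet, b: CandidateSet) -> CandidateSet:
    """Set union; a gene present in both keeps its larger passing count."""
    merged: dict[str, int] = dict(a.genes)
    for gene, n in b.genes:
        merged[gene] = max(merged.get(gene, 0), n)
    genes = sorted(merged.items(), key=lambda kv: (-kv[1], kv[0]))
    return CandidateSet(
        genes=[(g, int(n)) for g, n in genes],
        threshold=min(a.threshold, b.threshold),
        provenance="union",
        params={"a": a.provenance, "b": b.provenance},
    )


def scatter_data(tab: pd.DataFrame) -> pd.DataFrame:
    """Export x = rep1 lfc, y = rep2 lfc for plotting."""
    reps = _rep_labels(tab)
    if len(reps) < 2:
        raise ValueError("scatter export needs two replicates")
    out = pd.DataFrame(
        {"gene": tab["gene"], "x": tab[f"lfc_{reps[0]}"], "y": tab[f"lfc_{reps[1]}"]},
        index=tab.index,
    )
    if "pass_all" in tab.columns:
        out["pass_all"] = tab["pass_all"]
    return out
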