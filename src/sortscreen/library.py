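"""sgRNA library representation and CSV I/O.

A pooled CRISPR knockout library is a table of guides: each guide has a
unique identifier, a target gene symbol, and a 20-nt protospacer sequence.
Non-targeting control guides carry the reserved gene label
:data:`NONTARGETING_GENE` so downstream gene-level aggregation can skip
them deterministically.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: Reserved gene label for non-targeting control guides.
NONTARGETING_GENE = "NonTargeting"

SPACER_LENGTH = 20
_SPACER_ALPHABET = frozenset("ACGT")

#: Fixed CSV schema, in column order.
CSV_COLUMNS = ("sgrna_id", "gene", "spacer")


class LibraryValidationError(ValueError):
    """Raised when a library or one of its entries violates an invariant."""


@dataclass(frozen=True)
class SgRNA:
    """One guide: id, target gene symbol and 20-nt spacer (A/C/G/T)."""

    id: str
    gene: str
    spacer: str

    def __post_init__(self) -> None:
        if not self.id:
            raise LibraryValidationError("sgRNA id must be non-empty")
        if not self.gene:
            raise LibraryValidationError(f"sgRNA {self.id!r}: gene must be non-empty")
        if len(self.spacer) != SPACER_LENGTH:
            raise LibraryValidationError(
                f"sgRNA {self.id!r}: spacer length {len(self.spacer)} != {SPACER_LENGTH}"
            )
        if not _SPACER_ALPHABET.issuperset(self.spacer):
            bad = sorted(set(self.spacer) - _SPACER_ALPHABET)
            raise LibraryValidationError(
                f"sgRNA {self.id!r}: spacer contains non-ACGT characters {bad}"
            )


@dataclass
class SgRNALibrary:
    """Ordered, validated collection of :class:`SgRNA` entries.

    Invariants enforced at construction:

    * ids are unique;
    * no spacer sequence maps to two different ids.
    """

    entries: list[SgRNA] = field(default_factory=list)
    name: str = "library"

    def __post_init__(self) -> None:
        seen_ids: dict[str, int] = {}
        seen_spacers: dict[str, str] = {}
        for row, sg in enumerate(self.entries):
            if sg.id in seen_ids:
                raise LibraryValidationError(
                    f"duplicate sgRNA id {sg.id!r} (rows {seen_ids[sg.id]} and {row})"
                )
            seen_ids[sg.id] = row
            prev = seen_spacers.get(sg.spacer)
            if prev is not None and prev != sg.id:
                raise LibraryValidationError(
                    f"spacer {sg.spacer} shared by sgRNAs {prev!r} and {sg.id!r}"
                )
            seen_spacers[sg.spacer] = sg.id

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[SgRNA]:
        return iter(self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SgRNALibrary):
            return NotImplemented
        return self.entries == other.entries

    @property
    def ids(self) -> list[str]:
        return [sg.id for sg in self.entries]

    @property
    def spacers(self) -> list[str]:
        return [sg.spacer for sg in self.entries]

    def gene_of(self, sgrna_id: str) -> str:
        return self._id_to_gene()[sgrna_id]

    def _id_to_gene(self) -> dict[str, str]:
        return {sg.id: sg.gene for sg in self.entries}

    def gene_index(self, include_nontargeting: bool = True) -> dict[str, list[SgRNA]]:
        """Map gene symbol -> list of its guides, preserving library order."""
        index: dict[str, list[SgRNA]] = {}
        for sg in self.entries:
            if not include_nontargeting and sg.gene == NONTARGETING_GENE:
                continue
            index.setdefault(sg.gene, []).append(sg)
        return index

    def genes(self, include_nontargeting: bool = False) -> list[str]:
        """Distinct gene symbols in library order."""
        return list(self.gene_index(include_nontargeting))

    def spacer_index(self) -> dict[str, str]:
        """Map spacer sequence -> sgRNA id (spacers are unique per library)."""
        return {sg.spacer: sg.id for sg in self.entries}


def read_library(path: str | Path, fmt: str = "csv", name: str | None = None) -> SgRNALibrary:
    """Read a library from a CSV with header columns ``sgrna_id,gene,spacer``.

    Lowercase spacers are upcased with a logged notice; any other schema or
    content problem raises :class:`LibraryValidationError` naming the row.
    """
    if fmt != "csv":
        raise ValueError(f"unsupported library format {fmt!r}")
    path = Path(path)
    entries: list[SgRNA] = []
    upcased = 0
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise LibraryValidationError(
                f"{path}: missing required columns {sorted(missing)}"
            )
        for row_no, rec in enumerate(reader, start=2):  # header is line 1
            spacer = (rec["spacer"] or "").strip()
            if spacer != spacer.upper():
                spacer = spacer.upper()
                upcased += 1
            try:
                entries.append(SgRNA(id=rec["sgrna_id"].strip(), gene=rec["gene"].strip(), spacer=spacer))
            except LibraryValidationError as err:
                raise LibraryValidationError(f"{path} line {row_no}: {err}") from err
    if upcased:
        logger.info("%s: upcased %d lowercase spacer(s) on load", path, upcased)
    return SgRNALibrary(entries=entries, name=name or path.stem)


def write_library(lib: SgRNALibrary, path: str | Path) -> None:
    """Write a library as CSV; ``read_library(write_library(x)) == x``."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for sg in lib.entries:
            writer.writerow((sg.id, sg.gene, sg.spacer))


def library_from_records(records: Iterable[tuple[str, str, str]], name: str = "library") -> SgRNALibrary:
    """Build a library from (id, gene, spacer) tuples."""
    return SgRNALibrary(entries=[SgRNA(*r) for r in records], name=name)
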