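"""Exact-match sgRNA quantification from amplicon FASTQ.

Counting is strict: a read contributes to a guide only if a 20-mer in the
read is identical to that guide's spacer. The primary path anchors on the
constant vector sequence immediately 5' of the spacer (its position varies
read-to-read because of the staggered amplicon primer); when the anchor is
absent — e.g. destroyed by a sequencing error — an optional fallback scans
every 20-mer of the read against the spacer set and assigns only if exactly
one library spacer occurs. Ambiguous or unmatched reads are counted as
unassigned. Counting is streaming: memory is proportional to library size,
not FASTQ size.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .counttable import CountTable, SampleStats, merge_counts  # noqa: F401  (merge re-export)
from .library import SPACER_LENGTH, SgRNALibrary
from .simulate import ANCHOR

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def count_reads(
    fastq: str | Path,
    lib: SgRNALibrary,
    sample_name: str,
    anchor: str = ANCHOR,
    stagger_max: int = 8,
    fallback_scan: bool = True,
    search_revcomp: bool = False,
) -> CountTable:
    """Count exact spacer matches in a FASTQ (optionally gzipped).

    For each read the anchor is searched within the window allowed by the
    primer stagger (offsets ``0 .. stagger_max + anchor slack``); the 20 nt
    following the first anchor occurrence must equal a library spacer
    exactly. Reads without a usable anchor fall back (if enabled) to
    scanning all 20-mers; a read matching two or more distinct spacers is
    unassigned. Returns a single-column :class:`CountTable` whose stats
    satisfy assigned + unassigned == total.
    """
    fastq = Path(fastq)
    spacer_to_idx = {sg.spacer: i for i, sg in enumerate(lib.entries)}
    if search_revcomp:
        for i, sg in enumerate(lib.entries):
            spacer_to_idx.setdefault(_revcomp(sg.spacer), i)
    counts = np.zeros(len(lib), dtype=np.int64)
    # anchor may start anywhere within the stagger window plus the constant
    # region preceding it; cap the search there so random downstream hits
    # (e.g. in the scaffold) cannot masquerade as the primer anchor
    search_end = stagger_max + len(ANCHOR) + 15 + len(anchor)
    total = 0
    unassigned = 0
    with pysam.FastxFile(str(fastq)) as fh:
        for rec in fh:
            total += 1
            seq = rec.sequence.upper()
            idx = _assign(seq, anchor, search_end, spacer_to_idx, fallback_scan)
            if idx is None:
                unassigned += 1
            else:
                counts[idx] += 1
    logger.info(
        "%s: %d reads, %d assigned, %d unassigned",
        sample_name, total, total - unassigned, unassigned,
    )
    return CountTable.from_counts(
        sgrna_ids=lib.ids,
        genes=[sg.gene for sg in lib.entries],
        columns={sample_name: counts},
        stats={sample_name: SampleStats(total_reads=total, unassigned=unassigned)},
    )


def _assign(
    seq: str,
    anchor: str,
    search_end: int,
    spacer_to_idx: dict[str, int],
    fallback_scan: bool,
) -> int | None:
    pos = seq.find(anchor, 0, search_end)
    if pos >= 0:
        start = pos + len(anchor)
        spacer = seq[start:start + SPACER_LENGTH]
        if len(spacer) < SPACER_LENGTH:
            return None  # read too short after anchor
        return spacer_to_idx.get(spacer)  # exact match or unassigned
    if not fallback_scan:
        return None
    # position-free rescue: assign only if exactly one library spacer occurs
    found: int | None = None
    for i in range(len(seq) - SPACER_LENGTH + 1):
        idx = spacer_to_idx.get(seq[i:i + SPACER_LENGTH])
        if idx is not None:
            if found is not None and idx != found:
                return None  # ambiguous
            found = idx
    return found


def count_samples(
    fastqs: Sequence[tuple[str | Path, str]],
    lib: SgRNALibrary,
    **kwargs,
) -> CountTable:
    """Count several (fastq, sample_name) inputs and merge the columns."""
    tables = [count_reads(fq, lib, name, **kwargs) for fq, name in fastqs]
    return merge_counts(tables)
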