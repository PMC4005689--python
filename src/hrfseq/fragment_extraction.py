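"""From read pairs / paired alignments to canonical fragments.

A fragment is a (termination site, priming site) pair on the reference RNA:
the termination site is the last reverse-transcribed nucleotide (5'-most
aligned position of the cDNA-derived first mate), the priming site is the
first sequenced nucleotide of the second mate (3'-most reference position of
the pair).  All coordinates are 1-based and inclusive, on the sense strand.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

MIN_READ_LENGTH_AFTER_TRIM = 15

#: SAM tag carrying the ligated barcode on emitted/ingested records
BARCODE_TAG = "BC"

FRAGMENT_COLUMNS = ["rna_id", "termination_pos", "priming_pos", "barcode", "read_count"]


@dataclass(frozen=True)
class Fragment:
    rna_id: str
    termination_pos: int
    priming_pos: int
    barcode: str

    def __post_init__(self) -> None:
        if self.termination_pos > self.priming_pos:
            raise ValueError(
                f"termination_pos {self.termination_pos} > priming_pos "
                f"{self.priming_pos}"
            )
        if self.termination_pos < 1:
            raise ValueError("coordinates are 1-based; termination_pos < 1")

    @property
    def span(self) -> int:
        """Nucleotides covered, inclusive of both endpoints."""
        return self.priming_pos - self.termination_pos + 1


@dataclass
class SplitResult:
    """Outcome of peeling the barcode off a raw read pair."""

    barcode: str | None
    read1: str | None
    read2: str | None
    kept: bool
    reason: str | None = None
    ambiguous: bool = False  # barcode contains N


def split_barcode(
    read1: str,
    read2: str,
    length: int = 7,
    min_length: int = MIN_READ_LENGTH_AFTER_TRIM,
) -> SplitResult:
    """Remove the barcode from a read pair.

    The first ``length`` bases of read 1 are the barcode; the last ``length``
    bases of read 2 (its reverse-complement image) are removed.  Pairs where
    either trimmed read is shorter than ``min_length`` are discarded.
    """
    if len(read1) <= length:
        return SplitResult(None, None, None, False, reason="read1_shorter_than_barcode")
    barcode = read1[:length]
    trimmed1 = read1[length:]
    trimmed2 = read2[:-length] if length else read2
    if len(trimmed1) < min_length or len(trimmed2) < min_length:
        return SplitResult(barcode, trimmed1, trimmed2, False, reason="too_short_after_trim")
    ambiguous = "N" in barcode
    return SplitResult(barcode, trimmed1, trimmed2, True, ambiguous=ambiguous)


def trim_untemplated(
    query_sequence: str,
    reference: str,
    reference_start: int,
    max_trim: int = 3,
) -> int:
    """Adjusted 1-based termination position after untemplated-base trimming.

    Reverse transcriptase can append up to a few untemplated nucleotides to
    the cDNA 3' end; after mapping these show up as contiguous mismatches at
    the 5' (left, termination) end of the first mate.  Contiguous mismatching
    bases, up to ``max_trim``, are trimmed and the termination position moves
    downstream accordingly.  Matching bases are never trimmed.

    Parameters
    ----------
    query_sequence:
        Aligned portion of mate 1 (soft clips excluded), reference-forward.
    reference:
        Full reference sequence.
    reference_start:
        0-based leftmost reference coordinate of the alignment.
    """
    trimmed = 0
    limit = min(max_trim, len(query_sequence))
    for i in range(limit):
        ref_pos = reference_start + i
        if ref_pos >= len(reference):
            break
        if query_sequence[i].upper() == reference[ref_pos].upper():
            break
        trimmed += 1
    return reference_start + trimmed + 1  # 1-based


def _resolve_pairs(alignments, tallies: Counter):
    """Group primary mapped records by query name into (mate1, mate2) pairs."""
    pending: dict[str, object] = {}
    for rec in alignments:
        tallies["records_in"] += 1
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            tallies["skipped_secondary_supplementary_unmapped"] += 1
            continue
        if not rec.is_paired:
            tallies["skipped_unpaired"] += 1
            continue
        mate = pending.pop(rec.query_name, None)
        if mate is None:
            pending[rec.query_name] = rec
            continue
        first, second = (rec, mate) if rec.is_read1 else (mate, rec)
        if not (first.is_read1 and second.is_read2):
            tallies["skipped_bad_mate_flags"] += 2
            continue
        yield first, second
    tallies["skipped_missing_mate"] += len(pending)


def fragments_from_alignments(
    alignments,
    reference: str,
    rna_id: str,
    max_trim: int = 3,
) -> pd.DataFrame:
    """Build a read-level fragment table from paired sense-strand alignments.

    Mate 1 must align forward (its leftmost position is the termination
    site after untemplated trimming); mate 2 must align reverse (its
    rightmost position, the first sequenced base, is the priming site).
    Reverse-orientation pairs are rejected, not rescued.  The barcode is
    read from the ``BC`` tag of mate 1 (``N`` placeholder when absent).

    Returns one row per kept pair with ``read_count = 1``.
    """
    rows = []
    tallies = Counter()
    pair_iter = _resolve_pairs(alignments, tallies)
    for mate1, mate2 in pair_iter:
        tallies["paired"] += 1
        if mate1.is_reverse or not mate2.is_reverse:
            tallies["wrong_orientation"] += 1
            continue
        term = trim_untemplated(
            mate1.query_alignment_sequence or "",
            reference,
            mate1.reference_start,
            max_trim=max_trim,
        )
        prime = mate2.reference_end  # 0-based exclusive end == 1-based inclusive
        if term > prime:
            tallies["termination_after_priming"] += 1
            continue
        barcode = mate1.get_tag(BARCODE_TAG) if mate1.has_tag(BARCODE_TAG) else "N"
        rows.append((rna_id, term, prime, barcode, 1))
        tallies["kept"] += 1
    logger.info("fragment extraction tallies: %s", dict(tallies))
    out = pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)
    out.attrs["tallies"] = dict(tallies)
    return out


def aggregate_fragments(table: pd.DataFrame) -> pd.DataFrame:
    """Collapse a read-level table to one row per fragment.

    ``read_count`` sums all reads (including ambiguous barcodes); ``k``
    counts distinct barcodes over the ACGT alphabet only — barcodes with N
    contribute reads but not barcode diversity.
    """
    if table.empty:
        return pd.DataFrame(
            columns=["rna_id", "termination_pos", "priming_pos", "read_count", "k"]
        )
    key = ["rna_id", "termination_pos", "priming_pos"]
    valid = ~table["barcode"].astype(str).str.contains("N")
    reads = table.groupby(key, sort=True)["read_count"].sum()
    k = (
        table.loc[valid]
        .groupby(key, sort=True)["barcode"]
        .nunique()
        .reindex(reads.index, fill_value=0)
    )
    out = pd.DataFrame({"read_count": reads, "k": k}).reset_index()
    return out


def span_filter(table: pd.DataFrame, min_span: int = 100) -> pd.DataFrame:
    """Drop rows spanning fewer than ``min_span`` nucleotides (inclusive span).

    ``min_span = 0`` leaves the table unchanged.  Applied to neutralize
    library size selection; single-primer analyses typically skip it.
    """
    if min_span <= 0:
        return table
    span = table["priming_pos"] - table["termination_pos"] + 1
    kept = table[span >= min_span].reset_index(drop=True)
    logger.info("span filter: kept %d of %d rows", len(kept), len(table))
    return kept
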