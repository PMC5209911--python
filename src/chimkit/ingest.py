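"""Convert SAM/BAM records into split-read and mate-pair evidence.

Two evidence streams feed chimera detection:

* **split reads** — a read aligned in exactly two genomic segments, either
  as one spliced primary alignment (a single ``N`` CIGAR gap; same
  chromosome and strand) or as a primary plus one supplementary alignment
  described by the ``SA`` tag (any chromosomes, strands or order);
* **mate pairs** — read pairs with both mates aligned, used downstream as
  discordant paired-end evidence.

Read pairs reported at more than ``max_hits`` positions (``NH`` tag) are
treated as unmapped and excluded from both streams.  BAM 0-based half-open
coordinates are converted to 1-based inclusive here and nowhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pysam

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SegmentMapping:
    """One aligned genomic segment of a read (1-based inclusive).

    ``read_start``/``read_end`` give the 0-based half-open range of read
    bases (in the original sequencing orientation) covered by the segment.
    """

    chrom: str
    start: int
    end: int
    strand: str
    read_start: int = 0
    read_end: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SplitRead:
    """A read split into two genomic segments, in 5'→3' read order."""

    read_id: str
    mate_index: int
    seg_a: SegmentMapping
    seg_b: SegmentMapping
    nh: int = 1


@dataclass
class MatePair:
    """Both mates of one read pair, each as a list of aligned blocks."""

    read_id: str
    mate1: list[SegmentMapping] = field(default_factory=list)
    mate2: list[SegmentMapping] = field(default_factory=list)
    nh: int = 1

    @property
    def both_mapped(self) -> bool:
        return bool(self.mate1) and bool(self.mate2)


@dataclass
class IngestReport:
    """Counts of records set aside during ingestion."""

    multi_gap_reads: int = 0
    multimapped_pairs: int = 0
    bad_sa_records: int = 0
    high_mismatch_records: int = 0


_CIGAR_CONSUMES_QUERY = {0, 1, 4, 7, 8}  # M I S = X
_CIGAR_CONSUMES_REF = {0, 2, 3, 7, 8}  # M D N = X


def _cigar_read_span(cigartuples, reverse: bool) -> tuple[int, int, int]:
    """(read_start, read_end, read_length) in original read orientation."""
    leading = trailing = 0
    aligned = 0
    total = 0
    seen_aligned = False
    for op, ln in cigartuples:
        if op in (4, 5):  # S or H
            total += ln
            if seen_aligned:
                trailing += ln
            else:
                leading += ln
        elif op in _CIGAR_CONSUMES_QUERY:
            seen_aligned = True
            aligned += ln
            total += ln
    if reverse:
        leading, trailing = trailing, leading
    return leading, leading + aligned, total


def _split_from_n_gap(rec: pysam.AlignedSegment) -> tuple[SegmentMapping, SegmentMapping]:
    """Two flank segments of a single-N-gap spliced alignment, read order."""
    strand = "-" if rec.is_reverse else "+"
    ref = rec.reference_start + 1  # to 1-based
    flanks: list[tuple[int, int]] = []  # (start, end) 1-based inclusive
    cur_start = ref
    cur = ref
    for op, ln in rec.cigartuples:
        if op == 3:  # N: close current flank
            flanks.append((cur_start, cur - 1))
            cur += ln
            cur_start = cur
        elif op in _CIGAR_CONSUMES_REF:
            cur += ln
    flanks.append((cur_start, cur - 1))
    assert len(flanks) == 2
    # read-local extents per flank
    rs, re_, _ = _cigar_read_span(rec.cigartuples, rec.is_reverse)
    # query bases consumed before/after the N gap
    before = after = 0
    past_gap = False
    for op, ln in rec.cigartuples:
        if op == 3:
            past_gap = True
        elif op in (0, 1, 7, 8):
            if past_gap:
                after += ln
            else:
                before += ln
    if not rec.is_reverse:
        local = [(rs, rs + before), (rs + before, re_)]
        ordered = [0, 1]
    else:
        # genomic-left flank is the 3' end of the read
        local = [(re_ - before, re_), (rs, rs + after)]
        ordered = [1, 0]
    segs = [
        SegmentMapping(rec.reference_name, s, e, strand, local[i][0], local[i][1])
        for i, (s, e) in enumerate(flanks)
    ]
    return segs[ordered[0]], segs[ordered[1]]


def _cigarstring_to_tuples(cigar: str) -> list[tuple[int, int]]:
    ops = "MIDNSHP=X"
    out = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            out.append((ops.index(ch), int(num)))
            num = ""
    return out


def _segment_from_record(rec: pysam.AlignedSegment) -> SegmentMapping:
    rs, re_, _ = _cigar_read_span(rec.cigartuples, rec.is_reverse)
    return SegmentMapping(
        rec.reference_name,
        rec.reference_start + 1,
        rec.reference_end,  # pysam reference_end is exclusive == 1-based inclusive end
        "-" if rec.is_reverse else "+",
        rs,
        re_,
    )


def _segment_from_sa(entry: str) -> SegmentMapping:
    chrom, pos, strand, cigar, _mapq, _nm = entry.split(",")[:6]
    tuples = _cigarstring_to_tuples(cigar)
    ref_len = sum(ln for op, ln in tuples if op in _CIGAR_CONSUMES_REF)
    start = int(pos)
    rs, re_, _ = _cigar_read_span(tuples, strand == "-")
    return SegmentMapping(chrom, start, start + ref_len - 1, strand, rs, re_)


def ingest_alignments(
    path: str, max_hits: int = 10, max_mismatch_rate: float | None = None
) -> tuple[list[SplitRead], list[MatePair], IngestReport]:
    """Extract split reads and mate pairs from a SAM/BAM file.

    Records are grouped by read name; a pair whose NH exceeds ``max_hits``
    on either mate is dropped from both streams.  Secondary and
    supplementary records never seed evidence themselves (supplementary
    segments are recovered through the primary's SA tag), so no read
    contributes more than one split read per mapping position.

    ``max_mismatch_rate`` optionally re-applies a mismatch cap at
    ingestion: records whose NM tag exceeds that fraction of their aligned
    length are dropped.  Off by default since mappers normally enforce
    their own cap.
    """
    report = IngestReport()
    by_name: dict[str, dict[int, pysam.AlignedSegment]] = {}
    with pysam.AlignmentFile(path, check_sq=False) as fh:
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if max_mismatch_rate is not None and rec.has_tag("NM"):
                aligned = sum(
                    ln for op, ln in rec.cigartuples if op in (0, 7, 8)
                )
                if aligned and rec.get_tag("NM") / aligned > max_mismatch_rate:
                    report.high_mismatch_records += 1
                    continue
            mate = 2 if rec.is_read2 else 1
            by_name.setdefault(rec.query_name, {})[mate] = rec

    splits: list[SplitRead] = []
    pairs: list[MatePair] = []
    for name in by_name:
        recs = by_name[name]
        nh = max(
            (rec.get_tag("NH") if rec.has_tag("NH") else 1) for rec in recs.values()
        )
        if nh > max_hits:
            report.multimapped_pairs += 1
            continue
        pair = MatePair(name, nh=nh)
        for mate_index, rec in sorted(recs.items()):
            blocks = [
                SegmentMapping(
                    rec.reference_name, s + 1, e, "-" if rec.is_reverse else "+"
                )
                for s, e in rec.get_blocks()
            ]
            if mate_index == 1:
                pair.mate1 = blocks
            else:
                pair.mate2 = blocks
            split = _split_of_record(rec, mate_index, nh, report)
            if split is not None:
                splits.append(split)
        if pair.both_mapped:
            pairs.append(pair)
    return splits, pairs, report


def _split_of_record(
    rec: pysam.AlignedSegment, mate_index: int, nh: int, report: IngestReport
) -> SplitRead | None:
    if rec.has_tag("SA"):
        sa = str(rec.get_tag("SA")).rstrip(";")
        entries = sa.split(";") if sa else []
        if len(entries) != 1:
            report.bad_sa_records += 1
            return None
        try:
            other = _segment_from_sa(entries[0])
        except (ValueError, IndexError):
            log.warning("unparseable SA tag on %s", rec.query_name)
            report.bad_sa_records += 1
            return None
        own = _segment_from_record(rec)
        seg_a, seg_b = sorted((own, other), key=lambda s: s.read_start)
        return SplitRead(rec.query_name, mate_index, seg_a, seg_b, nh)
    n_gaps = sum(1 for op, _ in (rec.cigartuples or []) if op == 3)
    if n_gaps == 1:
        seg_a, seg_b = _split_from_n_gap(rec)
        return SplitRead(rec.query_name, mate_index, seg_a, seg_b, nh)
    if n_gaps > 1:
        report.multi_gap_reads += 1
    return None
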