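"""Gene annotation model with fast exon-overlap queries.

Parses exon lines of a GTF (GFF2 dialect) into a per-chromosome interval
index and derives the catalogue of annotated splice sites: for every
transcript with two or more exons, each intron contributes one donor site
(last exonic base of the upstream-in-transcription exon) and one acceptor
site (first exonic base of the downstream exon).  Coordinates are 1-based
inclusive throughout, as in the GTF itself; single-exon transcripts have no
internal boundaries and therefore contribute no splice sites.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

from intervaltree import IntervalTree

log = logging.getLogger(__name__)

#: (chrom, position, strand) of a splice site.
Site = tuple[str, int, str]


class GtfError(ValueError):
    """Raised for a malformed GTF line, carrying its line number."""


@dataclass(frozen=True)
class Exon:
    """One annotated exon, 1-based inclusive coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"exon start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Gene:
    """A gene aggregated over its exon lines.

    ``exons`` is the union of exons over all transcripts; ``blocks`` is
    the same set with duplicate (start, end) intervals collapsed, which is
    the unit used for overlap accounting.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    biotype: str = "unknown"
    exons: list[Exon] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        return (min(e.start for e in self.exons), max(e.end for e in self.exons))

    @property
    def blocks(self) -> list[tuple[int, int]]:
        """Distinct exonic (start, end) intervals, sorted."""
        return sorted({(e.start, e.end) for e in self.exons})

    @property
    def is_pseudogene(self) -> bool:
        return "pseudogene" in self.biotype


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(attr_field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(attr_field))
    if not attrs:
        raise GtfError(f"line {lineno}: cannot parse attribute field {attr_field!r}")
    return attrs


class AnnotationIndex:
    """Interval-indexed exons plus gene table and splice-site catalogue.

    Attributes
    ----------
    genes : dict[str, Gene]
    exons : list[Exon]
    donor_sites, acceptor_sites : set[Site]
        Stranded genomic positions of annotated donor / acceptor splice
        sites, derived from transcript-internal exon boundaries.
    """

    def __init__(self, exons: Iterable[Exon]) -> None:
        self.exons: list[Exon] = list(exons)
        self.genes: dict[str, Gene] = {}
        self._trees: dict[str, IntervalTree] = {}
        self._unknown_chroms_logged: set[str] = set()
        by_transcript: dict[str, list[Exon]] = {}
        for exon in self.exons:
            gene = self.genes.get(exon.gene_id)
            if gene is None:
                gene = Gene(exon.gene_id, exon.gene_id, exon.chrom, exon.strand)
                self.genes[exon.gene_id] = gene
            gene.exons.append(exon)
            # interval tree is half-open; store [start, end+1)
            self._trees.setdefault(exon.chrom, IntervalTree()).addi(
                exon.start, exon.end + 1, exon
            )
            by_transcript.setdefault(exon.transcript_id, []).append(exon)

        self.donor_sites: set[Site] = set()
        self.acceptor_sites: set[Site] = set()
        self._donors_by_gene: dict[str, set[Site]] = {}
        self._acceptors_by_gene: dict[str, set[Site]] = {}
        for tx_exons in by_transcript.values():
            tx_exons = sorted(tx_exons, key=lambda e: e.start)
            for left, right in zip(tx_exons, tx_exons[1:]):
                strand = left.strand
                gene_id = left.gene_id
                if strand == "+":
                    donor: Site = (left.chrom, left.end, "+")
                    acceptor: Site = (right.chrom, right.start, "+")
                else:
                    # transcription runs right-to-left: the genomically
                    # downstream exon is transcribed first
                    donor = (right.chrom, right.start, "-")
                    acceptor = (left.chrom, left.end, "-")
                self.donor_sites.add(donor)
                self.acceptor_sites.add(acceptor)
                self._donors_by_gene.setdefault(gene_id, set()).add(donor)
                self._acceptors_by_gene.setdefault(gene_id, set()).add(acceptor)

    def set_biotype(self, gene_id: str, biotype: str) -> None:
        self.genes[gene_id].biotype = biotype or "unknown"

    def gene_donors(self, gene_id: str) -> set[Site]:
        return self._donors_by_gene.get(gene_id, set())

    def gene_acceptors(self, gene_id: str) -> set[Site]:
        return self._acceptors_by_gene.get(gene_id, set())

    def is_annotated_donor(self, site: Site) -> bool:
        return site in self.donor_sites

    def is_annotated_acceptor(self, site: Site) -> bool:
        return site in self.acceptor_sites

    def overlap(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> list[tuple[Exon, int]]:
        """All exons intersecting [start, end] with their overlap in bp.

        ``strand`` restricts hits to one strand; ``None`` queries both.
        An unknown chromosome yields an empty result (logged once).
        """
        if start > end:
            raise ValueError(f"query start {start} > end {end}")
        tree = self._trees.get(chrom)
        if tree is None:
            if chrom not in self._unknown_chroms_logged:
                log.warning("chromosome %s absent from annotation", chrom)
                self._unknown_chroms_logged.add(chrom)
            return []
        hits = []
        for iv in tree.overlap(start, end + 1):
            exon: Exon = iv.data
            if strand is not None and exon.strand != strand:
                continue
            ov = min(end, exon.end) - max(start, exon.start) + 1
            hits.append((exon, ov))
        hits.sort(key=lambda h: (h[0].start, h[0].end, h[0].gene_id, h[0].transcript_id))
        return hits

    def gene_overlap_bp(
        self, chrom: str, start: int, end: int, strand: str | None = None
    ) -> dict[str, int]:
        """Summed overlap per gene over collapsed exon blocks."""
        per_gene: dict[str, set[tuple[int, int, int, int]]] = {}
        for exon, _ in self.overlap(chrom, start, end, strand):
            lo, hi = max(start, exon.start), min(end, exon.end)
            per_gene.setdefault(exon.gene_id, set()).add((exon.start, exon.end, lo, hi))
        out: dict[str, int] = {}
        for gene_id, blocks in per_gene.items():
            # duplicate (start,end) blocks across transcripts collapse in the set
            seen = {(s, e): (lo, hi) for s, e, lo, hi in blocks}
            out[gene_id] = sum(hi - lo + 1 for lo, hi in seen.values())
        return out

    def best_gene(
        self, overlaps: dict[str, int]
    ) -> tuple[str | None, int]:
        """Gene with the largest summed exonic overlap.

        Ties go to protein_coding biotype first, then to the
        lexicographically smallest gene_id, so assignment is deterministic.
        """
        if not overlaps:
            return None, 0
        def key(gene_id: str) -> tuple:
            gene = self.genes[gene_id]
            return (
                -overlaps[gene_id],
                0 if gene.biotype == "protein_coding" else 1,
                gene_id,
            )
        best = min(overlaps, key=key)
        return best, overlaps[best]

    def transcripts_of(self, gene_id: str) -> dict[str, list[Exon]]:
        """Exons per transcript of one gene, sorted genomically."""
        out: dict[str, list[Exon]] = {}
        for exon in self.genes[gene_id].exons:
            out.setdefault(exon.transcript_id, []).append(exon)
        for tx in out.values():
            tx.sort(key=lambda e: e.start)
        return out


def read_gtf(path: str) -> AnnotationIndex:
    """Build an :class:`AnnotationIndex` from a (possibly gzipped) GTF.

    Only ``exon`` feature lines are used.  Gene biotype is taken from the
    ``gene_type`` or ``gene_biotype`` attribute (first found, exon or gene
    lines), defaulting to ``"unknown"``; gene name from ``gene_name``.
    Malformed lines raise :class:`GtfError` with the line number.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    exons: list[Exon] = []
    biotypes: dict[str, str] = {}
    names: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GtfError(f"line {lineno}: expected 9 tab-separated fields")
            chrom, _, feature, start, end, _, strand, _, attr_field = fields[:9]
            attrs = _parse_attributes(attr_field, lineno)
            gene_id = attrs.get("gene_id")
            if gene_id:
                bt = attrs.get("gene_type") or attrs.get("gene_biotype")
                if bt and gene_id not in biotypes:
                    biotypes[gene_id] = bt
                if "gene_name" in attrs and gene_id not in names:
                    names[gene_id] = attrs["gene_name"]
            if feature != "exon":
                continue
            if not gene_id or "transcript_id" not in attrs:
                raise GtfError(
                    f"line {lineno}: exon lacks gene_id/transcript_id attributes"
                )
            try:
                exon = Exon(chrom, int(start), int(end), strand,
                            gene_id, attrs["transcript_id"])
            except ValueError as exc:
                raise GtfError(f"line {lineno}: {exc}") from exc
            exons.append(exon)

    index = AnnotationIndex(exons)
    for gene_id, gene in index.genes.items():
        gene.biotype = biotypes.get(gene_id, "unknown")
        gene.gene_name = names.get(gene_id, gene_id)
    return index
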