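"""Discordant paired-end evidence and its consistency with junctions.

A mate pair whose two mates are assigned (by largest exonic overlap) to
two different genes is *discordant*.  For a candidate junction between
gene5 and gene3, a discordant pair connecting those genes is *consistent*
when its geometry agrees with the chimeric transcript implied by the
junction: the gene5 mate lies upstream of (or abuts) the donor site and is
oriented along transcription, the gene3 mate lies downstream of (or abuts)
the acceptor and faces back toward the junction, and the implied
transcript-space insert stays below a configurable bound.  Everything else
is *inconsistent* — which may reflect another isoform or a misalignment,
so inconsistent pairs are counted but do not by themselves veto a
junction.
"""

from __future__ import annotations

from dataclasses import dataclass

from .annotation import AnnotationIndex
from .ingest import MatePair, SegmentMapping
from .junctions import AnnotatedJunction, JunctionCluster

#: default bound on the implied transcript-space insert, bp.
DEFAULT_MAX_INSERT = 1000


@dataclass(frozen=True)
class MateAssignment:
    gene_id: str
    overlap_bp: int
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class DiscordantPair:
    """A read pair whose mates land in two different genes."""

    read_id: str
    mate1: MateAssignment
    mate2: MateAssignment

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset((self.mate1.gene_id, self.mate2.gene_id))

    def mate_in(self, gene_id: str) -> MateAssignment:
        if self.mate1.gene_id == gene_id:
            return self.mate1
        if self.mate2.gene_id == gene_id:
            return self.mate2
        raise KeyError(gene_id)


@dataclass
class JunctionSupport:
    """Read support of one junction; total = split + consistent PE."""

    nb_split: int = 0
    nb_staggered: int = 0
    nb_consistent_pe: int = 0
    nb_inconsistent_pe: int = 0

    @property
    def nb_total(self) -> int:
        return self.nb_split + self.nb_consistent_pe


def _assign_mate(
    blocks: list[SegmentMapping], index: AnnotationIndex, stranded: bool
) -> MateAssignment | None:
    """Exonic-overlap gene assignment of one mate (all aligned blocks)."""
    totals: dict[str, int] = {}
    for blk in blocks:
        strand = blk.strand if stranded else None
        for gene_id, bp in index.gene_overlap_bp(
            blk.chrom, blk.start, blk.end, strand
        ).items():
            totals[gene_id] = totals.get(gene_id, 0) + bp
    gene_id, bp = index.best_gene(totals)
    if gene_id is None:
        return None
    return MateAssignment(
        gene_id,
        bp,
        blocks[0].chrom,
        min(b.start for b in blocks),
        max(b.end for b in blocks),
        blocks[0].strand,
    )


def find_discordant(
    pairs: list[MatePair], index: AnnotationIndex, stranded: bool = False
) -> list[DiscordantPair]:
    """Pairs with both mates mapped to exons of two different genes."""
    out: list[DiscordantPair] = []
    for pair in pairs:
        if not pair.both_mapped:
            continue
        a1 = _assign_mate(pair.mate1, index, stranded)
        a2 = _assign_mate(pair.mate2, index, stranded)
        if a1 is None or a2 is None or a1.gene_id == a2.gene_id:
            continue
        out.append(DiscordantPair(pair.read_id, a1, a2))
    return out


def _exonic_distance(
    index: AnnotationIndex, gene_id: str, chrom: str, start: int, end: int
) -> int:
    """Exonic bp of ``gene_id`` inside [start, end] — a transcript-space
    proxy for genomic distance that discounts introns."""
    gene = index.genes[gene_id]
    if gene.chrom != chrom or start > end:
        return 0
    total = 0
    for bstart, bend in gene.blocks:
        lo, hi = max(start, bstart), min(end, bend)
        if lo <= hi:
            total += hi - lo + 1
    return total


def assess_consistency(
    junction: AnnotatedJunction,
    pair: DiscordantPair,
    index: AnnotationIndex,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> str:
    """Judge one discordant pair against one junction.

    Returns ``"consistent"`` or ``"inconsistent"``.  The pair must connect
    the junction's two parent genes (contract; KeyError otherwise).  The
    implied insert is measured in transcript space by intersecting the
    mate-to-junction interval with the parent gene's exon blocks.
    """
    if pair.gene_set != frozenset((junction.gene5, junction.gene3)):
        raise ValueError("pair does not connect the junction's parent genes")
    donor = junction.sites.donor
    acceptor = junction.sites.acceptor
    m5 = pair.mate_in(junction.gene5)
    m3 = pair.mate_in(junction.gene3)

    # positional check: mate5 upstream of/abutting the donor, mate3
    # downstream of/abutting the acceptor, in transcription direction
    if donor[2] == "+":
        if m5.chrom != donor[0] or m5.end > donor[1]:
            return "inconsistent"
        part5 = _exonic_distance(index, junction.gene5, m5.chrom, m5.start, donor[1])
    else:
        if m5.chrom != donor[0] or m5.start < donor[1]:
            return "inconsistent"
        part5 = _exonic_distance(index, junction.gene5, m5.chrom, donor[1], m5.end)
    if acceptor[2] == "+":
        if m3.chrom != acceptor[0] or m3.start < acceptor[1]:
            return "inconsistent"
        part3 = _exonic_distance(index, junction.gene3, m3.chrom, acceptor[1], m3.end)
    else:
        if m3.chrom != acceptor[0] or m3.end > acceptor[1]:
            return "inconsistent"
        part3 = _exonic_distance(index, junction.gene3, m3.chrom, m3.start, acceptor[1])

    # orientation check: mates face inward along the chimeric transcript —
    # the upstream (gene5) mate reads the transcript sense so aligns on the
    # donor strand, the downstream (gene3) mate reads antisense so aligns
    # opposite the acceptor strand; which of R1/R2 plays which role is free
    # (non-directional protocols), but the geometry itself is not
    if not (m5.strand == donor[2] and m3.strand != acceptor[2]):
        return "inconsistent"

    if part5 + part3 > max_insert:
        return "inconsistent"
    return "consistent"


def attach_support(
    junction: AnnotatedJunction,
    discordant: list[DiscordantPair],
    index: AnnotationIndex,
    max_insert: int = DEFAULT_MAX_INSERT,
) -> tuple[JunctionSupport, list[str]]:
    """Fill the support counters of one junction.

    Every discordant pair connecting the junction's gene pair is judged
    once; a pair may support several isoform junctions of the same gene
    pair and is counted for each.  Returns the support plus the supporting
    read ids (split members and consistent pairs).
    """
    cluster: JunctionCluster = junction.cluster
    support = JunctionSupport(
        nb_split=cluster.nb_split, nb_staggered=cluster.nb_staggered
    )
    reads = set(cluster.read_ids)
    genes = frozenset((junction.gene5, junction.gene3))
    for pair in discordant:
        if pair.gene_set != genes:
            continue
        verdict = assess_consistency(junction, pair, index, max_insert)
        if verdict == "consistent":
            support.nb_consistent_pe += 1
            reads.add(pair.read_id)
        else:
            support.nb_inconsistent_pe += 1
    return support, sorted(reads)
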