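"""Split-read junction building: orientation, clustering, annotation.

A split read defines a putative splice junction between the 3' end of its
first segment and the 5' start of its second.  Because library protocols
may be unstranded, the transcribed orientation of the junction is inferred
from the genome: the intron flanks are read in both possible orientations
and the one matching an extended splice-site consensus (GT-AG, GC-AG,
ATATC-A. or GTATC-AT, ``.`` meaning any base) is kept.  Oriented reads
sharing the exact same donor/acceptor pair are clustered; distinct outer
mapping coordinates among cluster members ("staggered" reads, the
ladder-like pattern of genuine junctions) are counted separately from raw
split support.  Finally each junction side is assigned to the annotated
gene with the largest exonic overlap, and junctions connecting two
different genes become chimeric candidates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotation import AnnotationIndex, Site
from .ingest import SegmentMapping, SplitRead
from .seq import Genome

log = logging.getLogger(__name__)

#: donor/acceptor intron-flank consensus classes, in match priority.
MOTIF_CLASSES: tuple[tuple[str, str, str], ...] = (
    ("GT-AG", "GT", "AG"),
    ("GC-AG", "GC", "AG"),
    ("GTATC-AT", "GTATC", "AT"),
    ("ATATC-A.", "ATATC", "A."),
)


@dataclass(frozen=True)
class SpliceSitePair:
    """Oriented donor/acceptor sites of one junction.

    ``donor`` is the last exonic base of the 5' side, ``acceptor`` the
    first exonic base of the 3' side, both (chrom, pos, strand) with
    1-based positions.
    """

    donor: Site
    acceptor: Site
    motif_class: str

    @property
    def junction_id(self) -> str:
        d, a = self.donor, self.acceptor
        return f"{d[0]}_{d[1]}_{d[2]}:{a[0]}_{a[1]}_{a[2]}"


@dataclass(frozen=True)
class OrientedSplit:
    """A split read after orientation: segments relabelled donor/acceptor side."""

    read_id: str
    sites: SpliceSitePair
    donor_seg: SegmentMapping
    acceptor_seg: SegmentMapping

    @property
    def donor_outer(self) -> int:
        seg, (_, _, strand) = self.donor_seg, self.sites.donor
        return seg.start if strand == "+" else seg.end

    @property
    def acceptor_outer(self) -> int:
        seg, (_, _, strand) = self.acceptor_seg, self.sites.acceptor
        return seg.end if strand == "+" else seg.start


class OrientationRejection(Exception):
    """A split read whose junction orientation cannot be established."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


def _flanks_for(
    genome: Genome, donor_seg: SegmentMapping, donor_strand: str,
    acceptor_seg: SegmentMapping, acceptor_strand: str,
) -> tuple[Site, Site, str, str]:
    """Candidate sites plus intron flank sequences for one orientation.

    The donor flank is the first 5 intron bases 3' of the donor site and
    the acceptor flank the last 2 intron bases 5' of the acceptor site,
    both read in transcript sense.  Raises ValueError at chromosome edges.
    """
    if donor_strand == "+":
        donor: Site = (donor_seg.chrom, donor_seg.end, "+")
        hi = min(donor_seg.end + 5, genome.length(donor_seg.chrom))
        if hi < donor_seg.end + 2:
            raise ValueError("donor flank truncated at chromosome edge")
        dflank = genome.fetch(donor_seg.chrom, donor_seg.end + 1, hi)
    else:
        donor = (donor_seg.chrom, donor_seg.start, "-")
        lo = max(donor_seg.start - 5, 1)
        if lo > donor_seg.start - 2:
            raise ValueError("donor flank truncated at chromosome edge")
        dflank = genome.fetch_stranded(donor_seg.chrom, lo, donor_seg.start - 1, "-")
    if acceptor_strand == "+":
        acceptor: Site = (acceptor_seg.chrom, acceptor_seg.start, "+")
        aflank = genome.fetch(
            acceptor_seg.chrom, acceptor_seg.start - 2, acceptor_seg.start - 1
        )
    else:
        acceptor = (acceptor_seg.chrom, acceptor_seg.end, "-")
        aflank = genome.fetch_stranded(
            acceptor_seg.chrom, acceptor_seg.end + 1, acceptor_seg.end + 2, "-"
        )
    return donor, acceptor, dflank, aflank


def _motif_of(dflank: str, aflank: str) -> str | None:
    for name, dm, am in MOTIF_CLASSES:
        if len(dflank) < len(dm) or len(aflank) < 2:
            continue
        if not dflank.startswith(dm):
            continue
        if am == "A.":
            if aflank[0] == "A":
                return name
        elif aflank == am:
            return name
    return None


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def orient_split(
    read: SplitRead, genome: Genome, allowed: tuple[str, ...] = ("F", "R")
) -> OrientedSplit:
    """Infer the 5'→3' orientation of a split read from splice motifs.

    Orientation ``F`` takes the read as the transcript sense (segment A is
    the donor side); ``R`` takes its reverse complement (segment B becomes
    the donor side on flipped strands).  For stranded libraries the caller
    restricts ``allowed`` to the protocol-implied orientation; by default
    both are examined and the motif decides.  Raises
    :class:`OrientationRejection` with reason ``"edge"``, ``"no consensus"``
    or ``"ambiguous"``.
    """
    candidates: list[OrientedSplit] = []
    edge = False
    for orientation in allowed:
        if orientation == "F":
            args = (read.seg_a, read.seg_a.strand, read.seg_b, read.seg_b.strand)
            dseg, aseg = read.seg_a, read.seg_b
        else:
            args = (
                read.seg_b, _flip(read.seg_b.strand),
                read.seg_a, _flip(read.seg_a.strand),
            )
            dseg, aseg = read.seg_b, read.seg_a
        try:
            donor, acceptor, dflank, aflank = _flanks_for(genome, *args)
        except (ValueError, KeyError):
            edge = True
            continue
        motif = _motif_of(dflank, aflank)
        if motif is not None:
            candidates.append(
                OrientedSplit(read.read_id, SpliceSitePair(donor, acceptor, motif),
                              dseg, aseg)
            )
    if len(candidates) == 1:
        return candidates[0]
    if len(candidates) > 1:
        raise OrientationRejection("ambiguous")
    raise OrientationRejection("edge" if edge else "no consensus")


@dataclass
class JunctionCluster:
    """All oriented split reads sharing one exact (donor, acceptor) pair."""

    sites: SpliceSitePair
    members: list[OrientedSplit] = field(default_factory=list)

    @property
    def nb_split(self) -> int:
        return len(self.members)

    @property
    def nb_staggered(self) -> int:
        return len({(m.donor_outer, m.acceptor_outer) for m in self.members})

    @property
    def donor_external(self) -> int:
        """Most distal donor-side coordinate over members."""
        outers = [m.donor_outer for m in self.members]
        return min(outers) if self.sites.donor[2] == "+" else max(outers)

    @property
    def acceptor_external(self) -> int:
        outers = [m.acceptor_outer for m in self.members]
        return max(outers) if self.sites.acceptor[2] == "+" else min(outers)

    @property
    def read_ids(self) -> list[str]:
        return sorted({m.read_id for m in self.members})


def cluster_splits(oriented: list[OrientedSplit]) -> list[JunctionCluster]:
    """Group oriented split reads by exact junction coordinates."""
    by_sites: dict[tuple[Site, Site], JunctionCluster] = {}
    for read in oriented:
        key = (read.sites.donor, read.sites.acceptor)
        cluster = by_sites.get(key)
        if cluster is None:
            cluster = by_sites[key] = JunctionCluster(read.sites)
        cluster.members.append(read)
    return sorted(by_sites.values(), key=lambda c: c.sites.junction_id)


@dataclass
class AnnotatedJunction:
    """A junction cluster with per-side gene assignment."""

    cluster: JunctionCluster
    gene5: str | None = None
    gene3: str | None = None
    overlap5: int = 0
    overlap3: int = 0
    annotated5: bool = False
    annotated3: bool = False

    @property
    def sites(self) -> SpliceSitePair:
        return self.cluster.sites

    @property
    def is_candidate(self) -> bool:
        return (
            self.gene5 is not None
            and self.gene3 is not None
            and self.gene5 != self.gene3
        )


def annotate_junction(
    cluster: JunctionCluster, index: AnnotationIndex, stranded: bool = False
) -> AnnotatedJunction:
    """Assign each junction side to its highest-overlap gene.

    The side span runs from the junction position to the cluster's most
    distal member coordinate; it is intersected with collapsed exon blocks
    per gene, restricted to the site strand when ``stranded``.  Ties go to
    protein_coding biotype, then the smallest gene_id.
    """
    donor, acceptor = cluster.sites.donor, cluster.sites.acceptor
    dspan = tuple(sorted((donor[1], cluster.donor_external)))
    aspan = tuple(sorted((acceptor[1], cluster.acceptor_external)))
    ov5 = index.gene_overlap_bp(donor[0], *dspan, donor[2] if stranded else None)
    ov3 = index.gene_overlap_bp(acceptor[0], *aspan, acceptor[2] if stranded else None)
    gene5, bp5 = index.best_gene(ov5)
    gene3, bp3 = index.best_gene(ov3)
    return AnnotatedJunction(
        cluster,
        gene5=gene5,
        gene3=gene3,
        overlap5=bp5,
        overlap3=bp3,
        annotated5=index.is_annotated_donor(donor),
        annotated3=index.is_annotated_acceptor(acceptor),
    )


def select_chimeric(junctions: list[AnnotatedJunction]) -> list[AnnotatedJunction]:
    """Keep junctions whose two sides fall in two different genes."""
    kept = []
    for j in junctions:
        if j.is_candidate:
            kept.append(j)
        elif j.gene5 is None or j.gene3 is None:
            log.debug("junction %s dropped: unannotated side", j.sites.junction_id)
    return kept
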