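"""Splice-motif orientation, junction clustering and gene annotation."""

from __future__ import annotations

import numpy as np
import pytest

from chimkit.annotation import AnnotationIndex, Exon
from chimkit.ingest import SegmentMapping, SplitRead
from chimkit.junctions import (
    JunctionCluster,
    OrientationRejection,
    OrientedSplit,
    SpliceSitePair,
    annotate_junction,
    cluster_splits,
    orient_split,
    select_chimeric,
)
from chimkit.seq import Genome


def _genome(tmp_path, seq: str, chrom="chrT"):
    path = tmp_path / "g.fa"
    path.write_text(f">{chrom}\n{seq}\n")
    return Genome(str(path))


def _base_seq(length=400, seed=3):
    rng = np.random.default_rng(seed)
    # biased away from G so no accidental GT/GC donors appear in flanks
    return list("".join(rng.choice(list("ACT"), length)))


def _split(seg_a, seg_b, read_id="r1"):
    return SplitRead(read_id, 1, seg_a, seg_b, 1)


class TestOrientation:
    def test_forward_gt_ag(self, tmp_path):
        """exonA | GT...AG | exonB on the plus strand."""
        seq = _base_seq()
        seq[100:102] = "GT"  # intron start, 1-based 101-102
        seq[198:200] = "AG"  # intron end, 1-based 199-200
        genome = _genome(tmp_path, "".join(seq))
        read = _split(SegmentMapping("chrT", 71, 100, "+", 0, 30),
                      SegmentMapping("chrT", 201, 230, "+", 30, 60))
        oriented = orient_split(read, genome)
        assert oriented.sites.donor == ("chrT", 100, "+")
        assert oriented.sites.acceptor == ("chrT", 201, "+")
        assert oriented.sites.motif_class == "GT-AG"

    def test_reverse_complement_recovers_minus_strand(self, tmp_path):
        """The same construct on the minus strand: forward genome shows
        CT...AC and the read (sequenced antisense) is flipped to '-'."""
        seq = _base_seq()
        seq[100:102] = "CT"
        seq[198:200] = "AC"
        genome = _genome(tmp_path, "".join(seq))
        # read as sequenced matches the forward genome: segments on '+',
        # 5' read part at the genomically-left exon
        read = _split(SegmentMapping("chrT", 71, 100, "+", 0, 30),
                      SegmentMapping("chrT", 201, 230, "+", 30, 60))
        oriented = orient_split(read, genome)
        assert oriented.sites.donor == ("chrT", 201, "-")
        assert oriented.sites.acceptor == ("chrT", 100, "-")
        assert oriented.sites.motif_class == "GT-AG"

    def test_no_consensus_rejected(self, tmp_path):
        genome = _genome(tmp_path, "".join(_base_seq()))
        read = _split(SegmentMapping("chrT", 71, 100, "+", 0, 30),
                      SegmentMapping("chrT", 201, 230, "+", 30, 60))
        with pytest.raises(OrientationRejection, match="no consensus"):
            orient_split(read, genome)

    def test_extended_motifs(self, tmp_path):
        seq = _base_seq()
        seq[100:105] = "GTATC"
        seq[198:200] = "AT"
        genome = _genome(tmp_path, "".join(seq))
        read = _split(SegmentMapping("chrT", 71, 100, "+", 0, 30),
                      SegmentMapping("chrT", 201, 230, "+", 30, 60))
        assert orient_split(read, genome).sites.motif_class == "GTATC-AT"

    def test_ambiguous_rejected(self, tmp_path):
        """A construct matching ATATC-A. forward and GTATC-AT reversed."""
        seq = _base_seq()
        seq[100:105] = "ATATC"  # forward donor flank
        seq[195:200] = "GATAC"  # revcomp = GTATC, reverse donor flank
        genome = _genome(tmp_path, "".join(seq))
        read = _split(SegmentMapping("chrT", 71, 100, "+", 0, 30),
                      SegmentMapping("chrT", 201, 230, "+", 30, 60))
        with pytest.raises(OrientationRejection, match="ambiguous"):
            orient_split(read, genome)

    def test_chromosome_edge_rejected(self, tmp_path):
        genome = _genome(tmp_path, "".join(_base_seq(120)))
        # both candidate flanks run off a chromosome end
        read = _split(SegmentMapping("chrT", 91, 120, "+", 0, 30),
                      SegmentMapping("chrT", 1, 30, "+", 30, 60))
        with pytest.raises(OrientationRejection, match="edge"):
            orient_split(read, genome)

    def test_orientation_idempotent(self, tmp_path):
        """Re-orienting the segments of an oriented junction returns the
        same splice-site pair."""
        seq = _base_seq()
        seq[100:102] = "GT"
        seq[198:200] = "AG"
        genome = _genome(tmp_path, "".join(seq))
        read = _split(SegmentMapping("chrT", 71, 100, "+", 0, 30),
                      SegmentMapping("chrT", 201, 230, "+", 30, 60))
        first = orient_split(read, genome)
        again = orient_split(
            SplitRead("r1b", 1, first.donor_seg, first.acceptor_seg, 1), genome
        )
        assert again.sites == first.sites


def _oriented(donor_pos, acceptor_pos, donor_outer, acceptor_outer,
              read_id="r", chrom="chr1"):
    sites = SpliceSitePair((chrom, donor_pos, "+"), (chrom, acceptor_pos, "+"),
                           "GT-AG")
    dseg = SegmentMapping(chrom, donor_outer, donor_pos, "+")
    aseg = SegmentMapping(chrom, acceptor_pos, acceptor_outer, "+")
    return OrientedSplit(read_id, sites, dseg, aseg)


class TestClustering:
    def test_staggered_counting(self):
        reads = [_oriented(500, 900, 500 - 30 - i, 900 + 45 - i, f"r{i}")
                 for i in range(5)]
        (cluster,) = cluster_splits(reads)
        assert cluster.nb_split == 5
        assert cluster.nb_staggered == 5

    def test_duplicates_collapse_to_one_offset(self):
        reads = [_oriented(500, 900, 470, 945, f"r{i}") for i in range(5)]
        (cluster,) = cluster_splits(reads)
        assert cluster.nb_split == 5
        assert cluster.nb_staggered == 1

    def test_distinct_acceptors_make_distinct_clusters(self):
        reads = [_oriented(500, 900, 470, 945), _oriented(500, 950, 470, 995)]
        assert len(cluster_splits(reads)) == 2

    def test_external_boundaries_enclose_members(self):
        reads = [_oriented(500, 900, 500 - 30 - i, 900 + 45 - i, f"r{i}")
                 for i in range(5)]
        (cluster,) = cluster_splits(reads)
        assert cluster.donor_external == 466
        assert cluster.acceptor_external == 945
        assert all(cluster.donor_external <= m.donor_outer for m in cluster.members)
        assert all(cluster.acceptor_external >= m.acceptor_outer
                   for m in cluster.members)

    def test_partition_property(self):
        """Every oriented read lands in exactly one cluster."""
        rng = np.random.default_rng(9)
        reads = []
        for i in range(200):
            dpos = int(rng.choice([500, 600, 700]))
            apos = int(rng.choice([900, 1200]))
            reads.append(_oriented(dpos, apos, dpos - int(rng.integers(10, 40)),
                                   apos + int(rng.integers(10, 40)), f"r{i}"))
        clusters = cluster_splits(reads)
        assert sum(c.nb_split for c in clusters) == len(reads)
        seen = [m.read_id for c in clusters for m in c.members]
        assert sorted(seen) == sorted(r.read_id for r in reads)


@pytest.fixture()
def two_gene_index():
    exons = [
        Exon("chr1", 400, 520, "+", "geneX", "geneX.t1"),
        Exon("chr1", 460, 520, "+", "geneY", "geneY.t1"),  # overlapping gene
        Exon("chr1", 900, 1100, "+", "geneZ", "geneZ.t1"),
        Exon("chr1", 1200, 1300, "+", "geneZ", "geneZ.t1"),
    ]
    index = AnnotationIndex(exons)
    for g in ("geneX", "geneY", "geneZ"):
        index.set_biotype(g, "protein_coding")
    return index


class TestAnnotation:
    def test_higher_overlap_wins(self, two_gene_index):
        # donor side spans 481-520: geneX overlap 40, geneY overlap 40?
        # use 469-520: geneX 52, geneY 52 -> tie; use 441-520: X 80, Y 61
        reads = [_oriented(520, 900, 441, 940)]
        (cluster,) = cluster_splits(reads)
        annotated = annotate_junction(cluster, two_gene_index)
        assert annotated.gene5 == "geneX"
        assert annotated.overlap5 == 80
        assert annotated.gene3 == "geneZ"

    def test_annotated_flags_from_site_catalogue(self, two_gene_index):
        # geneZ has an internal boundary: donor at 1100, acceptor at 1200
        reads = [_oriented(520, 1200, 441, 1240)]
        (cluster,) = cluster_splits(reads)
        annotated = annotate_junction(cluster, two_gene_index)
        assert not annotated.annotated5  # 520 is a gene-terminal exon end
        assert annotated.annotated3  # 1200 is an annotated acceptor

    def test_same_gene_junction_is_not_candidate(self, two_gene_index):
        reads = [_oriented(1100, 1200, 1050, 1240)]
        (cluster,) = cluster_splits(reads)
        annotated = annotate_junction(cluster, two_gene_index)
        assert annotated.gene5 == annotated.gene3 == "geneZ"
        assert not annotated.is_candidate
        assert select_chimeric([annotated]) == []

    def test_unassigned_side_dropped(self, two_gene_index):
        reads = [_oriented(520, 5000, 441, 5040)]  # acceptor intergenic
        (cluster,) = cluster_splits(reads)
        annotated = annotate_junction(cluster, two_gene_index)
        assert annotated.gene3 is None
        assert select_chimeric([annotated]) == []

    def test_chimeric_candidate_selected(self, two_gene_index):
        reads = [_oriented(520, 900, 441, 940)]
        (cluster,) = cluster_splits(reads)
        annotated = annotate_junction(cluster, two_gene_index)
        assert select_chimeric([annotated]) == [annotated]
        assert annotated.sites.junction_id == "chr1_520_+:chr1_900_+"
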