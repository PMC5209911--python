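"""Support tiers, identity and homology filters, classification, reports."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chimkit.annotation import AnnotationIndex, Exon
from chimkit.filters import (
    CATEGORIES,
    ChimericJunction,
    FilterConfig,
    TierThresholds,
    classify,
    identity_filters,
    similarity_filter,
    support_filter,
    tier_of,
    write_outputs,
)
from chimkit.junctions import SpliceSitePair
from chimkit.pairs import JunctionSupport
from chimkit.seq import Genome


def _junction(nb_split=5, nb_pe=5, annotated5=True, annotated3=True,
              donor=("chr1", 1000, "+"), acceptor=("chr1", 50_000, "+"),
              gene5="geneA", gene3="geneB", nb_inconsistent=0):
    j = ChimericJunction(
        sites=SpliceSitePair(donor, acceptor, "GT-AG"),
        gene5=gene5,
        gene3=gene3,
        support=JunctionSupport(nb_split, nb_split, nb_pe, nb_inconsistent),
        annotated5=annotated5,
        annotated3=annotated3,
    )
    j.category = classify(j.sites)
    return j


class TestTiers:
    @pytest.mark.parametrize(
        "a5,a3,expected",
        [(True, True, "annotated"), (True, False, "novel"),
         (False, True, "novel"), (False, False, "novel")],
    )
    def test_both_sides_required_for_annotated_tier(self, a5, a3, expected):
        j = _junction(annotated5=a5, annotated3=a3)
        assert tier_of(j, FilterConfig()) == expected

    def test_either_side_mode(self):
        cfg = FilterConfig(annotated_requires_both=False)
        assert tier_of(_junction(annotated5=True, annotated3=False), cfg) == "annotated"


class TestSupportFilter:
    @pytest.mark.parametrize(
        "split,pe,annotated,ok",
        [
            (2, 1, True, True),   # total 3: minimal annotated-tier pass
            (1, 1, True, False),  # total 2 < 3
            (1, 2, True, True),
            (0, 3, True, False),  # split reads are compulsory
            (3, 0, True, False),  # consistent PE reads are compulsory
            (3, 3, False, True),  # total 6: minimal novel-tier pass
            (3, 2, False, False),
            (2, 4, False, False),
            (5, 1, False, False),
        ],
    )
    def test_tiered_thresholds(self, split, pe, annotated, ok):
        j = _junction(nb_split=split, nb_pe=pe,
                      annotated5=annotated, annotated3=annotated)
        assert (support_filter(j, FilterConfig()) == []) is ok

    def test_inconsistent_pairs_do_not_veto_by_default(self):
        j = _junction(nb_split=5, nb_pe=2, nb_inconsistent=50)
        assert support_filter(j, FilterConfig()) == []
        cfg = FilterConfig(max_inconsistent_fraction=0.5)
        assert "inconsistent_fraction" in support_filter(j, cfg)


@pytest.fixture()
def mito_index():
    exons = [
        Exon("chr1", 1000, 2000, "+", "geneA", "geneA.t1"),
        Exon("chr1", 50_000, 51_000, "+", "geneB", "geneB.t1"),
        Exon("chrM", 100, 900, "+", "geneM", "geneM.t1"),
        Exon("chr1", 80_000, 81_000, "+", "genePs", "genePs.t1"),
    ]
    idx = AnnotationIndex(exons)
    idx.set_biotype("geneA", "protein_coding")
    idx.set_biotype("geneB", "protein_coding")
    idx.set_biotype("geneM", "protein_coding")
    idx.set_biotype("genePs", "transcribed_unprocessed_pseudogene")
    return idx


class TestIdentityFilters:
    def test_mitochondrial_gene_fails(self, mito_index):
        j = _junction(gene3="geneM", acceptor=("chrM", 400, "+"))
        assert identity_filters(j, FilterConfig(), mito_index) == ["mitochondrial"]

    def test_pseudogene_fails(self, mito_index):
        j = _junction(gene5="genePs", donor=("chr1", 80_500, "+"))
        assert identity_filters(j, FilterConfig(), mito_index) == ["pseudogene"]
        cfg = FilterConfig(filter_pseudogenes=False)
        assert identity_filters(j, cfg, mito_index) == []

    def test_clean_pair_passes(self, mito_index):
        assert identity_filters(_junction(), FilterConfig(), mito_index) == []


def _similarity_fixture(tmp_path, block_a, block_b):
    """Two single-exon genes embedding the given blocks, with forced
    mismatches at the block boundaries."""
    rng = np.random.default_rng(17)
    ctx_a = "".join(rng.choice(list("ACGT"), 60))
    ctx_b = "".join(rng.choice(list("ACGT"), 60))
    exon_a = ctx_a + "AAAAAA" + block_a + "AAAAAA" + ctx_a[::-1]
    exon_b = ctx_b + "CCCCCC" + block_b + "CCCCCC" + ctx_b[::-1]
    seq = "N" * 50 + exon_a + "N" * 50 + exon_b + "N" * 50
    fasta = tmp_path / "sim.fa"
    fasta.write_text(">chrS\n" + seq + "\n")
    a0, a1 = 51, 50 + len(exon_a)
    b0, b1 = a1 + 51, a1 + 50 + len(exon_b)
    idx = AnnotationIndex([
        Exon("chrS", a0, a1, "+", "geneA", "geneA.t1"),
        Exon("chrS", b0, b1, "+", "geneB", "geneB.t1"),
    ])
    idx.set_biotype("geneA", "protein_coding")
    idx.set_biotype("geneB", "protein_coding")
    j = ChimericJunction(
        sites=SpliceSitePair(("chrS", a1, "+"), ("chrS", b0, "+"), "GT-AG"),
        gene5="geneA", gene3="geneB", support=JunctionSupport(9, 9, 9, 0),
    )
    return idx, Genome(str(fasta)), j


_FLIP = {"A": "C", "C": "A", "G": "T", "T": "G"}


class TestSimilarityFilter:
    def test_identical_50bp_block_fails(self, tmp_path):
        block = "".join(np.random.default_rng(1).choice(list("ACGT"), 50))
        idx, genome, j = _similarity_fixture(tmp_path, block, block)
        assert similarity_filter(j, FilterConfig(), genome, idx) == ["similarity"]

    def test_40bp_at_90pct_fails_boundary_inclusive(self, tmp_path):
        block = "".join(np.random.default_rng(2).choice(list("ACGT"), 40))
        mutated = list(block)
        for pos in (7, 15, 23, 31):
            mutated[pos] = _FLIP[mutated[pos]]
        idx, genome, j = _similarity_fixture(tmp_path, block, "".join(mutated))
        assert similarity_filter(j, FilterConfig(), genome, idx) == ["similarity"]

    def test_40bp_below_90pct_passes(self, tmp_path):
        block = "".join(np.random.default_rng(2).choice(list("ACGT"), 40))
        mutated = list(block)
        for pos in (5, 12, 19, 26, 33):  # 5 substitutions: 87.5% identity
            mutated[pos] = _FLIP[mutated[pos]]
        idx, genome, j = _similarity_fixture(tmp_path, block, "".join(mutated))
        assert similarity_filter(j, FilterConfig(), genome, idx) == []

    def test_short_perfect_block_passes(self, tmp_path):
        block = "".join(np.random.default_rng(3).choice(list("ACGT"), 25))
        idx, genome, j = _similarity_fixture(tmp_path, block, block)
        assert similarity_filter(j, FilterConfig(), genome, idx) == []

    def test_unrelated_genes_pass(self, tmp_path):
        rng = np.random.default_rng(4)
        a = "".join(rng.choice(list("ACGT"), 40))
        b = "".join(rng.choice(list("ACGT"), 40))
        idx, genome, j = _similarity_fixture(tmp_path, a, b)
        assert similarity_filter(j, FilterConfig(), genome, idx) == []


class TestClassify:
    @pytest.mark.parametrize(
        "donor,acceptor,expected",
        [
            (("chr1", 10_000, "+"), ("chr1", 60_000, "+"), "readthrough"),
            (("chr1", 10_000, "+"), ("chr1", 260_000, "+"), "intrachromosomal"),
            (("chr1", 10_000, "+"), ("chr1", 110_000, "+"), "intrachromosomal"),
            (("chr1", 109_999, "+"), ("chr1", 10_000, "+"), "inverted"),
            (("chr1", 260_000, "-"), ("chr1", 10_000, "-"), "intrachromosomal"),
            (("chr1", 60_000, "-"), ("chr1", 10_000, "-"), "readthrough"),
            (("chr1", 10_000, "-"), ("chr1", 60_000, "-"), "inverted"),
            (("chr1", 10_000, "+"), ("chr1", 60_000, "-"), "interstrand"),
            (("chr19", 10_000, "+"), ("chr7", 60_000, "-"), "interchromosomal"),
        ],
    )
    def test_categories(self, donor, acceptor, expected):
        assert classify(SpliceSitePair(donor, acceptor, "GT-AG")) == expected

    def test_exact_100kb_is_intrachromosomal(self):
        sites = SpliceSitePair(("chr1", 1, "+"), ("chr1", 100_001, "+"), "GT-AG")
        assert classify(sites) == "intrachromosomal"
        sites = SpliceSitePair(("chr1", 1, "+"), ("chr1", 100_000, "+"), "GT-AG")
        assert classify(sites) == "readthrough"

    def test_category_total_and_orientation_invariant(self):
        """Every junction gets exactly one category, decided by orientation
        rather than by which side was listed first."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            donor = (f"chr{rng.integers(1, 3)}", int(rng.integers(1, 3 * 10**5)),
                     "+-"[rng.integers(2)])
            acceptor = (f"chr{rng.integers(1, 3)}", int(rng.integers(1, 3 * 10**5)),
                        "+-"[rng.integers(2)])
            cat = classify(SpliceSitePair(donor, acceptor, "GT-AG"))
            assert cat in CATEGORIES


class TestMonotonicityAndOutputs:
    def _random_junctions(self, n=150, seed=23):
        rng = np.random.default_rng(seed)
        out = []
        for i in range(n):
            out.append(
                _junction(
                    nb_split=int(rng.integers(0, 8)),
                    nb_pe=int(rng.integers(0, 8)),
                    annotated5=bool(rng.integers(2)),
                    annotated3=bool(rng.integers(2)),
                    donor=("chr1", 1000 + i, "+"),
                )
            )
        return out

    def test_raising_thresholds_never_grows_kept_set(self):
        junctions = self._random_junctions()
        base = FilterConfig()
        kept_base = {
            j.junction_id for j in junctions if not support_filter(j, base)
        }
        rng = np.random.default_rng(31)
        for _ in range(20):
            bump = [int(rng.integers(0, 3)) for _ in range(6)]
            stricter = FilterConfig(
                annotated=TierThresholds(1 + bump[0], 1 + bump[1], 3 + bump[2]),
                novel=TierThresholds(3 + bump[3], 3 + bump[4], 6 + bump[5]),
            )
            kept = {
                j.junction_id for j in junctions if not support_filter(j, stricter)
            }
            assert kept <= kept_base

    def test_written_files_partition_candidates(self, tmp_path, mito_index):
        junctions = self._random_junctions(40)
        junctions.append(_junction(gene3="geneM", acceptor=("chrM", 400, "+"),
                                   nb_split=0, nb_pe=0))
        for j in junctions:
            j.filter_reasons = support_filter(j, FilterConfig())
            j.filter_reasons += identity_filters(j, FilterConfig(), mito_index)
        paths = write_outputs(junctions, tmp_path / "out")
        kept = pd.read_csv(paths["kept"], sep="\t")
        cand = pd.read_csv(paths["candidates"], sep="\t")
        disc = pd.read_csv(paths["discarded"], sep="\t")
        assert len(kept) + len(disc) == len(cand) == len(junctions)
        assert set(kept.junction_id).isdisjoint(disc.junction_id)
        assert set(kept.junction_id) | set(disc.junction_id) == set(cand.junction_id)
        # multiple failure reasons are comma-separated in one column
        multi = disc[disc.junction_id == junctions[-1].junction_id]
        reasons = multi.reason.iloc[0].split(",")
        assert "mitochondrial" in reasons and len(reasons) >= 2
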