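"""Junction filtering, five-way classification and TSV reporting.

Candidate junctions pass through a fixed rule set before being reported:

* **support tiers** — junctions whose donor and acceptor both coincide
  with annotated splice sites need at least 1 split read, 1 consistent
  paired-end read and 3 total (split + consistent PE) reads; junctions
  with any novel side need 3 / 3 / 6;
* **identity filters** — junctions touching the mitochondrial chromosome
  or a pseudogene parent are discarded as likely mapping artefacts;
* **exonic-similarity filter** — junctions whose parent genes share a
  local exonic alignment of at least 30 bp at 90% identity or more are
  discarded, since reads from such paralogous pairs misalign easily.

Surviving and discarded junctions are classified into five categories by
the geometry of donor and acceptor: *readthrough* and *intrachromosomal*
(same chromosome, strand and expected transcriptional order, separated by
less than resp. at least 100 kb), *inverted* (same chromosome and strand,
unexpected order), *interstrand* and *interchromosomal*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import Align

from .annotation import AnnotationIndex
from .junctions import AnnotatedJunction, SpliceSitePair
from .pairs import JunctionSupport
from .seq import Genome

SCHEMA_VERSION = "1"

CATEGORIES = (
    "readthrough",
    "intrachromosomal",
    "inverted",
    "interstrand",
    "interchromosomal",
)


@dataclass(frozen=True)
class TierThresholds:
    min_consistent_pe: int
    min_split: int
    min_total: int


@dataclass
class FilterConfig:
    """Tunable thresholds of the filtering stage (defaults as published)."""

    annotated: TierThresholds = field(
        default_factory=lambda: TierThresholds(1, 1, 3)
    )
    novel: TierThresholds = field(default_factory=lambda: TierThresholds(3, 3, 6))
    mito_chroms: frozenset[str] = frozenset({"chrM", "MT"})
    filter_pseudogenes: bool = True
    similarity_min_len: int = 30
    similarity_min_ident: float = 90.0
    readthrough_max_dist: int = 100_000
    #: treat a junction as annotated-tier only when both sides are annotated
    annotated_requires_both: bool = True
    #: optional veto on junctions whose discordant pairs are mostly
    #: inconsistent; None disables it (inconsistent pairs have benign
    #: explanations such as other isoforms, so they do not veto by default)
    max_inconsistent_fraction: float | None = None


@dataclass
class ChimericJunction:
    """A fully assembled chimeric junction ready for reporting."""

    sites: SpliceSitePair
    gene5: str
    gene3: str
    support: JunctionSupport
    annotated5: bool = False
    annotated3: bool = False
    category: str = ""
    read_ids: list[str] = field(default_factory=list)
    filter_reasons: list[str] = field(default_factory=list)

    @property
    def junction_id(self) -> str:
        return self.sites.junction_id

    @property
    def kept(self) -> bool:
        return not self.filter_reasons

    @property
    def length(self) -> int | None:
        """Genomic donor→acceptor distance; defined on one chromosome only."""
        if self.sites.donor[0] != self.sites.acceptor[0]:
            return None
        return abs(self.sites.acceptor[1] - self.sites.donor[1])


def tier_of(junction: ChimericJunction, cfg: FilterConfig) -> str:
    """``"annotated"`` or ``"novel"`` support tier of a junction."""
    if cfg.annotated_requires_both:
        annotated = junction.annotated5 and junction.annotated3
    else:
        annotated = junction.annotated5 or junction.annotated3
    return "annotated" if annotated else "novel"


def support_filter(junction: ChimericJunction, cfg: FilterConfig) -> list[str]:
    """Tiered minimum-support check; returns failure reasons (empty = pass)."""
    tier = tier_of(junction, cfg)
    thr = cfg.annotated if tier == "annotated" else cfg.novel
    s = junction.support
    reasons = []
    if s.nb_split < thr.min_split:
        reasons.append(f"split<{thr.min_split}")
    if s.nb_consistent_pe < thr.min_consistent_pe:
        reasons.append(f"consistent_pe<{thr.min_consistent_pe}")
    if s.nb_total < thr.min_total:
        reasons.append(f"total<{thr.min_total}")
    if cfg.max_inconsistent_fraction is not None:
        n_pe = s.nb_consistent_pe + s.nb_inconsistent_pe
        if n_pe and s.nb_inconsistent_pe / n_pe > cfg.max_inconsistent_fraction:
            reasons.append("inconsistent_fraction")
    return reasons


def identity_filters(
    junction: ChimericJunction, cfg: FilterConfig, index: AnnotationIndex
) -> list[str]:
    """Mitochondrial-chromosome and pseudogene-parent checks."""
    reasons = []
    genes = [index.genes[junction.gene5], index.genes[junction.gene3]]
    if any(g.chrom in cfg.mito_chroms for g in genes):
        reasons.append("mitochondrial")
    if cfg.filter_pseudogenes and any(g.is_pseudogene for g in genes):
        reasons.append("pseudogene")
    return reasons


def _make_aligner() -> Align.PairwiseAligner:
    # fixed local scoring so the filter is reproducible: match +1,
    # mismatch -2, gap open -3, gap extend -1
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    return aligner


def best_exonic_alignment(
    index: AnnotationIndex, genome: Genome, gene_a: str, gene_b: str
) -> tuple[int, float]:
    """Best local alignment between the exonic sequences of two genes.

    Each gene contributes its collapsed exon blocks, read in transcription
    sense; every block of one gene is aligned against every block of the
    other and the (aligned length, percent identity) of the best-scoring
    alignment over all pairs is returned — (0, 0.0) when nothing aligns.
    """
    aligner = _make_aligner()
    ga, gb = index.genes[gene_a], index.genes[gene_b]
    seqs_a = [
        genome.fetch_stranded(ga.chrom, s, e, ga.strand) for s, e in ga.blocks
    ]
    seqs_b = [
        genome.fetch_stranded(gb.chrom, s, e, gb.strand) for s, e in gb.blocks
    ]
    best = (0, 0.0)
    best_score = 0.0
    for sa in seqs_a:
        for sb in seqs_b:
            score = aligner.score(sa, sb)
            if score <= best_score or score <= 0:
                continue
            aln = next(iter(aligner.align(sa, sb)))
            counts = aln.counts()
            columns = counts.identities + counts.mismatches + counts.gaps
            if columns == 0:
                continue
            identity = counts.identities / columns * 100.0
            best_score = score
            best = (columns, identity)
    return best


def similarity_filter(
    junction: ChimericJunction,
    cfg: FilterConfig,
    genome: Genome,
    index: AnnotationIndex,
) -> list[str]:
    """Parent-gene exonic homology check.

    Fails when the best local alignment between the parents' exonic
    sequences spans at least ``similarity_min_len`` columns at
    ``similarity_min_ident`` percent identity or more (both inclusive).
    Missing sequence skips the check (the junction passes).
    """
    try:
        length, identity = best_exonic_alignment(
            index, genome, junction.gene5, junction.gene3
        )
    except (KeyError, ValueError):
        return []
    if length >= cfg.similarity_min_len and identity >= cfg.similarity_min_ident:
        return ["similarity"]
    return []


def classify(sites: SpliceSitePair, cfg: FilterConfig | None = None) -> str:
    """Five-way geometric category of a junction.

    Expected genomic order means the acceptor lies downstream of the donor
    in the transcription direction of the shared strand; the read-through
    vs intrachromosomal boundary is exclusive (a distance of exactly
    ``readthrough_max_dist`` is intrachromosomal).
    """
    max_dist = (cfg or FilterConfig()).readthrough_max_dist
    (dchrom, dpos, dstrand) = sites.donor
    (achrom, apos, astrand) = sites.acceptor
    if dchrom != achrom:
        return "interchromosomal"
    if dstrand != astrand:
        return "interstrand"
    expected = apos > dpos if dstrand == "+" else apos < dpos
    if not expected:
        return "inverted"
    return "readthrough" if abs(apos - dpos) < max_dist else "intrachromosomal"


def apply_filters(
    junctions: list[AnnotatedJunction],
    supports: list[tuple[JunctionSupport, list[str]]],
    cfg: FilterConfig,
    genome: Genome | None,
    index: AnnotationIndex,
) -> list[ChimericJunction]:
    """Assemble, classify and filter candidate junctions.

    All filters are evaluated (no short-circuit) so the discard report can
    list every applicable reason.  ``genome=None`` skips the similarity
    filter.
    """
    out = []
    for annotated, (support, read_ids) in zip(junctions, supports):
        j = ChimericJunction(
            sites=annotated.sites,
            gene5=annotated.gene5,
            gene3=annotated.gene3,
            support=support,
            annotated5=annotated.annotated5,
            annotated3=annotated.annotated3,
            read_ids=read_ids,
        )
        j.category = classify(j.sites, cfg)
        reasons = support_filter(j, cfg)
        reasons += identity_filters(j, cfg, index)
        if genome is not None:
            reasons += similarity_filter(j, cfg, genome, index)
        j.filter_reasons = reasons
        out.append(j)
    return out


_COLUMNS = [
    "junction_id",
    "category",
    "gene5",
    "gene3",
    "nb_split",
    "nb_staggered",
    "nb_consistent_pe",
    "nb_inconsistent_pe",
    "nb_total",
    "annotated5",
    "annotated3",
    "length",
    "schema_version",
    "supporting_reads",
]


def _row(j: ChimericJunction) -> dict:
    return {
        "junction_id": j.junction_id,
        "category": j.category,
        "gene5": j.gene5,
        "gene3": j.gene3,
        "nb_split": j.support.nb_split,
        "nb_staggered": j.support.nb_staggered,
        "nb_consistent_pe": j.support.nb_consistent_pe,
        "nb_inconsistent_pe": j.support.nb_inconsistent_pe,
        "nb_total": j.support.nb_total,
        "annotated5": int(j.annotated5),
        "annotated3": int(j.annotated3),
        "length": "" if j.length is None else j.length,
        "schema_version": SCHEMA_VERSION,
        "supporting_reads": ",".join(j.read_ids),
    }


def write_outputs(
    junctions: list[ChimericJunction], out_dir: str | Path
) -> dict[str, Path]:
    """Write kept / all-candidate / discarded junction TSVs.

    ``discarded.tsv`` carries a comma-separated ``reason`` column listing
    every filter the junction failed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "kept": out_dir / "chimeric_junctions.tsv",
        "candidates": out_dir / "chimeric_junctions_candidates.tsv",
        "discarded": out_dir / "chimeric_junctions_discarded.tsv",
    }
    all_rows = pd.DataFrame(
        [_row(j) for j in junctions], columns=_COLUMNS
    )
    kept_mask = [j.kept for j in junctions]
    all_rows.to_csv(paths["candidates"], sep="\t", index=False)
    all_rows[kept_mask].to_csv(paths["kept"], sep="\t", index=False)
    discarded = all_rows[[not k for k in kept_mask]].copy()
    discarded["reason"] = [
        ",".join(j.filter_reasons) for j in junctions if not j.kept
    ]
    discarded.to_csv(paths["discarded"], sep="\t", index=False)
    return paths
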