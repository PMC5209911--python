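"""End-to-end chimera detection from aligned reads.

Chains the evidence modules: alignment ingestion → splice-motif
orientation → junction clustering → gene annotation → discordant-pair
consistency → filtering and classification → TSV reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

from .annotation import AnnotationIndex, read_gtf
from .filters import ChimericJunction, FilterConfig, apply_filters, write_outputs
from .ingest import ingest_alignments
from .junctions import (
    OrientationRejection,
    annotate_junction,
    cluster_splits,
    orient_split,
    select_chimeric,
)
from .pairs import DEFAULT_MAX_INSERT, attach_support, find_discordant
from .seq import Genome

log = logging.getLogger(__name__)


@dataclass
class DetectionResult:
    junctions: list[ChimericJunction] = field(default_factory=list)
    rejections: dict[str, int] = field(default_factory=dict)

    @property
    def kept(self) -> list[ChimericJunction]:
        return [j for j in self.junctions if j.kept]


def detect(
    alignments: str | Path,
    genome_path: str | Path,
    gtf_path: str | Path,
    out_dir: str | Path | None = None,
    cfg: FilterConfig | None = None,
    max_hits: int = 10,
    max_insert: int = DEFAULT_MAX_INSERT,
    stranded: bool = False,
    index: AnnotationIndex | None = None,
) -> DetectionResult:
    """Run the full detection pipeline on a SAM/BAM file.

    ``stranded`` restricts junction-side gene assignment to the inferred
    strand (unstranded libraries search both).  When ``out_dir`` is given,
    kept / candidate / discarded junction TSVs are written there.
    """
    cfg = cfg or FilterConfig()
    index = index if index is not None else read_gtf(str(gtf_path))
    genome = Genome(str(genome_path))

    splits, mate_pairs, report = ingest_alignments(str(alignments), max_hits=max_hits)
    log.info(
        "ingested %d split reads, %d mate pairs (%d multimapped pairs dropped)",
        len(splits), len(mate_pairs), report.multimapped_pairs,
    )

    oriented = []
    rejections: dict[str, int] = {}
    for split in splits:
        try:
            oriented.append(orient_split(split, genome))
        except OrientationRejection as rej:
            rejections[rej.reason] = rejections.get(rej.reason, 0) + 1

    clusters = cluster_splits(oriented)
    annotated = [annotate_junction(c, index, stranded=stranded) for c in clusters]
    candidates = select_chimeric(annotated)
    discordant = find_discordant(mate_pairs, index, stranded=stranded)
    supports = [
        attach_support(j, discordant, index, max_insert) for j in candidates
    ]
    junctions = apply_filters(candidates, supports, cfg, genome, index)
    if out_dir is not None:
        write_outputs(junctions, out_dir)
    return DetectionResult(junctions=junctions, rejections=rejections)
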