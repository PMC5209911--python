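"""Chimeric-transcript and RNA-seq read simulation with truth records.

The simulator consumes a genome and an annotation and emits, per
requested chimera class, transcripts joining an annotated donor site of
one gene to an annotated acceptor site of another gene whose relative
geometry satisfies the class definition (read-through, intrachromosomal,
inverted, interstrand, interchromosomal).  Each chimeric sequence is the
5' parent transcript through the donor followed by the 3' parent
transcript from the acceptor.  A configurable fraction of annotation
transcripts is added as non-chimeric background, with the chimera parent
transcripts always included since an expressed chimera usually comes with
expressed parents.

Paired-end reads are drawn with a normal fragment-size model and uniform
base errors, under the non-directional convention (either mate may read
the transcript sense).  Because the mapping stage of real pipelines is out
of scope here, reads are also projected through their transcript's exon
structure into *truth alignments*: genomic SAM records with spliced
(``N``) CIGARs where the pieces are colinear and primary + supplementary
(``SA`` tag) records otherwise, so the detection pipeline can be exercised
end to end with no external mapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .annotation import AnnotationIndex, Exon, Site
from .filters import CATEGORIES, FilterConfig, classify
from .junctions import SpliceSitePair
from .seq import Genome, revcomp

log = logging.getLogger(__name__)

#: genomic block of a transcript: (chrom, start, end, strand), 1-based.
Block = tuple[str, int, int, str]


@dataclass
class SimConfig:
    """Simulation parameters; the seed fixes every sampling decision."""

    counts: dict[str, int] = field(
        default_factory=lambda: {c: 50 for c in CATEGORIES}
    )
    bg_fraction: float = 0.6
    read_len: int = 75
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    coverage: float = 10.0
    error_rate: float = 0.0
    seed: int = 0
    #: minimum exonic length of each chimera part, bp — keeps junctions far
    #: enough from transcript ends for both read types to span them
    min_part: int = 200
    #: biotypes eligible as background / parents (None = all)
    biotypes: tuple[str, ...] | None = None
    readthrough_max_dist: int = 100_000


@dataclass
class SimTranscript:
    """A transcript to sequence: exon blocks in transcript order + sequence."""

    tx_id: str
    blocks: list[Block]
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class SimulatedChimera:
    chimera_id: str
    label: str
    gene5: str
    gene3: str
    tx5: str
    tx3: str
    donor: Site
    acceptor: Site
    transcript: SimTranscript


@dataclass
class ReadOrigin:
    """Where one simulated fragment came from, in transcript coordinates."""

    read_id: str
    tx_id: str
    start: int  # 0-based in transcript
    frag_len: int
    mate1_sense: bool  # True: mate1 reads the transcript sense strand


class SimulationError(RuntimeError):
    pass


def _transcript_blocks(exons: list[Exon], strand: str) -> list[Block]:
    """Exons (genomic order) → blocks in transcript order."""
    ordered = exons if strand == "+" else list(reversed(exons))
    return [(e.chrom, e.start, e.end, strand) for e in ordered]


def _blocks_seq(blocks: list[Block], genome: Genome) -> str:
    return "".join(genome.fetch_stranded(c, s, e, st) for c, s, e, st in blocks)


def _five_prime_options(
    index: AnnotationIndex, gene_id: str, min_part: int
) -> list[tuple[Site, str, list[Block]]]:
    """(donor site, transcript, blocks through the donor) per eligible donor."""
    out = []
    strand = index.genes[gene_id].strand
    for tx_id, exons in sorted(index.transcripts_of(gene_id).items()):
        blocks = _transcript_blocks(exons, strand)
        cum = 0
        for k, (chrom, s, e, st) in enumerate(blocks[:-1]):
            cum += e - s + 1
            donor: Site = (chrom, e if st == "+" else s, st)
            if cum >= min_part:
                out.append((donor, tx_id, blocks[: k + 1]))
    return out


def _three_prime_options(
    index: AnnotationIndex, gene_id: str, min_part: int
) -> list[tuple[Site, str, list[Block]]]:
    """(acceptor site, transcript, blocks from the acceptor) per eligible acceptor."""
    out = []
    strand = index.genes[gene_id].strand
    for tx_id, exons in sorted(index.transcripts_of(gene_id).items()):
        blocks = _transcript_blocks(exons, strand)
        total = sum(e - s + 1 for _, s, e, _ in blocks)
        cum = 0
        for k, (chrom, s, e, st) in enumerate(blocks):
            if k > 0:
                acceptor: Site = (chrom, s if st == "+" else e, st)
                if total - cum >= min_part:
                    out.append((acceptor, tx_id, blocks[k:]))
            cum += e - s + 1
    return out


def _eligible_genes(index: AnnotationIndex, cfg: SimConfig) -> list[str]:
    genes = []
    for gene_id in sorted(index.genes):
        gene = index.genes[gene_id]
        if cfg.biotypes is not None and gene.biotype not in cfg.biotypes:
            continue
        genes.append(gene_id)
    return genes


def simulate_chimeras(
    index: AnnotationIndex, genome: Genome, cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SimulatedChimera]:
    """Sample chimeric transcripts satisfying each requested class geometry.

    Candidate (donor, acceptor) joins are enumerated over eligible gene
    pairs, partitioned by the five-way classification of their implied
    junction, and sampled without replacement, preferring distinct gene
    pairs within a class.  Raises :class:`SimulationError` when a class's
    candidate pool is smaller than the requested count.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    fcfg = FilterConfig(readthrough_max_dist=cfg.readthrough_max_dist)
    genes = _eligible_genes(index, cfg)
    fives = {g: _five_prime_options(index, g, cfg.min_part) for g in genes}
    threes = {g: _three_prime_options(index, g, cfg.min_part) for g in genes}

    pools: dict[str, list[tuple]] = {c: [] for c in CATEGORIES}
    for g5 in genes:
        for g3 in genes:
            if g5 == g3:
                continue
            for donor, tx5, blocks5 in fives[g5]:
                for acceptor, tx3, blocks3 in threes[g3]:
                    label = classify(
                        SpliceSitePair(donor, acceptor, "GT-AG"), fcfg
                    )
                    pools[label].append(
                        (g5, g3, donor, tx5, blocks5, acceptor, tx3, blocks3)
                    )

    chimeras: list[SimulatedChimera] = []
    used_junctions: set[tuple[Site, Site]] = set()
    n = 0
    for label in CATEGORIES:
        want = cfg.counts.get(label, 0)
        pool = pools[label]
        if want == 0:
            continue
        if len(pool) < want:
            raise SimulationError(
                f"class {label}: pool of {len(pool)} candidate junctions "
                f"smaller than requested count {want}"
            )
        order = rng.permutation(len(pool))
        picked: list[tuple] = []
        used_pairs: set[tuple[str, str]] = set()
        # first pass prefers distinct gene pairs; second pass fills up with
        # distinct junctions only
        for strict in (True, False):
            for i in order:
                if len(picked) == want:
                    break
                cand = pool[i]
                g5, g3, donor, _, _, acceptor, _, _ = cand
                if (donor, acceptor) in used_junctions:
                    continue
                if strict and (g5, g3) in used_pairs:
                    continue
                picked.append(cand)
                used_pairs.add((g5, g3))
                used_junctions.add((donor, acceptor))
        if len(picked) < want:
            raise SimulationError(
                f"class {label}: only {len(picked)} distinct junctions available"
            )
        for g5, g3, donor, tx5, blocks5, acceptor, tx3, blocks3 in picked:
            n += 1
            blocks = list(blocks5) + list(blocks3)
            tx = SimTranscript(f"chimera_{n:04d}", blocks, _blocks_seq(blocks, genome))
            chimeras.append(
                SimulatedChimera(
                    tx.tx_id, label, g5, g3, tx5, tx3, donor, acceptor, tx
                )
            )
    return chimeras


def sample_background(
    index: AnnotationIndex, genome: Genome, cfg: SimConfig,
    parents: list[tuple[str, str]],
    rng: np.random.Generator | None = None,
) -> list[SimTranscript]:
    """Uniform sample of annotation transcripts plus forced chimera parents.

    ``parents`` lists (gene_id, transcript_id) of the chimeras' parent
    transcripts; they are united with the sample (no duplicates).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    all_tx: list[tuple[str, str]] = []
    for gene_id in _eligible_genes(index, cfg):
        for tx_id in sorted(index.transcripts_of(gene_id)):
            all_tx.append((gene_id, tx_id))
    k = round(cfg.bg_fraction * len(all_tx))
    chosen_idx = rng.choice(len(all_tx), size=k, replace=False) if k else []
    chosen = {all_tx[i] for i in chosen_idx}
    chosen.update((g, t) for g, t in parents)
    out = []
    for gene_id, tx_id in sorted(chosen):
        exons = index.transcripts_of(gene_id)[tx_id]
        blocks = _transcript_blocks(exons, index.genes[gene_id].strand)
        out.append(SimTranscript(tx_id, blocks, _blocks_seq(blocks, genome)))
    return out


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        options = bases[bases != arr[i]]
        arr[i] = options[rng.integers(len(options))]
    return arr.tobytes().decode()


def generate_reads(
    transcripts: list[SimTranscript], cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[tuple[str, str, str]], list[ReadOrigin]]:
    """Draw paired-end reads from transcripts.

    Per transcript, ``round(coverage × length / (2 × read_len))`` fragments
    are drawn with normal(insert_mean, insert_sd) lengths clamped to
    [read_len, transcript length]; the mates are the fragment ends, one
    sense and one reverse-complemented, with the sense mate assigned to
    R1 or R2 at random (non-directional protocol).  Returns
    ``(reads, origins)`` where each read entry is (read_id, mate1_seq,
    mate2_seq).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    reads: list[tuple[str, str, str]] = []
    origins: list[ReadOrigin] = []
    for tx in transcripts:
        if tx.length < cfg.read_len:
            log.warning("transcript %s shorter than read length; skipped", tx.tx_id)
            continue
        n = round(cfg.coverage * tx.length / (2 * cfg.read_len))
        for i in range(n):
            flen = int(np.clip(round(rng.normal(cfg.insert_mean, cfg.insert_sd)),
                               cfg.read_len, tx.length))
            start = int(rng.integers(0, tx.length - flen + 1))
            frag = tx.seq[start : start + flen]
            sense = frag[: cfg.read_len]
            anti = revcomp(frag[-cfg.read_len :])
            mate1_sense = bool(rng.random() < 0.5)
            m1, m2 = (sense, anti) if mate1_sense else (anti, sense)
            read_id = f"sim_{tx.tx_id}_{i:05d}"
            reads.append(
                (
                    read_id,
                    _apply_errors(m1, cfg.error_rate, rng),
                    _apply_errors(m2, cfg.error_rate, rng),
                )
            )
            origins.append(ReadOrigin(read_id, tx.tx_id, start, flen, mate1_sense))
    return reads, origins


def write_fastq(
    reads: list[tuple[str, str, str]], path1: str | Path, path2: str | Path
) -> None:
    qual = None
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for read_id, m1, m2 in reads:
            qual = "I" * len(m1)
            f1.write(f"@{read_id}/1\n{m1}\n+\n{qual}\n")
            f2.write(f"@{read_id}/2\n{m2}\n+\n{'I' * len(m2)}\n")


# ---------------------------------------------------------------------------
# truth-alignment projection


@dataclass
class _Piece:
    """One colinear genomic piece of a projected mate."""

    chrom: str
    strand: str  # alignment strand on the genome
    intervals: list[tuple[int, int]]  # genomic order, 1-based inclusive
    read_start: int  # read-local, original orientation, 0-based half-open
    read_end: int

    @property
    def ref_start(self) -> int:
        return self.intervals[0][0]

    def cigar(self, read_len: int) -> list[tuple[int, int]]:
        """CIGAR tuples in genomic order, soft clips included."""
        if self.strand == "+":
            lead, trail = self.read_start, read_len - self.read_end
        else:
            lead, trail = read_len - self.read_end, self.read_start
        ops: list[tuple[int, int]] = []
        if lead:
            ops.append((4, lead))
        prev_end = None
        for s, e in self.intervals:
            if prev_end is not None:
                gap = s - prev_end - 1
                if gap > 0:
                    ops.append((3, gap))
            if ops and ops[-1][0] == 0:
                ops[-1] = (0, ops[-1][1] + e - s + 1)
            else:
                ops.append((0, e - s + 1))
            prev_end = e
        if trail:
            ops.append((4, trail))
        return ops

    def cigar_string(self, read_len: int) -> str:
        names = "MIDNSHP=X"
        return "".join(f"{ln}{names[op]}" for op, ln in self.cigar(read_len))


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def project_mate(
    blocks: list[Block], t_start: int, t_end: int, sense: str
) -> list[_Piece]:
    """Project a mate covering transcript [t_start, t_end) onto the genome.

    ``sense`` is the mate's strand relative to the transcript.  Returns
    pieces in read order; consecutive projected intervals are joined with
    an intron (``N``) gap when they are colinear on one chromosome and
    strand, and start a new piece otherwise.
    """
    raw: list[tuple[str, str, int, int, int, int]] = []
    offset = 0
    for chrom, bs, be, bstrand in blocks:
        blen = be - bs + 1
        lo, hi = max(t_start, offset), min(t_end, offset + blen)
        if lo < hi:
            if bstrand == "+":
                gs, ge = bs + (lo - offset), bs + (hi - 1 - offset)
            else:
                gs, ge = be - (hi - 1 - offset), be - (lo - offset)
            if sense == "+":
                rs, re_ = lo - t_start, hi - t_start
            else:
                rs, re_ = t_end - hi, t_end - lo
            strand = bstrand if sense == "+" else _flip(bstrand)
            raw.append((chrom, strand, gs, ge, rs, re_))
        offset += blen
    if sense == "-":
        raw.reverse()  # read order

    pieces: list[_Piece] = []
    for chrom, strand, gs, ge, rs, re_ in raw:
        if pieces:
            p = pieces[-1]
            if p.chrom == chrom and p.strand == strand:
                if strand == "+" and gs > p.intervals[-1][1]:
                    if gs == p.intervals[-1][1] + 1:
                        p.intervals[-1] = (p.intervals[-1][0], ge)
                    else:
                        p.intervals.append((gs, ge))
                    p.read_end = re_
                    continue
                if strand == "-" and ge < p.intervals[0][0]:
                    if ge == p.intervals[0][0] - 1:
                        p.intervals[0] = (gs, p.intervals[0][1])
                    else:
                        p.intervals.insert(0, (gs, ge))
                    p.read_end = re_
                    continue
        pieces.append(_Piece(chrom, strand, [(gs, ge)], rs, re_))
    return pieces


def generate_truth_alignments(
    transcripts: dict[str, SimTranscript],
    reads: list[tuple[str, str, str]],
    origins: list[ReadOrigin],
    chrom_lengths: dict[str, int],
    out_sam: str | Path,
) -> int:
    """Write truth alignments for simulated reads as SAM; returns the
    number of read pairs written.

    Reads whose projection needs more than two pieces (e.g. crossing two
    incompatible junctions) are skipped with a warning, as are their mates.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    }
    n_written = 0
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as out:
        refs = {c: i for i, c in enumerate(chrom_lengths)}
        for (read_id, m1_seq, m2_seq), origin in zip(reads, origins):
            tx = transcripts[origin.tx_id]
            rl = len(m1_seq)
            sense_piece = project_mate(
                tx.blocks, origin.start, origin.start + rl, "+"
            )
            anti_piece = project_mate(
                tx.blocks, origin.start + origin.frag_len - rl,
                origin.start + origin.frag_len, "-",
            )
            if origin.mate1_sense:
                mates = [(1, m1_seq, sense_piece), (2, m2_seq, anti_piece)]
            else:
                mates = [(1, m1_seq, anti_piece), (2, m2_seq, sense_piece)]
            if any(len(p) > 2 for _, _, p in mates):
                log.warning("read %s spans >2 pieces; skipped", read_id)
                continue
            records = []
            primaries = {}
            for mate_index, seq, pieces in mates:
                primaries[mate_index] = pieces[0]
                for k, piece in enumerate(pieces):
                    rec = pysam.AlignedSegment()
                    rec.query_name = read_id
                    flag = 0x1 | 0x2  # paired, proper
                    flag |= 0x40 if mate_index == 1 else 0x80
                    if piece.strand == "-":
                        flag |= 0x10
                    if k > 0:
                        flag |= 0x800
                    rec.flag = flag
                    rec.reference_id = refs[piece.chrom]
                    rec.reference_start = piece.ref_start - 1
                    rec.mapping_quality = 60
                    rec.cigartuples = piece.cigar(rl)
                    rec.query_sequence = seq if piece.strand == "+" else revcomp(seq)
                    rec.query_qualities = pysam.qualitystring_to_array("I" * rl)
                    tags = [("NH", 1)]
                    if len(pieces) == 2:
                        other = pieces[1 - k]
                        tags.append(
                            (
                                "SA",
                                f"{other.chrom},{other.ref_start},{other.strand},"
                                f"{other.cigar_string(rl)},60,0;",
                            )
                        )
                    rec.set_tags(tags)
                    records.append((rec, mate_index))
            # mate cross-references from the primary pieces
            for rec, mate_index in records:
                other = primaries[2 if mate_index == 1 else 1]
                rec.next_reference_id = refs[other.chrom]
                rec.next_reference_start = other.ref_start - 1
                if other.strand == "-":
                    rec.flag |= 0x20
                out.write(rec)
            n_written += 1
    return n_written


# ---------------------------------------------------------------------------
# driver


def run_simulation(
    genome_path: str | Path,
    gtf_path: str | Path,
    cfg: SimConfig,
    out_dir: str | Path,
    index: AnnotationIndex | None = None,
) -> dict[str, Path]:
    """Full simulation: chimeras, background, reads, truth files.

    Writes ``transcripts.fa``, ``truth_junctions.tsv``, ``reads_1.fastq``,
    ``reads_2.fastq``, ``read_origins.tsv`` and ``truth_alignments.sam``
    into ``out_dir`` and returns the paths.  All randomness derives from
    ``cfg.seed``, so identical configurations give byte-identical outputs.
    """
    from .annotation import read_gtf  # local import to avoid cycle at import time

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index = index if index is not None else read_gtf(str(gtf_path))
    genome = Genome(str(genome_path))
    rng = np.random.default_rng(cfg.seed)

    chimeras = simulate_chimeras(index, genome, cfg, rng)
    parents = [(c.gene5, c.tx5) for c in chimeras] + [
        (c.gene3, c.tx3) for c in chimeras
    ]
    background = sample_background(index, genome, cfg, parents, rng)
    transcripts = [c.transcript for c in chimeras] + background
    by_id = {t.tx_id: t for t in transcripts}

    paths = {
        "transcripts": out_dir / "transcripts.fa",
        "truth": out_dir / "truth_junctions.tsv",
        "fastq1": out_dir / "reads_1.fastq",
        "fastq2": out_dir / "reads_2.fastq",
        "origins": out_dir / "read_origins.tsv",
        "sam": out_dir / "truth_alignments.sam",
    }
    with open(paths["transcripts"], "w") as fh:
        for tx in transcripts:
            fh.write(f">{tx.tx_id}\n{tx.seq}\n")
    with open(paths["truth"], "w") as fh:
        fh.write(
            "chimera_id\tclass\tgene5\tgene3\ttx5\ttx3\t"
            "donor_chrom\tdonor_pos\tdonor_strand\t"
            "acceptor_chrom\tacceptor_pos\tacceptor_strand\n"
        )
        for c in chimeras:
            fh.write(
                f"{c.chimera_id}\t{c.label}\t{c.gene5}\t{c.gene3}\t{c.tx5}\t{c.tx3}\t"
                f"{c.donor[0]}\t{c.donor[1]}\t{c.donor[2]}\t"
                f"{c.acceptor[0]}\t{c.acceptor[1]}\t{c.acceptor[2]}\n"
            )

    reads, origins = generate_reads(transcripts, cfg, rng)
    write_fastq(reads, paths["fastq1"], paths["fastq2"])
    with open(paths["origins"], "w") as fh:
        fh.write("read_id\ttx_id\tstart\tfrag_len\tmate1_sense\n")
        for o in origins:
            fh.write(
                f"{o.read_id}\t{o.tx_id}\t{o.start}\t{o.frag_len}\t"
                f"{int(o.mate1_sense)}\n"
            )
    chrom_lengths = {
        c: genome.length(c)
        for c in sorted({b[0] for t in transcripts for b in t.blocks})
    }
    generate_truth_alignments(by_id, reads, origins, chrom_lengths, paths["sam"])
    return paths
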