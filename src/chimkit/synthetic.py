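"""Seed-deterministic synthetic genome + annotation construction.

Builds a small multi-chromosome genome of random sequence with a
configurable number of multi-exon genes laid out on both strands, and the
matching GTF.  Canonical splice motifs (GT..AG in transcription sense) are
planted at every annotated intron boundary so that split reads over
annotated junctions — and over chimeric junctions joining annotated donor
and acceptor sites — can be oriented from the genome alone.  The builder
exists so simulations and tests run from nothing but a seed; it makes no
attempt to mimic base composition, repeats or paralogy of a real genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_BASES = np.array(list("ACGT"))


@dataclass
class SyntheticConfig:
    n_chroms: int = 3
    genes_per_chrom: int = 25
    gene_spacing: int = 10_000
    exon_len: tuple[int, int] = (120, 300)
    intron_len: tuple[int, int] = (150, 500)
    exons_per_gene: tuple[int, int] = (3, 6)
    #: fraction of genes carrying a second, exon-skipping transcript
    two_transcript_fraction: float = 0.5
    biotype: str = "protein_coding"
    include_mito: bool = False
    include_pseudogene: bool = False


@dataclass
class SynGene:
    gene_id: str
    chrom: str
    strand: str
    biotype: str
    exons: list[tuple[int, int]]  # 1-based inclusive, genomic order
    transcripts: dict[str, list[int]] = field(default_factory=dict)  # exon indices


@dataclass
class SyntheticGenomeAnnotation:
    chrom_seqs: dict[str, np.ndarray]  # arrays of single-character strings
    genes: list[SynGene]

    def sequence(self, chrom: str) -> str:
        return "".join(self.chrom_seqs[chrom])

    def write(self, out_dir: str | Path) -> tuple[Path, Path]:
        """Write genome FASTA and annotation GTF; returns their paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        fasta = out_dir / "genome.fa"
        gtf = out_dir / "annotation.gtf"
        with open(fasta, "w") as fh:
            for chrom, arr in self.chrom_seqs.items():
                fh.write(f">{chrom}\n")
                s = "".join(arr)
                for i in range(0, len(s), 80):
                    fh.write(s[i : i + 80] + "\n")
        with open(gtf, "w") as fh:
            for gene in self.genes:
                for tx_id, exon_idx in gene.transcripts.items():
                    for k in exon_idx:
                        start, end = gene.exons[k]
                        attrs = (
                            f'gene_id "{gene.gene_id}"; transcript_id "{tx_id}"; '
                            f'gene_type "{gene.biotype}"; gene_name "{gene.gene_id}";'
                        )
                        fh.write(
                            f"{gene.chrom}\tsynthetic\texon\t{start}\t{end}\t.\t"
                            f"{gene.strand}\t.\t{attrs}\n"
                        )
        return fasta, gtf


def _plant_motifs(seq: np.ndarray, gene: SynGene) -> None:
    """Write splice consensus dinucleotides into every intron of a gene.

    In transcription sense every intron must start with GT and end with AG;
    on the minus strand that is AC / CT on the forward genome.
    """
    for (s1, e1), (s2, _) in zip(gene.exons, gene.exons[1:]):
        # intron forward-genomic interval is [e1+1, s2-1]; 0-based array
        if gene.strand == "+":
            seq[e1] = "G"
            seq[e1 + 1] = "T"
            seq[s2 - 3] = "A"
            seq[s2 - 2] = "G"
        else:
            seq[e1] = "C"
            seq[e1 + 1] = "T"
            seq[s2 - 3] = "A"
            seq[s2 - 2] = "C"


def build_synthetic(
    cfg: SyntheticConfig, seed: int
) -> SyntheticGenomeAnnotation:
    """Construct the synthetic genome and gene models for one seed."""
    rng = np.random.default_rng(seed)
    chrom_len = cfg.genes_per_chrom * cfg.gene_spacing + 5_000
    chrom_seqs: dict[str, np.ndarray] = {}
    genes: list[SynGene] = []
    strand_cycle = "++--"  # adjacent same-strand pairs on both strands
    for ci in range(cfg.n_chroms):
        chrom = f"chr{ci + 1}"
        seq = rng.choice(_BASES, size=chrom_len)
        chrom_seqs[chrom] = seq
        for gi in range(cfg.genes_per_chrom):
            gene_id = f"G{ci + 1:02d}{gi + 1:03d}"
            strand = strand_cycle[gi % 4]
            n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            pos = gi * cfg.gene_spacing + int(rng.integers(500, 1500))
            exons = []
            for _ in range(n_exons):
                elen = int(rng.integers(*cfg.exon_len))
                exons.append((pos + 1, pos + elen))  # to 1-based inclusive
                pos += elen + int(rng.integers(*cfg.intron_len))
            gene = SynGene(gene_id, chrom, strand, cfg.biotype, exons)
            gene.transcripts[f"{gene_id}.t1"] = list(range(n_exons))
            if n_exons >= 4 and rng.random() < cfg.two_transcript_fraction:
                skip = int(rng.integers(1, n_exons - 1))
                gene.transcripts[f"{gene_id}.t2"] = [
                    k for k in range(n_exons) if k != skip
                ]
            _plant_motifs(seq, gene)
            genes.append(gene)

    if cfg.include_pseudogene:
        genes[-1].biotype = "processed_pseudogene"
    if cfg.include_mito:
        chrom_seqs["chrM"] = rng.choice(_BASES, size=4000)
        mito = SynGene("GMT001", "chrM", "+", cfg.biotype,
                       [(201, 500), (801, 1100), (1401, 1700)])
        mito.transcripts["GMT001.t1"] = [0, 1, 2]
        _plant_motifs(chrom_seqs["chrM"], mito)
        genes.append(mito)
    return SyntheticGenomeAnnotation(chrom_seqs, genes)
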