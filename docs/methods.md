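# Methods

## Scope and coordinate conventions

chimkit starts from *already aligned* paired-end RNA-seq: it does not map
reads. The domain model uses 1-based inclusive genomic coordinates
throughout (GTF-native); 0-based half-open BAM coordinates are converted
once, at alignment ingestion, and never leak further. A junction is an
ordered pair of stranded sites: the **donor** (last exonic base of the 5'
side) and the **acceptor** (first exonic base of the 3' side), after
5'→3' orientation.

## Annotation model

Only `exon` GTF lines are used. A gene's exon set is the union over its
transcripts, with duplicate (start, end) intervals collapsed for overlap
accounting, because junctions are compared to exons, not to transcripts.
The splice-site catalogue is positional and stranded: every transcript
intron contributes one donor and one acceptor site; single-exon
transcripts have no internal boundaries and contribute none. A junction
side is "annotated" iff its (chrom, position, strand) is in the
corresponding catalogue — sides are tested independently, not as pairs.
Exon interval queries go through `intervaltree`; unit and acceptance tests
compare them against a linear-scan oracle.

## Alignment ingestion

Two split-read shapes are recognised, both from primary records only:

* a CIGAR with exactly one `N` gap (one chromosome/strand) — kept so that
  intra-chromosomal chimeras present in a pre-made BAM are detectable;
* a primary plus exactly one `SA` supplementary (any chromosomes, strands
  or order). Supplementary records themselves never seed evidence, so a
  read yields at most one split per mapping position.

Reads with two or more `N` gaps are excluded from the split stream (they
remain usable as mates) and counted in a skip report. Pairs whose `NH`
exceeds `max_hits` (default 10) on either mate are treated as unmapped and
excluded from both streams; a missing `NH` is read as 1, which is
conservative and matches deduplicated BAMs. An optional
`max_mismatch_rate` re-applies a mismatch cap from the `NM` tag; it is off
by default because mappers enforce their own cap at alignment time.
Segment erosion/trimming is a mapper behaviour and is not re-implemented;
ingestion merely tolerates a couple of unaligned bases at read ends.

## Junction building

**Orientation.** For each split read both readings are examined: the read
as transcript sense, and its reverse complement. A reading is accepted
when the intron flanks match one of the four consensus classes (donor
flank immediately 3' of the donor, acceptor flank immediately 5' of the
acceptor, on the inferred strands): GT‑AG, GC‑AG, GTATC‑AT, ATATC‑A.
(`.` = any base; the two 5-mer classes cover the minor-spliceosome-like
extended motifs). If no reading matches, the read is rejected as
`no consensus`; if both match, as `ambiguous` — rejecting ties is the
conservative choice since orientation is a guarantee the caller makes.
Within one reading the classes are tested in the listed priority order.
For stranded libraries the caller can restrict the allowed readings and
use the motif purely as validation. Flanks that run off a chromosome end
reject the read with reason `edge`.

**Clustering.** One cluster per exact (donor, acceptor) pair.
`nb_split` is the member count; `nb_staggered` counts distinct
(donor-side outer coordinate, acceptor-side outer coordinate) *pairs*,
a two-dimensional — hence stricter — reading of the ladder pattern.
External boundaries are the most distal member coordinates per side.

**Gene assignment.** Each side's span (junction position to external
boundary) is intersected with collapsed exon blocks per gene; the gene
with the largest summed exonic overlap wins. Ties are broken
deterministically: protein_coding biotype first, then smallest gene_id.
Unstranded libraries search both strands; stranded ones the inferred
strand. Junctions whose sides land in two different genes are the
chimeric candidates; junctions with an unassigned side are dropped from
the candidate set (and logged) rather than carried forward.

## Discordant-pair consistency

Mates are assigned to genes with the same overlap rule (exonic overlap
only, summed over all aligned blocks, so a mate spanning an annotated
intron accumulates support from both exons). A pair whose mates land in
two different genes is discordant. For a junction between gene5 and
gene3, a pair connecting exactly that gene pair is **consistent** when:

* the gene5 mate lies upstream of (or abuts) the donor and the gene3 mate
  downstream of (or abuts) the acceptor, in each side's transcription
  direction;
* the mates face inward along the implied chimeric transcript — the
  gene5 mate aligns on the donor strand, the gene3 mate opposite the
  acceptor strand (which of R1/R2 plays which role is free, matching
  non-directional protocols);
* the implied insert does not exceed `max_insert` (default 1000 bp). The
  insert is measured in transcript space by intersecting each
  mate-to-junction interval with the parent gene's collapsed exon blocks,
  so intervening introns do not inflate it.

Inconsistent pairs are counted but do not veto a junction by default —
they can come from a different isoform of the same gene pair or from
misalignment. An optional `max_inconsistent_fraction` veto exists for
stringent runs. A pair may support several isoform junctions of one gene
pair and is counted for each.

## Filtering and classification

Defaults (all tunable in `FilterConfig`):

| parameter | default | meaning |
|---|---|---|
| annotated tier | ≥1 split, ≥1 consistent PE, ≥3 total | both splice sites annotated |
| novel tier | ≥3 split, ≥3 consistent PE, ≥6 total | any novel side |
| `mito_chroms` | {chrM, MT} | mitochondrial parent → discard |
| pseudogene rule | biotype contains "pseudogene" | pseudogene parent → discard |
| `similarity_min_len` / `similarity_min_ident` | 30 bp / 90% | exonic homology → discard |
| `readthrough_max_dist` | 100 000 bp | readthrough/intrachromosomal boundary |

"Total" is split + consistent PE, so both evidence types are compulsory —
misaligned reads rarely produce both. The annotated tier requires *both*
sides annotated (the strict reading; switchable via
`annotated_requires_both`). All filters are evaluated without
short-circuiting so the discard file can list every applicable reason.

The homology filter aligns every collapsed exon of one parent against
every exon of the other with a fixed local scheme (match +1, mismatch −2,
gap open −3, extend −1) via Biopython's `PairwiseAligner`, and tests the
best-scoring alignment: discard iff its column count ≥ 30 and identity
(matches / columns) ≥ 90%, both inclusive. Testing the score-optimal
alignment (rather than "any alignment") is a deliberate simplification;
it matches the thresholds exactly on clean shared blocks and is
reproducible, but a sub-optimal shorter alignment that alone clears both
thresholds would be missed.

Classification is a total function of junction geometry. Expected order
means the acceptor lies downstream of the donor in the shared strand's
transcription direction; the 100 kb comparison is exclusive ("closer
than"), so a distance of exactly 100 000 bp is intrachromosomal. The
reported junction `length` is the genomic |acceptor − donor| and is
defined only within one chromosome.

## Simulator

The simulator emits, per class, transcripts joining an annotated donor of
one gene to an annotated acceptor of another whose geometry satisfies the
class definition, with the sequence being the 5' parent transcript
through the donor plus the 3' parent from the acceptor. Donor/acceptor
choices are sampled uniformly over annotated internal boundaries (no
penultimate-exon preference is imposed), subject to each part being at
least `min_part` (200 bp) of exonic sequence so junctions stay spannable
by both read types. Junctions are distinct; distinct gene pairs are
preferred within a class. Background transcripts are a uniform
`bg_fraction` sample (default 0.6, the usual expressed fraction in one
condition) of annotation transcripts, with chimera parents forcibly
included since an expressed chimera usually implies expressed parents.

Reads: `round(coverage × length / (2 × read_len))` fragments per
transcript, normal(insert mean 300, sd 30) lengths clamped to
[read_len, transcript length], mates at fragment ends (one sense, one
reverse complement, mate order random — non-directional), uniform base
errors (default 0), constant high base quality. All sampling derives from
one seed; identical configurations are byte-identical.

Truth alignments project each mate through its transcript's exon blocks:
colinear pieces on one chromosome/strand are written as a single spliced
record (`N` gaps), incompatible pieces as primary + `SA` supplementary;
reads needing more than two pieces are skipped with a warning. This
bypasses mapping entirely, so detector tests measure the post-mapping
logic, not alignment quality.

The synthetic genome builder lays out 75 multi-exon genes (3–6 exons of
120–300 bp, introns 150–500 bp, one or two transcripts) over three
~255 kb chromosomes in a `++--` strand cycle, so same-strand adjacent
pairs (read-through pool), distant colinear pairs (> 100 kb,
intrachromosomal pool), wrong-order, opposite-strand and cross-chromosome
pairs all exist in quantity. Canonical GT..AG motifs (AC/CT on the
forward strand for minus-strand genes) are planted at every annotated
intron boundary so truth split reads are orientable from sequence alone.
The genome is otherwise i.i.d. random sequence: it has no repeats,
paralogy, expression heterogeneity, sequencing-quality structure or
alignment error, so perfect recovery there validates the pipeline's
bookkeeping and geometry, not robustness to real-data noise.

## Evaluation

Gene pairs are compared as ordered (5'→3') sets by default, with an
unordered switch for callers that do not orient; duplicates collapse
before counting. A junction true positive requires exact equality of all
six coordinate fields; per-side 1 bp shifts are false positives. Ratios
with empty denominators (0/0) are reported as undefined (`None`), never
coerced to 0 or 1. The junction distance is the sum of per-side absolute
coordinate differences (infinite across chromosomes); a pseudocount
belongs only in log-scale plotting, never in stored values. A
read-through stripper removes colinear junctions closer than 100 kb
before comparison against fusion-only gold standards.

## Problem sizes and numerical choices

The test suite and acceptance probes run on the synthetic genome above
(~0.8 Mb). End-to-end checks simulate two chimeras per class at 30×
transcript coverage, chosen so every junction comfortably exceeds the
deep-support regime (≥4 split reads, ≥3 consistent pairs). Threshold
probes locate the category boundary by integer bisection over classified
distances and the homology thresholds by grading substitutions (identity,
in 2.5%-steps on a 40 bp block with evenly spaced interior substitutions,
so the full block stays the optimal local alignment) and block lengths
(1 bp steps at perfect identity, with forced-mismatch flanks so the
alignment cannot extend past the planted block).

## Known limitations

* No alignment stage: sensitivity on real data is bounded by the upstream
  mapper's willingness to emit spliced and `SA`-tagged records.
* Split reads with three or more segments are ignored (two-piece splits
  are the overwhelmingly common case).
* The homology filter tests score-optimal local alignments only (above).
* Insert-size bounds are configuration, not estimated from the BAM.
* The annotated-tier definition treats sides independently; exotic cases
  where a donor of one gene matches an acceptor catalogue position of
  another are not distinguished.
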