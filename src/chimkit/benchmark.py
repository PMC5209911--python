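"""Two-level scoring of predicted chimeras against a reference set.

Predictions are compared with a reference at the *gene pair* level
(ordered 5'→3' pairs by default) and at the *junction* level, where a true
positive requires exact equality of donor and acceptor chromosome,
position and strand — a prediction shifted by a single base on either side
counts as a false positive.  Sensitivity is TP/(TP+FN) over the reference,
precision TP/(TP+FP) over the predictions, and F1 their harmonic mean;
0/0 ratios are reported as ``None`` rather than being coerced to 0 or 1.
A junction-to-junction distance (donor-side plus acceptor-side coordinate
difference) is provided for near-miss analysis, and read-through events
can be stripped from predictions before comparison, as is customary when
scoring against fusion-only gold standards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .annotation import Site
from .filters import FilterConfig, classify
from .junctions import SpliceSitePair

#: a junction for evaluation purposes: ((donor), (acceptor)) site tuples.
JunctionKey = tuple[Site, Site]


@dataclass(frozen=True)
class EvalResult:
    level: str
    tp: int
    fp: int
    fn: int

    @property
    def sn(self) -> float | None:
        total = self.tp + self.fn
        return self.tp / total if total else None

    @property
    def pr(self) -> float | None:
        total = self.tp + self.fp
        return self.tp / total if total else None

    @property
    def f1(self) -> float | None:
        sn, pr = self.sn, self.pr
        if sn is None or pr is None:
            return None
        if sn + pr == 0:
            return 0.0
        return 2 * sn * pr / (sn + pr)


@dataclass(frozen=True)
class JunctionDistance:
    donor_bp: float
    acceptor_bp: float

    @property
    def total(self) -> float:
        return self.donor_bp + self.acceptor_bp


def eval_gene_pairs(
    reference: list[tuple[str, str]],
    predictions: list[tuple[str, str]],
    ordered: bool = True,
) -> EvalResult:
    """Set comparison of (gene5, gene3) pairs, duplicates collapsed.

    ``ordered=False`` compares unordered pairs, for callers that do not
    orient their junctions.
    """
    if ordered:
        ref = set(reference)
        pred = set(predictions)
    else:
        ref = {frozenset(p) for p in reference}
        pred = {frozenset(p) for p in predictions}
    tp = len(ref & pred)
    return EvalResult("gene_pair", tp, len(pred) - tp, len(ref) - tp)


def eval_junctions(
    reference: list[JunctionKey], predictions: list[JunctionKey]
) -> EvalResult:
    """Exact-coordinate junction comparison.

    All six fields (chromosome, position, strand of donor and acceptor)
    must match; isoform junctions of one gene pair count independently.
    """
    ref = set(reference)
    pred = set(predictions)
    tp = len(ref & pred)
    return EvalResult("junction", tp, len(pred) - tp, len(ref) - tp)


def junction_distance(a: JunctionKey, b: JunctionKey) -> JunctionDistance:
    """Per-side absolute coordinate difference between two junctions.

    A side whose chromosomes differ has infinite distance.
    """
    def side(x: Site, y: Site) -> float:
        return abs(x[1] - y[1]) if x[0] == y[0] else float("inf")

    return JunctionDistance(side(a[0], b[0]), side(a[1], b[1]))


def strip_readthrough(
    predictions: list[JunctionKey], max_dist: int = 100_000
) -> list[JunctionKey]:
    """Drop junctions on one chromosome/strand in expected order closer
    than ``max_dist`` — the read-through events — keeping all others."""
    cfg = FilterConfig(readthrough_max_dist=max_dist)
    return [
        j
        for j in predictions
        if classify(SpliceSitePair(j[0], j[1], "none"), cfg) != "readthrough"
    ]


# ---------------------------------------------------------------------------
# TSV interchange

_JUNCTION_COLS = [
    "donor_chrom", "donor_pos", "donor_strand",
    "acceptor_chrom", "acceptor_pos", "acceptor_strand",
]


def read_reference(path: str | Path) -> tuple[list[tuple[str, str]], list[JunctionKey]]:
    """Read a reference/prediction TSV with gene5, gene3 and (optionally)
    junction coordinate columns; returns (gene pairs, junctions)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = list(zip(df["gene5"], df["gene3"]))
    junctions: list[JunctionKey] = []
    if all(c in df.columns for c in _JUNCTION_COLS):
        sub = df.dropna(subset=_JUNCTION_COLS)
        for row in sub.itertuples(index=False):
            junctions.append(
                (
                    (row.donor_chrom, int(row.donor_pos), row.donor_strand),
                    (row.acceptor_chrom, int(row.acceptor_pos), row.acceptor_strand),
                )
            )
    return pairs, junctions


def result_frame(results: list[EvalResult]) -> pd.DataFrame:
    rows = [
        {
            "level": r.level,
            "tp": r.tp,
            "fp": r.fp,
            "fn": r.fn,
            "sn": r.sn,
            "pr": r.pr,
            "f1": r.f1,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
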