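"""CIS-to-gene assignment and expression-effect prediction.

A called CIS is assigned to every gene model it overlaps, or failing that to
the nearest gene within a configurable radius (default 100 kb).  The
predicted direction of the expression effect follows standard murine
leukemia virus enhancer/promoter-insertion logic, encoded as named,
individually testable predicates:

* insertion within ``upstream_window`` bp upstream of the TSS, either
  orientation -> increased (enhancer activation of the promoter);
* insertion in the first exon (5' UTR proxy), either orientation ->
  increased (promoter insertion);
* insertion elsewhere in the gene body, either orientation -> decreased
  (transcript truncation / disruption);
* insertion within ``downstream_window`` bp downstream, either orientation
  -> increased (enhancer activation from 3');
* anything else -> no vote.

A call's prediction is the majority vote over its counted insertions; ties
or no votes give ``ambiguous``.  The rule windows are configuration, not
constants, because the underlying biology is a convention rather than a
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .ciscall import CISCall

INCREASED, DECREASED, AMBIGUOUS = "increased", "decreased", "ambiguous"


@dataclass(frozen=True)
class GeneModel:
    """A transcriptional unit: 0-based half-open coordinates, optional exons."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        for s, e in self.exons:
            if s < self.start or e > self.end or s >= e:
                raise ValueError(f"gene {self.gene_id}: exon ({s}, {e}) outside gene bounds")

    @property
    def tss(self) -> int:
        """Transcription start site (0-based base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def first_exon(self):
        """First exon in transcription order, or None."""
        if not self.exons:
            return None
        ordered = sorted(self.exons)
        return ordered[0] if self.strand == "+" else ordered[-1]


@dataclass(frozen=True)
class EffectRules:
    upstream_window: int = 10_000
    downstream_window: int = 10_000


# --- named predicates -------------------------------------------------------


def is_upstream(pos: int, gene: GeneModel, window: int) -> bool:
    if gene.strand == "+":
        return gene.start - window <= pos < gene.start
    return gene.end <= pos < gene.end + window


def is_downstream(pos: int, gene: GeneModel, window: int) -> bool:
    if gene.strand == "+":
        return gene.end <= pos < gene.end + window
    return gene.start - window <= pos < gene.start


def in_body(pos: int, gene: GeneModel) -> bool:
    return gene.start <= pos < gene.end


def in_first_exon(pos: int, gene: GeneModel) -> bool:
    fe = gene.first_exon
    return fe is not None and fe[0] <= pos < fe[1]


def is_sense(strand: str, gene: GeneModel) -> bool:
    return strand == gene.strand


def classify_insertion(pos: int, strand: str | None, gene: GeneModel, rules: EffectRules) -> str | None:
    """Vote of one insertion: increased / decreased / None (no vote)."""
    if is_upstream(pos, gene, rules.upstream_window):
        return INCREASED
    if in_body(pos, gene):
        if in_first_exon(pos, gene):
            return INCREASED
        return DECREASED
    if is_downstream(pos, gene, rules.downstream_window):
        return INCREASED
    return None


def predict_effect(call: CISCall, gene: GeneModel, rules: EffectRules = EffectRules()) -> str:
    """Majority vote across the call's counted insertions; ties -> ambiguous."""
    if all(s not in {"+", "-"} for s in call.strands):
        return AMBIGUOUS
    votes = [classify_insertion(p, s, gene, rules) for p, s in zip(call.positions, call.strands)]
    inc = sum(v == INCREASED for v in votes)
    dec = sum(v == DECREASED for v in votes)
    if inc == dec:
        return AMBIGUOUS
    return INCREASED if inc > dec else DECREASED


# --- assignment -------------------------------------------------------------


@dataclass
class CandidateGene:
    """One CIS-to-gene assignment (or an unassigned CIS)."""

    call: CISCall
    gene: GeneModel | None
    relation: str | None  # overlapping | upstream | downstream
    distance: int | None
    effect: str
    rank: int | None


def assign_genes(
    calls: Sequence[CISCall],
    genes: Sequence[GeneModel],
    max_distance: int = 100_000,
    rules: EffectRules = EffectRules(),
) -> list[CandidateGene]:
    """Map every CIS to its overlapping gene(s) or nearest gene in range.

    Overlap wins and yields one record per overlapped gene (distance 0);
    otherwise the nearest gene within ``max_distance`` bp is used (ties by
    gene ID); a CIS with no gene in range is retained unassigned.
    """
    trees: dict[str, IntervalTree] = {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, g)
        by_chrom.setdefault(g.chrom, []).append(g)

    out: list[CandidateGene] = []
    for call in calls:
        tree = trees.get(call.chrom)
        hits = sorted(
            (iv.data for iv in tree.overlap(call.start, call.end)), key=lambda g: g.gene_id
        ) if tree else []
        if hits:
            for g in hits:
                out.append(
                    CandidateGene(call, g, "overlapping", 0, predict_effect(call, g, rules), call.rank)
                )
            continue
        nearest, best_gap = None, None
        for g in by_chrom.get(call.chrom, []):
            # distance between the closest bases of the two intervals (>= 1)
            if g.start >= call.end:
                gap = g.start - (call.end - 1)
            else:
                gap = call.start - (g.end - 1)
            if gap <= max_distance and (
                best_gap is None or (gap, g.gene_id) < (best_gap, nearest.gene_id)
            ):
                nearest, best_gap = g, gap
        if nearest is None:
            out.append(CandidateGene(call, None, None, None, AMBIGUOUS, call.rank))
        else:
            side_upstream = (
                (call.end <= nearest.start) == (nearest.strand == "+")
            )
            relation = "upstream" if side_upstream else "downstream"
            out.append(
                CandidateGene(
                    call, nearest, relation, best_gap, predict_effect(call, nearest, rules), call.rank
                )
            )
    return out


def candidates_to_frame(candidates: Iterable[CandidateGene]) -> pd.DataFrame:
    rows = [
        {
            "gene": c.gene.gene_id if c.gene else "",
            "cis_id": c.call.cis_id,
            "chrom": c.call.chrom,
            "start": c.call.start,
            "end": c.call.end,
            "relation": c.relation or "",
            "distance": c.distance if c.distance is not None else "",
            "effect": c.effect,
            "rank": c.rank,
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=["gene", "cis_id", "chrom", "start", "end", "relation", "distance", "effect", "rank"],
    )


# --- gene model I/O ---------------------------------------------------------


def load_gff3(path) -> list[GeneModel]:
    """Gene models from GFF3 (gene + exon features), via gffutils."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    genes = []
    for f in db.features_of_type("gene"):
        exons = tuple(
            sorted((e.start - 1, e.end) for e in db.children(f, featuretype="exon"))
        )
        genes.append(
            GeneModel(
                gene_id=f.attributes.get("ID", [f.id])[0],
                chrom=f.seqid,
                strand=f.strand,
                start=f.start - 1,
                end=f.end,
                exons=exons,
            )
        )
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def load_bed12(path) -> list[GeneModel]:
    """Gene models from BED12 (blocks become exons)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: expected 12 BED columns")
            start, end = int(f[1]), int(f[2])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
            genes.append(GeneModel(f[3], f[0], f[5], start, end, exons))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes
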