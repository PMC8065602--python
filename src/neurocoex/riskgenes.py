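"""GWAS summary statistics -> disorder risk-gene lists via target blocks.

A target block is the interval around a tag SNP whose association p-value
passes the disorder's significance threshold (genome-wide 5e-8 for a
well-powered GWAS; relaxed, e.g. 1e-5, for an underpowered one).  Local
LD structure is approximated by a symmetric base-pair window around the
tag; overlapping blocks on a chromosome are merged, keeping the most
significant tag.  Every gene whose interval overlaps a block is a risk
gene of that disorder.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .io import ExpressionDataset, GeneAnnotation, GwasSummary

__all__ = ["TargetBlock", "RiskGeneSet", "define_blocks",
           "extract_risk_genes", "restrict_to_expressed"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetBlock:
    """Half-open genomic interval anchored on a significant tag SNP."""

    chrom: str
    start: int
    end: int
    tag_snp: str
    tag_pos: int  # 1-based
    tag_p: float

    def __post_init__(self) -> None:
        # tag (half-open [pos-1, pos)) must lie inside the block
        if not (self.start <= self.tag_pos - 1 < self.end):
            raise ValueError(
                f"tag SNP {self.tag_snp} at {self.tag_pos} outside block "
                f"[{self.start}, {self.end})")


@dataclass
class RiskGeneSet:
    """Disorder-labelled risk genes with per-gene provenance blocks."""

    disorder: str
    genes: list[str]
    provenance: dict[str, TargetBlock] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("risk genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            b = self.provenance.get(g)
            rows.append({
                "gene": g,
                "chrom": b.chrom if b else "",
                "block_start": b.start if b else -1,
                "block_end": b.end if b else -1,
                "tag_snp": b.tag_snp if b else "",
                "tag_p": b.tag_p if b else float("nan"),
            })
        return pd.DataFrame(rows)


def define_blocks(gwas: GwasSummary, threshold: float,
                  window: int = 250_000) -> list[TargetBlock]:
    """One merged block per cluster of sub-threshold SNPs.

    Each SNP with p < threshold spans tag position ± window (converted to
    0-based half-open coordinates); overlapping blocks on the same
    chromosome are merged and keep the lowest-p tag.  Order of GWAS rows
    never matters.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    hits = gwas.records[gwas.records["p"] < threshold]
    if hits.empty:
        return []
    blocks: list[TargetBlock] = []
    for chrom, sub in hits.groupby("chrom", sort=True):
        sub = sub.sort_values(["pos", "snp"]).reset_index(drop=True)
        cur = None
        for rec in sub.itertuples():
            start = max(rec.pos - 1 - window, 0)
            end = rec.pos + window
            if cur is None:
                cur = [start, end, rec.snp, rec.pos, rec.p]
            elif start < cur[1]:  # overlap with the running block
                cur[1] = max(cur[1], end)
                if rec.p < cur[4]:
                    cur[2], cur[3], cur[4] = rec.snp, rec.pos, rec.p
            else:
                blocks.append(TargetBlock(str(chrom), *cur[:2], cur[2], cur[3], cur[4]))
                cur = [start, end, rec.snp, rec.pos, rec.p]
        blocks.append(TargetBlock(str(chrom), *cur[:2], cur[2], cur[3], cur[4]))
    return blocks


def extract_risk_genes(blocks: list[TargetBlock], annotation: GeneAnnotation,
                       disorder: str,
                       max_tag_distance: int | None = None) -> RiskGeneSet:
    """All genes overlapping any block (half-open interval overlap).

    ``max_tag_distance``, when given, drops genes whose interval midpoint
    is farther than that many bp from the block's tag SNP — an optional
    guard against marginal genes in very large blocks.  Output order is
    genomic (chromosome, start).
    """
    if len(annotation) == 0:
        raise ValueError("annotation is empty")
    recs = annotation.records.sort_values(["chrom", "start", "gene"])
    genes: list[str] = []
    provenance: dict[str, TargetBlock] = {}
    for rec in recs.itertuples():
        for b in blocks:
            if b.chrom != rec.chrom:
                continue
            if rec.start < b.end and b.start < rec.end:
                if max_tag_distance is not None:
                    mid = (rec.start + rec.end) / 2
                    if abs(mid - (b.tag_pos - 0.5)) > max_tag_distance:
                        continue
                if rec.gene not in provenance:
                    genes.append(rec.gene)
                    provenance[rec.gene] = b
                elif b.tag_p < provenance[rec.gene].tag_p:
                    provenance[rec.gene] = b
    return RiskGeneSet(disorder, genes, provenance)


def restrict_to_expressed(riskset: RiskGeneSet,
                          dataset: ExpressionDataset) -> RiskGeneSet:
    """Drop risk genes absent from the expression dataset's gene universe."""
    universe = set(dataset.genes)
    kept = [g for g in riskset.genes if g in universe]
    removed = len(riskset.genes) - len(kept)
    if removed:
        log.info("%s: removed %d risk genes absent from expression data",
                 riskset.disorder, removed)
    if not kept:
        warnings.warn(
            f"no {riskset.disorder} risk genes present in the expression "
            "data; downstream enrichment will be skipped", stacklevel=2)
    return RiskGeneSet(riskset.disorder, kept,
                       {g: b for g, b in riskset.provenance.items() if g in set(kept)})
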