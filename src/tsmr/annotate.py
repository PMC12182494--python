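"""SNP-to-gene annotation by genomic-interval lookup.

Each instrument is assigned the nearest gene on its chromosome within a
window, formatted ``GENE(d)`` with d the distance in whole kilobases
(0 when the variant lies inside the gene).  Functional-consequence calls
require a variant-effect database and are out of scope; the annotation
carries gene and distance only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .sumstats import GeneInterval, SummaryRecord

__all__ = ["SnpAnnotation", "annotate"]


@dataclass(frozen=True)
class SnpAnnotation:
    snp_id: str
    chrom: str
    pos: int
    pval: float
    annot: str  # "GENE(d)" or "" when no gene within the window


def _distance(pos: int, gene: GeneInterval) -> int:
    """Base pairs from the variant to the nearer interval endpoint (0 inside)."""
    if gene.start <= pos <= gene.end:
        return 0
    return gene.start - pos if pos < gene.start else pos - gene.end


def annotate(
    snps: Sequence[SummaryRecord],
    genes: Sequence[GeneInterval],
    window_kb: float = 20.0,
) -> list[SnpAnnotation]:
    """Nearest-gene annotation within ``window_kb`` kilobases.

    Ties are broken by smaller distance, then alphabetical gene symbol, so
    the result is independent of gene-list order.  A variant with no gene
    in the window gets an empty annotation.
    """
    if window_kb < 0:
        raise ValueError("window_kb must be >= 0")
    window_bp = window_kb * 1000.0
    out: list[SnpAnnotation] = []
    for snp in snps:
        best: tuple[int, str] | None = None
        for gene in genes:
            if gene.chrom != snp.chrom:
                continue
            d = _distance(snp.pos, gene)
            if d > window_bp:
                continue
            if best is None or (d, gene.gene) < best:
                best = (d, gene.gene)
        annot = f"{best[1]}({best[0] // 1000})" if best is not None else ""
        out.append(SnpAnnotation(snp.snp_id, snp.chrom, snp.pos, snp.pval, annot))
    return out
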