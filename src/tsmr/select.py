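"""Instrument selection: p-value threshold filter and greedy LD clumping.

The conventional two-step recipe for building an instrument set from one
GWAS: keep variants associated with the exposure below a significance
threshold (default P < 1e-5, the relaxed threshold commonly used for
microbiome exposures), then thin correlated variants so that no two
retained instruments within the clumping window share r² above the cutoff
(default r² < 0.001 within 10,000 kb), keeping the smallest-p variant of
each linkage neighbourhood.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .errors import ClumpError
from .sumstats import LDMatrix, SummaryRecord

__all__ = ["SelectionConfig", "filter_by_pvalue", "clump"]


@dataclass(frozen=True)
class SelectionConfig:
    p_threshold: float = 1.0e-5
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ValueError("p_threshold must be in (0, 1)")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ValueError("clump_r2 must be in [0, 1]")
        if not self.clump_kb > 0:
            raise ValueError("clump_kb must be positive")


def filter_by_pvalue(
    records: Sequence[SummaryRecord], threshold: float = 1.0e-5
) -> list[SummaryRecord]:
    """Keep records with pval strictly below ``threshold``, preserving order."""
    return [r for r in records if r.pval < threshold]


def _chrom_key(chrom: str) -> tuple[int, str]:
    """Total order on chromosome labels: numeric first, then X/Y/MT, then lexical."""
    c = chrom.upper().removeprefix("CHR")
    if c.isdigit():
        return (int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c in special:
        return (special[c], "")
    return (1000, c)


def _order_key(rec: SummaryRecord) -> tuple:
    # greedy priority: smallest p, ties by chromosome, position, then id
    return (rec.pval, _chrom_key(rec.chrom), rec.pos, rec.snp_id)


def clump(
    records: Sequence[SummaryRecord],
    ld: LDMatrix,
    config: SelectionConfig = SelectionConfig(),
) -> list[SummaryRecord]:
    """Greedy LD clumping.

    Repeatedly take the unprocessed record with the smallest p-value as an
    index variant, retain it, and remove every unprocessed record on the
    same chromosome within ``clump_kb`` kilobases whose r² with the index is
    at or above ``clump_r2``.  Ties on p are broken by chromosome, position,
    then snp_id, so the result does not depend on input row order.  Returns
    the retained records sorted by chromosome then position.

    A record absent from the LD matrix is an error: assuming independence
    silently would corrupt the instrument set.
    """
    for rec in records:
        if rec.snp_id not in ld:
            raise ClumpError(f"SNP {rec.snp_id!r} missing from the LD matrix")

    window_bp = config.clump_kb * 1000.0
    ordered = sorted(records, key=_order_key)
    removed: set[str] = set()
    retained: list[SummaryRecord] = []
    for i, index_snp in enumerate(ordered):
        if index_snp.snp_id in removed:
            continue
        retained.append(index_snp)
        for other in ordered[i + 1 :]:
            if other.snp_id in removed:
                continue
            if other.chrom != index_snp.chrom:
                continue
            if abs(other.pos - index_snp.pos) > window_bp:
                continue
            if ld.r2_between(index_snp.snp_id, other.snp_id) >= config.clump_r2:
                removed.add(other.snp_id)
    return sorted(retained, key=lambda r: (_chrom_key(r.chrom), r.pos, r.snp_id))
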