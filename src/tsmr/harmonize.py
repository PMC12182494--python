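"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR joins effects estimated in different cohorts, which need not
report the same effect allele, the same strand, or the same variants.  This
module aligns the outcome table to the exposure sample's effect allele:

* same alleles, same order           -> kept unchanged (``aligned``)
* same alleles, swapped order        -> beta_out negated, eaf_out -> 1-eaf
* alleles match after complementing  -> treated as a strand flip, then the
  order check is re-applied (``strand_flipped``)
* palindromic variants (A/T or C/G)  -> strand cannot be resolved from the
  allele labels; orientation is inferred from effect-allele frequencies
  when both are available and informative, otherwise the variant is dropped
* variants present in only one table, or with irreconcilable alleles, are
  dropped with an explicit reason.

The frequency rule for palindromic variants: both eafs must lie outside
[0.5-w, 0.5+w] (default w = 0.08); if they fall on opposite sides of 0.5
the reported orientations disagree and the outcome effect is flipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .errors import HarmonizationError
from .sumstats import SummaryRecord

__all__ = ["HarmonizedPair", "harmonize", "retained_pairs"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

Status = Literal["aligned", "swapped", "strand_flipped", "palindromic_kept", "dropped"]


@dataclass(frozen=True)
class HarmonizedPair:
    """A variant's exposure and outcome effects on a common effect allele.

    ``status="dropped"`` pairs carry a ``reason`` and are excluded from
    estimation; fields from a missing side are NaN.
    """

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    status: Status
    reason: str = ""
    eaf_exp: float | None = None
    eaf_out: float | None = None
    chrom: str = ""
    pos: int = 0
    effect_allele: str = ""
    other_allele: str = ""

    @property
    def retained(self) -> bool:
        return self.status != "dropped"


def retained_pairs(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if p.retained]


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT[b] for b in allele)


def _is_palindromic(a1: str, a2: str) -> bool:
    return len(a1) == 1 and len(a2) == 1 and _COMPLEMENT[a1] == a2


def _check_unique(records: Sequence[SummaryRecord], label: str) -> dict[str, SummaryRecord]:
    index: dict[str, SummaryRecord] = {}
    for rec in records:
        if rec.snp_id in index:
            raise HarmonizationError(f"duplicate snp_id {rec.snp_id!r} in {label} table")
        index[rec.snp_id] = rec
    return index


def harmonize(
    exposure: Sequence[SummaryRecord],
    outcome: Sequence[SummaryRecord],
    palindromic_eaf_window: float = 0.08,
    palindromic_mode: str = "infer",
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure sample's effect alleles.

    ``palindromic_mode="infer"`` (default) orients palindromic variants from
    effect-allele frequencies; ``"drop"`` discards every palindromic variant
    unconditionally.  Pairs are returned in exposure order, followed by
    dropped placeholders for outcome-only variants.
    """
    if palindromic_mode not in ("infer", "drop"):
        raise ValueError(f"unknown palindromic_mode {palindromic_mode!r}")
    exp_index = _check_unique(exposure, "exposure")
    out_index = _check_unique(outcome, "outcome")

    pairs: list[HarmonizedPair] = []
    for e in exposure:
        o = out_index.get(e.snp_id)
        if o is None:
            pairs.append(_dropped(e, None, "missing_in_outcome"))
            continue
        pairs.append(_harmonize_one(e, o, palindromic_eaf_window, palindromic_mode))
    for o in outcome:
        if o.snp_id not in exp_index:
            pairs.append(_dropped(None, o, "missing_in_exposure"))
    return pairs


def _dropped(
    e: SummaryRecord | None, o: SummaryRecord | None, reason: str
) -> HarmonizedPair:
    ref = e if e is not None else o
    assert ref is not None
    return HarmonizedPair(
        snp_id=ref.snp_id,
        beta_exp=e.beta if e else math.nan,
        se_exp=e.se if e else math.nan,
        beta_out=o.beta if o else math.nan,
        se_out=o.se if o else math.nan,
        status="dropped",
        reason=reason,
        eaf_exp=e.eaf if e else None,
        eaf_out=o.eaf if o else None,
        chrom=ref.chrom,
        pos=ref.pos,
        effect_allele=ref.effect_allele,
        other_allele=ref.other_allele,
    )


def _pair(
    e: SummaryRecord,
    beta_out: float,
    se_out: float,
    eaf_out: float | None,
    status: Status,
    reason: str = "",
) -> HarmonizedPair:
    return HarmonizedPair(
        snp_id=e.snp_id,
        beta_exp=e.beta,
        se_exp=e.se,
        beta_out=beta_out,
        se_out=se_out,
        status=status,
        reason=reason,
        eaf_exp=e.eaf,
        eaf_out=eaf_out,
        chrom=e.chrom,
        pos=e.pos,
        effect_allele=e.effect_allele,
        other_allele=e.other_allele,
    )


def _harmonize_one(
    e: SummaryRecord, o: SummaryRecord, window: float, palindromic_mode: str
) -> HarmonizedPair:
    ea_e, oa_e = e.effect_allele, e.other_allele
    ea_o, oa_o = o.effect_allele, o.other_allele

    if _is_palindromic(ea_e, oa_e):
        if {ea_o, oa_o} != {ea_e, oa_e}:
            return _dropped(e, o, "allele_mismatch")
        if palindromic_mode == "drop":
            return _dropped(e, o, "palindromic_dropped_by_policy")
        return _harmonize_palindromic(e, o, window)

    # non-palindromic: try direct orientation, then a strand flip.
    for flipped_strand in (False, True):
        a1 = _complement(ea_o) if flipped_strand else ea_o
        a2 = _complement(oa_o) if flipped_strand else oa_o
        if (a1, a2) == (ea_e, oa_e):
            status: Status = "strand_flipped" if flipped_strand else "aligned"
            return _pair(e, o.beta, o.se, o.eaf, status)
        if (a1, a2) == (oa_e, ea_e):
            status = "strand_flipped" if flipped_strand else "swapped"
            eaf = None if o.eaf is None else 1.0 - o.eaf
            return _pair(e, -o.beta, o.se, eaf, status, reason="order_swapped")
    return _dropped(e, o, "allele_mismatch")


def _harmonize_palindromic(
    e: SummaryRecord, o: SummaryRecord, window: float
) -> HarmonizedPair:
    """Frequency-based orientation of an A/T or C/G variant.

    The allele labels cannot distinguish the two strands, so the outcome
    effect is first put on the exposure's allele order, then the two
    effect-allele frequencies arbitrate: both must be informative (outside
    the ambiguity window around 0.5); opposite sides of 0.5 imply the
    strand assignment was wrong and the effect is flipped once more.
    """
    beta_out, eaf_out = o.beta, o.eaf
    if (o.effect_allele, o.other_allele) == (e.other_allele, e.effect_allele):
        beta_out = -beta_out
        eaf_out = None if eaf_out is None else 1.0 - eaf_out

    if e.eaf is None or eaf_out is None:
        return _dropped(e, o, "palindromic_missing_eaf")
    lo, hi = 0.5 - window, 0.5 + window
    if lo <= e.eaf <= hi or lo <= eaf_out <= hi:
        return _dropped(e, o, "palindromic_ambiguous_eaf")
    if (e.eaf - 0.5) * (eaf_out - 0.5) < 0:
        beta_out = -beta_out
        eaf_out = 1.0 - eaf_out
    return _pair(e, beta_out, o.se, eaf_out, "palindromic_kept")
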