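"""Heterogeneity and robustness diagnostics for an instrument set.

Cochran's Q quantifies excess dispersion of the per-SNP Wald ratios around
the combined IVW estimate; leave-one-out recomputes the IVW estimate with
each instrument omitted in turn (single-SNP dominance check); single-SNP
and funnel tables feed forest and funnel plots.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EstimationError
from .estimators import WaldRatio, _p_normal

__all__ = [
    "HeterogeneityResult",
    "LeaveOneOutRow",
    "cochran_q",
    "leave_one_out",
    "single_snp",
    "funnel_data",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    method: str
    Q: float
    df: int
    p: float


@dataclass(frozen=True)
class LeaveOneOutRow:
    omitted_snp: str
    b: float
    se: float
    p: float


def _arrays(ratios: Sequence[WaldRatio]) -> tuple[np.ndarray, np.ndarray]:
    b = np.array([r.b for r in ratios], dtype=float)
    w = np.array([1.0 / r.se**2 for r in ratios], dtype=float)
    return b, w


def cochran_q(
    ratios: Sequence[WaldRatio], b_ivw: float | None = None
) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test against the fixed-effect IVW estimate.

    Q = Σ w_j (b_j − b_IVW)² with w_j = 1/se_j², referred to a chi-square
    with k−1 degrees of freedom (upper tail).  ``b_ivw`` defaults to the
    fixed-effect IVW estimate of the same ratios.
    """
    if len(ratios) < 2:
        raise EstimationError("Cochran's Q requires at least 2 ratios")
    b, w = _arrays(ratios)
    if b_ivw is None:
        b_ivw = float(np.sum(w * b) / np.sum(w))
    q = float(np.sum(w * (b - b_ivw) ** 2))
    df = len(ratios) - 1
    return HeterogeneityResult("IVW", q, df, float(stats.chi2.sf(q, df)))


def leave_one_out(ratios: Sequence[WaldRatio]) -> list[LeaveOneOutRow]:
    """Fixed-effect IVW with each SNP omitted in turn, rows in input order.

    Fixed-effect weighting is used regardless of the headline IVW mode so
    the k−1 subsets are compared on the same footing.
    """
    if len(ratios) < 3:
        raise EstimationError("leave-one-out requires at least 3 ratios")
    b, w = _arrays(ratios)
    sw, swb = float(np.sum(w)), float(np.sum(w * b))
    rows: list[LeaveOneOutRow] = []
    for j, r in enumerate(ratios):
        sw_j = sw - w[j]
        b_j = (swb - w[j] * b[j]) / sw_j
        se_j = sw_j**-0.5
        rows.append(LeaveOneOutRow(r.snp_id, float(b_j), float(se_j), _p_normal(b_j / se_j)))
    return rows


def single_snp(ratios: Sequence[WaldRatio]) -> pd.DataFrame:
    """Per-SNP Wald ratios in the reporting column schema."""
    return pd.DataFrame(
        {
            "SNP": [r.snp_id for r in ratios],
            "chr": [r.chrom for r in ratios],
            "pos": [r.pos for r in ratios],
            "effect_allele": [r.effect_allele for r in ratios],
            "b": [r.b for r in ratios],
            "se": [r.se for r in ratios],
            "p": [r.p for r in ratios],
        }
    )


def funnel_data(ratios: Sequence[WaldRatio], b_ivw: float) -> pd.DataFrame:
    """Per-SNP estimate vs precision (1/se) pairs for a funnel plot.

    The combined reference estimate is carried in ``df.attrs["b_reference"]``.
    """
    df = pd.DataFrame(
        {
            "SNP": [r.snp_id for r in ratios],
            "b": [r.b for r in ratios],
            "precision": [1.0 / r.se for r in ratios],
        }
    )
    df.attrs["b_reference"] = float(b_ivw)
    return df
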