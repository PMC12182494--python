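"""Two-sample MR estimators operating on summary statistics.

Four estimators with complementary robustness properties:

* **IVW** — inverse-variance-weighted meta-analysis of per-SNP Wald ratios.
  Efficient, but consistent only if *every* instrument is valid.
* **MR-Egger** — weighted regression of outcome on exposure effects with a
  free intercept.  The slope is consistent under InSIDE (instrument strength
  independent of direct effects); the intercept estimates average
  directional pleiotropy.
* **Weighted median** — consistent while valid instruments carry more than
  half of the total weight.
* **Weighted mode** — consistent while the largest homogeneous cluster of
  instruments is valid.

All estimators are first-order: the Wald-ratio standard error is
``se_out / |beta_exp|`` (delta method, exposure uncertainty ignored), which
is the convention used for the reported per-SNP tables this package mirrors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .errors import EstimationError
from .harmonize import HarmonizedPair

__all__ = [
    "Z95",
    "WaldRatio",
    "MRResult",
    "wald_ratios",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_mode",
]

#: 97.5% normal quantile used for all 95% confidence bounds.
Z95 = 1.959964


def _p_normal(z: float) -> float:
    return float(2.0 * stats.norm.sf(abs(z)))


@dataclass(frozen=True)
class WaldRatio:
    """Per-SNP causal estimate: outcome effect divided by exposure effect."""

    snp_id: str
    b: float
    se: float
    p: float
    chrom: str = ""
    pos: int = 0
    effect_allele: str = ""


@dataclass(frozen=True)
class MRResult:
    """One estimator's causal estimate on the log-odds scale plus OR columns.

    ``or_ = exp(b)`` exactly and the CI bounds are ``exp(b ± 1.959964·se)``,
    so ``log(or_uci95) − log(or_lci95) = 2·1.959964·se`` always holds.
    """

    method: str
    nsnp: int
    b: float
    se: float
    p: float
    or_: float
    or_lci95: float
    or_uci95: float
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_p: float | None = None


def _make_result(method: str, nsnp: int, b: float, se: float, p: float, **kw) -> MRResult:
    return MRResult(
        method=method,
        nsnp=nsnp,
        b=float(b),
        se=float(se),
        p=float(p),
        or_=math.exp(b),
        or_lci95=math.exp(b - Z95 * se),
        or_uci95=math.exp(b + Z95 * se),
        **kw,
    )


def _retained(pairs: Iterable[HarmonizedPair]) -> list[HarmonizedPair]:
    return [p for p in pairs if p.retained]


def wald_ratios(pairs: Iterable[HarmonizedPair]) -> list[WaldRatio]:
    """Per-SNP Wald ratios ``beta_out / beta_exp`` with delta-method SEs.

    Dropped pairs are excluded.  A retained pair with ``beta_exp == 0``
    is an error (the ratio is undefined), named per SNP.
    """
    out: list[WaldRatio] = []
    for pair in _retained(pairs):
        if pair.beta_exp == 0:
            raise EstimationError(f"{pair.snp_id}: beta_exp is 0, Wald ratio undefined")
        b = pair.beta_out / pair.beta_exp
        se = pair.se_out / abs(pair.beta_exp)
        out.append(
            WaldRatio(
                snp_id=pair.snp_id,
                b=b,
                se=se,
                p=_p_normal(b / se),
                chrom=pair.chrom,
                pos=pair.pos,
                effect_allele=pair.effect_allele,
            )
        )
    return out


def _weights(ratios: Sequence[WaldRatio]) -> tuple[np.ndarray, np.ndarray]:
    b = np.array([r.b for r in ratios], dtype=float)
    w = np.array([1.0 / r.se**2 for r in ratios], dtype=float)
    return b, w


def cochran_q_statistic(ratios: Sequence[WaldRatio]) -> float:
    """Q = Σ w_j (b_j − b_IVW)² against the fixed-effect IVW estimate."""
    b, w = _weights(ratios)
    b_ivw = np.sum(w * b) / np.sum(w)
    return float(np.sum(w * (b - b_ivw) ** 2))


def ivw(ratios: Sequence[WaldRatio], mode: str = "random") -> MRResult:
    """Inverse-variance-weighted meta-analysis of Wald ratios.

    ``mode="fixed"`` uses se = (Σ w_j)^(−1/2); ``mode="random"``
    (multiplicative random effects, the default) scales that by
    sqrt(max(1, Q/(k−1))), reducing to the fixed-effect answer when the
    ratios are homogeneous.  A single ratio is permitted and returned as-is.
    """
    if mode not in ("fixed", "random", "multiplicative-random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    if len(ratios) == 0:
        raise EstimationError("IVW requires at least one Wald ratio")
    b, w = _weights(ratios)
    sw = np.sum(w)
    b_hat = float(np.sum(w * b) / sw)
    se = float(sw**-0.5)
    if mode != "fixed" and len(ratios) >= 2:
        q = float(np.sum(w * (b - b_hat) ** 2))
        se *= math.sqrt(max(1.0, q / (len(ratios) - 1)))
    return _make_result("IVW", len(ratios), b_hat, se, _p_normal(b_hat / se))


def mr_egger(pairs: Iterable[HarmonizedPair]) -> MRResult:
    """MR-Egger: weighted regression of beta_out on beta_exp with intercept.

    Pairs are oriented so beta_exp ≥ 0 (both betas of a pair are flipped
    when beta_exp < 0 — the estimate must not depend on which allele is
    labelled the effect allele).  Weights are 1/se_out²; standard errors use
    a residual dispersion factor max(1, σ̂²) and p-values come from the t
    distribution with k−2 degrees of freedom.
    """
    kept = _retained(pairs)
    k = len(kept)
    if k < 3:
        raise EstimationError(f"MR-Egger requires >= 3 SNPs, got {k}")
    bx = np.array([p.beta_exp for p in kept], dtype=float)
    by = np.array([p.beta_out for p in kept], dtype=float)
    sy = np.array([p.se_out for p in kept], dtype=float)
    flip = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * flip, by * flip

    w = 1.0 / sy**2
    x = np.column_stack([np.ones(k), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    try:
        coef = np.linalg.solve(xtwx, xtwy)
        cov_unit = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        raise EstimationError("MR-Egger design is singular (no spread in beta_exp)")
    resid = by - x @ coef
    sigma2 = float(np.sum(w * resid**2) / (k - 2))
    cov = max(1.0, sigma2) * cov_unit
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
    p_slope = float(2.0 * stats.t.sf(abs(slope / se_slope), k - 2))
    p_int = float(2.0 * stats.t.sf(abs(intercept / se_int), k - 2))
    return _make_result(
        "MR-Egger",
        k,
        slope,
        se_slope,
        p_slope,
        egger_intercept=intercept,
        egger_intercept_se=se_int,
        egger_intercept_p=p_int,
    )


def _weighted_median_point(b: np.ndarray, w: np.ndarray) -> float:
    """Interpolated weighted median: b at standardized cumulative weight 0.5."""
    order = np.argsort(b, kind="stable")
    bs, ws = b[order], w[order]
    s = np.cumsum(ws)
    p = (s - ws / 2.0) / s[-1]
    return float(np.interp(0.5, p, bs))


def weighted_median(
    ratios: Sequence[WaldRatio], n_boot: int = 5000, seed: int = 0
) -> MRResult:
    """Weighted-median estimator with a seeded parametric-bootstrap SE.

    Each bootstrap replicate redraws b_j* ~ Normal(b_j, se_j) and recomputes
    the weighted median with the original inverse-variance weights; the SE
    is the standard deviation across replicates.
    """
    if len(ratios) < 3:
        raise EstimationError(f"weighted median requires >= 3 ratios, got {len(ratios)}")
    if n_boot < 100:
        raise EstimationError("n_boot < 100 gives an unstable bootstrap SE")
    b, w = _weights(ratios)
    se = np.array([r.se for r in ratios], dtype=float)
    est = _weighted_median_point(b, w)
    rng = np.random.default_rng(seed)
    draws = rng.normal(b, se, size=(n_boot, len(b)))
    boot = np.array([_weighted_median_point(row, w) for row in draws])
    se_boot = float(np.std(boot, ddof=1))
    return _make_result(
        "weighted-median", len(ratios), est, se_boot, _p_normal(est / se_boot)
    )


def _weighted_mode_bandwidth(b: np.ndarray, w: np.ndarray, factor: float) -> float:
    """Modified-Silverman bandwidth on the weighted ratio distribution."""
    wn = w / np.sum(w)
    mu = float(np.sum(wn * b))
    sd = math.sqrt(float(np.sum(wn * (b - mu) ** 2)))
    med = _weighted_median_point(b, w)
    mad = 1.4826 * _weighted_median_point(np.abs(b - med), w)
    scales = [s for s in (sd, mad) if s > 0]
    if not scales:
        return 0.0
    return factor * 0.9 * min(scales) * len(b) ** (-1.0 / 5.0)


def _golden_max(f, lo: float, hi: float, tol: float = 1e-10) -> float:
    """Golden-section search for the maximizer of f on [lo, hi]."""
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol * max(1.0, abs(a) + abs(b)):
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return (a + b) / 2.0


def _weighted_mode_point(b: np.ndarray, w: np.ndarray, factor: float) -> float:
    """Maximizer of the weighted Gaussian kernel density over the ratios."""
    if np.ptp(b) == 0.0:
        return float(b[0])
    h = _weighted_mode_bandwidth(b, w, factor)
    if h <= 0.0:
        return float(b[np.argmax(w)])

    grid = np.linspace(b.min() - 3.0 * h, b.max() + 3.0 * h, 512)
    dens = np.exp(-0.5 * ((grid[:, None] - b[None, :]) / h) ** 2) @ w
    i = int(np.argmax(dens))
    lo, hi = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]

    def f(x: float) -> float:
        return float(np.sum(w * np.exp(-0.5 * ((x - b) / h) ** 2)))

    return _golden_max(f, lo, hi)


def weighted_mode(
    ratios: Sequence[WaldRatio],
    bandwidth_factor: float = 1.0,
    n_boot: int = 5000,
    seed: int = 0,
) -> MRResult:
    """Mode-based estimator: peak of the weighted Wald-ratio density.

    The density is a Gaussian kernel mixture with inverse-variance weights
    and a modified-Silverman bandwidth scaled by ``bandwidth_factor``; the
    maximizer is located on a 512-point grid and refined by golden-section
    search.  The SE is a seeded parametric bootstrap (bandwidth recomputed
    per replicate).  If all ratios coincide the estimate is that common
    value and only the bootstrap contributes spread.
    """
    if len(ratios) < 3:
        raise EstimationError(f"weighted mode requires >= 3 ratios, got {len(ratios)}")
    if n_boot < 100:
        raise EstimationError("n_boot < 100 gives an unstable bootstrap SE")
    b, w = _weights(ratios)
    se = np.array([r.se for r in ratios], dtype=float)
    est = _weighted_mode_point(b, w, bandwidth_factor)
    rng = np.random.default_rng(seed)
    draws = rng.normal(b, se, size=(n_boot, len(b)))
    boot = np.array([_weighted_mode_point(row, w, bandwidth_factor) for row in draws])
    se_boot = float(np.std(boot, ddof=1))
    return _make_result(
        "weighted-mode", len(ratios), est, se_boot, _p_normal(est / se_boot)
    )
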