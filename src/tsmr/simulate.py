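"""Synthetic paired GWAS summary statistics with known ground truth.

Two-sample MR consumes only summary statistics, so the generator works
directly on that scale — no individual-level genotypes.  For each variant j:

* a minor-allele frequency ``maf_j ~ Uniform(maf_range)``;
* a true exposure effect ``gamma_j ~ Normal(0, gamma_sd²)`` truncated away
  from zero at ``|gamma| >= gamma_min`` so instruments can clear a P < 1e-5
  selection filter at realistic sample sizes;
* observed exposure effect ``beta_x ~ Normal(gamma_j, se_x)`` with
  ``se_x = 1/sqrt(2·maf·(1−maf)·n_exposure)``;
* a direct (pleiotropic) outcome effect ``alpha_j``, zero for valid
  instruments; for the designated invalid fraction it is drawn from
  ``Normal(pleiotropy_mean, pleiotropy_sd²)`` (directional when the mean is
  non-zero), or — when ``inside_violation`` — tied to instrument strength as
  ``alpha = pleiotropy_mean + inside_kappa·|gamma| + noise``;
* observed outcome effect
  ``beta_y ~ Normal(theta·gamma_j + sign(gamma_j)·alpha_j, se_y)`` on the
  log-odds scale.  The direct effect is expressed on the
  exposure-increasing allele, so "directional" pleiotropy pushes the
  outcome the same way regardless of which allele raises the exposure —
  the regime in which IVW is biased while the MR-Egger intercept recovers
  the mean direct effect under InSIDE.

Cross-sample bookkeeping hazards are simulated too: a fraction of variants
get complementary (palindromic A/T or C/G) allele pairs, and a fraction
have their allele order swapped in the outcome table (beta negated,
eaf -> 1−eaf), which the harmonization stage must undo.  The LD matrix is
block-diagonal with constant within-block correlation ``ld_rho`` (r²
reported).  Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .estimators import WaldRatio
from .sumstats import LDMatrix, SummaryRecord

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_pair",
    "load_config",
    "make_erysipelotrichia_fixture",
]

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("C", "A"), ("A", "G"), ("G", "A"),
    ("T", "C"), ("C", "T"), ("T", "G"), ("G", "T"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of one simulated exposure/outcome pair.

    Defaults mirror the data scales of a microbiome-exposure MR study:
    exposure GWAS of ~18k individuals (16S abundance consortium scale),
    binary outcome GWAS of 4881 individuals (1627 cases, 3254 controls),
    and a null causal effect.
    """

    n_snps: int = 50
    n_exposure: int = 18_340
    n_outcome: int = 4_881
    theta: float = 0.0
    prop_invalid: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.05
    inside_violation: bool = False
    inside_kappa: float = 1.0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    frac_palindromic: float = 0.2
    frac_flipped: float = 0.1
    gamma_sd: float = 0.08
    gamma_min: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ValueError("sample sizes must be >= 2")
        for name in ("prop_invalid", "frac_palindromic", "frac_flipped"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or (name == "prop_invalid" and v >= 1.0):
                raise ValueError(f"{name} out of range: {v}")
        if not np.isfinite(self.theta):
            raise ValueError("theta must be finite")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth written alongside a simulated dataset."""

    theta: float
    snp_ids: tuple[str, ...]
    gamma: tuple[float, ...]  # true exposure effects
    alpha: tuple[float, ...]  # true direct (pleiotropic) outcome effects
    invalid_snp_ids: tuple[str, ...]
    maf: tuple[float, ...]

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str) -> SimulationConfig:
    """Read a SimulationConfig from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    return SimulationConfig(**raw)


def _truncated_normal(rng, sd: float, minimum: float, size: int) -> np.ndarray:
    """Normal(0, sd²) with the band |x| < minimum resampled away."""
    x = rng.normal(0.0, sd, size)
    while True:
        bad = np.abs(x) < minimum
        if not bad.any():
            return x
        x[bad] = rng.normal(0.0, sd, int(bad.sum()))


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)


def simulate_pair(
    config: SimulationConfig,
) -> tuple[list[SummaryRecord], list[SummaryRecord], LDMatrix, SimulationTruth]:
    """Generate one exposure table, one outcome table, LD matrix, and truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_snps

    maf = rng.uniform(config.maf_range[0], config.maf_range[1], n)
    gamma = _truncated_normal(rng, config.gamma_sd, config.gamma_min, n)

    n_invalid = round(config.prop_invalid * n)
    invalid_idx = rng.choice(n, size=n_invalid, replace=False)
    alpha = np.zeros(n)
    if n_invalid:
        if config.inside_violation:
            alpha[invalid_idx] = (
                config.pleiotropy_mean
                + config.inside_kappa * np.abs(gamma[invalid_idx])
                + rng.normal(0.0, config.pleiotropy_sd, n_invalid)
            )
        else:
            alpha[invalid_idx] = rng.normal(
                config.pleiotropy_mean, config.pleiotropy_sd, n_invalid
            )

    se_x = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_exposure)
    se_y = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * config.n_outcome)
    beta_x = rng.normal(gamma, se_x)
    # alpha acts on the exposure-increasing orientation of each instrument
    beta_y = rng.normal(config.theta * gamma + np.sign(gamma) * alpha, se_y)

    # allele bookkeeping: palindromic subset, then outcome-order flips
    n_pal = round(config.frac_palindromic * n)
    pal_idx = set(rng.choice(n, size=n_pal, replace=False).tolist())
    n_flip = round(config.frac_flipped * n)
    flip_idx = set(rng.choice(n, size=n_flip, replace=False).tolist())
    pal_choices = rng.integers(0, len(_PALINDROMIC_PAIRS), n)
    nonpal_choices = rng.integers(0, len(_NONPALINDROMIC_PAIRS), n)

    snp_ids = [f"rs{1_000_000 + j}" for j in range(n)]
    p_x = _two_sided_p(beta_x / se_x)
    p_y = _two_sided_p(beta_y / se_y)

    exposure: list[SummaryRecord] = []
    outcome: list[SummaryRecord] = []
    for j in range(n):
        block = j // config.ld_block_size
        chrom = str(block % 22 + 1)
        pos = 1 + 10_000_000 * (block // 22) + 5_000 * (j % config.ld_block_size)
        if j in pal_idx:
            ea, oa = _PALINDROMIC_PAIRS[pal_choices[j]]
        else:
            ea, oa = _NONPALINDROMIC_PAIRS[nonpal_choices[j]]
        exposure.append(
            SummaryRecord(
                snp_id=snp_ids[j], chrom=chrom, pos=pos,
                effect_allele=ea, other_allele=oa, eaf=float(maf[j]),
                beta=float(beta_x[j]), se=float(se_x[j]), pval=float(p_x[j]),
                n=config.n_exposure,
            )
        )
        if j in flip_idx:
            out_ea, out_oa = oa, ea
            out_beta, out_eaf = -float(beta_y[j]), 1.0 - float(maf[j])
        else:
            out_ea, out_oa = ea, oa
            out_beta, out_eaf = float(beta_y[j]), float(maf[j])
        outcome.append(
            SummaryRecord(
                snp_id=snp_ids[j], chrom=chrom, pos=pos,
                effect_allele=out_ea, other_allele=out_oa, eaf=out_eaf,
                beta=out_beta, se=float(se_y[j]), pval=float(p_y[j]),
                n=config.n_outcome,
            )
        )

    truth = SimulationTruth(
        theta=config.theta,
        snp_ids=tuple(snp_ids),
        gamma=tuple(float(g) for g in gamma),
        alpha=tuple(float(a) for a in alpha),
        invalid_snp_ids=tuple(snp_ids[j] for j in sorted(invalid_idx.tolist())),
        maf=tuple(float(m) for m in maf),
    )
    return exposure, outcome, _block_ld(snp_ids, config), truth


def _block_ld(snp_ids: Sequence[str], config: SimulationConfig) -> LDMatrix:
    n = len(snp_ids)
    r2 = np.zeros((n, n))
    r2_within = config.ld_rho**2
    for start in range(0, n, config.ld_block_size):
        stop = min(start + config.ld_block_size, n)
        r2[start:stop, start:stop] = r2_within
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(tuple(snp_ids), r2)


# ---------------------------------------------------------------------------
# in-package worked example

#: Printed per-SNP estimates for the five Erysipelotrichia instruments
#: against childhood neuroblastoma (log-odds ratio per abundance unit).
_ERYSIPELOTRICHIA_ROWS = (
    ("rs10748005", "5", 3004171, "A", -1.226287714, 0.881003827, 0.163946327),
    ("rs2300774", "3", 195800811, "G", -0.729916118, 0.824245623, 0.375856529),
    ("rs35161940", "17", 70334286, "T", -1.625575773, 0.84377268, 0.054034919),
    ("rs4078432", "14", 48997206, "C", -0.427570132, 0.908389464, 0.637861894),
    ("rs8003149", "14", 56160904, "C", -0.8876358, 0.895507031, 0.321582898),
)


def make_erysipelotrichia_fixture() -> list[WaldRatio]:
    """The published five-SNP per-SNP worked example (class Erysipelotrichia
    vs childhood neuroblastoma): per-SNP b, se, p with chromosome/position
    as printed.  Their fixed-effect inverse-variance combination reproduces
    the published headline estimate b = −0.99077 (OR 0.371)."""
    return [
        WaldRatio(snp_id=s, chrom=c, pos=pos, effect_allele=a, b=b, se=se, p=p)
        for s, c, pos, a, b, se, p in _ERYSIPELOTRICHIA_ROWS
    ]
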