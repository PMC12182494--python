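"""Model/results interface over the MR estimators.

``MRModel`` holds the harmonized instrument set for one exposure–outcome
pair; ``fit`` returns an :class:`MRFit` carrying the causal estimate, its
uncertainty and odds-ratio scale, with the sensitivity diagnostics and
plots hanging off it — the familiar model → results shape.

>>> model = MRModel.from_wald_ratios(make_erysipelotrichia_fixture())
>>> res = model.fit(method="ivw", ivw_mode="fixed")
>>> round(res.b, 5), round(res.odds_ratio, 4)
(-0.99077, 0.3713)
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import estimators, sensitivity
from .errors import EstimationError
from .estimators import MRResult, WaldRatio
from .harmonize import HarmonizedPair, retained_pairs

__all__ = ["MRModel", "MRFit"]

_METHODS = ("ivw", "egger", "wmedian", "wmode")


class MRModel:
    """Harmonized instruments for one exposure–outcome pair.

    Construct from harmonized pairs (full information: MR-Egger available)
    or directly from per-SNP Wald ratios (ratio-only methods), e.g. when
    reproducing a published per-SNP table.
    """

    def __init__(
        self,
        pairs: Iterable[HarmonizedPair] | None = None,
        *,
        ratios: Sequence[WaldRatio] | None = None,
        exposure_name: str = "exposure",
    ) -> None:
        if (pairs is None) == (ratios is None):
            raise ValueError("provide exactly one of pairs or ratios")
        self.exposure_name = exposure_name
        if pairs is not None:
            self.pairs: list[HarmonizedPair] | None = retained_pairs(pairs)
            self._ratios = estimators.wald_ratios(self.pairs)
        else:
            self.pairs = None
            self._ratios = list(ratios)  # type: ignore[arg-type]

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[HarmonizedPair], exposure_name: str = "exposure"
    ) -> "MRModel":
        return cls(pairs=pairs, exposure_name=exposure_name)

    @classmethod
    def from_wald_ratios(
        cls, ratios: Sequence[WaldRatio], exposure_name: str = "exposure"
    ) -> "MRModel":
        return cls(ratios=ratios, exposure_name=exposure_name)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        beta_exp: str = "beta_exp",
        se_exp: str = "se_exp",
        beta_out: str = "beta_out",
        se_out: str = "se_out",
        snp_id: str = "snp_id",
        exposure_name: str = "exposure",
    ) -> "MRModel":
        """Build from a DataFrame of already-harmonized per-SNP effects."""
        pairs = [
            HarmonizedPair(
                snp_id=str(row[snp_id]),
                beta_exp=float(row[beta_exp]),
                se_exp=float(row[se_exp]),
                beta_out=float(row[beta_out]),
                se_out=float(row[se_out]),
                status="aligned",
            )
            for _, row in df.iterrows()
        ]
        return cls(pairs=pairs, exposure_name=exposure_name)

    @property
    def wald_ratios(self) -> list[WaldRatio]:
        return list(self._ratios)

    @property
    def nsnp(self) -> int:
        return len(self._ratios)

    def fit(
        self,
        method: str = "ivw",
        *,
        ivw_mode: str = "random",
        n_boot: int = 5000,
        bandwidth_factor: float = 1.0,
        seed: int = 0,
    ) -> "MRFit":
        """Fit one estimator; ``method`` in {ivw, egger, wmedian, wmode}."""
        if method not in _METHODS:
            raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
        if method == "ivw":
            res = estimators.ivw(self._ratios, mode=ivw_mode)
        elif method == "egger":
            if self.pairs is None:
                raise EstimationError(
                    "MR-Egger needs exposure/outcome effects; build the model from pairs"
                )
            res = estimators.mr_egger(self.pairs)
        elif method == "wmedian":
            res = estimators.weighted_median(self._ratios, n_boot=n_boot, seed=seed)
        else:
            res = estimators.weighted_mode(
                self._ratios,
                bandwidth_factor=bandwidth_factor,
                n_boot=n_boot,
                seed=seed,
            )
        return MRFit(self, res)

    def fit_all(
        self,
        methods: Sequence[str] = _METHODS,
        *,
        ivw_mode: str = "random",
        n_boot: int = 5000,
        bandwidth_factor: float = 1.0,
        seed: int = 0,
    ) -> list["MRFit"]:
        return [
            self.fit(
                m,
                ivw_mode=ivw_mode,
                n_boot=n_boot,
                bandwidth_factor=bandwidth_factor,
                seed=seed,
            )
            for m in methods
        ]


class MRFit:
    """One estimator's causal estimate plus diagnostics for its instrument set."""

    def __init__(self, model: MRModel, result: MRResult) -> None:
        self.model = model
        self.result = result

    # -- convenience accessors -------------------------------------------
    @property
    def method(self) -> str:
        return self.result.method

    @property
    def nsnp(self) -> int:
        return self.result.nsnp

    @property
    def b(self) -> float:
        return self.result.b

    @property
    def se(self) -> float:
        return self.result.se

    @property
    def pvalue(self) -> float:
        return self.result.p

    @property
    def odds_ratio(self) -> float:
        return self.result.or_

    def conf_int_or(self) -> tuple[float, float]:
        return self.result.or_lci95, self.result.or_uci95

    # -- diagnostics ------------------------------------------------------
    def cochran_q(self) -> sensitivity.HeterogeneityResult:
        return sensitivity.cochran_q(self.model.wald_ratios)

    def leave_one_out(self) -> pd.DataFrame:
        rows = sensitivity.leave_one_out(self.model.wald_ratios)
        return pd.DataFrame(
            {
                "omitted_snp": [r.omitted_snp for r in rows],
                "b": [r.b for r in rows],
                "se": [r.se for r in rows],
                "p": [r.p for r in rows],
            }
        )

    def single_snp(self) -> pd.DataFrame:
        return sensitivity.single_snp(self.model.wald_ratios)

    def funnel_data(self) -> pd.DataFrame:
        return sensitivity.funnel_data(self.model.wald_ratios, self.b)

    # -- presentation -----------------------------------------------------
    def summary(self) -> str:
        r = self.result
        lines = [
            "Two-sample Mendelian randomization",
            "=" * 52,
            f"Exposure:        {self.model.exposure_name}",
            f"Method:          {r.method}",
            f"Instruments:     {r.nsnp}",
            f"b (log OR):      {r.b: .6f}",
            f"SE:              {r.se: .6f}",
            f"p-value:         {r.p: .6g}",
            f"OR:              {r.or_: .6f}",
            f"95% CI (OR):     ({r.or_lci95:.6f}, {r.or_uci95:.6f})",
        ]
        if r.egger_intercept is not None:
            lines += [
                f"Egger intercept: {r.egger_intercept: .6f} "
                f"(SE {r.egger_intercept_se:.6f}, p {r.egger_intercept_p:.4g})",
            ]
        if self.nsnp >= 2:
            q = self.cochran_q()
            lines.append(f"Cochran's Q:     {q.Q:.4f} on {q.df} df (p {q.p:.4g})")
        lines.append("=" * 52)
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<MRFit {self.method} nsnp={self.nsnp} b={self.b:.4f} "
            f"p={self.pvalue:.4g}>"
        )

    # -- plotting (thin layers over the data tables) ----------------------
    def plot_funnel(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        df = self.funnel_data()
        ax.scatter(df["b"], df["precision"], s=20)
        ax.axvline(df.attrs["b_reference"], linestyle="--", color="grey")
        ax.set_xlabel("per-SNP estimate (b)")
        ax.set_ylabel("precision (1/SE)")
        return ax

    def plot_forest(self, ax=None):
        import matplotlib.pyplot as plt

        from .estimators import Z95

        if ax is None:
            _, ax = plt.subplots()
        df = self.single_snp()
        y = np.arange(len(df))[::-1]
        ax.errorbar(df["b"], y, xerr=Z95 * df["se"], fmt="o", capsize=2)
        ax.axvline(self.b, linestyle="--", color="grey")
        ax.axvline(0.0, color="black", linewidth=0.5)
        ax.set_yticks(y, df["SNP"])
        ax.set_xlabel("per-SNP estimate (b, 95% CI)")
        return ax

    def plot_leave_one_out(self, ax=None):
        import matplotlib.pyplot as plt

        from .estimators import Z95

        if ax is None:
            _, ax = plt.subplots()
        df = self.leave_one_out()
        y = np.arange(len(df))[::-1]
        ax.errorbar(df["b"], y, xerr=Z95 * df["se"], fmt="o", capsize=2)
        ax.axvline(self.b, linestyle="--", color="grey")
        ax.axvline(0.0, color="black", linewidth=0.5)
        ax.set_yticks(y, "omit " + df["omitted_snp"])
        ax.set_xlabel("IVW estimate without the named SNP (95% CI)")
        return ax
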