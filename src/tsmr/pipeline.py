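"""End-to-end orchestration: select -> harmonize -> estimate -> diagnose -> annotate.

Every stage logs how many variants entered, survived, and why the rest were
dropped; the returned summary (also written as JSON) is fully machine
readable and deterministic given the input files and seed.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

from . import sensitivity
from .annotate import annotate as annotate_snps
from .errors import EstimationError, NoInstrumentsError
from .harmonize import harmonize, retained_pairs
from .model import MRModel
from .select import SelectionConfig, clump, filter_by_pvalue
from .sumstats import (
    read_gene_intervals,
    read_ld_matrix,
    read_sumstats,
    write_results,
    write_run_summary,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("tsmr")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_NO_INSTRUMENTS = 3
EXIT_ESTIMATION = 4


@dataclass
class RunConfig:
    exposure_path: str
    outcome_path: str
    ld_path: str
    out_dir: str
    genes_path: str | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    palindromic_window: float = 0.08
    palindromic_mode: str = "infer"
    methods: Sequence[str] = ("ivw", "egger", "wmedian", "wmode")
    ivw_mode: str = "random"
    n_boot: int = 5000
    seed: int | None = None
    annotation_window_kb: float = 20.0
    exposure_name: str = "exposure"

    def __post_init__(self) -> None:
        bootstrap_methods = {"wmedian", "wmode"} & set(self.methods)
        if bootstrap_methods and self.seed is None:
            raise ValueError(
                f"seed is required for bootstrap methods {sorted(bootstrap_methods)}"
            )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write all result tables under ``out_dir``.

    Raises :class:`NoInstrumentsError` when selection/harmonization leaves
    no usable instrument, :class:`EstimationError` when a requested
    estimator cannot run on the surviving set.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    summary: dict = {"stages": {}, "results": []}

    # --- read ------------------------------------------------------------
    exposure, exp_rejected = read_sumstats(config.exposure_path)
    outcome, out_rejected = read_sumstats(config.outcome_path)
    ld = read_ld_matrix(config.ld_path)
    logger.info(
        "read: %d exposure rows (%d rejected), %d outcome rows (%d rejected)",
        len(exposure), len(exp_rejected), len(outcome), len(out_rejected),
    )
    summary["stages"]["read"] = {
        "exposure_rows": len(exposure) + len(exp_rejected),
        "exposure_valid": len(exposure),
        "exposure_rejected": len(exp_rejected),
        "outcome_rows": len(outcome) + len(out_rejected),
        "outcome_valid": len(outcome),
        "outcome_rejected": len(out_rejected),
    }

    # --- instrument selection -------------------------------------------
    sig = filter_by_pvalue(exposure, config.selection.p_threshold)
    logger.info("p-filter: %d of %d below %g", len(sig), len(exposure),
                config.selection.p_threshold)
    summary["stages"]["p_filter"] = {
        "in": len(exposure), "retained": len(sig),
        "dropped": len(exposure) - len(sig),
        "threshold": config.selection.p_threshold,
    }
    if not sig:
        raise NoInstrumentsError(
            f"no variant passes p < {config.selection.p_threshold:g}"
        )
    clumped = clump(sig, ld, config.selection)
    logger.info("clump: %d of %d retained", len(clumped), len(sig))
    summary["stages"]["clump"] = {
        "in": len(sig), "retained": len(clumped),
        "dropped": len(sig) - len(clumped),
    }

    # --- harmonization ---------------------------------------------------
    clumped_ids = {r.snp_id for r in clumped}
    outcome_subset = [r for r in outcome if r.snp_id in clumped_ids]
    pairs = harmonize(
        clumped, outcome_subset,
        palindromic_eaf_window=config.palindromic_window,
        palindromic_mode=config.palindromic_mode,
    )
    kept = retained_pairs(pairs)
    dropped = [p for p in pairs if not p.retained]
    logger.info("harmonize: %d retained, %d dropped", len(kept), len(dropped))
    summary["stages"]["harmonize"] = {
        "in": len(pairs), "retained": len(kept), "dropped": len(dropped),
        "drop_reasons": _count_reasons(dropped),
    }
    _write_harmonization_report(pairs, config.out_dir)
    if not kept:
        raise NoInstrumentsError("no instruments survive harmonization")

    # --- estimation ------------------------------------------------------
    model = MRModel.from_pairs(kept, exposure_name=config.exposure_name)
    fits = []
    for method in config.methods:
        try:
            fits.append(
                model.fit(
                    method,
                    ivw_mode=config.ivw_mode,
                    n_boot=config.n_boot,
                    seed=_derive_seed(config.seed, method),
                )
            )
        except EstimationError as exc:
            raise EstimationError(f"estimation [{method}]: {exc}") from exc
    summary["results"] = [
        {
            "method": f.result.method, "nsnp": f.result.nsnp,
            "b": f.result.b, "se": f.result.se, "p": f.result.p,
            "OR": f.result.or_, "OR_lci95": f.result.or_lci95,
            "OR_uci95": f.result.or_uci95,
            **(
                {
                    "egger_intercept": f.result.egger_intercept,
                    "egger_intercept_se": f.result.egger_intercept_se,
                    "egger_intercept_p": f.result.egger_intercept_p,
                }
                if f.result.egger_intercept is not None
                else {}
            ),
        }
        for f in fits
    ]

    # --- sensitivity -----------------------------------------------------
    ratios = model.wald_ratios
    diag = fits[0] if fits else None
    if model.nsnp >= 2:
        q = sensitivity.cochran_q(ratios)
        summary["heterogeneity"] = {"method": q.method, "Q": q.Q, "df": q.df, "p": q.p}
        with open(os.path.join(config.out_dir, "heterogeneity.tsv"), "w") as fh:
            fh.write("method\tQ\tdf\tp\n")
            fh.write(f"{q.method}\t{q.Q:.6g}\t{q.df}\t{q.p:.6g}\n")
    if model.nsnp >= 3:
        loo = sensitivity.leave_one_out(ratios)
        with open(os.path.join(config.out_dir, "leave_one_out.tsv"), "w") as fh:
            fh.write("omitted_snp\tb\tse\tp\n")
            for row in loo:
                fh.write(f"{row.omitted_snp}\t{row.b:.6g}\t{row.se:.6g}\t{row.p:.6g}\n")
    if diag is not None:
        diag.funnel_data().to_csv(
            os.path.join(config.out_dir, "funnel.tsv"), sep="\t", index=False,
            float_format="%.6g",
        )

    write_results(
        [f.result for f in fits], ratios, config.out_dir,
        exposure=config.exposure_name,
    )

    # --- annotation ------------------------------------------------------
    if config.genes_path:
        genes = read_gene_intervals(config.genes_path)
        kept_ids = {p.snp_id for p in kept}
        annotations = annotate_snps(
            [r for r in clumped if r.snp_id in kept_ids],
            genes,
            window_kb=config.annotation_window_kb,
        )
        with open(os.path.join(config.out_dir, "annotations.tsv"), "w") as fh:
            fh.write("CHR\tSNP\tBP\tP\tANNOT\n")
            for a in annotations:
                fh.write(f"{a.chrom}\t{a.snp_id}\t{a.pos}\t{a.pval:.6g}\t{a.annot}\n")
        summary["annotation"] = {
            "n_snps": len(annotations),
            "n_annotated": sum(1 for a in annotations if a.annot),
        }

    summary["seed"] = config.seed
    write_run_summary(summary, os.path.join(config.out_dir, "run_summary.json"))
    return summary


def _count_reasons(dropped) -> dict[str, int]:
    counts: dict[str, int] = {}
    for p in dropped:
        counts[p.reason] = counts.get(p.reason, 0) + 1
    return counts


def _derive_seed(seed: int | None, method: str) -> int:
    """Per-method seed stream: adding a method must not perturb another's draws."""
    if seed is None:
        return 0
    offset = {"ivw": 0, "egger": 1, "wmedian": 2, "wmode": 3}.get(method, 9)
    return (seed * 10 + offset) % (2**31 - 1)


def _write_harmonization_report(pairs, out_dir: str) -> None:
    with open(os.path.join(out_dir, "harmonization_report.tsv"), "w") as fh:
        fh.write("snp_id\tstatus\treason\n")
        for p in pairs:
            fh.write(f"{p.snp_id}\t{p.status}\t{p.reason}\n")
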