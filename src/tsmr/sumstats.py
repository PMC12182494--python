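"""GWAS summary-statistics I/O: records, LD matrices, gene intervals.

Tables are tab-separated with a header row.  The default column dialect is
GWAS-SSF-like (``snp_id, chrom, pos, effect_allele, other_allele, eaf, beta,
se, pval, n``); a user-supplied ``column_map`` adapts other dialects, since
public GWAS extracts (MiBioGen, IEU OpenGWAS, ...) do not share headers.
Coordinates are 1-based throughout; BED input is converted on read.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "SummaryRecord",
    "LDMatrix",
    "GeneInterval",
    "RowReport",
    "read_sumstats",
    "write_sumstats",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_gene_intervals",
    "write_results",
    "write_run_summary",
]

_VALID_BASES = frozenset("ACGT")

#: Default column names, in file order.
DEFAULT_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

_REQUIRED_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
)


@dataclass(frozen=True)
class SummaryRecord:
    """One variant's association statistics in one GWAS sample.

    ``beta`` is the per-allele effect of ``effect_allele`` (log-odds for a
    binary trait).  ``eaf`` and ``n`` are optional because published extracts
    frequently omit them; stages that need ``eaf`` (palindromic-variant
    orientation) must degrade explicitly rather than guess.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        object.__setattr__(self, "other_allele", self.other_allele.upper())
        if not self.snp_id:
            raise ValidationError("empty snp_id")
        if not set(self.effect_allele) <= _VALID_BASES or not self.effect_allele:
            raise ValidationError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} not over {{A,C,G,T}}"
            )
        if not set(self.other_allele) <= _VALID_BASES or not self.other_allele:
            raise ValidationError(
                f"{self.snp_id}: other allele {self.other_allele!r} not over {{A,C,G,T}}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not (isinstance(self.pos, (int, np.integer)) and self.pos >= 1):
            raise ValidationError(f"{self.snp_id}: pos must be a positive 1-based integer")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: beta is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.snp_id}: se must be > 0")
        if not (0.0 < self.pval <= 1.0):
            raise ValidationError(f"{self.snp_id}: pval must be in (0, 1]")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.snp_id}: eaf must be in [0, 1]")
        if self.n is not None and not self.n > 0:
            raise ValidationError(f"{self.snp_id}: n must be positive")


class RowReport(NamedTuple):
    """Why one input row was rejected during parsing."""

    row: int  # 0-based data-row index (header excluded)
    snp_id: str
    reason: str


@dataclass(frozen=True)
class LDMatrix:
    """Pairwise squared correlations (r²) between variants.

    Symmetric, unit diagonal, values in [0, 1].
    """

    snp_ids: tuple[str, ...]
    r2: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if r2.shape != (k, k):
            raise FormatError(f"LD matrix shape {r2.shape} does not match {k} labels")
        if len(set(self.snp_ids)) != k:
            raise FormatError("duplicate variant labels in LD matrix")
        if not np.allclose(r2, r2.T, atol=1e-8, rtol=0.0):
            i, j = np.unravel_index(np.argmax(np.abs(r2 - r2.T)), r2.shape)
            raise FormatError(
                f"LD matrix asymmetric beyond 1e-8 at ({self.snp_ids[i]}, {self.snp_ids[j]})"
            )
        r2 = np.clip((r2 + r2.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(r2, 1.0)
        r2.flags.writeable = False
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        object.__setattr__(
            self, "_index", {s: i for i, s in enumerate(self.snp_ids)}
        )

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index  # type: ignore[attr-defined]

    def r2_between(self, a: str, b: str) -> float:
        idx = self._index  # type: ignore[attr-defined]
        return float(self.r2[idx[a], idx[b]])

    @classmethod
    def identity(cls, snp_ids: Sequence[str]) -> "LDMatrix":
        return cls(tuple(snp_ids), np.eye(len(snp_ids)))


@dataclass(frozen=True)
class GeneInterval:
    """A gene's genomic footprint, 1-based inclusive."""

    gene: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"{self.gene}: invalid interval [{self.start}, {self.end}]"
            )


# ---------------------------------------------------------------------------
# readers / writers


def _resolve_columns(
    header: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map internal names -> file column names, checking required ones exist."""
    mapping = {name: name for name in DEFAULT_COLUMNS}
    if column_map:
        mapping.update(column_map)
    present = set(header)
    for name in _REQUIRED_COLUMNS:
        if mapping[name] not in present:
            raise FormatError(f"missing required column {mapping[name]!r}")
    return mapping


def read_sumstats(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[SummaryRecord], list[RowReport]]:
    """Read a tab-separated summary-statistics table.

    Returns ``(records, rejected)``.  Validation is total: every malformed
    row produces a :class:`RowReport` entry instead of being silently
    dropped.  Duplicate ``snp_id`` keeps the first occurrence and reports
    the rest.  A missing *required* column raises :class:`FormatError`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = _resolve_columns(df.columns, column_map)

    records: list[SummaryRecord] = []
    rejected: list[RowReport] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        row_d = dict(zip(df.columns, row))
        snp_id = row_d.get(cols["snp_id"], "")
        try:
            rec = _record_from_row(row_d, cols)
        except (ValidationError, ValueError) as exc:
            rejected.append(RowReport(i, snp_id, str(exc)))
            continue
        if rec.snp_id in seen:
            rejected.append(RowReport(i, rec.snp_id, "duplicate snp_id"))
            continue
        seen.add(rec.snp_id)
        records.append(rec)
    return records, rejected


def _record_from_row(row: Mapping[str, str], cols: Mapping[str, str]) -> SummaryRecord:
    def get(name: str) -> str:
        return str(row.get(cols[name], "")).strip()

    def opt_float(name: str) -> float | None:
        raw = get(name)
        if raw in ("", "NA", "nan", "NaN", "."):
            return None
        return float(raw)

    def opt_int(name: str) -> int | None:
        raw = get(name)
        if raw in ("", "NA", "nan", "NaN", "."):
            return None
        return int(float(raw))

    try:
        beta = float(get("beta"))
    except ValueError:
        raise ValidationError(f"non-numeric beta {get('beta')!r}") from None
    try:
        se = float(get("se"))
    except ValueError:
        raise ValidationError(f"non-numeric se {get('se')!r}") from None

    return SummaryRecord(
        snp_id=get("snp_id"),
        chrom=get("chrom"),
        pos=int(float(get("pos"))),
        effect_allele=get("effect_allele"),
        other_allele=get("other_allele"),
        beta=beta,
        se=se,
        pval=float(get("pval")),
        eaf=opt_float("eaf"),
        n=opt_int("n"),
    )


def _fmt(x: float | int | None) -> str:
    if x is None:
        return "NA"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return format(float(x), ".6g")


def write_sumstats(records: Iterable[SummaryRecord], path: str | os.PathLike) -> None:
    """Write records in the default tab-separated dialect (6 s.f. floats)."""
    with open(path, "w") as fh:
        fh.write("\t".join(DEFAULT_COLUMNS) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    [
                        r.snp_id,
                        r.chrom,
                        str(r.pos),
                        r.effect_allele,
                        r.other_allele,
                        _fmt(r.eaf),
                        _fmt(r.beta),
                        _fmt(r.se),
                        _fmt(r.pval),
                        _fmt(r.n),
                    ]
                )
                + "\n"
            )


def read_ld_matrix(path: str | os.PathLike) -> LDMatrix:
    """Read a square tab-separated r² matrix with matching row/column labels.

    Asymmetries beyond 1e-8 are rejected; values are clamped to [0, 1] and
    the diagonal is forced to exactly 1.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise FormatError(f"LD matrix is not square: {df.shape}")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        raise FormatError("LD matrix row labels do not match column labels")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric LD matrix entry: {exc}") from None
    return LDMatrix(tuple(rows), values)


def write_ld_matrix(ld: LDMatrix, path: str | os.PathLike) -> None:
    df = pd.DataFrame(ld.r2, index=list(ld.snp_ids), columns=list(ld.snp_ids))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_gene_intervals(path: str | os.PathLike) -> list[GeneInterval]:
    """Read BED-like gene intervals (chrom, start, end, gene; tab-separated).

    BED is 0-based half-open; intervals are converted to the internal
    1-based inclusive convention (start+1, end).
    """
    genes: list[GeneInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}:{line_no}: expected 4 BED columns")
            chrom, start, end, gene = parts[:4]
            genes.append(
                GeneInterval(gene=gene, chrom=chrom, start=int(start) + 1, end=int(end))
            )
    return genes


RESULT_COLUMNS = (
    "exposure",
    "method",
    "nsnp",
    "b",
    "se",
    "p",
    "OR",
    "OR_lci95",
    "OR_uci95",
)

PER_SNP_COLUMNS = ("SNP", "chr", "pos", "effect_allele", "b", "se", "p")


def write_results(results, per_snp, path: str | os.PathLike, exposure: str = "exposure"):
    """Write estimator results and per-SNP rows as two TSVs under ``path``.

    ``results`` is an iterable of objects with ``method/nsnp/b/se/p/or_/
    or_lci95/or_uci95`` attributes; ``per_snp`` an iterable with
    ``snp_id/chrom/pos/effect_allele/b/se/p``.  Numbers are printed at 6
    significant digits, so a round-trip read reproduces them to 6 s.f.
    Returns the two file paths.
    """
    os.makedirs(path, exist_ok=True)
    res_path = os.path.join(path, "mr_results.tsv")
    snp_path = os.path.join(path, "per_snp.tsv")
    with open(res_path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        exposure,
                        r.method,
                        str(r.nsnp),
                        _fmt(r.b),
                        _fmt(r.se),
                        _fmt(r.p),
                        _fmt(r.or_),
                        _fmt(r.or_lci95),
                        _fmt(r.or_uci95),
                    ]
                )
                + "\n"
            )
    with open(snp_path, "w") as fh:
        fh.write("\t".join(PER_SNP_COLUMNS) + "\n")
        for w in per_snp:
            fh.write(
                "\t".join(
                    [
                        w.snp_id,
                        w.chrom,
                        str(w.pos),
                        w.effect_allele,
                        _fmt(w.b),
                        _fmt(w.se),
                        _fmt(w.p),
                    ]
                )
                + "\n"
            )
    return res_path, snp_path


def write_run_summary(summary: Mapping, path: str | os.PathLike) -> None:
    """Machine-readable key-value run summary (JSON)."""
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
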