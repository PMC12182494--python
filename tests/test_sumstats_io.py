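"""Summary-statistics, LD-matrix and results I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tsmr import (
    FormatError,
    LDMatrix,
    SummaryRecord,
    ValidationError,
    make_erysipelotrichia_fixture,
    read_ld_matrix,
    read_sumstats,
    write_results,
    write_sumstats,
)
from tsmr.sumstats import read_gene_intervals

HEADER = "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn"


def _table2_tsv(tmp_path, rows):
    path = tmp_path / "sumstats.tsv"
    path.write_text(HEADER + "\n" + "\n".join(rows) + "\n")
    return path


def test_reads_published_per_snp_table(tmp_path):
    """The five printed per-SNP rows parse into five validated records."""
    rows = []
    for r in make_erysipelotrichia_fixture():
        other = "G" if r.effect_allele != "G" else "C"
        rows.append(
            f"{r.snp_id}\t{r.chrom}\t{r.pos}\t{r.effect_allele}\t{other}"
            f"\t\t{r.b}\t{r.se}\t{r.p}\t"
        )
    records, rejected = read_sumstats(_table2_tsv(tmp_path, rows))
    assert len(records) == 5 and not rejected
    by_id = {r.snp_id: r for r in records}
    assert by_id["rs2300774"].pos == 195800811
    assert by_id["rs2300774"].eaf is None and by_id["rs2300774"].n is None


def test_header_only_file_gives_empty_list(tmp_path):
    path = tmp_path / "empty.tsv"
    path.write_text(HEADER + "\n")
    records, rejected = read_sumstats(path)
    assert records == [] and rejected == []


@pytest.mark.parametrize(
    "bad_row, reason_frag",
    [
        ("rsX\t1\t100\tA\tG\t0.2\t0.1\t0\t0.5\t100", "se"),
        ("rsX\t1\t100\tA\tG\t0.2\tnot_a_number\t0.1\t0.5\t100", "beta"),
        ("rsX\t1\t100\tA\tA\t0.2\t0.1\t0.1\t0.5\t100", "allele"),
        ("rsX\t1\t100\tA\tG\t0.2\t0.1\t0.1\t1.5\t100", "pval"),
    ],
)
def test_invalid_rows_rejected_with_report(tmp_path, bad_row, reason_frag):
    """Malformed rows never vanish silently: each yields a report entry."""
    good = "rsOK\t1\t200\tC\tG\t0.3\t0.2\t0.1\t0.01\t100"
    path = tmp_path / "t.tsv"
    path.write_text(HEADER + f"\n{good}\n{bad_row}\n")
    records, rejected = read_sumstats(path)
    assert [r.snp_id for r in records] == ["rsOK"]
    assert len(rejected) == 1 and reason_frag in rejected[0].reason.lower()


def test_duplicate_snp_id_keeps_first_and_reports(tmp_path):
    row = "rsD\t1\t100\tA\tG\t0.2\t0.1\t0.1\t0.5\t100"
    path = tmp_path / "t.tsv"
    path.write_text(HEADER + f"\n{row}\n{row}\n")
    records, rejected = read_sumstats(path)
    assert len(records) == 1
    assert rejected[0].reason == "duplicate snp_id"


def test_missing_required_column_names_it(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text("snp_id\tchrom\tpos\n")
    with pytest.raises(FormatError, match="effect_allele"):
        read_sumstats(path)


def test_column_map_adapts_other_dialects(tmp_path):
    path = tmp_path / "t.tsv"
    path.write_text(
        "rsid\tCHR\tBP\tA1\tA2\tfreq\tb\tstderr\tP\tN\n"
        "rs1\t2\t500\ta\tg\t0.1\t0.3\t0.1\t0.001\t1000\n"
    )
    records, rejected = read_sumstats(
        path,
        column_map={
            "snp_id": "rsid", "chrom": "CHR", "pos": "BP",
            "effect_allele": "A1", "other_allele": "A2", "eaf": "freq",
            "beta": "b", "se": "stderr", "pval": "P", "n": "N",
        },
    )
    assert not rejected and records[0].effect_allele == "A"  # upper-cased
    assert records[0].n == 1000


@settings(max_examples=50, deadline=None)
@given(
    beta=st.floats(-5, 5, allow_nan=False),
    se=st.floats(1e-4, 10),
    pval=st.floats(1e-300, 1.0, exclude_min=False),
    eaf=st.one_of(st.none(), st.floats(0, 1)),
)
def test_sumstats_round_trip_6_sig_figs(tmp_path_factory, beta, se, pval, eaf):
    """read(write(x)) reproduces every numeric field to 6 significant digits."""
    rec = SummaryRecord(
        snp_id="rs1", chrom="7", pos=123456, effect_allele="A",
        other_allele="C", beta=beta, se=se, pval=pval, eaf=eaf, n=500,
    )
    path = tmp_path_factory.mktemp("rt") / "x.tsv"
    write_sumstats([rec], path)
    (back,), rejected = read_sumstats(path)
    assert not rejected
    for field in ("beta", "se", "pval", "eaf"):
        a, b = getattr(rec, field), getattr(back, field)
        if a is None:
            assert b is None
        else:
            assert b == pytest.approx(a, rel=1e-5, abs=1e-12)
    assert (back.snp_id, back.pos, back.n) == ("rs1", 123456, 500)


class TestLDMatrix:
    def test_identity_matrix_reads(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text(
            "\trs1\trs2\trs3\nrs1\t1\t0\t0\nrs2\t0\t1\t0\nrs3\t0\t0\t1\n"
        )
        ld = read_ld_matrix(path)
        assert ld.snp_ids == ("rs1", "rs2", "rs3")
        assert np.array_equal(ld.r2, np.eye(3))

    def test_slight_overshoot_clamped_to_one(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("\trs1\trs2\nrs1\t1.0000001\t0.5\nrs2\t0.5\t1\n")
        ld = read_ld_matrix(path)
        assert ld.r2[0, 0] == 1.0

    def test_asymmetry_rejected(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("\trs1\trs2\nrs1\t1\t0.5\nrs2\t0.1\t1\n")
        with pytest.raises(FormatError, match="asymmetric"):
            read_ld_matrix(path)

    def test_label_mismatch_rejected(self, tmp_path):
        path = tmp_path / "ld.tsv"
        path.write_text("\trs1\trs2\nrsA\t1\t0\nrs2\t0\t1\n")
        with pytest.raises(FormatError):
            read_ld_matrix(path)

    def test_non_square_rejected(self):
        with pytest.raises(FormatError):
            LDMatrix(("a", "b"), np.ones((2, 3)))


class TestWriteResults:
    def test_published_row_round_trips_at_6_sig_figs(self, tmp_path, worked_example):
        from tsmr import MRModel

        fit = MRModel.from_wald_ratios(worked_example).fit("ivw", ivw_mode="fixed")
        res_path, snp_path = write_results(
            [fit.result], worked_example, tmp_path, exposure="Erysipelotrichia"
        )
        text = open(res_path).read()
        assert "-0.990768" in text and "0.371291" in text
        header = text.splitlines()[0].split("\t")
        assert header == [
            "exposure", "method", "nsnp", "b", "se", "p", "OR",
            "OR_lci95", "OR_uci95",
        ]
        snp_header = open(snp_path).read().splitlines()[0].split("\t")
        assert snp_header == ["SNP", "chr", "pos", "effect_allele", "b", "se", "p"]

    def test_empty_results_give_header_only(self, tmp_path):
        res_path, snp_path = write_results([], [], tmp_path)
        assert len(open(res_path).read().splitlines()) == 1
        assert len(open(snp_path).read().splitlines()) == 1


def test_bed_intervals_convert_to_1_based(tmp_path):
    path = tmp_path / "genes.bed"
    path.write_text("3\t195746764\t195812053\tMUC4\n")
    (gene,) = read_gene_intervals(path)
    assert (gene.start, gene.end) == (195746765, 195812053)


def test_record_invariants_enforced():
    with pytest.raises(ValidationError):
        SummaryRecord("rs1", "1", 10, "A", "A", 0.1, 0.1, 0.5)
    with pytest.raises(ValidationError):
        SummaryRecord("rs1", "1", 0, "A", "G", 0.1, 0.1, 0.5)
    with pytest.raises(ValidationError):
        SummaryRecord("rs1", "1", 10, "A", "G", 0.1, 0.1, 0.0)
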