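"""Somatic hard-filter decisions, attribution, I/O and invariants."""

import numpy as np
import pandas as pd
import pytest

from ithpipe import simdata, variant_filter
from ithpipe.variant_filter import CRITERIA, FilterConfig, apply_somatic_filters


def make_record(**overrides):
    rec = {
        "patient": "P1",
        "sample": "P1_R1",
        "chrom": "1",
        "pos": 1000,
        "ref": "C",
        "alt": "T",
        "depth": 100,
        "alt_reads": 40,
        "plus_strand_alt": 20,
        "minus_strand_alt": 20,
        "gene": "GENE0001",
        "func": "exonic",
        "exonic_func": "nonsynonymous SNV",
        "dbsnp_af": 0.0,
        "converge_af": 0.0,
        "kg_af": 0.0,
        "esp_af": 0.0,
        "exac_af": 0.0,
        "sift": "tolerated",
        "polyphen": "benign",
        "context": "A[C>T]G",
        "kg_gold_indel": False,
    }
    rec.update(overrides)
    return rec


def run_one(**overrides):
    df = pd.DataFrame([make_record(**overrides)])
    passing, report = apply_somatic_filters(df)
    if report.n_pass:
        return "pass"
    (reason,) = [c for c, n in report.rejections.items() if n]
    return reason


def oracle_decision(rec: dict, cfg: FilterConfig = FilterConfig()) -> str:
    """Independent one-record re-implementation of the published criteria."""
    alt = rec["alt_reads"]
    bias = max(rec["plus_strand_alt"], rec["minus_strand_alt"]) / alt if alt else 0.0
    if bias >= cfg.max_strand_bias:
        return "strand_bias"
    if rec["depth"] < cfg.min_depth:
        return "depth"
    if alt < cfg.min_alt_reads:
        return "alt_reads"
    if alt / rec["depth"] < cfg.min_vaf:
        return "vaf"
    if (rec.get("dbsnp_af") or 0.0) >= cfg.max_dbsnp_af:
        return "dbsnp_af"
    if (rec.get("converge_af") or 0.0) >= cfg.max_converge_af:
        return "converge"
    if rec.get("kg_gold_indel") and (len(rec["ref"]) != 1 or len(rec["alt"]) != 1):
        return "kg_gold_indel"
    if any((rec.get(c) or 0.0) > cfg.max_pop_af for c in ("kg_af", "esp_af", "exac_af")):
        return "pop_af_0.015"
    if str(rec["func"]).lower() not in ("exonic", "splicing", "exonic;splicing"):
        return "region"
    return "pass"


class TestCriteria:
    def test_strand_bias_rejection(self):
        assert run_one(plus_strand_alt=38, minus_strand_alt=2) == "strand_bias"

    def test_minimal_clean_record_passes(self):
        assert run_one(depth=20, alt_reads=8, plus_strand_alt=4, minus_strand_alt=4) == "pass"

    def test_low_vaf_attributed_to_vaf_not_alt_reads(self):
        # alt_reads=9 >= 8 passes; VAF 0.09 < 0.1 is the first failure
        assert run_one(depth=100, alt_reads=9, plus_strand_alt=5, minus_strand_alt=4) == "vaf"

    def test_common_exac_variant_rejected(self):
        assert run_one(exac_af=0.02) == "pop_af_0.015"

    def test_pop_af_boundary_is_strict(self):
        # "larger than 0.015": exactly 0.015 passes
        assert run_one(kg_af=0.015) == "pass"

    def test_dbsnp_boundary_is_inclusive(self):
        # "AF >= 1%": exactly 0.01 is removed
        assert run_one(dbsnp_af=0.01) == "dbsnp_af"

    def test_gold_standard_indel_rejected(self):
        assert (
            run_one(ref="C", alt="CA", kg_gold_indel=True, exonic_func="frameshift insertion")
            == "kg_gold_indel"
        )

    def test_gold_flag_ignored_for_snv(self):
        assert run_one(kg_gold_indel=True) == "pass"

    def test_intronic_site_rejected(self):
        assert run_one(func="intronic") == "region"

    def test_missing_af_is_not_common(self):
        assert run_one(dbsnp_af=np.nan, kg_af=np.nan, esp_af=np.nan, exac_af=np.nan) == "pass"

    def test_empty_table(self):
        passing, report = apply_somatic_filters(pd.DataFrame(columns=list(make_record())))
        assert len(passing) == 0 and report.n_input == 0 and report.rejections == {}


class TestPlantedViolations:
    def test_report_counts_match_planted_truth(self):
        df, truth = simdata.simulate_filter_table(200, seed=3)
        passing, report = apply_somatic_filters(df)
        expected = truth.value_counts()
        assert report.n_pass == expected.get("pass", 0)
        for crit in CRITERIA:
            assert report.rejections.get(crit, 0) == expected.get(crit, 0), crit

    def test_decisions_match_independent_oracle(self):
        df, _ = simdata.simulate_filter_table(500, seed=11)
        passing, _ = apply_somatic_filters(df)
        passed_idx = set(passing.index)
        for i, rec in df.iterrows():
            assert (oracle_decision(rec.to_dict()) == "pass") == (i in passed_idx)


class TestInvariants:
    def test_filter_is_idempotent(self):
        df, _ = simdata.simulate_filter_table(400, seed=5)
        once, rep1 = apply_somatic_filters(df)
        twice, rep2 = apply_somatic_filters(once)
        assert rep2.n_pass == rep1.n_pass == len(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_pass_count_monotone_in_vaf_threshold(self):
        df, _ = simdata.simulate_filter_table(400, seed=7)
        counts = []
        for v in (0.0, 0.05, 0.1, 0.2, 0.5, 0.9):
            _, rep = apply_somatic_filters(df, FilterConfig(min_vaf=v))
            counts.append(rep.n_pass)
        assert counts == sorted(counts, reverse=True)


class TestIO:
    def test_tsv_round_trip(self, tmp_path, sim_patient):
        variants = sim_patient[0]
        path = tmp_path / "v.tsv"
        variant_filter.write_variants_tsv(variants, path)
        back = variant_filter.read_variants(path, dialect="tsv")
        pd.testing.assert_frame_equal(
            variants.reset_index(drop=True),
            back[variants.columns].reset_index(drop=True),
            check_dtype=False,
        )

    def test_alt_reads_exceeding_depth_is_row_error(self):
        df = pd.DataFrame([make_record(alt_reads=150)])
        with pytest.raises(ValueError, match="row 0"):
            apply_somatic_filters(df)

    def test_negative_depth_rejected(self):
        df = pd.DataFrame([make_record(depth=-5)])
        with pytest.raises(ValueError, match="negative depth"):
            apply_somatic_filters(df)

    def test_vcf_reader_populates_afs_and_missing_stays_nan(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DBSNP_AF,Number=1,Type=Float,Description="x">\n'
            '##INFO=<ID=GENE,Number=1,Type=String,Description="x">\n'
            '##INFO=<ID=FUNC,Number=1,Type=String,Description="x">\n'
            '##INFO=<ID=PATIENT,Number=1,Type=String,Description="x">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">\n'
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="x">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t1000\t.\tC\tT\t.\t.\tDBSNP_AF=0.2;GENE=TP53;FUNC=exonic;PATIENT=P1\tDP:AD\t100:60,40\n"
            "1\t2000\t.\tG\tA\t.\t.\tGENE=KRAS;FUNC=exonic;PATIENT=P1\tDP:AD\t80:50,30\n"
        )
        df = variant_filter.read_variants(vcf, dialect="vcf")
        assert len(df) == 2
        assert df.loc[df["pos"] == 1000, "dbsnp_af"].iloc[0] == pytest.approx(0.2)
        assert np.isnan(df.loc[df["pos"] == 2000, "dbsnp_af"].iloc[0])
        assert df["pos"].tolist() == [1000, 2000]  # 1-based preserved
        assert df["alt_reads"].tolist() == [40, 30]
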