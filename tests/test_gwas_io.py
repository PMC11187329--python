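"""Summary-statistics I/O and effect-allele harmonization."""

import numpy as np
import pytest

from lipidmr.gwas_io import (
    GwasRecord,
    SummaryTable,
    harmonize,
    kept_pairs,
    read_summary_tsv,
    write_summary_tsv,
)
from lipidmr.mr_core import ivw
from lipidmr.synthetic import SimConfig, simulate_target

from conftest import make_record

HEADER = "snp_id\tchrom\tpos\teffect_allele\tother_allele\teaf\tbeta\tse\tpval\tn"


def _write(tmp_path, lines, name="sumstats.tsv"):
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestReadWrite:
    def test_well_formed_rows_round_trip(self, tmp_path):
        path = _write(
            tmp_path,
            [
                HEADER,
                "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-10\t1000",
                "rs2\t1\t200\tC\tT\t0.5\t-0.2\t0.02\t1e-12\t1000",
                "rs3\t2\t300\tg\ta\t\t0.05\t0.01\t0.5\t",  # lower case, missing eaf/n
            ],
        )
        table = read_summary_tsv(path)
        assert len(table) == 3
        assert table.get("rs3").effect_allele == "G"  # upper-cased on read
        assert table.get("rs3").eaf is None and table.get("rs3").n is None

    def test_invalid_rows_dropped_with_survivors_kept(self, tmp_path, caplog):
        path = _write(
            tmp_path,
            [
                HEADER,
                "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-10\t1000",
                "rs2\t1\t200\tC\tT\t0.5\t0.2\t0\t1e-12\t1000",  # se = 0
                "rs3\t1\t300\tAT\tG\t0.5\t0.2\t0.02\t1e-12\t1000",  # indel
                "rs4\t1\t400\tA\tG\t0.3\tnot_a_number\t0.02\t1e-12\t1000",
                "rs5\t1\t500\tA\tG\t0.3\t0.1\t0.01\t1e-10\t1000",
            ],
        )
        with caplog.at_level("WARNING"):
            table = read_summary_tsv(path)
        assert table.snp_ids() == ["rs1", "rs5"]
        assert "3 row(s) dropped" in caplog.text

    def test_missing_required_column_is_an_error(self, tmp_path):
        path = _write(tmp_path, ["snp_id\tchrom\tpos", "rs1\t1\t100"])
        with pytest.raises(ValueError, match="missing required column"):
            read_summary_tsv(path)

    def test_column_map_reads_foreign_headers(self, tmp_path):
        path = _write(
            tmp_path,
            [
                "rsid\tCHR\tBP\tA1\tA2\tfreq\tb\tstderr\tP\tN",
                "rs1\t1\t100\tA\tG\t0.3\t0.1\t0.01\t1e-10\t1000",
            ],
        )
        table = read_summary_tsv(
            path,
            column_map={
                "snp_id": "rsid", "chrom": "CHR", "pos": "BP",
                "effect_allele": "A1", "other_allele": "A2", "eaf": "freq",
                "beta": "b", "se": "stderr", "pval": "P", "n": "N",
            },
        )
        assert table.snp_ids() == ["rs1"]

    def test_write_then_read_is_identity(self, tmp_path, rng):
        records = [
            make_record(
                snp_id=f"rs{i}",
                pos=100 + i,
                beta=float(rng.normal()),
                se=float(rng.uniform(0.001, 0.1)),
                pval=float(rng.uniform(1e-300, 1)),
                eaf=None if i % 3 == 0 else float(rng.uniform(0, 1)),
                n=None if i % 4 == 0 else float(rng.integers(1, 10**6)),
            )
            for i in range(25)
        ]
        table = SummaryTable("trait", records)
        path = tmp_path / "out.tsv"
        write_summary_tsv(table, path)
        back = read_summary_tsv(path, trait_label="trait")
        assert back.records == table.records

    def test_empty_table_writes_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_summary_tsv(SummaryTable("t", []), path)
        assert path.read_text().strip() == HEADER
        assert len(read_summary_tsv(path)) == 0

    def test_duplicate_snp_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            SummaryTable("t", [make_record(), make_record()])


class TestHarmonize:
    def _tables(self, exp_rec, out_rec):
        return SummaryTable("x", [exp_rec]), SummaryTable("y", [out_rec])

    def test_identical_orientation_kept(self):
        exp, out = self._tables(
            make_record(ea="A", oa="G", beta=0.1),
            make_record(ea="A", oa="G", beta=0.05),
        )
        (pair,) = harmonize(exp, out)
        assert pair.action == "kept" and pair.beta_outcome == 0.05

    def test_swapped_alleles_flip_outcome_sign(self):
        exp, out = self._tables(
            make_record(ea="A", oa="G", beta=0.1),
            make_record(ea="G", oa="A", beta=0.05, eaf=0.7),
        )
        (pair,) = harmonize(exp, out)
        assert pair.action == "flipped" and pair.beta_outcome == -0.05

    def test_strand_complement_kept(self):
        exp, out = self._tables(
            make_record(ea="A", oa="G", beta=0.1),
            make_record(ea="T", oa="C", beta=0.05),
        )
        (pair,) = harmonize(exp, out)
        assert pair.action == "kept" and pair.beta_outcome == 0.05

    def test_palindrome_near_half_frequency_dropped(self):
        exp, out = self._tables(
            make_record(ea="A", oa="T", eaf=0.49),
            make_record(ea="A", oa="T", eaf=0.49),
        )
        (pair,) = harmonize(exp, out, palindrome_eaf_window=0.08)
        assert pair.action == "dropped_palindromic"

    def test_palindrome_outside_window_aligned_by_frequency(self):
        exp, out = self._tables(
            make_record(ea="A", oa="T", eaf=0.2, beta=0.1),
            make_record(ea="A", oa="T", eaf=0.8, beta=0.05),  # reported for the other allele
        )
        (pair,) = harmonize(exp, out)
        assert pair.action == "flipped" and pair.beta_outcome == -0.05

    def test_irreconcilable_alleles_dropped_as_mismatch(self):
        exp, out = self._tables(
            make_record(ea="A", oa="G"),
            make_record(ea="A", oa="C"),
        )
        (pair,) = harmonize(exp, out)
        assert pair.action == "dropped_mismatch"

    def test_snps_missing_from_outcome_are_omitted(self):
        exp = SummaryTable("x", [make_record("rs1"), make_record("rs2", pos=2)])
        out = SummaryTable("y", [make_record("rs1")])
        pairs = harmonize(exp, out)
        assert [p.snp_id for p in pairs] == ["rs1"]

    def test_harmonization_is_idempotent(self):
        """Re-harmonizing an outcome rewritten in exposure orientation
        changes nothing."""
        cfg = SimConfig(n_targets=1, j_snps=10, seed=11, palindromic_fraction=0.3)
        exp, ctrl, _, _, _, _ = simulate_target(cfg, 0)
        first = kept_pairs(harmonize(exp, ctrl))
        # rebuild the outcome on the exposure's alleles from the pairs
        aligned = SummaryTable(
            "aligned",
            [
                GwasRecord(
                    snp_id=p.snp_id,
                    chrom=exp.get(p.snp_id).chrom,
                    pos=exp.get(p.snp_id).pos,
                    effect_allele=exp.get(p.snp_id).effect_allele,
                    other_allele=exp.get(p.snp_id).other_allele,
                    beta=p.beta_outcome,
                    se=p.se_outcome,
                    pval=0.5,
                    eaf=p.eaf_exposure,
                )
                for p in first
            ],
        )
        second = kept_pairs(harmonize(exp, aligned))
        assert [(p.snp_id, p.beta_outcome) for p in second] == [
            (p.snp_id, p.beta_outcome) for p in first
        ]
        assert all(p.action == "kept" for p in second)

    def test_global_allele_relabeling_leaves_ivw_unchanged(self):
        """Flipping every outcome row's allele labels (with beta negation
        and frequency complement) is invisible downstream."""
        cfg = SimConfig(n_targets=1, j_snps=12, seed=5, theta_control=0.3)
        exp, ctrl, _, _, _, _ = simulate_target(cfg, 0)
        flipped = SummaryTable(
            "flipped",
            [
                GwasRecord(
                    snp_id=r.snp_id,
                    chrom=r.chrom,
                    pos=r.pos,
                    effect_allele=r.other_allele,
                    other_allele=r.effect_allele,
                    beta=-r.beta,
                    se=r.se,
                    pval=r.pval,
                    eaf=None if r.eaf is None else 1 - r.eaf,
                    n=r.n,
                )
                for r in ctrl
            ],
        )
        res_a = ivw(kept_pairs(harmonize(exp, ctrl)))
        res_b = ivw(kept_pairs(harmonize(exp, flipped)))
        assert res_a.beta == pytest.approx(res_b.beta, rel=1e-12)
        assert res_a.se == pytest.approx(res_b.se, rel=1e-12)
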