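"""Cis selection, greedy LD clumping, F statistics, instrument assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipidmr.gwas_io import SummaryTable
from lipidmr.instruments import (
    TargetSpec,
    build_instrument_set,
    f_statistics,
    ld_clump,
    select_cis_snps,
)
from lipidmr.synthetic import SimConfig, simulate_target

from conftest import make_record

TARGET = TargetSpec(
    gene_symbol="GENE", chrom="1", gene_start=1_000_000, gene_end=1_050_000, lipid_trait="LDL"
)


class TestSelectCisSnps:
    @pytest.mark.parametrize(
        "pos,pval,chrom,included",
        [
            (900_000, 1e-12, "1", True),  # lower boundary inclusive
            (1_150_000, 1e-12, "1", True),  # upper boundary inclusive
            (1_150_001, 1e-12, "1", False),  # one past the window
            (899_999, 1e-12, "1", False),
            (1_020_000, 6e-8, "1", False),  # threshold is strict <
            (1_020_000, 4.9e-8, "1", True),
            (1_020_000, 1e-12, "2", False),  # wrong chromosome
        ],
    )
    def test_window_and_threshold_policy(self, pos, pval, chrom, included):
        table = SummaryTable("x", [make_record(pos=pos, pval=pval, chrom=chrom)])
        result = select_cis_snps(table, TARGET, window_bp=100_000, p_threshold=5e-8)
        assert (len(result) == 1) == included

    def test_empty_result_is_valid(self):
        table = SummaryTable("x", [make_record(pos=5_000_000)])
        assert len(select_cis_snps(table, TARGET)) == 0

    def test_nesting_in_window_and_threshold(self, rng):
        """Wider windows and looser thresholds only ever add SNPs."""
        records = [
            make_record(
                snp_id=f"rs{i}",
                pos=int(rng.integers(500_000, 1_600_000)),
                pval=float(10 ** rng.uniform(-20, 0)),
            )
            for i in range(200)
        ]
        table = SummaryTable("x", records)
        prev_w = set()
        for w in (0, 50_000, 100_000, 300_000):
            ids = set(select_cis_snps(table, TARGET, window_bp=w).snp_ids())
            assert prev_w <= ids
            prev_w = ids
        prev_p = set()
        for p in (1e-12, 5e-8, 1e-4, 1.0):
            ids = set(select_cis_snps(table, TARGET, p_threshold=p).snp_ids())
            assert prev_p <= ids
            prev_p = ids


def _ld_frame(ids, entries):
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    np.fill_diagonal(mat.values, 1.0)
    for a, b, r2 in entries:
        mat.loc[a, b] = r2
        mat.loc[b, a] = r2
    return mat


def _clump_oracle_ok(candidates: SummaryTable, retained: SummaryTable, ld, thr) -> bool:
    """Exhaustive check of the greedy-clumping contract: all retained
    pairs are below threshold, and every discarded SNP has a
    better-ranked retained SNP at or above threshold."""
    rank = {r.snp_id: (r.pval, r.pos, r.snp_id) for r in candidates}
    kept = retained.snp_ids()
    for i, a in enumerate(kept):
        for b in kept[i + 1 :]:
            if float(ld.loc[a, b]) >= thr:
                return False
    discarded = [s for s in candidates.snp_ids() if s not in set(kept)]
    for d in discarded:
        if not any(float(ld.loc[d, k]) >= thr and rank[k] < rank[d] for k in kept):
            return False
    return True


class TestLdClump:
    def test_worked_example(self):
        """A beats B (r²=0.5); C independent of both -> {A, C}."""
        table = SummaryTable(
            "x",
            [
                make_record("A", pos=1, pval=1e-10),
                make_record("B", pos=2, pval=1e-9),
                make_record("C", pos=3, pval=1e-8),
            ],
        )
        ld = _ld_frame(["A", "B", "C"], [("A", "B", 0.5)])
        assert ld_clump(table, ld, r2_threshold=0.001).snp_ids() == ["A", "C"]

    def test_independent_snps_all_retained(self):
        table = SummaryTable("x", [make_record(f"rs{i}", pos=i + 1, pval=1e-9) for i in range(5)])
        ld = _ld_frame(table.snp_ids(), [])
        assert len(ld_clump(table, ld)) == 5

    def test_perfect_ld_keeps_smaller_p(self):
        table = SummaryTable(
            "x", [make_record("A", pos=1, pval=1e-8), make_record("B", pos=2, pval=1e-12)]
        )
        ld = _ld_frame(["A", "B"], [("A", "B", 1.0)])
        assert ld_clump(table, ld).snp_ids() == ["B"]

    def test_missing_snp_in_ld_matrix_names_it(self):
        table = SummaryTable("x", [make_record("A", pos=1), make_record("B", pos=2)])
        ld = _ld_frame(["A"], [])
        with pytest.raises(KeyError, match="'B'"):
            ld_clump(table, ld)

    def test_tie_break_by_position_then_id(self):
        table = SummaryTable(
            "x",
            [
                make_record("rsB", pos=10, pval=1e-9),
                make_record("rsA", pos=5, pval=1e-9),
            ],
        )
        ld = _ld_frame(["rsA", "rsB"], [("rsA", "rsB", 1.0)])
        assert ld_clump(table, ld).snp_ids() == ["rsA"]

    @given(st.integers(min_value=0, max_value=2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_exhaustive_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        j = int(rng.integers(1, 13))
        table = SummaryTable(
            "x",
            [
                make_record(
                    f"rs{i}",
                    pos=int(rng.integers(1, 1000)) * 10 + i,
                    pval=float(rng.choice([1e-10, 1e-9, 1e-8])),
                )
                for i in range(j)
            ],
        )
        r2 = rng.uniform(0, 1, (j, j)) * (rng.random((j, j)) < 0.4)
        r2 = np.triu(r2, 1)
        r2 = r2 + r2.T + np.eye(j)
        ld = pd.DataFrame(r2, index=table.snp_ids(), columns=table.snp_ids())
        thr = float(rng.choice([0.001, 0.1, 0.5]))
        retained = ld_clump(table, ld, r2_threshold=thr)
        assert _clump_oracle_ok(table, retained, ld, thr)


class TestFStatistics:
    def test_closed_forms_and_mean(self):
        table = SummaryTable(
            "x",
            [
                make_record("a", pos=1, beta=0.1, se=0.02),  # F = 25
                make_record("b", pos=2, beta=0.03, se=0.01),  # F = 9
            ],
        )
        f, mean_f = f_statistics(table)
        assert f == pytest.approx([25.0, 9.0])
        assert mean_f == pytest.approx(17.0)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="no instruments"):
            f_statistics(SummaryTable("x", []))

    def test_all_strong_implies_strong_mean(self, rng):
        records = [
            make_record(f"rs{i}", pos=i + 1, beta=float(b), se=0.01)
            for i, b in enumerate(rng.uniform(0.032, 0.3, 30))  # each F > 10
        ]
        _, mean_f = f_statistics(SummaryTable("x", records))
        assert mean_f > 10

    def test_r2_based_alternative(self):
        rec = make_record(beta=0.1, se=0.003, eaf=0.5, n=100_000.0)
        f, _ = f_statistics(SummaryTable("x", [rec]), method="r2")
        r2 = 2 * 0.5 * 0.5 * 0.1**2
        assert f[0] == pytest.approx(r2 * (100_000 - 2) / (1 - r2))


class TestBuildInstrumentSet:
    def test_recovers_planted_count(self):
        cfg = SimConfig(n_targets=1, j_snps=12, seed=42)
        exp, ctrl, _, ld, target, truth = simulate_target(cfg, 0)
        inst = build_instrument_set(exp, ctrl, target, ld)
        assert inst.n_snps == 12
        assert set(p.snp_id for p in inst.pairs) == set(truth.snp_ids)
        assert inst.mean_f > 10 and not inst.weak_instruments
        assert inst.provenance["n_cis_significant"] == 12

    def test_perfect_ld_pair_among_planted_removes_one(self):
        cfg = SimConfig(n_targets=1, j_snps=12, seed=42)
        exp, ctrl, _, ld, target, _ = simulate_target(cfg, 0)
        a, b = exp.records[0].snp_id, exp.records[1].snp_id
        ld.loc[a, b] = ld.loc[b, a] = 1.0
        inst = build_instrument_set(exp, ctrl, target, ld)
        assert inst.n_snps == 11

    def test_no_significant_snps_gives_empty_set(self):
        cfg = SimConfig(n_targets=1, j_snps=4, seed=1)
        exp, ctrl, _, ld, target, _ = simulate_target(cfg, 0)
        far_target = TargetSpec(
            gene_symbol="FAR", chrom=target.chrom,
            gene_start=target.gene_start + 50_000_000,
            gene_end=target.gene_end + 50_000_000,
            lipid_trait="LDL",
        )
        inst = build_instrument_set(exp, ctrl, far_target, ld)
        assert inst.n_snps == 0 and np.isnan(inst.mean_f)
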