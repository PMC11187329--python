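"""Sensitivity battery for the simulated study.

Re-runs the gated study, writes the per-target sensitivity summary
(Cochran Q/I2, Egger intercept, MR-PRESSO, leave-one-out robustness) to
results/sensitivity.tsv, and exports the funnel-plot scatter and
leave-one-out series for the gate-passed causal targets.
"""

from pathlib import Path

import pandas as pd

from lipidmr.gwas_io import read_summary_tsv
from lipidmr.pipeline import StudyConfig, Thresholds, render_sensitivity, run_study
from lipidmr.sensitivity import funnel_data

import importlib.util

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "synthetic_study"

_spec = importlib.util.spec_from_file_location("build_instruments", Path(__file__).parent / "02_build_instruments.py")
_mod = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_mod)
load_targets = _mod.load_targets


def main() -> None:
    cfg = StudyConfig(
        exposures={
            "LDL": read_summary_tsv(DATA / "exposure_ldl.tsv", trait_label="LDL"),
            "TG": read_summary_tsv(DATA / "exposure_tg.tsv", trait_label="TG"),
        },
        control_outcome=read_summary_tsv(DATA / "outcome_control.tsv"),
        disease_outcome=read_summary_tsv(DATA / "outcome_disease.tsv"),
        targets=load_targets(),
        ld=pd.read_csv(DATA / "ld_matrix.tsv", sep="\t", index_col=0),
        thresholds=Thresholds(presso_n_sim=500),
        seed=2024,
    )
    reports = run_study(cfg)
    out = render_sensitivity(reports, ROOT / "results" / "sensitivity.tsv")
    print(f"wrote {out}")

    export_dir = ROOT / "results" / "sensitivity_exports"
    export_dir.mkdir(parents=True, exist_ok=True)
    for r in reports:
        if not r.gate_passed or r.outcome_sensitivity is None:
            continue
        gene = r.target.gene_symbol
        funnel_data(r.outcome_instruments.pairs).to_csv(
            export_dir / f"{gene}_funnel.tsv", sep="\t", index=False
        )
        r.outcome_sensitivity.loo.rows.to_csv(
            export_dir / f"{gene}_leave_one_out.tsv", sep="\t", index=False
        )
        het = r.outcome_sensitivity.heterogeneity
        egg = r.outcome_sensitivity.egger_intercept
        pres = r.outcome_sensitivity.presso
        print(
            f"  {gene}: Q={het.q:.2f} (p={het.pval:.3f}, I2={het.i2:.1f}%), "
            f"Egger intercept={egg.intercept.beta:+.4f} (p={egg.intercept.pval:.3f}), "
            f"PRESSO global p={pres.global_pval:.3f}, outliers={sorted(pres.outliers) or 'none'}, "
            f"LOO robust={r.outcome_sensitivity.loo.robust}"
        )


if __name__ == "__main__":
    main()
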