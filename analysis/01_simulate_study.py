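"""Simulate the study's input data: a five-target synthetic panel.

Generates two-sample GWAS summary statistics for three LDL-trait and two
TG-trait drug-target genes, planting a positive-control effect
(theta_control = 0.4) at every target and a disease effect
(theta_disease = 0.5) at the first target of each trait only.  Writes
the exposure/outcome tables, LD matrix, target list and ground truth
under results/synthetic_study/.
"""

from pathlib import Path

import pandas as pd

from lipidmr.gwas_io import write_summary_tsv
from lipidmr.synthetic import SimConfig, simulate_study

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic_study"
SEED = 2024

CFG = SimConfig(
    n_targets=5,
    j_snps=12,
    lipid_traits=("LDL", "LDL", "LDL", "TG", "TG"),
    theta_control=0.4,
    theta_disease=(0.5, 0.0, 0.0, 0.5, 0.0),
    palindromic_fraction=0.2,
    seed=SEED,
)


def main() -> None:
    study, truth = simulate_study(CFG)
    OUT.mkdir(parents=True, exist_ok=True)
    for trait, table in study.exposures.items():
        write_summary_tsv(table, OUT / f"exposure_{trait.lower()}.tsv")
    write_summary_tsv(study.control_outcome, OUT / "outcome_control.tsv")
    write_summary_tsv(study.disease_outcome, OUT / "outcome_disease.tsv")
    study.ld.to_csv(OUT / "ld_matrix.tsv", sep="\t")
    pd.DataFrame(
        [
            {
                "gene_symbol": t.gene_symbol,
                "chrom": t.chrom,
                "gene_start": t.gene_start,
                "gene_end": t.gene_end,
                "lipid_trait": t.lipid_trait,
                "drug_label": t.drug_label,
            }
            for t in study.targets
        ]
    ).to_csv(OUT / "targets.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "gene_symbol": gene,
                "lipid_trait": next(t.lipid_trait for t in study.targets if t.gene_symbol == gene),
                "theta_control": tr.theta_control,
                "theta_disease": tr.theta_disease,
                "n_planted_snps": len(tr.snp_ids),
            }
            for gene, tr in truth.per_target.items()
        ]
    ).to_csv(OUT / "ground_truth.tsv", sep="\t", index=False)

    print(f"seed {SEED}: simulated {len(study.targets)} targets, "
          f"{sum(len(v) for v in study.exposures.values())} exposure SNPs "
          f"({CFG.j_snps} instruments + {CFG.n_decoys} decoys per target)")
    for gene, tr in truth.per_target.items():
        print(f"  {gene}: theta_control={tr.theta_control} theta_disease={tr.theta_disease}")
    print(f"wrote tables to {OUT}")


if __name__ == "__main__":
    main()
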