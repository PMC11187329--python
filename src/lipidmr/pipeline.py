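"""Two-stage gated drug-target MR workflow over a panel of targets.

For each drug-target gene, instruments are built from the matching lipid
exposure GWAS and first taken to a positive-control outcome with an
established causal relationship (coronary heart disease for
lipid-lowering).  Only targets whose control IVW estimate is significant
proceed to the disease outcome of interest; instruments are
re-harmonized against each outcome, so counts may differ between
stages.  Rendering reproduces the standard results-table schema
(Targets, F, SNP n, Beta (95%CI), Se, OR (95%CI), p).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gwas_io import SummaryTable
from .instruments import InstrumentSet, TargetSpec, build_instrument_set
from .mr_core import MrResult, ivw
from .sensitivity import SensitivityReport, sensitivity_report

__all__ = [
    "Thresholds",
    "StudyConfig",
    "TargetReport",
    "run_target",
    "run_study",
    "render_tables",
    "render_sensitivity",
    "format_p",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """All tunable cut-offs of the workflow, with conventional defaults."""

    p_threshold: float = 5e-8
    window_bp: int = 100_000
    r2_threshold: float = 0.001
    f_threshold: float = 10.0
    gate_alpha: float = 0.05
    palindrome_eaf_window: float = 0.08
    ivw_mode: str = "multiplicative_random"
    presso_n_sim: int = 1000


@dataclass
class StudyConfig:
    """Inputs of a full gated study.

    ``exposures`` maps lipid trait ("LDL"/"TG") to its exposure GWAS;
    every target's ``lipid_trait`` must have a matching entry.  ``ld``
    is one square r² matrix covering all exposure SNPs.
    """

    exposures: dict[str, SummaryTable]
    control_outcome: SummaryTable
    disease_outcome: SummaryTable
    targets: list[TargetSpec]
    ld: pd.DataFrame
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    def validate(self) -> None:
        for t in self.targets:
            if t.lipid_trait not in self.exposures:
                raise ValueError(
                    f"target {t.gene_symbol}: no exposure table for trait {t.lipid_trait!r}"
                )


@dataclass
class TargetReport:
    """Everything computed for one target across both stages."""

    target: TargetSpec
    control_instruments: InstrumentSet | None = None
    control_result: MrResult | None = None
    control_sensitivity: SensitivityReport | None = None
    gate_passed: bool = False
    outcome_instruments: InstrumentSet | None = None
    outcome_result: MrResult | None = None
    outcome_sensitivity: SensitivityReport | None = None
    error: str | None = None


def _stage_seed(seed: int, gene: str, stage: str) -> int:
    return zlib.adler32(f"{seed}:{gene}:{stage}".encode()) & 0x7FFFFFFF


def run_target(cfg: StudyConfig, target: TargetSpec) -> TargetReport:
    """Run the gated two-stage analysis for one target.

    Stage 1 builds instruments against the positive-control outcome and
    estimates the control IVW effect; the gate passes iff the set is
    nonempty and the control p-value is below ``gate_alpha``.  Stage 2
    (only when gated through) rebuilds/re-harmonizes the instruments
    against the disease outcome and repeats estimation plus the full
    sensitivity battery.
    """
    cfg.validate()
    th = cfg.thresholds
    exposure = cfg.exposures[target.lipid_trait]
    report = TargetReport(target=target)

    control_set = build_instrument_set(
        exposure,
        cfg.control_outcome,
        target,
        cfg.ld,
        window_bp=th.window_bp,
        p_threshold=th.p_threshold,
        r2_threshold=th.r2_threshold,
        palindrome_eaf_window=th.palindrome_eaf_window,
    )
    report.control_instruments = control_set
    if control_set.n_snps == 0:
        log.info("%s: no instruments — blank row, gate closed", target.gene_symbol)
        return report
    report.control_result = ivw(control_set.pairs, mode=th.ivw_mode)
    report.control_sensitivity = sensitivity_report(
        control_set.pairs,
        n_sim=th.presso_n_sim,
        seed=_stage_seed(cfg.seed, target.gene_symbol, "control"),
    )
    report.gate_passed = report.control_result.pval < th.gate_alpha
    log.info(
        "%s: control IVW beta=%.3f p=%.3g — gate %s",
        target.gene_symbol,
        report.control_result.beta,
        report.control_result.pval,
        "passed" if report.gate_passed else "closed",
    )
    if not report.gate_passed:
        return report

    outcome_set = build_instrument_set(
        exposure,
        cfg.disease_outcome,
        target,
        cfg.ld,
        window_bp=th.window_bp,
        p_threshold=th.p_threshold,
        r2_threshold=th.r2_threshold,
        palindrome_eaf_window=th.palindrome_eaf_window,
    )
    report.outcome_instruments = outcome_set
    if outcome_set.n_snps == 0:
        log.warning("%s: instruments lost in disease-outcome harmonization", target.gene_symbol)
        return report
    report.outcome_result = ivw(outcome_set.pairs, mode=th.ivw_mode)
    report.outcome_sensitivity = sensitivity_report(
        outcome_set.pairs,
        n_sim=th.presso_n_sim,
        seed=_stage_seed(cfg.seed, target.gene_symbol, "disease"),
    )
    return report


def run_study(cfg: StudyConfig) -> list[TargetReport]:
    """Run every target in configuration order; one target's failure is
    recorded on its report and does not abort the others."""
    cfg.validate()
    reports = []
    for target in cfg.targets:
        try:
            reports.append(run_target(cfg, target))
        except Exception as exc:  # noqa: BLE001 — per-target isolation
            log.error("%s: failed (%s)", target.gene_symbol, exc)
            reports.append(TargetReport(target=target, error=str(exc)))
    n_gate = sum(r.gate_passed for r in reports)
    log.info("study complete: %d/%d targets passed the positive-control gate", n_gate, len(reports))
    return reports


def format_p(p: float) -> str:
    """p to 3 decimals, or 2-digit scientific notation below 0.001."""
    return f"{p:.2E}" if p < 0.001 else f"{p:.3f}"


def _result_row(gene: str, mean_f: float | None, res: MrResult | None, n_snps: int) -> dict:
    if res is None:
        return {
            "Targets": gene,
            "F": "",
            "SNP_n": n_snps,
            "Beta_95CI": "",
            "Se": "",
            "OR_95CI": "",
            "p": "",
        }
    return {
        "Targets": gene,
        "F": "" if mean_f is None or np.isnan(mean_f) else f"{mean_f:.4f}",
        "SNP_n": n_snps,
        "Beta_95CI": f"{res.beta:.3f} ({res.ci_low:.3f}, {res.ci_high:.3f})",
        "Se": f"{res.se:.3f}",
        "OR_95CI": f"{res.or_value:.3f} ({res.or_ci_low:.3f}, {res.or_ci_high:.3f})",
        "p": format_p(res.pval),
    }


def render_tables(reports: Sequence[TargetReport], out_dir: str | Path) -> dict[str, Path]:
    """Write the four results tables (control/disease x LDL/TG) as TSV.

    Control tables carry one row per configured target (blank where no
    instruments survived); disease tables carry only gate-passed
    targets, mirroring the two-stage design.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    columns = ["Targets", "F", "SNP_n", "Beta_95CI", "Se", "OR_95CI", "p"]
    for trait in ("LDL", "TG"):
        trait_reports = [r for r in reports if r.target.lipid_trait == trait]
        if not trait_reports:
            continue
        control_rows = []
        disease_rows = []
        for r in trait_reports:
            inst = r.control_instruments
            n = inst.n_snps if inst is not None else 0
            mean_f = inst.mean_f if inst is not None else None
            control_rows.append(_result_row(r.target.gene_symbol, mean_f, r.control_result, n))
            if r.gate_passed and r.outcome_result is not None:
                oinst = r.outcome_instruments
                disease_rows.append(
                    _result_row(r.target.gene_symbol, oinst.mean_f, r.outcome_result, oinst.n_snps)
                )
        for stage, rows in (("control", control_rows), ("disease", disease_rows)):
            name = f"{stage}_{trait.lower()}.tsv"
            path = out_dir / name
            pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
            written[name] = path
    return written


def render_sensitivity(reports: Sequence[TargetReport], path: str | Path) -> Path:
    """One-row-per-(target, stage) sensitivity summary as TSV."""
    rows = []
    for r in reports:
        for stage, sens in (("control", r.control_sensitivity), ("disease", r.outcome_sensitivity)):
            if sens is None:
                continue
            het = sens.heterogeneity
            egg = sens.egger_intercept
            pres = sens.presso
            rows.append(
                {
                    "Target": r.target.gene_symbol,
                    "trait": r.target.lipid_trait,
                    "stage": stage,
                    "Q": None if het is None else round(het.q, 4),
                    "Q_df": None if het is None else het.df,
                    "Q_pval": None if het is None else round(het.pval, 4),
                    "I2": None if het is None else round(het.i2, 3),
                    "egger_intercept": None if egg is None else round(egg.intercept.beta, 5),
                    "egger_intercept_p": None if egg is None else round(egg.intercept.pval, 4),
                    "presso_global_p": None if pres is None else round(pres.global_pval, 4),
                    "presso_outliers": None if pres is None else ",".join(sorted(pres.outliers)),
                    "loo_robust": None if sens.loo is None else sens.loo.robust,
                }
            )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
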