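"""Synthetic two-sample GWAS summary statistics with known ground truth.

Summary statistics are simulated directly (no individual-level
genotypes): for SNP j with effect-allele frequency f_j and sample size
n, the standard error of a standardized per-allele effect is
se_j = 1/sqrt(2 f_j (1−f_j) n), and the estimated effect is a normal
draw around the truth.  Outcome effects follow the instrumental-variable
model β_Yj = θ·β_Xj + α_j, with the pleiotropy offsets α_j set by the
chosen regime; exposure and outcome draws are independent, matching the
non-overlapping two-sample design.  LD enters only through the r²
matrix handed to clumping; estimator noise stays independent across
SNPs (a documented simplification).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_io import GwasRecord, HarmonizedPair, SummaryTable
from .instruments import TargetSpec
from .pipeline import StudyConfig, Thresholds

__all__ = [
    "PleiotropyRegime",
    "SimConfig",
    "TargetTruth",
    "StudyTruth",
    "gwas_se",
    "block_ld_matrix",
    "simulate_pairs",
    "simulate_target",
    "simulate_study",
]

_NON_PALINDROMIC = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class PleiotropyRegime:
    """Distribution of the direct (non-exposure-mediated) outcome effects.

    ``none``: α_j = 0; ``balanced``: α_j ~ N(0, sigma²) (InSIDE holds,
    mean zero); ``directional``: α_j ~ N(mu, sigma²) (average pleiotropy
    mu, what the Egger intercept estimates).
    """

    mode: str = "none"
    mu: float = 0.0
    sigma: float = 0.0

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.mode == "none":
            return np.zeros(size)
        if self.mode == "balanced":
            return rng.normal(0.0, self.sigma, size)
        if self.mode == "directional":
            return rng.normal(self.mu, self.sigma, size)
        raise ValueError(f"unknown pleiotropy mode {self.mode!r}")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator.

    Sample sizes default to the magnitudes of the real datasets the
    generator stands in for (lipid exposure 188,577; control outcome
    60,801 + 123,504; disease outcome 1,092 + 211,139 — totals used).
    Exposure effects |β_X| ~ U[0.08, 0.15] with random sign, which at
    those sample sizes yields genome-wide-significant instruments with
    per-SNP F in the hundreds, matching the reported mean-F magnitudes.
    """

    n_targets: int = 5
    j_snps: int = 12
    gene_length: int = 50_000
    window_bp: int = 100_000
    beta_low: float = 0.08
    beta_high: float = 0.15
    eaf_low: float = 0.05
    eaf_high: float = 0.95
    n_exposure: int = 188_577
    n_control: int = 184_305
    n_disease: int = 212_231
    theta_control: float | tuple = 0.4
    theta_disease: float | tuple = 0.0
    pleiotropy: PleiotropyRegime = field(default_factory=PleiotropyRegime)
    n_outliers: int = 0
    outlier_offset: float = 0.0
    ld_block_size: int = 1
    ld_within_block_r2: float = 0.0
    palindromic_fraction: float = 0.1
    n_decoys: int = 20
    lipid_traits: tuple | None = None  # per-target; default all "LDL"
    seed: int = 0

    def __post_init__(self):
        if self.n_targets < 0 or self.j_snps < 1:
            raise ValueError("n_targets must be >= 0 and j_snps >= 1")
        if not (0 < self.eaf_low < self.eaf_high < 1):
            raise ValueError("eaf bounds must satisfy 0 < low < high < 1")
        if self.beta_low <= 0 or self.beta_high < self.beta_low:
            raise ValueError("beta bounds must satisfy 0 < low <= high")
        if min(self.n_exposure, self.n_control, self.n_disease) < 2:
            raise ValueError("sample sizes must be >= 2")
        if not 0 <= self.palindromic_fraction <= 1:
            raise ValueError("palindromic_fraction must be in [0, 1]")
        if self.ld_block_size < 1 or not 0 <= self.ld_within_block_r2 <= 1:
            raise ValueError("invalid LD block specification")

    def theta_for(self, which: str, index: int) -> float:
        value = self.theta_control if which == "control" else self.theta_disease
        if isinstance(value, (tuple, list)):
            return float(value[index])
        return float(value)

    def trait_for(self, index: int) -> str:
        if self.lipid_traits is None:
            return "LDL"
        return self.lipid_traits[index]


@dataclass
class TargetTruth:
    """Ground truth planted for one target."""

    theta_control: float
    theta_disease: float
    snp_ids: list[str]
    beta_x: np.ndarray
    alpha: np.ndarray  # disease-outcome pleiotropy offsets
    outlier_ids: list[str]
    ld_blocks: list[list[str]]


@dataclass
class StudyTruth:
    per_target: dict[str, TargetTruth]


def gwas_se(eaf: np.ndarray | float, n: float) -> np.ndarray | float:
    """Standard error of a standardized per-allele GWAS effect:
    1/sqrt(2·eaf·(1−eaf)·n)."""
    return 1.0 / np.sqrt(2.0 * np.asarray(eaf) * (1.0 - np.asarray(eaf)) * n)


def block_ld_matrix(snp_ids: Sequence[str], blocks: Sequence[Sequence[str]], r2: float) -> pd.DataFrame:
    """Square r² matrix: unit diagonal, ``r2`` within each block, 0 elsewhere."""
    ids = list(snp_ids)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    np.fill_diagonal(mat.values, 1.0)
    for block in blocks:
        for a in block:
            for b in block:
                if a != b:
                    mat.loc[a, b] = r2
    return mat


def simulate_pairs(
    j: int,
    theta: float,
    *,
    n_exposure: int = 188_577,
    n_outcome: int = 212_231,
    beta_low: float = 0.08,
    beta_high: float = 0.15,
    eaf_low: float = 0.05,
    eaf_high: float = 0.95,
    pleiotropy: PleiotropyRegime | None = None,
    n_outliers: int = 0,
    outlier_offset: float = 0.0,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[list[HarmonizedPair], dict]:
    """Directly simulate J harmonized exposure/outcome pairs.

    The estimator-level workhorse: skips table I/O and harmonization and
    returns ready-to-use pairs plus the planted truth (true per-SNP
    exposure effects, pleiotropy offsets, outlier indices).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pleiotropy = pleiotropy or PleiotropyRegime()
    eaf = rng.uniform(eaf_low, eaf_high, j)
    beta_x = rng.uniform(beta_low, beta_high, j) * rng.choice([-1.0, 1.0], j)
    se_x = np.asarray(gwas_se(eaf, n_exposure))
    se_y = np.asarray(gwas_se(eaf, n_outcome))
    alpha = pleiotropy.draw(rng, j)
    outlier_idx = rng.choice(j, size=n_outliers, replace=False) if n_outliers else np.array([], int)
    offset = np.zeros(j)
    offset[outlier_idx] = outlier_offset
    bx_hat = rng.normal(beta_x, se_x)
    # pleiotropy offsets act on the exposure-increasing allele: the sign
    # flip keeps "directional" meaning directional after allele coding
    orient = np.sign(beta_x)
    by_hat = rng.normal(theta * beta_x + orient * (alpha + offset), se_y)
    pairs = [
        HarmonizedPair(
            snp_id=f"rs{k}",
            beta_exposure=float(bx_hat[k]),
            se_exposure=float(se_x[k]),
            beta_outcome=float(by_hat[k]),
            se_outcome=float(se_y[k]),
            eaf_exposure=float(eaf[k]),
            action="kept",
        )
        for k in range(j)
    ]
    truth = {
        "theta": theta,
        "beta_x": beta_x,
        "alpha": alpha,
        "outlier_idx": outlier_idx,
        "eaf": eaf,
    }
    return pairs, truth


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(z))
    return np.clip(p, np.nextafter(0, 1), 1.0)


def simulate_target(
    cfg: SimConfig,
    target_index: int,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[SummaryTable, SummaryTable, SummaryTable, pd.DataFrame, TargetSpec, TargetTruth]:
    """Simulate one target's exposure, control and disease tables plus LD.

    Plants ``j_snps`` genome-wide-significant SNPs inside the cis window
    of a synthetic gene region (one chromosome per target) and
    ``n_decoys`` null SNPs outside it.  Palindromic instruments receive
    frequencies away from 0.5 so that frequency-based strand alignment
    stays unambiguous; roughly half of the outcome rows are written in
    the opposite allele orientation (labels swapped, beta negated,
    frequency complemented) to exercise harmonization.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed if seed is None else seed)
    chrom = str((target_index % 22) + 1)
    gene_start = 50_000_000 + target_index * 10_000_000
    gene_end = gene_start + cfg.gene_length
    target = TargetSpec(
        gene_symbol=f"GENE{target_index}",
        chrom=chrom,
        gene_start=gene_start,
        gene_end=gene_end,
        lipid_trait=cfg.trait_for(target_index),
        drug_label=f"synthetic-drug-{target_index}",
    )

    j = cfg.j_snps
    prefix = f"rs{target_index}_"
    ids = [f"{prefix}{k}" for k in range(j)]
    pos = rng.choice(
        np.arange(gene_start - cfg.window_bp, gene_end + cfg.window_bp + 1),
        size=j,
        replace=False,
    )
    n_pal = int(round(cfg.palindromic_fraction * j))
    pal_mask = np.zeros(j, bool)
    if n_pal:
        pal_mask[rng.choice(j, size=n_pal, replace=False)] = True
    eaf = rng.uniform(cfg.eaf_low, cfg.eaf_high, j)
    # keep palindromic instruments resolvable by frequency
    margin = 0.15
    for k in np.where(pal_mask)[0]:
        side = rng.choice([-1.0, 1.0])
        eaf[k] = rng.uniform(cfg.eaf_low, max(cfg.eaf_low + 0.01, 0.5 - margin))
        if side > 0:
            eaf[k] = 1.0 - eaf[k]
    beta_x = rng.uniform(cfg.beta_low, cfg.beta_high, j) * rng.choice([-1.0, 1.0], j)
    se_x = np.asarray(gwas_se(eaf, cfg.n_exposure))
    bx_hat = rng.normal(beta_x, se_x)
    px = _two_sided_p(bx_hat / se_x)

    alleles = []
    for k in range(j):
        pool = _PALINDROMIC if pal_mask[k] else _NON_PALINDROMIC
        alleles.append(pool[rng.integers(len(pool))])

    theta_c = cfg.theta_for("control", target_index)
    theta_d = cfg.theta_for("disease", target_index)
    alpha = cfg.pleiotropy.draw(rng, j)
    outlier_idx = (
        rng.choice(j, size=cfg.n_outliers, replace=False) if cfg.n_outliers else np.array([], int)
    )
    offset = np.zeros(j)
    offset[outlier_idx] = cfg.outlier_offset

    se_yc = np.asarray(gwas_se(eaf, cfg.n_control))
    se_yd = np.asarray(gwas_se(eaf, cfg.n_disease))
    byc_hat = rng.normal(theta_c * beta_x, se_yc)
    # pleiotropy/outlier offsets oriented to the exposure-increasing allele
    byd_hat = rng.normal(theta_d * beta_x + np.sign(beta_x) * (alpha + offset), se_yd)

    # decoys: null SNPs outside the cis window
    n_dec = cfg.n_decoys
    dec_ids = [f"{prefix}decoy{k}" for k in range(n_dec)]
    dec_pos = rng.choice(
        np.arange(gene_end + cfg.window_bp + 10_000, gene_end + cfg.window_bp + 1_010_000),
        size=n_dec,
        replace=False,
    ) if n_dec else np.array([], int)
    dec_eaf = rng.uniform(cfg.eaf_low, cfg.eaf_high, n_dec)
    dec_se_x = np.asarray(gwas_se(dec_eaf, cfg.n_exposure)) if n_dec else np.array([])
    dec_bx = rng.normal(0.0, dec_se_x) if n_dec else np.array([])
    dec_alleles = [_NON_PALINDROMIC[rng.integers(len(_NON_PALINDROMIC))] for _ in range(n_dec)]

    def exposure_records():
        recs = []
        for k in range(j):
            recs.append(
                GwasRecord(
                    snp_id=ids[k],
                    chrom=chrom,
                    pos=int(pos[k]),
                    effect_allele=alleles[k][0],
                    other_allele=alleles[k][1],
                    beta=float(bx_hat[k]),
                    se=float(se_x[k]),
                    pval=float(px[k]),
                    eaf=float(eaf[k]),
                    n=float(cfg.n_exposure),
                )
            )
        for k in range(n_dec):
            z = dec_bx[k] / dec_se_x[k]
            recs.append(
                GwasRecord(
                    snp_id=dec_ids[k],
                    chrom=chrom,
                    pos=int(dec_pos[k]),
                    effect_allele=dec_alleles[k][0],
                    other_allele=dec_alleles[k][1],
                    beta=float(dec_bx[k]),
                    se=float(dec_se_x[k]),
                    pval=float(_two_sided_p(np.array([z]))[0]),
                    eaf=float(dec_eaf[k]),
                    n=float(cfg.n_exposure),
                )
            )
        return recs

    def outcome_records(by_hat, se_y, n_total, flip_mask):
        recs = []
        for k in range(j):
            ea, oa = alleles[k]
            beta = float(by_hat[k])
            f = float(eaf[k])
            if flip_mask[k]:
                ea, oa = oa, ea
                beta = -beta
                f = 1.0 - f
            z = beta / se_y[k]
            recs.append(
                GwasRecord(
                    snp_id=ids[k],
                    chrom=chrom,
                    pos=int(pos[k]),
                    effect_allele=ea,
                    other_allele=oa,
                    beta=beta,
                    se=float(se_y[k]),
                    pval=float(_two_sided_p(np.array([z]))[0]),
                    eaf=f,
                    n=float(n_total),
                )
            )
        return recs

    flip_c = rng.random(j) < 0.5
    flip_d = rng.random(j) < 0.5
    exposure = SummaryTable(f"{target.lipid_trait}_exposure", exposure_records())
    control = SummaryTable("control_outcome", outcome_records(byc_hat, se_yc, cfg.n_control, flip_c))
    disease = SummaryTable("disease_outcome", outcome_records(byd_hat, se_yd, cfg.n_disease, flip_d))

    blocks = [
        ids[b : b + cfg.ld_block_size] for b in range(0, j, cfg.ld_block_size)
    ] if cfg.ld_block_size > 1 else [[i] for i in ids]
    # decoys never become clumping candidates (null or out-of-window),
    # so the matrix covers the plantable instruments only
    ld = block_ld_matrix(ids, [b for b in blocks if len(b) > 1], cfg.ld_within_block_r2)

    truth = TargetTruth(
        theta_control=theta_c,
        theta_disease=theta_d,
        snp_ids=ids,
        beta_x=beta_x,
        alpha=alpha,
        outlier_ids=[ids[k] for k in outlier_idx],
        ld_blocks=[list(b) for b in blocks if len(b) > 1],
    )
    return exposure, control, disease, ld, target, truth


def simulate_study(cfg: SimConfig, seed: int | None = None) -> tuple[StudyConfig, StudyTruth]:
    """Assemble a full multi-target study with known ground truth.

    Per-target tables are concatenated into per-trait exposure tables
    and shared control/disease outcome tables; the LD matrix is
    block-diagonal across targets.  ``cfg.theta_disease`` may be a
    per-target sequence to plant causal effects at chosen targets only.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    exposures: dict[str, list[GwasRecord]] = {}
    control_records: list[GwasRecord] = []
    disease_records: list[GwasRecord] = []
    targets: list[TargetSpec] = []
    truths: dict[str, TargetTruth] = {}
    ld_parts: list[pd.DataFrame] = []
    for i in range(cfg.n_targets):
        exp, ctrl, dis, ld, target, truth = simulate_target(cfg, i, rng=rng)
        targets.append(target)
        truths[target.gene_symbol] = truth
        exposures.setdefault(target.lipid_trait, []).extend(exp.records)
        control_records.extend(ctrl.records)
        disease_records.extend(dis.records)
        ld_parts.append(ld)

    if ld_parts:
        all_ids = [i for part in ld_parts for i in part.index]
        ld_full = pd.DataFrame(0.0, index=all_ids, columns=all_ids)
        for part in ld_parts:
            ld_full.loc[part.index, part.columns] = part.values
    else:
        ld_full = pd.DataFrame()

    study = StudyConfig(
        exposures={
            trait: SummaryTable(f"{trait}_exposure", recs) for trait, recs in exposures.items()
        },
        control_outcome=SummaryTable("control_outcome", control_records),
        disease_outcome=SummaryTable("disease_outcome", disease_records),
        targets=targets,
        ld=ld_full,
        thresholds=Thresholds(),
        seed=int(rng.integers(2**31)),
    )
    return study, StudyTruth(per_target=truths)
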