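"""Genetic-instrument construction for a drug-target gene.

Instruments are cis variants: genome-wide-significant SNPs within a
fixed window of the gene body encoding the drug's protein target, pruned
to approximate linkage-equilibrium by greedy clumping and screened for
instrument strength with per-SNP F statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas_io import HarmonizedPair, SummaryTable, harmonize, kept_pairs

__all__ = [
    "TargetSpec",
    "InstrumentSet",
    "select_cis_snps",
    "ld_clump",
    "f_statistics",
    "build_instrument_set",
    "cis_window_bed",
]

log = logging.getLogger(__name__)

#: conventional weak-instrument threshold on the mean F statistic
F_WEAK_THRESHOLD = 10.0


@dataclass(frozen=True)
class TargetSpec:
    """A drug-target gene with its genomic region and trait annotation.

    ``lipid_trait`` names the exposure the target's instruments proxy:
    ``"LDL"`` (LDL cholesterol, SD units) or ``"TG"`` (triglycerides).
    Coordinates are 1-based inclusive gene-body bounds.
    """

    gene_symbol: str
    chrom: str
    gene_start: int
    gene_end: int
    lipid_trait: str
    drug_label: str = ""

    def __post_init__(self):
        if self.gene_start > self.gene_end:
            raise ValueError(f"{self.gene_symbol}: gene_start > gene_end")
        if self.lipid_trait not in ("LDL", "TG"):
            raise ValueError(f"{self.gene_symbol}: lipid_trait must be 'LDL' or 'TG'")


@dataclass
class InstrumentSet:
    """Harmonized exposure/outcome pairs passing cis selection, with F.

    ``provenance`` records the SNP count at every pipeline stage
    (cis-significant, post-clump, post-harmonization).
    """

    target: TargetSpec
    pairs: list[HarmonizedPair]
    f_per_snp: np.ndarray
    mean_f: float
    weak_instruments: bool
    provenance: dict = field(default_factory=dict)

    @property
    def n_snps(self) -> int:
        return len(self.pairs)


def select_cis_snps(
    table: SummaryTable,
    target: TargetSpec,
    window_bp: int = 100_000,
    p_threshold: float = 5e-8,
) -> SummaryTable:
    """Genome-wide-significant SNPs within the cis window of the target.

    The window is anchored to the gene body: positions in
    ``[gene_start - window_bp, gene_end + window_bp]``, boundaries
    inclusive; the significance filter is strict (``pval < p_threshold``).
    An empty result is a valid outcome (a target with no usable proxy).
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    lo = target.gene_start - window_bp
    hi = target.gene_end + window_bp
    return table.filter(
        lambda r: r.chrom == target.chrom and lo <= r.pos <= hi and r.pval < p_threshold
    )


def ld_clump(
    candidates: SummaryTable,
    ld: pd.DataFrame,
    r2_threshold: float = 0.001,
) -> SummaryTable:
    """Greedy LD clumping keyed by p-value.

    Candidates are ranked by ascending p-value (ties broken by ascending
    position, then lexicographic snp_id); the best remaining SNP is
    retained and every remaining SNP with r² >= ``r2_threshold`` against
    it is discarded, until none remain.  Returns the retained SNPs in
    retention order.

    ``ld`` is a square r² matrix (DataFrame) indexed by snp_id on both
    axes; it must cover every candidate.
    """
    for snp_id in candidates.snp_ids():
        if snp_id not in ld.index or snp_id not in ld.columns:
            raise KeyError(f"SNP {snp_id!r} missing from the LD matrix")

    ranked = sorted(candidates, key=lambda r: (r.pval, r.pos, r.snp_id))
    retained = []
    remaining = list(ranked)
    while remaining:
        best = remaining.pop(0)
        retained.append(best)
        row = ld.loc[best.snp_id]
        remaining = [r for r in remaining if float(row[r.snp_id]) < r2_threshold]
    return SummaryTable(candidates.trait_label, retained)


def f_statistics(
    snps: SummaryTable | Sequence[HarmonizedPair],
    method: str = "wald",
) -> tuple[np.ndarray, float]:
    """Per-SNP instrument-strength F statistics and their mean.

    The default is the squared Wald statistic F = (beta/se)² on the
    exposure association.  ``method="r2"`` uses the variance-explained
    form F = R²(n−2)/(1−R²) with R² = 2·eaf(1−eaf)·beta² (standardized
    trait); it requires eaf and n on every record and is provided as an
    alternative, not the default.

    Mean F <= 10 conventionally flags a weak instrument set (the caller
    decides what to do with the flag).
    """
    records = list(snps)
    if not records:
        raise ValueError("no instruments: cannot compute F statistics")
    if method == "wald":
        if isinstance(records[0], HarmonizedPair):
            f = np.array([(p.beta_exposure / p.se_exposure) ** 2 for p in records])
        else:
            f = np.array([(r.beta / r.se) ** 2 for r in records])
    elif method == "r2":
        f = []
        for r in records:
            if isinstance(r, HarmonizedPair):
                raise ValueError("method='r2' needs full records with eaf and n")
            if r.eaf is None or r.n is None:
                raise ValueError(f"{r.snp_id}: method='r2' requires eaf and n")
            r2 = 2 * r.eaf * (1 - r.eaf) * r.beta**2
            if not (0 <= r2 < 1):
                raise ValueError(f"{r.snp_id}: variance explained {r2:.3g} outside [0, 1)")
            f.append(r2 * (r.n - 2) / (1 - r2))
        f = np.array(f)
    else:
        raise ValueError(f"unknown F-statistic method {method!r}")
    return f, float(f.mean())


def build_instrument_set(
    exposure: SummaryTable,
    outcome: SummaryTable,
    target: TargetSpec,
    ld: pd.DataFrame,
    *,
    window_bp: int = 100_000,
    p_threshold: float = 5e-8,
    r2_threshold: float = 0.001,
    palindrome_eaf_window: float = 0.08,
    f_method: str = "wald",
) -> InstrumentSet:
    """Compose cis selection, clumping, harmonization and F screening.

    Selection runs on the exposure table before harmonization, so SNPs
    unavailable in (or irreconcilable with) the outcome reduce the final
    instrument count.  A zero-SNP result is returned as an empty set,
    never as an error.
    """
    cis = select_cis_snps(exposure, target, window_bp=window_bp, p_threshold=p_threshold)
    clumped = ld_clump(cis, ld, r2_threshold=r2_threshold) if len(cis) else cis
    pairs = harmonize(clumped, outcome, palindrome_eaf_window=palindrome_eaf_window)
    usable = kept_pairs(pairs)
    provenance = {
        "n_cis_significant": len(cis),
        "n_after_clump": len(clumped),
        "n_harmonized": len(usable),
        "n_dropped_palindromic": sum(p.action == "dropped_palindromic" for p in pairs),
        "n_dropped_mismatch": sum(p.action == "dropped_mismatch" for p in pairs),
        "n_missing_in_outcome": len(clumped) - len(pairs),
    }
    log.info(
        "%s: %d cis-significant -> %d after clumping -> %d harmonized",
        target.gene_symbol,
        len(cis),
        len(clumped),
        len(usable),
    )
    if not usable:
        return InstrumentSet(
            target=target,
            pairs=[],
            f_per_snp=np.array([]),
            mean_f=math.nan,
            weak_instruments=False,
            provenance=provenance,
        )
    if f_method == "wald":
        f, mean_f = f_statistics(usable, method="wald")
    else:
        retained_ids = {p.snp_id for p in usable}
        f, mean_f = f_statistics(
            clumped.filter(lambda r: r.snp_id in retained_ids), method=f_method
        )
    weak = mean_f <= F_WEAK_THRESHOLD
    if weak:
        log.warning("%s: mean F = %.2f <= %.0f — weak instrument set", target.gene_symbol, mean_f, F_WEAK_THRESHOLD)
    return InstrumentSet(
        target=target,
        pairs=usable,
        f_per_snp=f,
        mean_f=mean_f,
        weak_instruments=weak,
        provenance=provenance,
    )


def cis_window_bed(targets: Sequence[TargetSpec], window_bp: int = 100_000) -> str:
    """BED (0-based half-open) text for the cis windows of ``targets``."""
    lines = []
    for t in targets:
        start0 = max(0, t.gene_start - window_bp - 1)
        end = t.gene_end + window_bp
        lines.append(f"{t.chrom}\t{start0}\t{end}\t{t.gene_symbol}")
    return "\n".join(lines) + "\n"
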