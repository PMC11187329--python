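"""Packaged configuration data: the drug-target panel and the published
summary estimates used as the reporting-transform reference.

``targets_grch37.tsv`` lists the nine lipid drug-target genes (eight
LDL-trait rows, five TG-trait rows; ANGPTL3, PPARA, LDLR and LPL appear
under both traits) with approximate GRCh37 gene-body coordinates.

``reference_estimates.tsv`` holds the previously reported IVW rows
(target, instrument count, β, se, CI, OR, p) for the positive-control
(coronary heart disease) and disease (acne vulgaris) stages; it is the
machine-checked surface for the β→OR/p reporting transforms and for the
positive-control gate.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .instruments import TargetSpec

__all__ = [
    "load_targets",
    "load_reference_estimates",
    "parse_reported_p",
    "reported_gate",
]


def _data_path(name: str):
    return resources.files("lipidmr").joinpath("data", name)


def load_targets() -> list[TargetSpec]:
    """The shipped drug-target panel as TargetSpec objects (config order)."""
    with resources.as_file(_data_path("targets_grch37.tsv")) as path:
        df = pd.read_csv(path, sep="\t")
    return [
        TargetSpec(
            gene_symbol=row.gene_symbol,
            chrom=str(row.chrom),
            gene_start=int(row.gene_start),
            gene_end=int(row.gene_end),
            lipid_trait=row.lipid_trait,
            drug_label=row.drug_label,
        )
        for row in df.itertuples(index=False)
    ]


def load_reference_estimates() -> pd.DataFrame:
    """Published per-target IVW rows for both stages (``p`` as printed text)."""
    with resources.as_file(_data_path("reference_estimates.tsv")) as path:
        return pd.read_csv(path, sep="\t", dtype={"p": str, "target": str})


def parse_reported_p(p_text: str) -> tuple[float, bool]:
    """Parse a printed p-value; returns (value, is_upper_bound).

    ``"<0.001"`` parses to (0.001, True): the true value is below the
    returned bound.
    """
    s = str(p_text).strip()
    if s.startswith("<"):
        return float(s[1:]), True
    return float(s), False


def reported_gate(alpha: float = 0.05) -> dict[str, list[str]]:
    """Targets whose reported positive-control IVW p-value passes the gate.

    A target passes iff it has at least one instrument and its reported
    control-stage p is below ``alpha`` (an upper-bound entry like
    ``<0.001`` passes whenever the bound itself is <= alpha).
    """
    df = load_reference_estimates()
    out: dict[str, list[str]] = {}
    for trait in ("LDL", "TG"):
        passed = []
        sub = df[(df["stage"] == "control") & (df["trait"] == trait)]
        for row in sub.itertuples(index=False):
            if int(row.n_snps) == 0 or pd.isna(row.p):
                continue
            value, is_bound = parse_reported_p(row.p)
            if (is_bound and value <= alpha) or (not is_bound and value < alpha):
                passed.append(row.target)
        out[trait] = sorted(passed)
    return out
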