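"""Reading, validation and harmonization of GWAS summary statistics.

The unit of computation is one SNP's association summary for one trait
(:class:`GwasRecord`); a :class:`SummaryTable` is an ordered, id-unique
collection of them for a single trait.  Harmonization aligns an exposure
and an outcome table to a common effect allele so that downstream causal
estimators see per-allele effects on the same allelic scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GwasRecord",
    "SummaryTable",
    "HarmonizedPair",
    "read_summary_tsv",
    "write_summary_tsv",
    "harmonize",
    "kept_pairs",
    "pairs_to_frame",
    "CANONICAL_COLUMNS",
]

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of the TSV dialect
CANONICAL_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

_REQUIRED_COLUMNS = (
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
)


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association summary for one trait.

    ``beta`` is the per-effect-allele effect: log-odds for binary traits,
    SD units for continuous lipid traits.  ``eaf`` and ``n`` may be
    missing (``None``).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    def validation_errors(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        errs: list[str] = []
        if not self.snp_id:
            errs.append("empty snp_id")
        if self.effect_allele not in VALID_ALLELES:
            errs.append(f"effect_allele {self.effect_allele!r} not a single-base SNV allele")
        if self.other_allele not in VALID_ALLELES:
            errs.append(f"other_allele {self.other_allele!r} not a single-base SNV allele")
        if self.effect_allele == self.other_allele:
            errs.append("effect_allele equals other_allele")
        if not (isinstance(self.pos, (int, np.integer)) and self.pos >= 1):
            errs.append(f"pos {self.pos!r} not a positive 1-based coordinate")
        if not (math.isfinite(self.beta)):
            errs.append("beta not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            errs.append(f"se {self.se!r} not > 0")
        if not (0 < self.pval <= 1):
            errs.append(f"pval {self.pval!r} not in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            errs.append(f"eaf {self.eaf!r} not in [0, 1]")
        if self.n is not None and not self.n > 0:
            errs.append(f"n {self.n!r} not > 0")
        return errs

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G variants whose strand cannot be resolved from alleles."""
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"C", "G"}


class SummaryTable:
    """Ordered collection of :class:`GwasRecord` with unique ``snp_id``."""

    def __init__(self, trait_label: str, records: Iterable[GwasRecord]):
        self.trait_label = trait_label
        self.records: list[GwasRecord] = list(records)
        seen: set[str] = set()
        for rec in self.records:
            if rec.snp_id in seen:
                raise ValueError(f"duplicate snp_id {rec.snp_id!r} in table {trait_label!r}")
            seen.add(rec.snp_id)
        self._index = {rec.snp_id: rec for rec in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GwasRecord]:
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> GwasRecord:
        return self._index[snp_id]

    def snp_ids(self) -> list[str]:
        return [rec.snp_id for rec in self.records]

    def filter(self, predicate) -> "SummaryTable":
        """New table with the records satisfying ``predicate``, order kept."""
        return SummaryTable(self.trait_label, (r for r in self.records if predicate(r)))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp_id": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))

    @classmethod
    def from_frame(cls, df: pd.DataFrame, trait_label: str) -> "SummaryTable":
        records = []
        for row in df.itertuples(index=False):
            records.append(
                GwasRecord(
                    snp_id=str(row.snp_id),
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    effect_allele=str(row.effect_allele),
                    other_allele=str(row.other_allele),
                    beta=float(row.beta),
                    se=float(row.se),
                    pval=float(row.pval),
                    eaf=None if pd.isna(row.eaf) else float(row.eaf),
                    n=None if pd.isna(row.n) else float(row.n),
                )
            )
        return cls(trait_label, records)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SummaryTable({self.trait_label!r}, n={len(self)})"


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome effects for one SNP expressed on one effect allele.

    ``action`` records what harmonization did: ``kept`` (orientations
    already agreed), ``flipped`` (outcome beta negated to match the
    exposure allele), ``dropped_palindromic`` (strand-ambiguous variant
    with near-0.5 frequency), or ``dropped_mismatch`` (allele sets
    irreconcilable even after strand complement).
    """

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None
    action: str

    @property
    def usable(self) -> bool:
        return self.action in ("kept", "flipped")


def read_summary_tsv(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_label: str | None = None,
) -> SummaryTable:
    """Read a tab-separated summary-statistics file into a validated table.

    Parameters
    ----------
    path
        Tab-delimited file with a header line.
    column_map
        Optional mapping ``canonical_name -> column name in the file`` for
        reading GWAS-catalog-style exports; canonical names are
        ``snp_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
        pval, n`` (``eaf`` and ``n`` optional).
    trait_label
        Label for the table; defaults to the file stem.

    Rows violating record invariants (non-positive se, indel alleles,
    out-of-range frequencies, ...) are dropped with a per-row reason in
    the log; row order of the surviving records is preserved.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    colmap = dict(column_map or {})
    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = colmap.get(canonical, canonical)
        if source in df.columns:
            rename[source] = canonical
    df = df.rename(columns=rename)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    records: list[GwasRecord] = []
    n_dropped = 0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line numbers incl. header
        d = row._asdict()
        try:
            rec = GwasRecord(
                snp_id=str(d["snp_id"]).strip(),
                chrom=str(d["chrom"]).strip(),
                pos=int(float(d["pos"])),
                effect_allele=str(d["effect_allele"]).strip().upper(),
                other_allele=str(d["other_allele"]).strip().upper(),
                beta=float(d["beta"]),
                se=float(d["se"]),
                pval=float(d["pval"]),
                eaf=_opt_float(d.get("eaf")),
                n=_opt_float(d.get("n")),
            )
        except (TypeError, ValueError) as exc:
            log.warning("%s line %d: unparseable row dropped (%s)", path.name, i, exc)
            n_dropped += 1
            continue
        errs = rec.validation_errors()
        if errs:
            log.warning("%s line %d (%s): dropped — %s", path.name, i, rec.snp_id, "; ".join(errs))
            n_dropped += 1
            continue
        records.append(rec)
    if n_dropped:
        log.warning("%s: %d row(s) dropped during validation", path.name, n_dropped)
    return SummaryTable(trait_label or path.stem, records)


def _opt_float(value) -> float | None:
    if value is None:
        return None
    s = str(value).strip()
    if s == "" or s.lower() in ("na", "nan", "none"):
        return None
    return float(s)


def write_summary_tsv(table: SummaryTable, path: str | Path) -> None:
    """Write a table in the canonical TSV dialect at full float precision.

    The output round-trips exactly through :func:`read_summary_tsv`.
    """
    df = table.to_frame()
    # str() of a float is the shortest round-trip representation
    df.to_csv(path, sep="\t", index=False, na_rep="")


def harmonize(
    exposure: SummaryTable,
    outcome: SummaryTable,
    palindrome_eaf_window: float = 0.08,
) -> list[HarmonizedPair]:
    """Align outcome effects to the exposure's effect allele, SNP by SNP.

    For each SNP shared between the two tables:

    * same allele orientation (directly or after strand complement) — kept;
    * effect/other alleles swapped — outcome beta negated (``flipped``);
    * palindromic (A/T, C/G) variants with exposure eaf within
      ``palindrome_eaf_window`` of 0.5 — dropped (strand unresolvable);
      outside the window they are aligned by allele frequency;
    * irreconcilable allele sets — dropped as mismatch.

    SNPs absent from either table are omitted; no LD-proxy lookup is
    attempted.
    """
    pairs: list[HarmonizedPair] = []
    w = palindrome_eaf_window
    for exp in exposure:
        if exp.snp_id not in outcome:
            continue
        out = outcome.get(exp.snp_id)
        base = dict(
            snp_id=exp.snp_id,
            beta_exposure=exp.beta,
            se_exposure=exp.se,
            beta_outcome=out.beta,
            se_outcome=out.se,
            eaf_exposure=exp.eaf,
        )
        exp_alleles = (exp.effect_allele, exp.other_allele)
        out_alleles = (out.effect_allele, out.other_allele)
        out_comp = (_COMPLEMENT[out.effect_allele], _COMPLEMENT[out.other_allele])

        reconcilable = set(out_alleles) == set(exp_alleles) or set(out_comp) == set(exp_alleles)
        if not reconcilable:
            pairs.append(HarmonizedPair(action="dropped_mismatch", **base))
            continue

        if exp.is_palindromic:
            # allele labels cannot resolve strand; use frequency if informative
            if (
                exp.eaf is None
                or out.eaf is None
                or abs(exp.eaf - 0.5) <= w
            ):
                pairs.append(HarmonizedPair(action="dropped_palindromic", **base))
                continue
            # align the outcome so both effect-allele frequencies sit on the
            # same side of 0.5
            eaf_out = out.eaf if out_alleles == exp_alleles or out_comp == exp_alleles else 1 - out.eaf
            if (exp.eaf - 0.5) * (eaf_out - 0.5) >= 0:
                pairs.append(HarmonizedPair(action="kept", **base))
            else:
                base["beta_outcome"] = -out.beta
                pairs.append(HarmonizedPair(action="flipped", **base))
            continue

        if out_alleles == exp_alleles or out_comp == exp_alleles:
            pairs.append(HarmonizedPair(action="kept", **base))
        else:  # swapped orientation (directly or on the other strand)
            base["beta_outcome"] = -out.beta
            pairs.append(HarmonizedPair(action="flipped", **base))
    return pairs


def kept_pairs(pairs: Sequence[HarmonizedPair]) -> list[HarmonizedPair]:
    """The usable (kept or flipped) subset, order preserved."""
    return [p for p in pairs if p.usable]


def pairs_to_frame(pairs: Sequence[HarmonizedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "snp_id": p.snp_id,
                "beta_exposure": p.beta_exposure,
                "se_exposure": p.se_exposure,
                "beta_outcome": p.beta_outcome,
                "se_outcome": p.se_outcome,
                "eaf_exposure": p.eaf_exposure,
                "action": p.action,
            }
            for p in pairs
        ],
        columns=[
            "snp_id",
            "beta_exposure",
            "se_exposure",
            "beta_outcome",
            "se_outcome",
            "eaf_exposure",
            "action",
        ],
    )
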