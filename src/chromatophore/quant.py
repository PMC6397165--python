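"""Spectral-count quantitation: loading normalization and abundance indices.

The pipeline compares protein abundance across chromatophore color classes
(yellow, red, brown) from label-free spectral counts ``c_{p,s}``.  Two
normalizations are applied in sequence:

1. *Loading normalization* — per-sample factors ``f_s = T_s / T_ref`` from
   column totals correct for unequal protein loading between samples
   (``f_ref = 1``; the study reports 1, 2.2 and 1.8 for yellow, red, brown).
2. *Peptide scaling* — each protein's count is divided by its expected
   tryptic peptide count ``k_p`` and multiplied by the dataset-average ``k̄``
   (65.5 for the study's database), yielding the "normalized peptide count"
   abundance index ``AI_{p,s} = (c_{p,s} / f_s) / k_p × k̄``.

Category breakdowns and contaminant filtering (skin-surface bacterial
ribosomal proteins, preparation enzymes) complete the compositional analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from chromatophore.digest import (
    DigestParams,
    ProteinRecord,
    expected_peptide_count,
    mean_expected_peptides,
)

MIN_TOTAL = "min-total"


def validate_count_table(table: pd.DataFrame) -> None:
    """Check the SpectralCountTable invariants (counts ≥ 0, a positive total)."""
    if (table.to_numpy() < 0).any():
        raise ValueError("count table contains negative entries")
    if not (table.sum(axis=0) > 0).any():
        raise ValueError("count table has no sample with a positive total")


@dataclass(frozen=True)
class LoadingFactors:
    """Per-sample loading factors; the reference sample has factor 1."""

    factors: Mapping[str, float]
    reference: str

    def __post_init__(self) -> None:
        if abs(self.factors[self.reference] - 1.0) > 1e-12:
            raise ValueError("reference sample factor must be 1")
        if any(f <= 0 for f in self.factors.values()):
            raise ValueError("all loading factors must be positive")

    def __getitem__(self, sample: str) -> float:
        return self.factors[sample]


@dataclass
class ContaminantRules:
    """Case-insensitive description rules plus an explicit id blocklist.

    Defaults match the study's contaminant classes: bacterial ribosomal
    proteins from the skin surface and enzymes used in sample preparation
    (trypsin, collagenase, papain).  Empty rules act as the identity filter.
    """

    keywords: list[str] = field(
        default_factory=lambda: [
            "ribosomal protein",
            "trypsin",
            "collagenase",
            "papain",
        ]
    )
    patterns: list[str] = field(default_factory=list)
    id_blocklist: list[str] = field(default_factory=list)

    def compiled(self) -> list[re.Pattern]:
        pats = []
        for p in self.patterns:
            try:
                pats.append(re.compile(p, re.IGNORECASE))
            except re.error as exc:
                raise ValueError(f"malformed contaminant regex {p!r}: {exc}")
        return pats

    @classmethod
    def none(cls) -> "ContaminantRules":
        return cls(keywords=[], patterns=[], id_blocklist=[])


def loading_factors(
    table: pd.DataFrame, reference: str = MIN_TOTAL
) -> LoadingFactors:
    """Loading factors from column totals: ``f_s = T_s / T_ref``.

    ``reference`` names the sample fixed at 1, or ``"min-total"`` (default)
    to use the sample with the smallest total so every factor is ≥ 1 — the
    convention that makes the study's yellow sample the reference.
    """
    validate_count_table(table)
    totals = table.sum(axis=0)
    if reference == MIN_TOTAL:
        reference = str(totals.idxmin())
    if reference not in table.columns:
        raise KeyError(f"unknown reference sample {reference!r}")
    t_ref = float(totals[reference])
    if t_ref <= 0:
        raise ValueError(f"reference sample {reference!r} has zero total")
    factors = {str(s): float(totals[s]) / t_ref for s in table.columns}
    return LoadingFactors(factors=factors, reference=reference)


def normalize_loading(
    table: pd.DataFrame, factors: LoadingFactors
) -> pd.DataFrame:
    """Divide each sample column by its loading factor (reference unchanged)."""
    missing = set(map(str, table.columns)) ^ set(factors.factors)
    if missing:
        raise ValueError(f"sample mismatch between table and factors: {missing}")
    out = table.astype(float).copy()
    for s in out.columns:
        out[s] = out[s] / factors[str(s)]
    return out


def abundance_index(count: float, k_p: int, k_bar: float) -> float:
    """Peptide-scaled abundance index: ``count / k_p × k̄``."""
    if k_p < 1:
        raise ValueError("k_p must be >= 1 (a protein yields >= 1 peptide)")
    if k_bar <= 0:
        raise ValueError("k_bar must be positive")
    return count / k_p * k_bar


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class AbundanceIndexTable:
    """Float abundance indices with a rounded-integer view.

    ``values`` holds ``AI_{p,s}``; ``integer`` rounds half away from zero,
    matching the integers the study prints as "normalized peptide counts".
    """

    values: pd.DataFrame
    k_p: pd.Series
    k_bar: float
    factors: LoadingFactors | None

    @property
    def integer(self) -> pd.DataFrame:
        return pd.DataFrame(
            _round_half_away(self.values.to_numpy()).astype(int),
            index=self.values.index,
            columns=self.values.columns,
        )


def abundance_table(
    table: pd.DataFrame,
    proteins: Sequence[ProteinRecord],
    params: DigestParams = DigestParams(),
    reference: str = MIN_TOTAL,
    loading_normalize: bool = True,
) -> AbundanceIndexTable:
    """Full quantitation: loading factors → normalization → peptide scaling.

    ``loading_normalize=False`` is the granule-sample mode, where overall
    protein loading between samples is deliberately not normalized.

    Raises if any table protein lacks a sequence in ``proteins``.
    """
    validate_count_table(table)
    by_id = {p.id: p for p in proteins}
    missing = [pid for pid in table.index if str(pid) not in by_id]
    if missing:
        raise KeyError(f"no sequence for protein ids: {missing}")

    if loading_normalize:
        factors = loading_factors(table, reference)
        norm = normalize_loading(table, factors)
    else:
        factors = None
        norm = table.astype(float)

    k_bar = mean_expected_peptides([by_id[str(p)] for p in table.index], params)
    k_p = pd.Series(
        {p: expected_peptide_count(by_id[str(p)], params) for p in table.index}
    )
    values = norm.div(k_p, axis=0) * k_bar
    return AbundanceIndexTable(values=values, k_p=k_p, k_bar=k_bar, factors=factors)


def category_percentages(
    table: pd.DataFrame, categories: Mapping[str, str]
) -> pd.DataFrame:
    """Per-sample percentage of total counts in each functional category.

    Proteins without a mapping fall into ``"uncharacterized"``.  Percentages
    per sample sum to 100.
    """
    cats = pd.Series(
        [categories.get(str(p), "uncharacterized") for p in table.index],
        index=table.index,
    )
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero sample total for: {bad}")
    sums = table.groupby(cats).sum()
    return 100.0 * sums / totals


def contaminant_filter(
    records: Sequence[ProteinRecord],
    rules: ContaminantRules | None = None,
) -> tuple[list[ProteinRecord], list[tuple[ProteinRecord, str]]]:
    """Partition records into (kept, removed-with-reason).

    A record is removed iff any keyword/regex matches its description
    (case-insensitive) or its id is blocklisted.  The partition is exhaustive
    and disjoint; kept + removed always equals the input count.
    """
    rules = ContaminantRules() if rules is None else rules
    patterns = rules.compiled()
    blocked = set(rules.id_blocklist)
    kept: list[ProteinRecord] = []
    removed: list[tuple[ProteinRecord, str]] = []
    for rec in records:
        reason = None
        if rec.id in blocked:
            reason = f"id blocklisted: {rec.id}"
        else:
            desc = rec.description.lower()
            for kw in rules.keywords:
                if kw.lower() in desc:
                    reason = f"keyword: {kw}"
                    break
            if reason is None:
                for pat in patterns:
                    if pat.search(rec.description):
                        reason = f"pattern: {pat.pattern}"
                        break
        if reason is None:
            kept.append(rec)
        else:
            removed.append((rec, reason))
    return kept, removed
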