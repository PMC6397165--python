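"""Acceptance filters for identification and annotation tables.

The pipeline consumes — never runs — the upstream search and alignment
tools.  Identification entries (protein score, discriminant score, best
peptide expectation value) are accepted with score >= 22, discriminant >=
0.0 and expectation <= 0.01; annotation hits are accepted at e-value <=
1e-10.  S-crystallin calls require > 90% query coverage and > 60% identity
against an S-crystallin reference (strict inequalities) — the rule that
separates S-crystallins from their homologous glutathione S-transferases.

Boundary semantics are deliberate: the identification thresholds are
inclusive, the S-crystallin rule is strict.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

PROTEIN_SCORE_MIN = 22.0
DISCRIMINANT_MIN = 0.0
EXPECTATION_MAX = 0.01
EVALUE_MAX = 1e-10
SCRYSTALLIN_COVERAGE_MIN = 90.0  # strict >
SCRYSTALLIN_IDENTITY_MIN = 60.0  # strict >


@dataclass(frozen=True)
class AnnotationHit:
    """One BLAST-style tabular hit.

    ``query_coverage`` may be None when the tabular dialect lacks a qcovs
    column; :func:`coverage_percent` derives it from alignment length and
    query length instead.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float
    query_coverage: float | None = None
    alignment_length: int | None = None
    query_length: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.percent_identity <= 100:
            raise ValueError("percent identity must lie in [0, 100]")
        if self.evalue < 0 or not math.isfinite(self.evalue):
            raise ValueError("e-value must be finite and non-negative")
        if self.query_coverage is not None and not 0 <= self.query_coverage <= 100:
            raise ValueError("query coverage must lie in [0, 100]")


@dataclass(frozen=True)
class IdentificationEntry:
    """Search-engine protein identification summary."""

    protein_id: str
    protein_score: float
    discriminant_score: float
    peptide_expectation: float

    def __post_init__(self) -> None:
        for name in ("protein_score", "discriminant_score"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0 < self.peptide_expectation <= 1:
            raise ValueError("peptide expectation value must lie in (0, 1]")


def coverage_percent(hit: AnnotationHit) -> float:
    """Query coverage in percent, from qcovs or alignment/query lengths."""
    if hit.query_coverage is not None:
        return hit.query_coverage
    if hit.alignment_length is None or not hit.query_length:
        raise ValueError(
            f"hit {hit.query_id}->{hit.subject_id}: no coverage column and "
            "no alignment/query lengths to derive it from"
        )
    return min(100.0, 100.0 * hit.alignment_length / hit.query_length)


def interval_union_coverage(
    intervals: Sequence[tuple[int, int]], query_length: int
) -> float:
    """Coverage from the union of (qstart, qend) intervals, in percent.

    Option for multi-domain or overlapping hits, where summing alignment
    lengths would double-count shared query positions.
    """
    if query_length <= 0:
        raise ValueError("query_length must be positive")
    spans = sorted((min(a, b), max(a, b)) for a, b in intervals)
    covered = 0
    cur_start, cur_end = None, None
    for a, b in spans:
        if cur_end is None or a > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = a, b
        else:
            cur_end = max(cur_end, b)
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return min(100.0, 100.0 * covered / query_length)


def filter_identifications(
    entries: Iterable[IdentificationEntry],
    score_min: float = PROTEIN_SCORE_MIN,
    discriminant_min: float = DISCRIMINANT_MIN,
    expectation_max: float = EXPECTATION_MAX,
) -> list[IdentificationEntry]:
    """Keep entries with score >= 22, discriminant >= 0.0, expectation <= 0.01."""
    return [
        e
        for e in entries
        if e.protein_score >= score_min
        and e.discriminant_score >= discriminant_min
        and e.peptide_expectation <= expectation_max
    ]


def filter_hits_by_evalue(
    hits: Iterable[AnnotationHit], threshold: float = EVALUE_MAX
) -> list[AnnotationHit]:
    """Keep hits with e-value <= threshold, preserving input order."""
    out = []
    for h in hits:
        if h.evalue < 0:
            raise ValueError(f"negative e-value on hit {h.query_id}")
        if h.evalue <= threshold:
            out.append(h)
    return out


def classify_s_crystallin(hit: AnnotationHit) -> bool:
    """True iff coverage > 90% and identity > 60% (both strict).

    The subject is assumed to be an S-crystallin reference; a hit failing
    the rule is left as GST-like.
    """
    return (
        coverage_percent(hit) > SCRYSTALLIN_COVERAGE_MIN
        and hit.percent_identity > SCRYSTALLIN_IDENTITY_MIN
    )


def best_hit(hits: Iterable[AnnotationHit]) -> dict[str, AnnotationHit]:
    """One best hit per query: lowest e-value, ties by higher bitscore,
    then lexicographic subject id."""
    grouped: dict[str, list[AnnotationHit]] = {}
    for h in hits:
        grouped.setdefault(h.query_id, []).append(h)
    best: dict[str, AnnotationHit] = {}
    for qid, group in grouped.items():
        if not group:
            logger.info("query %s: empty hit group skipped", qid)
            continue
        best[qid] = min(group, key=lambda h: (h.evalue, -h.bitscore, h.subject_id))
    return best


def hits_from_blast_frame(df, qcov_column: str = "qcovs") -> list[AnnotationHit]:
    """Convert a BLAST tabular DataFrame (outfmt-6 dialect) to hits."""
    out = []
    has_cov = qcov_column in df.columns
    for row in df.itertuples(index=False):
        d = row._asdict()
        out.append(
            AnnotationHit(
                query_id=str(d["qseqid"]),
                subject_id=str(d["sseqid"]),
                percent_identity=float(d["pident"]),
                evalue=float(d["evalue"]),
                bitscore=float(d["bitscore"]),
                query_coverage=float(d[qcov_column]) if has_cov else None,
                alignment_length=int(d["length"]) if "length" in d else None,
            )
        )
    return out
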