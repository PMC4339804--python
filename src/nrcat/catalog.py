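"""Ortholog assignment and family cataloguing.

Verified candidates are assigned to the 48-receptor human reference
nomenclature by best combined DBD+LBD region similarity (LBD-only for the
DBD-less NR0B path), with a reciprocal-best-hit flag as the offline
stand-in for curated orthology annotations. Assignments roll up into a
species x receptor presence matrix of copy counts and per-subfamily
summaries, the tabular analogues of family-census figures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .conservation import region_similarity
from .domain_annotation import DomainAnnotation
from .seqcore import DEFAULT_SCHEME, ScoringScheme, SeqRecord
from .synthetic_data import NRTemplate

logger = logging.getLogger("nrcat")

__all__ = [
    "OrthologAssignment",
    "assign_orthologs",
    "build_presence_matrix",
    "subfamily_summary",
    "ASSIGNMENT_FLOOR",
]

ASSIGNMENT_FLOOR = 30.0  # minimum combined similarity to accept any assignment
AMBIGUITY_MARGIN = 0.01  # top-two relative gap below which a call is flagged


@dataclass(frozen=True)
class OrthologAssignment:
    candidate_id: str
    species: str
    assigned_symbol: str
    score: float  # combined DBD+LBD percent similarity to the template
    reciprocal: bool
    ambiguous: bool
    paralog_group_size: int


def _candidate_regions(
    record: SeqRecord, annotation: DomainAnnotation
) -> tuple[str | None, str | None]:
    dbd = record.residues[slice(*annotation.dbd)] if annotation.dbd else None
    lbd = record.residues[slice(*annotation.lbd)] if annotation.lbd else None
    return dbd, lbd


def _template_score(
    dbd: str | None,
    lbd: str | None,
    template: NRTemplate,
    scheme: ScoringScheme,
) -> float | None:
    """Combined similarity of candidate regions to one template; the
    template side is the reference denominator. ``None`` when the pair has
    no comparable region (e.g. DBD-less template vs DBD-only data)."""
    parts: list[float] = []
    if lbd is not None:
        parts.append(region_similarity(template.lbd_sequence, lbd, scheme))
    if dbd is not None and not template.lacks_dbd:
        parts.append(region_similarity(template.dbd_sequence, dbd, scheme))
    if not parts:
        return None
    return sum(parts) / len(parts)


def assign_orthologs(
    candidates: list[tuple[SeqRecord, DomainAnnotation]],
    reference_templates: list[NRTemplate],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> list[OrthologAssignment]:
    """Assign each verified candidate to its best-scoring reference.

    Only verified annotations participate. The reciprocal flag marks
    candidates that are also their assigned template's best candidate
    within the species; near-ties (top two scores within 1% relative) are
    flagged as ambiguous rather than silently resolved. Candidates scoring
    below the assignment floor against every template are reported and
    dropped.
    """
    verified = [(r, a) for r, a in candidates if a.verified]
    scored: list[tuple[SeqRecord, DomainAnnotation, list[tuple[float, str]]]] = []
    for rec, ann in verified:
        dbd, lbd = _candidate_regions(rec, ann)
        per_template: list[tuple[float, str]] = []
        for tpl in reference_templates:
            sc = _template_score(dbd, lbd, tpl, scheme)
            if sc is not None:
                per_template.append((sc, tpl.symbol))
        per_template.sort(key=lambda x: (-x[0], x[1]))
        scored.append((rec, ann, per_template))

    # best template per candidate
    best: dict[str, tuple[float, str, bool]] = {}
    for rec, ann, per_template in scored:
        if not per_template or per_template[0][0] < ASSIGNMENT_FLOOR:
            logger.warning("assign_orthologs: %s unassigned (below floor)", rec.id)
            continue
        top_score, top_symbol = per_template[0]
        ambiguous = (
            len(per_template) > 1
            and per_template[0][0] > 0
            and (per_template[0][0] - per_template[1][0]) / per_template[0][0]
            < AMBIGUITY_MARGIN
        )
        best[rec.id] = (top_score, top_symbol, ambiguous)

    # reciprocal check: per (species, symbol), the best-scoring candidate
    species_of = {rec.id: rec.species for rec, _, _ in scored}
    top_candidate: dict[tuple[str, str], str] = {}
    for cid, (score, symbol, _amb) in best.items():
        key = (species_of[cid], symbol)
        cur = top_candidate.get(key)
        if cur is None or best[cur][0] < score or (best[cur][0] == score and cid < cur):
            top_candidate[key] = cid

    group_sizes: dict[tuple[str, str], int] = {}
    for cid, (_s, symbol, _a) in best.items():
        key = (species_of[cid], symbol)
        group_sizes[key] = group_sizes.get(key, 0) + 1

    out = [
        OrthologAssignment(
            candidate_id=cid,
            species=species_of[cid],
            assigned_symbol=symbol,
            score=score,
            reciprocal=top_candidate[(species_of[cid], symbol)] == cid,
            ambiguous=ambiguous,
            paralog_group_size=group_sizes[(species_of[cid], symbol)],
        )
        for cid, (score, symbol, ambiguous) in best.items()
    ]
    out.sort(key=lambda a: (a.species, a.assigned_symbol, a.candidate_id))
    return out


def build_presence_matrix(
    assignments: list[OrthologAssignment],
    species_list: list[str],
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Species x receptor copy-count matrix, columns in manifest
    (subfamily) order; zero cells mean no ortholog was identified."""
    symbols = list(manifest["symbol"])
    matrix = pd.DataFrame(0, index=list(species_list), columns=symbols, dtype=int)
    for a in assignments:
        if a.species not in matrix.index:
            raise ValueError(f"assignment species {a.species!r} not in species list")
        if a.assigned_symbol not in matrix.columns:
            raise ValueError(f"symbol {a.assigned_symbol!r} not in manifest")
        matrix.loc[a.species, a.assigned_symbol] += 1
    return matrix


def subfamily_summary(matrix: pd.DataFrame, manifest: pd.DataFrame) -> dict:
    """Per-species totals, per-subfamily subtotals and paralog counts
    (``sum(max(copies - 1, 0))``)."""
    subfamily_of = dict(zip(manifest["symbol"], manifest["subfamily"]))
    subfamilies = sorted(set(subfamily_of.values()))
    out: dict = {}
    for species, row in matrix.iterrows():
        sub_counts = {s: 0 for s in subfamilies}
        for symbol, count in row.items():
            sub_counts[subfamily_of[symbol]] += int(count)
        out[species] = {
            "total": int(row.sum()),
            "subfamilies": sub_counts,
            "paralogs": int(sum(max(int(c) - 1, 0) for c in row)),
        }
    return out
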