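"""Boundary-rule domain annotation and rule-based NR verification.

The DBD is located by its double C4 zinc-finger motif: the annotated
segment starts two residues before the first conserved cysteine of the
detected finger grammar, runs through both fingers and a 12-residue
C-terminal extension, and is then adjusted into the canonical 75-80
residue window. The LBD is located by helix-anchored alignment to an
annotated reference: the candidate region downstream of the DBD is
globally aligned to the reference LBD and the reference anchors (12th
residue of helix 3 through the end of helix 10) are mapped through the
alignment onto candidate coordinates.

Verification is rule-based: a candidate is accepted as an NR when it
carries both domains with an adequate normalized LBD alignment score, or —
for candidates without any DBD — when its best-scoring reference is one of
the DBD-less NR0B receptors and the LBD score clears a stricter threshold.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

from .seqcore import (
    AA_TO_INDEX,
    DEFAULT_SCHEME,
    GAP,
    ScoringScheme,
    SeqRecord,
    glocal_align,
)
from .synthetic_data import (
    DBD_LENGTH_WINDOW,
    FINGER1_LEN,
    FINGER1_OFFSETS,
    FINGER2_LEN,
    FINGER2_OFFSETS,
    NRTemplate,
)

logger = logging.getLogger("nrcat")

__all__ = [
    "ZincFingerPair",
    "DomainAnnotation",
    "find_c4_fingers",
    "annotate_dbd",
    "annotate_lbd",
    "annotate_candidate",
    "verify_nr",
    "CTE_TAIL",
    "DEFAULT_THETA1",
    "DEFAULT_THETA2",
]

CTE_TAIL = 12  # residues appended after the last finger cysteine
DEFAULT_THETA1 = 0.4  # normalized LBD score floor, DBD+LBD path
DEFAULT_THETA2 = 0.5  # stricter floor for the DBD-less (NR0B) path


@dataclass(frozen=True)
class ZincFingerPair:
    """Eight cysteines of a double C4 zinc finger and the two finger spans."""

    cys_positions: tuple[int, ...]
    finger1_span: tuple[int, int]
    finger2_span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.cys_positions) != 8:
            raise ValueError("a C4 double finger has 8 cysteines")


def find_c4_fingers(
    seq: str | SeqRecord,
    linker_range: tuple[int, int] = (13, 19),
) -> list[ZincFingerPair]:
    """Scan for the double-finger grammar ``C-x2-C-x13-C-x2-C`` +
    linker(13-19) + ``C-x5-C-x9-C-x2-C``; returns all non-overlapping
    matches left to right (finger-internal spacing is exact, only the
    inter-finger linker is tolerant)."""
    s = seq.residues if isinstance(seq, SeqRecord) else seq
    lo, hi = linker_range
    if not (0 < lo <= hi):
        raise ValueError("invalid linker range")
    pat = re.compile(
        rf"C.{{2}}C.{{13}}C.{{2}}C(.{{{lo},{hi}}}?)C.{{5}}C.{{9}}C.{{2}}C"
    )
    out: list[ZincFingerPair] = []
    pos = 0
    while True:
        m = pat.search(s, pos)
        if m is None:
            break
        start = m.start()
        linker_len = len(m.group(1))
        f2 = start + FINGER1_LEN + linker_len
        cys = tuple(
            [start + o for o in FINGER1_OFFSETS] + [f2 + o for o in FINGER2_OFFSETS]
        )
        out.append(
            ZincFingerPair(
                cys_positions=cys,
                finger1_span=(start, start + FINGER1_LEN),
                finger2_span=(f2, f2 + FINGER2_LEN),
            )
        )
        pos = m.end()
    return out


def annotate_dbd(
    seq: str | SeqRecord,
    fingers: list[ZincFingerPair] | None = None,
    cte_tail: int = CTE_TAIL,
    window: tuple[int, int] = DBD_LENGTH_WINDOW,
) -> tuple[int, int] | None:
    """DBD interval from the boundary rule, or ``None`` without a finger pair.

    Start = first finger cysteine - 2 (clamped at 0 with a warning); end =
    last finger cysteine + ``cte_tail``, then adjusted so the length falls
    in ``window`` (extended if short, truncated if long), never beyond the
    sequence end. When several finger pairs exist the most N-terminal one
    is the DBD.
    """
    s = seq.residues if isinstance(seq, SeqRecord) else seq
    if fingers is None:
        fingers = find_c4_fingers(s)
    if not fingers:
        return None
    pair = fingers[0]
    first_cys, last_cys = pair.cys_positions[0], pair.cys_positions[-1]
    start = first_cys - 2
    if start < 0:
        logger.warning("annotate_dbd: start clamped to 0 (first cysteine at %d)", first_cys)
        start = 0
    end = min(last_cys + 1 + cte_tail, len(s))
    lo, hi = window
    if end - start < lo:
        end = min(start + lo, len(s))
    elif end - start > hi:
        end = start + hi
    return (start, end)


def _lbd_self_score(reference: NRTemplate, scheme: ScoringScheme) -> float:
    S = scheme.matrix
    return float(sum(S[AA_TO_INDEX[c], AA_TO_INDEX[c]] for c in reference.lbd_sequence))


def annotate_lbd(
    seq: str | SeqRecord,
    reference: NRTemplate,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    search_from: int = 0,
) -> tuple[tuple[int, int] | None, float]:
    """Helix-anchored LBD interval by alignment to an annotated reference.

    The candidate region from ``search_from`` (the DBD end, or 0 without a
    DBD) is globally aligned to the reference LBD; the reference anchors —
    helix-3 start + 11 and helix-10 end — are mapped through the alignment
    onto candidate coordinates. The score is the alignment score normalized
    by the reference LBD self-score (1.0 for the reference itself). An
    empty or reversed mapped interval yields ``(None, score)``.
    """
    s = seq.residues if isinstance(seq, SeqRecord) else seq
    region = s[search_from:]
    if not region:
        return None, float("-inf")
    ref_lbd = reference.lbd_sequence
    aln = glocal_align(region, ref_lbd, scheme)
    norm = aln.score / _lbd_self_score(reference, scheme)
    lbd_off = reference.lbd_interval[0]
    core_start, core_end = reference.core_lbd_interval
    # anchors in reference-LBD-local coordinates
    a_start = core_start - lbd_off
    a_last = core_end - 1 - lbd_off  # map the last residue, end is +1
    cand_pos, ref_pos = aln.a_span[0], 0
    map_start = map_last = None
    for ca, cb in zip(aln.aligned_a, aln.aligned_b):
        if cb != GAP:
            if ref_pos == a_start and ca != GAP:
                map_start = cand_pos
            elif ref_pos == a_start and ca == GAP:
                map_start = cand_pos  # next candidate residue to the right
            if ref_pos == a_last:
                map_last = cand_pos if ca != GAP else cand_pos - 1
            ref_pos += 1
        if ca != GAP:
            cand_pos += 1
    if map_start is None or map_last is None:
        return None, norm
    start = search_from + map_start
    end = search_from + map_last + 1
    if end <= start:
        return None, norm
    return (start, end), norm


@dataclass
class DomainAnnotation:
    """Domain intervals and the verification verdict for one candidate."""

    gene_id: str
    dbd: tuple[int, int] | None
    lbd: tuple[int, int] | None
    lbd_alignment_score: float
    best_reference: str | None = None
    verified: bool = False
    assigned_class: str = "rejected"  # NR | NR0B-candidate | rejected


def annotate_candidate(
    record: SeqRecord,
    templates: list[NRTemplate],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    reference_hint: str | None = None,
) -> DomainAnnotation:
    """Full annotation of one candidate.

    The DBD comes from the boundary rule alone. For the LBD, the reference
    is the hinted template when given, otherwise the template with the
    best normalized LBD score (hinting with the top search hit's query
    avoids 48 alignments per candidate in the pipeline).
    """
    dbd = annotate_dbd(record.residues)
    search_from = dbd[1] if dbd else 0
    refs = (
        [t for t in templates if t.symbol == reference_hint]
        if reference_hint
        else templates
    )
    if not refs:
        raise ValueError(f"unknown reference hint {reference_hint!r}")
    best: tuple[float, str, tuple[int, int] | None] | None = None
    for ref in refs:
        interval, score = annotate_lbd(record.residues, ref, scheme, search_from)
        if best is None or score > best[0]:
            best = (score, ref.symbol, interval)
    score, ref_symbol, interval = best
    return DomainAnnotation(
        gene_id=record.id,
        dbd=dbd,
        lbd=interval,
        lbd_alignment_score=score,
        best_reference=ref_symbol,
    )


def verify_nr(
    candidate: SeqRecord,
    annotation: DomainAnnotation,
    templates: list[NRTemplate],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    theta1: float = DEFAULT_THETA1,
    theta2: float = DEFAULT_THETA2,
) -> DomainAnnotation:
    """Set the verification flag and class on an annotation.

    DBD + LBD with normalized LBD score >= ``theta1`` -> verified NR.
    No DBD: the candidate is re-scored against all templates; if the best
    reference is an NR0B (DBD-less) receptor and the score >= ``theta2``,
    it is a verified NR0B candidate. Everything else is rejected.
    """
    ann = annotation
    if ann.dbd is not None and ann.lbd is not None and ann.lbd_alignment_score >= theta1:
        ann.verified = True
        ann.assigned_class = "NR"
        return ann
    if ann.dbd is None:
        best_score, best_ref, best_interval = float("-inf"), None, None
        for ref in templates:
            interval, score = annotate_lbd(candidate.residues, ref, scheme, 0)
            if score > best_score:
                best_score, best_ref, best_interval = score, ref, interval
        if best_ref is not None and best_ref.lacks_dbd and best_score >= theta2 and best_interval:
            ann.lbd = best_interval
            ann.lbd_alignment_score = best_score
            ann.best_reference = best_ref.symbol
            ann.verified = True
            ann.assigned_class = "NR0B-candidate"
            return ann
    ann.verified = False
    ann.assigned_class = "rejected"
    return ann
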