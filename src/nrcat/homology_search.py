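"""Seed-and-extend protein homology search with Karlin–Altschul E-values.

This reimplements the identification stage of the cataloguing procedure at
desk scale: reference NR domain sequences are searched against a target
proteome by exact k-mer seeding, ungapped X-drop extension along each
seeded diagonal and, for diagonals passing a trigger score, an exact
Smith–Waterman gapped alignment of the query/target pair. Hit significance
uses ``E = K * m * n * exp(-lambda * S)`` with lambda solved from the
scoring scheme and background residue frequencies, and K a configured
constant (only the threshold semantics and relative ordering of E-values
matter for the pipeline).

The E-value cutoff is not fixed a priori: :func:`calibrate_cutoff` sets it
just loose enough to recover every known NR gene of a designated
calibration proteome — the classic recipe of tuning human-query cutoffs
against the most diverged fish receptor set.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq

from .seqcore import (
    AA_TO_INDEX,
    DEFAULT_SCHEME,
    GAP,
    ScoringScheme,
    SeqRecord,
    local_align,
    percent_identity,
)

logger = logging.getLogger("nrcat")

__all__ = [
    "KarlinAltschulParams",
    "SeedIndex",
    "SearchHit",
    "estimate_ka_params",
    "build_index",
    "search",
    "calibrate_cutoff",
    "CalibrationError",
    "merge_and_dedupe",
    "write_hits_tsv",
]

DEFAULT_K = 4
DEFAULT_KA_CONSTANT = 0.13  # K in E = K*m*n*exp(-lambda*S); configured, not computed
UNGAPPED_XDROP = 20
GAPPED_TRIGGER = 25  # ungapped score needed before running the gapped stage


@dataclass(frozen=True)
class KarlinAltschulParams:
    """lambda and K of the extreme-value statistics, with the query (m) and
    database (n) residue counts the E-value refers to."""

    lam: float
    K: float
    m: int
    n: int

    def evalue(self, raw_score: float) -> float:
        log_e = math.log(self.K * self.m * self.n) - self.lam * raw_score
        return max(math.exp(max(log_e, -700.0)), 5e-324)

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.K)) / math.log(2.0)


def estimate_ka_params(
    scheme: ScoringScheme | np.ndarray,
    m: int,
    n: int,
    background_freqs: np.ndarray | None = None,
    K: float = DEFAULT_KA_CONSTANT,
) -> KarlinAltschulParams:
    """Solve ``sum_ij p_i p_j exp(lambda * s_ij) = 1`` for lambda > 0.

    ``scheme`` may be a :class:`ScoringScheme` or a bare substitution
    matrix. Requires a valid scoring regime: negative expected score and at
    least one positive score. The root is found with Brent's method and
    verified to a residual below 1e-9.
    """
    matrix = scheme if isinstance(scheme, np.ndarray) else scheme.matrix
    p = background_freqs if background_freqs is not None else np.full(20, 1 / 20)
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.shape[0] > matrix.shape[0]:
        raise ValueError("background frequency vector does not fit the matrix")
    if not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background frequencies must sum to 1")
    S = matrix[: len(p), : len(p)].astype(float)
    pp = np.outer(p, p)
    expected = float((pp * S).sum())
    if expected >= 0 or S.max() <= 0:
        raise ValueError(
            "no valid lambda: expected score must be negative with some positive score"
        )

    def f(lam: float) -> float:
        return float((pp * np.exp(lam * S)).sum()) - 1.0

    hi = 0.5
    while f(hi) < 0:
        hi *= 2.0
        if hi > 100:  # pragma: no cover
            raise RuntimeError("failed to bracket lambda")
    lam = float(brentq(f, 1e-12, hi, xtol=1e-14, rtol=8.9e-16))
    if abs(f(lam)) > 1e-9:  # pragma: no cover
        raise RuntimeError("lambda root did not converge")
    return KarlinAltschulParams(lam=lam, K=K, m=int(m), n=int(n))


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------


@dataclass
class SeedIndex:
    """Exact k-mer index over a target proteome."""

    k: int
    words: dict[str, list[tuple[str, int]]]
    sequences: dict[str, SeqRecord]

    @property
    def database_size(self) -> int:
        return sum(len(r.residues) for r in self.sequences.values())


def build_index(proteome: list[SeqRecord], k: int = DEFAULT_K) -> SeedIndex:
    """Index every k-mer of every target; sequences shorter than k are
    skipped with a log note."""
    if not (3 <= k <= 6):
        raise ValueError("k must be in [3, 6]")
    words: dict[str, list[tuple[str, int]]] = {}
    sequences: dict[str, SeqRecord] = {}
    for rec in proteome:
        if rec.id in sequences:
            raise ValueError(f"duplicate target id {rec.id!r}")
        sequences[rec.id] = rec
        if len(rec.residues) < k:
            logger.info("build_index: skipping %r (shorter than k=%d)", rec.id, k)
            continue
        s = rec.residues
        for off in range(len(s) - k + 1):
            words.setdefault(s[off : off + k], []).append((rec.id, off))
    return SeedIndex(k=k, words=words, sequences=sequences)


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    target_id: str
    raw_score: float
    bit_score: float
    evalue: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    identity_pct: float
    aln_length: int
    mismatches: int
    gap_opens: int


def _ungapped_extend(q: str, t: str, qpos: int, tpos: int, k: int, S, xdrop: int) -> int:
    """Score of the best X-drop ungapped extension through the seed."""
    score = sum(S[AA_TO_INDEX[q[qpos + i]], AA_TO_INDEX[t[tpos + i]]] for i in range(k))
    best = run = score
    i, j = qpos + k, tpos + k
    while i < len(q) and j < len(t):
        run += S[AA_TO_INDEX[q[i]], AA_TO_INDEX[t[j]]]
        if run > best:
            best = run
        if run < best - xdrop:
            break
        i += 1
        j += 1
    right_gain = best - score
    best = run = score
    i, j = qpos - 1, tpos - 1
    while i >= 0 and j >= 0:
        run += S[AA_TO_INDEX[q[i]], AA_TO_INDEX[t[j]]]
        if run > best:
            best = run
        if run < best - xdrop:
            break
        i -= 1
        j -= 1
    left_gain = best - score
    return int(score + left_gain + right_gain)


def search(
    query: SeqRecord,
    index: SeedIndex,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    params: KarlinAltschulParams | None = None,
    e_cutoff: float = 1e-25,
) -> list[SearchHit]:
    """Seeded search of one query against an indexed proteome.

    Seeds are grouped by (target, diagonal); each diagonal is extended
    ungapped with an X-drop; targets whose best diagonal reaches the
    trigger score get an exact Smith–Waterman gapped alignment, from which
    score, spans and identity are reported. The best hit per target with
    ``E <= e_cutoff`` is kept, sorted by ascending E-value.
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    if params is None:
        params = estimate_ka_params(scheme, m=len(query), n=index.database_size)
    S = scheme.matrix
    k = index.k
    q = query.residues
    seeds: dict[tuple[str, int], tuple[int, int]] = {}
    for qpos in range(len(q) - k + 1):
        for tid, tpos in index.words.get(q[qpos : qpos + k], ()):
            key = (tid, tpos - qpos)
            if key not in seeds:
                seeds[key] = (qpos, tpos)
    best_ungapped: dict[str, int] = {}
    for (tid, _diag), (qpos, tpos) in seeds.items():
        sc = _ungapped_extend(q, index.sequences[tid].residues, qpos, tpos, k, S, UNGAPPED_XDROP)
        if sc > best_ungapped.get(tid, -(10**9)):
            best_ungapped[tid] = sc
    hits: list[SearchHit] = []
    for tid, sc in best_ungapped.items():
        if sc < GAPPED_TRIGGER:
            continue
        aln = local_align(query, index.sequences[tid], scheme)
        if aln.score <= 0:
            continue
        ev = params.evalue(aln.score)
        if ev > e_cutoff:
            continue
        ident = percent_identity(aln, "a")
        mismatches = sum(
            1
            for x, y in zip(aln.aligned_a, aln.aligned_b)
            if x != GAP and y != GAP and x != y
        )
        gap_opens = 0
        in_gap = False
        for x, y in zip(aln.aligned_a, aln.aligned_b):
            if x == GAP or y == GAP:
                if not in_gap:
                    gap_opens += 1
                in_gap = True
            else:
                in_gap = False
        hits.append(
            SearchHit(
                query_id=query.id,
                target_id=tid,
                raw_score=aln.score,
                bit_score=params.bit_score(aln.score),
                evalue=ev,
                query_span=aln.a_span,
                target_span=aln.b_span,
                identity_pct=ident,
                aln_length=len(aln),
                mismatches=mismatches,
                gap_opens=gap_opens,
            )
        )
    hits.sort(key=lambda h: (h.evalue, h.target_id))
    return hits


class CalibrationError(RuntimeError):
    """Raised when some known NR gene of the calibration proteome cannot be
    recovered at any cutoff below the ceiling."""

    def __init__(self, missing: list[str]):
        self.missing = missing
        super().__init__(
            "calibration failed; undetected calibration genes: " + ", ".join(missing)
        )


def calibrate_cutoff(
    reference_queries: list[SeqRecord],
    calibration_proteome: list[SeqRecord],
    true_gene_ids: set[str],
    scheme: ScoringScheme = DEFAULT_SCHEME,
    k: int = DEFAULT_K,
    ceiling: float = 10.0,
) -> float:
    """Choose the E-value cutoff just loose enough for full recall.

    Returns ``max over true genes of (min over queries of best-hit E)``,
    i.e. the loosest per-gene requirement; searching with the returned
    cutoff recovers every listed gene of the calibration proteome.
    """
    index = build_index(calibration_proteome, k)
    best_e: dict[str, float] = {}
    for qry in reference_queries:
        for hit in search(qry, index, scheme, e_cutoff=ceiling):
            if hit.target_id in true_gene_ids:
                if hit.evalue < best_e.get(hit.target_id, math.inf):
                    best_e[hit.target_id] = hit.evalue
    missing = sorted(g for g in true_gene_ids if g not in best_e)
    if missing:
        raise CalibrationError(missing)
    return max(best_e.values())


def merge_and_dedupe(
    hit_sets: list[list[SearchHit]],
    proteome: list[SeqRecord],
) -> tuple[list[str], dict[str, list[str]]]:
    """Combine hit sets over one proteome into unique candidate genes.

    Targets appearing in several hit sets are counted once; targets with
    byte-identical residue strings are collapsed onto the lexicographically
    smallest id. Returns the sorted candidate ids and a report mapping each
    kept id to the ids merged into it.
    """
    by_id = {r.id: r for r in proteome}
    union: set[str] = set()
    for hits in hit_sets:
        for h in hits:
            if h.target_id not in by_id:
                raise ValueError(f"hit target {h.target_id!r} not in proteome")
            union.add(h.target_id)
    by_seq: dict[str, list[str]] = {}
    for tid in sorted(union):
        by_seq.setdefault(by_id[tid].residues, []).append(tid)
    candidates: list[str] = []
    report: dict[str, list[str]] = {}
    for ids in by_seq.values():
        keep = min(ids)
        candidates.append(keep)
        merged = [x for x in ids if x != keep]
        if merged:
            report[keep] = merged
            logger.info("merge_and_dedupe: %s absorbs identical %s", keep, merged)
    return sorted(candidates), report


def write_hits_tsv(hits: list[SearchHit], path: str | Path) -> Path:
    """Write hits in the de-facto 12-column tabular layout (1-based,
    inclusive coordinates, as BLAST outfmt 6 prints them)."""
    path = Path(path)
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.target_id,
                        f"{h.identity_pct:.3f}",
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.query_span[0] + 1),
                        str(h.query_span[1]),
                        str(h.target_span[0] + 1),
                        str(h.target_span[1]),
                        f"{h.evalue:.2e}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )
    return path
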