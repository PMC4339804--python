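"""Foundational sequence types and alignment kernels.

Everything downstream of FASTA input flows through this module: the
:class:`SeqRecord` container, BLOSUM-based affine-gap pairwise alignment
(global Needleman–Wunsch/Gotoh and local Smith–Waterman), percent identity
with an explicit reference-side denominator, and a progressive multiple
aligner (neighbor-joining guide tree over pairwise p-distances, then
profile–profile merging with sum-of-pairs scoring).

Conventions
-----------
* Alphabet: the 20 standard amino acids plus ``X`` (unknown).
* All coordinates are 0-based, half-open.
* A gap of length *k* costs ``gap_open + k * gap_extend`` (BLAST-style).
* Traceback ties are broken deterministically: diagonal (match/mismatch)
  over gap-in-``a`` over gap-in-``b``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

logger = logging.getLogger("nrcat")

# ---------------------------------------------------------------------------
# Alphabet and scoring
# ---------------------------------------------------------------------------

ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
GAP = "-"


class FastaParseError(ValueError):
    """Raised for malformed FASTA input; message names the offending line."""


@lru_cache(maxsize=None)
def load_substitution_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """Load a packaged substitution matrix as a 21x21 int32 array.

    Matrices come from Biopython's bundled NCBI-format tables, re-indexed
    onto :data:`ALPHABET`.
    """
    from Bio.Align import substitution_matrices

    raw = substitution_matrices.load(name)
    out = np.zeros((len(ALPHABET), len(ALPHABET)), dtype=np.int32)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = int(raw[a, b])
    if not np.array_equal(out, out.T):
        raise ValueError(f"substitution matrix {name!r} is not symmetric")
    return out


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix plus affine gap penalties.

    ``gap_open=11, gap_extend=1`` with BLOSUM62 are the conventional
    protein-BLAST defaults; a length-1 gap costs 12.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend >= 0):
            raise ValueError("require gap_open >= gap_extend >= 0")

    @property
    def matrix(self) -> np.ndarray:
        return load_substitution_matrix(self.matrix_name)


DEFAULT_SCHEME = ScoringScheme()


# ---------------------------------------------------------------------------
# Records and FASTA I/O
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SeqRecord:
    """A protein sequence with identity and species tag."""

    id: str
    residues: str
    species: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SeqRecord id must be nonempty")
        if not self.residues:
            raise ValueError(f"SeqRecord {self.id!r}: residues must be nonempty")
        bad = set(self.residues) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"SeqRecord {self.id!r}: illegal residue(s) {sorted(bad)}; "
                f"alphabet is {ALPHABET}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def encode(residues: str) -> np.ndarray:
    """Encode residues as int8 indices into :data:`ALPHABET`."""
    return np.array([AA_TO_INDEX[c] for c in residues], dtype=np.int8)


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a protein FASTA file.

    The header convention is ``>id [species=tag] [description]``.  Duplicate
    ids, illegal residues and residues before the first header are rejected
    with the offending line number in the message.
    """
    path = Path(path)
    records: list[SeqRecord] = []
    seen: set[str] = set()
    header: tuple[str, str, str] | None = None
    chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        rid, species, desc = header
        residues = "".join(chunks)
        if not residues:
            raise FastaParseError(f"{path}:{line_no}: record {rid!r} has no residues")
        records.append(SeqRecord(id=rid, residues=residues, species=species, description=desc))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(line_no)
                fields = line[1:].split()
                if not fields:
                    raise FastaParseError(f"{path}:{line_no}: empty FASTA header")
                rid = fields[0]
                if rid in seen:
                    raise FastaParseError(f"{path}:{line_no}: duplicate id {rid!r}")
                seen.add(rid)
                species = ""
                desc_parts = []
                for tok in fields[1:]:
                    if tok.startswith("species="):
                        species = tok[len("species=") :]
                    else:
                        desc_parts.append(tok)
                header = (rid, species, " ".join(desc_parts))
            else:
                if header is None:
                    raise FastaParseError(f"{path}:{line_no}: sequence data before first header")
                seq = line.strip().upper()
                bad = set(seq) - set(ALPHABET)
                if bad:
                    raise FastaParseError(
                        f"{path}:{line_no}: illegal residue(s) {sorted(bad)} in record"
                    )
                chunks.append(seq)
        flush(line_no if "line_no" in locals() else 0)
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path, width: int = 60) -> Path:
    """Write records as FASTA wrapped at ``width`` columns; returns the path."""
    path = Path(path)
    seen: set[str] = set()
    with open(path, "w") as fh:
        for rec in records:
            if rec.id in seen:
                raise ValueError(f"duplicate id {rec.id!r} on write")
            seen.add(rec.id)
            header = f">{rec.id}"
            if rec.species:
                header += f" species={rec.species}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Pairwise alignment (Gotoh affine-gap DP, numba-compiled)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseAlignment:
    """A gapped pairwise alignment; ``a_span``/``b_span`` are the half-open
    residue intervals of the two input sequences covered by the alignment."""

    aligned_a: str
    aligned_b: str
    score: float
    mode: str  # "global" | "local"
    a_span: tuple[int, int]
    b_span: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings must have equal length")
        for x, y in zip(self.aligned_a, self.aligned_b):
            if x == GAP and y == GAP:
                raise ValueError("gap/gap column in alignment")

    def __len__(self) -> int:
        return len(self.aligned_a)


_NEG = np.int64(-(10**15))


@njit(cache=False)
def _gotoh_global(a, b, S, go, ge):  # pragma: no cover - exercised via wrapper
    m, n = a.shape[0], b.shape[0]
    M = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    X = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # gap in a (consumes b)
    Y = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # gap in b (consumes a)
    # pointers: per state, where we came from (0=M, 1=X, 2=Y)
    pM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    M[0, 0] = 0
    for j in range(1, n + 1):
        X[0, j] = -(go + ge * j)
        pX[0, j] = 1
    for i in range(1, m + 1):
        Y[i, 0] = -(go + ge * i)
        pY[i, 0] = 2
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = S[ai, b[j - 1]]
            # M: best predecessor, tie-break M > X > Y
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            pM[i, j] = ptr
            # X: gap in a, consumes b[j-1]
            op = M[i, j - 1] - (go + ge)
            ext = X[i, j - 1] - ge
            if op >= ext:
                X[i, j] = op
                pX[i, j] = 0
            else:
                X[i, j] = ext
                pX[i, j] = 1
            # Y: gap in b, consumes a[i-1]
            op = M[i - 1, j] - (go + ge)
            ext = Y[i - 1, j] - ge
            if op >= ext:
                Y[i, j] = op
                pY[i, j] = 0
            else:
                Y[i, j] = ext
                pY[i, j] = 2
    # terminal state, tie-break M > X > Y
    state = 0
    best = M[m, n]
    if X[m, n] > best:
        best = X[m, n]
        state = 1
    if Y[m, n] > best:
        best = Y[m, n]
        state = 2
    # traceback: moves 0=diag, 1=gap-in-a, 2=gap-in-b
    moves = np.empty(m + n, dtype=np.uint8)
    k = 0
    i, j = m, n
    while i > 0 or j > 0:
        if state == 0:
            nxt = pM[i, j]
            moves[k] = 0
            i -= 1
            j -= 1
        elif state == 1:
            nxt = pX[i, j]
            moves[k] = 1
            j -= 1
        else:
            nxt = pY[i, j]
            moves[k] = 2
            i -= 1
        state = nxt
        k += 1
    return best, moves[:k][::-1].copy()


@njit(cache=False)
def _gotoh_glocal(a, b, S, go, ge):  # pragma: no cover - exercised via wrapper
    """Semi-global: b fully aligned, leading/trailing unaligned residues of
    a are free. Returns (score, moves, a_start)."""
    m, n = a.shape[0], b.shape[0]
    M = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    X = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    Y = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    pM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    for i in range(m + 1):
        M[i, 0] = 0  # free leading skip of a
    for j in range(1, n + 1):
        X[0, j] = -(go + ge * j)
        pX[0, j] = 1
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = S[ai, b[j - 1]]
            best = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > best:
                best = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > best:
                best = Y[i - 1, j - 1]
                ptr = 2
            M[i, j] = best + s
            pM[i, j] = ptr
            op = M[i, j - 1] - (go + ge)
            ext = X[i, j - 1] - ge
            if op >= ext:
                X[i, j] = op
                pX[i, j] = 0
            else:
                X[i, j] = ext
                pX[i, j] = 1
            op = M[i - 1, j] - (go + ge)
            ext = Y[i - 1, j] - ge
            if op >= ext:
                Y[i, j] = op
                pY[i, j] = 0
            else:
                Y[i, j] = ext
                pY[i, j] = 2
    # free trailing skip of a: best over rows at column n, tie -> smallest i
    best = _NEG
    bi = 0
    state = 0
    for i in range(m + 1):
        if M[i, n] > best:
            best = M[i, n]
            bi = i
            state = 0
        if X[i, n] > best:
            best = X[i, n]
            bi = i
            state = 1
    moves = np.empty(m + n, dtype=np.uint8)
    k = 0
    i, j = bi, n
    while j > 0:
        if state == 0:
            if j == 0:
                break
            nxt = pM[i, j]
            moves[k] = 0
            i -= 1
            j -= 1
            k += 1
            if j == 0:
                break
            state = nxt
        elif state == 1:
            nxt = pX[i, j]
            moves[k] = 1
            j -= 1
            k += 1
            state = nxt
        else:
            nxt = pY[i, j]
            moves[k] = 2
            i -= 1
            k += 1
            state = nxt
    return best, moves[:k][::-1].copy(), i, bi


@njit(cache=False)
def _sw_local(a, b, S, go, ge):  # pragma: no cover - exercised via wrapper
    m, n = a.shape[0], b.shape[0]
    M = np.zeros((m + 1, n + 1), dtype=np.int64)
    X = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    Y = np.full((m + 1, n + 1), _NEG, dtype=np.int64)
    pM = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0=M,1=X,2=Y,3=start
    pX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = np.int64(0)
    bi, bj = 0, 0
    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = S[ai, b[j - 1]]
            prev = M[i - 1, j - 1]
            ptr = 0
            if X[i - 1, j - 1] > prev:
                prev = X[i - 1, j - 1]
                ptr = 1
            if Y[i - 1, j - 1] > prev:
                prev = Y[i - 1, j - 1]
                ptr = 2
            if prev < 0:  # start a fresh alignment at this pair
                prev = 0
                ptr = 3
            val = prev + s
            if val <= 0:  # dead cell
                val = 0
                ptr = 3
            M[i, j] = val
            pM[i, j] = ptr
            op = M[i, j - 1] - (go + ge)
            ext = X[i, j - 1] - ge
            if op >= ext:
                X[i, j] = op
                pX[i, j] = 0
            else:
                X[i, j] = ext
                pX[i, j] = 1
            op = M[i - 1, j] - (go + ge)
            ext = Y[i - 1, j] - ge
            if op >= ext:
                Y[i, j] = op
                pY[i, j] = 0
            else:
                Y[i, j] = ext
                pY[i, j] = 2
            if M[i, j] > best:
                best = M[i, j]
                bi, bj = i, j
    moves = np.empty(m + n, dtype=np.uint8)
    k = 0
    i, j = bi, bj
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            if M[i, j] == 0:
                break  # reached the empty-prefix start
            nxt = pM[i, j]
            moves[k] = 0
            i -= 1
            j -= 1
            k += 1
            if nxt == 3:
                break  # alignment began with this residue pair
            state = nxt
        elif state == 1:
            nxt = pX[i, j]
            moves[k] = 1
            j -= 1
            k += 1
            state = nxt
        else:
            nxt = pY[i, j]
            moves[k] = 2
            i -= 1
            k += 1
            state = nxt
    return best, moves[:k][::-1].copy(), i, j, bi, bj


def _moves_to_alignment(a: str, b: str, moves: np.ndarray, ai0: int, bj0: int) -> tuple[str, str]:
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = ai0, bj0
    for mv in moves:
        if mv == 0:
            out_a.append(a[i])
            out_b.append(b[j])
            i += 1
            j += 1
        elif mv == 1:
            out_a.append(GAP)
            out_b.append(b[j])
            j += 1
        else:
            out_a.append(a[i])
            out_b.append(GAP)
            i += 1
    return "".join(out_a), "".join(out_b)


def global_align(a: SeqRecord | str, b: SeqRecord | str, s: ScoringScheme = DEFAULT_SCHEME) -> PairwiseAlignment:
    """Optimal global (Needleman–Wunsch/Gotoh) alignment under affine gaps."""
    sa = a.residues if isinstance(a, SeqRecord) else a
    sb = b.residues if isinstance(b, SeqRecord) else b
    if not sa or not sb:
        raise ValueError("global_align requires nonempty sequences")
    score, moves = _gotoh_global(encode(sa), encode(sb), s.matrix, s.gap_open, s.gap_extend)
    aligned_a, aligned_b = _moves_to_alignment(sa, sb, moves, 0, 0)
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        mode="global",
        a_span=(0, len(sa)),
        b_span=(0, len(sb)),
    )


def glocal_align(a: SeqRecord | str, b: SeqRecord | str, s: ScoringScheme = DEFAULT_SCHEME) -> PairwiseAlignment:
    """Semi-global alignment: all of ``b`` against a region of ``a``, with
    free (unpenalised) leading/trailing residues of ``a``. The tool for
    locating a domain-sized reference inside a full-length protein."""
    sa = a.residues if isinstance(a, SeqRecord) else a
    sb = b.residues if isinstance(b, SeqRecord) else b
    if not sa or not sb:
        raise ValueError("glocal_align requires nonempty sequences")
    score, moves, a0, a1 = _gotoh_glocal(encode(sa), encode(sb), s.matrix, s.gap_open, s.gap_extend)
    aligned_a, aligned_b = _moves_to_alignment(sa, sb, moves, int(a0), 0)
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        mode="glocal",
        a_span=(int(a0), int(a1)),
        b_span=(0, len(sb)),
    )


def local_align(a: SeqRecord | str, b: SeqRecord | str, s: ScoringScheme = DEFAULT_SCHEME) -> PairwiseAlignment:
    """Optimal local (Smith–Waterman) alignment; empty alignment scores 0."""
    sa = a.residues if isinstance(a, SeqRecord) else a
    sb = b.residues if isinstance(b, SeqRecord) else b
    if not sa or not sb:
        raise ValueError("local_align requires nonempty sequences")
    score, moves, i0, j0, i1, j1 = _sw_local(encode(sa), encode(sb), s.matrix, s.gap_open, s.gap_extend)
    if score <= 0:
        return PairwiseAlignment("", "", 0.0, "local", (0, 0), (0, 0))
    aligned_a, aligned_b = _moves_to_alignment(sa, sb, moves, int(i0), int(j0))
    return PairwiseAlignment(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(score),
        mode="local",
        a_span=(int(i0), int(i1)),
        b_span=(int(j0), int(j1)),
    )


def percent_identity(aln: PairwiseAlignment, reference_side: str = "a") -> float:
    """Percent identity with the reference side's aligned residues as the
    denominator: ``100 * identical_columns / reference_non_gap_columns``."""
    if reference_side not in ("a", "b"):
        raise ValueError("reference_side must be 'a' or 'b'")
    ref = aln.aligned_a if reference_side == "a" else aln.aligned_b
    other = aln.aligned_b if reference_side == "a" else aln.aligned_a
    denom = sum(1 for c in ref if c != GAP)
    if denom == 0:
        raise ValueError("percent_identity undefined: no reference residues in alignment")
    ident = sum(1 for x, y in zip(ref, other) if x != GAP and x == y)
    return 100.0 * ident / denom


# ---------------------------------------------------------------------------
# Multiple sequence alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MSA:
    """A multiple alignment: ordered taxa ids and equal-length gapped rows."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate taxa ids in MSA")
        if self.rows:
            L = len(self.rows[0])
            if any(len(r) != L for r in self.rows):
                raise ValueError("MSA rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, taxon: str) -> str:
        return self.rows[self.ids.index(taxon)]

    def degapped(self, taxon: str) -> str:
        return self.row(taxon).replace(GAP, "")

    def subset(self, taxa: Sequence[str]) -> "MSA":
        return MSA(tuple(taxa), tuple(self.row(t) for t in taxa))


_GAP_CODE = len(ALPHABET)  # 21st profile slot


def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency profile over the 21-letter alphabet + gap slot."""
    L = len(rows[0])
    prof = np.zeros((L, _GAP_CODE + 1), dtype=np.float64)
    for r in rows:
        for i, c in enumerate(r):
            prof[i, _GAP_CODE if c == GAP else AA_TO_INDEX[c]] += 1.0
    prof /= len(rows)
    return prof


@lru_cache(maxsize=8)
def _profile_score_matrix(matrix_name: str, gap_extend: int) -> np.ndarray:
    """Extend the substitution matrix with a gap slot for sum-of-pairs
    column scoring: residue-vs-gap costs the extension penalty, gap-vs-gap 0."""
    S = load_substitution_matrix(matrix_name).astype(np.float64)
    n = S.shape[0]
    out = np.zeros((n + 1, n + 1), dtype=np.float64)
    out[:n, :n] = S
    out[n, :n] = -float(gap_extend)
    out[:n, n] = -float(gap_extend)
    return out


def _profile_align(rows_a: list[str], rows_b: list[str], s: ScoringScheme) -> tuple[list[str], list[str]]:
    """Global profile–profile alignment with sum-of-pairs column scores and
    affine gaps; returns the two row groups padded to common columns."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    Sx = _profile_score_matrix(s.matrix_name, s.gap_extend)
    col = pa @ Sx @ pb.T  # (La, Lb) expected pair score per column pairing
    m, n = col.shape
    go, ge = float(s.gap_open), float(s.gap_extend)
    NEG = -1e18
    M = np.full((m + 1, n + 1), NEG)
    X = np.full((m + 1, n + 1), NEG)
    Y = np.full((m + 1, n + 1), NEG)
    ptrM = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrX = np.zeros((m + 1, n + 1), dtype=np.uint8)
    ptrY = np.zeros((m + 1, n + 1), dtype=np.uint8)
    M[0, 0] = 0.0
    for j in range(1, n + 1):
        X[0, j] = -(go + ge * j)
        ptrX[0, j] = 1
    for i in range(1, m + 1):
        Y[i, 0] = -(go + ge * i)
        ptrY[i, 0] = 2
    for i in range(1, m + 1):
        diag_prev = np.stack((M[i - 1, :-1], X[i - 1, :-1], Y[i - 1, :-1]))
        choice = np.argmax(diag_prev, axis=0)
        M[i, 1:] = diag_prev[choice, np.arange(n)] + col[i - 1]
        ptrM[i, 1:] = choice
        # X depends on same row left-to-right: scalar loop
        for j in range(1, n + 1):
            op = M[i, j - 1] - (go + ge)
            ext = X[i, j - 1] - ge
            if op >= ext:
                X[i, j] = op
                ptrX[i, j] = 0
            else:
                X[i, j] = ext
                ptrX[i, j] = 1
            op = M[i - 1, j] - (go + ge)
            ext = Y[i - 1, j] - ge
            if op >= ext:
                Y[i, j] = op
                ptrY[i, j] = 0
            else:
                Y[i, j] = ext
                ptrY[i, j] = 2
    state = int(np.argmax([M[m, n], X[m, n], Y[m, n]]))
    i, j = m, n
    moves: list[int] = []
    while i > 0 or j > 0:
        if state == 0:
            state = int(ptrM[i, j])
            moves.append(0)
            i -= 1
            j -= 1
        elif state == 1:
            state = int(ptrX[i, j])
            moves.append(1)
            j -= 1
        else:
            state = int(ptrY[i, j])
            moves.append(2)
            i -= 1
    moves.reverse()
    out_a = [""] * len(rows_a)
    out_b = [""] * len(rows_b)
    ia = ib = 0
    for mv in moves:
        if mv == 0:
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ia += 1
            ib += 1
        elif mv == 1:
            for k in range(len(rows_a)):
                out_a[k] += GAP
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
        else:
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k in range(len(rows_b)):
                out_b[k] += GAP
            ia += 1
    return out_a, out_b


def _pairwise_p_distance(a: str, b: str, s: ScoringScheme) -> float:
    aln = global_align(a, b, s)
    comp = ident = 0
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x != GAP and y != GAP:
            comp += 1
            if x == y:
                ident += 1
    return 1.0 - ident / comp if comp else 1.0


def progressive_msa(records: Sequence[SeqRecord], s: ScoringScheme = DEFAULT_SCHEME) -> MSA:
    """Progressive multiple alignment.

    Guide tree: neighbor joining on pairwise p-distances from global
    alignments (midpoint-free; the NJ trifurcation is merged left to right).
    Profiles are merged by global profile–profile alignment with sum-of-pairs
    scoring. No iterative refinement.
    """
    if len(records) < 2:
        raise ValueError("progressive_msa requires at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    by_id = {r.id: r for r in records}
    if len(records) == 2:
        aln = global_align(records[0], records[1], s)
        return MSA((ids[0], ids[1]), (aln.aligned_a, aln.aligned_b))

    from .phylogenetics import DistanceMatrix, nj_tree

    n = len(records)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dm[i, j] = dm[j, i] = _pairwise_p_distance(records[i].residues, records[j].residues, s)
    tree = nj_tree(DistanceMatrix(tuple(ids), dm))

    def merge(node) -> tuple[list[str], list[str]]:
        """Returns (taxa, rows) for the subtree."""
        if node.is_tip():
            return [node.name], [by_id[node.name].residues]
        parts = [merge(c) for c in node.children]
        taxa, rows = parts[0]
        for t2, r2 in parts[1:]:
            rows, rows2 = _profile_align(rows, r2, s)
            taxa = taxa + t2
            rows = rows + rows2
        return taxa, rows

    taxa, rows = merge(tree)
    order = {t: k for k, t in enumerate(taxa)}
    out_ids = tuple(sorted(taxa, key=lambda t: ids.index(t)))
    out_rows = tuple(rows[order[t]] for t in out_ids)
    return MSA(out_ids, out_rows)
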