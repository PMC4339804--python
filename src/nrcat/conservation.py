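"""Cross-species similarity and conservation statistics.

Per-domain similarity is percent identity from a global alignment of the
two extracted regions, with the reference (human-side) aligned residues as
the denominator. Window-averaged conservation profiles summarise a
multiple alignment against its reference row; the three-group
classification and the two-species relative-proximity summary condense the
similarity table the way the comparative figures of NR surveys do.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqcore import DEFAULT_SCHEME, GAP, MSA, ScoringScheme, global_align, percent_identity

__all__ = [
    "SimilarityRecord",
    "ConservationProfile",
    "GroupAssignment",
    "region_similarity",
    "windowed_conservation",
    "classify_group",
    "relative_proximity",
]


@dataclass(frozen=True)
class SimilarityRecord:
    nr_symbol: str
    species: str
    region: str  # "DBD" | "LBD"
    similarity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.similarity <= 100.0):
            raise ValueError("similarity must be a percentage")


def region_similarity(
    reference_seq: str,
    ortholog_seq: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> float:
    """Percent identity of an ortholog region against the reference region,
    counted over the reference's aligned residues."""
    if not reference_seq or not ortholog_seq:
        raise ValueError("both regions must be nonempty")
    aln = global_align(reference_seq, ortholog_seq, scheme)
    return percent_identity(aln, "a")


@dataclass(frozen=True)
class ConservationProfile:
    """Per-reference-column identity fractions and their window average."""

    nr_symbol: str
    region: str
    raw: tuple[float, ...]
    windowed: tuple[float, ...]
    window: int

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.windowed):
            raise ValueError("raw/windowed length mismatch")
        for v in self.raw + self.windowed:
            if not (0.0 <= v <= 1.0):
                raise ValueError("profile values must lie in [0, 1]")


def windowed_conservation(
    msa: MSA,
    reference_row: str,
    w: int = 10,
    nr_symbol: str = "",
    region: str = "",
) -> ConservationProfile:
    """Identity-to-reference profile, window averaged across ``w`` residues.

    For each column where the reference row has a residue, the raw value is
    the fraction of non-reference rows carrying the identical residue (gaps
    count as mismatches). The windowed value at reference position ``i``
    averages the raw values over ``[i - w//2, i + ceil(w/2))`` clamped to
    the profile; ``w=1`` returns the raw profile.
    """
    if w < 1:
        raise ValueError("window must be >= 1")
    if reference_row not in msa.ids:
        raise ValueError(f"reference row {reference_row!r} not in MSA")
    ref = msa.row(reference_row)
    others = [r for t, r in zip(msa.ids, msa.rows) if t != reference_row]
    if not others:
        raise ValueError("MSA must contain at least one non-reference row")
    raw: list[float] = []
    for col, c in enumerate(ref):
        if c == GAP:
            continue
        raw.append(sum(1 for r in others if r[col] == c) / len(others))
    arr = np.array(raw)
    half_lo, half_hi = w // 2, (w + 1) // 2
    windowed = [
        float(arr[max(0, i - half_lo) : min(len(arr), i + half_hi)].mean())
        for i in range(len(arr))
    ]
    return ConservationProfile(
        nr_symbol=nr_symbol,
        region=region,
        raw=tuple(raw),
        windowed=tuple(windowed),
        window=w,
    )


@dataclass(frozen=True)
class GroupAssignment:
    nr_symbol: str
    group: int
    min_similarity: float
    max_similarity: float


def classify_group(
    similarities: Mapping[str, float] | Sequence[float],
    nr_symbol: str = "",
    high: float = 90.0,
    low: float = 85.0,
) -> GroupAssignment:
    """Three-way conservation grouping of one receptor's cross-species
    similarities.

    Group 1: every species >= ``high`` (uniformly conserved).
    Group 3: every species < ``low`` (uniformly divergent).
    Group 2: everything else (the broad 60-100% band).
    Precedence 1, then 3, then 2 resolves the overlapping verbal ranges.
    """
    values = list(similarities.values()) if isinstance(similarities, Mapping) else list(similarities)
    if not values:
        raise ValueError("need at least one similarity value")
    lo, hi = min(values), max(values)
    if lo >= high:
        group = 1
    elif hi < low:
        group = 3
    else:
        group = 2
    return GroupAssignment(nr_symbol=nr_symbol, group=group, min_similarity=lo, max_similarity=hi)


def relative_proximity(
    reference_species: str,
    species_a: str,
    species_b: str,
    similarity_table: pd.DataFrame,
) -> dict:
    """Which of two species is closer to the reference, receptor by receptor.

    ``similarity_table`` holds similarities *to the reference species*
    (rows = NR symbols, columns = species). Returns the per-NR winner and
    the summary percentages (share won by each species, share tied), the
    comparison behind rodent-versus-dolphin style proximity panels.
    """
    for sp in (species_a, species_b):
        if sp not in similarity_table.columns:
            raise ValueError(f"species {sp!r} missing from similarity table")
    sub = similarity_table[[species_a, species_b]].dropna()
    winners: dict[str, str] = {}
    tally = {species_a: 0, species_b: 0, "equivalent": 0}
    for symbol, row in sub.iterrows():
        if row[species_a] > row[species_b]:
            win = species_a
        elif row[species_b] > row[species_a]:
            win = species_b
        else:
            win = "equivalent"
        winners[symbol] = win
        tally[win] += 1
    n = len(sub)
    if n == 0:
        raise ValueError("no receptors shared by both species")
    return {
        "reference": reference_species,
        "n_compared": n,
        "winners": winners,
        "percent": {k: 100.0 * v / n for k, v in tally.items()},
    }
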