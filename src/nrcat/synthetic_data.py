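"""Ground-truthed synthetic proteomes.

The simulator emits one proteome per species by evolving a human-like set
of 48 nuclear-receptor (NR) templates along a species tree, with
domain-specific substitution rates (DBD slowest, inter-domain linkers
fastest), gene duplication and loss, and random decoy proteins as negative
controls. Because no indels are simulated, every emitted gene keeps its
template's domain coordinates, so the ground truth
(:class:`SyntheticTruth`) stays exactly checkable for every downstream
stage: homology search, domain annotation, ortholog assignment, presence
matrices and tree building.

Template grammar
----------------
Non-NR0B templates carry a DNA-binding domain realising the double C4
zinc-finger motif ``C-x2-C-x13-C-x2-C`` + 15-residue inter-finger linker +
``C-x5-C-x9-C-x2-C``, preceded by a 2-residue lead and followed by a
C-terminal extension sized so the whole DBD spans 75-80 residues. The
ligand-binding domain is a 12-helix bundle whose helix-3(+11)..helix-10
core — the interval the boundary-rule annotator extracts — spans 170-210
residues. NR0B1/NR0B2 lack the DBD entirely.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import phylogenetics as phylo
from .seqcore import ALPHABET, SeqRecord, global_align, percent_identity

logger = logging.getLogger("nrcat")

AA20 = ALPHABET[:20]  # mutable alphabet: no X in simulated sequences

# C4 double zinc-finger grammar (relative cysteine offsets; linker = 15 in
# generated templates, 13-19 tolerated by the detector).
FINGER1_OFFSETS = (0, 3, 17, 20)
FINGER2_OFFSETS = (0, 6, 16, 19)
FINGER1_LEN = 21
FINGER2_LEN = 20
TEMPLATE_LINKER_LEN = 15
C4_PATTERN = re.compile(r"C.{2}C.{13}C.{2}C.{13,19}?C.{5}C.{9}C.{2}C")

DBD_LENGTH_WINDOW = (75, 80)
LBD_LENGTH_WINDOW = (170, 210)

REGION_DBD, REGION_LBD, REGION_LINKER = 0, 1, 2


def default_manifest_path() -> Path:
    return Path(str(resources.files("nrcat").joinpath("data/nr_manifest.tsv")))


@dataclass(frozen=True)
class NRTemplate:
    """A reference NR with annotated domain architecture."""

    symbol: str
    trivial_name: str
    subfamily: str  # NR0 .. NR6
    group: str  # e.g. NR3A
    sequence: str
    dbd_interval: tuple[int, int] | None
    zf_cys_positions: tuple[int, ...] | None
    lbd_interval: tuple[int, int]
    helix_intervals: tuple[tuple[int, int], ...]
    lacks_dbd: bool

    def __post_init__(self) -> None:
        if self.lacks_dbd != (self.group == "NR0B"):
            raise ValueError(f"{self.symbol}: lacks_dbd must hold exactly for NR0B")
        if self.lacks_dbd:
            if self.dbd_interval is not None or self.zf_cys_positions is not None:
                raise ValueError(f"{self.symbol}: NR0B template cannot carry a DBD")
        else:
            lo, hi = self.dbd_interval
            if not (DBD_LENGTH_WINDOW[0] <= hi - lo <= DBD_LENGTH_WINDOW[1]):
                raise ValueError(f"{self.symbol}: DBD length {hi - lo} outside window")
            if len(self.zf_cys_positions) != 8:
                raise ValueError(f"{self.symbol}: need 8 zinc-finger cysteines")
            for p in self.zf_cys_positions:
                if not (lo <= p < hi) or self.sequence[p] != "C":
                    raise ValueError(f"{self.symbol}: cysteine annotation invalid at {p}")
        llo, lhi = self.lbd_interval
        if not (LBD_LENGTH_WINDOW[0] <= lhi - llo <= LBD_LENGTH_WINDOW[1]):
            raise ValueError(f"{self.symbol}: LBD length {lhi - llo} outside window")
        if len(self.helix_intervals) != 12:
            raise ValueError(f"{self.symbol}: need 12 helix intervals")
        prev_end = llo
        for h0, h1 in self.helix_intervals:
            if h0 < prev_end or h1 <= h0 or h1 > lhi:
                raise ValueError(f"{self.symbol}: helix intervals malformed")
            prev_end = h1

    @property
    def lbd_sequence(self) -> str:
        return self.sequence[slice(*self.lbd_interval)]

    @property
    def dbd_sequence(self) -> str | None:
        return None if self.lacks_dbd else self.sequence[slice(*self.dbd_interval)]

    @property
    def core_lbd_interval(self) -> tuple[int, int]:
        """Helix-3(+11) .. helix-10 end: the interval the annotator extracts."""
        h3, h10 = self.helix_intervals[2], self.helix_intervals[9]
        return (h3[0] + 11, h10[1])

    def region_codes(self) -> np.ndarray:
        codes = np.full(len(self.sequence), REGION_LINKER, dtype=np.int8)
        if not self.lacks_dbd:
            codes[slice(*self.dbd_interval)] = REGION_DBD
        codes[slice(*self.lbd_interval)] = REGION_LBD
        return codes


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def _random_noncys(rng: np.random.Generator, n: int) -> str:
    letters = [c for c in AA20 if c != "C"]
    return "".join(rng.choice(letters, size=n))


def _build_dbd(rng: np.random.Generator) -> tuple[str, tuple[int, ...]]:
    """DBD with the C4 grammar; returns (sequence, relative cys positions)."""
    lead = _random_noncys(rng, 2)
    finger1 = ["?"] * FINGER1_LEN
    for off in FINGER1_OFFSETS:
        finger1[off] = "C"
    finger2 = ["?"] * FINGER2_LEN
    for off in FINGER2_OFFSETS:
        finger2[off] = "C"
    fill = iter(_random_noncys(rng, FINGER1_LEN + FINGER2_LEN))
    finger1 = [c if c == "C" else next(fill) for c in finger1]
    finger2 = [c if c == "C" else next(fill) for c in finger2]
    linker = _random_noncys(rng, TEMPLATE_LINKER_LEN)
    cte_len = int(rng.integers(17, 23))  # total 58 + cte in [75, 80]
    cte = _random_noncys(rng, cte_len)
    seq = lead + "".join(finger1) + linker + "".join(finger2) + cte
    c1 = 2
    f2 = 2 + FINGER1_LEN + TEMPLATE_LINKER_LEN
    cys = tuple([c1 + o for o in FINGER1_OFFSETS] + [f2 + o for o in FINGER2_OFFSETS])
    return seq, cys


def _build_lbd(rng: np.random.Generator) -> tuple[str, tuple[tuple[int, int], ...]]:
    """12-helix LBD; helices 3..10 sized so the helix3(+11)..helix10 core
    spans 172-182 residues (and the full bundle stays within 170-210)."""
    flank = 3  # helices 1, 2, 11, 12
    loops = 1
    core_helices = [22] * 8  # helices 3..10
    extra = int(rng.integers(0, 11))
    for _ in range(extra):
        core_helices[int(rng.integers(0, 8))] += 1
    lens = [flank, flank] + core_helices + [flank, flank]
    seq_parts: list[str] = []
    intervals: list[tuple[int, int]] = []
    pos = 0
    for k, hl in enumerate(lens):
        if k > 0:
            seq_parts.append(_random_noncys(rng, loops))
            pos += loops
        intervals.append((pos, pos + hl))
        seq_parts.append(_random_noncys(rng, hl))
        pos += hl
    return "".join(seq_parts), tuple(intervals)


def build_reference_templates(
    manifest_path: str | Path | None = None,
    seed: int = 0,
    max_identity: float = 70.0,
) -> list[NRTemplate]:
    """Generate the 48-receptor reference set from the packaged manifest.

    Deterministic for a fixed seed; templates are rejection-sampled so that
    no two exceed ``max_identity`` percent global identity.
    """
    path = Path(manifest_path) if manifest_path else default_manifest_path()
    manifest = pd.read_csv(path, sep="\t", dtype=str)
    if len(manifest) != 48:
        raise ValueError(f"manifest must list 48 receptors, got {len(manifest)}")
    if manifest["symbol"].duplicated().any():
        raise ValueError("manifest has duplicate symbols")
    rng = np.random.default_rng(seed)
    templates: list[NRTemplate] = []
    for row in manifest.itertuples(index=False):
        lacks_dbd = str(row.lacks_dbd) == "1"
        for _attempt in range(50):
            nterm = _random_seq(rng, int(rng.integers(20, 61)))
            parts = [nterm]
            pos = len(nterm)
            dbd_interval = None
            cys_positions = None
            if not lacks_dbd:
                dbd_seq, rel_cys = _build_dbd(rng)
                dbd_interval = (pos, pos + len(dbd_seq))
                cys_positions = tuple(pos + c for c in rel_cys)
                parts.append(dbd_seq)
                pos += len(dbd_seq)
            hinge = _random_seq(rng, int(rng.integers(15, 41)))
            parts.append(hinge)
            pos += len(hinge)
            lbd_seq, rel_helices = _build_lbd(rng)
            lbd_interval = (pos, pos + len(lbd_seq))
            helices = tuple((pos + a, pos + b) for a, b in rel_helices)
            parts.append(lbd_seq)
            pos += len(lbd_seq)
            parts.append(_random_seq(rng, int(rng.integers(5, 16))))
            seq = "".join(parts)
            if all(
                percent_identity(global_align(seq, t.sequence), "a") < max_identity
                for t in templates
            ):
                break
        else:  # pragma: no cover - vanishingly unlikely with random sequences
            raise RuntimeError(f"could not sample a distinct template for {row.symbol}")
        templates.append(
            NRTemplate(
                symbol=row.symbol,
                trivial_name=row.trivial_name,
                subfamily=row.subfamily,
                group=row.group,
                sequence=seq,
                dbd_interval=dbd_interval,
                zf_cys_positions=cys_positions,
                lbd_interval=lbd_interval,
                helix_intervals=helices,
                lacks_dbd=lacks_dbd,
            )
        )
    return templates


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------

#: Twelve toxicological model species; branch lengths are expected
#: substitutions per site at the linker (fastest) rate.
DEFAULT_SPECIES_TREE_NEWICK = (
    "((((((human:0.055,dolphin:0.065)cetartiodactyla:0.02,"
    "(mouse:0.045,rat:0.045)rodentia:0.045)mammalia:0.05,"
    "((chicken:0.03,duck:0.03)aves:0.04,turtle:0.06)sauropsida:0.04)amniota:0.02,"
    "frog:0.12)tetrapoda:0.04,"
    "(zebrafish:0.09,(medaka:0.055,(tilapia:0.04,stickleback:0.04)percomorpha:0.02)"
    "acanthomorpha:0.03)teleostei:0.10)root);"
)


def default_species_tree() -> TreeNode:
    return phylo.read_newick(DEFAULT_SPECIES_TREE_NEWICK)


@dataclass(frozen=True)
class ForcedEvent:
    """A scripted duplication or loss: applied to every copy of ``symbol``
    on the branch *above* the node named ``branch``."""

    branch: str
    symbol: str
    kind: str  # "loss" | "duplication"

    def __post_init__(self) -> None:
        if self.kind not in ("loss", "duplication"):
            raise ValueError("kind must be 'loss' or 'duplication'")


#: Scripted events emulating well-known lineage patterns: loss of PXR
#: (NR1I2) in birds, and a teleost-ancestor duplication of RORg (NR1F3).
DEFAULT_FORCED_EVENTS = (
    ForcedEvent("aves", "NR1I2", "loss"),
    ForcedEvent("teleostei", "NR1F3", "duplication"),
)


@dataclass(frozen=True)
class EvolveConfig:
    """Simulation parameters.

    Rates are multipliers on branch length (linker = 1 by construction);
    the constraint ``dbd <= lbd <= linker`` encodes the conservation
    ordering DBD > LBD > linker.
    """

    rate_dbd: float = 0.3
    rate_lbd: float = 0.6
    rate_linker: float = 1.0
    duplication_prob: float = 0.004
    loss_prob: float = 0.004
    decoys_per_species: int = 100
    decoy_length_mean: float = 350.0
    decoy_length_sd: float = 80.0
    decoy_min_length: int = 60
    seed: int = 0
    forced_events: tuple[ForcedEvent, ...] = DEFAULT_FORCED_EVENTS

    def __post_init__(self) -> None:
        if not (0 < self.rate_dbd <= self.rate_lbd <= self.rate_linker):
            raise ValueError("require 0 < rate_dbd <= rate_lbd <= rate_linker")
        for p in (self.duplication_prob, self.loss_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("event probabilities must be in [0, 1]")

    @property
    def region_rates(self) -> np.ndarray:
        return np.array([self.rate_dbd, self.rate_lbd, self.rate_linker])


@dataclass
class TruthRecord:
    gene_id: str
    species: str
    origin_symbol: str
    is_paralog: bool
    is_decoy: bool
    events: str
    dbd_start: int | None
    dbd_end: int | None
    lbd_start: int | None
    lbd_end: int | None
    substitutions: int


@dataclass
class SyntheticTruth:
    """Per-gene ground truth emitted alongside the proteomes."""

    records: list[TruthRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def genes_of(self, species: str, include_decoys: bool = False) -> list[TruthRecord]:
        return [
            r
            for r in self.records
            if r.species == species and (include_decoys or not r.is_decoy)
        ]

    def record(self, gene_id: str) -> TruthRecord:
        for r in self.records:
            if r.gene_id == gene_id:
                return r
        raise KeyError(gene_id)

    def copy_number(self, species: str, symbol: str) -> int:
        return sum(
            1
            for r in self.records
            if r.species == species and not r.is_decoy and r.origin_symbol == symbol
        )

    def write(self, tsv_path: str | Path, json_path: str | Path | None = None) -> None:
        df = self.to_frame()
        df.to_csv(tsv_path, sep="\t", index=False)
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump([vars(r) for r in self.records], fh, indent=1)


@dataclass
class _GeneState:
    template: NRTemplate
    residues: np.ndarray  # char array
    immutable: np.ndarray  # bool mask (zinc-finger cysteines)
    regions: np.ndarray
    is_paralog: bool
    substitutions: int
    events: list[str]


def make_decoys(
    n: int,
    length_params: tuple[float, float, int] = (350.0, 80.0, 60),
    seed: int = 0,
    species: str = "",
    composition: np.ndarray | None = None,
) -> list[SeqRecord]:
    """Random background proteins; any draw matching the C4 double-finger
    grammar is rejected and resampled."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    mean, sd, min_len = length_params
    letters = np.array(list(AA20))
    probs = composition if composition is not None else np.full(20, 1 / 20)
    out: list[SeqRecord] = []
    for i in range(n):
        while True:
            L = max(min_len, int(round(rng.normal(mean, sd))))
            seq = "".join(rng.choice(letters, size=L, p=probs))
            if not C4_PATTERN.search(seq):
                break
        prefix = f"{species}_" if species else ""
        out.append(SeqRecord(id=f"{prefix}decoy_{i:04d}", residues=seq, species=species))
    return out


def _mutate(gene: _GeneState, t: float, cfg: EvolveConfig, rng: np.random.Generator) -> None:
    if t <= 0:
        return
    p_site = 1.0 - np.exp(-t * cfg.region_rates[gene.regions])
    hit = (rng.random(len(gene.residues)) < p_site) & ~gene.immutable
    idx = np.flatnonzero(hit)
    for i in idx:
        cur = gene.residues[i]
        choices = [c for c in AA20 if c != cur]
        gene.residues[i] = choices[int(rng.integers(0, 19))]
    gene.substitutions += len(idx)


def evolve_proteomes(
    templates: list[NRTemplate],
    tree: TreeNode,
    cfg: EvolveConfig,
) -> tuple[dict[str, list[SeqRecord]], SyntheticTruth]:
    """Evolve the template set along the species tree.

    Per branch and per gene copy: loss (scripted or with ``loss_prob``),
    then duplication (scripted or with ``duplication_prob``), then sitewise
    substitution with probability ``1 - exp(-t * rate_region)``; replacement
    residues are uniform over the 19 alternatives and zinc-finger cysteines
    never mutate. Decoys are appended per species. Returns the proteomes
    and the ground truth (a bijection onto the non-decoy records).
    """
    rng = np.random.default_rng(cfg.seed)
    forced: dict[tuple[str, str], str] = {
        (ev.branch, ev.symbol): ev.kind for ev in cfg.forced_events
    }
    root_genes = [
        _GeneState(
            template=t,
            residues=np.array(list(t.sequence)),
            immutable=np.isin(
                np.arange(len(t.sequence)),
                np.array(t.zf_cys_positions or [], dtype=int),
            ),
            regions=t.region_codes(),
            is_paralog=False,
            substitutions=0,
            events=[],
        )
        for t in templates
    ]
    proteomes: dict[str, list[SeqRecord]] = {}
    truth = SyntheticTruth()

    def copy_gene(g: _GeneState) -> _GeneState:
        return _GeneState(
            template=g.template,
            residues=g.residues.copy(),
            immutable=g.immutable,
            regions=g.regions,
            is_paralog=g.is_paralog,
            substitutions=g.substitutions,
            events=list(g.events),
        )

    def descend(node: TreeNode, genes: list[_GeneState]) -> None:
        for child in node.children:
            label = child.name or ""
            branch_genes: list[_GeneState] = []
            for g in genes:
                kind = forced.get((label, g.template.symbol))
                if kind == "loss" or (kind is None and rng.random() < cfg.loss_prob):
                    logger.debug("loss of %s on branch to %s", g.template.symbol, label)
                    continue
                g2 = copy_gene(g)
                if kind == "duplication" or (
                    kind is None and rng.random() < cfg.duplication_prob
                ):
                    g3 = copy_gene(g2)
                    g3.is_paralog = True
                    g3.events.append(f"duplication@{label}")
                    g2.events.append(f"duplication@{label}")
                    branch_genes.extend([g2, g3])
                else:
                    branch_genes.append(g2)
            t = float(child.length or 0.0)
            for g in branch_genes:
                _mutate(g, t, cfg, rng)
            if child.is_tip():
                species = child.name
                counts: dict[str, int] = {}
                records: list[SeqRecord] = []
                for g in branch_genes:
                    k = counts.get(g.template.symbol, 0) + 1
                    counts[g.template.symbol] = k
                    gid = f"{species}_{g.template.symbol}_{k}"
                    seq = "".join(g.residues)
                    records.append(SeqRecord(id=gid, residues=seq, species=species))
                    tpl = g.template
                    truth.records.append(
                        TruthRecord(
                            gene_id=gid,
                            species=species,
                            origin_symbol=tpl.symbol,
                            is_paralog=g.is_paralog,
                            is_decoy=False,
                            events=";".join(g.events),
                            dbd_start=None if tpl.lacks_dbd else tpl.dbd_interval[0],
                            dbd_end=None if tpl.lacks_dbd else tpl.dbd_interval[1],
                            lbd_start=tpl.lbd_interval[0],
                            lbd_end=tpl.lbd_interval[1],
                            substitutions=g.substitutions,
                        )
                    )
                decoys = make_decoys(
                    cfg.decoys_per_species,
                    (cfg.decoy_length_mean, cfg.decoy_length_sd, cfg.decoy_min_length),
                    seed=int(rng.integers(0, 2**31)),
                    species=species,
                )
                for d in decoys:
                    truth.records.append(
                        TruthRecord(
                            gene_id=d.id,
                            species=species,
                            origin_symbol="",
                            is_paralog=False,
                            is_decoy=True,
                            events="",
                            dbd_start=None,
                            dbd_end=None,
                            lbd_start=None,
                            lbd_end=None,
                            substitutions=0,
                        )
                    )
                proteomes[species] = records + decoys
            else:
                descend(child, branch_genes)

    descend(tree, root_genes)
    return proteomes, truth
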