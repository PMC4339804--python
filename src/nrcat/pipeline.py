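"""End-to-end orchestration: simulate -> search -> annotate -> catalog ->
conserve -> tree, plus benchmark evaluation against the simulator's truth.

A :class:`RunConfig` (YAML-loadable; seed mandatory) drives every stage;
the effective configuration is echoed into the output directory, every
stage logs its record counts, and a fixed seed reproduces byte-identical
artifacts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog as cat
from . import conservation as cons
from . import domain_annotation as da
from . import homology_search as hs
from . import phylogenetics as phylo
from . import synthetic_data as sd
from .seqcore import MSA, DEFAULT_SCHEME, ScoringScheme, SeqRecord, write_fasta

logger = logging.getLogger("nrcat")

__all__ = ["RunConfig", "BenchmarkReport", "run_pipeline", "evaluate_against_truth", "PipelineResult"]

STAGES = ("simulate", "search", "annotate", "catalog", "conserve", "tree", "evaluate")


@dataclass(frozen=True)
class RunConfig:
    """Pipeline parameters; defaults mirror the survey's stated settings
    (10-residue conservation windows, 1000 bootstrap replicates,
    recall-calibrated E-value cutoffs)."""

    outdir: str
    seed: int
    manifest_path: str | None = None
    species_tree_newick: str | None = None
    calibration_species: str = "zebrafish"
    reference_species: str = "human"
    # simulation
    rate_dbd: float = 0.3
    rate_lbd: float = 0.6
    rate_linker: float = 1.0
    duplication_prob: float = 0.004
    loss_prob: float = 0.004
    decoys_per_species: int = 100
    # search
    seed_word_size: int = 4
    e_ceiling: float = 10.0
    #: The calibrated cutoff is exact for the calibration proteome; species
    #: more diverged than it need slack, so the applied cutoff is the
    #: calibrated value times this margin (still far below any decoy E).
    calibration_margin: float = 1e6
    # domain verification
    theta1: float = da.DEFAULT_THETA1
    theta2: float = da.DEFAULT_THETA2
    # conservation
    window: int = 10
    group_high: float = 90.0
    group_low: float = 85.0
    profile_symbols: tuple[str, ...] = ("NR2B1", "NR3A1", "NR0B2")
    proximity_pair: tuple[str, str] = ("dolphin", "mouse")
    # phylogenetics
    tree_symbols: tuple[str, ...] = ("NR3A1",)
    bootstrap_B: int = 1000
    deletion_mode: str = "pairwise"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.deletion_mode not in ("pairwise", "complete"):
            raise ValueError("deletion_mode must be 'pairwise' or 'complete'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" not in data:
            raise ValueError(f"config {path}: seed is mandatory")
        for key in ("profile_symbols", "tree_symbols", "proximity_pair"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def echo(self, outdir: Path) -> None:
        data = asdict(self)
        for key in ("profile_symbols", "tree_symbols", "proximity_pair"):
            data[key] = list(data[key])
        with open(outdir / "config.yaml", "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class BenchmarkReport:
    """Pipeline metrics against the simulator's ground truth."""

    identification_precision: float
    identification_recall: float
    assignment_accuracy: float
    presence_matrix_exact: bool
    presence_mismatched_cells: int
    dbd_start_offsets: dict[int, int]
    dbd_end_offsets: dict[int, int]
    orphan_ids: list[str]
    n_true_genes: int
    n_verified: int
    runtime_seconds: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = asdict(self)
        data["dbd_start_offsets"] = {str(k): v for k, v in self.dbd_start_offsets.items()}
        data["dbd_end_offsets"] = {str(k): v for k, v in self.dbd_end_offsets.items()}
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)


@dataclass
class PipelineResult:
    """In-memory handles to everything the pipeline produced."""

    outdir: Path
    templates: list
    proteomes: dict[str, list[SeqRecord]]
    truth: sd.SyntheticTruth
    e_cutoff: float | None = None
    hits: dict[str, list[hs.SearchHit]] = field(default_factory=dict)
    candidates: dict[str, list[str]] = field(default_factory=dict)
    merge_reports: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    annotations: dict[str, da.DomainAnnotation] = field(default_factory=dict)
    assignments: list[cat.OrthologAssignment] = field(default_factory=list)
    presence: pd.DataFrame | None = None
    summary: dict | None = None
    similarity: dict[str, pd.DataFrame] = field(default_factory=dict)
    groups: dict[str, cons.GroupAssignment] = field(default_factory=dict)
    proximity: dict | None = None
    trees: dict[str, str] = field(default_factory=dict)
    report: BenchmarkReport | None = None
    stage_seconds: dict[str, float] = field(default_factory=dict)


def _query_records(templates) -> list[SeqRecord]:
    """Search queries: each template's concatenated DBD+LBD (LBD only for
    the DBD-less NR0B receptors)."""
    out = []
    for t in templates:
        seq = (t.dbd_sequence or "") + t.lbd_sequence
        out.append(SeqRecord(id=t.symbol, residues=seq, species="reference"))
    return out


def _best_ortholog_regions(result: PipelineResult, scheme: ScoringScheme):
    """Per (symbol, species): extracted DBD/LBD of the best-scoring
    assigned candidate (the 'best alignment ortholog' when paralogs exist)."""
    by_id = {
        rec.id: rec for recs in result.proteomes.values() for rec in recs
    }
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for a in result.assignments:
        key = (a.assigned_symbol, a.species)
        if key not in best or a.score > best[key][0]:
            best[key] = (a.score, a.candidate_id)
    regions: dict[tuple[str, str], tuple[str | None, str | None]] = {}
    for (symbol, species), (_score, cid) in best.items():
        ann = result.annotations[cid]
        rec = by_id[cid]
        dbd = rec.residues[slice(*ann.dbd)] if ann.dbd else None
        lbd = rec.residues[slice(*ann.lbd)] if ann.lbd else None
        regions[(symbol, species)] = (dbd, lbd)
    return regions


def run_pipeline(
    config: RunConfig,
    through: str = "evaluate",
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> PipelineResult:
    """Run the pipeline up to and including stage ``through``."""
    if through not in STAGES:
        raise ValueError(f"unknown stage {through!r}; stages are {STAGES}")
    last = STAGES.index(through)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.echo(outdir)
    timings: dict[str, float] = {}

    def stage_enabled(name: str) -> bool:
        return STAGES.index(name) <= last

    # ----- simulate ---------------------------------------------------
    t0 = time.perf_counter()
    templates = sd.build_reference_templates(config.manifest_path, seed=config.seed)
    newick = config.species_tree_newick or sd.DEFAULT_SPECIES_TREE_NEWICK
    tree = phylo.read_newick(newick)
    evolve_cfg = sd.EvolveConfig(
        rate_dbd=config.rate_dbd,
        rate_lbd=config.rate_lbd,
        rate_linker=config.rate_linker,
        duplication_prob=config.duplication_prob,
        loss_prob=config.loss_prob,
        decoys_per_species=config.decoys_per_species,
        seed=(config.seed + 1) % 2**31,
    )
    proteomes, truth = sd.evolve_proteomes(templates, tree, evolve_cfg)
    species_list = sorted(proteomes)
    write_fasta(
        [SeqRecord(id=t.symbol, residues=t.sequence, species="reference") for t in templates],
        outdir / "templates.fasta",
    )
    for species, recs in proteomes.items():
        write_fasta(recs, outdir / f"proteome_{species}.fasta")
    truth.write(outdir / "truth.tsv", outdir / "truth.json")
    result = PipelineResult(outdir=outdir, templates=templates, proteomes=proteomes, truth=truth)
    timings["simulate"] = time.perf_counter() - t0
    logger.info(
        "simulate: %d templates, %d species, %d sequences",
        len(templates),
        len(proteomes),
        sum(len(v) for v in proteomes.values()),
    )
    if not stage_enabled("search"):
        result.stage_seconds = timings
        return result

    # ----- search ------------------------------------------------------
    t0 = time.perf_counter()
    queries = _query_records(templates)
    calib_species = config.calibration_species
    if calib_species not in proteomes:
        raise ValueError(f"calibration species {calib_species!r} not simulated")
    calib_true = {r.gene_id for r in truth.genes_of(calib_species)}
    calibrated = hs.calibrate_cutoff(
        queries,
        proteomes[calib_species],
        calib_true,
        scheme,
        k=config.seed_word_size,
        ceiling=config.e_ceiling,
    )
    e_cutoff = min(calibrated * config.calibration_margin, config.e_ceiling)
    result.e_cutoff = e_cutoff
    logger.info(
        "search: calibrated E-value cutoff %.3e on %s (applied with margin: %.3e)",
        calibrated,
        calib_species,
        e_cutoff,
    )
    for species in species_list:
        index = hs.build_index(proteomes[species], config.seed_word_size)
        hit_sets = [hs.search(q, index, scheme, e_cutoff=e_cutoff) for q in queries]
        all_hits = sorted(
            (h for hits in hit_sets for h in hits),
            key=lambda h: (h.evalue, h.query_id, h.target_id),
        )
        result.hits[species] = all_hits
        hs.write_hits_tsv(all_hits, outdir / f"hits_{species}.tsv")
        cands, report = hs.merge_and_dedupe(hit_sets, proteomes[species])
        result.candidates[species] = cands
        result.merge_reports[species] = report
        logger.info(
            "search[%s]: %d hits -> %d candidates (%d merged)",
            species,
            len(all_hits),
            len(cands),
            sum(len(v) for v in report.values()),
        )
    timings["search"] = time.perf_counter() - t0
    if not stage_enabled("annotate"):
        result.stage_seconds = timings
        return result

    # ----- annotate ----------------------------------------------------
    t0 = time.perf_counter()
    rows = []
    for species in species_list:
        by_id = {r.id: r for r in proteomes[species]}
        best_query: dict[str, str] = {}
        for h in result.hits[species]:  # hits sorted by ascending E
            best_query.setdefault(h.target_id, h.query_id)
        n_verified = 0
        for cid in result.candidates[species]:
            rec = by_id[cid]
            ann = da.annotate_candidate(
                rec, templates, scheme, reference_hint=best_query.get(cid)
            )
            ann = da.verify_nr(rec, ann, templates, scheme, config.theta1, config.theta2)
            result.annotations[cid] = ann
            n_verified += ann.verified
            for label, interval in (("DBD", ann.dbd), ("LBD", ann.lbd)):
                if interval:
                    rows.append(
                        {
                            "gene_id": cid,
                            "start": interval[0],
                            "end": interval[1],
                            "domain": label,
                            "score": round(ann.lbd_alignment_score, 4),
                            "class": ann.assigned_class,
                        }
                    )
        logger.info(
            "annotate[%s]: %d candidates, %d verified",
            species,
            len(result.candidates[species]),
            n_verified,
        )
    pd.DataFrame(rows).to_csv(outdir / "domains.tsv", sep="\t", index=False)
    with open(outdir / "annotations.json", "w") as fh:
        json.dump(
            {cid: asdict(a) for cid, a in sorted(result.annotations.items())},
            fh,
            indent=1,
        )
    timings["annotate"] = time.perf_counter() - t0
    if not stage_enabled("catalog"):
        result.stage_seconds = timings
        return result

    # ----- catalog ------------------------------------------------------
    t0 = time.perf_counter()
    manifest = pd.read_csv(
        config.manifest_path or sd.default_manifest_path(), sep="\t", dtype=str
    )
    pairs = []
    by_id = {rec.id: rec for recs in proteomes.values() for rec in recs}
    for cid, ann in result.annotations.items():
        pairs.append((by_id[cid], ann))
    result.assignments = cat.assign_orthologs(pairs, templates, scheme)
    result.presence = cat.build_presence_matrix(result.assignments, species_list, manifest)
    result.summary = cat.subfamily_summary(result.presence, manifest)
    pd.DataFrame([asdict(a) for a in result.assignments]).to_csv(
        outdir / "assignments.tsv", sep="\t", index=False
    )
    result.presence.to_csv(outdir / "presence_matrix.tsv", sep="\t")
    with open(outdir / "subfamily_summary.json", "w") as fh:
        json.dump(result.summary, fh, indent=1)
    logger.info(
        "catalog: %d assignments; species totals %s",
        len(result.assignments),
        {s: v["total"] for s, v in result.summary.items()},
    )
    timings["catalog"] = time.perf_counter() - t0
    if not stage_enabled("conserve"):
        result.stage_seconds = timings
        return result

    # ----- conserve -----------------------------------------------------
    t0 = time.perf_counter()
    regions = _best_ortholog_regions(result, scheme)
    ref_sp = config.reference_species
    sim_frames: dict[str, pd.DataFrame] = {}
    for region_idx, region_name in ((0, "DBD"), (1, "LBD")):
        table = pd.DataFrame(
            np.nan, index=[t.symbol for t in templates], columns=species_list
        )
        for t in templates:
            ref = regions.get((t.symbol, ref_sp))
            if ref is None or ref[region_idx] is None:
                continue
            for species in species_list:
                other = regions.get((t.symbol, species))
                if other is None or other[region_idx] is None:
                    continue
                table.loc[t.symbol, species] = cons.region_similarity(
                    ref[region_idx], other[region_idx], scheme
                )
        table.to_csv(outdir / f"similarity_{region_name.lower()}.tsv", sep="\t")
        sim_frames[region_name] = table
    result.similarity = sim_frames
    lbd = sim_frames["LBD"]
    for symbol, row in lbd.iterrows():
        vals = row.drop(labels=[ref_sp]).dropna()
        if len(vals):
            result.groups[symbol] = cons.classify_group(
                dict(vals), symbol, config.group_high, config.group_low
            )
    with open(outdir / "groups.json", "w") as fh:
        json.dump({s: asdict(g) for s, g in sorted(result.groups.items())}, fh, indent=1)
    sp_a, sp_b = config.proximity_pair
    result.proximity = cons.relative_proximity(ref_sp, sp_a, sp_b, lbd)
    with open(outdir / "proximity.json", "w") as fh:
        json.dump(result.proximity, fh, indent=1)
    profile_rows = []
    for symbol in config.profile_symbols:
        members = [
            (sp, regions[(symbol, sp)][1])
            for sp in species_list
            if (symbol, sp) in regions and regions[(symbol, sp)][1]
        ]
        if len(members) < 2 or ref_sp not in dict(members):
            continue
        from .seqcore import progressive_msa

        msa = progressive_msa(
            [SeqRecord(id=sp, residues=seq, species=sp) for sp, seq in members], scheme
        )
        prof = cons.windowed_conservation(
            msa, ref_sp, config.window, nr_symbol=symbol, region="LBD"
        )
        for pos, (r, wv) in enumerate(zip(prof.raw, prof.windowed)):
            profile_rows.append(
                {"symbol": symbol, "position": pos, "raw": round(r, 4), "windowed": round(wv, 4)}
            )
    pd.DataFrame(profile_rows).to_csv(outdir / "profiles.tsv", sep="\t", index=False)
    timings["conserve"] = time.perf_counter() - t0
    logger.info("conserve: %d receptors grouped", len(result.groups))
    if not stage_enabled("tree"):
        result.stage_seconds = timings
        return result

    # ----- tree ---------------------------------------------------------
    t0 = time.perf_counter()
    from .seqcore import progressive_msa

    builder = phylo.msa_nj_builder(config.deletion_mode)
    for symbol in config.tree_symbols:
        members = []
        for species in species_list:
            reg = regions.get((symbol, species))
            if reg is None:
                continue
            combined = (reg[0] or "") + (reg[1] or "")
            if combined:
                members.append(SeqRecord(id=species, residues=combined, species=species))
        if len(members) < 3:
            logger.warning("tree[%s]: fewer than 3 species with regions; skipped", symbol)
            continue
        msa = progressive_msa(members, scheme)
        tree_b = phylo.bootstrap_support(
            msa, builder, B=config.bootstrap_B, seed=(config.seed + 2) % 2**31
        )
        text = phylo.write_newick(tree_b)
        result.trees[symbol] = text
        (outdir / f"tree_{symbol}.nwk").write_text(text)
    timings["tree"] = time.perf_counter() - t0
    if not stage_enabled("evaluate"):
        result.stage_seconds = timings
        return result

    # ----- evaluate -----------------------------------------------------
    t0 = time.perf_counter()
    result.report = evaluate_against_truth(result)
    timings["evaluate"] = time.perf_counter() - t0
    result.report.runtime_seconds = dict(timings)
    result.report.to_json(outdir / "benchmark_report.json")
    result.stage_seconds = timings
    return result


def evaluate_against_truth(
    result: PipelineResult, truth: sd.SyntheticTruth | None = None
) -> BenchmarkReport:
    """Join pipeline outputs to the simulator's truth on gene id.

    Identification counts one found gene per truth record: ids absorbed by
    sequence-level deduplication count as found through the id that kept
    them. Unknown ids appear in ``orphan_ids`` rather than failing.
    """
    truth = truth or result.truth
    true_ids = {r.gene_id for r in truth.records if not r.is_decoy}
    decoy_ids = {r.gene_id for r in truth.records if r.is_decoy}
    found: set[str] = set()
    orphans: list[str] = []
    verified_ids = [cid for cid, a in result.annotations.items() if a.verified]
    for cid in verified_ids:
        members = [cid]
        for species, report in result.merge_reports.items():
            if cid in report:
                members.extend(report[cid])
        for m in members:
            if m in true_ids:
                found.add(m)
            elif m not in decoy_ids:
                orphans.append(m)
    tp = sum(1 for cid in verified_ids if cid in true_ids)
    fp = len(verified_ids) - tp
    precision = tp / (tp + fp) if verified_ids else 0.0
    recall = len(found) / len(true_ids) if true_ids else 0.0

    correct = sum(
        1
        for a in result.assignments
        if a.candidate_id in true_ids
        and truth.record(a.candidate_id).origin_symbol == a.assigned_symbol
    )
    accuracy = correct / len(result.assignments) if result.assignments else 0.0

    start_offsets: dict[int, int] = {}
    end_offsets: dict[int, int] = {}
    for cid in verified_ids:
        if cid not in true_ids:
            continue
        rec = truth.record(cid)
        ann = result.annotations[cid]
        if rec.dbd_start is not None and ann.dbd is not None:
            ds = ann.dbd[0] - rec.dbd_start
            de = ann.dbd[1] - rec.dbd_end
            start_offsets[ds] = start_offsets.get(ds, 0) + 1
            end_offsets[de] = end_offsets.get(de, 0) + 1

    mismatched = 0
    exact = result.presence is not None
    if result.presence is not None:
        # dedupe-collapsed identical copies cannot be distinguished; count
        # truth copies net of collapsed ids
        collapsed: set[str] = set()
        for report in result.merge_reports.values():
            for kept, merged in report.items():
                collapsed.update(merged)
        for species in result.presence.index:
            for symbol in result.presence.columns:
                true_copies = sum(
                    1
                    for r in truth.records
                    if r.species == species
                    and not r.is_decoy
                    and r.origin_symbol == symbol
                    and r.gene_id not in collapsed
                )
                if int(result.presence.loc[species, symbol]) != true_copies:
                    mismatched += 1
        exact = mismatched == 0

    return BenchmarkReport(
        identification_precision=precision,
        identification_recall=recall,
        assignment_accuracy=accuracy,
        presence_matrix_exact=exact,
        presence_mismatched_cells=mismatched,
        dbd_start_offsets=start_offsets,
        dbd_end_offsets=end_offsets,
        orphan_ids=sorted(orphans),
        n_true_genes=len(true_ids),
        n_verified=len(verified_ids),
    )
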