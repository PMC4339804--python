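"""Seeded homology search, E-value statistics, calibration and dedup."""

import math

import numpy as np
import pytest

import nrcat.phylogenetics as phylo
from nrcat.homology_search import (
    CalibrationError,
    build_index,
    calibrate_cutoff,
    estimate_ka_params,
    merge_and_dedupe,
    search,
)
from nrcat.seqcore import ALPHABET, SeqRecord, local_align
from nrcat.synthetic_data import EvolveConfig, evolve_proteomes, make_decoys
from conftest import random_peptide


def _match_mismatch_matrix(match=1, mismatch=-1, n=21):
    S = np.full((n, n), mismatch, dtype=np.int32)
    np.fill_diagonal(S, match)
    return S


class TestKarlinAltschul:
    def test_match_mismatch_lambda_closed_form(self):
        """For +1/-1 scoring on a uniform 20-letter background the defining
        equation (1/20)e^l + (19/20)e^-l = 1 has the root l = ln 19."""
        params = estimate_ka_params(_match_mismatch_matrix(), m=100, n=1000)
        assert params.lam == pytest.approx(math.log(19), abs=1e-9)

    def test_lambda_agrees_with_independent_bisection(self):
        from nrcat.seqcore import load_substitution_matrix

        S = load_substitution_matrix("BLOSUM62")[:20, :20].astype(float)
        p = np.full(20, 1 / 20)
        pp = np.outer(p, p)

        def f(lam):
            return float((pp * np.exp(lam * S)).sum()) - 1.0

        lo, hi = 1e-9, 2.0
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
        from nrcat.seqcore import DEFAULT_SCHEME

        params = estimate_ka_params(DEFAULT_SCHEME, m=10, n=10)
        assert params.lam == pytest.approx((lo + hi) / 2, abs=1e-8)

    def test_all_positive_matrix_has_no_lambda(self):
        with pytest.raises(ValueError, match="no valid lambda"):
            estimate_ka_params(_match_mismatch_matrix(match=2, mismatch=1), m=10, n=10)

    def test_evalue_linear_in_database_size(self):
        p1 = estimate_ka_params(_match_mismatch_matrix(), m=50, n=1000)
        p2 = estimate_ka_params(_match_mismatch_matrix(), m=50, n=2000)
        assert p2.evalue(30) == pytest.approx(2 * p1.evalue(30))

    def test_evalue_strictly_decreasing_in_score(self):
        p = estimate_ka_params(_match_mismatch_matrix(), m=50, n=1000)
        evs = [p.evalue(s) for s in range(10, 60, 5)]
        assert all(a > b for a, b in zip(evs, evs[1:]))


class TestSeedIndex:
    def test_homopolymer_offsets(self):
        idx = build_index([SeqRecord(id="t", residues="AAAA")], k=3)
        assert idx.words["AAA"] == [("t", 0), ("t", 1)]

    def test_every_kmer_found_by_scanning(self):
        rng = np.random.default_rng(4)
        proteome = [
            SeqRecord(id=f"t{i}", residues=random_peptide(rng, 50, ALPHABET[:20]))
            for i in range(5)
        ]
        idx = build_index(proteome, k=4)
        for rec in proteome:
            s = rec.residues
            for off in range(len(s) - 3):
                word = s[off : off + 4]
                assert (rec.id, off) in idx.words[word]

    def test_empty_proteome(self):
        assert build_index([], k=4).words == {}

    def test_k_range_enforced(self):
        with pytest.raises(ValueError):
            build_index([], k=7)

    def test_short_sequence_skipped_not_fatal(self):
        idx = build_index([SeqRecord(id="s", residues="MK")], k=4)
        assert idx.words == {}
        assert "s" in idx.sequences


class TestSearch:
    @pytest.fixture(scope="class")
    @staticmethod
    def proteome():
        rng = np.random.default_rng(10)
        return [
            SeqRecord(id=f"t{i}", residues=random_peptide(rng, 120, ALPHABET[:20]))
            for i in range(20)
        ]

    def test_identical_entry_ranks_first_with_full_identity(self, proteome):
        query = SeqRecord(id="q", residues=proteome[7].residues)
        idx = build_index(proteome, k=4)
        hits = search(query, idx, e_cutoff=1.0)
        assert hits and hits[0].target_id == "t7"
        assert hits[0].identity_pct == 100.0

    def test_decoys_yield_no_hits_at_strict_cutoff(self, templates):
        decoys = make_decoys(100, seed=8)
        idx = build_index(decoys, k=4)
        tpl = templates[3]
        query = SeqRecord(id=tpl.symbol, residues=tpl.dbd_sequence + tpl.lbd_sequence)
        assert search(query, idx, e_cutoff=1e-25) == []

    def test_reported_score_equals_full_smith_waterman(self, templates):
        """The seeded search must report the exact local-alignment optimum
        for every reported pair."""
        tree = phylo.read_newick("(a:0.15,b:0.1)root;")
        cfg = EvolveConfig(seed=6, decoys_per_species=5, forced_events=())
        proteomes, _ = evolve_proteomes(templates[:10], tree, cfg)
        idx = build_index(proteomes["a"], k=4)
        tpl = templates[2]
        query = SeqRecord(id=tpl.symbol, residues=(tpl.dbd_sequence or "") + tpl.lbd_sequence)
        hits = search(query, idx, e_cutoff=1.0)
        assert hits
        for h in hits:
            target = next(r for r in proteomes["a"] if r.id == h.target_id)
            assert h.raw_score == local_align(query, target).score

    def test_evalue_order_matches_score_order(self, proteome, templates):
        tpl = templates[5]
        query = SeqRecord(id=tpl.symbol, residues=tpl.sequence)
        mixed = proteome + [
            SeqRecord(id="planted", residues=tpl.sequence),
            SeqRecord(id="partial", residues=tpl.sequence[:150]),
        ]
        hits = search(query, build_index(mixed, k=4), e_cutoff=10.0)
        assert len(hits) >= 2
        by_score = sorted(hits, key=lambda h: -h.raw_score)
        assert [h.target_id for h in by_score] == [h.target_id for h in hits]

    def test_cutoff_must_be_positive(self, proteome):
        q = SeqRecord(id="q", residues=proteome[0].residues)
        with pytest.raises(ValueError):
            search(q, build_index(proteome), e_cutoff=0.0)


class TestCalibration:
    def test_cutoff_is_loosest_per_gene_requirement(self, templates):
        """The calibrated cutoff equals the max over calibration genes of
        their best-hit E-value, recomputed here independently."""
        tree = phylo.read_newick("(fugu:0.2,other:0.05)root;")
        cfg = EvolveConfig(seed=13, decoys_per_species=10, forced_events=())
        proteomes, truth = evolve_proteomes(templates[:12], tree, cfg)
        queries = [
            SeqRecord(id=t.symbol, residues=(t.dbd_sequence or "") + t.lbd_sequence)
            for t in templates[:12]
        ]
        true_ids = {r.gene_id for r in truth.genes_of("fugu")}
        cutoff = calibrate_cutoff(queries, proteomes["fugu"], true_ids)
        idx = build_index(proteomes["fugu"])
        best = {}
        for q in queries:
            for h in search(q, idx, e_cutoff=10.0):
                if h.target_id in true_ids:
                    best[h.target_id] = min(best.get(h.target_id, math.inf), h.evalue)
        assert set(best) == true_ids
        assert cutoff == max(best.values())
        # full recall at the calibrated cutoff
        found = set()
        for q in queries:
            for h in search(q, idx, e_cutoff=cutoff):
                found.add(h.target_id)
        assert true_ids <= found

    def test_self_calibration_gives_tiny_cutoff(self, templates):
        queries = [
            SeqRecord(id=t.symbol, residues=(t.dbd_sequence or "") + t.lbd_sequence)
            for t in templates[:8]
        ]
        proteome = [SeqRecord(id=f"g{q.id}", residues=q.residues) for q in queries]
        cutoff = calibrate_cutoff(queries, proteome, {r.id for r in proteome})
        assert cutoff < 1e-50

    def test_undetectable_gene_is_named(self, templates):
        rng = np.random.default_rng(0)
        queries = [SeqRecord(id="q", residues=templates[0].sequence)]
        proteome = [
            SeqRecord(id="real", residues=templates[0].sequence),
            SeqRecord(id="unrelated", residues=random_peptide(rng, 200, ALPHABET[:20])),
        ]
        with pytest.raises(CalibrationError, match="unrelated"):
            calibrate_cutoff(queries, proteome, {"real", "unrelated"})


class TestMergeAndDedupe:
    def _hit(self, target):
        from nrcat.homology_search import SearchHit

        return SearchHit(
            query_id="q", target_id=target, raw_score=100, bit_score=40,
            evalue=1e-30, query_span=(0, 10), target_span=(0, 10),
            identity_pct=100.0, aln_length=10, mismatches=0, gap_opens=0,
        )

    def test_shared_target_counted_once(self):
        proteome = [SeqRecord(id="t1", residues="MKVLAHT")]
        cands, report = merge_and_dedupe([[self._hit("t1")], [self._hit("t1")]], proteome)
        assert cands == ["t1"] and report == {}

    def test_identical_sequences_collapse_to_smallest_id(self):
        proteome = [
            SeqRecord(id="tB", residues="MKVLAHT"),
            SeqRecord(id="tA", residues="MKVLAHT"),
        ]
        cands, report = merge_and_dedupe([[self._hit("tA"), self._hit("tB")]], proteome)
        assert cands == ["tA"]
        assert report == {"tA": ["tB"]}

    def test_disjoint_sets_union(self):
        rng = np.random.default_rng(1)
        proteome = [
            SeqRecord(id=f"t{i}", residues=random_peptide(rng, 20, ALPHABET[:20]))
            for i in range(7)
        ]
        set1 = [self._hit(f"t{i}") for i in range(3)]
        set2 = [self._hit(f"t{i}") for i in range(3, 7)]
        cands, report = merge_and_dedupe([set1, set2], proteome)
        assert len(cands) == 7 and report == {}
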