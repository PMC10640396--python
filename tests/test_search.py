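import itertools

import networkx as nx
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from motifdex.geometry import (
    PairDescriptor,
    ResidueGeometry,
    pair_descriptors,
    parse_structure,
)
from motifdex.index_builder import (
    IndexNotFoundError,
    PairRecord,
    build_index,
    enumerate_pairs,
)
from motifdex.search import (
    QueryError,
    ToleranceConfig,
    assemble_candidates,
    bins_for_window,
    build_query_graph,
    candidate_pairs,
    monomorphism_filter,
    query_mst,
    search,
    superpose_rmsd,
)
from motifdex.variants import MotifVariant, make_policy
from motifdex.fixtures import rigid_transform

from conftest import pick_compact_query
from oracle import kabsch_rmsd


def _residue(rid, aa, ca, cm=None):
    ca = np.asarray(ca, float)
    cm = ca + np.array([1.0, 0.4, -0.3]) if cm is None else np.asarray(cm, float)
    return ResidueGeometry(rid, aa, ca, cm, ca - cm)


def _random_residues(rng, n, letters="ACDEFGHIKLMNPQRSTVWY", box=15.0):
    return [
        _residue(
            f"A{i + 1}",
            letters[rng.integers(len(letters))],
            rng.uniform(0, box, 3),
            rng.uniform(0, box, 3),
        )
        for i in range(n)
    ]


class TestQueryGraph:
    def test_three_residues_three_edges(self):
        residues = _random_residues(np.random.default_rng(0), 5)
        motif = build_query_graph(residues, ["A1", "A2", "A3"])
        assert len(motif.nodes) == 3
        assert len(motif.edges) == 3

    def test_five_residues_ten_edges(self):
        residues = _random_residues(np.random.default_rng(0), 6)
        motif = build_query_graph(residues, ["A1", "A2", "A3", "A4", "A5"])
        assert len(motif.edges) == 10

    def test_edges_recomputable_from_nodes(self):
        residues = _random_residues(np.random.default_rng(1), 4)
        motif = build_query_graph(residues, ["A1", "A2", "A4"])
        for (a, b), desc in motif.edges.items():
            assert desc == pair_descriptors(motif.nodes[a], motif.nodes[b])

    def test_missing_residue_id_raises_and_names_it(self):
        residues = _random_residues(np.random.default_rng(0), 3)
        with pytest.raises(QueryError, match="Z99"):
            build_query_graph(residues, ["A1", "Z99"])

    def test_duplicate_ids_rejected(self):
        residues = _random_residues(np.random.default_rng(0), 3)
        with pytest.raises(QueryError, match="duplicate"):
            build_query_graph(residues, ["A1", "A1"])


class TestQueryMST:
    def test_three_node_motif_keeps_all_edges(self):
        residues = _random_residues(np.random.default_rng(2), 3)
        motif = build_query_graph(residues, ["A1", "A2", "A3"])
        assert len(query_mst(motif)) == 3

    def test_five_node_motif_pruned_to_spanning_tree(self):
        residues = _random_residues(np.random.default_rng(3), 5)
        motif = build_query_graph(residues, [f"A{i}" for i in range(1, 6)])
        edges = query_mst(motif)
        assert len(edges) == 4
        g = nx.Graph(edges)
        assert set(g.nodes) == set(motif.nodes)
        assert nx.is_tree(g)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_exhaustive_minimum_spanning_tree(self, seed):
        rng = np.random.default_rng(seed)
        residues = _random_residues(rng, 6)
        motif = build_query_graph(residues, [f"A{i}" for i in range(1, 7)])
        weights = {e: float(rng.uniform(1, 100)) for e in motif.edges}
        got = set(query_mst(motif, weights))
        best, best_w = None, np.inf
        nodes = set(motif.nodes)
        for combo in itertools.combinations(sorted(motif.edges), 5):
            g = nx.Graph(combo)
            if set(g.nodes) == nodes and nx.is_connected(g):
                w = sum(weights[e] for e in combo)
                if w < best_w:
                    best, best_w = set(combo), w
        assert got == best


class TestCandidatePairs:
    def test_bin_window_for_distance(self):
        tol = ToleranceConfig(dist_tol=1.0, angle_tol=20.0)
        keys = bins_for_window(PairDescriptor(5.5, 5.5, 90.0), "CH", tol)
        assert {k.ca_bin for k in keys} == {4, 5, 6}

    def test_missing_index_raises(self, tmp_path):
        with pytest.raises(IndexNotFoundError):
            candidate_pairs(tmp_path, "CH", PairDescriptor(5, 5, 90),
                            ToleranceConfig())

    def test_matches_linear_scan_of_all_records(self, decoy_set):
        all_records = []
        for sid, residues in decoy_set["residues"].items():
            all_records.extend(enumerate_pairs(residues, sid))
        rng = np.random.default_rng(17)
        for _ in range(60):
            base = all_records[rng.integers(len(all_records))]
            target = PairDescriptor(
                max(0.0, base.d_ca + rng.uniform(-0.4, 0.4)),
                max(0.0, base.d_cm + rng.uniform(-0.4, 0.4)),
                float(np.clip(base.angle + rng.uniform(-8, 8), 0, 180)),
            )
            tol = ToleranceConfig(dist_tol=float(rng.uniform(0.2, 1.5)),
                                  angle_tol=float(rng.uniform(5, 25)))
            got = {
                (r.structure_id, r.res1_id, r.res2_id)
                for r in candidate_pairs(decoy_set["dir"], base.pair_type,
                                         target, tol)
            }
            expected = {
                (r.structure_id, r.res1_id, r.res2_id)
                for r in all_records
                if r.pair_type == base.pair_type
                and abs(r.d_ca - target.d_ca) <= tol.dist_tol
                and abs(r.d_cm - target.d_cm) <= tol.dist_tol
                and abs(r.angle - target.angle) <= tol.angle_tol
            }
            assert got == expected


class TestAssembleCandidates:
    def test_unshared_middle_residue_discards_structure(self):
        rec1 = PairRecord("s", "A10", "A20", 5.0, 5.0, 90.0, "CH")
        rec2 = PairRecord("s", "A30", "A40", 6.0, 6.0, 80.0, "HS")
        out = assemble_candidates(
            {("x", "y"): [rec1], ("y", "z"): [rec2]},
            [("x", "y"), ("y", "z")],
            {"x": "C", "y": "H", "z": "S"},
        )
        assert out == {}

    def test_shared_residue_yields_full_embedding(self):
        rec1 = PairRecord("s", "A10", "A20", 5.0, 5.0, 90.0, "CH")
        rec2 = PairRecord("s", "A20", "A40", 6.0, 6.0, 80.0, "HS")
        out = assemble_candidates(
            {("x", "y"): [rec1], ("y", "z"): [rec2]},
            [("x", "y"), ("y", "z")],
            {"x": "C", "y": "H", "z": "S"},
        )
        assert out == {"s": [{"x": "A10", "y": "A20", "z": "A40"}]}

    def test_same_type_pairs_tried_in_both_orientations(self):
        rec1 = PairRecord("s", "A10", "A20", 5.0, 5.0, 90.0, "CC")
        out = assemble_candidates(
            {("x", "y"): [rec1]}, [("x", "y")], {"x": "C", "y": "C"}
        )
        assert sorted(map(tuple, (sorted(m.items()) for m in out["s"]))) == [
            (("x", "A10"), ("y", "A20")),
            (("x", "A20"), ("y", "A10")),
        ]


class TestMonomorphism:
    def test_query_against_itself_contains_identity(self):
        residues = _random_residues(np.random.default_rng(4), 4, box=10.0)
        motif = build_query_graph(residues, [r.residue_id for r in residues])
        variant = MotifVariant(tuple(sorted(motif.types.items())), 0)
        mappings = monomorphism_filter(residues, variant, motif,
                                       ToleranceConfig(0.5, 10.0))
        assert {pos: pos for pos in motif.nodes} in mappings

    def test_wrong_wiring_rejected(self):
        # Equilateral triangle query; candidate has the right pair
        # distances pairwise but a collinear arrangement, so one edge is
        # out of tolerance.
        query = [
            _residue("A1", "C", (0, 0, 0)),
            _residue("A2", "C", (6, 0, 0)),
            _residue("A3", "C", (3, 3 * np.sqrt(3), 0)),
        ]
        motif = build_query_graph(query, ["A1", "A2", "A3"])
        candidate = [
            _residue("B1", "C", (0, 0, 0)),
            _residue("B2", "C", (6, 0, 0)),
            _residue("B3", "C", (12, 0, 0)),
        ]
        variant = MotifVariant(tuple(sorted(motif.types.items())), 0)
        assert monomorphism_filter(candidate, variant, motif,
                                   ToleranceConfig(0.5, 180.0)) == []

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_exhaustive_permutation_search(self, seed):
        rng = np.random.default_rng(seed)
        candidate = _random_residues(rng, 7, letters="CHS", box=8.0)
        query = _random_residues(rng, 3, letters="CHS", box=8.0)
        query = [
            ResidueGeometry(f"q{i}", r.aa_type, r.ca, r.cm, r.r_vec)
            for i, r in enumerate(query)
        ]
        motif = build_query_graph(query, [r.residue_id for r in query])
        tol = ToleranceConfig(dist_tol=3.0, angle_tol=60.0)
        variant = MotifVariant(tuple(sorted(motif.types.items())), 0)
        got = monomorphism_filter(candidate, variant, motif, tol)

        positions = sorted(motif.nodes)
        expected = []
        for combo in itertools.permutations(candidate, len(positions)):
            assigned = dict(zip(positions, combo))
            if any(assigned[p].aa_type != motif.types[p] for p in positions):
                continue
            ok = True
            for (a, b), qd in motif.edges.items():
                td = pair_descriptors(assigned[a], assigned[b])
                if (abs(td.d_ca - qd.d_ca) > tol.dist_tol
                        or abs(td.d_cm - qd.d_cm) > tol.dist_tol
                        or abs(td.angle - qd.angle) > tol.angle_tol):
                    ok = False
                    break
            if ok:
                expected.append({p: assigned[p].residue_id for p in positions})
        key = lambda m: tuple(sorted(m.items()))
        assert sorted(got, key=key) == sorted(expected, key=key)


class TestSuperposition:
    def test_identical_sets_give_zero(self):
        pts = np.random.default_rng(0).normal(size=(5, 3))
        assert superpose_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-9)

    def test_rigidly_moved_set_gives_zero(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 3))
        rot = Rotation.random(rng=rng).as_matrix()
        moved = pts @ rot.T + rng.uniform(-10, 10, 3)
        assert superpose_rmsd(pts, moved) == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_kabsch_svd(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.normal(size=(5, 3))
        q = rng.normal(size=(5, 3))
        assert superpose_rmsd(p, q) == pytest.approx(kabsch_rmsd(p, q), abs=1e-9)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            superpose_rmsd(np.zeros((2, 3)), np.ones((2, 3)))


class TestEndToEnd:
    def test_indexed_structure_retrieves_itself_at_zero_rmsd(self, planted_index):
        path = next(p for p in planted_index["paths"] if p.stem == "synth_005")
        residues = parse_structure(path)
        rng = np.random.default_rng(23)
        chosen = pick_compact_query(residues, rng, 3)
        motif = build_query_graph(residues, [r.residue_id for r in chosen])
        hits = search(planted_index["dir"], motif,
                      make_policy("strict", motif.types),
                      ToleranceConfig(0.5, 10.0))
        self_hits = [h for h in hits if h.structure_id == "synth_005"]
        identity = tuple(sorted((p, p) for p in motif.nodes))
        assert any(h.mapping == identity for h in self_hits)
        assert min(h.rmsd for h in self_hits) == pytest.approx(0.0, abs=1e-7)

    def test_planted_motifs_found_decoys_clean(self, planted_index):
        residues = parse_structure(planted_index["query_path"])
        motif = build_query_graph(residues, planted_index["query_ids"])
        hits = search(planted_index["dir"], motif,
                      make_policy("strict", motif.types),
                      ToleranceConfig(0.5, 10.0))
        import json

        truth = json.loads(
            (planted_index["root"] / "structs" / "truth.json").read_text()
        )
        planted_ids = {t["structure_id"] for t in truth["planted"]}
        assert {h.structure_id for h in hits} == planted_ids
        for h in hits:
            assert h.rmsd < 1e-3

    def test_tolerance_monotonicity(self, planted_index):
        residues = parse_structure(planted_index["query_path"])
        motif = build_query_graph(residues, planted_index["query_ids"])
        policy = make_policy("strict", motif.types)
        previous: set = set()
        for dist_tol, angle_tol in [(0.25, 5.0), (0.5, 10.0), (1.0, 20.0),
                                    (2.0, 40.0)]:
            hits = search(planted_index["dir"], motif, policy,
                          ToleranceConfig(dist_tol, angle_tol))
            current = {(h.structure_id, h.mapping) for h in hits}
            assert previous <= current
            previous = current

    def test_strategy_nesting_preserves_hits_and_rmsd(self, planted_index):
        residues = parse_structure(planted_index["query_path"])
        motif = build_query_graph(residues, planted_index["query_ids"])
        tol = ToleranceConfig(0.5, 10.0)
        results = {}
        for strategy in ("strict", "relaxed", "fully_relaxed"):
            policy = make_policy(strategy, motif.types, max_mutations=1)
            hits = search(planted_index["dir"], motif, policy, tol)
            results[strategy] = {
                (h.structure_id, h.mapping): h.rmsd for h in hits
            }
        assert set(results["strict"]) <= set(results["relaxed"])
        assert set(results["relaxed"]) <= set(results["fully_relaxed"])
        for key, rmsd in results["strict"].items():
            assert results["fully_relaxed"][key] == pytest.approx(rmsd, abs=1e-9)

    def test_worker_count_invariance(self, planted_index):
        residues = parse_structure(planted_index["query_path"])
        motif = build_query_graph(residues, planted_index["query_ids"])
        policy = make_policy("strict", motif.types)
        tol = ToleranceConfig(0.5, 10.0)
        h1 = search(planted_index["dir"], motif, policy, tol, workers=1)
        h4 = search(planted_index["dir"], motif, policy, tol, workers=4)
        assert h1 == h4

    def test_hits_survive_rigid_transform_of_targets(self, planted_index,
                                                     tmp_path):
        # Transform every target file by a different rigid motion, rebuild
        # the index and search again: same structures and mappings, RMSDs
        # equal within the PDB coordinate precision (0.001 Å per axis).
        moved_dir = tmp_path / "moved"
        moved_dir.mkdir()
        moved = [
            rigid_transform(p, seed=i + 1, out_path=moved_dir / p.name)
            for i, p in enumerate(planted_index["paths"])
        ]
        index_dir = tmp_path / "idx"
        build_index(moved, index_dir)
        residues = parse_structure(planted_index["query_path"])
        motif = build_query_graph(residues, planted_index["query_ids"])
        policy = make_policy("strict", motif.types)
        tol = ToleranceConfig(0.5, 10.0)
        before = search(planted_index["dir"], motif, policy, tol)
        after = search(index_dir, motif, policy, tol)
        as_key = lambda hits: {(h.structure_id, h.mapping): h.rmsd for h in hits}
        kb, ka = as_key(before), as_key(after)
        assert set(kb) == set(ka)
        for key, rmsd in kb.items():
            assert ka[key] == pytest.approx(rmsd, abs=5e-3)
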