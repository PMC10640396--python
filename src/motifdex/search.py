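"""Index-backed search for 3D structural motifs.

A query motif — a handful of residues picked from a structure file — is
represented as a fully connected, weighted, undirected graph whose nodes
are residues and whose edges carry the three pair descriptors. The search
proceeds in stages:

1. For motifs of four or more residues the graph is pruned to a minimum
   spanning tree (Kruskal). Pairwise geometric constraints are transitive,
   so the tree's n−1 edges suffice to locate candidates while minimizing
   the amount of index data loaded; edges are weighted by their estimated
   selectivity (the number of index rows in the bins their tolerance window
   overlaps), so the cheapest edges are used. Motifs of two or three
   residues are not pruned.
2. For each tree edge, every index bin overlapping the tolerance window is
   loaded and rows are filtered to the closed interval [value − tol,
   value + tol] on each descriptor.
3. Edge hits are joined structure by structure: a candidate structure must
   link the hits of successive edges through shared residues, consistently
   with the tree topology, or it is discarded.
4. The tree stage cannot see non-tree edges, so survivors may contain the
   right pairs wired up the wrong way. A subgraph-monomorphism filter over
   the fully connected graph of the identified residues keeps only
   injective, type-compatible mappings in which every one of the query's
   C(n,2) edges satisfies the tolerances.
5. Each surviving mapping is scored by least-squares RMSD after optimal
   rigid-body superposition (quaternion characteristic-polynomial method),
   using Cα coordinates, Cμ coordinates, or both.

Variant-tolerant searches run the same pipeline once per residue-type
variant, share the bin cache, pool hits, and deduplicate identical residue
mappings keeping the lowest mutation count.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
from Bio.PDB.qcprot import QCPSuperimposer

from .geometry import PairDescriptor, ResidueGeometry, pair_descriptors
from .index_builder import (
    ANGLE_BIN_WIDTH,
    DIST_BIN_WIDTH,
    MAX_ANGLE_BIN,
    MAX_CA_BIN,
    BinKey,
    IndexManifest,
    PairRecord,
    canonical_pair_type,
    load_bin,
    load_manifest,
    load_structure_residues,
)
from .variants import MotifVariant, SubstitutionPolicy, expand_variants

Edge = tuple[str, str]


class QueryError(ValueError):
    """Invalid query specification (unknown or duplicate residue ids)."""


@dataclass(frozen=True)
class ToleranceConfig:
    """Geometric matching tolerances and RMSD settings.

    ``dist_tol`` applies to both the Cα–Cα and Cμ–Cμ distances (Å);
    ``angle_tol`` to the R-vector angle (degrees). Defaults mirror the
    index bin widths. ``rmsd_mode`` selects which pseudoatoms enter the
    superposition; ``rmsd_threshold`` (Å), when set, drops hits above it.
    """

    dist_tol: float = 1.0
    angle_tol: float = 20.0
    rmsd_mode: str = "both"
    rmsd_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.dist_tol <= 0 or self.angle_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.rmsd_mode not in ("ca", "cm", "both"):
            raise ValueError(f"unknown rmsd_mode {self.rmsd_mode!r}")


@dataclass(frozen=True)
class QueryMotif:
    """Fully connected weighted graph over the query residues."""

    nodes: dict[str, ResidueGeometry]            # position -> geometry
    edges: dict[Edge, PairDescriptor]            # sorted (pos, pos) -> descriptor

    @property
    def types(self) -> dict[str, str]:
        return {pos: r.aa_type for pos, r in self.nodes.items()}


@dataclass(frozen=True)
class SearchHit:
    structure_id: str
    mapping: tuple[tuple[str, str], ...]  # sorted (query position, target residue)
    matched_types: tuple[tuple[str, str], ...]
    mutation_count: int
    rmsd: float

    @property
    def mapping_dict(self) -> dict[str, str]:
        return dict(self.mapping)


def build_query_graph(
    residues: list[ResidueGeometry], residue_ids: list[str]
) -> QueryMotif:
    """Select the query residues from a parsed structure and connect them.

    Raises :class:`QueryError` when an id is missing or duplicated.
    """
    if len(set(residue_ids)) != len(residue_ids):
        dupes = sorted({r for r in residue_ids if residue_ids.count(r) > 1})
        raise QueryError(f"duplicate query residue ids: {dupes}")
    if len(residue_ids) < 2:
        raise QueryError("a query motif needs at least 2 residues")
    by_id = {r.residue_id: r for r in residues}
    missing = [rid for rid in residue_ids if rid not in by_id]
    if missing:
        raise QueryError(f"residue ids not found in structure: {missing}")
    nodes = {rid: by_id[rid] for rid in residue_ids}
    edges = {
        tuple(sorted((a, b))): pair_descriptors(nodes[a], nodes[b])
        for a, b in itertools.combinations(sorted(nodes), 2)
    }
    return QueryMotif(nodes=nodes, edges=edges)


# ---------------------------------------------------------------------------
# Bin enumeration and candidate loading


def _bin_range(lo: float, hi: float, width: float, cap: int | None) -> range:
    first = max(int(math.floor(lo / width)), 0)
    last = int(math.floor(hi / width))
    if cap is not None:
        last = min(last, cap)
    return range(first, last + 1)


def bins_for_window(target: PairDescriptor, pair_type: str,
                    tol: ToleranceConfig) -> list[BinKey]:
    """All bins overlapping the closed tolerance window around *target*."""
    ca_bins = _bin_range(target.d_ca - tol.dist_tol, target.d_ca + tol.dist_tol,
                         DIST_BIN_WIDTH, MAX_CA_BIN)
    cm_bins = _bin_range(target.d_cm - tol.dist_tol, target.d_cm + tol.dist_tol,
                         DIST_BIN_WIDTH, None)
    ang_bins = _bin_range(target.angle - tol.angle_tol, target.angle + tol.angle_tol,
                          ANGLE_BIN_WIDTH, MAX_ANGLE_BIN)
    if target.d_ca - tol.dist_tol > (MAX_CA_BIN + 1) * DIST_BIN_WIDTH:
        return []  # window entirely beyond the indexation cutoff
    pt = canonical_pair_type(pair_type[0], pair_type[1])
    return [
        BinKey(pt, ca, cm, ang)
        for ca, cm, ang in itertools.product(ca_bins, cm_bins, ang_bins)
    ]


def _within(record: PairRecord, target: PairDescriptor,
            tol: ToleranceConfig) -> bool:
    return (
        abs(record.d_ca - target.d_ca) <= tol.dist_tol
        and abs(record.d_cm - target.d_cm) <= tol.dist_tol
        and abs(record.angle - target.angle) <= tol.angle_tol
    )


class _BinCache:
    """Per-search cache of loaded index bins, shared across variants."""

    def __init__(self, index_dir: Path):
        self.index_dir = index_dir
        self._cache: dict[BinKey, list[PairRecord]] = {}

    def load(self, key: BinKey) -> list[PairRecord]:
        if key not in self._cache:
            self._cache[key] = load_bin(self.index_dir, key)
        return self._cache[key]


def candidate_pairs(
    index_dir: str | Path,
    pair_type: str,
    target: PairDescriptor,
    tol: ToleranceConfig,
    _cache: _BinCache | None = None,
) -> list[PairRecord]:
    """All index records matching *target* within the tolerances.

    Bins are only a prefilter: every overlapping bin is loaded and its rows
    are then tested against the closed intervals on the raw descriptors.
    """
    load_manifest(index_dir)  # raises IndexNotFoundError when absent
    cache = _cache or _BinCache(Path(index_dir))
    out = []
    for key in bins_for_window(target, pair_type, tol):
        out.extend(r for r in cache.load(key) if _within(r, target, tol))
    return out


# ---------------------------------------------------------------------------
# MST pruning


def _edge_selectivity(
    manifest: IndexManifest, pair_type: str, target: PairDescriptor,
    tol: ToleranceConfig,
) -> int:
    counts = manifest.bin_counts
    return sum(
        counts.get(key.filename.removesuffix(".parquet"), 0)
        for key in bins_for_window(target, pair_type, tol)
    )


def query_mst(
    motif: QueryMotif, weights: dict[Edge, float] | None = None
) -> list[Edge]:
    """Edges to search the index for.

    Motifs of up to three residues keep all their edges. Larger motifs are
    pruned to a minimum spanning tree via Kruskal's algorithm; ``weights``
    (default: equal) typically hold per-edge selectivity estimates so the
    cheapest edges are kept. Deterministic for fixed weights.
    """
    if len(motif.nodes) <= 3:
        return sorted(motif.edges)
    graph = nx.Graph()
    graph.add_nodes_from(sorted(motif.nodes))
    for edge in sorted(motif.edges):
        w = weights.get(edge, 0.0) if weights else 0.0
        graph.add_edge(*edge, weight=w)
    mst = nx.minimum_spanning_edges(graph, algorithm="kruskal", data=False)
    return [tuple(sorted(e)) for e in mst]


def _connected_order(edges: list[Edge]) -> list[Edge]:
    """Reorder edges so each one (after the first) touches a seen node."""
    remaining = list(edges)
    ordered = [remaining.pop(0)]
    seen = set(ordered[0])
    while remaining:
        for i, (u, v) in enumerate(remaining):
            if u in seen or v in seen:
                ordered.append(remaining.pop(i))
                seen.update((u, v))
                break
        else:  # disconnected edge list: process arbitrarily (not reachable for MSTs)
            ordered.append(remaining.pop(0))
            seen.update(ordered[-1])
    return ordered


# ---------------------------------------------------------------------------
# Candidate assembly (iterative per-edge join)


def _orientations(
    record: PairRecord, aa_x: str, aa_y: str
) -> list[tuple[str, str]]:
    """Ways to assign (record.res1, record.res2) to query nodes (x, y).

    Record residues are canonically ordered by type, so a mixed-type pair
    has exactly one valid orientation; a same-type pair has two.
    """
    t1, t2 = record.pair_type[0], record.pair_type[1]
    if t1 == t2:
        return [(record.res1_id, record.res2_id),
                (record.res2_id, record.res1_id)]
    if aa_x == t1:
        return [(record.res1_id, record.res2_id)]
    return [(record.res2_id, record.res1_id)]


def assemble_candidates(
    edge_hits: dict[Edge, list[PairRecord]],
    edges: list[Edge],
    variant_types: dict[str, str],
) -> dict[str, list[dict[str, str]]]:
    """Join per-edge index hits into per-structure motif-tree embeddings.

    Edges are processed in an order that keeps the covered query nodes
    connected; after each edge only structures whose accumulated hits can
    be joined on shared residues survive. Returns, per surviving structure,
    every injective assignment of query nodes to residues consistent with
    all processed edges.
    """
    by_structure: dict[str, dict[Edge, list[PairRecord]]] = {}
    for edge, hits in edge_hits.items():
        for rec in hits:
            by_structure.setdefault(rec.structure_id, {}).setdefault(
                edge, []
            ).append(rec)

    ordered = _connected_order(edges)
    out: dict[str, list[dict[str, str]]] = {}
    for sid, hits in by_structure.items():
        if any(edge not in hits for edge in ordered):
            continue  # some tree edge has no hit in this structure
        partials: list[dict[str, str]] = [{}]
        for x, y in ordered:
            aa_x, aa_y = variant_types[x], variant_types[y]
            extended: list[dict[str, str]] = []
            for part in partials:
                for rec in hits[(x, y)]:
                    for rx, ry in _orientations(rec, aa_x, aa_y):
                        px, py = part.get(x), part.get(y)
                        if px is not None and px != rx:
                            continue
                        if py is not None and py != ry:
                            continue
                        new = dict(part)
                        if px is None:
                            if rx in new.values():
                                continue  # injectivity
                            new[x] = rx
                        if py is None:
                            if ry in new.values():
                                continue
                            new[y] = ry
                        extended.append(new)
            # drop duplicate partial assignments
            uniq = {tuple(sorted(p.items())): p for p in extended}
            partials = list(uniq.values())
            if not partials:
                break
        if partials:
            out[sid] = partials
    return out


# ---------------------------------------------------------------------------
# Monomorphism filter


def monomorphism_filter(
    candidate_residues: list[ResidueGeometry],
    variant: MotifVariant,
    motif: QueryMotif,
    tol: ToleranceConfig,
) -> list[dict[str, str]]:
    """Mappings of query positions onto candidate residues that satisfy
    every query edge.

    The candidate residues (those identified by the tree-edge join) form a
    fully connected graph with recomputed descriptors on every edge; a
    subgraph monomorphism then requires each query node's residue type and
    all C(n,2) query edges — not only the spanning-tree ones — to match
    within tolerance. This eliminates arrangements whose pairs are
    individually correct but wired differently than the query.
    """
    types = variant.types
    target = nx.Graph()
    for res in candidate_residues:
        target.add_node(res.residue_id, aa=res.aa_type)
    for a, b in itertools.combinations(candidate_residues, 2):
        target.add_edge(a.residue_id, b.residue_id, d=pair_descriptors(a, b))

    query = nx.Graph()
    for pos in motif.nodes:
        query.add_node(pos, aa=types[pos])
    for (a, b), desc in motif.edges.items():
        query.add_edge(a, b, d=desc)

    def node_match(t: dict, q: dict) -> bool:
        return t["aa"] == q["aa"]

    def edge_match(t: dict, q: dict) -> bool:
        td, qd = t["d"], q["d"]
        return (
            abs(td.d_ca - qd.d_ca) <= tol.dist_tol
            and abs(td.d_cm - qd.d_cm) <= tol.dist_tol
            and abs(td.angle - qd.angle) <= tol.angle_tol
        )

    matcher = nx.algorithms.isomorphism.GraphMatcher(
        target, query, node_match=node_match, edge_match=edge_match
    )
    mappings = [
        {pos: res for res, pos in m.items()}
        for m in matcher.subgraph_monomorphisms_iter()
    ]
    mappings.sort(key=lambda m: tuple(sorted(m.items())))
    return mappings


# ---------------------------------------------------------------------------
# RMSD superposition


def superpose_rmsd(query_coords: np.ndarray, target_coords: np.ndarray) -> float:
    """Minimal least-squares RMSD over rigid-body superpositions (Å).

    Uses the quaternion characteristic-polynomial (QCP) method, which
    yields a proper rotation (no reflection). Requires at least 3 points.
    """
    query_coords = np.asarray(query_coords, dtype=float)
    target_coords = np.asarray(target_coords, dtype=float)
    if query_coords.shape != target_coords.shape:
        raise ValueError("coordinate sets must have equal shape")
    if query_coords.shape[0] < 3:
        raise ValueError("superposition needs at least 3 points")
    sup = QCPSuperimposer()
    sup.set(query_coords, target_coords)
    sup.run()
    # The eigenvalue-based rms (sqrt(E0 - 2*lambda_max)) loses precision
    # near zero; evaluate the residual of the optimal rotation explicitly.
    rot, tran = sup.get_rotran()
    diff = target_coords @ rot + tran - query_coords
    return float(np.sqrt((diff ** 2).sum() / len(query_coords)))


def _mapping_coords(
    motif: QueryMotif,
    mapping: dict[str, str],
    target_residues: dict[str, ResidueGeometry],
    mode: str,
) -> tuple[np.ndarray, np.ndarray]:
    q_pts, t_pts = [], []
    for pos in sorted(mapping):
        q, t = motif.nodes[pos], target_residues[mapping[pos]]
        if mode in ("ca", "both"):
            q_pts.append(q.ca)
            t_pts.append(t.ca)
        if mode in ("cm", "both"):
            q_pts.append(q.cm)
            t_pts.append(t.cm)
    return np.array(q_pts), np.array(t_pts)


# ---------------------------------------------------------------------------
# End-to-end search


def _search_variant(
    index_dir: Path,
    motif: QueryMotif,
    variant: MotifVariant,
    tol: ToleranceConfig,
    manifest: IndexManifest,
    cache: _BinCache,
    residue_cache: dict[str, dict[str, ResidueGeometry]],
) -> list[SearchHit]:
    types = variant.types
    weights = {
        edge: float(
            _edge_selectivity(
                manifest, canonical_pair_type(types[edge[0]], types[edge[1]]),
                desc, tol,
            )
        )
        for edge, desc in motif.edges.items()
    }
    edges = query_mst(motif, weights)
    edge_hits: dict[Edge, list[PairRecord]] = {}
    for edge in edges:
        pt = canonical_pair_type(types[edge[0]], types[edge[1]])
        edge_hits[edge] = candidate_pairs(
            index_dir, pt, motif.edges[edge], tol, _cache=cache
        )
    candidates = assemble_candidates(edge_hits, edges, types)

    hits: list[SearchHit] = []
    for sid in sorted(candidates):
        if sid not in residue_cache:
            residue_cache[sid] = {
                r.residue_id: r for r in load_structure_residues(index_dir, sid)
            }
        residues_by_id = residue_cache[sid]
        identified = sorted({rid for emb in candidates[sid] for rid in emb.values()})
        mappings = monomorphism_filter(
            [residues_by_id[rid] for rid in identified], variant, motif, tol
        )
        for mapping in mappings:
            q_pts, t_pts = _mapping_coords(motif, mapping, residues_by_id,
                                           tol.rmsd_mode)
            rmsd = superpose_rmsd(q_pts, t_pts)
            hits.append(
                SearchHit(
                    structure_id=sid,
                    mapping=tuple(sorted(mapping.items())),
                    matched_types=variant.assignment,
                    mutation_count=variant.mutation_count,
                    rmsd=rmsd,
                )
            )
    return hits


def search(
    index_dir: str | Path,
    motif: QueryMotif,
    policy: SubstitutionPolicy,
    tol: ToleranceConfig = ToleranceConfig(),
    workers: int = 1,
) -> list[SearchHit]:
    """Find every indexed structure containing a motif similar to the query.

    Runs the full pipeline for each residue-type variant allowed by
    *policy*, pools the hits, deduplicates identical (structure, mapping)
    hits keeping the lowest mutation count, applies the RMSD threshold if
    any, and sorts ascending by RMSD then structure id. The result is
    independent of ``workers``.
    """
    index_dir = Path(index_dir)
    manifest = load_manifest(index_dir)
    variants = expand_variants(motif.types, policy)
    cache = _BinCache(index_dir)
    residue_cache: dict[str, dict[str, ResidueGeometry]] = {}

    all_hits: list[SearchHit] = []
    for variant in variants:  # variants are ordered by ascending mutation count
        all_hits.extend(
            _search_variant(index_dir, motif, variant, tol, manifest, cache,
                            residue_cache)
        )

    best: dict[tuple[str, tuple], SearchHit] = {}
    for hit in all_hits:
        key = (hit.structure_id, hit.mapping)
        if key not in best or hit.mutation_count < best[key].mutation_count:
            best[key] = hit
    hits = [
        h for h in best.values()
        if tol.rmsd_threshold is None or h.rmsd <= tol.rmsd_threshold
    ]
    hits.sort(key=lambda h: (h.rmsd, h.structure_id, h.mapping))
    return hits
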