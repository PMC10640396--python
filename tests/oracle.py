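"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's index machinery: descriptors are
recomputed with plain trigonometry, RMSD with a Kabsch SVD superposition,
and motif search by exhaustive enumeration of residue tuples. They are
slow but obviously correct at small scale.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from motifdex.geometry import ResidueGeometry


def descriptor_oracle(a: ResidueGeometry, b: ResidueGeometry):
    """(d_ca, d_cm, angle°) computed with explicit arithmetic."""
    d_ca = math.sqrt(sum((x - y) ** 2 for x, y in zip(a.ca, b.ca)))
    d_cm = math.sqrt(sum((x - y) ** 2 for x, y in zip(a.cm, b.cm)))
    dot = sum(x * y for x, y in zip(a.r_vec, b.r_vec))
    na = math.sqrt(sum(x * x for x in a.r_vec))
    nb = math.sqrt(sum(x * x for x in b.r_vec))
    cos = max(-1.0, min(1.0, dot / (na * nb)))
    return d_ca, d_cm, math.degrees(math.acos(cos))


def kabsch_rmsd(p: np.ndarray, q: np.ndarray) -> float:
    """Minimal RMSD via Kabsch SVD with proper-rotation correction."""
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    diff = pc @ rot.T - qc
    return float(np.sqrt((diff ** 2).sum() / len(p)))


def _pairwise_ok(query_desc, target_desc, dist_tol, angle_tol) -> bool:
    return (
        abs(query_desc[0] - target_desc[0]) <= dist_tol
        and abs(query_desc[1] - target_desc[1]) <= dist_tol
        and abs(query_desc[2] - target_desc[2]) <= angle_tol
    )


def brute_force_search(
    structures: dict[str, list[ResidueGeometry]],
    query_nodes: dict[str, ResidueGeometry],
    dist_tol: float = 1.0,
    angle_tol: float = 20.0,
    rmsd_mode: str = "both",
) -> list[tuple[str, tuple[tuple[str, str], ...], float]]:
    """Exhaustive strict motif search ignoring any index.

    Enumerates every injective assignment of query positions to same-type
    residues in every structure and accepts it when all C(n,2) residue-pair
    descriptors lie within the tolerances. A target pair with a Cα–Cα
    distance beyond the 20 Å indexation cutoff cannot be represented in an
    index, so assignments containing such a pair are excluded to match the
    search contract. Returns sorted (structure_id, mapping, rmsd) triples.
    """
    positions = sorted(query_nodes)
    q_desc = {
        (a, b): descriptor_oracle(query_nodes[a], query_nodes[b])
        for a, b in itertools.combinations(positions, 2)
    }
    hits = []
    for sid, residues in structures.items():
        pools = [
            [r for r in residues if r.aa_type == query_nodes[pos].aa_type]
            for pos in positions
        ]
        for combo in itertools.product(*pools):
            if len({r.residue_id for r in combo}) != len(combo):
                continue
            assigned = dict(zip(positions, combo))
            ok = True
            for (a, b), qd in q_desc.items():
                td = descriptor_oracle(assigned[a], assigned[b])
                if td[0] > 20.0 or not _pairwise_ok(qd, td, dist_tol, angle_tol):
                    ok = False
                    break
            if not ok:
                continue
            q_pts, t_pts = [], []
            for pos in positions:
                qr, tr = query_nodes[pos], assigned[pos]
                if rmsd_mode in ("ca", "both"):
                    q_pts.append(qr.ca)
                    t_pts.append(tr.ca)
                if rmsd_mode in ("cm", "both"):
                    q_pts.append(qr.cm)
                    t_pts.append(tr.cm)
            rmsd = kabsch_rmsd(np.array(q_pts), np.array(t_pts))
            mapping = tuple(
                sorted((pos, assigned[pos].residue_id) for pos in positions)
            )
            hits.append((sid, mapping, rmsd))
    hits.sort()
    return hits
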