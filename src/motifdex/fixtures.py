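"""Synthetic protein-structure fixtures with fully known geometry.

Real motif-search validation data would need curated structure downloads;
instead this module writes minimal, valid PDB files whose residue
pseudoatom geometry is chosen by a seeded random generator, so that every
descriptor, index record and search hit can be predicted exactly:

* decoy residues get random types and positions (minimum 3 Å Cα–Cα
  separation) inside a cubic box;
* a planted motif — an explicit list of residues with their Cα/Cμ
  coordinates — can be transplanted into a chosen number of structures
  after a random proper rigid-body transform, which leaves all pair
  descriptors unchanged;
* a sidecar ``truth.json`` records exactly where motifs were planted.

The same seed always produces byte-identical files. Residues are written
with a full backbone (N, CA, C, O) plus a single CB pseudoatom placed at
the intended side-chain centroid, so the file round-trips through the
parser to exactly the intended Cμ; glycine is written with backbone atoms
positioned to give the intended R vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import ONE_TO_THREE, STANDARD_AA, parse_structure

#: Reserved seed for which rigid_transform applies the identity transform.
IDENTITY_SEED = 0


class FixtureError(RuntimeError):
    """Fixture generation failed (e.g. infeasible packing)."""


@dataclass(frozen=True)
class PlantedResidue:
    """One residue of a motif to be transplanted into structures.

    ``r_vec`` is only needed for glycine (whose Cμ equals its Cα); for
    other residues it defaults to Cα − Cμ, matching the parser.
    """

    aa: str
    ca: tuple[float, float, float]
    cm: tuple[float, float, float]
    r_vec: tuple[float, float, float] | None = None

    def resolved_r_vec(self) -> np.ndarray:
        if self.r_vec is not None:
            return np.asarray(self.r_vec, dtype=float)
        if self.aa == "G":
            return np.array([1.2, 0.0, 0.0])  # deterministic default direction
        return np.asarray(self.ca, dtype=float) - np.asarray(self.cm, dtype=float)


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    n_structures: int = 10
    residues_per_structure: int = 30
    box_size: float = 40.0
    planted_motif: tuple[PlantedResidue, ...] = ()
    transplant_count: int = 0

    def __post_init__(self) -> None:
        if self.transplant_count > self.n_structures:
            raise FixtureError("cannot plant the motif in more structures than exist")
        for res in self.planted_motif:
            if res.aa not in STANDARD_AA:
                raise FixtureError(f"invalid planted amino acid {res.aa!r}")


# ---------------------------------------------------------------------------
# Minimal PDB writing


def _atom_line(serial: int, name: str, resname: str, chain: str, resseq: int,
               pos: np.ndarray, element: str) -> str:
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"ATOM  {serial:5d} {name_field:4s} {resname:3s} {chain:1s}{resseq:4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2s}"
    )


def _perpendicular(v: np.ndarray) -> np.ndarray:
    axis = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(v, axis)) > 0.9 * np.linalg.norm(v):
        axis = np.array([0.0, 1.0, 0.0])
    p = np.cross(v, axis)
    return p / np.linalg.norm(p)


def _residue_atoms(aa: str, ca: np.ndarray, cm: np.ndarray,
                   r_vec: np.ndarray) -> list[tuple[str, np.ndarray, str]]:
    """Atoms whose parsed pseudoatoms reproduce (ca, cm, r_vec) exactly."""
    if aa == "G":
        # Midpoint of N and C must be ca - r_vec; split them along a
        # perpendicular so the file looks like a plausible backbone.
        mid = ca - r_vec
        t = 1.2 * _perpendicular(r_vec)
        return [
            ("N", mid + t, "N"),
            ("CA", ca, "C"),
            ("C", mid - t, "C"),
            ("O", mid - t + np.array([0.0, 0.0, 1.2]), "O"),
        ]
    # A single CB heavy side-chain atom makes the centroid equal cm exactly.
    return [
        ("N", ca + np.array([-1.2, 0.8, 0.0]), "N"),
        ("CA", ca, "C"),
        ("C", ca + np.array([1.2, 0.8, 0.0]), "C"),
        ("O", ca + np.array([1.9, 1.7, 0.0]), "O"),
        ("CB", cm, "C"),
    ]


def write_structure(
    residues: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]],
    path: Path,
    chain: str = "A",
    first_resseq: int = 1,
) -> None:
    """Write residues given as (aa, ca, cm, r_vec) tuples to a PDB file."""
    lines: list[str] = []
    serial = 1
    for i, (aa, ca, cm, r_vec) in enumerate(residues):
        resname = ONE_TO_THREE[aa]
        for name, pos, element in _residue_atoms(aa, ca, cm, r_vec):
            lines.append(_atom_line(serial, name, resname, chain,
                                    first_resseq + i, pos, element))
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_motif_structure(motif: tuple[PlantedResidue, ...], path: Path,
                          chain: str = "A", first_resseq: int = 1) -> list[str]:
    """Write the planted motif itself as a query structure file.

    Returns the residue ids of the motif residues in the written file.
    """
    residues = [
        (r.aa, np.asarray(r.ca, float), np.asarray(r.cm, float),
         r.resolved_r_vec())
        for r in motif
    ]
    write_structure(residues, path, chain=chain, first_resseq=first_resseq)
    return [f"{chain}{first_resseq + i}" for i in range(len(motif))]


# ---------------------------------------------------------------------------
# Structure-set generation


def _random_decoys(
    rng: np.random.Generator, n: int, box: float,
    existing_ca: list[np.ndarray],
) -> list[tuple[str, np.ndarray, np.ndarray, np.ndarray]]:
    letters = sorted(STANDARD_AA)
    out: list[tuple[str, np.ndarray, np.ndarray, np.ndarray]] = []
    placed = list(existing_ca)
    for _ in range(n):
        for _attempt in range(1000):
            ca = rng.uniform(0.0, box, size=3)
            if all(np.linalg.norm(ca - p) >= 3.0 for p in placed):
                break
        else:
            raise FixtureError(
                f"cannot pack {n} residues with 3 Å separation in a "
                f"{box} Å box"
            )
        placed.append(ca)
        aa = letters[rng.integers(0, 20)]
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(1.5, 3.0)
        if aa == "G":
            cm = ca.copy()
            r_vec = 1.2 * direction
        else:
            cm = ca + length * direction
            r_vec = ca - cm
        out.append((aa, ca, cm, r_vec))
    return out


def _transplant(
    rng: np.random.Generator,
    motif: tuple[PlantedResidue, ...],
    box: float,
    decoy_ca: list[np.ndarray],
) -> list[tuple[str, np.ndarray, np.ndarray, np.ndarray]]:
    cas = np.array([r.ca for r in motif], dtype=float)
    cms = np.array([r.cm for r in motif], dtype=float)
    rvs = np.array([r.resolved_r_vec() for r in motif], dtype=float)
    center = cas.mean(axis=0)
    for _attempt in range(1000):
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(5.0, box - 5.0, size=3)
        new_ca = (cas - center) @ rot.T + shift
        if np.any(new_ca < 0.0) or np.any(new_ca > box):
            continue
        ok = all(
            np.linalg.norm(ca - p) >= 3.0 for ca in new_ca for p in decoy_ca
        )
        if ok:
            new_cm = (cms - center) @ rot.T + shift
            new_rv = rvs @ rot.T
            return [
                (motif[i].aa, new_ca[i], new_cm[i], new_rv[i])
                for i in range(len(motif))
            ]
    raise FixtureError("could not place the planted motif clash-free")


def generate_structures(spec: FixtureSpec, out_dir: str | Path) -> list[Path]:
    """Write the synthetic structure set and its truth file.

    Returns the structure file paths in order. The motif, when present, is
    transplanted (after a random rigid transform) into the first
    ``transplant_count`` structures; planted residues are numbered from 901
    so they are recognizable in the truth file. ``truth.json`` lists each
    planted (structure, residue ids) entry.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    paths: list[Path] = []
    truth: list[dict] = []
    width = max(3, len(str(spec.n_structures - 1)))
    for i in range(spec.n_structures):
        sid = f"synth_{i:0{width}d}"
        path = out_dir / f"{sid}.pdb"
        decoys = _random_decoys(rng, spec.residues_per_structure,
                                spec.box_size, [])
        lines_residues = list(decoys)
        planted_ids: list[dict] = []
        if spec.planted_motif and i < spec.transplant_count:
            planted = _transplant(rng, spec.planted_motif, spec.box_size,
                                  [d[1] for d in decoys])
            for j, (aa, *_rest) in enumerate(planted):
                planted_ids.append({"id": f"A{901 + j}", "aa": aa})
            _write_with_plant(decoys, planted, path)
        else:
            write_structure(lines_residues, path)
        if planted_ids:
            truth.append({"structure_id": sid, "residues": planted_ids})
        paths.append(path)
    (out_dir / "truth.json").write_text(
        json.dumps({"planted": truth, "seed": spec.seed}, indent=2) + "\n"
    )
    return paths


def _write_with_plant(decoys, planted, path: Path) -> None:
    lines: list[str] = []
    serial = 1
    for i, (aa, ca, cm, r_vec) in enumerate(decoys):
        for name, pos, element in _residue_atoms(aa, ca, cm, r_vec):
            lines.append(_atom_line(serial, name, ONE_TO_THREE[aa], "A",
                                    1 + i, pos, element))
            serial += 1
    for j, (aa, ca, cm, r_vec) in enumerate(planted):
        for name, pos, element in _residue_atoms(aa, ca, cm, r_vec):
            lines.append(_atom_line(serial, name, ONE_TO_THREE[aa], "A",
                                    901 + j, pos, element))
            serial += 1
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Rigid transforms of existing files


def rigid_transform(path: str | Path, seed: int,
                    out_path: str | Path | None = None) -> Path:
    """Apply one random proper rotation + translation to every atom.

    Seed :data:`IDENTITY_SEED` (0) is reserved for the identity transform.
    Residue and atom naming are unchanged; pair descriptors are preserved
    up to the coordinate precision of the output format.
    """
    path = Path(path)
    out_path = Path(out_path) if out_path else path.with_name(
        f"{path.stem}_rt{seed}{path.suffix}"
    )
    structure = gemmi.read_structure(str(path))
    if seed != IDENTITY_SEED:
        rng = np.random.default_rng(seed)
        rot = Rotation.random(rng=rng).as_matrix()
        shift = rng.uniform(-20.0, 20.0, size=3)
        for model in structure:
            for chain in model:
                for residue in chain:
                    for atom in residue:
                        p = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                        q = rot @ p + shift
                        atom.pos = gemmi.Position(*q)
    structure.setup_entities()
    structure.write_pdb(str(out_path))
    return out_path
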