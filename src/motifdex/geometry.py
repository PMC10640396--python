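"""Per-residue pseudoatoms and rotation-invariant residue-pair descriptors.

Every residue is reduced to two pseudoatoms: its alpha-carbon (Cα) and its
side-chain centroid (Cμ, the mean of the heavy side-chain atom coordinates).
A pair of residues is then described by three numbers that are invariant
under rigid-body motion of the structure:

* the Cα–Cα distance,
* the Cμ–Cμ distance,
* the angle between the two vectors R = Cα − Cμ.

Glycine has no heavy side-chain atoms, so by convention Cμ = Cα and
R = Cα − C_NC, where C_NC is the midpoint of the backbone N and C atoms.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

logger = logging.getLogger("motifdex")

#: One-letter codes of the 20 standard amino acids.
STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# Backbone atoms never contribute to the side-chain centroid; OXT is
# excluded from all computations.
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


class ParseError(Exception):
    """The structure file could not be read or contains no usable residue."""


class EmptyStructureError(ParseError):
    """The file parsed but yielded zero usable amino-acid residues."""


class DegenerateGeometryError(ValueError):
    """A residue has a zero-length R vector, so no pair angle is defined."""


@dataclass(frozen=True)
class ResidueGeometry:
    """Pseudoatom representation of one amino-acid residue.

    Attributes
    ----------
    residue_id
        Chain id immediately followed by the residue sequence number and
        insertion code if present, e.g. ``"A46"`` or ``"B102A"``.
    aa_type
        One-letter amino-acid code.
    ca, cm
        Cα and side-chain-centroid coordinates in Å.
    r_vec
        Cα − Cμ (or the glycine substitute Cα − C_NC), in Å.
    """

    residue_id: str
    aa_type: str
    ca: np.ndarray
    cm: np.ndarray
    r_vec: np.ndarray

    def __post_init__(self) -> None:
        if self.aa_type not in STANDARD_AA:
            raise ValueError(f"not a standard amino acid: {self.aa_type!r}")


@dataclass(frozen=True)
class PairDescriptor:
    """Rotation-invariant geometric description of one residue pair."""

    d_ca: float
    d_cm: float
    angle: float  # degrees, in [0, 180]


def pair_descriptors(a: ResidueGeometry, b: ResidueGeometry) -> PairDescriptor:
    """Compute the three pair descriptors for residues *a* and *b*.

    The angle is arccos of the normalized dot product of the two R vectors,
    clamped to [−1, 1] before arccos for numerical safety. Symmetric in its
    arguments.
    """
    d_ca = float(np.linalg.norm(a.ca - b.ca))
    d_cm = float(np.linalg.norm(a.cm - b.cm))
    na = float(np.linalg.norm(a.r_vec))
    nb = float(np.linalg.norm(b.r_vec))
    if na == 0.0 or nb == 0.0:
        raise DegenerateGeometryError(
            f"zero-length R vector for {a.residue_id if na == 0.0 else b.residue_id}"
        )
    cos = float(np.dot(a.r_vec, b.r_vec)) / (na * nb)
    cos = max(-1.0, min(1.0, cos))
    return PairDescriptor(d_ca=d_ca, d_cm=d_cm, angle=math.degrees(math.acos(cos)))


def _detect_format(path: Path, fmt: str) -> gemmi.CoorFormat:
    if fmt == "pdb":
        return gemmi.CoorFormat.Pdb
    if fmt == "mmcif":
        return gemmi.CoorFormat.Mmcif
    if fmt == "auto":
        suffix = path.suffix.lower()
        if suffix in {".pdb", ".ent"}:
            return gemmi.CoorFormat.Pdb
        if suffix in {".cif", ".mmcif"}:
            return gemmi.CoorFormat.Mmcif
        return gemmi.CoorFormat.Detect
    raise ValueError(f"unknown format {fmt!r}; expected pdb, mmcif or auto")


def _select_altlocs(residue: gemmi.Residue) -> dict[str, gemmi.Atom]:
    """Keep one atom per atom name: highest occupancy, ties → first listed."""
    chosen: dict[str, gemmi.Atom] = {}
    for atom in residue:
        name = atom.name
        if name not in chosen or atom.occ > chosen[name].occ:
            chosen[name] = atom
    return chosen


def _pos(atom: gemmi.Atom) -> np.ndarray:
    return np.array([atom.pos.x, atom.pos.y, atom.pos.z], dtype=float)


def parse_structure(path: str | Path, fmt: str = "auto") -> list[ResidueGeometry]:
    """Parse a PDB or mmCIF file into per-residue pseudoatom geometry.

    Only the first model of multi-model files is read; all chains are
    included. Non-standard residues (hetero groups, modified residues) are
    skipped. A residue is usable when it has a Cα atom and, for non-glycine,
    at least one heavy side-chain atom or, for glycine, backbone N and C
    atoms; unusable residues are skipped with a logged warning.

    Raises
    ------
    ParseError
        If the file cannot be read.
    EmptyStructureError
        If no usable residue remains.
    """
    path = Path(path)
    try:
        structure = gemmi.read_structure(str(path), format=_detect_format(path, fmt))
    except Exception as exc:  # gemmi raises RuntimeError/ValueError variants
        raise ParseError(f"cannot parse structure file {path}: {exc}") from exc
    if len(structure) == 0:
        raise EmptyStructureError(f"no model in structure file {path}")

    out: list[ResidueGeometry] = []
    model = structure[0]
    for chain in model:
        for residue in chain:
            aa = THREE_TO_ONE.get(residue.name.upper())
            if aa is None:
                continue  # hetero / non-standard residue
            atoms = _select_altlocs(residue)
            rid = f"{chain.name}{residue.seqid.num}{(residue.seqid.icode or ' ').strip()}"
            ca_atom = atoms.get("CA")
            if ca_atom is None:
                logger.warning("%s: residue %s has no CA atom; skipped", path.name, rid)
                continue
            ca = _pos(ca_atom)
            if aa == "G":
                n_atom, c_atom = atoms.get("N"), atoms.get("C")
                if n_atom is None or c_atom is None:
                    logger.warning(
                        "%s: Gly %s lacks backbone N/C atoms; skipped", path.name, rid
                    )
                    continue
                cm = ca.copy()
                r_vec = ca - 0.5 * (_pos(n_atom) + _pos(c_atom))
            else:
                side = [
                    _pos(atom)
                    for name, atom in atoms.items()
                    if name not in _BACKBONE_ATOMS and not atom.element.is_hydrogen
                ]
                if not side:
                    logger.warning(
                        "%s: residue %s has no heavy side-chain atom; skipped",
                        path.name, rid,
                    )
                    continue
                cm = np.mean(side, axis=0)
                r_vec = ca - cm
            if float(np.linalg.norm(r_vec)) == 0.0:
                logger.warning(
                    "%s: residue %s has a zero-length R vector; skipped", path.name, rid
                )
                continue
            out.append(ResidueGeometry(rid, aa, ca, cm, r_vec))

    if not out:
        raise EmptyStructureError(f"no usable amino-acid residue in {path}")
    return out
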