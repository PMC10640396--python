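from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from motifdex.fixtures import (
    FixtureSpec,
    PlantedResidue,
    generate_structures,
    write_motif_structure,
)
from motifdex.geometry import parse_structure
from motifdex.index_builder import build_index, load_manifest


CYS_HIS_SER_GLY_MOTIF = (
    PlantedResidue("C", (0.0, 0.0, 0.0), (-1.5, 0.5, 0.0)),
    PlantedResidue("H", (6.0, 1.0, 0.0), (7.0, 2.0, 1.0)),
    PlantedResidue("S", (3.0, 5.0, 2.0), (4.0, 6.0, 2.0)),
    PlantedResidue("G", (2.0, -4.0, 3.0), (2.0, -4.0, 3.0)),
)


@pytest.fixture(scope="session")
def planted_set(tmp_path_factory):
    """10 decoy structures, 3 of which carry a rigidly transplanted motif."""
    root = tmp_path_factory.mktemp("planted")
    spec = FixtureSpec(
        seed=7,
        n_structures=13,
        residues_per_structure=25,
        box_size=40.0,
        planted_motif=CYS_HIS_SER_GLY_MOTIF,
        transplant_count=3,
    )
    paths = generate_structures(spec, root / "structs")
    query_path = root / "query.pdb"
    query_ids = write_motif_structure(CYS_HIS_SER_GLY_MOTIF, query_path)
    return {"root": root, "paths": paths, "query_path": query_path,
            "query_ids": query_ids, "spec": spec}


@pytest.fixture(scope="session")
def planted_index(planted_set):
    index_dir = planted_set["root"] / "index"
    manifest = build_index(planted_set["paths"], index_dir)
    return {"dir": index_dir, "manifest": manifest, **planted_set}


@pytest.fixture(scope="session")
def decoy_set(tmp_path_factory):
    """50 decoy-only structures plus their parsed residues, indexed."""
    root = tmp_path_factory.mktemp("decoys")
    spec = FixtureSpec(seed=11, n_structures=50, residues_per_structure=30,
                       box_size=40.0)
    paths = generate_structures(spec, root / "structs")
    residues = {p.stem: parse_structure(p) for p in paths}
    index_dir = root / "index"
    manifest = build_index(paths, index_dir)
    return {"root": root, "paths": paths, "residues": residues,
            "dir": index_dir, "manifest": manifest}


def pick_compact_query(residues, rng: np.random.Generator, size: int,
                       max_ca: float = 19.0):
    """Pick `size` residues of one structure with pairwise d_ca <= max_ca."""
    order = rng.permutation(len(residues))
    for start in order:
        chosen = [residues[start]]
        for idx in order:
            r = residues[idx]
            if r.residue_id in {c.residue_id for c in chosen}:
                continue
            if all(np.linalg.norm(r.ca - c.ca) <= max_ca for c in chosen):
                chosen.append(r)
            if len(chosen) == size:
                return chosen
    return None
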