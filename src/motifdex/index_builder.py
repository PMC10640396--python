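"""Build and read the inverted index of binned residue-pair geometries.

The index maps a (pair type, geometry bin) key to every occurrence of that
residue pair across a set of structures. Pair types are the 210 unordered
combinations of the 20 standard amino acids. Geometry bins discretize the
three pair descriptors: 1 Å bins for the two distances and 20° bins for the
R-vector angle. Only pairs with Cα–Cα distance ≤ 20 Å are indexed, so Cα
bins run 0–19; Cμ–Cμ distances may exceed 20 Å (centroids can lie farther
apart than the Cα atoms), so Cμ bins are not capped.

On disk an index directory contains:

* ``pairs/<pair_type>/<pair_type>_<ca>_<cm>_<angle>.parquet`` — one
  compressed columnar table per non-empty bin,
* ``residues/<structure_id>.parquet`` — per-structure pseudoatom tables,
  used to recompute descriptors and superpose hits at search time,
* ``manifest.json`` — human-readable metadata and per-bin record counts.

During the build, occurrences are appended to plain per-bin CSV files; a
finalize pass then sorts and deduplicates each bin and rewrites it as a
compressed table, which makes the finished index invariant to the number of
worker processes used.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .geometry import (
    PairDescriptor,
    ParseError,
    ResidueGeometry,
    STANDARD_AA,
    pair_descriptors,
    parse_structure,
)

logger = logging.getLogger("motifdex")

FORMAT_VERSION = 1
DEFAULT_CA_CUTOFF = 20.0
DIST_BIN_WIDTH = 1.0
ANGLE_BIN_WIDTH = 20.0
MAX_CA_BIN = 19
MAX_ANGLE_BIN = 8

_PAIR_COLUMNS = ["structure_id", "res1_id", "res2_id", "d_ca", "d_cm", "angle"]
_RESIDUE_COLUMNS = [
    "residue_id", "aa",
    "ca_x", "ca_y", "ca_z", "cm_x", "cm_y", "cm_z", "r_x", "r_y", "r_z",
]

#: All 210 valid pair-type codes ("AA", "AC", ..., "YY").
ALL_PAIR_TYPES = frozenset(
    "".join(sorted(p))
    for p in itertools.combinations_with_replacement(sorted(STANDARD_AA), 2)
)


class IndexError_(Exception):
    """Base class for index build/read failures."""


class IndexNotFoundError(IndexError_):
    pass


class IndexIntegrityError(IndexError_):
    pass


@dataclass(frozen=True)
class PairRecord:
    """One indexed residue-pair occurrence.

    ``pair_type`` is derived metadata: the canonically ordered two-letter
    code of the pair, with ``res1_id`` belonging to the alphabetically
    smaller amino acid (ties broken by residue id).
    """

    structure_id: str
    res1_id: str
    res2_id: str
    d_ca: float
    d_cm: float
    angle: float
    pair_type: str


@dataclass(frozen=True, order=True)
class BinKey:
    pair_type: str
    ca_bin: int
    cm_bin: int
    angle_bin: int

    def __post_init__(self) -> None:
        if self.pair_type not in ALL_PAIR_TYPES:
            raise ValueError(f"invalid pair type {self.pair_type!r}")
        if not (0 <= self.ca_bin <= MAX_CA_BIN):
            raise ValueError(f"ca_bin out of range: {self.ca_bin}")
        if self.cm_bin < 0 or not (0 <= self.angle_bin <= MAX_ANGLE_BIN):
            raise ValueError("bin index out of range")

    @property
    def filename(self) -> str:
        return (
            f"{self.pair_type}_{self.ca_bin}_{self.cm_bin}_{self.angle_bin}.parquet"
        )

    def path(self, index_dir: Path) -> Path:
        return Path(index_dir) / "pairs" / self.pair_type / self.filename


@dataclass
class IndexManifest:
    format_version: int
    ca_cutoff: float
    dist_bin_width: float
    angle_bin_width: float
    n_structures: int
    n_pair_records: int
    structure_ids: list[str]
    skipped_files: list[str]
    bin_counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "IndexManifest":
        return cls(**json.loads(text))


def canonical_pair_type(aa1: str, aa2: str) -> str:
    """Return the canonically (alphabetically) ordered two-letter pair code."""
    if aa1 not in STANDARD_AA or aa2 not in STANDARD_AA:
        raise ValueError(f"invalid amino-acid letters: {aa1!r}, {aa2!r}")
    return aa1 + aa2 if aa1 <= aa2 else aa2 + aa1


def bin_key(pair_type: str, d: PairDescriptor) -> BinKey:
    """Map a descriptor to its index bin.

    Distances use floor(d / 1 Å); a Cα distance of exactly the 20 Å cutoff
    falls in the last bin (19). Angles use floor(angle / 20°) with exactly
    180° assigned to bin 8. The pair-type letters are canonically ordered.
    """
    if d.d_ca > DEFAULT_CA_CUTOFF:
        raise ValueError(f"d_ca {d.d_ca} exceeds the {DEFAULT_CA_CUTOFF} Å cutoff")
    return BinKey(
        pair_type=canonical_pair_type(pair_type[0], pair_type[1]),
        ca_bin=min(int(math.floor(d.d_ca / DIST_BIN_WIDTH)), MAX_CA_BIN),
        cm_bin=int(math.floor(d.d_cm / DIST_BIN_WIDTH)),
        angle_bin=min(int(math.floor(d.angle / ANGLE_BIN_WIDTH)), MAX_ANGLE_BIN),
    )


def enumerate_pairs(
    residues: list[ResidueGeometry],
    structure_id: str,
    ca_cutoff: float = DEFAULT_CA_CUTOFF,
) -> list[PairRecord]:
    """All unordered residue pairs of one structure with d_ca ≤ the cutoff.

    Residues within each record are stored in canonical order: the residue
    with the alphabetically smaller one-letter code is ``res1``; same-type
    pairs are ordered by residue id. Descriptors are symmetric, so no value
    depends on the ordering.
    """
    records: list[PairRecord] = []
    for a, b in itertools.combinations(residues, 2):
        d = pair_descriptors(a, b)
        if d.d_ca > ca_cutoff:
            continue
        if (a.aa_type, a.residue_id) > (b.aa_type, b.residue_id):
            a, b = b, a
        records.append(
            PairRecord(
                structure_id=structure_id,
                res1_id=a.residue_id,
                res2_id=b.residue_id,
                d_ca=d.d_ca,
                d_cm=d.d_cm,
                angle=d.angle,
                pair_type=a.aa_type + b.aa_type,
            )
        )
    return records


def _residue_frame(residues: list[ResidueGeometry]) -> pd.DataFrame:
    rows = [
        (r.residue_id, r.aa_type, *r.ca, *r.cm, *r.r_vec) for r in residues
    ]
    return pd.DataFrame(rows, columns=_RESIDUE_COLUMNS)


def _process_structure(
    path: Path, fmt: str, ca_cutoff: float
) -> tuple[str, list[PairRecord] | None, pd.DataFrame | None]:
    structure_id = path.stem
    try:
        residues = parse_structure(path, fmt=fmt)
    except ParseError as exc:
        logger.warning("skipping %s: %s", path, exc)
        return structure_id, None, None
    return (
        structure_id,
        enumerate_pairs(residues, structure_id, ca_cutoff=ca_cutoff),
        _residue_frame(residues),
    )


def build_index(
    structure_paths: list[str | Path],
    out_dir: str | Path,
    workers: int = 1,
    fmt: str = "auto",
    ca_cutoff: float = DEFAULT_CA_CUTOFF,
    overwrite: bool = False,
) -> IndexManifest:
    """Index a set of structure files into *out_dir*.

    Structures are parsed and their pairs enumerated independently (in
    parallel when ``workers > 1``); occurrences are appended to per-bin CSV
    files and a finalize pass sorts, deduplicates and compresses each bin,
    so the finished index does not depend on the worker count. Unparseable
    files are logged, skipped and listed in the manifest.
    """
    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    if manifest_path.exists():
        if not overwrite:
            raise IndexError_(
                f"{out_dir} already contains a finalized index (use overwrite)"
            )
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "_INCOMPLETE"
    marker.touch()
    tmp_dir = out_dir / "_tmp"
    tmp_dir.mkdir(exist_ok=True)
    (out_dir / "residues").mkdir(exist_ok=True)

    paths = [Path(p) for p in structure_paths]
    ids = [p.stem for p in paths]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise IndexError_(f"duplicate structure ids: {sorted(dupes)}")

    results = Parallel(n_jobs=max(1, workers))(
        delayed(_process_structure)(p, fmt, ca_cutoff) for p in paths
    )

    structure_ids: list[str] = []
    skipped: list[str] = []
    try:
        for (sid, records, residue_frame), path in zip(results, paths):
            if records is None:
                skipped.append(path.name)
                continue
            structure_ids.append(sid)
            residue_frame.to_parquet(out_dir / "residues" / f"{sid}.parquet")
            by_bin: dict[BinKey, list[PairRecord]] = {}
            for rec in records:
                key = bin_key(
                    rec.pair_type,
                    PairDescriptor(rec.d_ca, rec.d_cm, rec.angle),
                )
                by_bin.setdefault(key, []).append(rec)
            for key, recs in by_bin.items():
                csv_path = tmp_dir / key.filename.replace(".parquet", ".csv")
                new_file = not csv_path.exists()
                with csv_path.open("a") as fh:
                    if new_file:
                        fh.write(",".join(_PAIR_COLUMNS) + "\n")
                    for r in recs:
                        fh.write(
                            f"{r.structure_id},{r.res1_id},{r.res2_id},"
                            f"{r.d_ca!r},{r.d_cm!r},{r.angle!r}\n"
                        )

        # Finalize: sort + deduplicate each bin and rewrite it compressed.
        bin_counts: dict[str, int] = {}
        n_records = 0
        for csv_path in sorted(tmp_dir.glob("*.csv")):
            frame = pd.read_csv(csv_path, dtype={"structure_id": str,
                                                 "res1_id": str, "res2_id": str})
            frame = (
                frame.drop_duplicates()
                .sort_values(["structure_id", "res1_id", "res2_id"])
                .reset_index(drop=True)
            )
            stem = csv_path.stem
            pair_type = stem.split("_", 1)[0]
            dest = out_dir / "pairs" / pair_type
            dest.mkdir(parents=True, exist_ok=True)
            frame.to_parquet(dest / f"{stem}.parquet")
            bin_counts[stem] = len(frame)
            n_records += len(frame)
        shutil.rmtree(tmp_dir)
    except OSError as exc:
        raise IndexError_(
            f"index build aborted ({exc}); partial index marked by {marker}"
        ) from exc

    manifest = IndexManifest(
        format_version=FORMAT_VERSION,
        ca_cutoff=ca_cutoff,
        dist_bin_width=DIST_BIN_WIDTH,
        angle_bin_width=ANGLE_BIN_WIDTH,
        n_structures=len(structure_ids),
        n_pair_records=n_records,
        structure_ids=sorted(structure_ids),
        skipped_files=sorted(skipped),
        bin_counts=dict(sorted(bin_counts.items())),
    )
    manifest_path.write_text(manifest.to_json())
    marker.unlink()
    return manifest


def load_manifest(index_dir: str | Path) -> IndexManifest:
    path = Path(index_dir) / "manifest.json"
    if not path.exists():
        raise IndexNotFoundError(f"no index manifest at {path}")
    if (Path(index_dir) / "_INCOMPLETE").exists():
        raise IndexIntegrityError(f"index at {index_dir} is marked incomplete")
    return IndexManifest.from_json(path.read_text())


def _frame_to_records(frame: pd.DataFrame, pair_type: str) -> list[PairRecord]:
    return [
        PairRecord(
            structure_id=row.structure_id,
            res1_id=row.res1_id,
            res2_id=row.res2_id,
            d_ca=row.d_ca,
            d_cm=row.d_cm,
            angle=row.angle,
            pair_type=pair_type,
        )
        for row in frame.itertuples(index=False)
    ]


def load_bin(index_dir: str | Path, key: BinKey) -> list[PairRecord]:
    """Load all records of one bin; a bin with no occurrences yields []."""
    path = key.path(Path(index_dir))
    if not path.exists():
        return []
    try:
        frame = pd.read_parquet(path)
    except Exception as exc:
        raise IndexIntegrityError(f"corrupted index table {path}: {exc}") from exc
    return _frame_to_records(frame, key.pair_type)


def load_structure_residues(
    index_dir: str | Path, structure_id: str
) -> list[ResidueGeometry]:
    """Recover the pseudoatom geometry of one indexed structure."""
    path = Path(index_dir) / "residues" / f"{structure_id}.parquet"
    if not path.exists():
        raise IndexNotFoundError(f"structure {structure_id!r} not in index")
    frame = pd.read_parquet(path)
    return [
        ResidueGeometry(
            residue_id=row.residue_id,
            aa_type=row.aa,
            ca=np.array([row.ca_x, row.ca_y, row.ca_z]),
            cm=np.array([row.cm_x, row.cm_y, row.cm_z]),
            r_vec=np.array([row.r_x, row.r_y, row.r_z]),
        )
        for row in frame.itertuples(index=False)
    ]
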