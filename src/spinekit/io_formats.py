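"""Reading and writing external representations.

Meshes travel as VRML 2.0 ``IndexedFaceSet`` (the dialect Imaris exports),
Wavefront OBJ or PLY; per-spine feature tables and query results travel as
CSV.  Coordinates are micrometres throughout and are passed through
unchanged — no axis convention is imposed, since positions are only used as
metadata.

The VRML support is deliberately narrow: ``coord Coordinate { point [...] }``
plus a ``coordIndex`` list (``-1``-terminated polygons, fan-triangulated).
Materials, transforms and prototypes are ignored.  OBJ and PLY go through
:mod:`trimesh`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .errors import (
    EmptyMeshError,
    InvalidMeshError,
    MeshFormatError,
    SchemaError,
    SpinekitError,
)

__all__ = [
    "TriangleMesh",
    "SpineRecord",
    "FeatureTable",
    "CANONICAL_FEATURES",
    "DEFAULT_ALIASES",
    "REGIONS",
    "read_mesh",
    "write_mesh",
    "read_feature_table",
    "write_feature_table",
    "write_scores",
    "write_colored_mesh",
]

#: Canonical feature column names used across the toolkit.
CANONICAL_FEATURES = [
    "Volume",
    "Area",
    "Length",
    "MaxDiameter",
    "NeckMeanDiameter",
    "PotentialPeak",
]

#: Header aliases accepted on input (Imaris-style exports), case-insensitive.
DEFAULT_ALIASES = {
    "spine volume": "Volume",
    "spine part volume": "Volume",
    "spine volume um3": "Volume",
    "volume": "Volume",
    "spine area": "Area",
    "spine area um2": "Area",
    "area": "Area",
    "spine length": "Length",
    "spine length um": "Length",
    "length": "Length",
    "spine max diameter": "MaxDiameter",
    "spine maximum diameter": "MaxDiameter",
    "max diameter": "MaxDiameter",
    "maxdiameter": "MaxDiameter",
    "spine neck mean diameter": "NeckMeanDiameter",
    "neck mean diameter": "NeckMeanDiameter",
    "neckmeandiameter": "NeckMeanDiameter",
    "membrane potential peak": "PotentialPeak",
    "membrane pot. peak": "PotentialPeak",
    "potentialpeak": "PotentialPeak",
}

REGIONS = ("apical_main", "apical_collateral", "basal", "unknown")

_META_COLUMNS = ("id", "x", "y", "z", "region", "spine_class")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """A triangle surface mesh of a single spine, coordinates in µm."""

    vertices: np.ndarray
    faces: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        v, f = self.vertices, self.faces
        if v.ndim != 2 or v.shape[1] != 3:
            raise InvalidMeshError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise InvalidMeshError(f"faces must be (m, 3), got {f.shape}")
        if len(f) < 1:
            raise EmptyMeshError("mesh has no faces")
        if not np.isfinite(v).all():
            raise InvalidMeshError("non-finite vertex coordinate")
        if f.min(initial=0) < 0 or f.max(initial=-1) >= len(v):
            raise InvalidMeshError("face index out of range")
        degenerate = (
            (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        )
        if degenerate.any():
            raise InvalidMeshError(
                f"{int(degenerate.sum())} degenerate face(s) with repeated indices"
            )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, name: str = "") -> "TriangleMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), name=name)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriangleMesh":
        """Rigidly moved copy (rotation 3x3, translation 3-vector)."""
        return TriangleMesh(
            self.vertices @ np.asarray(rotation).T + np.asarray(translation),
            self.faces.copy(),
            name=self.name,
        )


@dataclass
class SpineRecord:
    """One spine: identifier, position (µm), region label and feature values.

    Missing features are simply absent from :attr:`features`; they are never
    imputed at the I/O layer.
    """

    id: str
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    region: str = "unknown"
    features: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.region not in REGIONS:
            raise SchemaError(
                f"unknown region {self.region!r}; expected one of {REGIONS}"
            )
        for k, v in self.features.items():
            if not np.isfinite(v):
                raise SchemaError(f"non-finite value for feature {k!r} on {self.id!r}")


@dataclass
class FeatureTable:
    """The retrieval corpus: an ordered set of spine records."""

    records: list[SpineRecord]
    feature_names: list[str]
    spine_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(f"duplicate spine ids: {dupes}")
        for r in self.records:
            extra = set(r.features) - set(self.feature_names)
            if extra:
                raise SchemaError(
                    f"record {r.id!r} has features outside the table schema: {sorted(extra)}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def record(self, spine_id: str) -> SpineRecord:
        for r in self.records:
            if r.id == spine_id:
                return r
        raise KeyError(spine_id)

    def feature_array(self, name: str) -> np.ndarray:
        """Values of one feature aligned with :attr:`records`; NaN = missing."""
        return np.array(
            [r.features.get(name, np.nan) for r in self.records], dtype=float
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "id": r.id,
                "x": r.position[0],
                "y": r.position[1],
                "z": r.position[2],
                "region": r.region,
            }
            if self.spine_classes:
                row["spine_class"] = self.spine_classes.get(r.id, "")
            for name in self.feature_names:
                row[name] = r.features.get(name, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# VRML 2.0 IndexedFaceSet subset
# ---------------------------------------------------------------------------

_VRML_COMMENT = re.compile(r"#[^\n]*")


def _vrml_block(text: str, keyword: str, opener: str, closer: str, path) -> str:
    """Extract the bracketed block following ``keyword``."""
    m = re.search(rf"\b{keyword}\b", text)
    if m is None:
        line = None
        raise MeshFormatError(f"missing {keyword!r}", path=path, line=line)
    start = text.find(opener, m.end())
    if start < 0:
        raise MeshFormatError(
            f"missing {opener!r} after {keyword!r}",
            path=path,
            line=text.count("\n", 0, m.end()) + 1,
        )
    depth = 0
    for i in range(start, len(text)):
        if text[i] == opener:
            depth += 1
        elif text[i] == closer:
            depth -= 1
            if depth == 0:
                return text[start + 1 : i]
    raise MeshFormatError(
        f"unterminated {keyword!r} block",
        path=path,
        line=text.count("\n", 0, start) + 1,
    )


def _read_vrml(path: Path) -> TriangleMesh:
    raw = path.read_text(encoding="utf-8", errors="replace")
    first = raw.lstrip().splitlines()[0] if raw.strip() else ""
    if not first.startswith("#VRML"):
        raise MeshFormatError("not a VRML file (missing #VRML header)", path=path, line=1)
    text = _VRML_COMMENT.sub("", raw)

    ifs = _vrml_block(text, "IndexedFaceSet", "{", "}", path)
    coord = _vrml_block(ifs, "Coordinate", "{", "}", path)
    point_src = _vrml_block(coord, "point", "[", "]", path)
    index_src = _vrml_block(ifs, "coordIndex", "[", "]", path)

    try:
        points = np.array(point_src.replace(",", " ").split(), dtype=np.float64)
    except ValueError as exc:
        raise MeshFormatError(f"bad coordinate data: {exc}", path=path) from exc
    if points.size == 0 or points.size % 3:
        raise MeshFormatError(
            f"coordinate list has {points.size} numbers (not a multiple of 3)",
            path=path,
        )
    vertices = points.reshape(-1, 3)

    idx_tokens = index_src.replace(",", " ").split()
    try:
        indices = [int(t) for t in idx_tokens]
    except ValueError as exc:
        raise MeshFormatError(f"bad coordIndex token: {exc}", path=path) from exc

    faces: list[tuple[int, int, int]] = []
    poly: list[int] = []
    for ix in indices + [-1]:
        if ix == -1:
            if len(poly) >= 3:
                for k in range(1, len(poly) - 1):  # fan triangulation
                    faces.append((poly[0], poly[k], poly[k + 1]))
            elif poly:
                raise MeshFormatError(
                    f"polygon with {len(poly)} vertices", path=path
                )
            poly = []
        else:
            poly.append(ix)
    if not faces:
        raise EmptyMeshError(f"no faces in {path}")

    name_m = re.search(r"\bDEF\s+(\S+)", text)
    name = name_m.group(1) if name_m else path.stem
    return TriangleMesh(vertices, np.array(faces, dtype=np.int64), name=name)


def _write_vrml(mesh: TriangleMesh, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#VRML V2.0 utf8\n")
        fh.write(f"DEF {mesh.name or path.stem} Shape {{\n")
        fh.write("  geometry IndexedFaceSet {\n")
        fh.write("    coord Coordinate {\n      point [\n")
        for v in mesh.vertices:
            fh.write(f"        {v[0]:.9g} {v[1]:.9g} {v[2]:.9g},\n")
        fh.write("      ]\n    }\n    coordIndex [\n")
        for f in mesh.faces:
            fh.write(f"      {f[0]}, {f[1]}, {f[2]}, -1,\n")
        fh.write("    ]\n  }\n}\n")


# ---------------------------------------------------------------------------
# Mesh entry points
# ---------------------------------------------------------------------------

_EXT_FORMAT = {".wrl": "vrml", ".vrml": "vrml", ".obj": "obj", ".ply": "ply"}


def _resolve_format(path: Path, fmt: str | None) -> str:
    if fmt is not None and fmt != "auto":
        if fmt not in ("vrml", "obj", "ply"):
            raise ValueError(f"unknown mesh format {fmt!r}")
        return fmt
    try:
        return _EXT_FORMAT[path.suffix.lower()]
    except KeyError:
        raise MeshFormatError(
            f"cannot infer mesh format from suffix {path.suffix!r}", path=path
        ) from None


def read_mesh(path, fmt: str | None = "auto") -> TriangleMesh:
    """Read a spine surface mesh from VRML 2.0 / OBJ / PLY.

    Quad (and larger) polygons are fan-triangulated; coordinates are taken
    as µm and passed through unchanged.
    """
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if fmt == "vrml":
        return _read_vrml(path)
    try:
        tm = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:
        raise MeshFormatError(f"{fmt} parse failure: {exc}", path=path) from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"no geometry in {path}")
        tm = trimesh.util.concatenate(geoms)
    if tm.faces is None or len(tm.faces) == 0:
        raise EmptyMeshError(f"no faces in {path}")
    return TriangleMesh.from_trimesh(tm, name=path.stem)


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = "auto") -> Path:
    """Write a mesh as VRML 2.0 / OBJ / PLY (format from suffix by default)."""
    path = Path(path)
    fmt = _resolve_format(path, fmt)
    if fmt == "vrml":
        _write_vrml(mesh, path)
    else:
        mesh.to_trimesh().export(str(path), file_type=fmt)
    return path


def write_colored_mesh(mesh: TriangleMesh, score: float, colormap: str, path) -> Path:
    """Export a PLY with every vertex painted the colormap color of ``score``.

    This is the file-based analogue of ranking color codes: one spine, one
    score in [0, 1], one color.
    """
    import matplotlib

    if not (0.0 <= score <= 1.0):
        raise ValueError(f"score must be in [0, 1], got {score}")
    cmap = matplotlib.colormaps[colormap]
    rgba = np.array(cmap(float(score)))
    tm = mesh.to_trimesh()
    tm.visual.vertex_colors = np.tile(
        (rgba * 255).round().astype(np.uint8), (len(tm.vertices), 1)
    )
    path = Path(path)
    tm.export(str(path), file_type="ply", encoding="ascii")
    return path


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

def _canonical_column(col: str, aliases: dict[str, str]) -> str:
    key = col.strip().lower()
    # strip unit suffixes such as "(µm³)" or "[um]"
    key = re.sub(r"[\(\[].*?[\)\]]", "", key).strip()
    return aliases.get(key, col.strip())


def read_feature_table(path, aliases: dict[str, str] | None = None) -> FeatureTable:
    """Read a per-spine feature table from CSV.

    Header required; an ``id`` column required.  Unparseable numeric cells
    become flagged-missing values rather than errors; an absent ``region``
    column defaults every record to ``unknown``.
    """
    alias_map = dict(DEFAULT_ALIASES)
    if aliases:
        alias_map.update({k.strip().lower(): v for k, v in aliases.items()})

    df = pd.read_csv(path, dtype=str)
    df.columns = [_canonical_column(c, alias_map) for c in df.columns]
    lower = {c.lower(): c for c in df.columns}
    if "id" not in lower:
        raise SchemaError(f"no id column in {path}; columns: {list(df.columns)}")
    id_col = lower["id"]

    ids = df[id_col].astype(str)
    if ids.duplicated().any():
        raise SchemaError(
            f"duplicate spine ids: {sorted(ids[ids.duplicated()].unique())}"
        )

    meta_lower = {m: lower.get(m) for m in _META_COLUMNS}
    feature_cols = [
        c
        for c in df.columns
        if c not in {v for v in meta_lower.values() if v is not None}
    ]

    def _num(cell) -> float | None:
        if cell is None or (isinstance(cell, float) and np.isnan(cell)):
            return None
        try:
            v = float(cell)
        except (TypeError, ValueError):
            return None
        return v if np.isfinite(v) else None

    records = []
    classes: dict[str, str] = {}
    for _, row in df.iterrows():
        pos = tuple(
            _num(row[meta_lower[a]]) or 0.0 if meta_lower[a] else 0.0
            for a in ("x", "y", "z")
        )
        region = "unknown"
        if meta_lower["region"] and isinstance(row[meta_lower["region"]], str):
            cand = row[meta_lower["region"]].strip()
            if cand in REGIONS:
                region = cand
        feats = {}
        for c in feature_cols:
            v = _num(row[c])
            if v is not None:
                feats[c] = v
        rid = str(row[id_col])
        records.append(SpineRecord(rid, pos, region, feats))
        if meta_lower["spine_class"] and isinstance(row[meta_lower["spine_class"]], str):
            classes[rid] = row[meta_lower["spine_class"]].strip()

    return FeatureTable(records, feature_cols, spine_classes=classes)


def write_feature_table(table: FeatureTable, path) -> Path:
    """Write a feature table as CSV (missing features become empty cells)."""
    path = Path(path)
    table.to_dataframe().to_csv(path, index=False)
    return path


def write_scores(table: FeatureTable, scores, path) -> Path:
    """Write query results: id, region, features, score and rank, rank order.

    ``scores`` is a :class:`~spinekit.cbir.ScoreResult`; only scored spines
    are written, in ranking order.
    """
    path = Path(path)
    missing = [i for i in scores.ranking if i not in set(table.ids)]
    if missing:
        raise SpinekitError(f"scored ids absent from table: {missing}")
    rows = []
    for rank, sid in enumerate(scores.ranking, start=1):
        r = table.record(sid)
        row = {"id": sid, "region": r.region}
        for name in table.feature_names:
            row[name] = r.features.get(name, np.nan)
        row["score"] = scores.scores[sid]
        if scores.raw_scores is not None and sid in scores.raw_scores:
            row["raw_score"] = scores.raw_scores[sid]
        row["rank"] = rank
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")
    return path
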