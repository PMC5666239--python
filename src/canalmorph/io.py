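"""Reading and writing landmark data, specimen metadata, trees and result tables.

Landmark files come in two dialects:

* **CSV (long format)** — columns ``specimen_id, landmark_index, x, y, z`` with
  1-based landmark indices in the file (0-based internally).  Unambiguous and
  diff-friendly.
* **TPS** — classic ``LM3=k`` blocks of whitespace-separated coordinate lines,
  with ``ID=`` records naming each specimen.

Trees are Newick with branch lengths (read through dendropy); metadata is a CSV
with one row per specimen.  Result tables are written as TSV plus a JSON
sidecar carrying seeds and parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

ECOMORPH_LABELS = ("CG", "GB", "TC", "TG", "Tr", "Tw", "unique", "fossil")

METADATA_COLUMNS = (
    "specimen_id",
    "species",
    "island",
    "ecomorph",
    "sex_age_class",
    "skull_length",
    "skull_width",
    "perch_height",
    "perch_diameter",
)


class LandmarkFormatError(ValueError):
    """Malformed landmark file (ragged k, bad coordinate, bad block)."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered set of k 3D landmarks (mm)."""

    specimen_id: str
    coords: np.ndarray  # (k, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(
                f"{self.specimen_id}: coords must be (k, 3), got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")

    @property
    def k(self) -> int:
        return self.coords.shape[0]


@dataclass
class ShapeDataset:
    """Landmark configurations with matching metadata (one row per specimen)."""

    configurations: list[LandmarkConfiguration]
    metadata: pd.DataFrame | None = None
    scheme: object | None = None  # SlidingScheme, optional

    def __post_init__(self) -> None:
        ks = {c.k for c in self.configurations}
        if len(ks) > 1:
            raise LandmarkFormatError(f"inconsistent landmark counts: {sorted(ks)}")
        if self.metadata is not None:
            ids = [c.specimen_id for c in self.configurations]
            meta_ids = list(self.metadata["specimen_id"])
            if sorted(ids) != sorted(meta_ids):
                missing = set(ids) ^ set(meta_ids)
                raise ValueError(
                    f"metadata/configuration specimen ids do not match "
                    f"bijectively; mismatched: {sorted(missing)[:10]}"
                )
            # align metadata rows to configuration order
            self.metadata = (
                self.metadata.set_index("specimen_id").loc[ids].reset_index()
            )

    @property
    def n(self) -> int:
        return len(self.configurations)

    @property
    def k(self) -> int:
        return self.configurations[0].k

    @property
    def ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """Stacked (n, k, 3) coordinate array."""
        return np.stack([c.coords for c in self.configurations])

    def subset(self, ids) -> "ShapeDataset":
        ids = list(ids)
        keep = {i for i in ids}
        configs = [c for c in self.configurations if c.specimen_id in keep]
        order = {sid: j for j, sid in enumerate(ids)}
        configs.sort(key=lambda c: order[c.specimen_id])
        meta = None
        if self.metadata is not None:
            meta = self.metadata[self.metadata["specimen_id"].isin(keep)].copy()
        return ShapeDataset(configs, meta, self.scheme)


def _read_landmarks_csv(path: Path) -> list[LandmarkConfiguration]:
    df = pd.read_csv(path)
    required = {"specimen_id", "landmark_index", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise LandmarkFormatError(
            f"{path}: landmark CSV needs columns {sorted(required)}"
        )
    for col in ("x", "y", "z"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise LandmarkFormatError(
                f"{path}: non-numeric {col!r} value near line {line}"
            )
    configs = []
    for sid, grp in df.groupby("specimen_id", sort=False):
        grp = grp.sort_values("landmark_index")
        idx = grp["landmark_index"].to_numpy()
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise LandmarkFormatError(
                f"{path}: specimen {sid!r} has non-contiguous 1-based "
                f"landmark indices"
            )
        configs.append(
            LandmarkConfiguration(str(sid), grp[["x", "y", "z"]].to_numpy(float))
        )
    return configs


def _read_landmarks_tps(path: Path) -> list[LandmarkConfiguration]:
    configs = []
    k = None
    coords: list[list[float]] = []
    sid = None
    n_block = 0

    def flush(lineno):
        nonlocal coords, sid, k
        if k is None:
            return
        if len(coords) != k:
            raise LandmarkFormatError(
                f"{path}: block ending near line {lineno} has {len(coords)} "
                f"coordinate lines, expected LM3={k}"
            )
        configs.append(
            LandmarkConfiguration(sid or f"specimen_{len(configs) + 1}",
                                  np.asarray(coords))
        )
        coords, sid, k = [], None, None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                if k is not None:
                    flush(lineno)
                n_block += 1
                k = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                sid = line.split("=", 1)[1].strip()
            elif "=" in line and not line[0].isdigit() and line[0] not in "+-.":
                continue  # IMAGE=, SCALE=, ... ignored
            else:
                parts = line.split()
                if len(parts) != 3:
                    raise LandmarkFormatError(
                        f"{path}:{lineno}: expected 3 coordinates, got {line!r}"
                    )
                try:
                    coords.append([float(p) for p in parts])
                except ValueError as exc:
                    raise LandmarkFormatError(
                        f"{path}:{lineno}: non-numeric coordinate in {line!r}"
                    ) from exc
    flush("EOF")
    return configs


def read_landmarks(path, fmt: str | None = None,
                   metadata: pd.DataFrame | None = None) -> ShapeDataset:
    """Read landmark configurations from a CSV (long format) or TPS file."""
    path = Path(path)
    if fmt is None:
        fmt = "tps" if path.suffix.lower() == ".tps" else "csv"
    if fmt == "csv":
        configs = _read_landmarks_csv(path)
    elif fmt == "tps":
        configs = _read_landmarks_tps(path)
    else:
        raise ValueError(f"unknown landmark format {fmt!r}")
    if not configs:
        raise LandmarkFormatError(f"{path}: no specimens found")
    ks = {c.k: c.specimen_id for c in configs}
    if len(ks) > 1:
        raise LandmarkFormatError(
            f"{path}: ragged landmark counts across specimens: "
            + ", ".join(f"{sid}(k={k})" for k, sid in sorted(ks.items()))
        )
    return ShapeDataset(configs, metadata=metadata)


def write_landmarks(dataset: ShapeDataset | list[LandmarkConfiguration],
                    path, fmt: str | None = None) -> None:
    """Write configurations to CSV (long format) or TPS."""
    configs = (dataset.configurations
               if isinstance(dataset, ShapeDataset) else list(dataset))
    path = Path(path)
    if fmt is None:
        fmt = "tps" if path.suffix.lower() == ".tps" else "csv"
    if fmt == "csv":
        rows = []
        for c in configs:
            for i, (x, y, z) in enumerate(c.coords, start=1):
                rows.append((c.specimen_id, i, x, y, z))
        pd.DataFrame(
            rows, columns=["specimen_id", "landmark_index", "x", "y", "z"]
        ).to_csv(path, index=False, float_format="%.17g")
    elif fmt == "tps":
        with open(path, "w") as fh:
            for c in configs:
                fh.write(f"LM3={c.k}\n")
                for x, y, z in c.coords:
                    fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
                fh.write(f"ID={c.specimen_id}\n")
    else:
        raise ValueError(f"unknown landmark format {fmt!r}")


def read_metadata(path) -> pd.DataFrame:
    """Read the specimen metadata CSV; adds derived ``head_proportion``."""
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: metadata missing columns {sorted(missing)}")
    bad = ~df["ecomorph"].isin(ECOMORPH_LABELS) & df["ecomorph"].notna()
    if bad.any():
        raise ValueError(
            f"{path}: ecomorph labels outside {ECOMORPH_LABELS}: "
            f"{sorted(df.loc[bad, 'ecomorph'].unique())}"
        )
    df["specimen_id"] = df["specimen_id"].astype(str)
    return add_head_proportion(df)


def add_head_proportion(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        df["head_proportion"] = df["skull_length"] / df["skull_width"]
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    cols = [c for c in METADATA_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_tree(path_or_string, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted tree with branch lengths; errors if lengths are absent."""
    src = str(path_or_string)
    if src.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=src, schema=schema)
    else:
        tree = dendropy.Tree.get(path=src, schema=schema)
    labels = [t.label for t in tree.taxon_namespace]
    if len(set(labels)) != len(labels):
        raise ValueError("tree tip labels are not unique")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError(
                "tree has edges without branch lengths; comparative methods "
                "require them"
            )
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = tip_depths(tree)
    vals = np.array(list(depths.values()))
    return bool(np.ptp(vals) <= rel_tol * max(vals.max(), 1e-300))


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return {leaf.taxon.label: float(leaf.root_distance)
            for leaf in tree.leaf_node_iter()}


def match_tree_to_data(tree: dendropy.Tree, species: list[str]):
    """Check a bijective species <-> tip match; report mismatches loudly."""
    tips = {t.label for t in tree.taxon_namespace}
    sp = list(species)
    dup = {s for s in sp if sp.count(s) > 1}
    missing_in_tree = sorted(set(sp) - tips)
    missing_in_data = sorted(tips - set(sp))
    if dup or missing_in_tree or missing_in_data:
        raise ValueError(
            "species/tree mismatch: "
            f"duplicated species rows: {sorted(dup)}; "
            f"species absent from tree: {missing_in_tree}; "
            f"tips absent from data: {missing_in_data}"
        )
    return [s for s in sp]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_results(tables: dict, outdir, params: dict | None = None) -> list[Path]:
    """Write result tables: DataFrames as TSV, everything else into JSON.

    A ``results.json`` sidecar always carries ``params`` (seeds, problem
    sizes) plus the non-tabular results, so a run can be reproduced exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    sidecar: dict = {"params": _jsonable(params or {})}
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            p = outdir / f"{name}.tsv"
            obj.to_csv(p, sep="\t", index=False, float_format="%.10g")
            written.append(p)
        else:
            sidecar[name] = _jsonable(obj)
    p = outdir / "results.json"
    with open(p, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    written.append(p)
    return written
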