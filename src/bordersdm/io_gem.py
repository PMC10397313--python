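"""File surfaces: GEM tables, annotation/assignment tables, gene sets, geometry.

The GEM format is the Stereo-seq community convention: tab-separated text
with one record per (gene, x, y, count), where x and y are integer DNB-bin
indices and the count column is named ``MIDCount`` (or ``UMICount`` in some
dialects). Extra columns are tolerated and dropped; duplicate (gene, x, y)
rows are summed on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import wkt as shapely_wkt
from shapely.geometry.base import BaseGeometry

from .config import DISTANT_LABEL, LAYER_LABELS, NONE_LABEL

__all__ = [
    "GemTable",
    "GemFormatError",
    "read_gem",
    "write_gem",
    "read_annotation",
    "write_annotation",
    "read_assignment_table",
    "write_assignment_table",
    "read_gene_sets",
    "write_gene_sets",
    "export_geometry",
]

_COUNT_ALIASES = ("MIDCount", "UMICount", "MIDCounts", "count")
_GENE_ALIASES = ("geneID", "gene", "geneName")

ASSIGNMENT_COLUMNS = ["spot_id", "x_um", "y_um", "layer", "tile", "cell_type"]
_VALID_LAYERS = set(LAYER_LABELS) | {DISTANT_LABEL, NONE_LABEL}


class GemFormatError(ValueError):
    """A GEM (or related table) file violates the expected format."""


@dataclass(frozen=True)
class GemTable:
    """Long-format nanoscale expression records.

    ``frame`` has columns ``gene`` (string), ``x``, ``y`` (non-negative
    integer bin indices) and ``count`` (positive integers); one row per
    unique (gene, x, y).
    """

    frame: pd.DataFrame

    @classmethod
    def from_records(cls, frame: pd.DataFrame) -> "GemTable":
        """Validate and aggregate raw records into a GemTable.

        Stores the gene column as a categorical and coordinates/counts as
        int32 — GEM tables run to tens of millions of records, so compact
        dtypes matter. Duplicate (gene, x, y) rows are summed and the table
        is sorted by (gene, x, y).
        """
        cols = {}
        for col in ("x", "y", "count"):
            numeric = pd.to_numeric(frame[col], errors="coerce")
            if numeric.isna().any() or (numeric != numeric.round()).any():
                raise GemFormatError(f"column {col!r} contains non-integer values")
            cols[col] = numeric.to_numpy(dtype=np.int64)
        if (cols["count"] < 1).any():
            raise GemFormatError("counts must be >= 1")
        if (cols["x"] < 0).any() or (cols["y"] < 0).any():
            raise GemFormatError("bin coordinates must be >= 0")
        gene = frame["gene"]
        if not isinstance(gene.dtype, pd.CategoricalDtype):
            gene = gene.astype(str).astype("category")
        gene = gene.cat.remove_unused_categories()
        codes = gene.cat.codes.to_numpy(dtype=np.int64)
        x, y, count = cols["x"], cols["y"], cols["count"]
        n = len(codes)
        if n == 0:
            empty = pd.DataFrame(
                {"gene": gene, "x": x.astype(np.int32), "y": y.astype(np.int32),
                 "count": count.astype(np.int32)}
            )
            return cls(empty)
        nx, ny = int(x.max()) + 1, int(y.max()) + 1
        n_genes = len(gene.cat.categories)
        if float(n_genes) * nx * ny < 2**62:
            packed = (codes * nx + x) * ny + y
            order = np.argsort(packed, kind="stable")
            sp = packed[order]
            starts = np.concatenate([[0], np.flatnonzero(np.diff(sp)) + 1])
            sums = np.add.reduceat(count[order], starts)
            take = order[starts]
            out = pd.DataFrame(
                {
                    "gene": pd.Categorical.from_codes(
                        codes[take].astype(np.int32), categories=gene.cat.categories
                    ),
                    "x": x[take].astype(np.int32),
                    "y": y[take].astype(np.int32),
                    "count": sums.astype(np.int32),
                }
            )
        else:  # coordinates too large to pack: defer to pandas
            tmp = pd.DataFrame({"gene": gene, "x": x, "y": y, "count": count})
            out = tmp.groupby(["gene", "x", "y"], sort=True, as_index=False, observed=True)[
                "count"
            ].sum()
            out["x"] = out["x"].astype(np.int32)
            out["y"] = out["y"].astype(np.int32)
            out["count"] = out["count"].astype(np.int32)
        return cls(out.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def total_count(self) -> int:
        return int(self.frame["count"].sum())

    @property
    def genes(self) -> list[str]:
        return sorted(self.frame["gene"].astype(str).unique().tolist())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GemTable):
            return NotImplemented
        return self.frame.reset_index(drop=True).equals(other.frame.reset_index(drop=True))


def read_gem(path: str | Path) -> GemTable:
    """Read a GEM table; duplicate (gene, x, y) rows are summed."""
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError as err:
        raise GemFormatError(f"{path}: no header found") from err
    cols = {c.lower(): c for c in raw.columns}
    gene_col = next((cols[a.lower()] for a in _GENE_ALIASES if a.lower() in cols), None)
    count_col = next((cols[a.lower()] for a in _COUNT_ALIASES if a.lower() in cols), None)
    missing = [
        name
        for name, col in (("geneID", gene_col), ("x", cols.get("x")), ("y", cols.get("y")), ("MIDCount", count_col))
        if col is None
    ]
    if missing:
        raise GemFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    frame = pd.DataFrame(
        {
            "gene": raw[gene_col],
            "x": raw[cols["x"]],
            "y": raw[cols["y"]],
            "count": raw[count_col],
        }
    )
    for col in ("x", "y", "count"):
        numeric = pd.to_numeric(frame[col], errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round())
        if bad.any():
            # +2: 1-based line numbers and one header line
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise GemFormatError(f"{path}: non-integer value in column {col!r} at line {line}")
        frame[col] = numeric.astype(np.int64)
    return GemTable.from_records(frame)


def write_gem(gem: GemTable, path: str | Path) -> None:
    out = gem.frame.rename(columns={"gene": "geneID", "count": "MIDCount"})
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Annotation tables: spot_id, x, y (µm), cell_type, optional subtype columns.

def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    cols = ["spot_id", "x_um", "y_um", "cell_type"]
    extra = [c for c in ("subtype", "hep_class") if c in annotation.columns]
    annotation.loc[:, cols + extra].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    required = {"spot_id", "x_um", "y_um", "cell_type"}
    missing = required - set(df.columns)
    if missing:
        raise GemFormatError(f"{path}: missing annotation column(s): {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Assignment tables: one row per spot with its (layer, tile) membership.

def _validate_assignment(assignment: pd.DataFrame) -> pd.DataFrame:
    missing = set(ASSIGNMENT_COLUMNS) - set(assignment.columns)
    if missing:
        raise ValueError(f"assignment table missing column(s): {sorted(missing)}")
    out = assignment.loc[:, ASSIGNMENT_COLUMNS].copy()
    out["layer"] = out["layer"].astype(str)
    bad_layers = set(out["layer"]) - _VALID_LAYERS
    if bad_layers:
        raise ValueError(f"invalid layer label(s): {sorted(bad_layers)}")
    tiles = out["tile"].astype(str)
    in_layer = out["layer"].isin(LAYER_LABELS)
    numeric = pd.to_numeric(tiles.where(tiles != NONE_LABEL), errors="coerce")
    if in_layer.any():
        vals = numeric[in_layer]
        if vals.isna().any() or (vals < 1).any():
            raise ValueError("tiles of layer spots must be integers >= 1")
    if ((~in_layer) & tiles.ne(NONE_LABEL)).any():
        raise ValueError("spots outside the six layers must have tile 'none'")
    out["tile"] = tiles
    return out


def write_assignment_table(assignment: pd.DataFrame, path: str | Path) -> None:
    """Write spot → (layer, tile) assignments as TSV with a stable column order."""
    _validate_assignment(assignment).to_csv(path, sep="\t", index=False)


def read_assignment_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"layer": str, "tile": str})
    return _validate_assignment(df)


# ---------------------------------------------------------------------------
# Gene sets / marker panels: two-column TSV (set_name, gene_id).

def read_gene_sets(path: str | Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["set_name", "gene_id"]:
        raise GemFormatError(f"{path}: expected columns set_name, gene_id")
    sets: dict[str, list[str]] = {}
    for name, sub in df.groupby("set_name", sort=False):
        sets[str(name)] = sub["gene_id"].tolist()
    return sets


def write_gene_sets(sets: dict[str, list[str]], path: str | Path) -> None:
    rows = [(name, g) for name, genes in sets.items() for g in genes]
    pd.DataFrame(rows, columns=["set_name", "gene_id"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Geometry export: WKT text plus a JSON manifest.

def export_geometry(
    out_dir: str | Path,
    border: BaseGeometry | None = None,
    layers: dict[str, BaseGeometry] | None = None,
    tiles: pd.DataFrame | None = None,
    manifest: dict | None = None,
) -> None:
    """Write border/layer/tile geometries as WKT files with a manifest.

    ``tiles`` is a frame with columns layer, tile and a ``polygon`` column of
    shapely geometries.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    if border is not None:
        (out_dir / "border.wkt").write_text(border.wkt + "\n")
        written["border"] = "border.wkt"
    if layers is not None:
        lines = [f"{name}\t{geom.wkt}" for name, geom in layers.items()]
        (out_dir / "layers.wkt.tsv").write_text("\n".join(lines) + "\n")
        written["layers"] = "layers.wkt.tsv"
    if tiles is not None:
        lines = [
            f"{row.layer}\t{row.tile}\t{row.polygon.wkt}" for row in tiles.itertuples()
        ]
        (out_dir / "tiles.wkt.tsv").write_text("\n".join(lines) + "\n")
        written["tiles"] = "tiles.wkt.tsv"
    meta = dict(manifest or {})
    meta["files"] = written
    (out_dir / "geometry.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_wkt(path: str | Path) -> BaseGeometry:
    return shapely_wkt.loads(Path(path).read_text().strip())
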