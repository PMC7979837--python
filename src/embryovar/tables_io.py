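"""CSV schemas and run configuration.

The pipeline exchanges five plain-text tables:

* **spots CSV** — one row per detected point object (a membrane spot or a
  single-mRNA spot): ``spot_id,kind,gene,x_um,y_um,z_um,intensity,cell_id``.
  Coordinates are continuous physical micrometres; any voxel-to-physical
  conversion is the caller's responsibility.  ``cell_id`` is an opaque string
  label (segmentation software exports arbitrary labels, never assume an
  integer index); an empty field means *unassigned*.
* **counts CSV** — one row per cell:
  ``cell_id,centroid_x_um,centroid_y_um,centroid_z_um,<gene1>,<gene2>,...``
* **adjacency CSV** — one unordered cell pair per row: ``cell_a,cell_b``,
  lexicographically sorted within each row and across rows.
* **scores CSV** — per (cell, gene) variability statistics:
  ``cell_id,gene,fano,nv,pv_raw,pv_filtered,n_neighbours``.
* **config** — a flat key/value YAML file, see :class:`RunConfig`.

All files are comma-separated UTF-8 with a mandatory header row and ``.`` as
the decimal mark; scientific notation is accepted on input.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SchemaError",
    "TableParseError",
    "ConfigError",
    "ConsistencyError",
    "SpotRecord",
    "ExpressionTable",
    "RunConfig",
    "read_spot_table",
    "write_spot_table",
    "read_counts_table",
    "write_counts_table",
    "read_adjacency_table",
    "write_adjacency_table",
    "write_scores_table",
    "read_scores_table",
    "write_outputs",
    "load_config",
    "effective_expansion_um",
]


class SchemaError(ValueError):
    """A required column is missing or a column has the wrong role."""


class TableParseError(ValueError):
    """A cell of the table could not be parsed; message names the row."""


class ConfigError(ValueError):
    """Invalid or conflicting run-configuration keys."""


class ConsistencyError(ValueError):
    """Objects that must share a cell-ID universe do not."""


SPOT_KINDS = ("membrane", "mrna")

#: canonical column order of the spots CSV
SPOT_COLUMNS = ("spot_id", "kind", "gene", "x_um", "y_um", "z_um", "intensity", "cell_id")

CENTROID_COLUMNS = ("centroid_x_um", "centroid_y_um", "centroid_z_um")

SCORE_COLUMNS = ("cell_id", "gene", "fano", "nv", "pv_raw", "pv_filtered", "n_neighbours")


@dataclass(slots=True)
class SpotRecord:
    """A single detected point object (membrane spot or single mRNA).

    Unknown CSV columns encountered on read are carried in ``extra`` and
    written back verbatim, so third-party metadata survives a round trip.
    """

    spot_id: str
    kind: str
    x_um: float
    y_um: float
    z_um: float
    gene: str = ""
    intensity: float | None = None
    cell_id: str = ""
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.kind not in SPOT_KINDS:
            raise ValueError(f"spot {self.spot_id!r}: unknown kind {self.kind!r}")
        for name in ("x_um", "y_um", "z_um"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"spot {self.spot_id!r}: non-finite {name}")
        if self.intensity is not None and self.intensity < 0:
            raise ValueError(f"spot {self.spot_id!r}: negative intensity")
        if self.kind == "membrane" and self.gene:
            raise ValueError(f"spot {self.spot_id!r}: membrane spot with gene label")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x_um, self.y_um, self.z_um], dtype=float)


@dataclass
class ExpressionTable:
    """Per-cell, per-gene integer mRNA counts plus cell centroids.

    ``counts`` is a DataFrame indexed by cell_id with one integer column per
    gene; ``centroids`` is a DataFrame on the same index with columns
    ``centroid_x_um, centroid_y_um, centroid_z_um``.
    """

    counts: pd.DataFrame
    centroids: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts.index = self.counts.index.astype(str)
        self.centroids.index = self.centroids.index.astype(str)
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ConsistencyError(f"duplicate cell_ids in counts: {dup[:5]}")
        if not self.counts.index.equals(self.centroids.index):
            raise ConsistencyError("counts and centroids must share one cell per row")
        arr = self.counts.to_numpy()
        if arr.size and (np.any(arr < 0) or not np.allclose(arr, np.round(arr))):
            raise ValueError("counts must be nonnegative integers")
        self.counts = self.counts.astype(int)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genes(self) -> list[str]:
        return list(self.counts.columns)

    def centroid_array(self) -> np.ndarray:
        return self.centroids[list(CENTROID_COLUMNS)].to_numpy(dtype=float)


@dataclass
class RunConfig:
    """Analysis parameters with their pipeline defaults.

    expansion_um
        Polygon expansion radius *r* for contact-neighbour detection
        (default 0.6 μm, roughly 10% of a blastoderm cell diameter).
    expansion_fraction
        Alternative to ``expansion_um``: a fraction of the median cell
        diameter (e.g. 0.1).  Exactly one of the two may be set explicitly.
    radius_um
        Search radius *R* for the centroid-distance neighbour alternative.
    pv_group_mean_threshold
        Neighbour-group mean mRNA count below which the filtered PV score is
        zeroed (default 1, inclusive).
    histogram_bin_width
        Width of the per-cell count-histogram bins (default 5).
    """

    expansion_um: float = 0.6
    expansion_fraction: float | None = None
    radius_um: float | None = None
    pv_group_mean_threshold: float = 1.0
    histogram_bin_width: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expansion_fraction is None and not self.expansion_um > 0:
            raise ConfigError("expansion_um must be > 0")
        if self.expansion_fraction is not None and not self.expansion_fraction > 0:
            raise ConfigError("expansion_fraction must be > 0")
        if self.radius_um is not None and self.radius_um < 0:
            raise ConfigError("radius_um must be >= 0")
        if not math.isfinite(self.pv_group_mean_threshold) or self.pv_group_mean_threshold < 0:
            raise ConfigError("pv_group_mean_threshold must be finite and >= 0")
        if int(self.histogram_bin_width) < 1:
            raise ConfigError("histogram_bin_width must be >= 1")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


_CONFIG_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path | None) -> RunConfig:
    """Load a :class:`RunConfig` from a flat key/value YAML file.

    Absent keys take their defaults; setting both ``expansion_um`` and
    ``expansion_fraction`` is a conflict error because only one expansion
    rule can be active.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config file {path} is not a key-value mapping")
    unknown = sorted(set(raw) - _CONFIG_KEYS)
    if unknown:
        raise ConfigError(f"unknown config keys: {unknown}")
    if "expansion_um" in raw and "expansion_fraction" in raw:
        raise ConfigError(
            "conflicting keys: set either expansion_um or expansion_fraction, not both"
        )
    return RunConfig(**raw)


def effective_expansion_um(config: RunConfig, median_cell_diameter_um: float | None = None) -> float:
    """Resolve the active expansion rule to a radius in μm.

    When ``expansion_fraction`` is set the radius is
    ``fraction × median cell diameter`` (the fraction-of-a-cell-diameter
    reading of the fixed 0.6 μm default).
    """
    if config.expansion_fraction is None:
        return float(config.expansion_um)
    if median_cell_diameter_um is None or not median_cell_diameter_um > 0:
        raise ConfigError("expansion_fraction requires a positive median cell diameter")
    return float(config.expansion_fraction) * float(median_cell_diameter_um)


# ---------------------------------------------------------------------------
# spots CSV


def _numeric_column(df: pd.DataFrame, col: str, path, required: bool) -> np.ndarray:
    """Parse one column to float, naming the first offending row on failure."""
    raw = df[col].str.strip()
    vals = pd.to_numeric(raw.replace("", "nan"), errors="coerce")
    bad = vals.isna() & (raw != "")
    if required:
        bad |= raw == ""
        bad |= ~np.isfinite(vals.fillna(0.0)) & (raw != "")
    if bad.any():
        # +2: one for the header row, one for 0-based indexing
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise TableParseError(f"{path}: non-numeric value in column {col!r} at row {row}")
    # reparse through numpy for exact (round-trippable) float conversion
    return raw.replace("", "nan").to_numpy(dtype=np.float64)


def read_spot_table(path: str | Path, kind: str) -> list[SpotRecord]:
    """Read a spots CSV, returning validated :class:`SpotRecord` objects.

    ``kind`` selects the expected spot kind; if the file carries a ``kind``
    column, only matching rows are returned (a single export may mix
    membrane and mRNA spots).  Unknown columns are preserved per record.
    """
    if kind not in SPOT_KINDS:
        raise ValueError(f"kind must be one of {SPOT_KINDS}")
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["spot_id", "x_um", "y_um", "z_um"]
    if kind == "mrna":
        required.append("gene")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if "kind" in df.columns:
        df = df[df["kind"].str.strip().isin(["", kind])].reset_index(drop=True)
    xs = _numeric_column(df, "x_um", path, required=True)
    ys = _numeric_column(df, "y_um", path, required=True)
    zs = _numeric_column(df, "z_um", path, required=True)
    if "intensity" in df.columns:
        inten = _numeric_column(df, "intensity", path, required=False)
    else:
        inten = np.full(len(df), np.nan)
    genes = df["gene"].str.strip() if "gene" in df.columns else pd.Series([""] * len(df))
    cells = df["cell_id"].str.strip() if "cell_id" in df.columns else pd.Series([""] * len(df))
    extra_cols = [c for c in df.columns if c not in SPOT_COLUMNS]
    records: list[SpotRecord] = []
    for i in range(len(df)):
        rec = SpotRecord(
            spot_id=df["spot_id"].iloc[i].strip(),
            kind=kind,
            x_um=float(xs[i]),
            y_um=float(ys[i]),
            z_um=float(zs[i]),
            gene=str(genes.iloc[i]),
            intensity=None if np.isnan(inten[i]) else float(inten[i]),
            cell_id=str(cells.iloc[i]),
            extra={c: df[c].iloc[i] for c in extra_cols} if extra_cols else {},
        )
        rec.validate()
        records.append(rec)
    return records


def write_spot_table(records: Sequence[SpotRecord], path: str | Path) -> Path:
    """Write spots to CSV in the canonical column order (extras appended)."""
    path = Path(path)
    extra_keys = sorted({k for r in records for k in r.extra})
    # floats are serialised with repr (shortest round-trip form) so that a
    # write/read cycle is the exact identity
    rows = {
        "spot_id": [r.spot_id for r in records],
        "kind": [r.kind for r in records],
        "gene": [r.gene for r in records],
        "x_um": [repr(float(r.x_um)) for r in records],
        "y_um": [repr(float(r.y_um)) for r in records],
        "z_um": [repr(float(r.z_um)) for r in records],
        "intensity": ["" if r.intensity is None else repr(float(r.intensity)) for r in records],
        "cell_id": [r.cell_id for r in records],
    }
    for k in extra_keys:
        rows[k] = [r.extra.get(k, "") for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# counts / adjacency / scores CSVs


def write_counts_table(expr: ExpressionTable, path: str | Path) -> Path:
    path = Path(path)
    out = pd.concat([expr.centroids[list(CENTROID_COLUMNS)], expr.counts], axis=1)
    out.index.name = "cell_id"
    out.to_csv(path)
    return path


def read_counts_table(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, dtype={"cell_id": str}).set_index("cell_id")
    missing = [c for c in CENTROID_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    gene_cols = [c for c in df.columns if c not in CENTROID_COLUMNS]
    return ExpressionTable(counts=df[gene_cols], centroids=df[list(CENTROID_COLUMNS)])


def write_adjacency_table(edges: Iterable[tuple[str, str]], path: str | Path) -> Path:
    """Write an edge list: each unordered pair once, sorted within and across rows."""
    path = Path(path)
    pairs = sorted({tuple(sorted((str(a), str(b)))) for a, b in edges})
    pd.DataFrame(pairs, columns=["cell_a", "cell_b"]).to_csv(path, index=False)
    return path


def read_adjacency_table(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("cell_a", "cell_b") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return [tuple(sorted((a, b))) for a, b in zip(df["cell_a"], df["cell_b"])]


def write_scores_table(scores, path: str | Path) -> Path:
    """Write the per-(cell, gene) variability scores CSV."""
    path = Path(path)
    frame = scores.frame if hasattr(scores, "frame") else scores
    frame[list(SCORE_COLUMNS)].to_csv(path, index=False)
    return path


def read_scores_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"cell_id": str, "gene": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def write_outputs(expr: ExpressionTable, graph, scores, outdir: str | Path) -> dict[str, Path]:
    """Write counts, adjacency and scores CSVs; all three objects must agree
    on the cell-ID universe.  Returns a name → path manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table_cells = set(expr.cell_ids)
    graph_cells = set(graph.cells)
    frame = scores.frame if hasattr(scores, "frame") else scores
    score_cells = set(frame["cell_id"].astype(str))
    if table_cells != graph_cells or (score_cells and score_cells != table_cells):
        offenders = sorted(
            (table_cells ^ graph_cells) | (score_cells ^ table_cells if score_cells else set())
        )
        raise ConsistencyError(f"cell-ID universes differ; offending ids: {offenders[:10]}")
    manifest = {
        "counts": write_counts_table(expr, outdir / "counts.csv"),
        "adjacency": write_adjacency_table(graph.sorted_edges(), outdir / "adjacency.csv"),
        "scores": write_scores_table(scores, outdir / "scores.csv"),
    }
    return manifest
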