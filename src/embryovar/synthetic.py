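"""Synthetic cellular-blastoderm embryos for end-to-end pipeline testing.

The generator emulates the data a segmentation/spot-detection export
produces for a blastoderm-stage embryo, at the level the pipeline actually
consumes — detected spots with coordinates, never images:

* a columnar **monolayer** of ~2000 hexagonal-prism cells (centre spacing =
  one cell diameter, default 6 μm) spanning a 9.6 μm apical–basal depth,
  laid out on a jitterable hexagonal lattice over a rectangular (optionally
  ellipse-masked) sheet.  The anterior–posterior (AP) axis maps to lattice
  x, normalised to [0, 1];
* ground-truth **adjacency**: lattice cells sharing a hexagon edge.
  Interior cells have exactly six true neighbours;
* per-gene **expression profiles** along AP — periodic stripes
  (pair-rule-like, default seven), a broad logistic-edged domain
  (gap-gene-like), a monotone gradient, uniform, or off — with graded
  rather than sharp borders;
* integer per-cell **counts** drawn from Poisson or overdispersed
  negative-binomial noise around the profile mean;
* **membrane spots** on each prism's lateral faces and apical rim (corner
  vertices always included so a zero-jitter cloud reconstructs the exact
  prism), displaced by isotropic Gaussian jitter;
* **mRNA spots** placed uniformly inside the generating cell's prism,
  optionally inset from the faces so boundary ambiguity cannot arise; the
  generating cell is recorded in ``extra["true_cell_id"]`` while ``cell_id``
  is left blank for the pipeline to fill.

Everything is deterministic under a fixed seed; one embryo seed fans out to
per-stage seeds by fixed offsets so stages can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.special import expit

from .geometry import NeighbourGraph
from .tables_io import ExpressionTable, SpotRecord

__all__ = [
    "PatternSpec",
    "SimParams",
    "LatticeCell",
    "SyntheticEmbryo",
    "default_gene_panel",
    "generate_lattice",
    "expression_profile",
    "sample_counts",
    "sample_membrane_spots",
    "sample_mrna_spots",
    "generate_embryo",
    "thin_two_channels",
]

_SQRT3 = np.sqrt(3.0)


@dataclass(slots=True)
class PatternSpec:
    """An AP expression profile for one gene.

    profile ∈ {stripes, broad_domain, gradient, uniform, off}.  Stripe
    centres are evenly spaced on [stripe_lo, stripe_hi]; ``stripe_sigma``
    is the Gaussian stripe half-width in AP units.  Broad domains are
    logistic-edged plateaus centred at ``centre`` with width ``width`` and
    edge softness ``edge_softness``; gradients decay exponentially with
    length scale ``decay``.  ``peak_mean_count`` sets the profile maximum
    in mRNA per cell.
    """

    gene: str
    profile: str = "uniform"
    peak_mean_count: float = 50.0
    n_stripes: int = 7
    stripe_lo: float = 0.25
    stripe_hi: float = 0.90
    stripe_sigma: float = 0.022
    centre: float = 0.5
    width: float = 0.25
    edge_softness: float = 0.03
    decay: float = 0.35

    def __post_init__(self) -> None:
        if self.peak_mean_count < 0:
            raise ValueError("peak_mean_count must be >= 0")
        if self.n_stripes < 1:
            raise ValueError("n_stripes must be >= 1")
        if self.profile not in {"stripes", "broad_domain", "gradient", "uniform", "off"}:
            raise ValueError(f"unknown profile {self.profile!r}")


def default_gene_panel() -> list[PatternSpec]:
    """Five-gene blastoderm panel: a seven-stripe pair-rule-like pattern and
    four gap-gene-like domains/gradients, with peak levels of order 10²
    mRNA per cell as seen for strongly expressed segmentation genes."""
    return [
        PatternSpec("eve", "stripes", peak_mean_count=80.0),
        PatternSpec("Kr", "broad_domain", peak_mean_count=120.0, centre=0.50, width=0.20),
        PatternSpec("hb", "gradient", peak_mean_count=100.0, decay=0.30),
        PatternSpec("kni", "broad_domain", peak_mean_count=60.0, centre=0.70, width=0.15),
        PatternSpec("gt", "broad_domain", peak_mean_count=50.0, centre=0.85, width=0.12),
    ]


@dataclass
class SimParams:
    """Simulation parameters; defaults pinned to the blastoderm data scale
    (~2000 cells, ~40 membrane spots per cell ≈ 80,000 total, 9.6 μm depth,
    6 μm columnar cells)."""

    n_cells_target: int = 2000
    cell_diameter_um: float = 6.0
    depth_um: float = 9.6
    aspect: float = 3.0  # AP length : DV width of the sheet
    ellipse_mask: bool = False
    lattice_jitter_um: float = 0.0
    membrane_spots_per_cell: int = 40
    membrane_jitter_um: float = 0.1
    mrna_inset_um: float = 0.1
    genes: list[PatternSpec] = field(default_factory=default_gene_panel)
    count_noise: str = "negative_binomial"
    nb_fano: float = 3.0  # variance/mean of the negative-binomial noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_target < 7:
            raise ValueError("n_cells_target must be >= 7")
        for name in ("cell_diameter_um", "depth_um", "aspect"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        if self.lattice_jitter_um < 0 or self.membrane_jitter_um < 0:
            raise ValueError("jitter must be >= 0")
        if self.membrane_jitter_um >= self.cell_diameter_um / 2:
            raise ValueError("membrane_jitter_um must be < cell_diameter_um / 2")
        if self.membrane_spots_per_cell < 12:
            raise ValueError("need >= 12 membrane spots per cell (prism corners)")
        if self.count_noise not in {"poisson", "negative_binomial"}:
            raise ValueError(f"unknown count_noise {self.count_noise!r}")
        if self.count_noise == "negative_binomial" and not self.nb_fano > 1:
            raise ValueError("nb_fano must be > 1 for negative-binomial noise")


@dataclass(slots=True)
class LatticeCell:
    """One prism cell: hexagonal footprint vertices (6, 2) in μm around
    ``centre``, extruded from z=0 (apical) to z=depth (basal)."""

    cell_id: str
    row: int
    col: int
    centre: np.ndarray  # (2,)
    footprint: np.ndarray  # (6, 2) vertices, counter-clockwise
    z0: float
    z1: float
    ap: float  # normalised AP position in [0, 1]

    @property
    def centroid(self) -> np.ndarray:
        return np.array([self.centre[0], self.centre[1], 0.5 * (self.z0 + self.z1)])

    def prism_volume_um3(self, spacing: float) -> float:
        return float(_SQRT3 / 2.0 * spacing**2 * (self.z1 - self.z0))


@dataclass
class SyntheticEmbryo:
    cells: list[LatticeCell]
    true_adjacency: NeighbourGraph
    true_counts: ExpressionTable
    membrane_spots: list[SpotRecord]
    mrna_spots: list[SpotRecord]
    params: SimParams

    @property
    def cell_ids(self) -> list[str]:
        return [c.cell_id for c in self.cells]


def _hex_vertices(spacing: float) -> np.ndarray:
    """Vertices of the tiling hexagon (circumradius s/√3, vertex at 30°)."""
    r = spacing / _SQRT3
    ang = np.deg2rad(30.0 + 60.0 * np.arange(6))
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


#: unit normals of the three hexagon axis pairs (|n·p| <= apothem inside)
_HEX_NORMALS = np.array(
    [[np.cos(a), np.sin(a)] for a in np.deg2rad([0.0, 60.0, 120.0])]
)


def generate_lattice(params: SimParams, seed: int | None = None):
    """Lay out the cell monolayer and its ground-truth adjacency.

    Cells sit on a hexagonal lattice (row offset s/2, row spacing s·√3/2)
    cropped to a rectangle of the requested aspect ratio, optionally masked
    to the inscribed ellipse.  True neighbours are lattice pairs one centre
    spacing apart, i.e. exactly the hexagon-edge-sharing pairs.  Because the
    sheet is cropped to a whole rows × cols rectangle the realised cell
    number approximates ``n_cells_target``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    s = params.cell_diameter_um
    rows = max(3, round(np.sqrt(params.n_cells_target / params.aspect)))
    cols = max(3, round(params.n_cells_target / rows))
    centres, rc = [], []
    for r in range(rows):
        y = r * s * _SQRT3 / 2.0
        off = (r % 2) * s / 2.0
        for c in range(cols):
            centres.append((c * s + off, y))
            rc.append((r, c))
    centres = np.asarray(centres)
    if params.ellipse_mask:
        mid = (centres.max(axis=0) + centres.min(axis=0)) / 2.0
        half = (centres.max(axis=0) - centres.min(axis=0)) / 2.0 + s / 2.0
        keep = (((centres - mid) / half) ** 2).sum(axis=1) <= 1.0
        centres, rc = centres[keep], [p for p, k in zip(rc, keep) if k]
    if len(centres) < 7:
        raise ValueError("lattice too small after masking")
    jitter = (
        rng.normal(0.0, params.lattice_jitter_um, centres.shape)
        if params.lattice_jitter_um > 0
        else np.zeros_like(centres)
    )
    xmin, xmax = centres[:, 0].min(), centres[:, 0].max()
    span = max(xmax - xmin, 1e-12)
    hexv = _hex_vertices(s)
    cells = [
        LatticeCell(
            cell_id=f"c{k:04d}",
            row=rc[k][0],
            col=rc[k][1],
            centre=centres[k] + jitter[k],
            footprint=hexv + centres[k] + jitter[k],
            z0=0.0,
            z1=params.depth_um,
            ap=float((centres[k, 0] - xmin) / span),
        )
        for k in range(len(centres))
    ]
    pairs = cKDTree(centres).query_pairs(r=1.05 * s, output_type="ndarray")
    edges = [(cells[i].cell_id, cells[j].cell_id) for i, j in pairs]
    graph = NeighbourGraph.from_edges(
        [c.cell_id for c in cells], edges, method="lattice", parameter_um=s
    )
    return cells, graph


def expression_profile(spec: PatternSpec, ap_position) -> np.ndarray | float:
    """Mean mRNA count of ``spec`` at normalised AP position(s) in [0, 1]."""
    scalar = np.ndim(ap_position) == 0
    ap = np.atleast_1d(np.asarray(ap_position, dtype=float))
    if np.any((ap < 0) | (ap > 1)):
        raise ValueError("ap_position must lie in [0, 1]")
    if spec.profile == "off":
        out = np.zeros_like(ap)
    elif spec.profile == "uniform":
        out = np.full_like(ap, spec.peak_mean_count)
    elif spec.profile == "stripes":
        centres = np.linspace(spec.stripe_lo, spec.stripe_hi, spec.n_stripes)
        bumps = np.exp(-((ap[..., None] - centres) ** 2) / (2.0 * spec.stripe_sigma**2))
        out = spec.peak_mean_count * bumps.sum(axis=-1)
    elif spec.profile == "broad_domain":
        lo, hi = spec.centre - spec.width / 2.0, spec.centre + spec.width / 2.0
        out = spec.peak_mean_count * expit((ap - lo) / spec.edge_softness) * expit(
            (hi - ap) / spec.edge_softness
        )
    else:  # gradient
        out = spec.peak_mean_count * np.exp(-ap / spec.decay)
    return float(out[0]) if scalar else out


def sample_counts(
    cells: Sequence[LatticeCell],
    specs: Sequence[PatternSpec],
    params: SimParams,
    seed: int,
) -> ExpressionTable:
    """Draw per-cell, per-gene integer counts around the profile means.

    Poisson noise gives Fano ≈ 1; negative-binomial noise is parameterised
    by its variance/mean ratio ``params.nb_fano`` (shape k = μ/(f−1)), so a
    setting of 3 yields counts with variance three times the mean.
    """
    rng = np.random.default_rng(seed)
    ap = np.array([c.ap for c in cells])
    ids = pd.Index([c.cell_id for c in cells], name="cell_id")
    counts = {}
    for spec in specs:
        mu = np.asarray(expression_profile(spec, ap), dtype=float)
        x = np.zeros(len(ap), dtype=int)
        pos = mu > 0
        if params.count_noise == "poisson":
            x[pos] = rng.poisson(mu[pos])
        else:
            k = mu[pos] / (params.nb_fano - 1.0)
            x[pos] = rng.negative_binomial(k, k / (k + mu[pos]))
        counts[spec.gene] = x
    centroids = pd.DataFrame(
        np.array([c.centroid for c in cells]),
        index=ids,
        columns=["centroid_x_um", "centroid_y_um", "centroid_z_um"],
    )
    return ExpressionTable(counts=pd.DataFrame(counts, index=ids), centroids=centroids)


def sample_membrane_spots(
    cells: Sequence[LatticeCell], params: SimParams, seed: int
) -> list[SpotRecord]:
    """Membrane-spot clouds: the 12 prism corners plus random points on the
    lateral faces and apical rim, all under isotropic Gaussian jitter."""
    rng = np.random.default_rng(seed)
    m = params.membrane_spots_per_cell
    n_rim = max(0, round(0.15 * (m - 12)))
    n_lat = m - 12 - n_rim
    records: list[SpotRecord] = []
    sid = 0
    for cell in cells:
        v = cell.footprint
        pts = []
        for z in (cell.z0, cell.z1):
            pts.append(np.column_stack([v, np.full(6, z)]))
        edge_i = rng.integers(0, 6, n_lat + n_rim)
        t = rng.random(n_lat + n_rim)[:, None]
        base = v[edge_i] + t * (v[(edge_i + 1) % 6] - v[edge_i])
        z_lat = rng.uniform(cell.z0, cell.z1, n_lat)
        z_rim = np.full(n_rim, cell.z0)
        pts.append(np.column_stack([base, np.concatenate([z_lat, z_rim])]))
        xyz = np.vstack(pts)
        if params.membrane_jitter_um > 0:
            xyz = xyz + rng.normal(0.0, params.membrane_jitter_um, xyz.shape)
        for p in xyz:
            records.append(
                SpotRecord(
                    spot_id=f"m{sid:06d}", kind="membrane",
                    x_um=float(p[0]), y_um=float(p[1]), z_um=float(p[2]),
                    cell_id=cell.cell_id,
                )
            )
            sid += 1
    return records


def _sample_in_hexagon(rng, n: int, apothem: float) -> np.ndarray:
    """Uniform points in a regular hexagon of the given apothem (vertex at 30°)."""
    out = np.empty((0, 2))
    circ = 2.0 * apothem / _SQRT3
    while len(out) < n:
        cand = rng.uniform(-circ, circ, (max(16, int(2.2 * (n - len(out)))), 2))
        inside = np.abs(cand @ _HEX_NORMALS.T).max(axis=1) <= apothem
        out = np.vstack([out, cand[inside]])
    return out[:n]


def sample_mrna_spots(
    cells: Sequence[LatticeCell],
    true_counts: ExpressionTable,
    params: SimParams,
    seed: int,
) -> list[SpotRecord]:
    """Place exactly ``count`` mRNA spots uniformly inside each cell prism.

    Spots are inset ``params.mrna_inset_um`` from every face so that none
    sits on a shared boundary.  ``cell_id`` is left unassigned (the pipeline
    fills it); the generating cell is recorded in ``extra['true_cell_id']``.
    Spot intensities are lognormal around 1, mimicking single-molecule
    brightness variation.
    """
    rng = np.random.default_rng(seed)
    apothem = params.cell_diameter_um / 2.0 - params.mrna_inset_um
    if apothem <= 0:
        raise ValueError("mrna_inset_um too large for the cell diameter")
    records: list[SpotRecord] = []
    sid = 0
    counts = true_counts.counts
    for cell in cells:
        row = counts.loc[cell.cell_id]
        for gene in counts.columns:
            n = int(row[gene])
            if n == 0:
                continue
            xy = _sample_in_hexagon(rng, n, apothem) + cell.centre
            z = rng.uniform(cell.z0 + params.mrna_inset_um, cell.z1 - params.mrna_inset_um, n)
            inten = rng.lognormal(0.0, 0.25, n)
            for k in range(n):
                records.append(
                    SpotRecord(
                        spot_id=f"r{sid:07d}", kind="mrna", gene=gene,
                        x_um=float(xy[k, 0]), y_um=float(xy[k, 1]), z_um=float(z[k]),
                        intensity=float(inten[k]),
                        extra={"true_cell_id": cell.cell_id},
                    )
                )
                sid += 1
    return records


def generate_embryo(params: SimParams | None = None) -> SyntheticEmbryo:
    """Generate a complete synthetic embryo from one seed.

    Stage seeds are fixed offsets of ``params.seed`` (lattice +0, counts +1,
    membrane +2, mRNA +3) so each stage is reproducible in isolation.
    """
    params = params or SimParams()
    cells, adjacency = generate_lattice(params, seed=params.seed)
    true_counts = sample_counts(cells, params.genes, params, seed=params.seed + 1)
    membrane = sample_membrane_spots(cells, params, seed=params.seed + 2)
    mrna = sample_mrna_spots(cells, true_counts, params, seed=params.seed + 3)
    return SyntheticEmbryo(
        cells=cells,
        true_adjacency=adjacency,
        true_counts=true_counts,
        membrane_spots=membrane,
        mrna_spots=mrna,
        params=params,
    )


def thin_two_channels(
    expr: ExpressionTable, p: float = 0.5, seed: int = 0
) -> tuple[ExpressionTable, ExpressionTable]:
    """Split counts into two channels by independent binomial thinning.

    Emulates interleaved probe sets against the same transcripts imaged in
    two colours: each channel independently detects each molecule with
    probability ``p``.
    """
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    rng = np.random.default_rng(seed)
    x = expr.counts.to_numpy()
    a = rng.binomial(x, p)
    b = rng.binomial(x, p)
    mk = lambda arr: ExpressionTable(
        counts=pd.DataFrame(arr, index=expr.counts.index, columns=expr.counts.columns),
        centroids=expr.centroids.copy(),
    )
    return mk(a), mk(b)
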