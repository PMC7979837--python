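"""Local single-cell expression-variability statistics.

Three per-cell measures are computed over *neighbour groups* — a focal cell
together with its immediate neighbours from the contact graph:

**Fano factor** ``F = Var(group) / Mean(group)``.  Variance and mean are
population measures of the whole group, so the statistic describes the
group, not the focal cell: it acts as a moving-window variability and
highlights regions (e.g. the graded edges of expression domains) where the
mRNA number changes most with position, but cannot single out one variable
cell inside its group.  The population (divide-by-n) variance is used by
default; the sample variance is available as an option.

**NV — numerical variability** of the focal cell *i* with counts
``x_j`` over its k neighbours:

    NV_i = (1/k) Σ_j |x_i − x_j|  /  X_max

where ``X_max`` is the maximum mRNA count per cell over the whole analysed
cell population for that gene.  NV is large only when the focal cell's
difference from its neighbours is numerically large relative to the level
the gene can reach, and is unchanged when a constant is added to the focal
cell and all its neighbours.

**PV — proportional variability** uses the same mean absolute difference
but normalises by the maximum count within the neighbour group itself
(focal cell included):

    PV_i = (1/k) Σ_j |x_i − x_j|  /  max(x_i, x_j ...)

A cell carrying a single transcript surrounded by non-expressing
neighbours scores the maximum PV of 1 even though the numerical difference
is tiny.  Both NV and PV live in [0, 1]: 0 means no variability, 1 maximal.

To focus PV on cells inside actual expression domains, a filter zeroes the
PV of any cell whose neighbour-group mean count falls below a threshold
(default 1 mRNA, inclusive); the raw value is kept alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations_with_replacement
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import NeighbourGraph
from .tables_io import ConsistencyError, ExpressionTable

__all__ = [
    "VariabilityScores",
    "fano_factor",
    "numerical_variability",
    "proportional_variability",
    "apply_pv_filter",
    "score_embryo",
    "count_histogram",
    "nascent_ratio",
    "channel_concordance",
    "nv_pv_extrema",
]


def _as_counts(values: Iterable[float], what: str = "counts") -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if arr.size and (np.any(arr < 0) or not np.allclose(arr, np.round(arr))):
        raise ValueError(f"{what} must be nonnegative integers")
    return arr


def fano_factor(group_values: Sequence[int], variance: str = "population") -> float:
    """Variance / mean of a neighbour group's mRNA counts.

    ``variance`` selects the population (``ddof=0``, default) or sample
    (``ddof=1``) estimator.  A group with mean 0 — no transcripts anywhere —
    returns 0 by convention rather than NaN, keeping score tables
    heatmap-friendly.
    """
    x = _as_counts(group_values, "group_values")
    if x.size == 0:
        raise ValueError("group must contain at least one cell")
    mean = x.mean()
    if mean == 0:
        return 0.0
    ddof = {"population": 0, "sample": 1}[variance]
    if x.size - ddof <= 0:
        return 0.0
    return float(x.var(ddof=ddof) / mean)


def numerical_variability(
    x_i: int, neighbour_values: Sequence[int], population_max: int
) -> float:
    """NV: mean absolute neighbour difference over the population maximum.

    ``population_max`` must dominate every count involved (it is the per-gene
    maximum over all analysed cells).  Returns 0 for an isolated cell (no
    neighbours) and for a silent gene (``population_max == 0``).
    """
    x = float(_as_counts([x_i], "x_i")[0])
    nb = _as_counts(neighbour_values, "neighbour_values")
    pmax = float(_as_counts([population_max], "population_max")[0])
    if nb.size == 0:
        return 0.0
    if pmax < max(x, nb.max()):
        raise ValueError("population_max must be >= every count in the population")
    if pmax == 0:
        return 0.0
    return float(np.abs(x - nb).mean() / pmax)


def proportional_variability(x_i: int, neighbour_values: Sequence[int]) -> float:
    """PV: mean absolute neighbour difference over the group maximum.

    The focal cell belongs to its own group, so a single transcript amid
    all-zero neighbours gives ``1/1 = 1`` — the defining maximal case.  An
    all-zero group (and an isolated cell) returns 0.
    """
    x = float(_as_counts([x_i], "x_i")[0])
    nb = _as_counts(neighbour_values, "neighbour_values")
    if nb.size == 0:
        return 0.0
    gmax = max(x, float(nb.max()))
    if gmax == 0:
        return 0.0
    return float(np.abs(x - nb).mean() / gmax)


def apply_pv_filter(
    pv_raw: float, group_values: Sequence[int], threshold: float = 1.0
) -> float:
    """Zero the PV score of cells outside expression domains.

    The raw PV is kept when the neighbour-group mean count (focal cell
    included) is at or above ``threshold``; otherwise the score is 0.  The
    threshold is inclusive: a group mean of exactly 1 retains its score.
    """
    x = _as_counts(group_values, "group_values")
    if x.size == 0 or x.mean() < threshold:
        return 0.0
    return float(pv_raw)


@dataclass
class VariabilityScores:
    """Per-(cell, gene) Fano / NV / PV table plus per-gene context.

    ``frame`` columns: cell_id, gene, fano, nv, pv_raw, pv_filtered,
    n_neighbours, group_mean, isolated.  ``population_max`` maps gene →
    the per-gene maximum count used to normalise NV.
    """

    frame: pd.DataFrame
    population_max: dict[str, int]
    pv_threshold: float

    def for_gene(self, gene: str) -> pd.DataFrame:
        return self.frame[self.frame["gene"] == gene].set_index("cell_id")


def score_embryo(
    expr: ExpressionTable,
    graph: NeighbourGraph,
    pv_threshold: float = 1.0,
    variance: str = "population",
) -> VariabilityScores:
    """Compute Fano, NV and PV for every cell and gene of an embryo.

    The neighbour group of each focal cell is the cell plus its immediate
    neighbours in ``graph``.  ``population_max`` is taken per gene over the
    analysed (segmented) cells in ``expr`` only.  Isolated cells — no
    neighbours at all — score 0 on all three measures and are flagged.
    Deterministic and independent of cell ordering.
    """
    cell_ids = expr.cell_ids
    missing = sorted(set(graph.cells) - set(cell_ids))
    if missing:
        raise ConsistencyError(f"cells in graph missing from counts table: {missing[:10]}")
    index = {c: k for k, c in enumerate(cell_ids)}
    nbr_idx = [
        np.array([index[n] for n in graph.neighbours(c)], dtype=int)
        if c in graph.cells else np.array([], dtype=int)
        for c in cell_ids
    ]
    rows: list[tuple] = []
    pop_max: dict[str, int] = {}
    for gene in expr.genes:
        x = expr.counts[gene].to_numpy(dtype=float)
        pmax = int(x.max()) if x.size else 0
        pop_max[gene] = pmax
        for k, cell in enumerate(cell_ids):
            nb = x[nbr_idx[k]]
            group = np.concatenate([[x[k]], nb])
            gmean = float(group.mean())
            if nb.size == 0:
                rows.append((cell, gene, 0.0, 0.0, 0.0, 0.0, 0, gmean, True))
                continue
            fano = fano_factor(group, variance=variance)
            diff = float(np.abs(x[k] - nb).mean())
            nv = diff / pmax if pmax > 0 else 0.0
            gmax = float(group.max())
            pv = diff / gmax if gmax > 0 else 0.0
            pvf = pv if gmean >= pv_threshold else 0.0
            rows.append((cell, gene, fano, nv, pv, pvf, int(nb.size), gmean, False))
    frame = pd.DataFrame(
        rows,
        columns=["cell_id", "gene", "fano", "nv", "pv_raw", "pv_filtered",
                 "n_neighbours", "group_mean", "isolated"],
    )
    return VariabilityScores(frame=frame, population_max=pop_max, pv_threshold=pv_threshold)


def count_histogram(
    values: Sequence[int], bin_width: int = 5, exclude_zero: bool = True
) -> dict[str, int]:
    """Histogram of per-cell mRNA counts in fixed-width integer bins.

    Bins are ``[1..w], [w+1..2w], ...`` labelled ``"1-5", "6-10", ...`` for
    the default width of five; zero-count cells are dropped when
    ``exclude_zero`` (their number reflects the pattern, not expression).
    Intermediate empty bins up to the maximum value are included so bar
    charts keep a linear axis.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    x = _as_counts(values, "values").astype(int)
    n_zero = int((x == 0).sum())
    x = x[x > 0]
    if x.size == 0 and (exclude_zero or n_zero == 0):
        return {}
    hist: dict[str, int] = {}
    if not exclude_zero and n_zero:
        hist["0"] = n_zero
    n_bins = int((x.max() - 1) // bin_width) + 1 if x.size else 0
    for k in range(n_bins):
        lo, hi = k * bin_width + 1, (k + 1) * bin_width
        hist[f"{lo}-{hi}"] = int(((x >= lo) & (x <= hi)).sum())
    return hist


def nascent_ratio(site_intensity: float, single_mrna_intensity: float) -> float:
    """Transcription-site to single-mRNA intensity ratio.

    Infers the number of nascent transcripts (polymerase occupancy) at a
    transcription site from its brightness relative to a reference
    single-molecule intensity — typically the median single-spot intensity
    over the embryo.
    """
    if site_intensity < 0:
        raise ValueError("site_intensity must be >= 0")
    if not single_mrna_intensity > 0:
        raise ValueError("single_mrna_intensity must be > 0")
    return float(site_intensity) / float(single_mrna_intensity)


def channel_concordance(counts_a: Sequence[int], counts_b: Sequence[int]) -> float:
    """Spearman rank correlation between two per-cell count vectors.

    Used to check spot-detection accuracy when the same transcripts are
    reported through two interleaved probe sets in different colours.
    Returns NaN (with a warning) when either vector is constant, where rank
    correlation is undefined.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 cells")
    if np.all(a == a[0]) or np.all(b == b[0]):
        warnings.warn("constant count vector: rank correlation undefined", stacklevel=2)
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.spearmanr(a, b).statistic)


def nv_pv_extrema(
    max_count: int = 20,
    exhaustive_sizes: tuple[int, ...] = (2, 3),
    n_random: int = 100_000,
    random_sizes: tuple[int, ...] = (4, 5, 6, 7, 8),
    seed: int = 0,
) -> dict[str, float | int]:
    """Extrema of NV and PV over neighbour-group count configurations.

    Enumerates every focal count 0..max_count against all neighbour
    multisets of the exhaustive sizes over the same value range, plus
    ``n_random`` seeded random configurations spread over the larger group
    sizes.  NV is normalised by the global maximum of the enumeration.
    Returns the minimum and maximum observed over both statistics and the
    number of configurations examined — a direct check that both measures
    stay within [0, 1] and attain the bounds.
    """
    focal = np.arange(max_count + 1, dtype=float)
    running_max, running_min, n_cfg = -np.inf, np.inf, 0

    def update(f, nb):
        nonlocal running_max, running_min, n_cfg
        diff = np.abs(f[:, None] - nb).mean(axis=1)
        nv = diff / max_count
        gmax = np.maximum(f, nb.max(axis=1))
        pv = np.divide(diff, gmax, out=np.zeros_like(diff), where=gmax > 0)
        both = np.concatenate([nv, pv])
        running_max = max(running_max, float(both.max()))
        running_min = min(running_min, float(both.min()))
        n_cfg += len(f)

    for size in exhaustive_sizes:
        combos = np.array(
            list(combinations_with_replacement(range(max_count + 1), size)), dtype=float
        )
        f = np.repeat(focal, len(combos))
        nb = np.tile(combos, (len(focal), 1))
        update(f, nb)
    rng = np.random.default_rng(seed)
    per_size = n_random // len(random_sizes)
    for size in random_sizes:
        f = rng.integers(0, max_count + 1, per_size).astype(float)
        nb = rng.integers(0, max_count + 1, (per_size, size)).astype(float)
        update(f, nb)
    return {"min": running_min, "max": running_max, "n_configurations": n_cfg}
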