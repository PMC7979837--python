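"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: surface distances come
from trimesh's exact point-to-triangle projections on densely sampled hull
boundaries, and neighbour sets from O(n²) pairwise comparison.
"""

from __future__ import annotations

import numpy as np
import trimesh
from trimesh.proximity import closest_point_naive


def _as_mesh(poly) -> trimesh.Trimesh:
    return trimesh.Trimesh(vertices=poly.vertices, faces=poly.faces, process=False)


def surface_samples(poly, edge_step: float = 0.05, n_face: int = 400, seed: int = 0) -> np.ndarray:
    """Vertices + subdivided edges + area-weighted random face points.

    Including every vertex exactly (and edge points densely) means the
    closest point between two polytopes — always attained on a vertex, an
    edge, or a flat face-parallel region — is sampled with essentially no
    bias when combined over both directions.
    """
    rng = np.random.default_rng(seed)
    pts = [poly.vertices]
    edges = {tuple(sorted((f[i], f[(i + 1) % 3]))) for f in poly.faces for i in range(3)}
    for a, b in edges:
        va, vb = poly.vertices[a], poly.vertices[b]
        n = max(2, int(np.linalg.norm(vb - va) / edge_step))
        t = np.linspace(0.0, 1.0, n + 1)[1:-1, None]
        if len(t):
            pts.append(va + t * (vb - va))
    tri = poly.vertices[poly.faces]
    areas = np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1) / 2
    face_i = rng.choice(len(tri), size=n_face, p=areas / areas.sum())
    r1, r2 = rng.random((2, n_face, 1))
    swap = (r1 + r2) > 1
    r1, r2 = np.where(swap, 1 - r1, r1), np.where(swap, 1 - r2, r2)
    t = tri[face_i]
    pts.append(t[:, 0] + r1 * (t[:, 1] - t[:, 0]) + r2 * (t[:, 2] - t[:, 0]))
    return np.vstack(pts)


def sampled_surface_distance(poly_a, poly_b, edge_step: float = 0.05, seed: int = 0) -> float:
    """Min distance between the two hull surfaces via exact point-to-mesh
    projection of dense boundary samples, taken in both directions.
    Returns 0 when one hull's vertices penetrate the other."""
    mesh_a, mesh_b = _as_mesh(poly_a), _as_mesh(poly_b)
    if poly_a.contains(poly_b.vertices).any() or poly_b.contains(poly_a.vertices).any():
        return 0.0
    d = np.inf
    for src, dst in ((poly_a, mesh_b), (poly_b, mesh_a)):
        samples = surface_samples(src, edge_step=edge_step, seed=seed)
        _, dists, _ = closest_point_naive(dst, samples)
        d = min(d, float(dists.min()))
    return d


def brute_force_radius_edges(ids, points, radius: float) -> set[tuple[str, str]]:
    """All unordered pairs within the radius by direct pairwise distances."""
    points = np.asarray(points, dtype=float)
    edges = set()
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if np.linalg.norm(points[i] - points[j]) <= radius:
                edges.add(tuple(sorted((ids[i], ids[j]))))
    return edges


def random_hull_pair(rng, offset_lo: float = 0.5, offset_hi: float = 5.5):
    """A random pair of convex point-cloud hulls with a random separation."""
    from embryovar.geometry import convex_polygon

    a = rng.normal(size=(15, 3))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    b = rng.normal(size=(15, 3)) + direction * rng.uniform(offset_lo, offset_hi)
    return convex_polygon("a", a), convex_polygon("b", b)
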