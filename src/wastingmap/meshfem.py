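"""Triangulation of the study region and linear finite-element assembly.

The spatial Matern field is represented as a Gaussian Markov random field on
a triangulation: the SPDE (kappa^2 - Laplacian)(tau x) = white noise,
discretized with piecewise-linear basis functions, turns into a sparse
precision matrix built from the mass matrix C and stiffness matrices G1, G2
assembled here.  The mesh extends past the study region by a buffer so the
Neumann boundary condition does not inflate the variance inside the domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree


@dataclass
class Mesh:
    """Structured triangulation with an inner (data) domain and outer buffer.

    vertices : (n_v, 2) float array, planar km coordinates.
    triangles : (n_t, 3) int array of vertex indices, positively oriented.
    inner : (n_v,) bool, True for vertices inside the inner (un-buffered) domain.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    inner: np.ndarray
    _vertex_tris: list | None = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        u = p[:, 1] - p[:, 0]
        v = p[:, 2] - p[:, 0]
        return 0.5 * (u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0])

    def _incident_triangles(self) -> list:
        if self._vertex_tris is None:
            vt: list = [[] for _ in range(self.n_vertices)]
            for t, tri in enumerate(self.triangles):
                for v in tri:
                    vt[v].append(t)
            self._vertex_tris = vt
        return self._vertex_tris


@dataclass
class FEMMatrices:
    """P1 finite-element matrices: lumped mass C (diagonal), stiffness G1,
    and G2 = G1 C^-1 G1 (the alpha=2 operator square)."""

    C: sp.dia_matrix
    G1: sp.csr_matrix
    G2: sp.csr_matrix


def build_mesh(region_or_points, max_edge_km: float, buffer_km: float = 0.0) -> Mesh:
    """Structured triangular mesh over a bounding box plus an outer buffer.

    Accepts either an object with a ``bbox`` attribute (x_min, x_max, y_min,
    y_max) or an (n, 2) array of points whose bounding box defines the inner
    domain.  Grid spacing is chosen so that no edge (including cell
    diagonals) exceeds ``max_edge_km`` anywhere.
    """
    if max_edge_km <= 0:
        raise ValueError("max_edge_km must be positive")
    if buffer_km < 0:
        raise ValueError("buffer_km must be nonnegative")
    if hasattr(region_or_points, "bbox"):
        x_min, x_max, y_min, y_max = region_or_points.bbox
    else:
        pts = np.asarray(region_or_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
            raise ValueError("need a region or at least 3 points")
        # collinearity check: rank of centred coordinates
        if np.linalg.matrix_rank(pts - pts.mean(axis=0)) < 2:
            raise ValueError("points are collinear; cannot build a 2-D mesh")
        x_min, x_max = pts[:, 0].min(), pts[:, 0].max()
        y_min, y_max = pts[:, 1].min(), pts[:, 1].max()
    if x_max <= x_min or y_max <= y_min:
        raise ValueError("degenerate bounding box")

    # cell diagonal = h*sqrt(2) is the longest edge of the split cell
    h = max_edge_km / np.sqrt(2.0)
    x0, x1 = x_min - buffer_km, x_max + buffer_km
    y0, y1 = y_min - buffer_km, y_max + buffer_km
    nx = max(int(np.ceil((x1 - x0) / h)), 1)
    ny = max(int(np.ceil((y1 - y0) / h)), 1)
    xs = np.linspace(x0, x1, nx + 1)
    ys = np.linspace(y0, y1, ny + 1)
    X, Y = np.meshgrid(xs, ys)
    vertices = np.column_stack([X.ravel(), Y.ravel()])

    def vid(i, j):  # row i (y), col j (x)
        return i * (nx + 1) + j

    tris = []
    for i in range(ny):
        for j in range(nx):
            v00, v10 = vid(i, j), vid(i, j + 1)
            v01, v11 = vid(i + 1, j), vid(i + 1, j + 1)
            tris.append((v00, v10, v11))
            tris.append((v00, v11, v01))
    triangles = np.array(tris, dtype=np.int64)
    eps = 1e-9
    inner = (
        (vertices[:, 0] >= x_min - eps)
        & (vertices[:, 0] <= x_max + eps)
        & (vertices[:, 1] >= y_min - eps)
        & (vertices[:, 1] <= y_max + eps)
    )
    return Mesh(vertices=vertices, triangles=triangles, inner=inner)


def fem_matrices(mesh: Mesh) -> FEMMatrices:
    """Assemble lumped mass C, stiffness G1 and G2 = G1 C^-1 G1.

    Per-triangle: the gradient of barycentric coordinate i is the rotated
    opposite edge over twice the area; the element stiffness is
    area * grad_i . grad_j, and mass lumping puts one third of each
    triangle's area on each of its vertices.
    """
    n_v = mesh.n_vertices
    p = mesh.vertices[mesh.triangles]  # (n_t, 3, 2)
    e0 = p[:, 2] - p[:, 1]
    e1 = p[:, 0] - p[:, 2]
    e2 = p[:, 1] - p[:, 0]
    area = 0.5 * (e2[:, 0] * (-e1)[:, 1] - e2[:, 1] * (-e1)[:, 0])
    bad = np.flatnonzero(area <= 1e-12)
    if bad.size:
        raise ValueError(f"degenerate (non-positive area) triangles: {bad.tolist()}")

    # grad lambda_k = rot90(edge opposite k) / (2A); rot90(v) = (-vy, vx)
    grads = np.stack([e0, e1, e2], axis=1)  # (n_t, 3, 2)
    grads = np.stack([-grads[..., 1], grads[..., 0]], axis=-1)
    grads /= (2.0 * area)[:, None, None]

    ke = np.einsum("tid,tjd->tij", grads, grads) * area[:, None, None]
    rows = np.repeat(mesh.triangles, 3, axis=1).ravel()
    cols = np.tile(mesh.triangles, (1, 3)).ravel()
    G1 = sp.coo_matrix((ke.ravel(), (rows, cols)), shape=(n_v, n_v)).tocsr()
    G1 = 0.5 * (G1 + G1.T)

    c = np.zeros(n_v)
    np.add.at(c, mesh.triangles.ravel(), np.repeat(area / 3.0, 3))
    C = sp.diags(c)
    Cinv = sp.diags(1.0 / c)
    G2 = (G1 @ Cinv @ G1).tocsr()
    return FEMMatrices(C=C, G1=G1, G2=G2)


def _barycentric(tri_pts: np.ndarray, point: np.ndarray) -> np.ndarray:
    a, b, c = tri_pts
    T = np.column_stack([b - a, c - a])
    try:
        lam = np.linalg.solve(T, point - a)
    except np.linalg.LinAlgError:
        return np.array([-1.0, -1.0, -1.0])
    return np.array([1.0 - lam[0] - lam[1], lam[0], lam[1]])


def projection_matrix(
    mesh: Mesh, locations: np.ndarray, on_outside: str = "raise"
):
    """Sparse (n_loc x n_v) barycentric interpolation matrix A.

    Row i holds the barycentric weights of location i inside its containing
    triangle: at most 3 nonzeros summing to 1.  Projecting mesh nodal values
    through A evaluates the piecewise-linear field at the locations, which
    is exact for linear functions.

    With ``on_outside="mask"`` returns ``(A, outside_indices)`` with
    all-zero rows for locations outside the mesh instead of raising.
    """
    locations = np.atleast_2d(np.asarray(locations, dtype=float))
    n_loc = len(locations)
    tree = cKDTree(mesh.vertices)
    incident = mesh._incident_triangles()
    k = min(6, mesh.n_vertices)
    _, nearest = tree.query(locations, k=k)
    nearest = np.atleast_2d(nearest)

    tol = 1e-9
    rows, cols, vals = [], [], []
    missing = []
    for i, loc in enumerate(locations):
        found = False
        seen: set = set()
        candidates = [t for v in nearest[i] for t in incident[v]]
        for t in candidates:
            if t in seen:
                continue
            seen.add(t)
            lam = _barycentric(mesh.vertices[mesh.triangles[t]], loc)
            if np.all(lam >= -tol):
                lam = np.clip(lam, 0.0, None)
                lam /= lam.sum()
                rows.extend([i] * 3)
                cols.extend(mesh.triangles[t])
                vals.extend(lam)
                found = True
                break
        if not found:
            # brute-force fall-back before declaring the point outside
            for t in range(mesh.n_triangles):
                if t in seen:
                    continue
                lam = _barycentric(mesh.vertices[mesh.triangles[t]], loc)
                if np.all(lam >= -tol):
                    lam = np.clip(lam, 0.0, None)
                    lam /= lam.sum()
                    rows.extend([i] * 3)
                    cols.extend(mesh.triangles[t])
                    vals.extend(lam)
                    found = True
                    break
        if not found:
            missing.append(i)
    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_loc, mesh.n_vertices))
    if missing and on_outside == "raise":
        raise ValueError(f"locations outside the mesh at indices: {missing}")
    if on_outside == "mask":
        return A, missing
    return A
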