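"""Triangulated domain, site projector, and the sparse Matérn (SPDE) precision.

A Matérn Gaussian field with smoothness ν = 1 on a planar domain is
represented as a Gaussian Markov random field on the vertices of a
triangulation: the solution of the SPDE (κ² − Δ) x(s) = W(s) discretized
with piecewise-linear finite elements has the sparse precision

    Q₀ = κ⁴ C + 2 κ² G + G C⁻¹ G,

with C the (lumped) mass matrix and G the stiffness matrix.  Q₀ implies a
unit-τ marginal variance of 1/(4π κ²) in the interior, so Q₀ is rescaled to
hit a requested marginal variance σ_w².  Observation sites inside a triangle
are mapped to its three vertices by a sparse projector whose rows sum to 1.

Distances are planar (km); the correlation range — the distance at which the
Matérn correlation falls to ≈ 0.1 — is ρ = √(8ν)/κ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import Delaunay, QhullError
from scipy.special import gamma as gamma_fn
from scipy.special import kv

__all__ = [
    "Mesh",
    "Projector",
    "SPDEPrecision",
    "build_mesh",
    "build_projector",
    "matern_correlation",
    "matern_range",
    "build_spde_precision",
    "ar1_time_precision",
    "sample_st_field",
]


@dataclass
class Mesh:
    """Planar triangulation: vertex coordinates, triangle index triples, hull flags."""

    vertices: np.ndarray          # (G, 2)
    triangles: np.ndarray         # (m, 3) int
    boundary: np.ndarray          # (G,) bool, True on the convex hull
    _delaunay: Delaunay | None = field(default=None, repr=False, compare=False)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def point_locator(self) -> Delaunay:
        if self._delaunay is None:
            self._delaunay = Delaunay(self.vertices)
        return self._delaunay

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        verts = pd.DataFrame(
            {
                "vertex_id": np.arange(self.n_vertices),
                "x": self.vertices[:, 0],
                "y": self.vertices[:, 1],
                "boundary": self.boundary.astype(int),
            }
        )
        tris = pd.DataFrame(self.triangles, columns=["v0", "v1", "v2"])
        return verts, tris


@dataclass
class Projector:
    """Sparse site→vertex map B (n_sites × G); rows sum to 1, ≤3 nonzeros each."""

    B: sp.csr_matrix
    site_ids: np.ndarray

    def row_for(self, site_id) -> np.ndarray:
        idx = np.flatnonzero(self.site_ids == site_id)
        if idx.size == 0:
            raise KeyError(f"unknown site_id {site_id!r}")
        return self.B[idx[0]].toarray().ravel()

    def to_frame(self) -> pd.DataFrame:
        coo = self.B.tocoo()
        return pd.DataFrame(
            {
                "site_id": self.site_ids[coo.row],
                "vertex": coo.col,
                "weight": coo.data,
            }
        )


@dataclass
class SPDEPrecision:
    """Sparse Matérn precision on mesh vertices, scaled to marginal variance sigma_w2."""

    kappa: float
    sigma_w2: float
    Q: sp.csc_matrix

    @property
    def n(self) -> int:
        return self.Q.shape[0]


def _site_xy(sites) -> np.ndarray:
    if isinstance(sites, pd.DataFrame):
        return np.column_stack([sites["x"].to_numpy(float), sites["y"].to_numpy(float)])
    xy = np.asarray(sites, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2:
        raise ValueError("sites must be a DataFrame with x,y or an (n, 2) array")
    return xy


def _hex_grid(xmin, xmax, ymin, ymax, spacing) -> np.ndarray:
    """Triangular-lattice point cloud covering the box (avoids cocircular quads)."""
    dy = spacing * np.sqrt(3.0) / 2.0
    ys = np.arange(ymin, ymax + dy, dy)
    pts = []
    for i, y in enumerate(ys):
        off = 0.5 * spacing if i % 2 else 0.0
        xs = np.arange(xmin + off, xmax + spacing, spacing)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    return np.vstack(pts)


def build_mesh(
    sites,
    max_edge_interior: float | None = None,
    max_edge_outer: float | None = None,
    buffer_width: float = 0.0,
) -> Mesh:
    """Delaunay triangulation covering the sites, optionally refined.

    With ``max_edge_interior`` set, a triangular lattice at that spacing covers
    the site bounding box (plus one spacing of margin); a coarser lattice at
    ``max_edge_outer`` spacing extends ``buffer_width`` beyond it, so boundary
    effects of the SPDE precision land on uninformative outer vertices.  With
    ``max_edge_interior=None`` the sites themselves are triangulated.
    """
    xy = _site_xy(sites)
    if xy.shape[0] < 3:
        raise ValueError("need at least 3 sites to build a mesh")
    if not np.all(np.isfinite(xy)):
        raise ValueError("site coordinates must be finite")
    centered = xy - xy.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(xy).max())) < 2:
        raise ValueError("sites are collinear; cannot triangulate a 2-D domain")

    if max_edge_interior is None:
        points = xy
    else:
        if max_edge_interior <= 0:
            raise ValueError("max_edge_interior must be positive")
        m = max_edge_interior
        xmin, ymin = xy.min(axis=0) - m
        xmax, ymax = xy.max(axis=0) + m
        points = _hex_grid(xmin, xmax, ymin, ymax, m)
        if buffer_width > 0:
            outer_edge = max_edge_outer if max_edge_outer is not None else 3.0 * m
            ring = _hex_grid(
                xmin - buffer_width,
                xmax + buffer_width,
                ymin - buffer_width,
                ymax + buffer_width,
                outer_edge,
            )
            inside = (
                (ring[:, 0] > xmin) & (ring[:, 0] < xmax)
                & (ring[:, 1] > ymin) & (ring[:, 1] < ymax)
            )
            points = np.vstack([points, ring[~inside]])

    try:
        tri = Delaunay(points)
    except QhullError as exc:  # pragma: no cover - rank check catches most
        raise ValueError(f"triangulation failed: {exc}") from exc

    boundary = np.zeros(points.shape[0], dtype=bool)
    boundary[np.unique(tri.convex_hull)] = True
    mesh = Mesh(
        vertices=tri.points,
        triangles=tri.simplices.copy(),
        boundary=boundary,
        _delaunay=tri,
    )
    areas = mesh.triangle_areas()
    if np.any(areas <= 1e-12):
        # drop degenerate slivers from the triangle list; point location still
        # uses the full Delaunay structure
        mesh.triangles = mesh.triangles[areas > 1e-12]
    return mesh


def build_projector(mesh: Mesh, sites, weight_mode: str = "equal_thirds") -> Projector:
    """Map each site to the vertices of its containing triangle.

    ``equal_thirds`` assigns weight 1/3 to each vertex of the containing
    triangle (the simple vertex-averaging rule); ``barycentric`` uses the
    site's barycentric coordinates, which reproduce linear functions exactly.
    A site coinciding with a vertex gets a single unit weight in both modes.
    """
    if weight_mode not in ("equal_thirds", "barycentric"):
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    xy = _site_xy(sites)
    if isinstance(sites, pd.DataFrame) and "site_id" in sites:
        site_ids = sites["site_id"].to_numpy()
    else:
        site_ids = np.arange(xy.shape[0])

    dela = mesh.point_locator()
    simplex = dela.find_simplex(xy, tol=1e-9)
    if np.any(simplex < 0):
        bad = site_ids[simplex < 0]
        raise ValueError(f"sites outside the mesh: {bad.tolist()}")

    rows, cols, vals = [], [], []
    Tmat = dela.transform[simplex]  # (n, 3, 2): affine map to barycentric
    for i in range(xy.shape[0]):
        verts = dela.simplices[simplex[i]]
        b = Tmat[i, :2] @ (xy[i] - Tmat[i, 2])
        bary = np.append(b, 1.0 - b.sum())
        j = np.argmax(bary)
        if bary[j] >= 1.0 - 1e-9:  # coincident with a vertex
            rows.append(i)
            cols.append(verts[j])
            vals.append(1.0)
            continue
        w = bary if weight_mode == "barycentric" else np.full(3, 1.0 / 3.0)
        rows.extend([i] * 3)
        cols.extend(verts.tolist())
        vals.extend(w.tolist())

    B = sp.csr_matrix(
        (vals, (rows, cols)), shape=(xy.shape[0], mesh.n_vertices)
    )
    return Projector(B=B, site_ids=site_ids)


def matern_correlation(h, kappa: float, nu: float = 1.0):
    """Matérn correlation C(h) = 2^{1-ν}/Γ(ν) (κh)^ν K_ν(κh), with C(0) = 1."""
    if kappa <= 0 or nu <= 0:
        raise ValueError("kappa and nu must be positive")
    h = np.asarray(h, dtype=float)
    if np.any(h < 0):
        raise ValueError("distance h must be nonnegative")
    kh = kappa * h
    with np.errstate(invalid="ignore", over="ignore"):
        c = (2.0 ** (1.0 - nu) / gamma_fn(nu)) * kh**nu * kv(nu, kh)
    c = np.where(kh == 0.0, 1.0, c)
    c = np.nan_to_num(c, nan=0.0)  # K_ν underflows to 0 at large kh
    return float(c) if c.ndim == 0 else c


def matern_range(kappa: float, nu: float = 1.0) -> float:
    """Distance at which the Matérn correlation drops to ≈ 0.1: ρ = √(8ν)/κ."""
    if kappa <= 0 or nu <= 0:
        raise ValueError("kappa and nu must be positive")
    return float(np.sqrt(8.0 * nu) / kappa)


def _fem_matrices(mesh: Mesh) -> tuple[sp.csc_matrix, sp.csc_matrix]:
    """Lumped mass matrix C (diagonal) and stiffness matrix G for P1 elements."""
    verts = mesh.vertices
    tris = mesh.triangles
    n = mesh.n_vertices
    c_diag = np.zeros(n)
    rows, cols, vals = [], [], []
    for t in tris:
        p = verts[t]
        e1 = p[1] - p[0]
        e2 = p[2] - p[0]
        area = 0.5 * abs(e1[0] * e2[1] - e1[1] * e2[0])
        if area <= 1e-12:
            raise ValueError("degenerate triangle in mesh (zero area)")
        c_diag[t] += area / 3.0
        # gradients of the three hat functions
        bmat = np.array(
            [
                [p[1, 1] - p[2, 1], p[2, 1] - p[0, 1], p[0, 1] - p[1, 1]],
                [p[2, 0] - p[1, 0], p[0, 0] - p[2, 0], p[1, 0] - p[0, 0]],
            ]
        ) / (2.0 * area)
        local = area * (bmat.T @ bmat)
        for a in range(3):
            for b in range(3):
                rows.append(t[a])
                cols.append(t[b])
                vals.append(local[a, b])
    C = sp.diags(c_diag, format="csc")
    G = sp.csc_matrix((vals, (rows, cols)), shape=(n, n))
    return C, G


def build_spde_precision(mesh: Mesh, kappa: float, sigma_w2: float) -> SPDEPrecision:
    """Assemble the ν=1 Matérn precision on the mesh, scaled to variance sigma_w2."""
    if kappa <= 0 or sigma_w2 <= 0:
        raise ValueError("kappa and sigma_w2 must be positive")
    C, G = _fem_matrices(mesh)
    c_inv = sp.diags(1.0 / C.diagonal(), format="csc")
    K = (kappa**2) * C + G
    Q0 = (K @ c_inv @ K).tocsc()
    # unit-τ marginal variance for α=2, d=2 is 1/(4π κ²)
    Q = (Q0 / (4.0 * np.pi * kappa**2 * sigma_w2)).tocsc()
    Q = ((Q + Q.T) * 0.5).tocsc()  # kill round-off asymmetry
    return SPDEPrecision(kappa=kappa, sigma_w2=sigma_w2, Q=Q)


def ar1_time_precision(a: float, T: int) -> sp.csc_matrix:
    """Precision of a stationary AR(1) with unit innovation variance.

    Tridiagonal with diagonal (1, 1+a², ..., 1+a², 1) and off-diagonal −a;
    log-determinant log(1 − a²) for every T.
    """
    if not (-1.0 < a < 1.0):
        raise ValueError("AR(1) coefficient a must satisfy |a| < 1")
    if T < 1:
        raise ValueError("T must be >= 1")
    if T == 1:
        return sp.csc_matrix(np.array([[1.0 - a**2]]))
    d = np.full(T, 1.0 + a**2)
    d[0] = d[-1] = 1.0
    off = np.full(T - 1, -a)
    return sp.diags([off, d, off], [-1, 0, 1], format="csc")


def sample_st_field(Q_s, a: float, T: int, seed) -> np.ndarray:
    """Draw ζ_1..ζ_T with ζ_t = a ζ_{t−1} + ω_t, ω_t ~ N(0, Q_s⁻¹).

    Started from the stationary distribution N(0, Q_s⁻¹/(1−a²)), so every
    time slice has the same marginal law.  Uses a dense Cholesky factor of
    the precision (meshes here are small).
    """
    if not (-1.0 < a < 1.0):
        raise ValueError("AR(1) coefficient a must satisfy |a| < 1")
    if T < 1:
        raise ValueError("T must be >= 1")
    Q = Q_s.Q if isinstance(Q_s, SPDEPrecision) else Q_s
    Qd = Q.toarray() if sp.issparse(Q) else np.asarray(Q, dtype=float)
    L = np.linalg.cholesky(Qd)  # Q = L Lᵀ; x = L⁻ᵀ z has precision Q
    rng = np.random.default_rng(seed)
    G = Qd.shape[0]
    out = np.empty((T, G))
    z = rng.standard_normal(G)
    out[0] = np.linalg.solve(L.T, z) / np.sqrt(1.0 - a**2)
    for t in range(1, T):
        w = np.linalg.solve(L.T, rng.standard_normal(G))
        out[t] = a * out[t - 1] + w
    return out
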