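"""Computational domains for cranial-vault simulations.

The embryonic cranial vault is a thin curved shell (~0.3 mm thick against a
~7 mm lateral extent), so the domain is represented as a triangulated
2-manifold surface: each triangle is a finite-volume cell, diffusion is
tangential, and fluxes between adjacent cells use a two-point flux
approximation (shared-edge length divided by centroid distance).

Three mesh builders are provided:

* :func:`build_dome_mesh` — an upper-half ellipsoid cap emulating the E17.5
  mouse cranial vault (length ~7 mm, height ~2.49 mm).
* :func:`build_sheet_mesh` — a flat rectangle, optionally periodic, for
  verification of the diffusion operator.
* :func:`build_interval_mesh` — a uniform 1D chain for dispersion-relation
  verification against the analytic growth rate of a single Fourier mode.

All coordinates are in millimetres; cell measures are mm^2 for surfaces and
mm for intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components


class MeshError(ValueError):
    """Raised for invalid mesh construction arguments or degenerate meshes."""


@dataclass
class SurfaceMesh:
    """A cell-centred finite-volume discretisation of a 2-manifold (or 1D chain).

    Attributes
    ----------
    cell_centroids : (n_cells, 3) float array, mm
    cell_areas : (n_cells,) float array
        Finite-volume cell measure: triangle area (mm^2) for surfaces,
        segment length (mm) for interval meshes.
    edges : (n_edges, 2) int array
        Pairs of adjacent cell indices (each internal face once).
    edge_flux_coeffs : (n_edges,) float array
        Two-point flux transmissibility: shared-edge length / centroid
        distance for surfaces, 1 / centroid distance for intervals.
    boundary_flags : (n_cells,) bool array
        True for cells owning at least one face without a neighbour.
    vertical_axis : (3,) float array
        Unit vector defining the superior (apex-ward) direction.
    dim : int
        Intrinsic dimension (2 for surfaces, 1 for intervals); controls the
        stability limit of explicit diffusion stepping.
    points, triangles : optional vertex arrays retained for export.
    """

    cell_centroids: np.ndarray
    cell_areas: np.ndarray
    edges: np.ndarray
    edge_flux_coeffs: np.ndarray
    boundary_flags: np.ndarray
    vertical_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    dim: int = 2
    points: np.ndarray | None = None
    triangles: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_centroids = np.asarray(self.cell_centroids, dtype=float)
        self.cell_areas = np.asarray(self.cell_areas, dtype=float)
        self.edges = np.asarray(self.edges, dtype=np.int64)
        self.edge_flux_coeffs = np.asarray(self.edge_flux_coeffs, dtype=float)
        self.boundary_flags = np.asarray(self.boundary_flags, dtype=bool)
        self.vertical_axis = np.asarray(self.vertical_axis, dtype=float)
        self.vertical_axis = self.vertical_axis / np.linalg.norm(self.vertical_axis)
        if self.n_cells == 0:
            raise MeshError("mesh has no cells")
        if np.any(self.cell_areas <= 0):
            raise MeshError("all cell measures must be positive")
        if self.edges.size and (
            np.any(self.edges[:, 0] == self.edges[:, 1])
            or self.edges.max() >= self.n_cells
            or self.edges.min() < 0
        ):
            raise MeshError("edges must connect two distinct existing cells")
        if np.any(self.edge_flux_coeffs <= 0):
            raise MeshError("all edge flux coefficients must be positive")
        self._lap: sp.csr_matrix | None = None

    @property
    def n_cells(self) -> int:
        return len(self.cell_areas)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self, weights: np.ndarray | None = None) -> sp.csr_matrix:
        """Symmetric cell-adjacency matrix, optionally with per-edge weights."""
        i, j = self.edges[:, 0], self.edges[:, 1]
        w = np.ones(self.n_edges) if weights is None else np.asarray(weights, float)
        a = sp.coo_matrix((w, (i, j)), shape=(self.n_cells, self.n_cells))
        return (a + a.T).tocsr()

    def is_connected(self) -> bool:
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        return n_comp == 1

    def flux_operator(self) -> sp.csr_matrix:
        """Unscaled flux operator F with (F u)_c = sum_edges coeff * (u_nbr - u_c).

        Row sums are zero (discrete conservation); dividing row c by
        ``cell_areas[c]`` yields the finite-volume Laplacian.
        """
        i, j = self.edges[:, 0], self.edges[:, 1]
        c = self.edge_flux_coeffs
        rows = np.concatenate([i, j, i, j])
        cols = np.concatenate([j, i, i, j])
        vals = np.concatenate([c, c, -c, -c])
        return sp.coo_matrix(
            (vals, (rows, cols)), shape=(self.n_cells, self.n_cells)
        ).tocsr()

    def laplacian_matrix(self) -> sp.csr_matrix:
        """Finite-volume Laplacian L = diag(1/area) @ flux_operator (zero-flux)."""
        if self._lap is None:
            self._lap = sp.diags(1.0 / self.cell_areas) @ self.flux_operator()
        return self._lap

    def min_spacing(self) -> float:
        """Minimum centroid-to-centroid distance across any internal face."""
        d = self.cell_centroids[self.edges[:, 0]] - self.cell_centroids[self.edges[:, 1]]
        return float(np.linalg.norm(d, axis=1).min())


@dataclass
class HeightField:
    """Per-cell height above the inferior rim along the superior axis (mm)."""

    x_rel: np.ndarray

    def __post_init__(self) -> None:
        self.x_rel = np.asarray(self.x_rel, dtype=float)


def compute_xrel(mesh: SurfaceMesh) -> HeightField:
    """Height of each cell centroid above the lowest cell along the vertical axis.

    The inferior rim of the dome is at ``x_rel = 0``; the apex of the default
    vault domain sits at ``x_rel ~ 2.49`` mm. Flat sheets give identically 0.
    """
    proj = mesh.cell_centroids @ mesh.vertical_axis
    return HeightField(x_rel=proj - proj.min())


def apply_laplacian(mesh: SurfaceMesh, fld: np.ndarray) -> np.ndarray:
    """Apply the zero-flux finite-volume Laplacian to a per-cell field.

    ``(lap u)_c = (1/area_c) * sum_{nbr} coeff_{c,nbr} (u_nbr - u_c)``; there is
    no flux across boundary faces, so the area-weighted sum of the result
    vanishes (discrete divergence theorem).
    """
    fld = np.asarray(fld, dtype=float)
    if fld.shape != (mesh.n_cells,):
        raise ValueError(
            f"field length {fld.shape} does not match cell count {mesh.n_cells}"
        )
    if not np.all(np.isfinite(fld)):
        raise FloatingPointError("field contains non-finite entries")
    # edge-difference scatter: constants are annihilated exactly
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    flux = mesh.edge_flux_coeffs * (fld[j] - fld[i])
    out = np.zeros(mesh.n_cells)
    np.add.at(out, i, flux)
    np.add.at(out, j, -flux)
    return out / mesh.cell_areas


# ---------------------------------------------------------------------------
# mesh builders
# ---------------------------------------------------------------------------

def _dome_latitude_rows(
    a: float, b: float, c: float, target_edge: float
) -> np.ndarray:
    """Latitude angles phi (0 = rim, pi/2 = apex) spaced ~target_edge apart.

    Rows are placed by walking the meridian of the mean-lateral ellipse in
    arc-length steps of ``target_edge``; the lowest interval is halved twice
    so the rim-adjacent cells are short enough that their centroids sit close
    to the rim plane (the per-cell height coordinate is centroid-based).
    """
    r_lat = 0.5 * (a + b)
    phis = [0.0]
    phi = 0.0
    while True:
        # meridian arc element ds/dphi for (r_lat cos phi, c sin phi)
        ds = np.hypot(r_lat * np.sin(phi), c * np.cos(phi))
        step = target_edge / max(ds, 1e-12)
        if phi + 1.5 * step >= np.pi / 2:
            break
        phi += step
        phis.append(phi)
    rows = np.array(phis)
    if len(rows) < 3:
        raise MeshError("target_edge too coarse to resolve the cap")
    # refine the rim band: split the first interval into quarters/halves
    first = rows[1]
    rows = np.concatenate([[0.0, 0.25 * first, 0.5 * first], rows[1:]])
    return rows


def _stitch_rings(
    idx_a: np.ndarray, ang_a: np.ndarray, idx_b: np.ndarray, ang_b: np.ndarray
) -> list[list[int]]:
    """Triangulate the band between two vertex rings (two-pointer merge)."""
    na, nb = len(idx_a), len(idx_b)
    ext_a = np.append(ang_a, ang_a[0] + 2 * np.pi)
    ext_b = np.append(ang_b, ang_b[0] + 2 * np.pi)
    faces = []
    i = j = 0
    while i < na or j < nb:
        advance_a = j >= nb or (i < na and ext_a[i + 1] <= ext_b[j + 1])
        if advance_a:
            faces.append([idx_a[i % na], idx_a[(i + 1) % na], idx_b[j % nb]])
            i += 1
        else:
            faces.append([idx_a[i % na], idx_b[(j + 1) % nb], idx_b[j % nb]])
            j += 1
    return faces


def _tri_mesh_from_arrays(
    points: np.ndarray, triangles: np.ndarray, dim: int = 2
) -> SurfaceMesh:
    """Assemble a SurfaceMesh from triangle soup: centroids, areas, TPFA edges."""
    centroids = points[triangles].mean(axis=1)
    v1 = points[triangles[:, 1]] - points[triangles[:, 0]]
    v2 = points[triangles[:, 2]] - points[triangles[:, 0]]
    areas = 0.5 * np.linalg.norm(np.cross(v1, v2), axis=1)
    if np.any(areas <= 0):
        raise MeshError("degenerate (zero-area) triangle in mesh")

    # face (vertex pair) -> owning triangles
    face_map: dict[tuple[int, int], list[int]] = {}
    for t, (a, b, c) in enumerate(triangles):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (u, v) if u < v else (v, u)
            face_map.setdefault(key, []).append(t)

    edges, coeffs = [], []
    n_boundary_faces = np.zeros(len(triangles), dtype=int)
    for (u, v), owners in face_map.items():
        if len(owners) == 2:
            t0, t1 = owners
            elen = np.linalg.norm(points[u] - points[v])
            cdist = np.linalg.norm(centroids[t0] - centroids[t1])
            edges.append((t0, t1))
            coeffs.append(elen / cdist)
        elif len(owners) == 1:
            n_boundary_faces[owners[0]] += 1
        else:
            raise MeshError("non-manifold face shared by >2 triangles")

    return SurfaceMesh(
        cell_centroids=centroids,
        cell_areas=areas,
        edges=np.array(edges, dtype=np.int64).reshape(-1, 2),
        edge_flux_coeffs=np.array(coeffs, dtype=float),
        boundary_flags=n_boundary_faces > 0,
        dim=dim,
        points=points,
        triangles=triangles,
    )


def build_dome_mesh(
    length: float = 7.0,
    width: float = 5.2,
    height: float = 2.49,
    target_edge: float = 0.15,
) -> SurfaceMesh:
    """Triangulated upper-half ellipsoid cap emulating the embryonic cranial vault.

    The cap has semi-axes ``(length/2, width/2, height)`` along (x, y, z), cut
    at the equatorial plane z = 0.  The rostral (snout-ward) direction is +x
    and the superior direction is +z.  Defaults give the ~7 mm long, ~2.49 mm
    high vault of the E17.5 mouse.

    The triangulation is built from latitude rings (vertex counts following
    the ring circumference) stitched into bands, with an apex fan and a
    refined pair of rows at the rim.

    Parameters
    ----------
    length, width, height : mm
        Rostro-caudal extent, lateral extent, and apex height of the cap.
    target_edge : mm
        Requested typical triangle edge length.
    """
    for name, val in (("length", length), ("width", width), ("height", height),
                      ("target_edge", target_edge)):
        if not val > 0:
            raise MeshError(f"{name} must be positive, got {val}")
    if target_edge >= min(length, width, height * 2) / 4:
        raise MeshError(
            f"target_edge={target_edge} too coarse to resolve a "
            f"{length}x{width}x{height} cap"
        )
    a, b, c = length / 2.0, width / 2.0, height
    rows = _dome_latitude_rows(a, b, c, target_edge)
    verts: list[np.ndarray] = []
    ring_idx: list[np.ndarray] = []
    ring_ang: list[np.ndarray] = []
    for k, phi in enumerate(rows):
        ra, rb = a * np.cos(phi), b * np.cos(phi)
        circ = np.pi * (3 * (ra + rb) - np.sqrt((3 * ra + rb) * (ra + 3 * rb)))
        n_k = max(6, int(round(circ / target_edge)))
        ang = 2 * np.pi * np.arange(n_k) / n_k + (k % 2) * np.pi / n_k
        ring_idx.append(len(verts) + np.arange(n_k))
        ring_ang.append(ang)
        verts.extend(
            np.column_stack(
                [ra * np.cos(ang), rb * np.sin(ang), np.full(n_k, c * np.sin(phi))]
            )
        )
    apex = len(verts)
    verts.append(np.array([0.0, 0.0, c]))
    faces: list[list[int]] = []
    for k in range(len(rows) - 1):
        faces.extend(
            _stitch_rings(ring_idx[k], ring_ang[k], ring_idx[k + 1], ring_ang[k + 1])
        )
    top = ring_idx[-1]
    for j in range(len(top)):
        faces.append([int(top[j]), int(top[(j + 1) % len(top)]), apex])
    mesh = _tri_mesh_from_arrays(
        np.asarray(verts), np.asarray(faces, dtype=np.int64)
    )
    if not mesh.is_connected():
        raise MeshError("dome mesh is not connected; refine target_edge")
    return mesh


def build_sheet_mesh(
    L: float, W: float, target_edge: float, periodic: bool = False
) -> SurfaceMesh:
    """Flat triangulated L x W rectangle in the z = 0 plane.

    Each grid square is split into two right triangles. With ``periodic``,
    opposite sides are identified (cell adjacency wraps; coordinates do not),
    leaving no boundary cells.
    """
    if not (L > 0 and W > 0 and target_edge > 0):
        raise MeshError("L, W and target_edge must be positive")
    nx = max(2, int(round(L / target_edge)))
    ny = max(2, int(round(W / target_edge)))
    hx, hy = L / nx, W / ny
    xs = np.linspace(0.0, L, nx + 1)
    ys = np.linspace(0.0, W, ny + 1)
    vid = lambda i, j: i * (ny + 1) + j  # noqa: E731
    points = np.array([[x, y, 0.0] for x in xs for y in ys])
    tris = []
    for i in range(nx):
        for j in range(ny):
            a, b = vid(i, j), vid(i + 1, j)
            c, d = vid(i + 1, j + 1), vid(i, j + 1)
            tris.append([a, b, c])
            tris.append([a, c, d])
    mesh = _tri_mesh_from_arrays(points, np.array(tris, dtype=np.int64))
    if periodic:
        mesh = _wrap_sheet_periodic(mesh, nx, ny, hx, hy, L, W)
    return mesh


def _wrap_sheet_periodic(
    mesh: SurfaceMesh, nx: int, ny: int, hx: float, hy: float, L: float, W: float
) -> SurfaceMesh:
    """Identify opposite sides of a structured sheet (torus topology)."""
    # cell layout: square (i, j) -> triangles 2*(i*ny+j) (lower) and +1 (upper)
    lower = lambda i, j: 2 * (i * ny + j)  # noqa: E731
    upper = lambda i, j: 2 * (i * ny + j) + 1  # noqa: E731
    extra_edges, extra_coeffs = [], []
    for j in range(ny):
        # x-wrap: right edge of square (nx-1, j) meets left edge of (0, j)
        extra_edges.append((lower(nx - 1, j), upper(0, j)))
        extra_coeffs.append(hy / hx)
    for i in range(nx):
        # y-wrap: top edge of square (i, ny-1) meets bottom edge of (i, 0)
        extra_edges.append((upper(i, ny - 1), lower(i, 0)))
        extra_coeffs.append(hx / hy)
    return SurfaceMesh(
        cell_centroids=mesh.cell_centroids,
        cell_areas=mesh.cell_areas,
        edges=np.vstack([mesh.edges, np.array(extra_edges, dtype=np.int64)]),
        edge_flux_coeffs=np.concatenate(
            [mesh.edge_flux_coeffs, np.array(extra_coeffs)]
        ),
        boundary_flags=np.zeros(mesh.n_cells, dtype=bool),
        dim=2,
        points=mesh.points,
        triangles=mesh.triangles,
    )


def build_interval_mesh(L: float, n_cells: int, periodic: bool = False) -> SurfaceMesh:
    """Uniform 1D chain of ``n_cells`` cells of measure L/n_cells along x.

    Used to verify the discrete dispersion relation: on the periodic interval
    the eigenfunctions of the Laplacian are cos(2*pi*m*x/L).
    """
    if n_cells < 4:
        raise MeshError(f"n_cells must be >= 4, got {n_cells}")
    if not L > 0:
        raise MeshError("L must be positive")
    h = L / n_cells
    x = (np.arange(n_cells) + 0.5) * h
    centroids = np.column_stack([x, np.zeros(n_cells), np.zeros(n_cells)])
    idx = np.arange(n_cells)
    if periodic:
        edges = np.column_stack([idx, (idx + 1) % n_cells])
        boundary = np.zeros(n_cells, dtype=bool)
    else:
        edges = np.column_stack([idx[:-1], idx[1:]])
        boundary = np.zeros(n_cells, dtype=bool)
        boundary[[0, -1]] = True
    return SurfaceMesh(
        cell_centroids=centroids,
        cell_areas=np.full(n_cells, h),
        edges=edges,
        edge_flux_coeffs=np.full(len(edges), 1.0 / h),
        boundary_flags=boundary,
        dim=1,
    )


# ---------------------------------------------------------------------------
# optional import/export
# ---------------------------------------------------------------------------

def load_mesh(path: str) -> SurfaceMesh:
    """Load a triangulated surface from any format trimesh reads (STL, PLY, OFF...).

    Quad faces are split into triangles by trimesh's loader. Requires the
    optional ``trimesh`` dependency.
    """
    import trimesh  # local import: optional dependency

    tm = trimesh.load_mesh(path)
    return _tri_mesh_from_arrays(
        np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64)
    )


def half_ellipsoid_area(a: float, b: float, c: float, n: int = 400) -> float:
    """Surface area of the upper half of an ellipsoid with semi-axes (a, b, c).

    Numerical quadrature of the parametric surface integral; used as an
    analytic cross-check for the dome mesh area.
    """
    from scipy.integrate import dblquad

    def integrand(theta: float, phi: float) -> float:
        st, ct = np.sin(theta), np.cos(theta)
        sp_, cp = np.sin(phi), np.cos(phi)
        # |r_theta x r_phi| for r = (a st cp, b st sp, c ct)
        ex = b * c * st * st * cp
        ey = a * c * st * st * sp_
        ez = a * b * st * ct
        return float(np.sqrt(ex * ex + ey * ey + ez * ez))

    val, _ = dblquad(integrand, 0.0, 2.0 * np.pi, 0.0, np.pi / 2.0)
    return val
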