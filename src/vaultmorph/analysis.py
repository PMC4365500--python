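"""Field thresholding, ossification-center counting, suture metrics, and export.

Bony regions are defined by strict thresholding of an osteoblast field
(``Co > 1.0`` ng/mm^3 by convention) followed by connected-component
labeling under mesh edge adjacency. Components are ordered
rostral-to-caudal (descending x), then left-to-right (ascending y), so bone
indices are stable across runs and mesh resolutions.

Suture gaps between bone pairs are measured as shortest paths through
sub-threshold cells, with the half-edges adjoining ossified cells excluded
from the length, so two touching regions have gap 0 and a one-cell-wide band
of width w measures ~w.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra

from .geometry import SurfaceMesh


def bone_mask(field: np.ndarray, threshold: float) -> np.ndarray:
    """Strict supra-threshold mask ``field > threshold`` (per-cell bool)."""
    field = np.asarray(field, dtype=float)
    if not np.all(np.isfinite(field)):
        raise FloatingPointError("field contains non-finite entries")
    return field > threshold


def labeled_components(mask: np.ndarray, mesh: SurfaceMesh) -> list[np.ndarray]:
    """Connected components of the masked cells, in deterministic order.

    Returns a list of cell-index arrays, ordered by area-weighted component
    centroid: descending x (rostral first), then ascending y.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (mesh.n_cells,):
        raise ValueError("mask length does not match cell count")
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    sub = mesh.adjacency()[np.ix_(idx, idx)]
    n_comp, lab = connected_components(sub, directed=False)
    comps = [idx[lab == c] for c in range(n_comp)]

    def sort_key(cells: np.ndarray) -> tuple[float, float]:
        w = mesh.cell_areas[cells]
        cen = np.average(mesh.cell_centroids[cells], axis=0, weights=w)
        return (-cen[0], cen[1])

    comps.sort(key=sort_key)
    return comps


@dataclass
class RegionReport:
    """Connected supra-threshold regions of a scalar field."""

    n_regions: int
    cell_counts: list[int]
    areas: list[float]        # mm^2
    centroids: list[np.ndarray]  # mm, area-weighted
    threshold: float
    components: list[np.ndarray]  # per-region cell indices


def count_regions(
    mask: np.ndarray, mesh: SurfaceMesh, threshold: float = np.nan
) -> RegionReport:
    """Label and measure the connected regions of a boolean per-cell mask."""
    comps = labeled_components(mask, mesh)
    areas, centroids = [], []
    for cells in comps:
        w = mesh.cell_areas[cells]
        areas.append(float(w.sum()))
        centroids.append(np.average(mesh.cell_centroids[cells], axis=0, weights=w))
    return RegionReport(
        n_regions=len(comps),
        cell_counts=[len(c) for c in comps],
        areas=areas,
        centroids=centroids,
        threshold=float(threshold),
        components=comps,
    )


def suture_gap(
    bones, mesh: SurfaceMesh, threshold: float = 1.0
) -> dict[tuple[int, int], float]:
    """Minimum through-gap distance (mm) between every pair of bones.

    For each pair, the shortest graph path from an ossified cell of one bone
    to one of the other, traversing only sub-threshold cells in between.
    Each edge contributes its centroid distance scaled by the fraction of
    its endpoints that are sub-threshold, so touching regions give exactly 0.
    Ossified cells of third bones block the path.
    """
    masks = [bone_mask(bones.Co[i], threshold) for i in range(bones.n_bones)]
    if bones.n_bones < 2:
        raise ValueError("suture_gap requires at least 2 bones")
    any_supra = np.any(masks, axis=0)
    i_e, j_e = mesh.edges[:, 0], mesh.edges[:, 1]
    elen = np.linalg.norm(
        mesh.cell_centroids[i_e] - mesh.cell_centroids[j_e], axis=1
    )
    gaps: dict[tuple[int, int], float] = {}
    for a in range(bones.n_bones):
        for b in range(a + 1, bones.n_bones):
            allowed = ~any_supra | masks[a] | masks[b]
            sub = ~any_supra
            # edge weight: centroid distance x (sub-threshold endpoint fraction)
            w = elen * 0.5 * (sub[i_e].astype(float) + sub[j_e].astype(float))
            keep = allowed[i_e] & allowed[j_e]
            g = sp.coo_matrix(
                (w[keep] + 1e-30, (i_e[keep], j_e[keep])),
                shape=(mesh.n_cells, mesh.n_cells),
            ).tocsr()
            # zero weights vanish in sparse storage; the 1e-30 keeps touching
            # edges in the graph without affecting distances measurably
            src = np.flatnonzero(masks[a])
            dist = dijkstra(g, directed=False, indices=src, min_only=True)
            dmin = dist[masks[b]].min() if masks[b].any() else np.inf
            gaps[(a + 1, b + 1)] = float(0.0 if dmin < 1e-12 else dmin)
    return gaps


# ---------------------------------------------------------------------------
# export: legacy-VTK snapshots and tidy CSV time series
# ---------------------------------------------------------------------------

def export_snapshot(state, mesh: SurfaceMesh, path: str) -> None:
    """Write mesh plus per-cell fields as an ASCII legacy-VTK unstructured grid.

    Field arrays are taken from the simulation state: Ca/Ch/Co when present,
    plus bone_XX / morphogen_XX per bone in stage 2.
    """
    arrays: dict[str, np.ndarray] = {}
    for name in ("Ca", "Ch", "Co"):
        val = getattr(state, name, None)
        if val is not None:
            arrays[name] = np.asarray(val, dtype=float)
    bones = getattr(state, "bones", None)
    if bones is not None:
        for i in range(bones.n_bones):
            arrays[f"bone_{i + 1:02d}"] = bones.Co[i]
            arrays[f"morphogen_{i + 1:02d}"] = bones.Cm[i]
    write_vtk(mesh, arrays, path)


def write_vtk(mesh: SurfaceMesh, cell_arrays: dict[str, np.ndarray], path: str) -> None:
    if mesh.points is None or mesh.triangles is None:
        raise ValueError("mesh has no vertex data to export")
    pts, tris = mesh.points, mesh.triangles
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvaultmorph snapshot\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            f.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
        f.write(f"CELLS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        f.write(f"CELL_TYPES {len(tris)}\n")
        f.write("\n".join(["5"] * len(tris)) + "\n")
        if cell_arrays:
            f.write(f"CELL_DATA {len(tris)}\n")
            for name, arr in cell_arrays.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{v:.17g}" for v in arr) + "\n")


def read_vtk(path: str) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Read back an ASCII legacy-VTK file written by :func:`write_vtk`."""
    with open(path) as f:
        tokens = f.read().split()
    pos = tokens.index("POINTS")
    n_pts = int(tokens[pos + 1])
    pts = np.array(tokens[pos + 3 : pos + 3 + 3 * n_pts], dtype=float).reshape(-1, 3)
    pos = tokens.index("CELLS")
    n_cells = int(tokens[pos + 1])
    raw = np.array(tokens[pos + 3 : pos + 3 + 4 * n_cells], dtype=np.int64)
    tris = raw.reshape(-1, 4)[:, 1:]
    arrays: dict[str, np.ndarray] = {}
    i = 0
    while i < len(tokens):
        if tokens[i] == "SCALARS":
            name = tokens[i + 1]
            start = i + 6  # SCALARS name type 1 LOOKUP_TABLE default
            arrays[name] = np.array(tokens[start : start + n_cells], dtype=float)
            i = start + n_cells
        else:
            i += 1
    return pts, tris, arrays


def summarize_timeseries(
    trajectory, mesh: SurfaceMesh, threshold: float = 1.0
) -> pd.DataFrame:
    """One tidy row per snapshot: time, field summaries, region counts, gaps."""
    rows = []
    for state in trajectory:
        row: dict[str, float] = {"t_seconds": state.t, "t_days": state.t / 86400.0}
        for name in ("Ca", "Ch", "Co"):
            val = getattr(state, name, None)
            if val is not None:
                row[f"{name}_min"] = float(np.min(val))
                row[f"{name}_max"] = float(np.max(val))
                row[f"{name}_mean"] = float(np.mean(val))
        co = getattr(state, "Co", None)
        bones = getattr(state, "bones", None)
        if bones is not None:
            co = bones.total_Co()
            for i in range(bones.n_bones):
                row[f"bone_{i + 1:02d}_area"] = float(
                    mesh.cell_areas[bone_mask(bones.Co[i], threshold)].sum()
                )
            if bones.n_bones >= 2:
                for (a, b), gap in suture_gap(bones, mesh, threshold).items():
                    row[f"gap_{a:02d}_{b:02d}"] = gap
        if co is not None:
            row["n_regions"] = count_regions(
                bone_mask(co, threshold), mesh, threshold
            ).n_regions
        rows.append(row)
    return pd.DataFrame(rows)
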