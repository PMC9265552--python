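"""Village service areas and village→raster transfer.

Village-scale registries attach cases to settlement points, not polygons.
Following standard GIS practice for such data, each village's service area
is its Voronoi cell clipped to the county boundary; raster cells are owned
by the village whose point is nearest to the cell center, which for points
inside the county is exactly Voronoi ownership.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint, Point, Polygon

from .grids import GridSpec, Surface

__all__ = ["VillagePartition", "build_voronoi", "rasterize_by_village"]


@dataclass
class VillagePartition:
    """Voronoi tessellation of a county by its village points.

    Attributes
    ----------
    village_ids : list
        Stable village identifiers, aligned with ``points``.
    points : (n, 2) ndarray
        Village coordinates in projected meters.
    polygons : dict
        village_id -> shapely Polygon (Voronoi cell ∩ county boundary).
    boundary : shapely Polygon
        The county outline.
    """

    village_ids: list
    points: np.ndarray
    polygons: dict
    boundary: Polygon

    def cell_index(self, grid: GridSpec) -> np.ndarray:
        """Owning-village index per raster cell (nearest generator).

        Returns an int array of grid shape holding positions into
        ``village_ids``; cells outside the boundary get -1.
        """
        X, Y = grid.center_arrays()
        pts = np.column_stack([X.ravel(), Y.ravel()])
        tree = cKDTree(self.points)
        _, owner = tree.query(pts)
        inside = shapely.contains_xy(self.boundary, pts[:, 0], pts[:, 1])
        owner = np.where(inside, owner, -1)
        return owner.reshape(grid.shape)


def build_voronoi(points, boundary: Polygon, village_ids=None) -> VillagePartition:
    """Clipped Voronoi tessellation of ``boundary`` by village ``points``.

    Raises ``ValueError`` on duplicate coordinates or points outside the
    boundary — both indicate corrupt input geodata rather than a recoverable
    condition.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("points must be a non-empty (n, 2) array")
    if village_ids is None:
        village_ids = list(range(len(pts)))
    if len(village_ids) != len(pts):
        raise ValueError("village_ids length mismatch")
    uniq = {(float(x), float(y)) for x, y in pts}
    if len(uniq) != len(pts):
        raise ValueError("duplicate village coordinates")
    if not np.all(shapely.contains_xy(boundary, pts[:, 0], pts[:, 1])):
        raise ValueError("all village points must lie inside the boundary")

    if len(pts) == 1:
        return VillagePartition(
            list(village_ids), pts, {village_ids[0]: Polygon(boundary)}, boundary
        )

    cells = shapely.voronoi_polygons(
        MultiPoint([Point(p) for p in pts]), extend_to=boundary.buffer(1.0)
    )
    # GEOS returns cells in arbitrary order; match each to its generator.
    polygons: dict = {}
    tree = cKDTree(pts)
    for geom in cells.geoms:
        rp = geom.representative_point()
        _, idx = tree.query([rp.x, rp.y])
        clipped = geom.intersection(boundary)
        if clipped.is_empty:
            continue
        vid = village_ids[int(idx)]
        if vid in polygons:  # clipping split never merges generators
            clipped = polygons[vid].union(clipped)
        polygons[vid] = clipped
    return VillagePartition(list(village_ids), pts, polygons, boundary)


def rasterize_by_village(
    values_per_village: dict,
    partition: VillagePartition,
    grid: GridSpec,
    weights: Surface | None = None,
) -> Surface:
    """Spread village totals over raster cells.

    Each village's value is apportioned over the cells it owns in proportion
    to ``weights`` (typically the population surface), so the raster reflects
    where people live rather than polygon area; with ``weights=None`` the
    value is split evenly over the village's cells.  Village and county
    totals are conserved exactly.
    """
    missing = [v for v in partition.village_ids if v not in values_per_village]
    if missing:
        raise ValueError(f"missing values for villages: {missing[:5]}")
    owner = partition.cell_index(grid)
    out = np.zeros(grid.shape)
    if weights is not None:
        if weights.grid != grid:
            raise ValueError("weights surface grid mismatch")
        w = np.nan_to_num(weights.values, nan=0.0)
    else:
        w = np.ones(grid.shape)
    for pos, vid in enumerate(partition.village_ids):
        mask = owner == pos
        val = float(values_per_village[vid])
        if val == 0.0:
            continue
        wsum = w[mask].sum()
        if not mask.any() or wsum <= 0:
            if val != 0.0:
                raise ValueError(
                    f"village {vid} has value {val} but no positive weight cells"
                )
            continue
        out[mask] = val * w[mask] / wsum
    return Surface(grid, out)
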