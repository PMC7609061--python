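"""Oxygen-diffusion proxy metrics of the capillary network.

Geometric surrogates for tissue oxygenation: how far tissue voxels lie from
the nearest vessel (extravascular distance), how densely capillaries cross
the tissue planes (capillary density per mm² of tissue), how far apart
neighbouring capillaries run (intercapillary distance), and the upper tail
of the capillary-only distance distribution (diffusion distance).  Distances
are Euclidean, spacing-weighted, and measured to the vessel phase (zero
inside vessels): the physical oxygen path length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .types import TissueMask
from .phantom import Tube, rasterize_tubes

DIFFUSION_PERCENTILE = 95.0


@dataclass
class DistanceField:
    """Distance-to-vessel field over tissue voxels (µm)."""

    values: np.ndarray          # µm; NaN outside tissue
    source: str                 # "all_vessels" | "capillaries_only"
    max_um: float
    median_um: float

    def to_tiff(self, path) -> None:
        import tifffile
        tifffile.imwrite(path, np.transpose(
            np.nan_to_num(self.values, nan=-1.0).astype(np.float32), (2, 1, 0)))


def extravascular_distance(
    vessel_mask: np.ndarray,
    tissue: TissueMask,
    spacing,
    source: str = "all_vessels",
) -> DistanceField:
    """Euclidean distance of every tissue voxel to the nearest vessel voxel.

    Max and median are taken over tissue voxels outside vessels.  Distance is
    zero inside vessels.
    """
    vessel_mask = np.asarray(vessel_mask, bool)
    if not vessel_mask.any():
        raise ValueError("no vasculature")
    spacing = np.asarray(spacing, float)
    dist = ndi.distance_transform_edt(~vessel_mask, sampling=spacing)
    values = np.where(tissue.mask, dist, np.nan)
    outside = tissue.mask & ~vessel_mask
    if outside.any():
        max_um = float(dist[outside].max())
        median_um = float(np.median(dist[outside]))
    else:
        max_um = median_um = 0.0
    return DistanceField(values=values, source=source,
                         max_um=max_um, median_um=median_um)


def _capillary_edges(graph):
    return [d for _, d in graph.segments() if d.get("is_capillary")]


def capillary_mask_from_graph(graph, shape, spacing) -> np.ndarray:
    """Rasterize the capillary-classified segments back into a voxel mask."""
    tubes = [Tube(points=d["points"], radius=max(float(np.mean(d["radii"])), 1e-3),
                  closed=d["closed"])
             for d in _capillary_edges(graph)]
    if not tubes:
        return np.zeros(shape, dtype=bool)
    return rasterize_tubes(tubes, shape, spacing)


def capillary_density(graph, tissue: TissueMask, spacing) -> float:
    """Capillary crossings per mm² of tissue, averaged over z-planes.

    For each z-plane with tissue, count intersections of capillary
    centerlines with the plane and divide by the tissue area of that plane;
    the reported density is the mean over planes.  Mirrors 2D histology
    capillary counting on transverse planes.
    """
    spacing = np.asarray(spacing, float)
    caps = _capillary_edges(graph)
    nz = tissue.mask.shape[2]
    dens = []
    for k in range(nz):
        area_mm2 = tissue.mask[:, :, k].sum() * spacing[0] * spacing[1] * 1e-6
        if area_mm2 <= 0:
            continue
        z = (k + 0.5) * spacing[2]
        crossings = 0
        for d in caps:
            pts = d["points"]
            if d["closed"]:
                pts = np.vstack([pts, pts[:1]])
            s = pts[:, 2] - z
            crossings += int(np.sum(s[:-1] * s[1:] < 0))
            crossings += int(np.sum(s == 0.0))
        dens.append(crossings / area_mm2)
    if not dens:
        raise ValueError("no tissue in any plane")
    return float(np.mean(dens))


def intercapillary_distance(graph, tissue: TissueMask | None = None,
                            spacing=None) -> float | None:
    """Mean nearest-neighbour distance between distinct capillaries (µm).

    For every capillary centerline point, the distance to the nearest
    centerline point of a *different* capillary segment — segments sharing a
    graph node are excluded to avoid trivially zero values at branch points.
    Returns None (missing) with fewer than two capillaries.
    """
    caps = [(sid, d, (u, v)) for (sid, d), (u, v, _k) in
            zip(graph.segments(), sorted(graph.g.edges(keys=True)))
            if d.get("is_capillary")]
    if len(caps) < 2:
        return None
    dists = []
    for i, (sid, d, nodes_i) in enumerate(caps):
        other_pts = [dj["points"] for j, (sj, dj, nodes_j) in enumerate(caps)
                     if j != i and not set(nodes_i) & set(nodes_j)]
        if not other_pts:
            continue
        tree = cKDTree(np.vstack(other_pts))
        dd, _ = tree.query(d["points"], workers=-1)
        dists.append(dd)
    if not dists:
        return None
    return float(np.mean(np.concatenate(dists)))


def diffusion_distance(field: DistanceField,
                       percentile: float = DIFFUSION_PERCENTILE) -> float:
    """Upper-tail extravascular distance to capillaries (µm).

    Defined here as the `percentile` (default 95th) of the capillary-only
    extravascular distance distribution over tissue voxels: the distance
    oxygen must cover to reach the worst-supplied few percent of tissue.
    """
    vals = field.values[np.isfinite(field.values)]
    vals = vals[vals > 0]
    if vals.size == 0:
        return 0.0
    return float(np.percentile(vals, percentile))
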