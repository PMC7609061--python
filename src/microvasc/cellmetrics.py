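"""Cell- and mural-coverage metrics.

Nuclei are detected in the DAPI channel and classified by their relation to
the vasculature: endothelial (inside a vessel), SMA+ perivascular (SMA
signal, within the adjacency threshold of a vessel surface — pericytes and
vascular smooth muscle), and myofibroblast (SMA+ but away from vessels).
Vessel-wall metrics quantify the SMA sheath: fraction of vessels covered,
sheath thickness, and a damage index for interrupted mural coverage of
non-capillary vessels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .types import TissueMask
from .preprocess import otsu_multithreshold
from .vasculometry import (VesselGraph, segment_metrics_from_data,
                           sma_coverage_fractions, SIZE_BOUNDS)

PERIVASCULAR_THRESHOLD_UM = 2.0
COVERAGE_CUTOFF = 0.5           # fraction of covered centerline points
NUCLEUS_MIN_VOLUME_UM3 = 4.0    # reject sub-nuclear specks
NUCLEUS_MERGE_FACTOR = 1.25     # blob bigger than this × median ⇒ merged flag
# two nuclei fused at 1 µm separation union to ~1.3 × a single nucleus
# volume; single-nucleus digitization varies by ≲10 %, leaving a margin


@dataclass
class CellRecord:
    centroid: np.ndarray        # (3,) µm
    cell_class: str             # endothelial | sma_perivascular | myofibroblast | other
    distance_to_vessel: float   # µm from vessel surface (0 inside)
    merged: bool = False        # detection flagged as possibly fused nuclei


def detect_nuclei(nuclei_channel: np.ndarray, tissue: TissueMask, spacing,
                  min_volume_um3: float = NUCLEUS_MIN_VOLUME_UM3):
    """Nucleus centroids from the DAPI channel.

    The channel is Otsu-thresholded within tissue (nuclei are the bright
    class over tissue background), connected components are taken as
    nuclei, and abnormally large blobs (>1.8 × median volume) are flagged
    as merged detections.  Returns (centroids µm, merged_flags).
    """
    spacing = np.asarray(spacing, float)
    vals = nuclei_channel[tissue.mask]
    if vals.size == 0 or np.unique(vals).size < 2:
        return [], []
    th = otsu_multithreshold(vals, 2)
    mask = (nuclei_channel >= th[-1]) & tissue.mask
    if not mask.any():
        return [], []
    lab, n = ndi.label(mask, structure=np.ones((3, 3, 3)))
    voxvol = float(np.prod(spacing))
    sizes = ndi.sum_labels(mask, lab, index=np.arange(1, n + 1)) * voxvol
    keep = np.flatnonzero(sizes >= min_volume_um3) + 1
    if keep.size == 0:
        return [], []
    coms = ndi.center_of_mass(mask, lab, index=keep)
    centroids = [(np.asarray(c) + 0.5) * spacing for c in coms]
    med = float(np.median(sizes[keep - 1]))
    merged = [bool(s > NUCLEUS_MERGE_FACTOR * med) for s in sizes[keep - 1]]
    return centroids, merged


def _sma_positive(centroid, sma_channel, sma_threshold, spacing,
                  radius_um=2.0) -> bool:
    """Upper-quartile SMA intensity near the centroid above threshold.

    The quartile tolerates the cell body only partly filling the cubic
    neighbourhood while still requiring a substantial bright fraction.
    """
    spacing = np.asarray(spacing, float)
    shape = np.array(sma_channel.shape)
    lo = np.maximum(((centroid - radius_um) / spacing).astype(int), 0)
    hi = np.minimum(((centroid + radius_um) / spacing).astype(int) + 1, shape)
    block = sma_channel[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    if block.size == 0:
        return False
    return float(np.percentile(block, 75)) > sma_threshold


def classify_cells(centroids, vessel_mask, sma_channel, spacing,
                   adjacency_um: float = PERIVASCULAR_THRESHOLD_UM,
                   tissue: TissueMask | None = None,
                   merged_flags=None,
                   graph: VesselGraph | None = None,
                   tissue_volume_mm3: float | None = None):
    """Assign each nucleus a class and report raw + normalized counts.

    Classes: endothelial — centroid inside the vessel mask; sma_perivascular
    — SMA+ and within `adjacency_um` of a vessel surface; myofibroblast —
    SMA+ and farther; other — SMA−, extravascular.  SMA positivity: mean SMA
    intensity in a 2 µm neighbourhood above the SMA channel's Otsu threshold.

    Normalizations (when denominators are available): per mm³ of tissue, per
    mm of vessel length, per mm³ of vessel volume.
    """
    from .vasculometry import _resample_iso
    spacing = np.asarray(spacing, float)
    vessel_mask = np.asarray(vessel_mask, bool)
    if vessel_mask.any():
        # distance to the vessel on an isotropically resampled grid:
        # anisotropic voxel-center distances overestimate the true
        # surface distance by up to half the coarsest spacing
        iso_mask, eff = _resample_iso(vessel_mask, spacing)
        dist_iso = ndi.distance_transform_edt(~iso_mask, sampling=eff)
    else:
        eff = spacing
        dist_iso = np.full(vessel_mask.shape, np.inf)
    from .vasculometry import _has_foreground
    sma_vals = (sma_channel[tissue.mask] if tissue is not None
                else np.asarray(sma_channel).ravel())
    if np.unique(sma_vals).size >= 2:
        sma_th = float(otsu_multithreshold(sma_vals, 2)[0])
        if not _has_foreground(sma_vals, sma_th):
            sma_th = np.inf  # no real SMA signal anywhere
    else:
        sma_th = np.inf
    shape = np.array(vessel_mask.shape)
    merged_flags = merged_flags or [False] * len(centroids)

    records = []
    for c, mflag in zip(centroids, merged_flags):
        c = np.asarray(c, float)
        idx = tuple(np.clip((c / spacing).astype(int), 0, shape - 1))
        # interpolate the distance field at the exact centroid: plain
        # voxel-center lookup quantizes by up to half the spacing
        if np.isfinite(dist_iso).all():
            coords = (c / np.asarray(eff) - 0.5).reshape(3, 1)
            d = float(ndi.map_coordinates(dist_iso, coords, order=1,
                                          mode="nearest")[0])
        else:
            d = np.inf
        if vessel_mask[idx]:
            cls = "endothelial"
            d = 0.0
        elif _sma_positive(c, sma_channel, sma_th, spacing):
            cls = "sma_perivascular" if d <= adjacency_um else "myofibroblast"
        else:
            cls = "other"
        records.append(CellRecord(centroid=c, cell_class=cls,
                                  distance_to_vessel=d, merged=mflag))

    counts = {k: sum(r.cell_class == k for r in records)
              for k in ("endothelial", "sma_perivascular", "myofibroblast", "other")}
    out = {"records": records, "counts": counts}

    norm = {}
    if tissue_volume_mm3 is not None:
        if tissue_volume_mm3 <= 0:
            raise ValueError("tissue volume must be > 0")
        norm["per_mm3_tissue"] = {k: v / tissue_volume_mm3
                                  for k, v in counts.items()}
    if graph is not None and graph.n_segments > 0:
        length_mm = graph.total_length_um() / 1000.0
        volume_mm3 = sum(segment_metrics_from_data(d).volume
                         for _, d in graph.segments()) * 1e-9
        if length_mm > 0:
            norm["per_mm_vessel_length"] = {k: v / length_mm
                                            for k, v in counts.items()}
        if volume_mm3 > 0:
            norm["per_mm3_vessel_volume"] = {k: v / volume_mm3
                                             for k, v in counts.items()}
    out["normalized"] = norm
    return out


def cell_records_to_csv(records, path) -> None:
    import pandas as pd
    pd.DataFrame([{
        "x_um": r.centroid[0], "y_um": r.centroid[1], "z_um": r.centroid[2],
        "class": r.cell_class, "distance_to_vessel_um": r.distance_to_vessel,
        "merged": r.merged,
    } for r in records]).to_csv(path, index=False)


def sma_coverage(graph: VesselGraph, sma_mask: np.ndarray, spacing,
                 coverage_cutoff: float = COVERAGE_CUTOFF,
                 probe_um: float = 2.0):
    """Percentage of vessels covered with SMA, plus per-segment fractions.

    A segment counts as covered when at least `coverage_cutoff` of its
    centerline points have SMA signal in the annulus just outside the local
    radius.
    """
    if graph.n_segments == 0:
        raise ValueError("empty vessel graph")
    sma_coverage_fractions(graph, sma_mask, spacing, probe_um=probe_um)
    fractions = [d["sma_coverage_fraction"] for _, d in graph.segments()]
    pct = 100.0 * np.mean([f >= coverage_cutoff for f in fractions])
    return float(pct), fractions


def sma_thickness(graph: VesselGraph, sma_mask: np.ndarray, spacing,
                  max_thickness_um: float = 8.0,
                  probe_um: float = 2.0) -> float | None:
    """Mean radial extent of the SMA sheath beyond the vessel radius (µm).

    For each SMA-covered centerline point, SMA voxels within a thin slab
    perpendicular to the local tangent are collected and the sheath outer
    radius is their maximal radial distance; thickness = outer radius −
    vessel radius, averaged over covered points.  Returns None when no point
    is covered.
    """
    spacing = np.asarray(spacing, float)
    sma_mask = np.asarray(sma_mask, bool)
    if not sma_mask.any():
        return None
    sma_idx = np.argwhere(sma_mask)
    sma_pts = (sma_idx + 0.5) * spacing
    from scipy.spatial import cKDTree
    tree = cKDTree(sma_pts)
    if sma_mask.any():
        dist_to_sma = ndi.distance_transform_edt(~sma_mask, sampling=spacing)
    shape = np.array(sma_mask.shape)
    slab_half = float(np.max(spacing)) / 2 + 1e-6

    thicknesses = []
    for _, d in graph.segments():
        pts, rr = d["points"], d["radii"]
        for i in range(len(pts)):
            idx = tuple(np.clip((pts[i] / spacing).astype(int), 0, shape - 1))
            if dist_to_sma[idx] > rr[i] + probe_um:
                continue  # not covered here
            # local tangent
            j0, j1 = max(i - 1, 0), min(i + 1, len(pts) - 1)
            tang = pts[j1] - pts[j0]
            tn = np.linalg.norm(tang)
            if tn < 1e-9:
                continue
            tang /= tn
            cand = tree.query_ball_point(pts[i], rr[i] + max_thickness_um)
            if not cand:
                continue
            rel = sma_pts[cand] - pts[i]
            axial = rel @ tang
            in_slab = np.abs(axial) <= slab_half
            if not in_slab.any():
                continue
            radial = np.linalg.norm(rel[in_slab] - np.outer(axial[in_slab], tang),
                                    axis=1)
            # 90th percentile: robust to digitization spikes and stray SMA
            outer = float(np.percentile(radial, 90))
            thicknesses.append(max(outer - rr[i], 0.0))
    if not thicknesses:
        return None
    return float(np.mean(thicknesses))


def damage_index(graph: VesselGraph,
                 coverage_cutoff: float = COVERAGE_CUTOFF) -> float | None:
    """Fraction of non-capillary vessels with interrupted mural coverage.

    Computed over segments of mean diameter > 3 µm: the share whose SMA
    coverage fraction falls below `coverage_cutoff`.  An in-house
    operational definition (the quantity is inherited from an external
    pipeline without a published formula); returns None when no
    non-capillary segments exist.
    """
    fractions = []
    for _, d in graph.segments():
        if "sma_coverage_fraction" not in d:
            raise ValueError("run sma_coverage / classify_vessels first")
        m = segment_metrics_from_data(d)
        if m.mean_diameter > SIZE_BOUNDS[0]:
            fractions.append(d["sma_coverage_fraction"])
    if not fractions:
        return None
    return float(np.mean([f < coverage_cutoff for f in fractions]))
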