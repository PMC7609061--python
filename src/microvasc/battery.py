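"""Ground-truth phantom battery.

Runs the full pipeline against phantoms whose geometry is known in closed
form and reports the recovered quantities next to their analytic values.
Every number is recomputed from scratch at call time; nothing is cached.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import phantom as ph
from . import preprocess, vasculometry, perfusion, cellmetrics, scores
from .types import TissueMask


def _graph_for(tubes, size, spacing, seed, noise=None):
    spec = ph.PhantomSpec(volume_size=size, spacing=spacing, tubes=tubes)
    img, truth = ph.generate_vascular_phantom(spec, noise=noise, seed=seed)
    tissue = TissueMask(mask=np.ones(img.shape, dtype=bool))
    vessel = vasculometry.segment_channel(
        img.channels["vessel"], tissue=tissue, spacing=spacing)
    graph = vasculometry.skeletonize_and_graph(vessel, spacing)
    return img, truth, tissue, vessel, graph


def run_battery(seed: int = 1) -> dict:
    """Recover the analytic phantom quantities; returns name → {value, n}."""
    rng = np.random.default_rng(seed)
    out: dict[str, dict] = {}

    def rec(name, value, n):
        out[name] = {"value": float(value), "n": int(n)}

    # --- straight cylinder r=2 µm, L=50 µm in 50³ µm³ at 0.5 µm spacing
    img, truth, tissue, vessel, g = _graph_for(
        [ph.straight_tube((0, 25, 25), (50, 25, 25), 2.0)],
        (50, 50, 50), (0.5, 0.5, 0.5), seed)
    m = vasculometry.segment_metrics(g, 0)
    vol_d, _ = vasculometry.minkowski_densities(vessel, tissue, img.spacing)
    n_vox = int(np.prod(img.shape))
    rec("cylinder_length_um", m.length, n_vox)                  # analytic 50
    rec("cylinder_tortuosity", m.tortuosity, n_vox)             # analytic 1.0
    rec("cylinder_mean_diameter_um", m.mean_diameter, n_vox)    # analytic 4.0
    rec("cylinder_volume_density_pct", vol_d, n_vox)            # analytic 0.503

    # --- Y junction topology
    _, _, _, _, gy = _graph_for(
        ph.y_junction((5, 25, 25), (25, 25, 25), (45, 10, 25), (45, 40, 25), 2.0),
        (50, 50, 50), (0.5, 0.5, 0.5), seed + 1)
    rec("y_junction_segments", gy.n_segments, n_vox)            # 3
    rec("y_junction_branching_nodes", gy.n_branching, n_vox)    # 1
    rec("y_junction_blind_ends", gy.n_blind_ends, n_vox)        # 3

    # --- ring (closed loop) R = 15 µm
    _, _, _, _, gr = _graph_for(
        [ph.ring_tube((25, 25, 25), 15.0, 2.0)],
        (50, 50, 50), (0.5, 0.5, 0.5), seed + 2)
    rec("ring_blind_ends", gr.n_blind_ends, n_vox)              # 0
    rec("ring_cycle_length_um", gr.total_length_um(), n_vox)    # 2π·15 = 94.25

    # --- semicircular arc tortuosity
    _, _, _, _, ga = _graph_for(
        [ph.arc_tube((25, 10, 25), 15.0, 2.0, 0.0, np.pi, plane="xy")],
        (50, 50, 50), (0.5, 0.5, 0.5), seed + 3)
    ma = vasculometry.segment_metrics(ga, 0)
    rec("arc_tortuosity", ma.tortuosity, n_vox)                 # π/2 = 1.571

    # --- extravascular distance vs brute force on a small grid
    shape, sp = (24, 20, 16), (0.5, 0.6, 0.7)
    vm = np.zeros(shape, dtype=bool)
    vm[5:9, 4:8, 3:7] = True
    vm[15:18, 12:16, 8:12] = True
    tis = TissueMask(mask=np.ones(shape, dtype=bool))
    fld = perfusion.extravascular_distance(vm, tis, sp)
    vpts = (np.argwhere(vm) + 0.5) * np.asarray(sp)
    centers = (np.indices(shape).reshape(3, -1).T + 0.5) * np.asarray(sp)
    from scipy.spatial import cKDTree
    brute, _ = cKDTree(vpts).query(centers, workers=-1)
    brute = np.where(vm.ravel(), 0.0, brute).reshape(shape)
    rec("distance_oracle_max_abs_error_um",
        float(np.nanmax(np.abs(fld.values - brute))), int(np.prod(shape)))

    # --- capillary grid: intercapillary distance equals the pitch
    pitch = 8.0
    tubes = ph.parallel_grid(pitch=pitch, radius=1.0,
                             volume_size=(48, 48, 15), axis=2)
    img_g, _, tis_g, ves_g, gg = _graph_for(
        tubes, (48, 48, 15), (0.5, 0.5, 1.5), seed + 4)
    vasculometry.classify_vessels(gg, np.zeros(img_g.shape, bool), img_g.spacing)
    icd = perfusion.intercapillary_distance(gg)
    rec("grid_intercapillary_distance_um", icd, int(np.prod(img_g.shape)))  # 8
    rec("grid_capillary_density_per_mm2",
        perfusion.capillary_density(gg, tis_g, img_g.spacing),
        int(np.prod(img_g.shape)))  # n_tubes / area = 36 / 0.002304 mm²

    # --- classification partition + capillary rule on a mixed phantom:
    # 8 bare capillaries (diameter 2.4 µm) and 2 SMA-sheathed arterioles
    # (diameter 5 µm), spaced so no sheath reaches a foreign vessel
    mix = [ph.straight_tube((2, 4 + 4 * i, 7.5), (46, 4 + 4 * i, 7.5), 1.2)
           for i in range(8)]
    mix += [ph.straight_tube((2, 42, 4.0), (46, 42, 4.0), 2.5, sma=True),
            ph.straight_tube((2, 42, 11.0), (46, 42, 11.0), 2.5, sma=True)]
    img_m, truth_m, tis_m, ves_m, gm = _graph_for(
        mix, (48, 48, 15), (0.5, 0.5, 0.5), seed + 5)
    sma_m = vasculometry.segment_channel(img_m.channels["sma"], tissue=tis_m,
                                         spacing=img_m.spacing)
    cls = vasculometry.classify_vessels(gm, sma_m, img_m.spacing)
    rec("mixed_size_class_percent_sum",
        sum(cls["size_class_percent"].values()), gm.n_segments)   # 100
    rec("mixed_capillary_percent",
        100.0 * cls["n_capillaries"] / gm.n_segments, gm.n_segments)  # 80

    # --- cell classification recovery
    cell_tubes = [ph.straight_tube((5, 12, 7.5), (43, 12, 7.5), 2.0, sma=True),
                  ph.straight_tube((5, 36, 7.5), (43, 36, 7.5), 1.2)]
    spec_c = ph.PhantomSpec(
        volume_size=(48, 48, 15), spacing=(0.5, 0.5, 1.5), tubes=cell_tubes,
        n_nuclei={"endothelial": 5, "sma_perivascular": 3,
                  "myofibroblast": 4, "other": 2})
    img_c, truth_c = ph.generate_vascular_phantom(spec_c, seed=seed + 6)
    tis_c = TissueMask(mask=np.ones(img_c.shape, dtype=bool))
    ves_c = vasculometry.segment_channel(img_c.channels["vessel"],
                                         tissue=tis_c, spacing=img_c.spacing)
    cents, merged = cellmetrics.detect_nuclei(img_c.channels["nuclei"],
                                              tis_c, img_c.spacing)
    tvol_mm3 = tis_c.volume_um3(img_c.spacing) * 1e-9
    res = cellmetrics.classify_cells(cents, ves_c, img_c.channels["sma"],
                                     img_c.spacing, tissue=tis_c,
                                     merged_flags=merged,
                                     tissue_volume_mm3=tvol_mm3)
    counts = res["counts"]
    rec("cells_endothelial_count", counts["endothelial"], len(cents))   # 5
    rec("cells_perivascular_count", counts["sma_perivascular"], len(cents))  # 3
    rec("cells_myofibroblast_count", counts["myofibroblast"], len(cents))    # 4
    norm = res["normalized"]["per_mm3_tissue"]["endothelial"]
    rec("cells_normalization_consistency",
        norm * tvol_mm3 / max(counts["endothelial"], 1), len(cents))    # 1.0

    # --- closed-form scores
    rec("wmsi_all_normal",
        scores.wmsi(scores.SegmentScoreTable([1] * 12)), 12)            # 1.0
    rec("wmsi_half_akinetic",
        scores.wmsi(scores.SegmentScoreTable([1] * 6 + [3] * 6)), 12)   # 2.0
    rec("infarct_size_half_pct", scores.echo_infarct_size(
        scores.SegmentScoreTable([1] * 6 + [2, 3, 4, 2, 3, 4])), 12)    # 50
    fs0 = ph.generate_flow_sample(100.0, 100.0, 10.0, n=10000,
                                  seed=int(rng.integers(2**31)))
    rec("smfi_equal_medians", scores.standardized_mfi(fs0), 10000)      # 0
    fs4 = ph.generate_flow_sample(500.0, 100.0, 50.0, n=10000,
                                  seed=int(rng.integers(2**31)))
    rec("smfi_shifted", scores.standardized_mfi(fs4), 10000)            # 4.0
    shg_img, zone = ph.generate_shg_texture((256, 256), 0.30,
                                            seed=int(rng.integers(2**31)))
    rec("shg_area_fraction_pct",
        scores.shg_metrics(shg_img, zone).pct_shg, int(zone.sum()))     # 30

    # --- determinism: identical seeds give bit-identical volumes
    spec_d = ph.PhantomSpec(
        volume_size=(30, 30, 12), spacing=(0.5, 0.5, 1.5),
        tubes=[ph.straight_tube((2, 15, 6), (28, 15, 6), 1.5)],
        n_nuclei={"other": 2})
    na = ph.NoiseParams(gaussian_sigma=4.0)
    im1, _ = ph.generate_vascular_phantom(spec_d, noise=na, seed=seed + 7)
    im2, _ = ph.generate_vascular_phantom(spec_d, noise=na, seed=seed + 7)
    identical = all(np.array_equal(im1.channels[c], im2.channels[c])
                    for c in im1.channels)
    rec("phantom_determinism", 1.0 if identical else 0.0,
        int(np.prod(im1.shape)))

    # --- monotonicity: adding vessel voxels never increases distances
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        vm_small = vm
        vm_big = vm_small.copy()
        vm_big[10:13, 10:13, 10:13] = True
        f_small = perfusion.extravascular_distance(vm_small, tis, sp)
        f_big = perfusion.extravascular_distance(vm_big, tis, sp)
        mono = (f_big.max_um <= f_small.max_um + 1e-9
                and f_big.median_um <= f_small.median_um + 1e-9)
    rec("distance_monotonicity", 1.0 if mono else 0.0, int(np.prod(shape)))

    return out
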