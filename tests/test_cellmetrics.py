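"""Nucleus detection/classification and SMA wall metrics on phantoms."""

import numpy as np
import pytest

import microvasc as mv
from microvasc import cellmetrics
from microvasc.types import TissueMask

from conftest import graph_from_tubes, full_tissue


@pytest.fixture(scope="module")
def classified(cell_phantom):
    img, truth = cell_phantom
    tissue = full_tissue(img.shape)
    vessel = mv.segment_channel(img.channels["vessel"], tissue=tissue,
                                spacing=img.spacing)
    centroids, merged = mv.detect_nuclei(img.channels["nuclei"], tissue,
                                         img.spacing)
    tvol = tissue.volume_um3(img.spacing) * 1e-9
    graph = mv.skeletonize_and_graph(vessel, img.spacing)
    res = mv.classify_cells(centroids, vessel, img.channels["sma"],
                            img.spacing, tissue=tissue, merged_flags=merged,
                            graph=graph, tissue_volume_mm3=tvol)
    return img, truth, centroids, res, tvol, graph


def test_detection_recall_and_precision(classified):
    img, truth, centroids, *_ = classified
    gt = np.array(truth.nuclei_positions)
    det = np.array(centroids)
    assert len(det) == len(gt)
    # every truth nucleus matched within 2 µm
    from scipy.spatial import cKDTree
    d, _ = cKDTree(det).query(gt)
    assert (d <= 2.0).all()


def test_class_counts_recover_truth_exactly(classified):
    _, truth, _, res, *_ = classified
    from collections import Counter
    want = Counter(truth.nuclei_classes)
    got = res["counts"]
    assert got["endothelial"] == want["endothelial"]
    assert got["sma_perivascular"] == want["sma_perivascular"]
    assert got["myofibroblast"] == want["myofibroblast"]


def test_class_partition_is_exclusive(classified):
    res = classified[3]
    for r in res["records"]:
        assert r.cell_class in ("endothelial", "sma_perivascular",
                                "myofibroblast", "other")
        if r.cell_class == "endothelial":
            assert r.distance_to_vessel == 0.0
        if r.cell_class == "sma_perivascular":
            assert r.distance_to_vessel <= cellmetrics.PERIVASCULAR_THRESHOLD_UM
        if r.cell_class == "myofibroblast":
            assert r.distance_to_vessel > cellmetrics.PERIVASCULAR_THRESHOLD_UM


def test_normalizations_consistent_with_raw_counts(classified):
    _, _, _, res, tvol, graph = classified
    counts = res["counts"]
    norm = res["normalized"]
    for cls, n in counts.items():
        assert norm["per_mm3_tissue"][cls] * tvol == pytest.approx(n)
    length_mm = graph.total_length_um() / 1000
    for cls, n in counts.items():
        assert norm["per_mm_vessel_length"][cls] * length_mm == pytest.approx(n)


def test_unit_convention_62_cells_per_microliter():
    """62 cells in 10⁻³ mm³ → 6.2 × 10⁴ per mm³."""
    rng = np.random.default_rng(0)
    centroids = list(rng.uniform(1, 9, size=(62, 3)))
    res = mv.classify_cells(centroids, np.zeros((20, 20, 20), bool),
                            np.zeros((20, 20, 20)), (0.5, 0.5, 0.5),
                            tissue_volume_mm3=1e-3)
    total = sum(res["normalized"]["per_mm3_tissue"].values())
    assert total == pytest.approx(6.2e4)


def test_no_sma_signal_means_no_mural_classes():
    rng = np.random.default_rng(1)
    centroids = list(rng.uniform(2, 8, size=(5, 3)))
    res = mv.classify_cells(centroids, np.zeros((20, 20, 20), bool),
                            rng.normal(8, 2, (20, 20, 20)), (0.5, 0.5, 0.5))
    assert res["counts"]["sma_perivascular"] == 0
    assert res["counts"]["myofibroblast"] == 0


def test_merged_nuclei_flagged():
    """Two nuclei 1 µm apart fuse into one oversized detection."""
    spec = mv.PhantomSpec(volume_size=(30, 30, 12), spacing=(0.5, 0.5, 1.5),
                          tubes=[], n_nuclei={"other": 6})
    img, truth = mv.generate_vascular_phantom(spec, seed=8)
    # paint an extra nucleus 1 µm from the first one
    from microvasc.phantom import _rasterize_spheres, NUCLEUS_RADIUS_UM
    p = truth.nuclei_positions[0] + np.array([1.0, 0, 0])
    extra = _rasterize_spheres([p], NUCLEUS_RADIUS_UM, img.shape, img.spacing)
    img.channels["nuclei"][extra] = 220.0
    tissue = full_tissue(img.shape)
    cents, merged = mv.detect_nuclei(img.channels["nuclei"], tissue,
                                     img.spacing)
    assert len(cents) == 6          # fused pair detected once
    assert any(merged)


@pytest.fixture(scope="module")
def sheathed():
    tubes = [mv.straight_tube((0, 12, 10), (40, 12, 10), 2.0, sma=True),
             mv.straight_tube((0, 28, 10), (40, 28, 10), 2.0)]
    return graph_from_tubes(tubes, size=(40, 40, 20),
                            spacing=(0.5, 0.5, 0.5), seed=12)


class TestSmaWall:
    def test_half_of_segments_covered(self, sheathed):
        img, truth, tissue, vessel, g = sheathed
        sma = mv.segment_channel(img.channels["sma"], tissue=tissue,
                                 spacing=img.spacing)
        pct, fractions = mv.sma_coverage(g, sma, img.spacing)
        assert pct == pytest.approx(50.0)
        assert max(fractions) > 0.9 and min(fractions) < 0.1

    def test_thickness_recovers_annulus(self, sheathed):
        img, truth, tissue, vessel, g = sheathed
        sma = mv.segment_channel(img.channels["sma"], tissue=tissue,
                                 spacing=img.spacing)
        th = mv.sma_thickness(g, sma, img.spacing)
        assert th == pytest.approx(1.5, abs=0.75)  # ±½ voxel + digitization

    def test_thickness_scales_with_annulus(self):
        def measure(t):
            tube = mv.straight_tube((0, 20, 10), (40, 20, 10), 2.0,
                                    sma=True, sheath_thickness=t)
            img, truth, tissue, vessel, g = graph_from_tubes(
                [tube], size=(40, 40, 20), spacing=(0.5, 0.5, 0.5), seed=13)
            sma = mv.segment_channel(img.channels["sma"], tissue=tissue,
                                     spacing=img.spacing)
            return mv.sma_thickness(g, sma, img.spacing)
        assert measure(3.0) == pytest.approx(2 * measure(1.5), rel=0.25)

    def test_no_sma_gives_missing_thickness(self):
        img, truth, tissue, vessel, g = graph_from_tubes(
            [mv.straight_tube((0, 20, 10), (40, 20, 10), 2.0)],
            size=(40, 40, 20), spacing=(0.5, 0.5, 0.5), seed=14)
        assert mv.sma_thickness(g, np.zeros(img.shape, bool),
                                img.spacing) is None
        with pytest.raises(ValueError):
            mv.sma_coverage(mv.VesselGraph(), np.zeros(img.shape, bool),
                            img.spacing)

    def test_partial_sheath_not_counted_covered(self):
        tube = mv.straight_tube((0, 20, 10), (40, 20, 10), 2.0,
                                sma=True, sma_fraction=0.3)
        img, truth, tissue, vessel, g = graph_from_tubes(
            [tube], size=(40, 40, 20), spacing=(0.5, 0.5, 0.5), seed=15)
        sma = mv.segment_channel(img.channels["sma"], tissue=tissue,
                                 spacing=img.spacing)
        pct, fractions = mv.sma_coverage(g, sma, img.spacing)
        assert pct == 0.0
        assert 0.1 < fractions[0] < 0.5


class TestDamageIndex:
    def _graph(self, fractions, seed):
        """Arterioles (diameter 5 µm) with given sheath fractions."""
        tubes = [mv.straight_tube((0, 8 + 8 * i, 10), (48, 8 + 8 * i, 10),
                                  2.5, sma=True, sma_fraction=f)
                 for i, f in enumerate(fractions)]
        img, truth, tissue, vessel, g = graph_from_tubes(
            tubes, size=(48, 48, 20), spacing=(0.5, 0.5, 0.5), seed=seed)
        sma = mv.segment_channel(img.channels["sma"], tissue=tissue,
                                 spacing=img.spacing)
        mv.classify_vessels(g, sma, img.spacing)
        return g

    def test_fully_sheathed_gives_zero(self):
        g = self._graph([1.0, 1.0, 1.0], seed=16)
        assert mv.damage_index(g) == 0.0

    def test_one_in_five_unsheathed_gives_point_two(self):
        g = self._graph([1.0, 1.0, 1.0, 1.0, 0.0], seed=17)
        assert mv.damage_index(g) == pytest.approx(0.2)

    def test_capillaries_only_flagged_missing(self, grid_case):
        img, truth, tissue, vessel, g = grid_case
        mv.classify_vessels(g, np.zeros(img.shape, bool), img.spacing)
        assert mv.damage_index(g) is None


def test_cell_records_csv(tmp_path, classified):
    res = classified[3]
    path = tmp_path / "cells.csv"
    cellmetrics.cell_records_to_csv(res["records"], path)
    import pandas as pd
    df = pd.read_csv(path)
    assert len(df) == len(res["records"])
    assert set(df["class"]) <= {"endothelial", "sma_perivascular",
                                "myofibroblast", "other"}
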