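"""Pipeline orchestration, report serialization, aggregation, CLI."""

import json
import warnings

import numpy as np
import pytest
import yaml

import microvasc as mv
from microvasc.report import (REPORT_ROWS, MetricReport, aggregate_reports,
                              aggregate_subjects, read_report, run_pipeline,
                              write_report)


@pytest.fixture(scope="module")
def phantom_image():
    tubes = [mv.straight_tube((5, 20, 7.5), (75, 20, 7.5), 2.5, sma=True),
             mv.straight_tube((5, 45, 7.5), (75, 45, 7.5), 1.2),
             mv.straight_tube((5, 60, 7.5), (75, 60, 7.5), 1.2)]
    spec = mv.PhantomSpec(
        volume_size=(100, 80, 15), spacing=(0.5, 0.5, 1.5), tubes=tubes,
        tissue_fraction=0.8,
        n_nuclei={"endothelial": 5, "sma_perivascular": 3,
                  "myofibroblast": 4, "other": 2})
    img, truth = mv.generate_vascular_phantom(spec, seed=3)
    return img, truth


@pytest.fixture(scope="module")
def report(phantom_image):
    img, _ = phantom_image
    return run_pipeline({"image": img})


def test_every_report_row_present_once(report):
    names = [n for n, _, _ in REPORT_ROWS]
    assert list(report.entries) == names
    assert len(set(names)) == len(names)


def test_report_values_match_phantom_truth(report, phantom_image):
    img, truth = phantom_image
    tvol = truth.tissue_volume_um3()
    # compare against the digitized truth mask: near-resolution capillaries
    # at 1.5 µm optical sections digitize coarsely, so the voxelized truth —
    # not the continuous capsule volume — is the right reference
    from microvasc.phantom import Tube, rasterize_tubes
    tubes = [Tube(points=c, radius=float(np.mean(r)))
             for c, r in zip(truth.centerlines, truth.radii)]
    digitized = rasterize_tubes(tubes, img.shape, img.spacing)
    digitized_density = 100 * digitized.sum() * img.voxel_volume / tvol
    assert report.value("vascular_volume_density") == pytest.approx(
        digitized_density, rel=0.05)
    assert report.value("endothelial_cells") * tvol * 1e-9 == pytest.approx(5)
    assert report.value("myofibroblasts") * tvol * 1e-9 == pytest.approx(4)
    assert report.value("sma_perivascular_cells") * tvol * 1e-9 == \
        pytest.approx(3)
    assert report.value("vessels_covered_with_sma") == pytest.approx(100 / 3,
                                                                     rel=0.01)


def test_rerun_is_deterministic(report, phantom_image):
    img, _ = phantom_image
    rep2 = run_pipeline({"image": img})
    for k, e in report.entries.items():
        assert (e.value == rep2.entries[k].value
                or (e.value is None and rep2.entries[k].value is None))


def test_empty_vasculature_flags_instead_of_crashing():
    spec = mv.PhantomSpec(volume_size=(40, 40, 12), spacing=(0.5, 0.5, 1.5),
                          tubes=[], n_nuclei={"other": 3})
    img, _ = mv.generate_vascular_phantom(
        spec, noise=mv.NoiseParams(gaussian_sigma=3.0), seed=4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = run_pipeline({"image": img})
    assert rep.value("vascular_volume_density") == 0.0
    vascular = ("tortuosity", "vascular_segments", "intercapillary_distance",
                "diffusion_distance")
    for name in vascular:
        assert rep.entries[name].missing
        assert rep.entries[name].reason


def test_parameters_echoed_for_provenance(report):
    assert report.parameters["adjacency_um"] == 2.0
    assert report.parameters["sma_negativity_cutoff"] == 0.1


@pytest.mark.parametrize("fmt", ["json", "csv"])
def test_write_read_round_trip(report, tmp_path, fmt):
    path = tmp_path / f"report.{fmt}"
    write_report(report, path, fmt=fmt)
    back = read_report(path, fmt=fmt)
    for k, e in report.entries.items():
        b = back.entries[k]
        assert (b.value == pytest.approx(e.value) if e.value is not None
                else b.value is None)
        assert b.missing == e.missing
        assert b.units == e.units
        assert b.normalization == e.normalization
    assert back.parameters == json.loads(json.dumps(report.parameters))


def test_csv_column_order_is_fixed(report, tmp_path):
    path = tmp_path / "report.csv"
    write_report(report, path, fmt="csv")
    header = path.read_text().splitlines()[0]
    assert header == "name,value,units,normalization,missing,reason,provenance"


def test_unknown_format_rejected(report, tmp_path):
    with pytest.raises(ValueError):
        write_report(report, tmp_path / "x.bin", fmt="xml")


def test_missing_entries_require_reason():
    rep = MetricReport()
    with pytest.raises(ValueError):
        rep.add("x", None, "um", missing=True)


def test_aggregation_is_batch_associative(report):
    r = report
    batched = aggregate_reports([aggregate_reports([r, r]), r])
    flat = aggregate_reports([r, r, r])
    for k in r.entries:
        a, b = batched.entries[k].value, flat.entries[k].value
        assert (a is None and b is None) or a == pytest.approx(b)
    two_level = aggregate_subjects({"m1": [r, r], "m2": [r]})
    for k in r.entries:
        v = two_level.entries[k].value
        assert v == r.entries[k].value or (
            v is None and r.entries[k].value is None)


def test_cli_run_and_phantom(tmp_path, phantom_image):
    from click.testing import CliRunner
    from microvasc.cli import main
    img, _ = phantom_image
    stack = tmp_path / "stack.tiff"
    img.to_tiff(stack)
    cfg = tmp_path / "cfg.yaml"
    cfg.write_text(yaml.safe_dump({"input": str(stack)}))
    out = tmp_path / "report.json"
    runner = CliRunner()
    res = runner.invoke(main, ["run", "--config", str(cfg),
                               "--out", str(out)])
    assert res.exit_code == 0, res.output
    rep = read_report(out)
    assert rep.value("vascular_volume_density") > 0

    spec = {"volume_size": [30, 30, 12], "spacing": [0.5, 0.5, 1.5],
            "tubes": [{"kind": "straight", "p0": [2, 15, 6],
                       "p1": [28, 15, 6], "radius": 1.5}],
            "n_nuclei": {"other": 2}}
    sp = tmp_path / "spec.yaml"
    sp.write_text(yaml.safe_dump(spec))
    res = runner.invoke(main, ["phantom", "--spec", str(sp), "--seed", "2",
                               "--out", str(tmp_path / "ph")])
    assert res.exit_code == 0, res.output
    assert (tmp_path / "ph" / "phantom.tiff").exists()
    assert (tmp_path / "ph" / "truth.json").exists()
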