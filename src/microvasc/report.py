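"""End-to-end pipeline orchestration and the metric report.

``run_pipeline`` chains preprocess → vasculometry → perfusion → cellmetrics
over one multi-channel volume and emits a :class:`MetricReport`: the full
battery of named microvasculature metrics, each with value, units,
normalization denominator and provenance.  Reports serialize losslessly to
JSON or CSV, and multi-image studies aggregate by averaging within subject
and then across subjects.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field, asdict

import numpy as np

from .types import VolumetricImage, TissueMask
from . import preprocess, vasculometry, perfusion, cellmetrics

log = logging.getLogger("microvasc")

NORMALIZATIONS = ("none", "per_mm3_tissue", "per_mm_vessel_length",
                  "per_mm2_tissue", "per_mm3_vessel_volume")

# (name, units, normalization) — the full report row battery
REPORT_ROWS = [
    ("vascular_volume_density", "%", "none"),
    ("vascular_surface_area_density", "um2/um3", "none"),
    ("vascular_segment_length", "um", "none"),
    ("vascular_segment_surface", "um2", "none"),
    ("vascular_segment_volume", "um3", "none"),
    ("tortuosity", "um/um", "none"),
    ("vascular_segments", "count", "per_mm3_tissue"),
    ("vascular_segments_per_length", "count", "per_mm_vessel_length"),
    ("vessels_diameter_le3_pct", "%", "none"),
    ("vessels_diameter_3to6_pct", "%", "none"),
    ("vessels_diameter_gt6_pct", "%", "none"),
    ("branching_nodes", "count", "per_mm3_tissue"),
    ("blind_ends", "count", "per_mm3_tissue"),
    ("branching_nodes_per_length", "count", "per_mm_vessel_length"),
    ("blind_ends_per_length", "count", "per_mm_vessel_length"),
    ("vessels_covered_with_sma", "%", "none"),
    ("sma_layer_thickness", "um", "none"),
    ("damage_index", "dimensionless", "none"),
    ("myofibroblasts", "count", "per_mm3_tissue"),
    ("myofibroblasts_per_length", "count", "per_mm_vessel_length"),
    ("myofibroblasts_per_vessel_volume", "count", "per_mm3_vessel_volume"),
    ("sma_perivascular_cells", "count", "per_mm3_tissue"),
    ("sma_perivascular_cells_per_length", "count", "per_mm_vessel_length"),
    ("sma_perivascular_cells_per_vessel_volume", "count", "per_mm3_vessel_volume"),
    ("maximal_extravascular_distance", "um", "none"),
    ("median_extravascular_distance", "um", "none"),
    ("capillary_density", "count", "per_mm2_tissue"),
    ("intercapillary_distance", "um", "none"),
    ("diffusion_distance", "um", "none"),
    ("endothelial_cells", "count", "per_mm3_tissue"),
    ("endothelial_cells_per_length", "count", "per_mm_vessel_length"),
    ("endothelial_cells_per_vessel_volume", "count", "per_mm3_vessel_volume"),
]

CSV_COLUMNS = ["name", "value", "units", "normalization", "missing", "reason",
               "provenance"]


@dataclass
class MetricEntry:
    name: str
    value: float | None
    units: str
    normalization: str = "none"
    provenance: str = ""
    missing: bool = False
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.missing and not self.reason:
            raise ValueError("missing entries must carry a reason")


@dataclass
class MetricReport:
    entries: dict[str, MetricEntry] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def add(self, name, value, units, normalization="none", provenance="",
            missing=False, reason=None) -> None:
        if name in self.entries:
            raise ValueError(f"duplicate metric {name!r}")
        if value is not None:
            value = float(value)
        self.entries[name] = MetricEntry(
            name=name, value=value, units=units, normalization=normalization,
            provenance=provenance, missing=missing, reason=reason)

    def __getitem__(self, name) -> MetricEntry:
        return self.entries[name]

    def value(self, name) -> float | None:
        return self.entries[name].value

    def to_dict(self) -> dict:
        return {"entries": {k: asdict(v) for k, v in self.entries.items()},
                "parameters": self.parameters}

    @classmethod
    def from_dict(cls, d) -> "MetricReport":
        rep = cls(parameters=d.get("parameters", {}))
        for k, e in d["entries"].items():
            rep.entries[k] = MetricEntry(**e)
        return rep


def write_report(report: MetricReport, path, fmt: str = "json") -> None:
    """Serialize a report; `fmt` ∈ {json, csv}. Round-trips losslessly."""
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
    elif fmt == "csv":
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=CSV_COLUMNS)
            w.writeheader()
            for e in report.entries.values():
                row = asdict(e)
                row["provenance"] = json.dumps(
                    {"module": e.provenance, "parameters": report.parameters}) \
                    if e.name == next(iter(report.entries)) else e.provenance
                w.writerow(row)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_report(path, fmt: str = "json") -> MetricReport:
    if fmt == "json":
        with open(path) as fh:
            return MetricReport.from_dict(json.load(fh))
    if fmt == "csv":
        rep = MetricReport()
        with open(path, newline="") as fh:
            first = True
            for row in csv.DictReader(fh):
                prov = row["provenance"]
                if first and prov.startswith("{"):
                    payload = json.loads(prov)
                    rep.parameters = payload.get("parameters", {})
                    prov = payload.get("module", "")
                first = False
                rep.entries[row["name"]] = MetricEntry(
                    name=row["name"],
                    value=float(row["value"]) if row["value"] else None,
                    units=row["units"], normalization=row["normalization"],
                    provenance=prov,
                    missing=row["missing"] in ("True", "true", "1"),
                    reason=row["reason"] or None)
        return rep
    raise ValueError(f"unknown format {fmt!r}")


DEFAULT_PARAMS = {
    "denoise": False,
    "denoise_strength": None,
    "n_levels": None,                  # None → automatic 3-vs-4 choice
    "segmentation_method": "otsu",
    "adjacency_um": cellmetrics.PERIVASCULAR_THRESHOLD_UM,
    "sma_negativity_cutoff": vasculometry.SMA_NEGATIVITY_CUTOFF,
    "coverage_cutoff": cellmetrics.COVERAGE_CUTOFF,
    "sma_probe_um": 2.0,
    "diffusion_percentile": perfusion.DIFFUSION_PERCENTILE,
    "prune_spurs": True,
}


def run_pipeline(config: dict) -> MetricReport:
    """Run preprocess → vasculometry → perfusion → cellmetrics on one volume.

    `config` supplies either ``image`` (a VolumetricImage) or ``input`` (a
    TIFF path, with optional ``spacing`` override) plus any of the parameter
    keys in DEFAULT_PARAMS.  Deterministic given config and inputs; every
    effective parameter is echoed into the report.  Stage failures abort
    with a stage-tagged error; an empty vasculature yields flagged-missing
    vascular metrics rather than a crash.
    """
    params = {**DEFAULT_PARAMS,
              **{k: v for k, v in config.items() if k in DEFAULT_PARAMS}}
    if "image" in config:
        image = config["image"]
    elif "input" in config:
        image = VolumetricImage.from_tiff(config["input"],
                                          spacing=config.get("spacing"))
    else:
        raise ValueError("config must provide 'image' or 'input'")

    report = MetricReport(parameters={k: v for k, v in params.items()})
    spacing = image.spacing
    stage = "preprocess"
    try:
        t0 = time.perf_counter()
        if params["denoise"]:
            image = preprocess.denoise_nonlocal_means(
                image, strength=params["denoise_strength"])
        tissue = preprocess.tissue_mask_from_nuclei(
            image.channels["nuclei"], n_levels=params["n_levels"])
        log.info("tissue mask: %d voxels (%.2fs)", tissue.volume_voxels,
                 time.perf_counter() - t0)

        stage = "vasculometry"
        t0 = time.perf_counter()
        vessel_mask = vasculometry.segment_channel(
            image.channels["vessel"], method=params["segmentation_method"],
            tissue=tissue, spacing=spacing)
        vessel_mask = preprocess.apply_tissue_mask(vessel_mask, tissue)
        sma_mask = vasculometry.segment_channel(
            image.channels["sma"], method=params["segmentation_method"],
            tissue=tissue, spacing=spacing)
        sma_mask = preprocess.apply_tissue_mask(sma_mask, tissue)
        graph = vasculometry.skeletonize_and_graph(
            vessel_mask, spacing, prune_spurs=params["prune_spurs"])
        log.info("graph: %d segments, %d voxels vessel (%.2fs)",
                 graph.n_segments, int(vessel_mask.sum()),
                 time.perf_counter() - t0)

        tissue_mm3 = tissue.volume_um3(spacing) * 1e-9
        _vascular_rows(report, image, tissue, vessel_mask, sma_mask, graph,
                       params, tissue_mm3)

        stage = "cellmetrics"
        _cell_rows(report, image, tissue, vessel_mask, sma_mask, graph,
                   params, tissue_mm3)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    for name, units, normalization in REPORT_ROWS:
        if name not in report.entries:
            report.add(name, None, units, normalization, provenance=stage,
                       missing=True, reason="not computed")
    # preserve canonical row order
    report.entries = {n: report.entries[n] for n, _, _ in REPORT_ROWS}
    return report


def _vascular_rows(report, image, tissue, vessel_mask, sma_mask, graph,
                   params, tissue_mm3) -> None:
    spacing = image.spacing
    vol_d, surf_d = vasculometry.minkowski_densities(vessel_mask, tissue, spacing)
    report.add("vascular_volume_density", vol_d, "%", provenance="vasculometry")
    report.add("vascular_surface_area_density", surf_d, "um2/um3",
               provenance="vasculometry")

    if graph.n_segments == 0:
        cell_rows = {"myofibroblasts", "sma_perivascular_cells",
                     "endothelial_cells"}
        for name, units, norm in REPORT_ROWS:
            base = name.replace("_per_length", "").replace(
                "_per_vessel_volume", "")
            if name in report.entries or base in cell_rows:
                continue
            report.add(name, None, units, norm, provenance="vasculometry",
                       missing=True, reason="empty vasculature")
        return

    cls = vasculometry.classify_vessels(
        graph, sma_mask, spacing, sma_cutoff=params["sma_negativity_cutoff"],
        probe_um=params["sma_probe_um"])
    mets = [vasculometry.segment_metrics_from_data(d) for _, d in graph.segments()]
    report.add("vascular_segment_length", np.mean([m.length for m in mets]),
               "um", provenance="vasculometry")
    report.add("vascular_segment_surface", np.mean([m.surface for m in mets]),
               "um2", provenance="vasculometry")
    report.add("vascular_segment_volume", np.mean([m.volume for m in mets]),
               "um3", provenance="vasculometry")
    torts = [m.tortuosity for m in mets if m.tortuosity_defined]
    if torts:
        report.add("tortuosity", np.mean(torts), "um/um", provenance="vasculometry")
    else:
        report.add("tortuosity", None, "um/um", provenance="vasculometry",
                   missing=True, reason="no open segments (all loops)")

    tall = vasculometry.network_tallies(graph, tissue_mm3)
    report.add("vascular_segments", tall["per_mm3_tissue"]["segments"],
               "count", "per_mm3_tissue", provenance="vasculometry")
    report.add("vascular_segments_per_length",
               tall["per_mm_vessel_length"]["segments"],
               "count", "per_mm_vessel_length", provenance="vasculometry")
    pct = cls["size_class_percent"]
    report.add("vessels_diameter_le3_pct", pct["<=3"], "%",
               provenance="vasculometry")
    report.add("vessels_diameter_3to6_pct", pct["3-6"], "%",
               provenance="vasculometry")
    report.add("vessels_diameter_gt6_pct", pct[">6"], "%",
               provenance="vasculometry")
    report.add("branching_nodes", tall["per_mm3_tissue"]["branching_nodes"],
               "count", "per_mm3_tissue", provenance="vasculometry")
    report.add("blind_ends", tall["per_mm3_tissue"]["blind_ends"],
               "count", "per_mm3_tissue", provenance="vasculometry")
    report.add("branching_nodes_per_length",
               tall["per_mm_vessel_length"]["branching_nodes"],
               "count", "per_mm_vessel_length", provenance="vasculometry")
    report.add("blind_ends_per_length",
               tall["per_mm_vessel_length"]["blind_ends"],
               "count", "per_mm_vessel_length", provenance="vasculometry")

    # --- SMA wall metrics
    cov_pct, _ = cellmetrics.sma_coverage(
        graph, sma_mask, spacing, coverage_cutoff=params["coverage_cutoff"],
        probe_um=params["sma_probe_um"])
    report.add("vessels_covered_with_sma", cov_pct, "%", provenance="cellmetrics")
    thick = cellmetrics.sma_thickness(graph, sma_mask, spacing,
                                      probe_um=params["sma_probe_um"])
    if thick is None:
        report.add("sma_layer_thickness", None, "um", provenance="cellmetrics",
                   missing=True, reason="no SMA-covered centerline points")
    else:
        report.add("sma_layer_thickness", thick, "um", provenance="cellmetrics")
    dmg = cellmetrics.damage_index(graph,
                                   coverage_cutoff=params["coverage_cutoff"])
    if dmg is None:
        report.add("damage_index", None, "dimensionless",
                   provenance="cellmetrics", missing=True,
                   reason="no non-capillary segments")
    else:
        report.add("damage_index", dmg, "dimensionless", provenance="cellmetrics")

    # --- oxygen-diffusion proxies
    fld = perfusion.extravascular_distance(vessel_mask, tissue, spacing)
    report.add("maximal_extravascular_distance", fld.max_um, "um",
               provenance="perfusion")
    report.add("median_extravascular_distance", fld.median_um, "um",
               provenance="perfusion")
    try:
        cap_dens = perfusion.capillary_density(graph, tissue, spacing)
        report.add("capillary_density", cap_dens, "count", "per_mm2_tissue",
                   provenance="perfusion")
    except ValueError as e:
        report.add("capillary_density", None, "count", "per_mm2_tissue",
                   provenance="perfusion", missing=True, reason=str(e))
    icd = perfusion.intercapillary_distance(graph, tissue, spacing)
    if icd is None:
        report.add("intercapillary_distance", None, "um",
                   provenance="perfusion", missing=True,
                   reason="fewer than two capillaries")
    else:
        report.add("intercapillary_distance", icd, "um", provenance="perfusion")
    cap_mask = perfusion.capillary_mask_from_graph(graph, tissue.mask.shape,
                                                   spacing)
    if cap_mask.any():
        cap_fld = perfusion.extravascular_distance(
            cap_mask, tissue, spacing, source="capillaries_only")
        dd = perfusion.diffusion_distance(
            cap_fld, percentile=params["diffusion_percentile"])
        report.add("diffusion_distance", dd, "um", provenance="perfusion")
    else:
        report.add("diffusion_distance", None, "um", provenance="perfusion",
                   missing=True, reason="no capillaries")


def _cell_rows(report, image, tissue, vessel_mask, sma_mask, graph, params,
               tissue_mm3) -> None:
    spacing = image.spacing
    centroids, merged = cellmetrics.detect_nuclei(
        image.channels["nuclei"], tissue, spacing)
    res = cellmetrics.classify_cells(
        centroids, vessel_mask, image.channels["sma"], spacing,
        adjacency_um=params["adjacency_um"], tissue=tissue,
        merged_flags=merged, graph=graph if graph.n_segments else None,
        tissue_volume_mm3=tissue_mm3)
    norm = res["normalized"]
    for cls, row in (("myofibroblasts", "myofibroblasts"),
                     ("sma_perivascular", "sma_perivascular_cells"),
                     ("endothelial", "endothelial_cells")):
        key = {"myofibroblasts": "myofibroblast",
               "sma_perivascular": "sma_perivascular",
               "endothelial": "endothelial"}[cls]
        report.add(row, norm["per_mm3_tissue"][key], "count",
                   "per_mm3_tissue", provenance="cellmetrics")
        if "per_mm_vessel_length" in norm:
            report.add(f"{row}_per_length", norm["per_mm_vessel_length"][key],
                       "count", "per_mm_vessel_length", provenance="cellmetrics")
        else:
            report.add(f"{row}_per_length", None, "count",
                       "per_mm_vessel_length", provenance="cellmetrics",
                       missing=True, reason="no vessel length")
        if "per_mm3_vessel_volume" in norm:
            report.add(f"{row}_per_vessel_volume",
                       norm["per_mm3_vessel_volume"][key], "count",
                       "per_mm3_vessel_volume", provenance="cellmetrics")
        else:
            report.add(f"{row}_per_vessel_volume", None, "count",
                       "per_mm3_vessel_volume", provenance="cellmetrics",
                       missing=True, reason="no vessel volume")


def aggregate_reports(reports: list[MetricReport]) -> MetricReport:
    """Average per-image reports into one (within-subject reduction).

    Missing entries are skipped; a metric missing in every image stays
    missing.  The mean over images is associative in the sense that
    averaging concatenated batches equals averaging all images at once.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    out = MetricReport(parameters={"aggregated_n": len(reports)})
    for name in reports[0].entries:
        entries = [r.entries[name] for r in reports if name in r.entries]
        vals = [e.value for e in entries if not e.missing and e.value is not None]
        proto = entries[0]
        if vals:
            out.add(name, float(np.mean(vals)), proto.units,
                    proto.normalization, provenance="aggregate")
        else:
            out.add(name, None, proto.units, proto.normalization,
                    provenance="aggregate", missing=True,
                    reason="missing in all images")
    return out


def aggregate_subjects(per_subject: dict[str, list[MetricReport]]) -> MetricReport:
    """Two-level reduction: mean within each subject, then across subjects."""
    per = [aggregate_reports(reps) for reps in per_subject.values()]
    return aggregate_reports(per)
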