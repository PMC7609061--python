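"""Scalar cardiac quantification scores.

Closed-form quantities defined outside the 3D pipeline: the standardized
median fluorescence intensity of a stained population against its
fluorescence-minus-one (FMO) control, the 12-segment echocardiographic
wall-motion score index (WMSI) and infarct size, second-harmonic-generation
(SHG) collagen texture metrics, and generic positive-area / positive-count
fractions for immunofluorescence quantification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

LEVELS = ("basal", "medial", "apical")
WALLS = ("anterior", "lateral", "posterior", "septal")
VALID_SCORES = {1, 2, 3, 4}


# ---------------------------------------------------------------------------
# Flow cytometry


def standardized_mfi(sample, literal: bool = False) -> float:
    """Standardized median fluorescence intensity.

    SMFI = (median_positive − median_FMO) / (2 · SD_FMO): the shift of the
    stained population's median above the FMO control background, in units
    of twice the control's spread.  ``literal=True`` instead computes the
    product form (median difference × 2 SD_FMO); the divided form is the
    standard standardization and the default.
    """
    pos = np.asarray(sample.events_positive, float)
    fmo = np.asarray(sample.events_fmo, float)
    sd_fmo = float(np.std(fmo, ddof=1)) if fmo.size > 1 else 0.0
    if sd_fmo <= 0:
        raise ValueError("degenerate FMO control: zero spread")
    diff = float(np.median(pos) - np.median(fmo))
    if literal:
        return diff * 2.0 * sd_fmo
    return diff / (2.0 * sd_fmo)


# ---------------------------------------------------------------------------
# Echocardiographic segmental scoring


@dataclass
class SegmentScoreTable:
    """12 left-ventricle segment contraction scores.

    Segments index (level ∈ {basal, medial, apical}) × (wall ∈ {anterior,
    lateral, posterior, septal}); each score is 1 (normal), 2 (hypokinesia),
    3 (akinesia) or 4 (dyskinesia/aneurysm).
    """

    scores: list[int] = field(default_factory=lambda: [1] * 12)

    def __post_init__(self) -> None:
        self.scores = [int(s) for s in self.scores]
        if len(self.scores) != 12:
            raise ValueError("exactly 12 segment scores required")
        bad = [s for s in self.scores if s not in VALID_SCORES]
        if bad:
            raise ValueError(f"scores must be in {{1,2,3,4}}, got {bad}")

    def as_matrix(self) -> np.ndarray:
        """3×4 (level × wall) score matrix."""
        return np.asarray(self.scores).reshape(3, 4)

    def to_csv(self, path) -> None:
        import pandas as pd
        rows = [{"level": lv, "wall": w, "score": s}
                for (lv, w), s in zip(
                    ((lv, w) for lv in LEVELS for w in WALLS), self.scores)]
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SegmentScoreTable":
        """Accepts long form (level, wall, score) or a bare 3×4 matrix."""
        import pandas as pd
        df = pd.read_csv(path)
        if {"level", "wall", "score"} <= set(df.columns):
            order = {(lv, w): i for i, (lv, w) in enumerate(
                (lv, w) for lv in LEVELS for w in WALLS)}
            df = df.assign(_o=[order[(lv, w)] for lv, w in
                               zip(df["level"], df["wall"])]).sort_values("_o")
            return cls(scores=df["score"].tolist())
        mat = df.to_numpy()
        if mat.shape == (3, 4):
            return cls(scores=mat.ravel().astype(int).tolist())
        raise ValueError("expected (level, wall, score) rows or a 3x4 matrix")


def wmsi(table: SegmentScoreTable) -> float:
    """Wall-motion score index: mean of the 12 segment scores, in [1, 4]."""
    return float(np.mean(table.scores))


def echo_infarct_size(table: SegmentScoreTable) -> float:
    """Echocardiographic infarct size: % of segments scored > 1
    (contractility abnormality) over the 12 LV segments."""
    abnormal = sum(s > 1 for s in table.scores)
    return 100.0 * abnormal / len(table.scores)


# ---------------------------------------------------------------------------
# SHG collagen texture


@dataclass
class ShgMetrics:
    """Collagen texture of an SHG image within a zone of interest."""

    pct_shg: float                  # % suprathreshold area fraction
    skewness: float | None          # asymmetry of the intensity distribution
    kurtosis: float | None          # spread-out-ness; non-excess (normal = 3)
    threshold_used: float
    moments_defined: bool = True
    excess_kurtosis: float | None = None


def shg_metrics(image: np.ndarray, zone_mask: np.ndarray,
                threshold="auto") -> ShgMetrics:
    """Collagen density (%SHG) and intensity-histogram shape within a zone.

    %SHG is simple threshold pixel counting: the percentage of zone pixels
    above `threshold` ("auto" = single-level Otsu within the zone).
    Skewness and kurtosis are moment-based over zone intensities; kurtosis
    is reported non-excess (normal = 3), with the excess value alongside.
    Constant zones keep a well-defined %SHG but flag the moments undefined.
    """
    image = np.asarray(image, float)
    zone_mask = np.asarray(zone_mask, bool)
    if zone_mask.shape != image.shape:
        raise ValueError("zone mask shape mismatch")
    if not zone_mask.any():
        raise ValueError("empty zone mask")
    vals = image[zone_mask]

    constant = np.ptp(vals) < 1e-12
    if threshold == "auto":
        if constant:
            # degenerate: everything is "signal" at, or nothing above, the
            # single intensity; count pixels > value-epsilon as positive
            th = float(vals[0]) - 1e-12
        else:
            from skimage.filters import threshold_otsu
            th = float(threshold_otsu(vals))
    else:
        th = float(threshold)
    pct = 100.0 * float(np.mean(vals > th))

    if constant:
        return ShgMetrics(pct_shg=pct, skewness=None, kurtosis=None,
                          threshold_used=th, moments_defined=False)
    skew = float(stats.skew(vals, bias=True))
    kurt_excess = float(stats.kurtosis(vals, fisher=True, bias=True))
    return ShgMetrics(pct_shg=pct, skewness=skew, kurtosis=kurt_excess + 3.0,
                      threshold_used=th, moments_defined=True,
                      excess_kurtosis=kurt_excess)


# ---------------------------------------------------------------------------
# Positive fractions


def positive_fraction(signal, reference, mode: str = "area") -> float:
    """Percentage of the reference that is signal-positive.

    ``mode="area"``: boolean masks; 100 × |signal ∩ reference| / |reference|
    (e.g. CA-IX covered area over total tissue area).  ``mode="count"``:
    `signal` and `reference` are sets/sequences of labels; percentage of
    reference objects that are also signal-positive (e.g. pSMAD2+ share of
    VSMCs).  Averaging across images and subjects is a separate reduction.
    """
    if mode == "area":
        signal = np.asarray(signal, bool)
        reference = np.asarray(reference, bool)
        if signal.shape != reference.shape:
            raise ValueError("mask shape mismatch")
        n_ref = int(reference.sum())
        if n_ref == 0:
            raise ValueError("empty reference")
        return 100.0 * int((signal & reference).sum()) / n_ref
    if mode == "count":
        ref = set(reference)
        if not ref:
            raise ValueError("empty reference")
        return 100.0 * len(set(signal) & ref) / len(ref)
    raise ValueError(f"unknown mode {mode!r}")
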