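"""Seeded synthetic phantoms with known ground truth.

No raw confocal stacks accompany the study this pipeline serves, so every
downstream stage is validated against phantoms: tubular CD31+ structures of
controlled radius, length and tortuosity, optional smooth-muscle-actin (SMA)
sheaths, scattered nuclei of known class, a tissue-vs-glass partition, and
Gaussian (optionally Poisson) noise.  Scalar-score inputs — flow-cytometry
event samples, fibrillar SHG textures, 12-segment echo score tables — are
generated here too.

Rasterization follows the centers-in convention: a voxel belongs to a tube
iff its center lies within the tube radius of the centerline.  All geometry
is in µm, points ordered (x, y, z).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .types import VolumetricImage

NUCLEUS_CLASSES = ("endothelial", "sma_perivascular", "myofibroblast", "other")

# Base channel intensities (arbitrary units). Tissue background exceeds the
# glass background (≈ 0), mirroring tissue-vs-slide contrast; foreground
# structures sit well above both.
DEFAULT_INTENSITY = {
    "glass": 0.0,
    "tissue": {"nuclei": 40.0, "vessel": 8.0, "sma": 8.0},
    "nucleus": 220.0,
    "vessel": 200.0,
    "sma": 200.0,
}

NUCLEUS_RADIUS_UM = 2.0


@dataclass
class Tube:
    """One tube primitive: an ordered centerline with constant radius."""

    points: np.ndarray          # (N, 3) µm
    radius: float               # µm
    sma: bool = False           # mural sheath present
    sma_fraction: float = 1.0   # longitudinal fraction of sheath coverage
    sheath_thickness: float = 1.5  # µm, annulus radial extent
    closed: bool = False        # ring: last point connects back to first

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("centerline must be (N, 3)")
        if self.radius <= 0:
            raise ValueError("tube radius must be > 0")
        if not 0.0 <= self.sma_fraction <= 1.0:
            raise ValueError("sma_fraction must be in [0, 1]")

    def arc_length(self) -> float:
        pts = self.points
        if self.closed:
            pts = np.vstack([pts, pts[:1]])
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())

    def analytic_volume(self) -> float:
        """Exact solid volume of the rasterized shape.

        The centers-in rule over a polyline produces a capsule: π r² L plus
        two hemispherical end caps for open tubes (no caps for closed
        loops).  Caps falling outside the volume bounds are not corrected
        for.
        """
        vol = np.pi * self.radius**2 * self.arc_length()
        if not self.closed:
            vol += 4.0 / 3.0 * np.pi * self.radius**3
        return float(vol)


def _resample_polyline(points: np.ndarray, step: float, closed: bool) -> np.ndarray:
    """Dense, uniformly spaced samples along a polyline (for rasterization)."""
    pts = np.vstack([points, points[:1]]) if closed else points
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 1e-12
    seg, seg_len, starts = seg[keep], seg_len[keep], pts[:-1][keep]
    if len(seg) == 0:
        return points[:1].copy()
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = cum[-1]
    n = max(int(np.ceil(total / step)) + 1, 2)
    s = np.linspace(0.0, total, n)
    idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg) - 1)
    frac = (s - cum[idx]) / seg_len[idx]
    return starts[idx] + seg[idx] * frac[:, None]


# ---------------------------------------------------------------------------
# Tube constructors


def straight_tube(p0, p1, radius, **kw) -> Tube:
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    n = max(int(np.linalg.norm(p1 - p0)) * 2, 2)
    pts = np.linspace(p0, p1, n)
    return Tube(points=pts, radius=radius, **kw)


def arc_tube(center, arc_radius, radius, angle_start=0.0, angle_end=np.pi,
             plane="xy", z=None, n_points=180, **kw) -> Tube:
    """Circular arc of radius `arc_radius` in an axis plane."""
    c = np.asarray(center, float)
    t = np.linspace(angle_start, angle_end, n_points)
    u, v = np.cos(t) * arc_radius, np.sin(t) * arc_radius
    pts = np.repeat(c[None, :], n_points, axis=0)
    ax = {"xy": (0, 1), "xz": (0, 2), "yz": (1, 2)}[plane]
    pts[:, ax[0]] += u
    pts[:, ax[1]] += v
    if z is not None:
        pts[:, 2] = z
    return Tube(points=pts, radius=radius, **kw)


def ring_tube(center, ring_radius, radius, plane="xy", n_points=256, **kw) -> Tube:
    """Closed circular loop (torus centerline)."""
    t = arc_tube(center, ring_radius, radius,
                 angle_start=0.0, angle_end=2 * np.pi * (1 - 1.0 / n_points),
                 plane=plane, n_points=n_points, **kw)
    t.closed = True
    return t


def y_junction(root, junction, tip_a, tip_b, radius, **kw) -> list[Tube]:
    """Three straight branches sharing one junction point."""
    return [
        straight_tube(root, junction, radius, **kw),
        straight_tube(junction, tip_a, radius, **kw),
        straight_tube(junction, tip_b, radius, **kw),
    ]


def parallel_grid(pitch, radius, volume_size, axis=2, margin=None, **kw) -> list[Tube]:
    """Square grid of parallel tubes along `axis`, spaced `pitch` µm apart."""
    size = np.asarray(volume_size, float)
    other = [a for a in range(3) if a != axis]
    if margin is None:
        margin = pitch / 2.0
    tubes = []
    for u in np.arange(margin, size[other[0]] - margin / 2, pitch):
        for v in np.arange(margin, size[other[1]] - margin / 2, pitch):
            p0, p1 = np.zeros(3), np.zeros(3)
            p0[other[0]] = p1[other[0]] = u
            p0[other[1]] = p1[other[1]] = v
            p1[axis] = size[axis]
            tubes.append(straight_tube(p0, p1, radius, **kw))
    return tubes


# ---------------------------------------------------------------------------
# Phantom specification and truth


@dataclass
class NoiseParams:
    gaussian_sigma: float = 0.0
    poisson: bool = False


@dataclass
class PhantomSpec:
    """Geometry of one synthetic volume.

    Defaults mirror the acquisition this pipeline targets: 15 µm-thick
    transverse sections imaged with ~0.5 µm in-plane sampling and 1.5 µm
    optical-section spacing.
    """

    volume_size: tuple[float, float, float] = (100.0, 100.0, 15.0)  # µm
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.5)           # µm/voxel
    tubes: list[Tube] = field(default_factory=list)
    # tissue occupies [0, tissue_fraction * Lx] along x; the rest is glass
    tissue_fraction: float = 1.0
    n_nuclei: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in NUCLEUS_CLASSES})
    perivascular_threshold: float = 2.0   # µm from vessel surface
    intensity: dict = field(default_factory=lambda: DEFAULT_INTENSITY)


@dataclass
class PhantomTruth:
    """Ground truth paired with a generated volume."""

    centerlines: list[np.ndarray]
    radii: list[np.ndarray]
    sma_label: list[bool]
    sma_fraction: list[float]
    closed: list[bool]
    nuclei_positions: list[np.ndarray]
    nuclei_classes: list[str]
    tissue_region: tuple[tuple[float, float], ...]  # ((x0,x1),(y0,y1),(z0,z1))
    seed: int
    perivascular_threshold: float = 2.0

    def tissue_volume_um3(self) -> float:
        return float(np.prod([hi - lo for lo, hi in self.tissue_region]))

    def analytic_vessel_volume(self) -> float:
        """Capsule volume Σ (π r² L + end caps) over all tubes."""
        total = 0.0
        for pts, r, closed in zip(self.centerlines, self.radii, self.closed):
            p = np.vstack([pts, pts[:1]]) if closed else pts
            L = np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
            rr = float(np.mean(r))
            total += np.pi * rr**2 * L
            if not closed:
                total += 4.0 / 3.0 * np.pi * rr**3
        return float(total)

    def to_json(self, path) -> None:
        payload = {
            "centerlines": [c.tolist() for c in self.centerlines],
            "radii": [r.tolist() for r in self.radii],
            "sma_label": list(self.sma_label),
            "sma_fraction": list(self.sma_fraction),
            "closed": list(self.closed),
            "nuclei_positions": [p.tolist() for p in self.nuclei_positions],
            "nuclei_classes": list(self.nuclei_classes),
            "tissue_region": [list(b) for b in self.tissue_region],
            "seed": self.seed,
            "perivascular_threshold": self.perivascular_threshold,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "PhantomTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            centerlines=[np.asarray(c) for c in d["centerlines"]],
            radii=[np.asarray(r) for r in d["radii"]],
            sma_label=d["sma_label"],
            sma_fraction=d["sma_fraction"],
            closed=d["closed"],
            nuclei_positions=[np.asarray(p) for p in d["nuclei_positions"]],
            nuclei_classes=d["nuclei_classes"],
            tissue_region=tuple(tuple(b) for b in d["tissue_region"]),
            seed=d["seed"],
            perivascular_threshold=d["perivascular_threshold"],
        )


# ---------------------------------------------------------------------------
# Rasterization


def _voxel_centers(shape, spacing):
    axes = [(np.arange(n) + 0.5) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def rasterize_tubes(tubes, shape, spacing, annulus=False):
    """Boolean mask of tube interiors (or SMA sheath annuli).

    Distances from voxel centers to the centerline are evaluated against a
    dense resampling of the polyline (step = min spacing / 4), so the
    rasterization error is well below a voxel.
    """
    spacing = np.asarray(spacing, float)
    step = float(spacing.min()) / 4.0
    mask = np.zeros(shape, dtype=bool)
    gx, gy, gz = _voxel_centers(shape, spacing)
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    for tube in tubes:
        if annulus and not tube.sma:
            continue
        dense = _resample_polyline(tube.points, step, tube.closed)
        if annulus and tube.sma_fraction < 1.0:
            seg_len = np.linalg.norm(np.diff(dense, axis=0), axis=1)
            cum = np.concatenate([[0.0], np.cumsum(seg_len)])
            dense = dense[cum <= tube.sma_fraction * cum[-1] + 1e-9]
            if len(dense) == 0:
                continue
        r_out = tube.radius + (tube.sheath_thickness if annulus else 0.0)
        # bounding box crop keeps the KD-tree query small
        lo = dense.min(axis=0) - r_out - spacing
        hi = dense.max(axis=0) + r_out + spacing
        inside = np.all((centers >= lo) & (centers <= hi), axis=1)
        pts = centers[inside]
        if len(pts) == 0:
            continue
        d, _ = cKDTree(dense).query(pts, workers=-1)
        if annulus:
            hit = (d > tube.radius) & (d <= r_out)
        else:
            hit = d <= tube.radius
        flat = np.zeros(mask.size, dtype=bool)
        flat[np.flatnonzero(inside)[hit]] = True
        mask |= flat.reshape(shape)
    return mask


def _rasterize_spheres(positions, radius, shape, spacing):
    mask = np.zeros(shape, dtype=bool)
    if len(positions) == 0:
        return mask
    gx, gy, gz = _voxel_centers(shape, spacing)
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    d, _ = cKDTree(np.asarray(positions, float)).query(centers, workers=-1)
    return (d <= radius).reshape(shape)


# ---------------------------------------------------------------------------
# Nucleus placement


def _surface_distance(point, tubes):
    """Distance from a point to the nearest tube surface (<0 means inside)."""
    best = np.inf
    for tube in tubes:
        dense = _resample_polyline(tube.points, tube.radius / 4 + 0.05, tube.closed)
        d = np.linalg.norm(dense - point, axis=1).min() - tube.radius
        best = min(best, d)
    return best


def _place_nuclei(spec: PhantomSpec, rng: np.random.Generator):
    """Rejection-sample nucleus centroids honoring the class geometry."""
    size = np.asarray(spec.volume_size, float)
    tx1 = spec.tissue_fraction * size[0]
    thr = spec.perivascular_threshold
    margin = NUCLEUS_RADIUS_UM
    positions, classes = [], []

    def in_tissue(p):
        return (margin <= p[0] <= tx1 - margin
                and margin <= p[1] <= size[1] - margin
                and margin <= p[2] <= size[2] - margin)

    def too_close(p):
        return any(np.linalg.norm(p - q) < 2.5 * NUCLEUS_RADIUS_UM
                   for q, _ in zip(positions, classes))

    tubes = spec.tubes
    for cls in NUCLEUS_CLASSES:
        want = spec.n_nuclei.get(cls, 0)
        placed = 0
        for _ in range(20000):
            if placed >= want:
                break
            if cls == "endothelial" and tubes:
                tube = tubes[rng.integers(len(tubes))]
                dense = _resample_polyline(tube.points, 1.0, tube.closed)
                p = dense[rng.integers(len(dense))].copy()
            elif cls == "sma_perivascular" and tubes:
                tube = tubes[rng.integers(len(tubes))]
                dense = _resample_polyline(tube.points, 1.0, tube.closed)
                c = dense[rng.integers(len(dense))]
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                # keep a voxel-quantization margin from the surface so the
                # centroid cannot fall into the digitized vessel mask
                d = tube.radius + rng.uniform(1.0, max(thr - 0.3, 1.2))
                p = c + v * d
                sd = _surface_distance(p, tubes)
                if sd > thr or sd < 1.0:
                    continue
            else:  # myofibroblast or other: away from every vessel surface
                p = rng.uniform([margin] * 3, [tx1 - margin, size[1] - margin,
                                               size[2] - margin])
                sd = _surface_distance(p, tubes) if tubes else np.inf
                # strictly beyond the adjacency threshold, with enough slack
                # that the cell's SMA halo stays clear of the mural-coverage
                # probe around vessels
                if sd < thr + NUCLEUS_RADIUS_UM + 2.0:
                    continue
            if not in_tissue(p) or too_close(p):
                continue
            positions.append(np.asarray(p, float))
            classes.append(cls)
            placed += 1
        if placed < want:
            raise RuntimeError(
                f"could not place {want} {cls} nuclei (placed {placed}); "
                "volume too crowded")
    return positions, classes


# ---------------------------------------------------------------------------
# Main phantom generator


def generate_vascular_phantom(
    spec: PhantomSpec,
    noise: NoiseParams | None = None,
    seed: int = 0,
) -> tuple[VolumetricImage, PhantomTruth]:
    """Rasterize a 3-channel volume (nuclei, vessel, sma) from `spec`.

    Deterministic given (spec, noise, seed).  Raises on tubes thinner than
    the voxel spacing ("unresolvable primitive") or extending outside the
    volume.
    """
    noise = noise or NoiseParams()
    rng = np.random.default_rng(seed)
    size = np.asarray(spec.volume_size, float)
    spacing = np.asarray(spec.spacing, float)
    shape = tuple(int(round(s / sp)) for s, sp in zip(size, spacing))

    min_sp = float(spacing.min())
    for tube in spec.tubes:
        if tube.radius < min_sp:
            raise ValueError(
                f"unresolvable primitive: radius {tube.radius} µm < voxel "
                f"spacing {min_sp} µm")
        if np.any(tube.points < -1e-9) or np.any(tube.points > size + 1e-9):
            raise ValueError("tube centerline extends outside the volume")

    inten = spec.intensity
    vessel_mask = rasterize_tubes(spec.tubes, shape, spacing)
    sma_mask = rasterize_tubes(spec.tubes, shape, spacing, annulus=True)

    positions, classes = _place_nuclei(spec, rng)
    nuclei_mask = _rasterize_spheres(positions, NUCLEUS_RADIUS_UM, shape, spacing)
    # perivascular and myofibroblast nuclei are themselves SMA+: paint a
    # small SMA halo so classification has signal to key on
    sma_pos = [p for p, c in zip(positions, classes)
               if c in ("sma_perivascular", "myofibroblast")]
    sma_mask |= _rasterize_spheres(sma_pos, NUCLEUS_RADIUS_UM + 0.5, shape, spacing)

    # tissue box: [0, f*Lx] × full y × full z
    nx_t = int(round(spec.tissue_fraction * shape[0]))
    tissue = np.zeros(shape, dtype=bool)
    tissue[:nx_t] = True

    channels = {}
    for name, fg_mask, fg_val in (
        ("nuclei", nuclei_mask, inten["nucleus"]),
        ("vessel", vessel_mask, inten["vessel"]),
        ("sma", sma_mask, inten["sma"]),
    ):
        ch = np.full(shape, inten["glass"], dtype=float)
        ch[tissue] = inten["tissue"][name]
        ch[fg_mask] = fg_val
        if noise.poisson:
            ch = rng.poisson(np.clip(ch, 0, None)).astype(float)
        if noise.gaussian_sigma > 0:
            ch = ch + rng.normal(0.0, noise.gaussian_sigma, shape)
        channels[name] = np.clip(ch, 0.0, None)

    image = VolumetricImage(channels=channels, spacing=tuple(spacing))
    truth = PhantomTruth(
        centerlines=[t.points.copy() for t in spec.tubes],
        radii=[np.full(len(t.points), t.radius) for t in spec.tubes],
        sma_label=[t.sma for t in spec.tubes],
        sma_fraction=[t.sma_fraction for t in spec.tubes],
        closed=[t.closed for t in spec.tubes],
        nuclei_positions=positions,
        nuclei_classes=classes,
        tissue_region=((0.0, nx_t * spacing[0]), (0.0, size[1]), (0.0, size[2])),
        seed=seed,
        perivascular_threshold=spec.perivascular_threshold,
    )
    return image, truth


# ---------------------------------------------------------------------------
# Scalar-score inputs


@dataclass
class FlowSample:
    """Fluorescence events for a stained sample and its FMO control."""

    events_positive: np.ndarray
    events_fmo: np.ndarray
    marker_name: str = ""
    low_n: bool = False

    def __post_init__(self) -> None:
        self.events_positive = np.asarray(self.events_positive, float)
        self.events_fmo = np.asarray(self.events_fmo, float)
        if self.events_positive.size == 0 or self.events_fmo.size == 0:
            raise ValueError("event lists must be non-empty")
        if not (np.all(np.isfinite(self.events_positive))
                and np.all(np.isfinite(self.events_fmo))):
            raise ValueError("intensities must be finite")

    def to_csv(self, path) -> None:
        import pandas as pd
        n = max(len(self.events_positive), len(self.events_fmo))
        df = pd.DataFrame({
            "positive": np.pad(self.events_positive, (0, n - len(self.events_positive)),
                               constant_values=np.nan),
            "fmo": np.pad(self.events_fmo, (0, n - len(self.events_fmo)),
                          constant_values=np.nan),
        })
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, marker_name="") -> "FlowSample":
        import pandas as pd
        df = pd.read_csv(path)
        return cls(events_positive=df["positive"].dropna().to_numpy(),
                   events_fmo=df["fmo"].dropna().to_numpy(),
                   marker_name=marker_name)


def generate_flow_sample(mu_pos, mu_fmo, sd_fmo, n=10000, sd_pos=None,
                         seed=0, marker_name="") -> FlowSample:
    """Normal event distributions for a stained/FMO pair.

    Medians and the FMO standard deviation converge to the stated parameters
    as n grows, so the downstream standardized MFI converges to
    (mu_pos − mu_fmo) / (2 sd_fmo).
    """
    if sd_fmo <= 0:
        raise ValueError("sd_fmo must be > 0")
    rng = np.random.default_rng(seed)
    sd_pos = sd_fmo if sd_pos is None else sd_pos
    return FlowSample(
        events_positive=rng.normal(mu_pos, sd_pos, n),
        events_fmo=rng.normal(mu_fmo, sd_fmo, n),
        marker_name=marker_name,
        low_n=n < 10,
    )


SHG_FIBER_THRESHOLD = 100.0
# intensity separating fiber pixels (≥150) from background (≤28) in
# generated textures; pass it explicitly to the %SHG stage for degenerate
# densities (0 or 1) where an automatic Otsu threshold has no two classes
# to separate


def generate_shg_texture(shape=(256, 256), fiber_density=0.3, seed=0,
                         zone_mask=None):
    """Fibrillar 2D texture with an exact suprathreshold fraction in-zone.

    A smooth anisotropic random field (long correlation length along one
    axis → fiber-like streaks) is thresholded at the in-zone quantile so that
    exactly ``round(fiber_density * n_zone)`` pixels are bright.  Bright
    pixels get intensities above :data:`SHG_FIBER_THRESHOLD`, the rest below
    it, guaranteeing the downstream %SHG stage recovers `fiber_density` to
    within one pixel.
    """
    if not 0.0 <= fiber_density <= 1.0:
        raise ValueError("fiber_density must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if zone_mask is None:
        zone_mask = np.ones(shape, dtype=bool)
    zone_mask = np.asarray(zone_mask, dtype=bool)
    if zone_mask.shape != tuple(shape):
        raise ValueError("zone mask shape mismatch")
    if not zone_mask.any():
        raise ValueError("empty zone mask")

    from scipy import ndimage as ndi
    field = ndi.gaussian_filter(rng.normal(size=shape), sigma=(1.0, 6.0))
    n_zone = int(zone_mask.sum())
    n_bright = int(round(fiber_density * n_zone))

    img = rng.uniform(2.0, 28.0, shape)   # dim background everywhere
    if n_bright >= n_zone:                # fully fibrotic: constant zone
        img[zone_mask] = 200.0
    elif n_bright > 0:
        zone_vals = field[zone_mask]
        order = np.argsort(zone_vals)[::-1]
        bright_flat = np.flatnonzero(zone_mask.ravel())[order[:n_bright]]
        bright = np.zeros(img.size, dtype=bool)
        bright[bright_flat] = True
        bright = bright.reshape(shape)
        img[bright] = rng.uniform(150.0, 255.0, n_bright)
    return img, zone_mask


def generate_score_table(seed=0, p_abnormal=0.5):
    """Random 12-segment echo score table; scores drawn over {1, 2, 3, 4}."""
    from .scores import SegmentScoreTable
    rng = np.random.default_rng(seed)
    p1 = 1.0 - p_abnormal
    probs = [p1, p_abnormal * 0.5, p_abnormal * 0.3, p_abnormal * 0.2]
    scores = rng.choice([1, 2, 3, 4], size=12, p=probs)
    return SegmentScoreTable(scores=list(map(int, scores)))
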