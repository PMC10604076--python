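"""Multimodal particle detection and mask fusion.

Each modality (bright-field, dark-field, HDR fluorescence) is segmented
independently: contrast-limited adaptive histogram equalization and
bilateral smoothing, Canny edge extraction, dilation and hole filling,
then connected-component labeling.  Candidate regions are filtered on
area, eccentricity, convexity, border proximity and mutual overlap, and
the three binary masks are fused by pixelwise OR under a convexity
constraint, recording which modalities contributed to each final region.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology
from skimage.exposure import equalize_adapthist
from skimage.feature import canny
from skimage.restoration import denoise_bilateral

MODALITIES = ("bright_field", "dark_field", "fluorescence")


@dataclass(frozen=True)
class DetectionConfig:
    # Canny hysteresis thresholds as fractions of the [0, 1] dynamic range
    canny_low: float = 0.10
    canny_high: float = 0.25
    canny_sigma: float = 2.0
    dilation_radius_px: int = 3
    area_min_px: int = 500
    area_max_px: int = 5200
    eccentricity_max: float = 0.85
    convexity_min: float = 0.85
    edge_margin_px: int = 10
    overlap_fraction_max: float = 0.20  # equivalent-disc overlap beyond this drops both
    clahe_clip: float = 0.01
    clahe_tiles: int = 8  # tiles per image axis
    bilateral_sigma_spatial: float = 2.0
    bilateral_sigma_range: float = 0.10

    def __post_init__(self):
        if not self.canny_low < self.canny_high:
            raise ValueError("canny_low must be < canny_high")
        if not self.area_min_px < self.area_max_px:
            raise ValueError("area_min_px must be < area_max_px")
        if not 0 <= self.eccentricity_max < 1:
            raise ValueError("eccentricity_max must be in [0, 1)")
        if not 0 < self.convexity_min <= 1:
            raise ValueError("convexity_min must be in (0, 1]")

    @classmethod
    def from_geometry(cls, r_outer_px: float, **overrides) -> "DetectionConfig":
        """Tie area bounds to the expected particle disc area.

        Bounds default to [0.25, 2.25]x the outer-disc area, wide enough
        to accept both the PEG-disc footprint seen in fluorescence and
        the full shell footprint seen in bright-field.
        """
        area = np.pi * r_outer_px ** 2
        cfg = cls(area_min_px=int(0.25 * area), area_max_px=int(np.ceil(2.25 * area)))
        return replace(cfg, **overrides) if overrides else cfg


@dataclass
class ParticleRegion:
    label: int
    centroid: tuple[float, float]
    area_px: int
    eccentricity: float
    convexity: float
    modalities: frozenset[str]
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col)

    @property
    def equivalent_radius(self) -> float:
        return float(np.sqrt(self.area_px / np.pi))


@dataclass
class DetectionMask:
    """Labeled particle mask: label_image (0 = background) plus region table."""

    label_image: np.ndarray
    regions: list[ParticleRegion]

    @property
    def n_regions(self) -> int:
        return len(self.regions)

    def binary(self) -> np.ndarray:
        return self.label_image > 0


def _regions_from_labels(label_image: np.ndarray,
                         modalities: frozenset[str]) -> DetectionMask:
    regions = []
    for p in measure.regionprops(label_image):
        regions.append(
            ParticleRegion(
                label=int(p.label),
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                area_px=int(p.area),
                eccentricity=float(p.eccentricity),
                convexity=float(p.solidity),  # area / convex-hull area
                modalities=modalities,
                bbox=tuple(int(v) for v in p.bbox),
            )
        )
    return DetectionMask(label_image=label_image, regions=regions)


def _relabel(label_image: np.ndarray, keep: list[ParticleRegion],
             modalities_by_old_label: dict[int, frozenset[str]] | None = None
             ) -> DetectionMask:
    """Contiguously relabel kept regions, preserving provenance."""
    out = np.zeros_like(label_image)
    regions = []
    for new_label, reg in enumerate(sorted(keep, key=lambda r: r.label), start=1):
        out[label_image == reg.label] = new_label
        mods = reg.modalities
        if modalities_by_old_label is not None:
            mods = modalities_by_old_label.get(reg.label, mods)
        regions.append(replace(reg, label=new_label, modalities=mods))
    return DetectionMask(label_image=out, regions=regions)


# ---------------------------------------------------------------------------
# preprocessing and per-modality detection


def preprocess(image: np.ndarray, config: DetectionConfig) -> np.ndarray:
    """Contrast-equalize and edge-preserving-smooth, rescaled to [0, 1]."""
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite pixels")
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    norm = (image - lo) / (hi - lo)
    kernel = max(8, min(norm.shape) // config.clahe_tiles)
    eq = equalize_adapthist(norm, kernel_size=kernel, clip_limit=config.clahe_clip)
    sm = denoise_bilateral(
        eq,
        sigma_color=config.bilateral_sigma_range,
        sigma_spatial=config.bilateral_sigma_spatial,
    )
    lo, hi = float(sm.min()), float(sm.max())
    if hi == lo:
        return np.zeros_like(sm)
    return (sm - lo) / (hi - lo)


def detect_modality(image: np.ndarray, config: DetectionConfig,
                    modality: str) -> DetectionMask:
    """Candidate particle regions in one preprocessed modality image.

    Canny edges -> dilation -> hole filling -> erosion (restoring the
    pre-dilation boundary) -> connected components.  No filtering; an
    empty mask is a valid result on a featureless image.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    image = np.asarray(image, dtype=float)
    if image.std() == 0:
        return DetectionMask(np.zeros(image.shape, dtype=np.int32), [])
    edges = canny(
        image,
        sigma=config.canny_sigma,
        low_threshold=config.canny_low,
        high_threshold=config.canny_high,
    )
    selem = morphology.disk(config.dilation_radius_px)
    mask = ndi.binary_dilation(edges, structure=selem)
    mask = ndi.binary_fill_holes(mask)
    mask = ndi.binary_erosion(mask, structure=selem, border_value=1)
    labels = measure.label(mask, connectivity=2).astype(np.int32)
    return _regions_from_labels(labels, frozenset({modality}))


# ---------------------------------------------------------------------------
# filtering


def _disc_overlap_fraction(r1: float, r2: float, d: float) -> float:
    """Area overlap of two discs divided by the smaller disc's area."""
    if d >= r1 + r2:
        return 0.0
    if d <= abs(r1 - r2):
        return 1.0
    # lens area of two intersecting circles
    a1 = r1 ** 2 * np.arccos((d ** 2 + r1 ** 2 - r2 ** 2) / (2 * d * r1))
    a2 = r2 ** 2 * np.arccos((d ** 2 + r2 ** 2 - r1 ** 2) / (2 * d * r2))
    a3 = 0.5 * np.sqrt(
        max((-d + r1 + r2) * (d + r1 - r2) * (d - r1 + r2) * (d + r1 + r2), 0.0)
    )
    lens = a1 + a2 - a3
    return float(lens / (np.pi * min(r1, r2) ** 2))


def filter_regions(mask: DetectionMask, config: DetectionConfig) -> DetectionMask:
    """Remove false-positive candidates and relabel contiguously.

    Drops regions outside the area window, above the eccentricity bound,
    below the convexity bound, with a bounding box inside the border
    margin, and both members of candidate pairs whose equivalent discs
    overlap beyond ``overlap_fraction_max``.
    """
    h, w = mask.label_image.shape
    m = config.edge_margin_px
    keep = []
    for reg in mask.regions:
        if not (config.area_min_px <= reg.area_px <= config.area_max_px):
            continue
        if reg.eccentricity > config.eccentricity_max:
            continue
        if reg.convexity < config.convexity_min:
            continue
        r0, c0, r1, c1 = reg.bbox
        if r0 < m or c0 < m or r1 > h - m or c1 > w - m:
            continue
        keep.append(reg)

    overlapping: set[int] = set()
    for i in range(len(keep)):
        for j in range(i + 1, len(keep)):
            a, b = keep[i], keep[j]
            d = float(np.hypot(a.centroid[0] - b.centroid[0],
                               a.centroid[1] - b.centroid[1]))
            if _disc_overlap_fraction(a.equivalent_radius, b.equivalent_radius,
                                      d) > config.overlap_fraction_max:
                overlapping.update((a.label, b.label))
    keep = [r for r in keep if r.label not in overlapping]
    return _relabel(mask.label_image, keep)


# ---------------------------------------------------------------------------
# fusion and evaluation


def fuse_masks(m_bf: DetectionMask | None, m_df: DetectionMask | None,
               m_fl: DetectionMask | None, config: DetectionConfig) -> DetectionMask:
    """Fuse per-modality masks by pixelwise OR under a convexity constraint.

    Connected components of the OR image are kept when their convexity
    (area over convex-hull area) reaches ``convexity_min``: slightly
    offset detections of one particle merge into a convex blob and
    survive, while dumbbells bridging two particles are removed.  Each
    fused region records the modalities whose masks intersect it.
    Absent modalities (None) are simply skipped.
    """
    inputs = [m for m in (m_bf, m_df, m_fl) if m is not None]
    if not inputs:
        raise ValueError("at least one modality mask is required")
    shape = inputs[0].label_image.shape
    if any(m.label_image.shape != shape for m in inputs):
        raise ValueError("masks must share one shape")

    fused_binary = np.zeros(shape, dtype=bool)
    for m in inputs:
        fused_binary |= m.binary()
    labels = measure.label(fused_binary, connectivity=2).astype(np.int32)
    candidate = _regions_from_labels(labels, frozenset())

    keep = [r for r in candidate.regions if r.convexity >= config.convexity_min]
    provenance: dict[int, frozenset[str]] = {}
    for reg in keep:
        sel = labels == reg.label
        mods = {
            next(iter(m.regions[0].modalities))
            for m in inputs
            if m.regions and bool(np.any(m.binary() & sel))
        }
        provenance[reg.label] = frozenset(mods)
    return _relabel(labels, keep, provenance)


def evaluate_detection(mask: DetectionMask, truth) -> tuple[float, float]:
    """(recall, precision) of a mask against SceneTruth.

    A detection matches a true particle when its centroid falls within
    the particle's outer radius; matching is one-to-one, greedy by
    distance.  An empty mask reports (0, 0).
    """
    n_true = truth.n_particles
    n_det = mask.n_regions
    if n_det == 0 or n_true == 0:
        return 0.0, 0.0
    centroids = np.array([r.centroid for r in mask.regions])
    d = np.linalg.norm(centroids[:, None, :] - truth.centers[None, :, :], axis=2)
    r_outer = truth.radii_px[:, 2]
    pairs = [
        (d[i, j], i, j)
        for i in range(n_det)
        for j in range(n_true)
        if d[i, j] <= r_outer[j]
    ]
    pairs.sort(key=lambda p: p[0])
    used_det: set[int] = set()
    used_true: set[int] = set()
    matched = 0
    for _, i, j in pairs:
        if i in used_det or j in used_true:
            continue
        used_det.add(i)
        used_true.add(j)
        matched += 1
    return matched / n_true, matched / n_det
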