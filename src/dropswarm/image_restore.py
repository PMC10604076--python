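"""HDR synthesis and image registration.

Reconstructs a relative-radiance map from an exposure-bracketed stack of
low-dynamic-range (LDR) fluorescence frames using mid-weighted Gaussian
HDR fusion, and brings the bright-field and dark-field images into the
HDR coordinate frame via rigid phase correlation after undoing a
second-order radial (chromatic) aberration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, sobel
from skimage.registration import phase_cross_correlation


class RegistrationError(ValueError):
    """Input has no spectral content usable for phase correlation."""


@dataclass(frozen=True)
class RigidShift:
    """Translation of a moving image relative to a reference, (row, col) px."""

    d_row: float
    d_col: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d_row, self.d_col], dtype=float)


@dataclass
class LDRStack:
    """Exposure-bracketed integer frames with matched exposure times (ms)."""

    frames: list[np.ndarray]
    exposure_times: list[float]
    saturation_value: int
    shifts: list[RigidShift] | None = None  # per-frame shift removed by register_stack

    def __post_init__(self):
        if len(self.frames) != len(self.exposure_times):
            raise ValueError("frames and exposure_times length mismatch")
        if not self.frames:
            raise ValueError("empty stack")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape:
                raise ValueError("all frames must share one shape")
        if any(t <= 0 for t in self.exposure_times):
            raise ValueError("exposure times must be positive")


@dataclass
class HDRImage:
    """Relative radiance map; valid_mask marks pixels with >= 1 usable LDR sample."""

    radiance: np.ndarray
    valid_mask: np.ndarray


@dataclass(frozen=True)
class AberrationModel:
    """Radial mapping r -> r * (1 + a1*r + a2*r^2) about a distortion center."""

    center: tuple[float, float]
    coeffs: tuple[float, float]

    def forward(self, r: np.ndarray) -> np.ndarray:
        a1, a2 = self.coeffs
        return r * (1.0 + a1 * r + a2 * r ** 2)

    def check_monotone(self, r_max: float) -> None:
        r = np.linspace(0.0, r_max, 2048)
        if np.any(np.diff(self.forward(r)) <= 0):
            raise ValueError("aberration mapping not monotone over [0, r_max]")


# ---------------------------------------------------------------------------
# phase correlation


def phase_correlate(reference: np.ndarray, moving: np.ndarray,
                    upsample_factor: int = 20) -> RigidShift:
    """Translation of ``moving`` relative to ``reference``.

    If ``moving == roll(reference, (dr, dc))`` the result is (dr, dc);
    shifting ``moving`` by the negated result aligns it to the
    reference.  Recovers pure integer shifts exactly on noiseless input
    and refines to subpixel via upsampled cross-correlation.
    """
    reference = np.asarray(reference, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if reference.shape != moving.shape:
        raise ValueError("images must share one shape")
    if reference.std() == 0 or moving.std() == 0:
        raise RegistrationError("constant image has no spectral content")
    shift, _, _ = phase_cross_correlation(
        reference, moving, upsample_factor=upsample_factor, normalization=None
    )
    # skimage returns the shift to apply to `moving`; the displacement of
    # moving relative to reference is its negation.
    return RigidShift(float(-shift[0]), float(-shift[1]))


def apply_shift(image: np.ndarray, shift: RigidShift) -> np.ndarray:
    """Translate an image by (d_row, d_col) with edge replication."""
    if shift.d_row == 0 and shift.d_col == 0:
        return np.asarray(image, dtype=float).copy()
    return ndi.shift(np.asarray(image, dtype=float),
                     (shift.d_row, shift.d_col), order=1, mode="nearest")


def register_stack(stack: LDRStack) -> LDRStack:
    """Align every frame to the first via phase correlation.

    The removed displacement of each frame is recorded in ``shifts``
    (the first frame's is (0, 0)).  Out-of-frame pixels introduced by
    shifting are filled by edge replication; they sit inside the
    detection edge margin and are excluded downstream.
    """
    if len(stack.frames) < 2:
        return LDRStack(
            [f.copy() for f in stack.frames],
            list(stack.exposure_times),
            stack.saturation_value,
            shifts=[RigidShift(0.0, 0.0)] * len(stack.frames),
        )
    ref = stack.frames[0].astype(float)
    out_frames = [stack.frames[0].copy()]
    shifts = [RigidShift(0.0, 0.0)]
    sat = stack.saturation_value
    for frame in stack.frames[1:]:
        d = phase_correlate(ref, frame.astype(float))
        aligned = apply_shift(frame.astype(float), RigidShift(-d.d_row, -d.d_col))
        out_frames.append(np.clip(np.rint(aligned), 0, sat).astype(frame.dtype))
        shifts.append(d)
    return LDRStack(out_frames, list(stack.exposure_times), sat, shifts=shifts)


# ---------------------------------------------------------------------------
# HDR synthesis


def _hdr_weights(z: np.ndarray, saturation_value: int) -> np.ndarray:
    """Gaussian weight centered mid-range; clipped values carry no information."""
    mid = saturation_value / 2.0
    sigma = saturation_value / 4.0
    w = np.exp(-((z - mid) ** 2) / (2.0 * sigma ** 2))
    w[z >= saturation_value] = 0.0
    return w


def synthesize_hdr(stack: LDRStack) -> HDRImage:
    """Fuse a registered LDR bracket into relative radiance (DN/ms).

    Per pixel: ``sum_i w(z_i) * z_i / t_i / sum_i w(z_i)`` with a
    Gaussian weight centered at half the saturation value (sigma a
    quarter of it) that down-weights under- and over-exposed samples and
    zeroes clipped ones.  Pixels saturated in every frame fall back to
    the shortest exposure's estimate and are flagged invalid.
    """
    z = np.stack([f.astype(np.float64) for f in stack.frames])
    t = np.asarray(stack.exposure_times, dtype=np.float64)[:, None, None]
    w = _hdr_weights(z, stack.saturation_value)
    wsum = w.sum(axis=0)
    valid = wsum > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        radiance = np.where(valid, (w * (z / t)).sum(axis=0) / wsum, 0.0)
    if not valid.all():
        i_short = int(np.argmin(np.asarray(stack.exposure_times)))
        fallback = z[i_short] / float(stack.exposure_times[i_short])
        radiance = np.where(valid, radiance, fallback)
    return HDRImage(radiance=radiance, valid_mask=valid)


# ---------------------------------------------------------------------------
# aberration correction


def default_aberration_model(shape: tuple[int, int],
                             coeffs: tuple[float, float]) -> AberrationModel:
    h, w = shape
    return AberrationModel(center=((h - 1) / 2.0, (w - 1) / 2.0), coeffs=coeffs)


def correct_aberration(image: np.ndarray, model: AberrationModel) -> np.ndarray:
    """Undo the radial distortion of ``model`` by inverse warping.

    The corrected value at ideal radius r is sampled from the distorted
    image at radius ``model.forward(r)`` (bilinear interpolation), which
    inverts the distortion without an explicit closed-form inverse.
    """
    image = np.asarray(image, dtype=float)
    a1, a2 = model.coeffs
    if a1 == 0 and a2 == 0:
        return image.copy()
    h, w = image.shape
    cr, cc = model.center
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dr, dc = rows - cr, cols - cc
    r = np.hypot(dr, dc)
    model.check_monotone(float(r.max()))
    r_dist = model.forward(r)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r > 0, r_dist / r, 1.0)
    coords = np.stack([cr + dr * scale, cc + dc * scale])
    return ndi.map_coordinates(image, coords, order=1, mode="nearest")


# ---------------------------------------------------------------------------
# cross-modality registration


def _edge_blob_image(image: np.ndarray, smooth_sigma: float) -> np.ndarray:
    """Gradient magnitude smoothed to particle-scale blobs.

    The three modalities place their sharp edges at different concentric
    radii of the same particles (shell rim vs PEG ring), so raw
    cross-modality phase correlation has no unique peak; smoothing the
    gradient magnitude to blob scale restores one at the true offset.
    """
    g = sobel(np.asarray(image, dtype=float))
    g = gaussian(g, sigma=smooth_sigma, preserve_range=True)
    return g - g.mean()


def register_to_reference(image: np.ndarray, reference: HDRImage,
                          smooth_sigma: float = 15.0) -> tuple[np.ndarray, RigidShift]:
    """Resample a bright/dark-field image into the HDR coordinate frame.

    Returns the registered image and the displacement that was removed.
    ``smooth_sigma`` (px) should be on the order of the particle radius.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != reference.radiance.shape:
        raise ValueError("image and reference must share one shape")
    shift = phase_correlate(
        _edge_blob_image(reference.radiance, smooth_sigma),
        _edge_blob_image(image, smooth_sigma),
    )
    registered = apply_shift(image, RigidShift(-shift.d_row, -shift.d_col))
    return registered, shift
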