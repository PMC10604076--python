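"""Ground-truthed synthetic multimodal well images.

The assay this package reads out suspends ~300 um amphiphilic particles
(a fluorescent aqueous droplet wrapped in a PEG hydrogel ring and a
non-fluorescent outer shell) in a well that is imaged in three
modalities: an exposure-bracketed fluorescence stack, a bright-field
image and a dark-field image.  This module renders such wells from a
known particle layout so that every downstream stage — HDR synthesis,
registration, detection, quantification, swarm statistics — can be
tested against ground truth without any external data.

Geometry per particle (concentric, radii in micrometers):

    droplet disc  (r < r_droplet)            fluorescent, radiance L
    PEG ring      (r_droplet <= r < r_peg)   fluorescent, peg_enrichment * L
    outer shell   (r_peg <= r < r_outer)     non-fluorescent

Per-particle radiance L is drawn log-normally around a
linear-with-saturation dose response, emulating particle-to-particle
dispersion.  Bright-field shows dark particle rims on a bright
background; dark-field shows bright scattering rings on a dark
background.  Bright- and dark-field carry configurable rigid shifts and
a second-order radial (chromatic-aberration-like) warp relative to the
fluorescence frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all particles."""


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic well.

    Radiance is expressed in sensor digital numbers per millisecond of
    exposure (DN/ms), so an LDR frame is ``clip(radiance * t_ms + noise)``
    at the configured bit depth.
    """

    image_height_px: int = 2464
    image_width_px: int = 3280
    pixel_scale: float = 5.6  # um per pixel (~0.2x magnification)
    n_particles: int = 150
    r_outer_um: float = 150.0
    r_peg_um: float = 120.0
    r_droplet_um: float = 90.0
    min_center_spacing_px: float | None = None  # default: 2.2 * r_outer_px
    edge_margin_px: int = 12
    concentration: float = 1.0  # analyte, ng/mL
    dose_slope: float = 0.6  # DN/ms per ng/mL
    dose_intercept: float = 0.05  # DN/ms at zero dose
    dose_saturation: float = 6.0  # DN/ms plateau
    particle_cv: float = 0.25
    peg_enrichment: float = 2.0
    background_level: float = 0.02  # DN/ms
    noise_sd: float = 2.0  # DN, additive per LDR frame
    aberration_coeffs_bf: tuple[float, float] = (2.0e-6, 0.0)
    aberration_coeffs_df: tuple[float, float] = (3.0e-6, 0.0)
    shift_bf: tuple[float, float] = (4.0, -6.0)  # (row, col) px
    shift_df: tuple[float, float] = (-5.0, 3.0)
    exposure_times_ms: tuple[float, ...] = (100.0, 500.0, 1000.0, 2000.0)
    bit_depth: int = 10
    seed: int = 0

    # -- derived quantities -------------------------------------------------

    @property
    def saturation_value(self) -> int:
        return 2 ** self.bit_depth - 1

    @property
    def r_outer_px(self) -> float:
        return self.r_outer_um / self.pixel_scale

    @property
    def r_peg_px(self) -> float:
        return self.r_peg_um / self.pixel_scale

    @property
    def r_droplet_px(self) -> float:
        return self.r_droplet_um / self.pixel_scale

    @property
    def spacing_px(self) -> float:
        if self.min_center_spacing_px is not None:
            return self.min_center_spacing_px
        return 2.2 * self.r_outer_px

    def dose_response_mean(self, concentration: float | None = None) -> float:
        """Mean droplet radiance (DN/ms) at a concentration, linear with plateau."""
        c = self.concentration if concentration is None else concentration
        return float(min(self.dose_intercept + self.dose_slope * c, self.dose_saturation))

    def validate(self) -> None:
        if not (0 < self.r_droplet_um < self.r_peg_um < self.r_outer_um):
            raise ValueError("radii must satisfy 0 < droplet < peg < outer")
        t = np.asarray(self.exposure_times_ms, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("exposure_times_ms must be positive and strictly increasing")
        if self.n_particles <= 0:
            raise ValueError("n_particles must be positive")
        for name in ("pixel_scale", "peg_enrichment"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.peg_enrichment < 1:
            raise ValueError("peg_enrichment must be >= 1")
        for name in ("particle_cv", "background_level", "noise_sd", "concentration"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kw) -> "SceneConfig":
        return dataclasses.replace(self, **kw)


def compact_well_config(seed: int = 0, **overrides) -> SceneConfig:
    """A half-field well retaining full particle scale and count.

    Same optics (5.6 um/px, ~54 px particle diameter) and the default
    ~150 particles as the full-frame configuration, on a 1640x1232 crop
    of the sensor.  This is the standard desk-scale study condition used
    by the package's examples and validation runs.
    """
    cfg = SceneConfig(image_height_px=1232, image_width_px=1640, seed=seed)
    return cfg.replace(**overrides) if overrides else cfg


@dataclass
class SceneTruth:
    """Ground-truth layout and radiometry for one synthetic well."""

    centers: np.ndarray  # (n, 2) float, (row, col), 0-based
    radii_px: np.ndarray  # (n, 3) float, columns (droplet, peg, outer)
    true_radiance: np.ndarray  # (n, 3) float, columns (droplet, peg, combined)
    label_map: np.ndarray  # (H, W) int32, 0 = background
    shortfall: int = 0  # particles requested minus particles placed

    @property
    def n_particles(self) -> int:
        return int(self.centers.shape[0])


# ---------------------------------------------------------------------------
# scene sampling


def _lognormal_radiance(rng: np.random.Generator, mean: float, cv: float, n: int) -> np.ndarray:
    """Log-normal draws with the given arithmetic mean and coefficient of variation."""
    if cv == 0 or mean == 0:
        return np.full(n, mean, dtype=float)
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)


def sample_scene(config: SceneConfig, max_attempts_per_particle: int = 2000) -> SceneTruth:
    """Place particles by rejection sampling and assign ground-truth radiance.

    Centers keep ``edge_margin_px + r_outer`` clear of the borders (a
    negative ``edge_margin_px`` deliberately allows edge-touching
    particles for exclusion tests) and pairwise spacing of at least
    ``spacing_px``.  Deterministic for a fixed ``config.seed``.

    Raises
    ------
    PlacementError
        If the configuration is over-packed and placement fails after a
        bounded number of attempts.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height_px, config.image_width_px
    margin = config.edge_margin_px + config.r_outer_px
    lo_r, hi_r = margin, h - 1 - margin
    lo_c, hi_c = margin, w - 1 - margin
    if hi_r <= lo_r or hi_c <= lo_c:
        raise PlacementError("image too small for the requested margin and particle size")

    spacing2 = config.spacing_px ** 2
    centers: list[tuple[float, float]] = []
    attempts = 0
    budget = max_attempts_per_particle * config.n_particles
    while len(centers) < config.n_particles:
        if attempts >= budget:
            raise PlacementError(
                f"placed {len(centers)}/{config.n_particles} particles after "
                f"{attempts} attempts; configuration is over-packed"
            )
        attempts += 1
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= spacing2 for rr, cc in centers):
            centers.append((r, c))

    centers_arr = np.asarray(centers, dtype=float)
    n = centers_arr.shape[0]
    radii = np.tile(
        np.array([config.r_droplet_px, config.r_peg_px, config.r_outer_px]), (n, 1)
    )

    mean = config.dose_response_mean()
    droplet_l = _lognormal_radiance(rng, mean, config.particle_cv, n)
    peg_l = config.peg_enrichment * droplet_l
    a_drop = np.pi * config.r_droplet_px ** 2
    a_peg = np.pi * (config.r_peg_px ** 2 - config.r_droplet_px ** 2)
    combined_l = (a_drop * droplet_l + a_peg * peg_l) / (a_drop + a_peg)
    true_radiance = np.stack([droplet_l, peg_l, combined_l], axis=1)

    label_map = np.zeros((h, w), dtype=np.int32)
    r_out = config.r_outer_px
    for i, (cr, cc) in enumerate(centers_arr, start=1):
        _paint_disc(label_map, cr, cc, r_out, i, only_background=True)

    return SceneTruth(
        centers=centers_arr,
        radii_px=radii,
        true_radiance=true_radiance,
        label_map=label_map,
        shortfall=config.n_particles - n,
    )


def _paint_disc(img: np.ndarray, cr: float, cc: float, radius: float, value,
                only_background: bool = False) -> None:
    """Assign ``value`` to pixels within ``radius`` of (cr, cc), in place."""
    h, w = img.shape
    r0 = max(int(np.floor(cr - radius)), 0)
    r1 = min(int(np.ceil(cr + radius)) + 1, h)
    c0 = max(int(np.floor(cc - radius)), 0)
    c1 = min(int(np.ceil(cc + radius)) + 1, w)
    rr, cols = np.ogrid[r0:r1, c0:c1]
    inside = (rr - cr) ** 2 + (cols - cc) ** 2 < radius ** 2
    if only_background:
        inside &= img[r0:r1, c0:c1] == 0
    img[r0:r1, c0:c1][inside] = value


def _paint_annulus(img: np.ndarray, cr: float, cc: float, r_in: float, r_out: float,
                   value: float) -> None:
    h, w = img.shape
    r0 = max(int(np.floor(cr - r_out)), 0)
    r1 = min(int(np.ceil(cr + r_out)) + 1, h)
    c0 = max(int(np.floor(cc - r_out)), 0)
    c1 = min(int(np.ceil(cc + r_out)) + 1, w)
    rr, cols = np.ogrid[r0:r1, c0:c1]
    d2 = (rr - cr) ** 2 + (cols - cc) ** 2
    band = (d2 >= r_in ** 2) & (d2 < r_out ** 2)
    img[r0:r1, c0:c1][band] = value


# ---------------------------------------------------------------------------
# rendering


def radiance_map(truth: SceneTruth, config: SceneConfig) -> np.ndarray:
    """Fluorescence radiance (DN/ms): background + droplet discs + PEG rings."""
    rad = np.full(
        (config.image_height_px, config.image_width_px),
        config.background_level,
        dtype=np.float64,
    )
    for i in range(truth.n_particles):
        cr, cc = truth.centers[i]
        r_d, r_p, _ = truth.radii_px[i]
        droplet_l, peg_l, _ = truth.true_radiance[i]
        _paint_annulus(rad, cr, cc, r_d, r_p, peg_l)
        _paint_disc(rad, cr, cc, r_d, droplet_l)
    return rad


def _radial_warp(image: np.ndarray, coeffs: tuple[float, float],
                 center: tuple[float, float] | None = None) -> np.ndarray:
    """Render the distorted view of ``image`` under r -> r(1 + a1 r + a2 r^2).

    A point of the ideal image at radius r appears in the distorted view
    at radius f(r); the distorted image is therefore sampled from the
    ideal one at the numerically inverted radius.
    """
    a1, a2 = coeffs
    if a1 == 0 and a2 == 0:
        return image.copy()
    h, w = image.shape
    if center is None:
        center = ((h - 1) / 2.0, (w - 1) / 2.0)
    cr, cc = center
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dr, dc = rows - cr, cols - cc
    s = np.hypot(dr, dc)
    r_max = float(s.max())
    grid = np.linspace(0.0, 1.2 * r_max, 4096)
    f = grid * (1.0 + a1 * grid + a2 * grid ** 2)
    if np.any(np.diff(f) <= 0):
        raise ValueError("aberration mapping not monotone over the image radii")
    r_src = np.interp(s, f, grid)  # f^{-1}(s)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(s > 0, r_src / s, 1.0)
    coords = np.stack([cr + dr * scale, cc + dc * scale])
    return ndi.map_coordinates(image, coords, order=1, mode="nearest")


def _rigid_shift(image: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    if shift == (0.0, 0.0):
        return image.copy()
    return ndi.shift(image, shift, order=1, mode="nearest")


def render_modalities(truth: SceneTruth, config: SceneConfig):
    """Render (fluorescence LDR stack, bright-field, dark-field) for a well.

    Returns
    -------
    frames : list of (H, W) uint16 arrays, one per exposure time
    bright_field : (H, W) float64 in [0, 1]
    dark_field : (H, W) float64 in [0, 1]

    The LDR frames are ``clip(rint(radiance * t + noise), 0, 2^bit_depth - 1)``.
    Bright-field shows a bright background with darkened particle rims;
    dark-field a dark background with bright PEG-ring scattering.  Both
    carry the configured rigid shifts and radial aberration warp.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 917]))
    rad = radiance_map(truth, config)
    sat = config.saturation_value

    frames = []
    for t in config.exposure_times_ms:
        frame = rad * t
        if config.noise_sd > 0:
            frame = frame + rng.normal(0.0, config.noise_sd, size=frame.shape)
        frames.append(np.clip(np.rint(frame), 0, sat).astype(np.uint16))

    h, w = rad.shape
    bf = np.full((h, w), 0.85, dtype=np.float64)
    df = np.full((h, w), 0.05, dtype=np.float64)
    rim = max(2.0, 0.08 * config.r_outer_px)
    for i in range(truth.n_particles):
        cr, cc = truth.centers[i]
        r_d, r_p, r_o = truth.radii_px[i]
        # bright-field: slightly darker interior, dark rim at the shell edge
        _paint_disc(bf, cr, cc, r_o, 0.75)
        _paint_annulus(bf, cr, cc, r_o - rim, r_o, 0.25)
        # dark-field: bright scattering over the PEG ring, faint shell rim
        _paint_annulus(df, cr, cc, r_o - rim, r_o, 0.35)
        _paint_annulus(df, cr, cc, r_d, r_p, 0.75)

    bf = _radial_warp(bf, config.aberration_coeffs_bf)
    df = _radial_warp(df, config.aberration_coeffs_df)
    bf = _rigid_shift(bf, config.shift_bf)
    df = _rigid_shift(df, config.shift_df)
    if config.noise_sd > 0:
        amp = config.noise_sd / (config.saturation_value + 1)
        bf = bf + rng.normal(0.0, amp, size=bf.shape)
        df = df + rng.normal(0.0, amp, size=df.shape)
    return frames, np.clip(bf, 0.0, 1.0), np.clip(df, 0.0, 1.0)


# ---------------------------------------------------------------------------
# intensity populations (stand-in for measured per-particle populations)


def sample_intensity_population(
    concentration: float,
    n: int,
    dose_params: tuple[float, float, float] = (0.6, 0.05, 6.0),
    cv: float = 0.25,
    seed: int = 0,
) -> np.ndarray:
    """Log-normal per-particle intensity population at a given dose.

    ``dose_params`` is (slope, intercept, saturation) of the
    linear-with-plateau dose response; ``cv`` the particle-to-particle
    coefficient of variation.  Deterministic per seed.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    slope, intercept, saturation = dose_params
    mean = min(intercept + slope * concentration, saturation)
    rng = np.random.default_rng(seed)
    return _lognormal_radiance(rng, mean, cv, n)
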