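"""Synthetic colorimetric well-image generator.

Emulates scanner images of AuNP–aptamer assay solutions in which the
solution color encodes amoxicillin concentration: dispersed gold
nanoparticles are purple-red, salt-aggregated ones blue-purple, and the
degree of aggregation rises monotonically with analyte concentration.
Concentration is mapped to an aggregation fraction by a Hill dose-response
curve, the fraction to a solution color by channel-wise linear
interpolation between the two endpoint colors, and the color to a raster
by drawing a jittered disk on a light background with multiplicative
lighting gain, radial vignetting and per-pixel Gaussian noise.

Every image is a pure function of its parameters and an integer seed, so
datasets regenerate bit-identically from a single master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DEFAULT_CONCENTRATIONS",
    "DoseResponseParams",
    "ColorModel",
    "RenderParams",
    "WellImage",
    "SyntheticDataset",
    "aggregation_fraction",
    "solution_color",
    "spectral_ratio",
    "render_well_image",
    "generate_dataset",
]

#: The 12-level amoxicillin concentration design, in µM.
DEFAULT_CONCENTRATIONS: tuple[float, ...] = (
    0.0, 0.05, 0.1, 0.2, 0.3, 0.5, 0.7, 1.1, 1.5, 2.3, 3.1, 3.9,
)

#: Replicates per concentration level in the default design.
DEFAULT_N_PER_GROUP = 100


@dataclass(frozen=True)
class DoseResponseParams:
    """Hill dose-response linking concentration (µM) to AuNP aggregation.

    ``ratio_min``/``ratio_max`` are the A620/A520 absorbance-ratio
    surrogates at zero and full aggregation (higher ratio = more
    aggregated).
    """

    ec50: float = 0.7        # µM; half-aggregation concentration
    hill_n: float = 1.2      # Hill cooperativity exponent
    ratio_min: float = 0.18  # dispersed-limit A620/A520 surrogate
    ratio_max: float = 0.95  # aggregated-limit A620/A520 surrogate
    # assay replication noise: per-replicate effective concentration is
    # c·(1 + N(0, conc_cv)) + N(0, conc_sd_abs), clipped at 0, emulating
    # pipetting/incubation variability of the wet assay. The image label
    # remains the design concentration.
    conc_cv: float = 0.12        # relative replicate variability
    conc_sd_abs: float = 0.03    # µM; absolute (blank-level) variability

    def __post_init__(self) -> None:
        if self.ec50 <= 0:
            raise ValueError(f"ec50 must be > 0, got {self.ec50}")
        if self.hill_n <= 0:
            raise ValueError(f"hill_n must be > 0, got {self.hill_n}")
        if not self.ratio_min < self.ratio_max:
            raise ValueError("ratio_min must be < ratio_max")
        if self.conc_cv < 0 or self.conc_sd_abs < 0:
            raise ValueError("replication noise parameters must be >= 0")


@dataclass(frozen=True)
class ColorModel:
    """Endpoint solution colors: dispersed purple-red vs aggregated blue-purple."""

    dispersed_rgb: tuple[float, float, float] = (178.0, 60.0, 96.0)
    aggregated_rgb: tuple[float, float, float] = (96.0, 72.0, 158.0)

    def __post_init__(self) -> None:
        for rgb in (self.dispersed_rgb, self.aggregated_rgb):
            if len(rgb) != 3 or not all(0 <= v <= 255 for v in rgb):
                raise ValueError(f"RGB triple out of [0, 255]: {rgb}")
        if tuple(self.dispersed_rgb) == tuple(self.aggregated_rgb):
            raise ValueError("endpoint colors must differ in at least one channel")


@dataclass(frozen=True)
class RenderParams:
    """Raster rendering / capture-nuisance parameters.

    The well disk is drawn at a jittered center and radius; the whole frame
    is modulated by a per-image multiplicative lighting gain and a radial
    vignette, then per-pixel Gaussian noise is added and the result clipped
    to [0, 255] 8-bit.
    """

    image_size: int = 128
    well_radius_mean: float = 44.0   # px
    well_radius_jitter: float = 4.0  # px, uniform half-width
    center_jitter: float = 5.0       # px, uniform half-width per axis
    lighting_gain_sd: float = 0.008  # multiplicative, per image
    pixel_noise_sd: float = 5.0      # intensity units, per pixel per channel
    background_rgb: tuple[float, float, float] = (232.0, 229.0, 224.0)
    vignette_strength: float = 0.06  # dimensionless in [0, 1)

    def __post_init__(self) -> None:
        if self.image_size < 50:
            raise ValueError("image_size must be >= 50")
        for name in ("well_radius_jitter", "center_jitter",
                     "lighting_gain_sd", "pixel_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.vignette_strength < 1:
            raise ValueError("vignette_strength must be in [0, 1)")
        max_reach = (self.image_size - 1) / 2 + self.center_jitter \
            + self.well_radius_mean + self.well_radius_jitter
        if max_reach > self.image_size - 1:
            raise ValueError(
                "well can exceed the frame under maximal jitter: "
                f"reach {max_reach:.1f} px vs frame {self.image_size} px"
            )


@dataclass
class WellImage:
    """One assay image: H×W×3 RGB raster plus optional true concentration."""

    pixels: np.ndarray                 # H×W×3, values in [0, 255], R,G,B order
    true_conc: float | None = None     # µM
    seed_tag: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H×W×3, got shape {px.shape}")
        if px.shape[0] < 50 or px.shape[1] < 50:
            raise ValueError("image must be at least 50×50")
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


@dataclass
class SyntheticDataset:
    """A full synthetic calibration set: |images| = |concentrations| × n_per_group."""

    images: list[WellImage]
    concentrations: tuple[float, ...]
    n_per_group: int
    master_seed: int

    def labels(self) -> np.ndarray:
        return np.array([im.true_conc for im in self.images], dtype=float)

    def __len__(self) -> int:
        return len(self.images)


def aggregation_fraction(c: float, p: DoseResponseParams) -> float:
    """Aggregated fraction of AuNPs at concentration ``c`` µM (Hill curve).

    f(c) = c^n / (c^n + ec50^n): zero at zero dose, 0.5 at ``ec50``,
    strictly increasing and saturating below 1.
    """
    c = float(c)
    if c < 0:
        raise ValueError(f"concentration must be >= 0, got {c}")
    if c == 0.0:
        return 0.0
    cn = c ** p.hill_n
    return cn / (cn + p.ec50 ** p.hill_n)


def solution_color(f: float, cm: ColorModel) -> np.ndarray:
    """Solution RGB at aggregation fraction ``f``: linear blend of endpoints."""
    f = float(f)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"aggregation fraction must be in [0, 1], got {f}")
    lo = np.asarray(cm.dispersed_rgb, dtype=float)
    hi = np.asarray(cm.aggregated_rgb, dtype=float)
    return lo + f * (hi - lo)


def spectral_ratio(f: float, p: DoseResponseParams) -> float:
    """A620/A520-style aggregation index at fraction ``f`` (affine surrogate)."""
    f = float(f)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"aggregation fraction must be in [0, 1], got {f}")
    return p.ratio_min + f * (p.ratio_max - p.ratio_min)


def well_geometry(rp: RenderParams, seed: int) -> tuple[float, float, float]:
    """Ground-truth (cx, cy, radius) of the disk rendered for this seed."""
    rng = np.random.default_rng(seed)
    mid = (rp.image_size - 1) / 2.0
    radius = rp.well_radius_mean + rng.uniform(-1, 1) * rp.well_radius_jitter
    cx = mid + rng.uniform(-1, 1) * rp.center_jitter
    cy = mid + rng.uniform(-1, 1) * rp.center_jitter
    return cx, cy, radius


def render_well_image(
    color: Sequence[float],
    rp: RenderParams = RenderParams(),
    seed: int = 0,
    true_conc: float | None = None,
) -> WellImage:
    """Render one well image of the given solution color.

    Identical ``(color, rp, seed)`` produce bit-identical rasters.
    """
    rng = np.random.default_rng(seed)
    n = rp.image_size
    mid = (n - 1) / 2.0

    radius = rp.well_radius_mean + rng.uniform(-1, 1) * rp.well_radius_jitter
    cx = mid + rng.uniform(-1, 1) * rp.center_jitter
    cy = mid + rng.uniform(-1, 1) * rp.center_jitter
    if (cx - radius < 0 or cx + radius > n - 1
            or cy - radius < 0 or cy + radius > n - 1):
        raise ValueError("rendered well exceeds the frame; check RenderParams")

    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    img = np.empty((n, n, 3), dtype=float)
    img[:] = np.asarray(rp.background_rgb, dtype=float)
    disk = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius ** 2
    img[disk] = np.asarray(color, dtype=float)

    if rp.vignette_strength > 0:
        half_diag = np.hypot(mid, mid)
        d2 = ((xx - mid) ** 2 + (yy - mid) ** 2) / half_diag ** 2
        img *= (1.0 - rp.vignette_strength * d2)[..., None]

    gain = 1.0 + rng.normal(0.0, rp.lighting_gain_sd) if rp.lighting_gain_sd > 0 else 1.0
    img *= max(gain, 0.1)

    if rp.pixel_noise_sd > 0:
        img += rng.normal(0.0, rp.pixel_noise_sd, size=img.shape)

    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return WellImage(pixels=pixels, true_conc=true_conc, seed_tag=f"seed={seed}")


def _image_seed(master_seed: int, group_index: int, replicate_index: int) -> int:
    """Stable per-image seed: master seed hashed with (level, replicate)."""
    ss = np.random.SeedSequence([int(master_seed), group_index, replicate_index])
    return int(ss.generate_state(1)[0])


def generate_dataset(
    concentrations: Sequence[float] = DEFAULT_CONCENTRATIONS,
    n_per_group: int = DEFAULT_N_PER_GROUP,
    dose: DoseResponseParams = DoseResponseParams(),
    colors: ColorModel = ColorModel(),
    render: RenderParams = RenderParams(),
    master_seed: int = 0,
) -> SyntheticDataset:
    """Generate the full seeded calibration dataset.

    Per-image seeds derive deterministically from ``master_seed`` and the
    (level, replicate) pair, so generation order never matters and two runs
    with the same master seed are identical.
    """
    concentrations = tuple(float(c) for c in concentrations)
    if len(concentrations) == 0:
        raise ValueError("concentration design must be non-empty")
    if any(c < 0 for c in concentrations):
        raise ValueError("negative concentration levels are not allowed")
    if len(set(concentrations)) != len(concentrations):
        warnings.warn("duplicate concentration levels in design", stacklevel=2)
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")

    images: list[WellImage] = []
    for gi, c in enumerate(concentrations):
        for ri in range(n_per_group):
            seed = _image_seed(master_seed, gi, ri)
            # separate stream for the chemistry so it never aliases the
            # render stream that starts from the same (level, replicate)
            chem = np.random.default_rng(
                np.random.SeedSequence([int(master_seed), gi, ri, 1])
            )
            c_eff = c * (1.0 + chem.normal(0.0, dose.conc_cv)) \
                + chem.normal(0.0, dose.conc_sd_abs)
            c_eff = max(c_eff, 0.0)
            rgb = solution_color(aggregation_fraction(c_eff, dose), colors)
            im = render_well_image(rgb, render, seed=seed, true_conc=c)
            im.seed_tag = f"g{gi:02d}r{ri:03d}s{seed}"
            images.append(im)
    return SyntheticDataset(
        images=images,
        concentrations=concentrations,
        n_per_group=int(n_per_group),
        master_seed=int(master_seed),
    )
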