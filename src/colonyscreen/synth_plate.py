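"""Synthetic matrix-deposited plate generator.

No deposited-plate image data exists for this platform, so every downstream
stage is exercised against simulated plates with known ground truth.  The
generator emulates the salient features of a real print:

* grid-positioned colonies at ~94% occupancy (deposition viability), with a
  small per-position doublet rate for coincident depositions;
* a variant mix (default: 0.5% x5_FLuc_red spiked into x5_FLuc);
* log-normal colony brightness calibrated to a clonal-plate intensity
  distribution of mean 0.14, SD 0.03 (arbitrary imager units);
* density-dependent colony radius (colonies shrink as matrix density grows);
* rendering through any bandpass filter set onto a dark background with a
  Gaussian PSF, shot noise and read noise, 16-bit by default.

Doublets are co-located at a single node and rendered as one disc whose
spectrum is the brightness-weighted sum of its two members — matching the
optical inability to resolve coincident depositions.

All randomness flows from one seeded generator in a fixed draw order
(occupancy, doublet flags, variant picks, brightnesses), so a plate is fully
reproducible from its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image
from scipy.ndimage import gaussian_filter

from .plate_layout import PlateLayout
from .spectral_screen import (
    DEFAULT_BANDS,
    REFERENCE_SPECTRA,
    EmissionSpectrum,
    FilterBand,
    band_intensity,
)

__all__ = [
    "OpticsModel",
    "ColonySite",
    "GroundTruthPlate",
    "RenderedPlate",
    "sample_ground_truth",
    "colony_radius_model",
    "render_plate",
    "write_image",
    "read_image",
    "DEFAULT_BRIGHTNESS_MEAN",
    "DEFAULT_BRIGHTNESS_CV",
    "DEFAULT_VARIANT_MIX",
]

#: Brightness calibration: clonal-plate colony intensity mean 0.14, SD 0.03
#: (imager units are arbitrary; only relative statistics are meaningful).
DEFAULT_BRIGHTNESS_MEAN = 0.14
DEFAULT_BRIGHTNESS_CV = 0.03 / 0.14

#: The flagship screening condition: a 0.5% red-shifted spike-in.
DEFAULT_VARIANT_MIX: dict[str, float] = {"x5_FLuc": 0.995, "x5_FLuc_red": 0.005}

#: Deposition viability and doublet rate of the printing process.
DEFAULT_VIABILITY = 0.94
DEFAULT_DOUBLET_RATE = 0.004


@dataclass(frozen=True)
class OpticsModel:
    """Camera/optics model for rendering.

    ``gain`` converts brightness units into expected detector counts, so a
    median colony (brightness 0.14) integrates to ~2.8e4 counts across a
    band set — comfortably above the default background of 100 counts/px.
    """

    pixel_um: float = 25.0
    psf_sigma_px: float = 1.0
    background_level: float = 100.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    bit_depth: int = 16
    gain: float = 2.0e5

    def __post_init__(self) -> None:
        if self.pixel_um <= 0:
            raise ValueError("pixel_um must be positive")
        for name in ("psf_sigma_px", "background_level", "read_noise_sd", "gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def saturation(self) -> int:
        return 2**self.bit_depth - 1

    def noiseless(self) -> "OpticsModel":
        """Copy with all noise sources off (PSF retained)."""
        return OpticsModel(
            pixel_um=self.pixel_um,
            psf_sigma_px=self.psf_sigma_px,
            background_level=self.background_level,
            read_noise_sd=0.0,
            shot_noise=False,
            bit_depth=self.bit_depth,
            gain=self.gain,
        )


@dataclass(frozen=True)
class ColonySite:
    """One occupied matrix node; doublets carry two variants/brightnesses."""

    row: int
    col: int
    occupancy: str  # 'single' | 'double'
    variant_ids: tuple[str, ...]
    brightnesses: tuple[float, ...]
    radius_px: float

    def __post_init__(self) -> None:
        expected = 2 if self.occupancy == "double" else 1
        if len(self.variant_ids) != expected or len(self.brightnesses) != expected:
            raise ValueError(
                f"{self.occupancy} site must carry exactly {expected} variant(s)"
            )

    @property
    def brightness(self) -> float:
        return float(sum(self.brightnesses))

    @property
    def variant(self) -> str:
        return "+".join(self.variant_ids)


@dataclass
class GroundTruthPlate:
    """Simulated plate: layout plus the occupied sites (empties are implicit)."""

    layout: PlateLayout
    sites: list[ColonySite]
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def occupied_count(self) -> int:
        return len(self.sites)

    @property
    def occupied_fraction(self) -> float:
        return self.occupied_count / self.layout.n_points

    def sites_with(self, variant: str, occupancy: str | None = None) -> list[ColonySite]:
        out = [s for s in self.sites if variant in s.variant_ids]
        if occupancy is not None:
            out = [s for s in out if s.occupancy == occupancy]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Truth table: one row per occupied position."""
        return pd.DataFrame(
            [
                {
                    "row": s.row,
                    "col": s.col,
                    "occupancy": s.occupancy,
                    "variant": s.variant,
                    "brightness": s.brightness,
                    "radius_px": s.radius_px,
                }
                for s in self.sites
            ],
            columns=["row", "col", "occupancy", "variant", "brightness", "radius_px"],
        )


def colony_radius_model(
    density_per_cm2: float,
    r_ref_px: float = 5.0,
    d_ref: float = 400.0,
    alpha: float = 1.0 / 3.0,
) -> float:
    """Density-dependent colony radius: ``r = r_ref * (d_ref / d) ** alpha``.

    Colonies compete for nutrients, so area shrinks monotonically as matrix
    density rises; the default exponent 1/3 gives a gentle power law that
    passes through ``r_ref_px`` at the reference density.  ``alpha=0`` turns
    the dependence off.
    """
    if density_per_cm2 <= 0:
        raise ValueError("density must be positive")
    if r_ref_px <= 0 or d_ref <= 0:
        raise ValueError("reference radius and density must be positive")
    return float(r_ref_px * (d_ref / density_per_cm2) ** alpha)


def sample_ground_truth(
    layout: PlateLayout,
    viability: float = DEFAULT_VIABILITY,
    doublet_rate: float = DEFAULT_DOUBLET_RATE,
    variant_mix: Mapping[str, float] | None = None,
    brightness_mean: float = DEFAULT_BRIGHTNESS_MEAN,
    brightness_cv: float = DEFAULT_BRIGHTNESS_CV,
    seed: int = 0,
    radius_px: float | None = None,
) -> GroundTruthPlate:
    """Draw a ground-truth plate.

    Each node independently: empty with probability ``1 - viability``;
    otherwise a single deposition, or a co-located double with probability
    ``doublet_rate``.  Cell variants are i.i.d. draws from ``variant_mix``;
    per-cell brightness is log-normal with the stated mean and CV.  The
    colony radius defaults to the density law at the layout's own matrix
    density.
    """
    if not 0.0 <= viability <= 1.0:
        raise ValueError("viability must lie in [0, 1]")
    if not 0.0 <= doublet_rate <= 1.0:
        raise ValueError("doublet_rate must lie in [0, 1]")
    mix = dict(DEFAULT_VARIANT_MIX if variant_mix is None else variant_mix)
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"variant_mix fractions sum to {total!r}, not 1")
    if any(f < 0 for f in mix.values()):
        raise ValueError("variant fractions must be non-negative")

    if radius_px is None:
        d = layout.nominal_density_per_cm2()
        radius_px = colony_radius_model(d) if d else 5.0

    names = sorted(mix)
    probs = np.array([mix[n] for n in names], dtype=float)
    probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    n = layout.n_points
    # fixed draw order: occupancy, doublet flags, variant picks, brightnesses
    occupied = rng.random(n) < viability
    doubles = rng.random(n) < doublet_rate
    variant_idx = rng.choice(len(names), size=(n, 2), p=probs)
    sigma2 = math.log(1.0 + brightness_cv**2)
    mu = math.log(brightness_mean) - sigma2 / 2.0
    bright = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=(n, 2))

    sites: list[ColonySite] = []
    for k in range(n):
        if not occupied[k]:
            continue
        row, col = divmod(k, layout.n_cols)
        n_cells = 2 if doubles[k] else 1
        sites.append(
            ColonySite(
                row=row,
                col=col,
                occupancy="double" if n_cells == 2 else "single",
                variant_ids=tuple(names[i] for i in variant_idx[k, :n_cells]),
                brightnesses=tuple(float(b) for b in bright[k, :n_cells]),
                radius_px=float(radius_px),
            )
        )
    params = dict(
        viability=viability,
        doublet_rate=doublet_rate,
        variant_mix=mix,
        brightness_mean=brightness_mean,
        brightness_cv=brightness_cv,
        radius_px=float(radius_px),
    )
    return GroundTruthPlate(layout=layout, sites=sites, seed=seed, params=params)


@dataclass
class RenderedPlate:
    """Per-band images plus the truth table and rendering geometry."""

    images: dict[str, np.ndarray]
    truth: pd.DataFrame
    ground_truth: GroundTruthPlate
    optics: OpticsModel
    margin_px: int

    def node_px(self, row: int, col: int) -> tuple[float, float]:
        """Pixel (x, y) of a grid node in the rendered images."""
        pitch_px = self.ground_truth.layout.pitch_um / self.optics.pixel_um
        return (self.margin_px + col * pitch_px, self.margin_px + row * pitch_px)

    def write(self, out_dir: str | Path, prefix: str = "plate", fmt: str = "tif") -> list[Path]:
        """Write one quantised image per band, band encoded in the file name."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for band_name, img in self.images.items():
            path = out_dir / f"{prefix}_{band_name}.{fmt}"
            write_image(path, img, bit_depth=self.optics.bit_depth)
            paths.append(path)
        return paths


def write_image(path: str | Path, image: np.ndarray, bit_depth: int = 16) -> Path:
    """Quantise a float image to 8/16-bit and write TIFF or PNG by suffix."""
    path = Path(path)
    dtype = np.uint16 if bit_depth == 16 else np.uint8
    q = np.clip(np.rint(image), 0, 2**bit_depth - 1).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, q)
    elif path.suffix.lower() == ".png":
        Image.fromarray(q).save(path)
    else:
        raise ValueError(f"unsupported image format: {path.suffix}")
    return path


def read_image(path: str | Path) -> np.ndarray:
    """Read a greyscale TIFF/PNG plate image as float64."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    return np.asarray(arr, dtype=float)


def _disc_stamp(radius_px: float) -> np.ndarray:
    """Unit-mass soft-edged disc (approximate pixel coverage weights)."""
    R = int(math.ceil(radius_px)) + 1
    yy, xx = np.mgrid[-R : R + 1, -R : R + 1]
    dist = np.hypot(xx, yy)
    w = np.clip(radius_px + 0.5 - dist, 0.0, 1.0)
    s = w.sum()
    if s <= 0:  # sub-pixel colony collapses onto its centre pixel
        w[R, R] = 1.0
        s = 1.0
    return w / s


def render_plate(
    gt: GroundTruthPlate,
    filter_set: Sequence[FilterBand] = DEFAULT_BANDS,
    optics: OpticsModel | None = None,
    seed: int = 0,
    spectra: Mapping[str, EmissionSpectrum] | None = None,
    margin_px: int | None = None,
) -> RenderedPlate:
    """Render one image per filter band plus the truth table.

    Each colony contributes a disc of its radius whose total (pre-noise,
    pre-blur) signal in a band is ``brightness * gain * band_fraction`` summed
    over its member cells, where ``band_fraction`` integrates the variant's
    emission model over the band.  Disc weights are normalised so the summed
    pixel signal conserves that total exactly.  The stack is then PSF-blurred,
    offset by the background level, and degraded by shot and read noise.
    Pixels clipped at saturation are recorded per colony in the truth table.
    """
    if len(filter_set) < 1:
        raise ValueError("need at least one filter band")
    optics = OpticsModel() if optics is None else optics
    spectra = REFERENCE_SPECTRA if spectra is None else spectra
    layout = gt.layout

    pitch_px = layout.pitch_um / optics.pixel_um
    if pitch_px < 1.0:
        raise ValueError(
            f"pixel scale {optics.pixel_um} um/px cannot resolve the "
            f"{layout.pitch_um} um grid pitch"
        )
    r_max = max((s.radius_px for s in gt.sites), default=5.0)
    if margin_px is None:
        margin_px = int(math.ceil(3 * r_max + 4 * optics.psf_sigma_px)) + 2
    height = int(round((layout.n_rows - 1) * pitch_px)) + 2 * margin_px + 1
    width = int(round((layout.n_cols - 1) * pitch_px)) + 2 * margin_px + 1

    missing = {v for s in gt.sites for v in s.variant_ids} - set(spectra)
    if missing:
        raise ValueError(f"no emission spectrum for variant(s): {sorted(missing)}")
    fractions = {
        v: np.array([band_intensity(spec, b) for b in filter_set])
        for v, spec in spectra.items()
    }

    canvases = [np.zeros((height, width), dtype=float) for _ in filter_set]
    stamp_cache: dict[float, np.ndarray] = {}
    stamp_extent: dict[int, tuple] = {}
    for s in gt.sites:
        stamp = stamp_cache.get(s.radius_px)
        if stamp is None:
            stamp = stamp_cache[s.radius_px] = _disc_stamp(s.radius_px)
        R = stamp.shape[0] // 2
        cx = int(round(margin_px + s.col * pitch_px))
        cy = int(round(margin_px + s.row * pitch_px))
        sl = (slice(cy - R, cy + R + 1), slice(cx - R, cx + R + 1))
        per_band = np.zeros(len(filter_set))
        for variant, b in zip(s.variant_ids, s.brightnesses):
            per_band += b * optics.gain * fractions[variant]
        for canvas, amount in zip(canvases, per_band):
            canvas[sl] += stamp * amount

    rng = np.random.default_rng(seed)
    images: dict[str, np.ndarray] = {}
    for band, canvas in zip(filter_set, canvases):
        img = canvas
        if optics.psf_sigma_px > 0:
            img = gaussian_filter(img, optics.psf_sigma_px, mode="constant")
        img = img + optics.background_level
        if optics.shot_noise:
            img = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        if optics.read_noise_sd > 0:
            img = img + rng.normal(0.0, optics.read_noise_sd, size=img.shape)
        np.clip(img, 0.0, float(optics.saturation), out=img)
        images[band.name] = img

    truth = gt.to_frame()
    saturated = []
    stack = np.stack(list(images.values()))
    for s in gt.sites:
        R = int(math.ceil(s.radius_px)) + 1
        cx = int(round(margin_px + s.col * pitch_px))
        cy = int(round(margin_px + s.row * pitch_px))
        patch = stack[:, max(cy - R, 0) : cy + R + 1, max(cx - R, 0) : cx + R + 1]
        saturated.append(bool(patch.max() >= optics.saturation))
    truth["saturated"] = saturated
    return RenderedPlate(
        images=images, truth=truth, ground_truth=gt, optics=optics, margin_px=margin_px
    )
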