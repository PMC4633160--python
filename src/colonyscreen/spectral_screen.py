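"""Bandpass photometry spectra and spectral-variant calling.

Each colony on a plate is imaged through a set of optical bandpass filters
(six by default, spanning 510-750 nm).  The integrated colony intensity in
each band forms a multi-point emission spectrum; dividing by the maximum
entry gives the normalised spectrum whose peak position is the feature that
separates spectral variants.  The flagship use case is screening a library
of firefly luciferase (FLuc) for red-shifted emission: the stabilised parent
x5_FLuc peaks near 550 nm while the S284T variant x5_FLuc_red peaks near
615 nm, so the two are well separated by the 550-600 nm and 590-640 nm bands.

Reference spectra are computed from a parametric emission model rather than
learned from data, which keeps the caller deterministic.  Classification is
nearest-reference in Euclidean distance on the normalised spectrum, with a
confidence rule requiring both a small absolute distance and a relative
margin over the runner-up.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .plate_layout import GridPosition, PlateLayout

if TYPE_CHECKING:  # pragma: no cover
    from .colony_quant import ColonyRecord

__all__ = [
    "FilterBand",
    "EmissionSpectrum",
    "SpectralCall",
    "ScreenResult",
    "DEFAULT_BANDS",
    "REFERENCE_SPECTRA",
    "band_intensity",
    "reference_vectors",
    "normalize_spectrum",
    "classify_spectrum",
    "call_plate",
    "sort_band_names",
]

log = logging.getLogger(__name__)

#: Wavelength window over which spectra are defined and unit-normalised (nm).
SPECTRUM_SUPPORT_NM = (400.0, 800.0)


@dataclass(frozen=True)
class FilterBand:
    """An optical bandpass window ``[low_nm, high_nm]``."""

    low_nm: float
    high_nm: float

    def __post_init__(self) -> None:
        if not self.low_nm < self.high_nm:
            raise ValueError("band requires low_nm < high_nm")
        lo, hi = SPECTRUM_SUPPORT_NM
        if self.low_nm < lo or self.high_nm > hi:
            raise ValueError(f"band must lie within [{lo:g}, {hi:g}] nm")

    @property
    def name(self) -> str:
        return f"{self.low_nm:g}-{self.high_nm:g}"


#: Default six-filter set: 50 nm windows on a 40 nm step covering 510-750 nm.
#: Only two bands are fixed by the screening protocol (550-600 and 590-640 nm);
#: the rest tile the stated 510-750 nm range and are fully configurable.
DEFAULT_BANDS: tuple[FilterBand, ...] = tuple(
    FilterBand(low, low + 50.0) for low in (510.0, 550.0, 590.0, 630.0, 670.0, 700.0)
)


@dataclass(frozen=True)
class EmissionSpectrum:
    """Parametric emission-spectrum model, unit area over 400-800 nm.

    ``shape='gaussian'`` (default) is a symmetric peak with the given FWHM —
    an adequate stand-in for the broad unimodal luciferase emission spectra.
    ``shape='uniform'`` is flat on ``peak_nm ± fwhm_nm/2`` and exists mainly
    for analytic checks.
    """

    peak_nm: float
    fwhm_nm: float = 70.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm_nm <= 0:
            raise ValueError("fwhm_nm must be positive")
        if self.shape not in ("gaussian", "uniform"):
            raise ValueError(f"unknown spectrum shape {self.shape!r}")

    def density(self, wavelengths_nm: np.ndarray) -> np.ndarray:
        """Spectral density at the given wavelengths (1/nm), zero outside support."""
        wl = np.asarray(wavelengths_nm, dtype=float)
        lo, hi = SPECTRUM_SUPPORT_NM
        if self.shape == "uniform":
            a = max(self.peak_nm - self.fwhm_nm / 2.0, lo)
            b = min(self.peak_nm + self.fwhm_nm / 2.0, hi)
            if b <= a:
                return np.zeros_like(wl)
            return np.where((wl >= a) & (wl <= b), 1.0 / (b - a), 0.0)
        sigma = self.fwhm_nm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        z = (wl - self.peak_nm) / sigma
        pdf = np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))
        # renormalise over the finite support so band fractions sum to 1
        norm = 0.5 * (
            math.erf((hi - self.peak_nm) / (sigma * math.sqrt(2.0)))
            - math.erf((lo - self.peak_nm) / (sigma * math.sqrt(2.0)))
        )
        if norm <= 0.0:
            return np.zeros_like(wl)
        return np.where((wl >= lo) & (wl <= hi), pdf / norm, 0.0)


#: Emission models for the two screened luciferase variants.  Peak positions
#: are the variants' known emission maxima; the common 70 nm FWHM reflects the
#: broad single-peaked shape of firefly luciferase emission.
REFERENCE_SPECTRA: dict[str, EmissionSpectrum] = {
    "x5_FLuc": EmissionSpectrum(550.0),
    "x5_FLuc_red": EmissionSpectrum(615.0),
}


def band_intensity(
    spectrum: EmissionSpectrum, band: FilterBand, step_nm: float = 0.5
) -> float:
    """Fraction of total emission falling inside a bandpass window.

    Trapezoidal integration of the unit-normalised spectrum at <= ``step_nm``
    sampling.  A band outside the spectrum's support integrates to ~0 rather
    than raising.
    """
    lo = max(band.low_nm, SPECTRUM_SUPPORT_NM[0])
    hi = min(band.high_nm, SPECTRUM_SUPPORT_NM[1])
    if hi <= lo:
        return 0.0
    n = int(math.ceil((hi - lo) / step_nm)) + 1
    wl = np.linspace(lo, hi, max(n, 2))
    return float(np.trapezoid(spectrum.density(wl), wl))


def reference_vectors(
    spectra: Mapping[str, EmissionSpectrum] | None = None,
    bands: Sequence[FilterBand] = DEFAULT_BANDS,
) -> dict[str, np.ndarray]:
    """Normalised per-band reference vectors for each variant's emission model."""
    spectra = REFERENCE_SPECTRA if spectra is None else spectra
    return {
        name: normalize_spectrum([band_intensity(spec, b) for b in bands])
        for name, spec in spectra.items()
    }


def normalize_spectrum(intensities: Sequence[float]) -> np.ndarray:
    """Scale a vector of band intensities to unit maximum."""
    arr = np.asarray(intensities, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError("intensities must be a non-empty 1-D vector")
    if np.any(arr < 0):
        raise ValueError("intensities must be non-negative")
    peak = arr.max()
    if peak <= 0:
        raise ValueError("no signal: all band intensities are zero")
    return arr / peak


@dataclass(frozen=True)
class SpectralCall:
    """Variant call for one colony.

    ``red_ratio`` is the intensity ratio of the second ratio band over the
    first (default 590-640 over 550-600) — a scalar red-shift index that is
    invariant to overall brightness.  ``confident`` requires the nearest
    reference to be within ``max_distance`` *and* the runner-up to be at
    least ``margin`` times farther.
    """

    grid_pos: GridPosition | None
    normalized_spectrum: np.ndarray
    variant: str
    distance: float
    red_ratio: float
    confident: bool


def classify_spectrum(
    norm: Sequence[float],
    references: Mapping[str, np.ndarray],
    max_distance: float = 0.35,
    ratio_bands: tuple[int, int] = (1, 2),
    margin: float = 1.2,
    grid_pos: GridPosition | None = None,
) -> SpectralCall:
    """Assign a normalised spectrum to its nearest reference variant."""
    if len(references) < 2:
        raise ValueError("need at least two reference variants")
    vec = np.asarray(norm, dtype=float)
    dists = {}
    for name, ref in references.items():
        ref = np.asarray(ref, dtype=float)
        if ref.shape != vec.shape:
            raise ValueError(
                f"reference {name!r} has length {ref.size}, spectrum has {vec.size}"
            )
        dists[name] = float(np.linalg.norm(vec - ref))
    ranked = sorted(dists.items(), key=lambda kv: kv[1])
    best_name, best_d = ranked[0]
    runner_d = ranked[1][1]
    confident = best_d <= max_distance and runner_d >= margin * best_d and (
        runner_d > best_d or best_d == 0.0
    )
    i, j = ratio_bands
    red_ratio = float(vec[j] / vec[i]) if vec[i] > 0 else float("inf")
    return SpectralCall(
        grid_pos=grid_pos,
        normalized_spectrum=vec,
        variant=best_name,
        distance=best_d,
        red_ratio=red_ratio,
        confident=confident,
    )


def sort_band_names(names: Sequence[str]) -> list[str]:
    """Order band-name keys ('510-560', ...) by their lower wavelength edge.

    Non-wavelength channel names (e.g. 'eGFP', 'mCherry') sort
    lexicographically after any wavelength bands.
    """

    def key(s: str):
        try:
            return (0, float(str(s).split("-")[0]), str(s))
        except ValueError:
            return (1, 0.0, str(s))

    return sorted(names, key=key)


@dataclass
class ScreenResult:
    """Output of :func:`call_plate`: all calls, the hit table, and a pick map."""

    calls: list[SpectralCall]
    hits: pd.DataFrame
    pick_map: str
    majority_variant: str | None

    def calls_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            row = {
                "row": c.grid_pos.row if c.grid_pos else -1,
                "col": c.grid_pos.col if c.grid_pos else -1,
                "block": c.grid_pos.block_id if c.grid_pos else None,
            }
            for k, v in enumerate(c.normalized_spectrum, start=1):
                row[f"s{k}"] = v
            row.update(
                variant=c.variant,
                distance=c.distance,
                red_ratio=c.red_ratio,
                confident=c.confident,
            )
            rows.append(row)
        return pd.DataFrame(rows)


def call_plate(
    records: "Sequence[ColonyRecord]",
    references: Mapping[str, np.ndarray] | None = None,
    layout: PlateLayout | None = None,
    max_distance: float = 0.35,
    margin: float = 1.2,
    ratio_bands: tuple[int, int] = (1, 2),
    majority_variant: str | None = None,
) -> ScreenResult:
    """Call every eligible colony on a plate and emit the hit list + pick map.

    Eligible records are grid-assigned and unflagged (merged/conflicting
    colonies mirror coincident depositions and are excluded from calling).
    Hits are confident calls to any non-majority variant; the pick map is a
    text plate chart ('.' empty node, 'o' majority, 'X' hit, '?' unconfident)
    plus a machine-readable table of (block, row, col).
    """
    references = reference_vectors() if references is None else references
    eligible = [r for r in records if r.grid_pos is not None and not r.flags]
    if not eligible:
        log.warning("call_plate: no eligible colony records; empty result")
        return ScreenResult([], _empty_hits(), _render_pick_map({}, layout), None)

    calls: list[SpectralCall] = []
    for rec in eligible:
        names = sort_band_names(list(rec.intensities))
        raw = [rec.intensities[n] for n in names]
        if max(raw) <= 0:
            continue  # no signal in any band; cannot be spectrally typed
        calls.append(
            classify_spectrum(
                normalize_spectrum(raw),
                references,
                max_distance=max_distance,
                ratio_bands=ratio_bands,
                margin=margin,
                grid_pos=rec.grid_pos,
            )
        )

    if majority_variant is None:
        confident = [c.variant for c in calls if c.confident] or [c.variant for c in calls]
        majority_variant = max(set(confident), key=confident.count) if confident else None

    hits = [c for c in calls if c.confident and c.variant != majority_variant]
    hits_df = pd.DataFrame(
        [
            {
                "block": c.grid_pos.block_id,
                "row": c.grid_pos.row,
                "col": c.grid_pos.col,
                "variant": c.variant,
                "distance": c.distance,
                "red_ratio": c.red_ratio,
            }
            for c in hits
        ],
        columns=["block", "row", "col", "variant", "distance", "red_ratio"],
    ).sort_values(["row", "col"], ignore_index=True)

    glyphs: dict[tuple[int, int], str] = {}
    for c in calls:
        key = (c.grid_pos.row, c.grid_pos.col)
        if not c.confident:
            glyphs[key] = "?"
        elif c.variant != majority_variant:
            glyphs[key] = "X"
        else:
            glyphs[key] = "o"
    pick_map = _render_pick_map(glyphs, layout)
    return ScreenResult(calls, hits_df, pick_map, majority_variant)


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame(columns=["block", "row", "col", "variant", "distance", "red_ratio"])


def _render_pick_map(glyphs: Mapping[tuple[int, int], str], layout: PlateLayout | None) -> str:
    if layout is None:
        if not glyphs:
            return ""
        n_rows = max(r for r, _ in glyphs) + 1
        n_cols = max(c for _, c in glyphs) + 1
    else:
        n_rows, n_cols = layout.n_rows, layout.n_cols
    lines = ["# pick map: '.'=empty 'o'=majority 'X'=hit '?'=unconfident"]
    for r in range(n_rows):
        lines.append("".join(glyphs.get((r, c), ".") for c in range(n_cols)))
    return "\n".join(lines) + "\n"
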