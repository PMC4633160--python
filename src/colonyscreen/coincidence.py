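"""Two-colour coincidence analysis: singlet purity of single-cell printing.

Printing a 1:1 mix of eGFP- and mCherry-expressing bacteria and imaging the
plate in both channels turns doublet depositions into a measurable quantity:
a position showing *both* colours received at least two cells.  Same-colour
doublets are optically invisible, so under a mix fraction ``m`` only a
fraction ``2 m (1 - m)`` of doublets (one half at 1:1) show two colours.
``purity_stats`` applies that correction to convert the observed two-colour
doublet rate into an estimate of the total doublet rate.

Singlet purity is reported with an exact (Clopper-Pearson) binomial 95% CI.
Colonies below threshold in both channels are excluded from the purity
denominator and reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import beta
from skimage.filters import threshold_otsu

from .colony_quant import ColonyRecord
from .plate_layout import GridPosition, PlateLayout, make_layout
from .synth_plate import (
    DEFAULT_BRIGHTNESS_CV,
    DEFAULT_BRIGHTNESS_MEAN,
    sample_ground_truth,
)

__all__ = [
    "ChannelCall",
    "PurityStats",
    "classify_channels",
    "purity_stats",
    "simulate_two_colour_records",
    "CALL_GREEN",
    "CALL_RED",
    "CALL_DOUBLE",
    "CALL_BELOW",
]

CALL_GREEN = "green-single"
CALL_RED = "red-single"
CALL_DOUBLE = "double"
CALL_BELOW = "below-threshold"


@dataclass(frozen=True)
class ChannelCall:
    """Per-colony two-channel classification; ``double`` iff both channels
    exceed their thresholds."""

    grid_pos: GridPosition | None
    I_green: float
    I_red: float
    call: str


@dataclass(frozen=True)
class PurityStats:
    """Singlet-purity summary of a two-colour plate.

    ``singlet_pct = 100 * (1 - n_double / n_colonies)`` over colonies above
    threshold; ``ci95`` is the exact binomial CI; ``est_total_doublet_pct``
    corrects the observed two-colour rate for invisible same-colour doublets.
    """

    n_colonies: int
    n_double: int
    singlet_pct: float
    ci95: tuple[float, float]
    est_total_doublet_pct: float
    n_below_threshold: int = 0


def classify_channels(
    records: Sequence[ColonyRecord],
    thresholds: Mapping[str, float] | None = None,
    channels: tuple[str, str] | None = None,
) -> list[ChannelCall]:
    """Classify each two-band colony record as green/red single, double, or
    below threshold.

    ``channels`` names the (green, red) intensity keys; by default the two
    keys are taken in sorted order ('eGFP' < 'mCherry', 'green' < 'red').
    ``thresholds`` maps channel name to an absolute cut; when omitted the cut
    is derived per channel from Otsu: Otsu separates the off/on populations,
    and the final threshold is the off-population mean + 6 SD.  A raw Otsu
    cut sits roughly midway to the on-population mean — inside the dim tail
    of the log-normal colony brightnesses — whereas referencing the cut to
    the off-channel noise keeps every genuine colony above threshold.
    """
    if not records:
        return []
    keys = set(records[0].intensities)
    if len(keys) != 2:
        raise ValueError(f"expected exactly two channels, got {sorted(keys)}")
    if channels is None:
        channels = tuple(sorted(keys))  # type: ignore[assignment]
    g_key, r_key = channels
    if {g_key, r_key} != keys:
        raise ValueError(f"channels {channels} missing from records with {sorted(keys)}")

    if thresholds is None:
        thresholds = {}
        for k in (g_key, r_key):
            vals = np.array([r.intensities[k] for r in records], dtype=float)
            t0 = float(threshold_otsu(vals)) if vals.min() < vals.max() else 0.0
            off = vals[vals <= t0]
            thresholds[k] = float(off.mean() + 6.0 * off.std()) if off.size else t0
    tg, tr = float(thresholds[g_key]), float(thresholds[r_key])

    calls = []
    for rec in records:
        g, r = rec.intensities[g_key], rec.intensities[r_key]
        if g > tg and r > tr:
            call = CALL_DOUBLE
        elif g > tg:
            call = CALL_GREEN
        elif r > tr:
            call = CALL_RED
        else:
            call = CALL_BELOW
        calls.append(ChannelCall(rec.grid_pos, float(g), float(r), call))
    return calls


def _clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def purity_stats(calls: Sequence[ChannelCall], mix_fraction: float = 0.5) -> PurityStats:
    """Singlet purity and corrected total doublet rate of a two-colour plate."""
    if not 0.0 < mix_fraction < 1.0:
        raise ValueError("mix_fraction must lie strictly between 0 and 1")
    counted = [c for c in calls if c.call != CALL_BELOW]
    n_below = len(calls) - len(counted)
    n = len(counted)
    if n == 0:
        raise ValueError("no colonies above threshold")
    n_double = sum(1 for c in counted if c.call == CALL_DOUBLE)
    singlet_pct = 100.0 * (1.0 - n_double / n)
    lo, hi = _clopper_pearson(n - n_double, n)
    observed_rate = n_double / n
    p_two_colour = 2.0 * mix_fraction * (1.0 - mix_fraction)
    est_total_pct = 100.0 * observed_rate / p_two_colour
    return PurityStats(
        n_colonies=n,
        n_double=n_double,
        singlet_pct=singlet_pct,
        ci95=(100.0 * lo, 100.0 * hi),
        est_total_doublet_pct=est_total_pct,
        n_below_threshold=n_below,
    )


def simulate_two_colour_records(
    n_positions: int,
    viability: float = 0.94,
    doublet_rate: float = 0.004,
    mix_fraction: float = 0.5,
    brightness_mean: float = DEFAULT_BRIGHTNESS_MEAN,
    brightness_cv: float = DEFAULT_BRIGHTNESS_CV,
    noise_sd: float = 0.005,
    seed: int = 0,
) -> list[ColonyRecord]:
    """Statistically simulate a two-colour (eGFP/mCherry) printed plate.

    Produces idealised photometry records directly from a ground-truth draw
    (no image rendering): each colony's channel intensity is the summed
    brightness of its member cells of that colour plus Gaussian measurement
    noise, clipped at zero.  ``mix_fraction`` is the eGFP fraction.
    """
    try:
        layout = make_layout(n_positions, 1.5)
    except ValueError:
        layout = PlateLayout(1, n_positions)
    gt = sample_ground_truth(
        layout,
        viability=viability,
        doublet_rate=doublet_rate,
        variant_mix={"eGFP": mix_fraction, "mCherry": 1.0 - mix_fraction},
        brightness_mean=brightness_mean,
        brightness_cv=brightness_cv,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    records = []
    for i, s in enumerate(gt.sites, start=1):
        I = {"eGFP": 0.0, "mCherry": 0.0}
        for variant, b in zip(s.variant_ids, s.brightnesses):
            I[variant] += b
        noisy = {
            k: max(v + float(rng.normal(0.0, noise_sd)), 0.0) for k, v in I.items()
        }
        records.append(
            ColonyRecord(
                label=i,
                centroid_px=(0.0, 0.0),
                area_px=1,
                intensities=noisy,
                grid_pos=GridPosition(s.row, s.col),
            )
        )
    return records
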