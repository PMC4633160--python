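"""Deposition scheduling: conventional single-stream vs multiplexed printing.

A conventional electrostatic sorter deposits one particle per stop, so a
rows x cols plate costs ``rows * cols`` stage stops, and the electromechanical
"dead time" per stop dominates total print time.  The sort-stream multiplexer
attenuates successive charge pulses so a burst of ``n_streams`` droplets fans
out over adjacent columns while the plate holds still: each row then needs
only ``ceil(cols / n_streams)`` stops.  Rows are visited in serpentine order.

The timing model is linear:
``plate_time = total_stops * t_stop + n_particles * t_drop``, with ``t_drop``
defaulting to 0 because in-burst deposition happens at the sort rate and is
negligible next to stage dead time.  ``calibrate_t_stop`` recovers the dead
time from a measured plate time.

``attenuation_levels`` gives the per-pulse charge attenuation factors under a
linear charge-to-deflection model: stream ``i`` of ``n`` lands
``i * stream_pitch`` short of full deflection, so its factor is
``(full_deflection - i * stream_pitch) / full_deflection``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator

from .plate_layout import PlateLayout

__all__ = [
    "SortSchedule",
    "ThroughputModel",
    "schedule",
    "plate_time",
    "calibrate_t_stop",
    "percent_improvement",
    "deposition_rate",
    "attenuation_levels",
]


@dataclass(frozen=True)
class SortSchedule:
    """Stop/translation bookkeeping for printing one plate."""

    layout: PlateLayout
    n_streams: int
    stops_per_row: int
    y_translations: int
    x_translations_per_row: int
    total_stops: int
    burst_size: int

    def stop_sequence(self) -> Iterator[tuple[int, int]]:
        """Serpentine (row, stop-index) visit order."""
        for row in range(self.layout.n_rows):
            stops = range(self.stops_per_row)
            if row % 2 == 1:
                stops = reversed(stops)
            for stop in stops:
                yield (row, stop)


@dataclass(frozen=True)
class ThroughputModel:
    """Per-stop dead time and per-particle in-burst deposition time (seconds)."""

    t_stop_s: float
    t_drop_s: float = 0.0

    def __post_init__(self) -> None:
        if self.t_stop_s < 0 or self.t_drop_s < 0:
            raise ValueError("times must be non-negative")


def schedule(layout: PlateLayout, n_streams: int = 1) -> SortSchedule:
    """Build the stop schedule for printing ``layout`` with ``n_streams`` streams."""
    if n_streams < 1:
        raise ValueError("n_streams must be >= 1")
    if n_streams > layout.n_cols:
        raise ValueError(
            f"n_streams={n_streams} exceeds the {layout.n_cols} columns of the layout"
        )
    stops_per_row = math.ceil(layout.n_cols / n_streams)
    return SortSchedule(
        layout=layout,
        n_streams=n_streams,
        stops_per_row=stops_per_row,
        y_translations=layout.n_rows,
        x_translations_per_row=stops_per_row,
        total_stops=layout.n_rows * stops_per_row,
        burst_size=n_streams,
    )


def plate_time(
    sched: SortSchedule, model: ThroughputModel, n_particles: int | None = None
) -> float:
    """Predicted seconds to print ``n_particles`` (default: every node)."""
    if n_particles is None:
        n_particles = sched.layout.n_points
    if n_particles < 0 or n_particles > sched.layout.n_points:
        raise ValueError("n_particles must lie in [0, layout points]")
    return sched.total_stops * model.t_stop_s + n_particles * model.t_drop_s


def calibrate_t_stop(measured_s: float, sched: SortSchedule) -> float:
    """Dead time per stop implied by a measured plate time (t_drop = 0)."""
    if measured_s <= 0:
        raise ValueError("measured time must be positive")
    return measured_s / sched.total_stops


def percent_improvement(t_baseline: float, t_new: float) -> float:
    """Throughput gain ``100 * (t_baseline - t_new) / t_baseline``, 1 decimal."""
    if t_baseline <= 0:
        raise ValueError("baseline time must be positive")
    if t_new < 0:
        raise ValueError("new time must be non-negative")
    return round(100.0 * (t_baseline - t_new) / t_baseline, 1)


def deposition_rate(n_particles: int, t_seconds: float, *, rounded: bool = False) -> float | int:
    """Particles deposited per second; ``rounded=True`` for integer reporting."""
    if t_seconds <= 0:
        raise ValueError("time must be positive")
    if n_particles < 0:
        raise ValueError("n_particles must be non-negative")
    rate = n_particles / t_seconds
    return round(rate) if rounded else rate


def attenuation_levels(
    n_streams: int, stream_pitch_um: float, full_deflection_um: float
) -> list[float]:
    """Charge attenuation factor per pulse of a burst, strictly decreasing in (0, 1].

    Linear charge-to-deflection model: stream ``i`` (0-based) lands
    ``i * stream_pitch_um`` short of the full deflection point.  The geometry
    is infeasible when the last stream's factor would fall to or below zero.
    """
    if n_streams < 1:
        raise ValueError("n_streams must be >= 1")
    if stream_pitch_um <= 0 or full_deflection_um <= 0:
        raise ValueError("pitches must be positive")
    if (n_streams - 1) * stream_pitch_um >= full_deflection_um:
        raise ValueError(
            f"geometry infeasible: {n_streams} streams at {stream_pitch_um} um "
            f"pitch do not fit within the {full_deflection_um} um full deflection"
        )
    return [
        (full_deflection_um - i * stream_pitch_um) / full_deflection_um
        for i in range(n_streams)
    ]
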