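"""Colony detection, photometry, and matrix-position assignment.

The imaging geometry is forgiving — bright colonies on dark charcoal agar at
a known lattice pitch — so segmentation is global thresholding (Otsu on a
max-projection across bands by default) followed by connected components and
a minimum-area filter.  A robust noise floor (median + 5 sigma of the image
MAD) guards against Otsu bisecting pure noise on empty plates.

Photometry is background-subtracted integrated intensity per band: the pixel
sum inside each labelled component minus area times a local background
estimate (median of an annulus around the colony, robust to plate-level
illumination gradients; a global background mode is also available).

Grid assignment fits a per-axis scale + translation from lattice coordinates
to detected centroids by iterated nearest-node least squares, then snaps each
colony to its nearest node within half a pitch.  Conflicts (two colonies on
one node) keep the nearer colony and flag the other; components spanning more
than one node are flagged as merged and excluded from spectral calling, the
same way coincident depositions are treated as unidentifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.morphology import disk
from skimage.segmentation import expand_labels

from .plate_layout import GridPosition, PlateLayout, position_coords

__all__ = [
    "ColonyRecord",
    "GridTransform",
    "GridFitError",
    "segment_colonies",
    "measure_colonies",
    "assign_to_grid",
    "flag_merged",
    "quantify_plate",
    "qc_summary",
    "records_to_frame",
    "records_from_frame",
]


@dataclass
class ColonyRecord:
    """One detected colony: centroid, area, per-band intensity, grid position."""

    label: int
    centroid_px: tuple[float, float]  # (x, y) in image pixels
    area_px: int
    intensities: dict[str, float]
    bbox: tuple[int, int, int, int] | None = None  # (min_row, min_col, max_row, max_col)
    grid_pos: GridPosition | None = None
    flags: set[str] = field(default_factory=set)


class GridFitError(ValueError):
    """Raised when the lattice cannot be fitted to the detected centroids."""


@dataclass(frozen=True)
class GridTransform:
    """Per-axis affine map from lattice micrometres to image pixels."""

    scale_x: float
    scale_y: float
    offset_x: float
    offset_y: float
    median_residual_px: float = float("nan")

    def node_px(self, layout: PlateLayout) -> np.ndarray:
        """(n_points, 2) array of predicted node pixel (x, y), row-major order."""
        cols, rows = np.meshgrid(np.arange(layout.n_cols), np.arange(layout.n_rows))
        ox, oy = layout.origin_um
        x = (ox + cols.ravel() * layout.pitch_um) * self.scale_x + self.offset_x
        y = (oy + rows.ravel() * layout.pitch_um) * self.scale_y + self.offset_y
        return np.column_stack([x, y])

    @property
    def pitch_px(self) -> float:
        return (abs(self.scale_x) + abs(self.scale_y)) / 2.0


def segment_colonies(
    image: np.ndarray,
    min_area_px: int = 5,
    threshold_method: str | float = "otsu",
) -> np.ndarray:
    """Label colonies in a single greyscale image.

    ``threshold_method`` is ``'otsu'`` (relative; invariant to global linear
    rescaling) or an absolute numeric threshold.  Components smaller than
    ``min_area_px`` are dropped and labels are renumbered consecutively.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D greyscale image, got ndim={img.ndim}")
    if isinstance(threshold_method, str):
        if threshold_method != "otsu":
            raise ValueError(f"unknown threshold_method {threshold_method!r}")
        # noise floor: Otsu happily bisects a colony-free noise image, so
        # require foreground to also clear median + 5 robust sigma
        med = float(np.median(img))
        sigma = 1.4826 * float(np.median(np.abs(img - med)))
        floor = med + 5.0 * sigma
        if img.min() == img.max():
            return np.zeros(img.shape, dtype=np.int32)
        thr = max(float(threshold_otsu(img)), floor)
    else:
        thr = float(threshold_method)
    mask = img > thr
    labels = sk_label(mask, connectivity=2)
    if min_area_px > 1 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        too_small = np.flatnonzero(counts < min_area_px)
        if too_small.size:
            labels[np.isin(labels, too_small)] = 0
        labels, _, _ = _relabel(labels)
    return labels.astype(np.int32)


def _relabel(labels: np.ndarray):
    ids = np.unique(labels)
    ids = ids[ids > 0]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[ids] = np.arange(1, ids.size + 1)
    return lut[labels], ids, lut


def measure_colonies(
    label_map: np.ndarray,
    images: Mapping[str, np.ndarray],
    background: str = "local-median",
    aperture_px: int = 2,
) -> list[ColonyRecord]:
    """Measure area and background-subtracted intensity per colony per band.

    Photometry integrates over each label expanded outward by ``aperture_px``
    (never into a neighbour): thresholding clips the soft disc edge and PSF
    tail, and the expanded aperture recovers that flux.  Reported ``area_px``
    stays the thresholded component size.  ``background`` is
    ``'local-median'`` (median of a 3-px annulus outside the aperture; the
    default, robust to plate-level illumination gradients) or ``'global'``
    (median of all unlabelled pixels per band).  Intensities are clipped at 0.
    """
    if background not in ("local-median", "global"):
        raise ValueError(f"unknown background mode {background!r}")
    if not images:
        raise ValueError("need at least one band image")
    band_names = list(images)
    for name, img in images.items():
        if np.asarray(img).shape != label_map.shape:
            raise ValueError(f"band {name!r} image shape differs from label map")
    n = int(label_map.max())
    if n == 0:
        return []

    idx = np.arange(1, n + 1)
    areas = np.bincount(label_map.ravel(), minlength=n + 1)[1:]
    cy, cx = np.transpose(
        ndi.center_of_mass(np.ones_like(label_map, dtype=float), label_map, idx)
    )
    aperture = expand_labels(label_map, distance=aperture_px) if aperture_px else label_map
    ap_areas = np.bincount(aperture.ravel(), minlength=n + 1)[1:]
    objects = ndi.find_objects(aperture)
    sums = {
        name: ndi.sum_labels(np.asarray(img, dtype=float), aperture, idx)
        for name, img in images.items()
    }

    global_bg = {
        name: float(np.median(np.asarray(img, dtype=float)[aperture == 0]))
        if np.any(aperture == 0)
        else 0.0
        for name, img in images.items()
    }

    annulus_foot = disk(3)
    pad = 4
    records: list[ColonyRecord] = []
    for i in idx:
        sl = objects[i - 1]
        exp = (
            slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, label_map.shape[0])),
            slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, label_map.shape[1])),
        )
        local = aperture[exp]
        bgs: dict[str, float] = {}
        if background == "local-median":
            ring = ndi.binary_dilation(local == i, structure=annulus_foot) & (local == 0)
            for name in band_names:
                patch = np.asarray(images[name], dtype=float)[exp]
                bgs[name] = float(np.median(patch[ring])) if ring.any() else global_bg[name]
        else:
            bgs = global_bg
        intens = {
            name: max(float(sums[name][i - 1] - ap_areas[i - 1] * bgs[name]), 0.0)
            for name in band_names
        }
        records.append(
            ColonyRecord(
                label=int(i),
                centroid_px=(float(cx[i - 1]), float(cy[i - 1])),
                area_px=int(areas[i - 1]),
                intensities=intens,
                bbox=(sl[0].start, sl[1].start, sl[0].stop, sl[1].stop),
            )
        )
    return records


def flag_merged(
    records: Sequence[ColonyRecord], pitch_px: float, span_factor: float = 1.2
) -> list[ColonyRecord]:
    """Flag components spanning more than one grid node as ``'merged'``.

    A single colony's bounding box is roughly its diameter, well under the
    pitch; neighbours that have grown together form one component whose long
    side exceeds the pitch.
    """
    for rec in records:
        if rec.bbox is None:
            continue
        span = max(rec.bbox[2] - rec.bbox[0], rec.bbox[3] - rec.bbox[1])
        if span > span_factor * pitch_px:
            rec.flags.add("merged")
    return list(records)


def assign_to_grid(
    records: Sequence[ColonyRecord],
    layout: PlateLayout,
    pixel_um: float,
    snap_radius_frac: float = 0.5,
    merge_span_factor: float = 1.2,
    max_iter: int = 4,
) -> tuple[list[ColonyRecord], list[GridPosition], GridTransform]:
    """Fit the lattice to detected centroids and snap colonies to nodes.

    Returns the records (with ``grid_pos`` and flags filled in), the list of
    nodes with no colony, and the fitted transform.  Raises
    :class:`GridFitError` when the median residual of assigned colonies
    exceeds a quarter pitch.
    """
    records = list(records)
    if len(records) < 4:
        raise GridFitError("need at least 4 detected colonies to fit the grid")
    cents = np.array([r.centroid_px for r in records], dtype=float)  # (x, y)
    nodes_um = np.array(
        [
            position_coords(layout, GridPosition(r, c))
            for r in range(layout.n_rows)
            for c in range(layout.n_cols)
        ],
        dtype=float,
    )

    sx = sy = 1.0 / pixel_um
    bx = float(cents[:, 0].mean() - sx * nodes_um[:, 0].mean())
    by = float(cents[:, 1].mean() - sy * nodes_um[:, 1].mean())
    pitch_px = layout.pitch_um / pixel_um

    for _ in range(max_iter):
        node_px = np.column_stack([nodes_um[:, 0] * sx + bx, nodes_um[:, 1] * sy + by])
        dist, nearest = cKDTree(node_px).query(cents)
        keep = dist < 0.6 * pitch_px
        if keep.sum() < 4:
            raise GridFitError("grid fit failed: too few centroids near any node")
        nominal = 1.0 / pixel_um
        for axis, update in ((0, "x"), (1, "y")):
            u = nodes_um[nearest[keep], axis]
            v = cents[keep, axis]
            if np.ptp(u) > 0:
                scale, off = np.polyfit(u, v, 1)
                # the pixel scale is known hardware geometry; allow only a
                # small refinement so a degenerate fit cannot collapse it
                scale = float(np.clip(scale, 0.9 * nominal, 1.1 * nominal))
                off = float(np.mean(v - u * scale))
            else:  # single row/column along this axis: translation only
                scale = sx if axis == 0 else sy
                off = float(np.mean(v - u * scale))
            if update == "x":
                sx, bx = float(scale), float(off)
            else:
                sy, by = float(scale), float(off)
        pitch_px = layout.pitch_um * (abs(sx) + abs(sy)) / 2.0

    node_px = np.column_stack([nodes_um[:, 0] * sx + bx, nodes_um[:, 1] * sy + by])
    dist, nearest = cKDTree(node_px).query(cents)

    snap = snap_radius_frac * pitch_px
    taken: dict[int, int] = {}  # node index -> record index
    for rec_i in np.argsort(dist):
        rec = records[rec_i]
        if dist[rec_i] > snap:
            rec.flags.add("off_grid")
            continue
        node_i = int(nearest[rec_i])
        if node_i in taken:
            rec.flags.add("conflict")
            continue
        taken[node_i] = int(rec_i)
        row, col = divmod(node_i, layout.n_cols)
        rec.grid_pos = GridPosition(row, col, layout.block_id(row, col))

    flag_merged(records, pitch_px, merge_span_factor)

    # residual over every colony within snap range (conflict losers
    # included): a structureless centroid cloud must not look like a fit
    # just because each node keeps its nearest point
    in_range = dist[dist <= snap]
    med_resid = float(np.median(in_range)) if in_range.size else float("inf")
    if med_resid > pitch_px / 4.0:
        raise GridFitError(
            f"grid fit failed: median residual {med_resid:.2f} px exceeds "
            f"pitch/4 = {pitch_px / 4.0:.2f} px"
        )
    unoccupied = [
        GridPosition(*divmod(i, layout.n_cols), layout.block_id(*divmod(i, layout.n_cols)))
        for i in range(layout.n_points)
        if i not in taken
    ]
    transform = GridTransform(sx, sy, bx, by, med_resid)
    return records, unoccupied, transform


def quantify_plate(
    images: Mapping[str, np.ndarray],
    layout: PlateLayout,
    pixel_um: float,
    min_area_px: int = 5,
    threshold_method: str | float = "otsu",
    background: str = "local-median",
) -> tuple[list[ColonyRecord], list[GridPosition], GridTransform, dict]:
    """Segment (on the max-projection), measure, and grid-assign a band stack."""
    stack = np.stack([np.asarray(img, dtype=float) for img in images.values()])
    labels = segment_colonies(stack.max(axis=0), min_area_px, threshold_method)
    records = measure_colonies(labels, images, background=background)
    records, unoccupied, transform = assign_to_grid(records, layout, pixel_um)
    return records, unoccupied, transform, qc_summary(records, unoccupied, layout, transform)


def qc_summary(
    records: Sequence[ColonyRecord],
    unoccupied: Sequence[GridPosition],
    layout: PlateLayout,
    transform: GridTransform | None = None,
) -> dict:
    """Plate-level quality metrics, including the viability estimate."""
    n_assigned = sum(1 for r in records if r.grid_pos is not None)
    return {
        "n_detected": len(records),
        "n_assigned": n_assigned,
        "n_flagged": sum(1 for r in records if r.flags),
        "n_unoccupied": len(unoccupied),
        "n_positions": layout.n_points,
        "viability_estimate": n_assigned / layout.n_points,
        "median_residual_px": (
            transform.median_residual_px if transform is not None else None
        ),
    }


def records_to_frame(records: Sequence[ColonyRecord]) -> pd.DataFrame:
    """Colonies table: label,row,col,centroid,area,I_<band>...,flags."""
    if records:
        from .spectral_screen import sort_band_names

        bands = sort_band_names(list(records[0].intensities))
    else:
        bands = []
    rows = []
    for r in records:
        d = {
            "label": r.label,
            "row": r.grid_pos.row if r.grid_pos else -1,
            "col": r.grid_pos.col if r.grid_pos else -1,
            "centroid_x": r.centroid_px[0],
            "centroid_y": r.centroid_px[1],
            "area_px": r.area_px,
        }
        for b in bands:
            d[f"I_{b}"] = r.intensities[b]
        d["flags"] = ";".join(sorted(r.flags))
        rows.append(d)
    cols = ["label", "row", "col", "centroid_x", "centroid_y", "area_px"]
    cols += [f"I_{b}" for b in bands] + ["flags"]
    return pd.DataFrame(rows, columns=cols)


def records_from_frame(df: pd.DataFrame, layout: PlateLayout | None = None) -> list[ColonyRecord]:
    """Rebuild colony records from a colonies table written by this package."""
    band_cols = [c for c in df.columns if c.startswith("I_")]
    records = []
    for _, row in df.iterrows():
        flags = set(str(row.get("flags", "")).split(";")) - {"", "nan"}
        grid_pos = None
        if int(row["row"]) >= 0:
            r, c = int(row["row"]), int(row["col"])
            block = layout.block_id(r, c) if layout is not None else None
            grid_pos = GridPosition(r, c, block)
        records.append(
            ColonyRecord(
                label=int(row["label"]),
                centroid_px=(float(row["centroid_x"]), float(row["centroid_y"])),
                area_px=int(row["area_px"]),
                intensities={c[2:]: float(row[c]) for c in band_cols},
                grid_pos=grid_pos,
                flags=flags,
            )
        )
    return records
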