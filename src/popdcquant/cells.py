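"""Plasma-membrane vs cytoplasm localization of reporters in single cells.

Cells co-expressing two tagged reporters are segmented into a plasma-membrane
band (guided by a lipophilic membrane dye such as DiD) and a cytoplasm (the
enclosed area minus the membrane band and the nucleus). The per-cell
localization ratio

    membrane mean / cytoplasm mean

per reporter is the statistic compared across co-transfection groups.
Backgrounds are subtracted from every channel before measurement.

Two segmentation paths exist: operator-supplied closed boundary polygons
(the faithful counterpart of manual outlining, takes precedence) and an
automatic mode that thresholds the membrane-dye channel and treats each
closed dye ridge as one cell.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.draw import polygon_perimeter
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .stack import MEMBRANE_MARKER, NUCLEUS, ChannelStack

logger = logging.getLogger(__name__)


@dataclass
class CellMasks:
    """Disjoint membrane/cytoplasm masks for one cell."""

    cell_id: int
    membrane: np.ndarray
    cytoplasm: np.ndarray
    flags: list[str] = field(default_factory=list)


def subtract_background(
    stack: ChannelStack, foreground: np.ndarray | None = None
) -> ChannelStack:
    """Subtract a per-channel background estimate, flooring at zero.

    The estimate is the median of pixels outside ``foreground`` (the union
    of all cell masks). Without a usable background region the 5th
    percentile of the whole channel is used instead, with a warning.
    Idempotent on noise-free input: a second pass subtracts zero.
    """
    out = {}
    use_fallback = foreground is None or not np.any(~foreground)
    if use_fallback and foreground is not None:
        logger.warning("%s: no background pixels; 5th-percentile fallback", stack.image_id)
    for role, img in stack.channels.items():
        if use_fallback:
            bg = float(np.percentile(img, 5))
        else:
            bg = float(np.median(img[~foreground]))
        out[role] = np.clip(img - bg, 0.0, None)
    return stack.with_channels(out)


def _nucleus_mask(stack: ChannelStack, within: np.ndarray) -> np.ndarray:
    """Otsu mask of the nucleus channel restricted to ``within``; empty when
    the channel is absent (degenerate-input rule: cytoplasm then spans the
    full enclosed interior minus the membrane band)."""
    if not stack.has(NUCLEUS):
        return np.zeros(stack.shape, dtype=bool)
    nuc = stack.channel(NUCLEUS)
    if np.ptp(nuc) == 0:
        return np.zeros(stack.shape, dtype=bool)
    mask = nuc > threshold_otsu(nuc)
    return mask & within


def segment_cell_from_polygon(
    stack: ChannelStack,
    boundary: np.ndarray,
    band_radius_px: int = 2,
    cell_id: int = 1,
) -> CellMasks:
    """Masks from an operator-supplied closed boundary polygon.

    ``boundary`` is an (N, 2) array of 0-based (row, col) vertices tracing
    the plasma membrane. The membrane mask is the rasterized perimeter
    dilated by a Euclidean disk of ``band_radius_px``; the cytoplasm is the
    enclosed area minus that band and minus the nucleus. Non-closing
    geometry (an enclosure that contains no interior) raises.
    """
    boundary = np.asarray(boundary, dtype=float)
    if boundary.ndim != 2 or boundary.shape[1] != 2 or len(boundary) < 3:
        raise ValueError("boundary must be an (N>=3, 2) array of row/col vertices")
    h, w = stack.shape
    perim = np.zeros((h, w), dtype=bool)
    rr, cc = polygon_perimeter(boundary[:, 0], boundary[:, 1], shape=(h, w), clip=True)
    perim[rr, cc] = True
    membrane = ndimage.binary_dilation(perim, structure=disk(band_radius_px))
    rr, cc = draw_polygon(boundary[:, 0], boundary[:, 1], shape=(h, w))
    fill = np.zeros((h, w), dtype=bool)
    fill[rr, cc] = True
    fill |= membrane
    interior = fill & ~membrane
    if not interior.any():
        raise ValueError("boundary polygon does not enclose any interior area")
    nucleus = _nucleus_mask(stack, interior)
    cytoplasm = interior & ~nucleus
    flags = []
    if not cytoplasm.any():
        flags.append("empty_cytoplasm")
        logger.warning("cell %d: nucleus covers the whole enclosed area", cell_id)
    return CellMasks(cell_id=cell_id, membrane=membrane, cytoplasm=cytoplasm, flags=flags)


def segment_cells_auto(
    stack: ChannelStack,
    band_dilation_px: int = 0,
    min_ring_px: int = 50,
    exclude_border: bool = True,
) -> list[CellMasks]:
    """Automatic segmentation from the membrane-dye channel.

    Thresholds the dye (Otsu), treats each connected dye ridge that encloses
    an interior as one cell: membrane mask = the ridge (optionally dilated
    by ``band_dilation_px``; the thresholded ridge already spans the
    membrane, so the default adds nothing), cytoplasm = enclosed area minus
    membrane minus nucleus. Open ridges and, by default, cells touching the
    image border are discarded.
    """
    did = stack.channel(MEMBRANE_MARKER)
    if np.ptp(did) == 0:
        return []
    ridge = did > threshold_otsu(did)
    labels = cc_label(ridge, connectivity=2)
    counts = np.bincount(labels.ravel())
    small = np.flatnonzero(counts < min_ring_px)
    labels[np.isin(labels, small[small > 0])] = 0
    cells: list[CellMasks] = []
    cid = 0
    for lab in range(1, labels.max() + 1):
        comp = labels == lab
        fill = ndimage.binary_fill_holes(comp)
        interior = fill & ~comp
        if not interior.any():  # open (non-closing) ridge: not a cell
            continue
        if exclude_border:
            edge = np.zeros_like(fill)
            edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
            if (fill & edge).any():
                continue
        membrane = comp
        if band_dilation_px > 0:
            membrane = ndimage.binary_dilation(membrane, structure=disk(band_dilation_px))
        nucleus = _nucleus_mask(stack, interior)
        cytoplasm = interior & ~membrane & ~nucleus
        cid += 1
        flags = []
        if not cytoplasm.any():
            flags.append("empty_cytoplasm")
        cells.append(CellMasks(cell_id=cid, membrane=membrane, cytoplasm=cytoplasm, flags=flags))
    return cells


def quantify_cell(
    stack: ChannelStack,
    masks: CellMasks,
    reporters: list[str] | None = None,
) -> dict:
    """Compartment means and localization ratios for one cell.

    ``reporters`` defaults to every channel that is not the membrane dye or
    the nucleus stain. Empty compartments flag the record and yield NaNs.
    """
    if reporters is None:
        reporters = [r for r in stack.roles if r not in (MEMBRANE_MARKER, NUCLEUS)]
    row: dict = {"image_id": stack.image_id, "cell_id": masks.cell_id}
    flags = list(masks.flags)
    mem_n = int(masks.membrane.sum())
    cyt_n = int(masks.cytoplasm.sum())
    if mem_n == 0:
        flags.append("empty_membrane")
    for rep in reporters:
        img = stack.channel(rep)
        mem = float(img[masks.membrane].mean()) if mem_n else np.nan
        cyt = float(img[masks.cytoplasm].mean()) if cyt_n else np.nan
        row[f"membrane_mean_{rep}"] = mem
        row[f"cytoplasm_mean_{rep}"] = cyt
        row[f"ratio_{rep}"] = mem / cyt if cyt_n and cyt > 0 and mem_n else np.nan
    row["flags"] = ";".join(sorted(set(flags)))
    return row


def quantify_cells(
    stack: ChannelStack,
    cells: list[CellMasks],
    reporters: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell measurement table for one image."""
    rows = [quantify_cell(stack, m, reporters) for m in cells]
    if not rows:
        return pd.DataFrame(columns=["image_id", "cell_id", "flags"])
    return pd.DataFrame(rows)


def analyze_image(
    stack: ChannelStack,
    roi_polygons: list[np.ndarray] | None = None,
    band_radius_px: int = 2,
) -> pd.DataFrame:
    """Background-subtract, segment (ROIs take precedence over auto mode)
    and quantify one field of cells."""
    stack = subtract_background(stack)
    if roi_polygons:
        cells = [
            segment_cell_from_polygon(stack, poly, band_radius_px, cell_id=i + 1)
            for i, poly in enumerate(roi_polygons)
        ]
    else:
        cells = segment_cells_auto(stack)
    return quantify_cells(stack, cells)


def load_roi_polygons(path: str | Path) -> list[np.ndarray]:
    """Read per-cell closed polygons (0-based row/col vertex lists) from JSON."""
    with open(path) as fh:
        data = json.load(fh)
    return [np.asarray(poly, dtype=float) for poly in data]
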