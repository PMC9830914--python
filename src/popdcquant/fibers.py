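"""Muscle-fiber segmentation and sarcolemma/cytoplasm compartment quantification.

The membrane-marker channel (an SGCA immunostain in the study this package
serves) outlines every fiber cross-section: fiber interiors are the
sub-threshold connected components, the sarcolemmal ring is a Euclidean
dilation of each fiber's outline, and the cytoplasm is the interior minus
that ring. Per-fiber mean intensities in both compartments feed the
SGCA-normalized sarcolemmal expression ratio

    sgca_norm_sarcolemma = target ring mean / membrane-marker ring mean

which is the per-fiber statistic compared across patient and control arms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import clear_border, relabel_sequential

from .stack import MEMBRANE_MARKER, TARGET, ChannelStack

logger = logging.getLogger(__name__)


@dataclass
class SegmentationConfig:
    """Fiber segmentation parameters.

    threshold_method
        ``"otsu"`` (default) thresholds the membrane-marker channel
        automatically; ``"fixed"`` uses ``fixed_threshold`` (a.u.).
    min_fiber_area_um2
        connected components smaller than this are dropped.
    exclude_border
        drop components touching the image edge (default on; also removes
        the background component of fields whose fibers do not tile fully).
    dilation_radius_px
        Euclidean disk radius used to grow the fiber outline into the
        sarcolemmal ring.
    """

    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_fiber_area_um2: float = 150.0
    exclude_border: bool = True
    dilation_radius_px: int = 2

    def __post_init__(self) -> None:
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required when threshold_method='fixed'")
        if self.dilation_radius_px < 1:
            raise ValueError("dilation_radius_px must be >= 1")
        if self.min_fiber_area_um2 < 0:
            raise ValueError("min_fiber_area_um2 must be >= 0")


@dataclass
class CompartmentMasks:
    """Disjoint ring/interior label maps plus the originating fiber regions.

    ``ring_labels[p] = k`` means pixel p belongs to fiber k's sarcolemmal
    ring; rings and interiors are disjoint within and across fibers.
    ``skipped`` lists fibers whose interior vanished under the ring.
    """

    fiber_labels: np.ndarray
    ring_labels: np.ndarray
    interior_labels: np.ndarray
    dilation_radius_px: int
    skipped: list[int] = field(default_factory=list)

    @property
    def fiber_ids(self) -> np.ndarray:
        ids = np.unique(self.interior_labels)
        return ids[ids > 0]

    def ring_mask(self, fiber_id: int) -> np.ndarray:
        return self.ring_labels == fiber_id

    def interior_mask(self, fiber_id: int) -> np.ndarray:
        return self.interior_labels == fiber_id


def segment_fibers(stack: ChannelStack, cfg: SegmentationConfig | None = None) -> np.ndarray:
    """Segment fiber interiors from the membrane-marker channel.

    Thresholds the marker, takes connected components (4-connectivity) of
    the sub-threshold region, removes small and (optionally) border-touching
    components, and renumbers labels 1..K in raster order. Returns the label
    image (0 = background). An all-background result is returned with a
    warning rather than raised.
    """
    cfg = cfg or SegmentationConfig()
    marker = stack.channel(MEMBRANE_MARKER)
    if cfg.threshold_method == "fixed":
        thr = float(cfg.fixed_threshold)
    else:
        if np.ptp(marker) == 0:  # uniform channel: nothing is sub-threshold
            logger.warning("%s: uniform marker channel, no fibers", stack.image_id)
            return np.zeros(marker.shape, dtype=np.int32)
        thr = float(threshold_otsu(marker))

    sub = marker < thr
    labels = cc_label(sub, connectivity=1)
    if cfg.exclude_border:
        labels = clear_border(labels)
    min_px = cfg.min_fiber_area_um2 / stack.pixel_size_um**2
    if min_px > 0 and labels.max() > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_px)
        labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    if labels.max() == 0:
        logger.warning("%s: no fibers found", stack.image_id)
    return labels.astype(np.int32)


def compartment_masks(labels: np.ndarray, dilation_radius_px: int = 2) -> CompartmentMasks:
    """Split each fiber into a sarcolemmal ring and a cytoplasmic interior.

    The fiber outline is the exterior boundary band of its interior (pixels
    adjacent to, but outside, the segmented region — where the bright marker
    sits). The ring is every pixel within Euclidean distance
    ``dilation_radius_px`` of that outline; a pixel reachable from two
    fibers' outlines goes to the nearer one (squared distances are compared
    in exact integer arithmetic; ties go to the lower fiber id). Interiors
    are the fiber regions minus all ring pixels.

    Fibers whose interior is wholly consumed by the ring are skipped and
    logged.
    """
    if dilation_radius_px < 1:
        raise ValueError("dilation_radius_px must be >= 1")
    labels = np.asarray(labels)
    h, w = labels.shape
    r = int(dilation_radius_px)
    r2 = r * r

    ids = np.unique(labels)
    ids = ids[ids > 0]
    best_d2 = np.full((h, w), np.iinfo(np.int64).max, dtype=np.int64)
    owner = np.zeros((h, w), dtype=np.int32)

    struct = ndimage.generate_binary_structure(2, 1)  # 4-connectivity cross
    objects = ndimage.find_objects(labels)
    for fid in ids:
        sl = objects[fid - 1]
        pad = r + 2
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, h)
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, w)
        region = labels[r0:r1, c0:c1] == fid
        outline = ndimage.binary_dilation(region, structure=struct) & ~region
        pts = np.argwhere(outline)
        if len(pts) == 0:
            continue
        tree = cKDTree(pts)
        box_rr, box_cc = np.mgrid[0 : r1 - r0, 0 : c1 - c0]
        pix = np.column_stack([box_rr.ravel(), box_cc.ravel()])
        _, nearest = tree.query(pix, workers=1)
        diff = pix - pts[nearest]
        d2 = (diff * diff).sum(axis=1).reshape(r1 - r0, c1 - c0)
        within = d2 <= r2
        sub_best = best_d2[r0:r1, c0:c1]
        sub_owner = owner[r0:r1, c0:c1]
        # strict < keeps the earlier (lower) id on exact ties
        take = within & (d2 < sub_best)
        sub_best[take] = d2[take]
        sub_owner[take] = fid

    ring = owner
    interior = np.where((labels > 0) & (ring == 0), labels, 0).astype(np.int32)

    skipped = []
    present = set(np.unique(interior).tolist())
    for fid in ids:
        if int(fid) not in present:
            skipped.append(int(fid))
            logger.warning(
                "fiber %d: interior empty at dilation radius %d; skipped", fid, r
            )
    if skipped:
        drop = np.isin(ring, skipped)
        ring = np.where(drop, 0, ring)
    return CompartmentMasks(
        fiber_labels=labels.astype(np.int32),
        ring_labels=ring.astype(np.int32),
        interior_labels=interior,
        dilation_radius_px=r,
        skipped=skipped,
    )


def quantify_fibers(
    stack: ChannelStack,
    masks: CompartmentMasks,
    pixel_size_um: float | None = None,
) -> pd.DataFrame:
    """Per-fiber compartment means, area and derived ratios.

    Returns one row per fiber with columns ``ring_mean_<role>`` /
    ``interior_mean_<role>`` for every channel present, the cross-sectional
    area (full fiber region, µm²), the SGCA-normalized sarcolemmal target
    level ``sgca_norm_sarcolemma`` and the sarcolemma:cytoplasm
    ``enrichment`` of the target. Fibers with a zero marker ring mean get a
    NaN ratio and a ``flags`` entry; callers exclude flagged rows from
    summaries.
    """
    px = stack.pixel_size_um if pixel_size_um is None else pixel_size_um
    ids = masks.fiber_ids
    if len(ids) == 0:
        cols = ["image_id", "fiber_id", "area_um2", "sgca_norm_sarcolemma", "enrichment", "flags"]
        return pd.DataFrame(columns=cols)

    area_px = ndimage.sum_labels(
        np.ones_like(masks.fiber_labels), labels=masks.fiber_labels, index=ids
    )
    out: dict[str, np.ndarray] = {
        "image_id": np.repeat(stack.image_id, len(ids)),
        "fiber_id": ids,
        "area_um2": area_px * px**2,
    }
    for role in stack.roles:
        img = stack.channel(role)
        out[f"ring_mean_{role}"] = ndimage.mean(img, labels=masks.ring_labels, index=ids)
        out[f"interior_mean_{role}"] = ndimage.mean(
            img, labels=masks.interior_labels, index=ids
        )
    df = pd.DataFrame(out)

    flags = np.full(len(ids), "", dtype=object)
    if TARGET in stack.roles and MEMBRANE_MARKER in stack.roles:
        marker_ring = df[f"ring_mean_{MEMBRANE_MARKER}"].to_numpy()
        target_ring = df[f"ring_mean_{TARGET}"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(marker_ring > 0, target_ring / marker_ring, np.nan)
        df["sgca_norm_sarcolemma"] = ratio
        bad = ~(marker_ring > 0)
        flags[bad] = "zero_marker_ring"
        if bad.any():
            logger.warning(
                "%s: %d fibers with zero marker ring mean flagged", stack.image_id, bad.sum()
            )
    if TARGET in stack.roles:
        t_int = df[f"interior_mean_{TARGET}"].to_numpy()
        t_ring = df[f"ring_mean_{TARGET}"].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            df["enrichment"] = np.where(t_int > 0, t_ring / t_int, np.nan)
    df["flags"] = flags
    return df


def analyze_image(
    stack: ChannelStack, cfg: SegmentationConfig | None = None
) -> tuple[pd.DataFrame, CompartmentMasks]:
    """Segment, split compartments and quantify one image in one call."""
    cfg = cfg or SegmentationConfig()
    labels = segment_fibers(stack, cfg)
    masks = compartment_masks(labels, cfg.dilation_radius_px)
    return quantify_fibers(stack, masks), masks
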