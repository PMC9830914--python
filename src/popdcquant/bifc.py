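"""Bimolecular fluorescence complementation (BiFC) quantification.

Split-fluorophore halves fused to two candidate partners reconstitute a
Venus fluorophore on interaction. Quantification is transfection-gated and
nucleus-excluded: pixels expressing the internal transfection control (mRFP)
above background are selected, nuclei are removed, and the per-image BiFC
signal is

    median Venus / median mRFP

over that mask. Group means of per-image signals are normalized to the
wild-type pair (== 1) and compared by one-way ANOVA with Dunnett's test —
the image, not the cell, is the replication unit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .stack import INTERACTION, NUCLEUS, TRANSFECTION_CONTROL, ChannelStack
from .stats import ComparisonResult, anova_dunnett

logger = logging.getLogger(__name__)


@dataclass
class BifcImageResult:
    """Transfection-gated median signals for one image."""

    image_id: str
    median_venus: float
    median_mrfp: float
    bifc_signal: float
    n_pixels: int


@dataclass
class BifcGroupResult:
    """Mean per-image BiFC signal of one group, wild-type-normalized."""

    label: str
    mean_signal: float
    normalized: float
    n_images: int


def select_transfected(
    stack: ChannelStack,
    mrfp_threshold: float | None = None,
    k_mad: float = 3.0,
) -> np.ndarray | None:
    """Mask of transfected, non-nuclear pixels.

    The default threshold is background + ``k_mad`` x MAD, estimated over
    the non-cell region (pixels below the control channel's Otsu level;
    the whole image when Otsu finds no structure). Nuclei (Otsu on the
    nucleus channel, when present) are removed. Returns None — image
    excluded — when the mask comes out empty.
    """
    control = stack.channel(TRANSFECTION_CONTROL)
    if mrfp_threshold is None:
        if np.ptp(control) == 0:
            bg_region = control
        else:
            bg_region = control[control <= threshold_otsu(control)]
        med = float(np.median(bg_region))
        mad = float(np.median(np.abs(bg_region - med)))
        mrfp_threshold = med + k_mad * mad
    mask = control > mrfp_threshold
    if stack.has(NUCLEUS):
        nuc = stack.channel(NUCLEUS)
        if np.ptp(nuc) > 0:
            mask &= ~(nuc > threshold_otsu(nuc))
    if not mask.any():
        logger.warning("%s: no transfected pixels; image excluded", stack.image_id)
        return None
    return mask


def bifc_image_signal(stack: ChannelStack, mask: np.ndarray) -> BifcImageResult | None:
    """Median Venus and mRFP over the transfected mask; None when the mRFP
    median is zero (signal undefined, image excluded)."""
    if mask is None or not mask.any():
        raise ValueError("mask must be non-empty; run select_transfected first")
    venus = float(np.median(stack.channel(INTERACTION)[mask]))
    mrfp = float(np.median(stack.channel(TRANSFECTION_CONTROL)[mask]))
    if mrfp <= 0:
        logger.warning("%s: zero mRFP median; image excluded", stack.image_id)
        return None
    return BifcImageResult(
        image_id=stack.image_id,
        median_venus=venus,
        median_mrfp=mrfp,
        bifc_signal=venus / mrfp,
        n_pixels=int(mask.sum()),
    )


def analyze_image(stack: ChannelStack, **kwargs) -> BifcImageResult | None:
    """Gate and measure one BiFC field; None when the image is excluded."""
    mask = select_transfected(stack, **kwargs)
    if mask is None:
        return None
    return bifc_image_signal(stack, mask)


def summarize_groups(
    per_image: pd.DataFrame,
    wildtype_label: str,
) -> tuple[list[BifcGroupResult], ComparisonResult | None]:
    """Group means of per-image BiFC signals, wild-type-normalized, with
    ANOVA + Dunnett vs the wild-type group.

    ``per_image`` needs columns ``group`` and ``bifc_signal``. A single
    group is normalized only (no test). The wild-type group must contribute
    at least 2 images.
    """
    required = {"group", "bifc_signal"}
    if not required <= set(per_image.columns):
        raise ValueError(f"per_image needs columns {sorted(required)}")
    if wildtype_label not in set(per_image["group"]):
        raise ValueError(f"wild-type group {wildtype_label!r} absent")
    groups = {
        str(g): grp["bifc_signal"].to_numpy(dtype=float)
        for g, grp in per_image.groupby("group", sort=True)
    }
    if groups[wildtype_label].size < 2:
        raise ValueError("wild-type group needs >= 2 images")
    wt_mean = float(groups[wildtype_label].mean())
    if wt_mean <= 0:
        raise ValueError("wild-type mean signal must be > 0")
    order = [wildtype_label] + sorted(g for g in groups if g != wildtype_label)
    results = [
        BifcGroupResult(
            label=g,
            mean_signal=float(groups[g].mean()),
            normalized=float(groups[g].mean()) / wt_mean,
            n_images=groups[g].size,
        )
        for g in order
    ]
    comparison = None
    if len(groups) > 1:
        comparison = anova_dunnett(groups, control_label=wildtype_label)
    return results, comparison
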