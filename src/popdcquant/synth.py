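"""Seeded synthetic microscopy images and BRET titrations with ground truth.

Every downstream stage of the package (fiber segmentation, compartment
quantification, BiFC gating, stoichiometry fitting, the statistics layer) is
exercised against images produced here, because the study's biopsy and
live-cell images are not available. Each generator returns the image data
*and* a :class:`GroundTruth` carrying the exact object masks and noise-free
intensities it implies, so recovery can be tested without circularity.

Emulated scenes
---------------
* **Biopsy cross-sections** (:func:`generate_biopsy`) — a mosaic of
  border-sharing polygonal muscle fibers built from a seeded, area-weighted
  power-diagram partition. The membrane-marker channel (SGCA-like) is bright
  only on each fiber's sarcolemmal ring; the target channel (POPDC-like)
  carries per-fiber ring/interior means with a group-level multiplicative
  effect on the ring.
* **Transfected-cell fields** (:func:`generate_cell_field`) — round cells
  with a DiD-like membrane ring, a nuclear disc, and reporter channels whose
  noise-free membrane:cytoplasm ratio equals the requested value exactly.
* **BiFC fields** (:func:`generate_bifc_field`) — mixed transfected /
  untransfected cells; the interaction (Venus-like) channel is a fixed
  efficiency times the transfection-control (mRFP-like) channel per cell.
* **Type-1 BRET titrations** (:func:`generate_bret_titration`) — donor and
  acceptor expression varied at constant total, BRET from the ideal
  stoichiometry curves of :mod:`popdcquant.qbret` plus background and noise.

All randomness flows through ``numpy.random.default_rng(seed)``; identical
spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .stack import (
    INTERACTION,
    MEMBRANE_MARKER,
    NUCLEUS,
    TARGET,
    TRANSFECTION_CONTROL,
    ChannelStack,
)


class CapacityError(ValueError):
    """The requested objects cannot be placed in the given field."""


# --------------------------------------------------------------------------
# specs


@dataclass
class BiopsySpec:
    """Parameters of a synthetic transverse muscle-section image.

    Intensities are arbitrary units (a.u.); areas are µm². ``group_effect``
    multiplies the target ring intensity only (control condition = 1.0),
    mirroring a change in sarcolemmal target abundance at constant membrane
    marker. ``intensity_cv`` is the coefficient of variation of a per-fiber
    multiplicative lognormal factor applied to the target channel.
    """

    n_fibers: int = 150
    field_size_px: tuple[int, int] = (640, 640)
    pixel_size_um: float = 1.5
    area_lognormal: tuple[float, float] = (np.log(3000.0), 0.3)
    ring_thickness_px: int = 3
    marker_ring_intensity: float = 150.0
    target_ring_intensity: float = 200.0
    target_interior_intensity: float = 12.0
    group_effect: float = 1.0
    intensity_cv: float = 0.1
    noise_sd: float = 5.0
    background: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_fibers < 1:
            raise ValueError("n_fibers must be >= 1")
        if self.ring_thickness_px < 1:
            raise ValueError("ring_thickness_px must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        for name in (
            "marker_ring_intensity",
            "target_ring_intensity",
            "target_interior_intensity",
            "noise_sd",
            "background",
            "intensity_cv",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.group_effect <= 0:
            raise ValueError("group_effect must be > 0")


@dataclass
class CellFieldSpec:
    """Parameters of a synthetic field of transfected cells.

    ``reporter_ratios`` maps reporter channel role to its true
    membrane:cytoplasm intensity ratio; the cytoplasmic level is
    ``cytoplasm_intensity`` a.u. in every cell (times a per-cell lognormal
    factor with CV ``intensity_cv``, which cancels in the ratio).
    """

    n_cells: int = 30
    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.25
    cell_radius_px: tuple[int, int] = (28, 40)
    nucleus_radius_px: int = 12
    membrane_ring_px: int = 3
    reporter_ratios: Mapping[str, float] = field(
        default_factory=lambda: {"reporter_popdc1": 4.5, "reporter_popdc2": 4.5}
    )
    did_intensity: float = 180.0
    cytoplasm_intensity: float = 60.0
    nucleus_intensity: float = 150.0
    intensity_cv: float = 0.1
    noise_sd: float = 4.0
    background: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.membrane_ring_px < 1:
            raise ValueError("membrane_ring_px must be >= 1")
        lo, hi = self.cell_radius_px
        if lo < 4 or hi < lo:
            raise ValueError("cell_radius_px must satisfy 4 <= lo <= hi")
        if self.nucleus_radius_px >= lo - self.membrane_ring_px:
            raise ValueError("nucleus must fit inside the smallest cell")
        if any(r <= 0 for r in self.reporter_ratios.values()):
            raise ValueError("reporter ratios must be > 0")
        if not self.reporter_ratios:
            raise ValueError("need at least one reporter channel")


@dataclass
class BifcFieldSpec:
    """Parameters of a synthetic BiFC field.

    ``efficiency`` is the per-cell interaction (Venus) : transfection-control
    (mRFP) intensity ratio; the wild-type pair corresponds to the value used
    as reference in :func:`popdcquant.bifc.summarize_groups`.
    """

    n_cells: int = 70
    field_size_px: tuple[int, int] = (400, 400)
    pixel_size_um: float = 1.0
    cell_radius_px: tuple[int, int] = (8, 13)
    nucleus_radius_px: int = 4
    transfected_fraction: float = 0.8
    efficiency: float = 1.0
    mrfp_intensity: float = 120.0
    nucleus_intensity: float = 150.0
    intensity_cv: float = 0.1
    noise_sd: float = 3.0
    background: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.transfected_fraction <= 1.0:
            raise ValueError("transfected_fraction must be in [0, 1]")
        if self.efficiency < 0:
            raise ValueError("efficiency must be >= 0")
        lo, hi = self.cell_radius_px
        if lo < 3 or hi < lo:
            raise ValueError("cell_radius_px must satisfy 3 <= lo <= hi")
        if self.nucleus_radius_px >= lo:
            raise ValueError("nucleus must fit inside the smallest cell")


@dataclass
class BretSimSpec:
    """Parameters of a simulated type-1 BRET titration.

    Donor and acceptor plasmid proportions vary across points while total
    expression stays constant, as in the constant-total transfection design.
    ``stoichiometry_n`` selects the ideal curve: 1 = monomer (bystander-only,
    linear in acceptor:donor ratio with slope ``bystander_slope``), n >= 2 =
    n-mer with saturating amplitude ``bmax``.
    """

    stoichiometry_n: int = 2
    bmax: float = 0.5
    bystander_slope: float = 0.05
    total_expression: float = 1000.0
    donor_fractions: tuple[float, ...] = (
        0.95, 0.90, 0.85, 0.80, 0.70, 0.60, 0.50, 0.40, 0.30, 0.22, 0.15, 0.10,
    )
    noise_sd: float = 0.02
    expression_noise_cv: float = 0.02
    background_bret: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.stoichiometry_n < 1:
            raise ValueError("stoichiometry_n must be >= 1")
        if self.bmax < 0:
            raise ValueError("bmax must be >= 0")
        if not all(0.0 < f < 1.0 for f in self.donor_fractions):
            raise ValueError("donor fractions must lie strictly in (0, 1)")
        if self.total_expression <= 0:
            raise ValueError("total_expression must be > 0")
        if self.noise_sd < 0 or self.expression_noise_cv < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class GroundTruth:
    """True masks and intensities behind one synthetic image.

    ``labels`` assigns each pixel its object id (0 = background);
    ``compartments`` holds per-compartment label maps (same id scheme) such
    as ``ring``/``interior`` for biopsies or ``membrane``/``cytoplasm``/
    ``nucleus`` for cell fields. ``true_means[role][compartment]`` is the
    noise-free mean intensity per object, aligned with ``object_ids``.
    """

    object_ids: np.ndarray
    labels: np.ndarray
    compartments: dict[str, np.ndarray]
    noise_free: dict[str, np.ndarray]
    areas_um2: np.ndarray | None = None
    true_means: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    info: dict = field(default_factory=dict)

    def mask(self, object_id: int) -> np.ndarray:
        return self.labels == object_id

    def compartment_mask(self, name: str, object_id: int) -> np.ndarray:
        return self.compartments[name] == object_id


# --------------------------------------------------------------------------
# shared placement helpers


def _dart_throw(
    rng: np.random.Generator,
    radii: np.ndarray,
    shape: tuple[int, int],
    pack: float,
    margin: np.ndarray,
    max_tries: int = 3000,
) -> np.ndarray:
    """Place circle centers by dart throwing; ``pack`` < 1 allows overlap.

    Raises :class:`CapacityError` when a center cannot be placed.
    """
    h, w = shape
    centers = np.empty((len(radii), 2))
    order = np.argsort(radii)[::-1]  # large objects first
    placed: list[int] = []
    for i in order:
        lo_r, lo_c = margin[i], margin[i]
        if h - 2 * margin[i] <= 1 or w - 2 * margin[i] <= 1:
            raise CapacityError("field too small for object radius")
        ok = False
        for _ in range(max_tries):
            p = np.array(
                [
                    rng.uniform(lo_r, h - lo_r),
                    rng.uniform(lo_c, w - lo_c),
                ]
            )
            if all(
                np.hypot(*(p - centers[j])) >= pack * (radii[i] + radii[j])
                for j in placed
            ):
                centers[i] = p
                placed.append(i)
                ok = True
                break
        if not ok:
            raise CapacityError(
                f"could not place object {i} after {max_tries} tries; "
                "field too small for the requested count/sizes"
            )
    return centers


# --------------------------------------------------------------------------
# biopsy mosaic


def _power_assign(
    coords: np.ndarray,
    seeds: np.ndarray,
    weights: np.ndarray,
    shape: tuple[int, int],
) -> np.ndarray:
    """Assign pixels to seeds by the additively weighted power metric.

    Pixel p belongs to argmin_i |p - s_i|^2 - w_i when that minimum is <= 0
    (inside some power circle); otherwise background. Background pockets
    fully enclosed by cells are then filled by the same argmin, so fibers
    share borders without trapped gaps (only the outer, border-touching
    background remains). Restricting the search to the 12 nearest seeds is
    exact in practice for mosaics whose power radii are commensurate with
    seed spacing.
    """
    from skimage.measure import label as cc_label

    k = min(len(seeds), 12)
    tree = cKDTree(seeds)
    dist, idx = tree.query(coords, k=k, workers=1)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]
    power = dist**2 - weights[idx]
    best = np.argmin(power, axis=1)
    rows = np.arange(len(coords))
    nearest = (idx[rows, best] + 1).astype(np.int32)
    labels = nearest.copy()
    labels[power[rows, best] > 0] = 0
    labels = labels.reshape(shape)
    nearest = nearest.reshape(shape)

    bg = labels == 0
    if bg.any():
        comps = cc_label(bg, connectivity=1)
        touches = np.unique(
            np.concatenate([comps[0, :], comps[-1, :], comps[:, 0], comps[:, -1]])
        )
        pocket = bg & ~np.isin(comps, touches)
        labels[pocket] = nearest[pocket]
    return labels


def _boundary_distance(labels: np.ndarray) -> np.ndarray:
    """Euclidean distance of each pixel to the nearest inter-object boundary
    pixel, where boundary pixels are those whose 4-neighbourhood (image edge
    counts as background) contains a different label."""
    padded = np.pad(labels, 1, constant_values=-1)
    center = padded[1:-1, 1:-1]
    boundary = np.zeros_like(center, dtype=bool)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        nb = padded[1 + dr : padded.shape[0] - 1 + dr, 1 + dc : padded.shape[1] - 1 + dc]
        boundary |= nb != center
    return ndimage.distance_transform_edt(~boundary)


def generate_biopsy(spec: BiopsySpec) -> tuple[ChannelStack, GroundTruth]:
    """Generate one synthetic transverse muscle-section image.

    Fibers are the cells of an area-weighted power diagram grown around a
    seeded point process; each cell's outermost ``ring_thickness_px`` band is
    the sarcolemmal ring (bright in the membrane-marker channel), the rest
    its interior. Power weights are iterated so each fiber's *interior* area
    tracks its lognormal draw. Gaussian noise is added last and images are
    clipped at zero.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    mu, sigma = spec.area_lognormal

    areas_um2 = rng.lognormal(mu, sigma, spec.n_fibers)
    areas_px = areas_um2 / spec.pixel_size_um**2
    r_int = np.sqrt(areas_px / np.pi)
    r_cell = r_int + spec.ring_thickness_px

    if np.sum(np.pi * r_cell**2) > 0.90 * h * w:
        raise CapacityError(
            f"field {h}x{w} px too small for {spec.n_fibers} fibers of this size"
        )
    # dense packings exceed the dart-throwing jamming limit, so start loose
    # and let Lloyd-style centroid moves spread the seeds
    centers = _dart_throw(rng, r_cell, (h, w), pack=0.72, margin=r_cell + 1.0)

    rr, cc = np.mgrid[0:h, 0:w]
    coords = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    weights = r_cell**2
    # feedback iterations: match each fiber's interior area to its draw,
    # relaxing seeds to cell centroids during the first sweeps
    for it in range(12):
        labels = _power_assign(coords, centers, weights, (h, w))
        dist = _boundary_distance(labels)
        interior = np.where(dist >= spec.ring_thickness_px, labels, 0)
        got = np.bincount(interior.ravel(), minlength=spec.n_fibers + 1)[1:]
        weights = np.maximum(
            weights + 0.8 * (areas_px - got) / np.pi,
            float(spec.ring_thickness_px + 1) ** 2,
        )
        if it < 6:
            flat = labels.ravel()
            counts = np.bincount(flat, minlength=spec.n_fibers + 1)[1:]
            sum_r = np.bincount(flat, weights=coords[:, 0], minlength=spec.n_fibers + 1)[1:]
            sum_c = np.bincount(flat, weights=coords[:, 1], minlength=spec.n_fibers + 1)[1:]
            nonempty = counts > 0
            centers = centers.copy()
            centers[nonempty, 0] = sum_r[nonempty] / counts[nonempty]
            centers[nonempty, 1] = sum_c[nonempty] / counts[nonempty]
    labels = _power_assign(coords, centers, weights, (h, w))
    dist = _boundary_distance(labels)
    interior = np.where(dist >= spec.ring_thickness_px, labels, 0)
    ring = np.where((labels > 0) & (interior == 0), labels, 0)

    interior_px = np.bincount(interior.ravel(), minlength=spec.n_fibers + 1)[1:]
    keep = interior_px > 0
    ids = np.arange(1, spec.n_fibers + 1)[keep]

    # per-fiber multiplicative heterogeneity on the target channel
    if spec.intensity_cv > 0:
        s = np.sqrt(np.log1p(spec.intensity_cv**2))
        factors = rng.lognormal(-0.5 * s**2, s, spec.n_fibers)
    else:
        factors = np.ones(spec.n_fibers)

    ring_val = np.zeros(spec.n_fibers + 1)
    int_val = np.zeros(spec.n_fibers + 1)
    ring_val[1:] = spec.group_effect * spec.target_ring_intensity * factors
    int_val[1:] = spec.target_interior_intensity * factors

    target_nf = spec.background + ring_val[ring] + int_val[interior]
    marker_nf = spec.background + np.where(ring > 0, spec.marker_ring_intensity, 0.0)

    def _noisy(img: np.ndarray) -> np.ndarray:
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        return np.clip(img, 0.0, None)

    stack = ChannelStack(
        {MEMBRANE_MARKER: _noisy(marker_nf), TARGET: _noisy(target_nf)},
        pixel_size_um=spec.pixel_size_um,
        image_id=f"biopsy_seed{spec.seed}",
    )

    gt = GroundTruth(
        object_ids=ids,
        labels=np.where(np.isin(labels, ids), labels, 0),
        compartments={"ring": ring, "interior": interior},
        noise_free={MEMBRANE_MARKER: marker_nf, TARGET: target_nf},
        areas_um2=interior_px[keep] * spec.pixel_size_um**2,
        true_means={
            TARGET: {
                "ring": spec.background + ring_val[ids],
                "interior": spec.background + int_val[ids],
            },
            MEMBRANE_MARKER: {
                "ring": np.full(len(ids), spec.background + spec.marker_ring_intensity),
                "interior": np.full(len(ids), spec.background),
            },
        },
        info={"group_effect": spec.group_effect, "factors": factors[keep]},
    )
    return stack, gt


# --------------------------------------------------------------------------
# transfected-cell fields


def generate_cell_field(spec: CellFieldSpec) -> tuple[ChannelStack, GroundTruth]:
    """Generate a field of round transfected cells.

    Each cell is a disc with a DiD-bright membrane annulus of thickness
    ``membrane_ring_px``, a nuclear disc, and reporter channels whose
    noise-free membrane:cytoplasm ratio equals ``reporter_ratios`` exactly
    (the nuclear disc carries cytoplasm-level reporter intensity so nuclear
    mask errors cannot bias the compartments).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    lo, hi = spec.cell_radius_px
    radii = rng.integers(lo, hi + 1, spec.n_cells).astype(float)
    centers = _dart_throw(rng, radii, (h, w), pack=1.05, margin=radii + 2.0)

    labels = np.zeros((h, w), dtype=np.int32)
    membrane = np.zeros_like(labels)
    interior = np.zeros_like(labels)
    nucleus = np.zeros_like(labels)
    rr, cc = np.mgrid[0:h, 0:w]
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        disc = d2 <= r**2
        inner = d2 <= (r - spec.membrane_ring_px) ** 2
        labels[disc] = i
        membrane[disc & ~inner] = i
        interior[inner] = i
        nucleus[d2 <= spec.nucleus_radius_px**2] = i
    cytoplasm = np.where((interior > 0) & (nucleus == 0), interior, 0)

    if spec.intensity_cv > 0:
        s = np.sqrt(np.log1p(spec.intensity_cv**2))
        factors = rng.lognormal(-0.5 * s**2, s, spec.n_cells)
    else:
        factors = np.ones(spec.n_cells)

    ids = np.arange(1, spec.n_cells + 1)
    noise_free: dict[str, np.ndarray] = {}
    true_means: dict[str, dict[str, np.ndarray]] = {}

    did = spec.background + np.where(membrane > 0, spec.did_intensity, 0.0)
    nuc = spec.background + np.where(nucleus > 0, spec.nucleus_intensity, 0.0)
    noise_free[MEMBRANE_MARKER] = did
    noise_free[NUCLEUS] = nuc

    fac = np.concatenate([[0.0], factors])
    for role, ratio in spec.reporter_ratios.items():
        c0 = spec.cytoplasm_intensity
        img = spec.background + np.zeros((h, w))
        img += np.where(membrane > 0, ratio * c0 * fac[membrane], 0.0)
        img += np.where((interior > 0), c0 * fac[interior], 0.0)
        noise_free[role] = img
        true_means[role] = {
            "membrane": spec.background + ratio * c0 * factors,
            "cytoplasm": spec.background + c0 * factors,
        }

    def _noisy(img: np.ndarray) -> np.ndarray:
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        return np.clip(img, 0.0, None)

    stack = ChannelStack(
        {role: _noisy(img) for role, img in noise_free.items()},
        pixel_size_um=spec.pixel_size_um,
        image_id=f"cells_seed{spec.seed}",
    )
    gt = GroundTruth(
        object_ids=ids,
        labels=labels,
        compartments={"membrane": membrane, "cytoplasm": cytoplasm, "nucleus": nucleus},
        noise_free=noise_free,
        true_means=true_means,
        info={
            "reporter_ratios": dict(spec.reporter_ratios),
            "factors": factors,
            "centers": centers,
            "radii": radii,
        },
    )
    return stack, gt


# --------------------------------------------------------------------------
# BiFC fields


def generate_bifc_field(spec: BifcFieldSpec) -> tuple[ChannelStack, GroundTruth]:
    """Generate a BiFC field of mixed transfected / untransfected cells.

    Transfected cells express the transfection control (mRFP-like) at a
    per-cell lognormal level; the interaction (Venus-like) channel is exactly
    ``efficiency`` times the control in each transfected cell. Untransfected
    cells are dark in both but nucleus-stained, so they are visible to the
    gating step only through the control threshold.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.field_size_px
    lo, hi = spec.cell_radius_px
    radii = rng.integers(lo, hi + 1, spec.n_cells).astype(float)
    centers = _dart_throw(rng, radii, (h, w), pack=1.05, margin=radii + 2.0)

    n_trans = int(round(spec.transfected_fraction * spec.n_cells))
    transfected = np.zeros(spec.n_cells, dtype=bool)
    transfected[rng.permutation(spec.n_cells)[:n_trans]] = True

    labels = np.zeros((h, w), dtype=np.int32)
    nucleus = np.zeros_like(labels)
    rr, cc = np.mgrid[0:h, 0:w]
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        labels[d2 <= r**2] = i
        nucleus[d2 <= spec.nucleus_radius_px**2] = i

    if spec.intensity_cv > 0:
        s = np.sqrt(np.log1p(spec.intensity_cv**2))
        factors = rng.lognormal(-0.5 * s**2, s, spec.n_cells)
    else:
        factors = np.ones(spec.n_cells)
    mrfp_level = np.where(transfected, spec.mrfp_intensity * factors, 0.0)
    venus_level = spec.efficiency * mrfp_level

    lv = np.concatenate([[0.0], mrfp_level])
    vv = np.concatenate([[0.0], venus_level])
    mrfp_nf = spec.background + lv[labels]
    venus_nf = spec.background + vv[labels]
    nuc_nf = spec.background + np.where(nucleus > 0, spec.nucleus_intensity, 0.0)

    def _noisy(img: np.ndarray) -> np.ndarray:
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        return np.clip(img, 0.0, None)

    stack = ChannelStack(
        {
            TRANSFECTION_CONTROL: _noisy(mrfp_nf),
            INTERACTION: _noisy(venus_nf),
            NUCLEUS: _noisy(nuc_nf),
        },
        pixel_size_um=spec.pixel_size_um,
        image_id=f"bifc_seed{spec.seed}",
    )
    gt = GroundTruth(
        object_ids=np.arange(1, spec.n_cells + 1),
        labels=labels,
        compartments={"cell": labels, "nucleus": nucleus},
        noise_free={
            TRANSFECTION_CONTROL: mrfp_nf,
            INTERACTION: venus_nf,
            NUCLEUS: nuc_nf,
        },
        true_means={
            TRANSFECTION_CONTROL: {"cell": spec.background + mrfp_level},
            INTERACTION: {"cell": spec.background + venus_level},
        },
        info={"transfected": transfected, "efficiency": spec.efficiency},
    )
    return stack, gt


# --------------------------------------------------------------------------
# BRET titrations


def generate_bret_titration(spec: BretSimSpec) -> pd.DataFrame:
    """Simulate a constant-total type-1 BRET titration.

    Returns one row per titration point with measured columns
    (``donor_lum``, ``acceptor_fluor``, ``bret_raw``, ``bret_background``)
    and the noise-free truth (``bret_true``, ``f_true``). Donor luminescence
    is proportional to the donor plasmid fraction, acceptor fluorescence to
    its complement, both at constant total; BRET follows the ideal curve for
    ``stoichiometry_n`` plus a constant background and Gaussian noise.
    """
    from .qbret import ideal_curve  # local import: qbret does not import synth

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    df = np.asarray(spec.donor_fractions, dtype=float)
    f_true = 1.0 - df

    donor_true = df * spec.total_expression
    acceptor_true = f_true * spec.total_expression
    cv = spec.expression_noise_cv
    donor_lum = donor_true * (1.0 + rng.normal(0.0, cv, df.size)) if cv > 0 else donor_true.copy()
    acceptor_fluor = (
        acceptor_true * (1.0 + rng.normal(0.0, cv, df.size)) if cv > 0 else acceptor_true.copy()
    )
    donor_lum = np.clip(donor_lum, 1e-9, None)
    acceptor_fluor = np.clip(acceptor_fluor, 0.0, None)

    bret_true = ideal_curve(
        spec.stoichiometry_n,
        bmax=spec.bmax,
        bystander_slope=spec.bystander_slope,
        f=f_true,
    )
    noise = rng.normal(0.0, spec.noise_sd, df.size) if spec.noise_sd > 0 else 0.0
    bret_raw = bret_true + spec.background_bret + noise

    return pd.DataFrame(
        {
            "donor_lum": donor_lum,
            "acceptor_fluor": acceptor_fluor,
            "bret_raw": bret_raw,
            "bret_background": spec.background_bret,
            "bret_true": bret_true,
            "f_true": f_true,
        }
    )


def bret_plate_table(spec: BretSimSpec) -> pd.DataFrame:
    """Simulated raw plate export: one dye well plus one matched DMSO
    (dye-free) background well per titration point, as read by
    :func:`popdcquant.qbret.correct_and_normalize`."""
    tit = generate_bret_titration(spec)
    rows = []
    for i, r in tit.iterrows():
        rows.append(
            {
                "well": f"P{i:02d}",
                "condition": f"point{i:02d}",
                "donor_lum": r["donor_lum"],
                "acceptor_fluor": r["acceptor_fluor"],
                "bret": r["bret_raw"],
                "is_background": False,
            }
        )
        rows.append(
            {
                "well": f"B{i:02d}",
                "condition": f"point{i:02d}",
                "donor_lum": r["donor_lum"],
                "acceptor_fluor": 0.0,
                "bret": r["bret_background"],
                "is_background": True,
            }
        )
    return pd.DataFrame(rows)
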