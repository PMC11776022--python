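"""Render CD34-style placental section images with pixel-level ground truth.

A slide is composed of irregular villous blobs in hematoxylin blue-purple,
AEC-red vessel discs strictly inside the villi, pale-pink fibrin deposits,
near-white intervillous space, and optional dark achromatic artifact
speckles in the intervillous space.  Colors are produced by a forward
Beer-Lambert render through the same stain matrix the imaging stage uses
for deconvolution, so the two are consistent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.draw import disk as draw_disk

from .. import config
from ..config import (
    LABEL_ARTIFACT,
    LABEL_BACKGROUND,
    LABEL_FIBRIN,
    LABEL_VILLI,
    STAIN_MATRIX,
)
from ..errors import ValidationError
from ..imaging import LabelMask, SlideImage

__all__ = ["SlideParams", "GroundTruth", "generate_slide"]


@dataclass
class SlideParams:
    """Generative knobs for one synthetic section.

    Defaults reproduce the cohort-mean histology: villous fraction 0.497 of
    the canvas, 1324 vessel cross-sections per mm² villous area with radii
    drawn uniformly in 3-9 µm (expected disc area ~123 µm², i.e. vessels
    cover ~16% of the villous area).
    """

    width_px: int = 512
    height_px: int = 512
    pixel_size_um: float = 2.0
    villous_fraction: float = 0.497
    fibrin_fraction: float = 0.03
    artifact_fraction: float = 0.01
    vessel_density_per_mm2: float = 1324.0
    vessel_radius_um_range: tuple[float, float] = (3.0, 9.0)
    #: fraction of vessels deliberately placed touching a neighbour
    vessel_touch_fraction: float = 0.10
    #: global multiplier on stain concentrations (1 = normal staining)
    stain_intensity: float = 1.0
    #: gaussian blob scale of the villous field, µm
    villous_scale_um: float = 60.0
    fibrin_scale_um: float = 25.0
    seed: int = 0

    def __post_init__(self):
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValidationError("canvas dimensions must be positive")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")
        for name in ("villous_fraction", "fibrin_fraction", "artifact_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.villous_fraction + self.fibrin_fraction > 1.0:
            raise ValidationError("villous_fraction + fibrin_fraction must be <= 1")
        if self.vessel_density_per_mm2 < 0:
            raise ValidationError("vessel_density_per_mm2 must be nonnegative")
        rmin, rmax = self.vessel_radius_um_range
        if not (0 < rmin <= rmax):
            raise ValidationError("vessel_radius_um_range must satisfy 0 < min <= max")
        if not 0 <= self.stain_intensity:
            raise ValidationError("stain_intensity must be nonnegative")


@dataclass
class GroundTruth:
    """Pixel-level truth accompanying a rendered slide."""

    label_mask: LabelMask
    vessel_mask: np.ndarray
    vessel_count: int
    class_counts: dict = field(default_factory=dict)


def _blob_field(shape, scale_px: float, rng: np.random.Generator) -> np.ndarray:
    """Smoothed white noise; thresholding it yields irregular blobs."""
    noise = rng.standard_normal(shape)
    return ndi.gaussian_filter(noise, sigma=scale_px)


def _threshold_to_fraction(fld: np.ndarray, fraction: float,
                           allowed: np.ndarray | None = None) -> np.ndarray:
    """Boolean mask covering ``fraction`` of the canvas, drawn from ``allowed``.

    Picks the top-valued pixels of the field, which keeps the achieved
    fraction exact up to integer rounding while preserving blob morphology.
    """
    n_total = fld.size
    n_want = int(round(fraction * n_total))
    mask = np.zeros(fld.shape, dtype=bool)
    if n_want == 0:
        return mask
    if allowed is None:
        flat_idx = np.argpartition(fld.ravel(), -n_want)[-n_want:]
        mask.ravel()[flat_idx] = True
    else:
        cand = np.flatnonzero(allowed.ravel())
        if len(cand) == 0:
            return mask
        n_want = min(n_want, len(cand))
        vals = fld.ravel()[cand]
        take = cand[np.argpartition(vals, -n_want)[-n_want:]]
        mask.ravel()[take] = True
    return mask


def _place_vessels(villi: np.ndarray, params: SlideParams,
                   rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Poisson placement of vessel discs strictly inside the villous mask."""
    px = params.pixel_size_um
    villous_mm2 = villi.sum() * px**2 / 1e6
    mean_count = params.vessel_density_per_mm2 * villous_mm2
    n = int(rng.poisson(mean_count)) if mean_count > 0 else 0
    vessel_mask = np.zeros(villi.shape, dtype=bool)
    if n == 0:
        return vessel_mask, 0

    rmin, rmax = params.vessel_radius_um_range
    radii_um = rng.uniform(rmin, rmax, size=n)
    dist_in = ndi.distance_transform_edt(villi)

    placed: list[tuple[float, float, float]] = []  # (row, col, r_px)
    n_placed = 0
    # candidate interior pixels per integer clearance, computed lazily
    cand_cache: dict[int, np.ndarray] = {}
    h, w = villi.shape
    for r_um in radii_um:
        r_px = r_um / px
        clearance = int(np.ceil(r_px)) + 1
        touch = placed and rng.random() < params.vessel_touch_fraction
        center = None
        if touch:
            # overlap a previous disc by 10% of the smaller radius
            pr, pc, pr_px = placed[rng.integers(len(placed))]
            d = pr_px + r_px - 0.1 * min(pr_px, r_px)
            theta = rng.uniform(0, 2 * np.pi)
            rr, cc = pr + d * np.sin(theta), pc + d * np.cos(theta)
            ir, ic = int(round(rr)), int(round(cc))
            if 0 <= ir < h and 0 <= ic < w and dist_in[ir, ic] >= clearance:
                center = (rr, cc)
        if center is None:
            if clearance not in cand_cache:
                cand_cache[clearance] = np.flatnonzero(dist_in.ravel() >= clearance)
            cand = cand_cache[clearance]
            if len(cand) == 0:
                continue
            idx = cand[rng.integers(len(cand))]
            center = (idx // w, idx % w)
        rr, cc = draw_disk(center, r_px, shape=villi.shape)
        vessel_mask[rr, cc] = True
        placed.append((center[0], center[1], r_px))
        n_placed += 1
    vessel_mask &= villi  # hard invariant: vessel pixels subset of villi
    return vessel_mask, n_placed


def _place_artifacts(background: np.ndarray, fraction: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Small dark speckle discs confined to the intervillous space."""
    mask = np.zeros(background.shape, dtype=bool)
    target = int(round(fraction * background.size))
    if target == 0:
        return mask
    cand = np.flatnonzero(background.ravel())
    if len(cand) == 0:
        return mask
    h, w = background.shape
    guard = 0
    while mask.sum() < target and guard < 100000:
        guard += 1
        idx = cand[rng.integers(len(cand))]
        r = rng.uniform(1.5, 4.0)
        rr, cc = draw_disk((idx // w, idx % w), r, shape=background.shape)
        mask[rr, cc] = True
    mask &= background
    return mask


def generate_slide(params: SlideParams) -> tuple[SlideImage, GroundTruth]:
    """Render one synthetic section and its ground truth.

    Deterministic: the same ``params`` (including ``params.seed``) always
    produce bit-identical image and truth.
    """
    rng = np.random.default_rng(params.seed)
    shape = (params.height_px, params.width_px)
    px = params.pixel_size_um

    villi = _threshold_to_fraction(
        _blob_field(shape, params.villous_scale_um / px, rng), params.villous_fraction
    )
    fibrin = _threshold_to_fraction(
        _blob_field(shape, params.fibrin_scale_um / px, rng),
        params.fibrin_fraction,
        allowed=~villi,
    )
    background = ~(villi | fibrin)
    vessel_mask, vessel_count = _place_vessels(villi, params, rng)
    artifacts = _place_artifacts(background, params.artifact_fraction, rng)
    background &= ~artifacts

    labels = np.full(shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[villi] = LABEL_VILLI
    labels[fibrin] = LABEL_FIBRIN
    labels[artifacts] = LABEL_ARTIFACT

    # forward Beer-Lambert render
    conc_h = np.empty(shape)
    conc_a = np.empty(shape)
    for cls, mask in (
        ("background", labels == LABEL_BACKGROUND),
        ("villi", villi & ~vessel_mask),
        ("vessel", vessel_mask),
        ("fibrin", fibrin),
    ):
        ch, ca = config.RENDER_CONCENTRATIONS[cls]
        if cls != "background":
            ch, ca = ch * params.stain_intensity, ca * params.stain_intensity
        n = int(mask.sum())
        jit = config.RENDER_CONCENTRATION_JITTER
        conc_h[mask] = ch * np.exp(rng.normal(0, jit, n))
        conc_a[mask] = ca * np.exp(rng.normal(0, jit, n))

    od = conc_h[..., None] * STAIN_MATRIX[0] + conc_a[..., None] * STAIN_MATRIX[1]
    rgb = np.clip(255.0 * 10.0 ** (-od), 0, 255)
    gray = config.ARTIFACT_GRAY_LEVEL
    rgb[artifacts] = gray * np.exp(
        rng.normal(0, 0.05, (int(artifacts.sum()), 1))
    ).clip(0.3, 2.0)
    rgb = np.clip(np.round(rgb), 0, 255).astype(np.uint8)

    image = SlideImage(rgb, px, id=f"synthetic-{params.seed}")
    label_mask = LabelMask(labels, px)
    counts = label_mask.class_counts()
    truth = GroundTruth(label_mask, vessel_mask, vessel_count, counts)
    return image, truth
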