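"""Tissue classification and vessel instance segmentation of CD34 sections.

The chain mirrors a whole-slide immunohistochemistry workflow: a global
intensity threshold finds tissue, a pixel classifier splits tissue into
villi / intervillous background / fibrin / staining artifacts, color
deconvolution extracts the AEC (CD34) channel, and a distance-transform
watershed turns the thresholded stain field into individual vessel
cross-sections with physical areas.

All masks share the label codes in :mod:`placentometry.config`:
0 background (intervillous space), 1 villi, 2 fibrin, 3 artifact, 4 excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.segmentation import watershed

from . import config
from .config import (
    LABEL_ARTIFACT,
    LABEL_BACKGROUND,
    LABEL_EXCLUDED,
    LABEL_FIBRIN,
    LABEL_VILLI,
    STAIN_MATRIX,
    TISSUE_INTENSITY_THRESHOLD,
)
from .errors import NoVillousTissueError, ValidationError

__all__ = [
    "SlideImage",
    "LabelMask",
    "VesselInstances",
    "QCReport",
    "detect_tissue",
    "apply_exclusions",
    "classify_villous_tissue",
    "extract_stain_channel",
    "deconvolve_stains",
    "segment_vessels",
    "qc_slide",
    "RuleBasedPixelClassifier",
    "TrainablePixelClassifier",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class SlideImage:
    """An 8-bit RGB section image with its physical pixel size.

    Parameters
    ----------
    rgb
        ``(H, W, 3)`` uint8 array.
    pixel_size_um
        Edge length of one pixel in micrometres.
    id
        Free-form slide identifier.
    """

    rgb: np.ndarray
    pixel_size_um: float
    id: str = ""

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValidationError("SlideImage.rgb must be (H, W, 3)")
        if self.rgb.dtype != np.uint8:
            raise ValidationError("SlideImage.rgb must be 8-bit (uint8)")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass
class LabelMask:
    """Per-pixel tissue class map sharing the slide's geometry.

    ``artifact_fraction_raw`` preserves the artifact share of tissue as seen
    *before* intervillous artifacts are merged into background, so slide QC
    can still flag heavily contaminated sections.
    """

    labels: np.ndarray
    pixel_size_um: float
    artifact_fraction_raw: float | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("LabelMask.labels must be 2-D")
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> dict[str, int]:
        """Pixel count per class; counts always sum to H*W."""
        return {
            name: int(np.count_nonzero(self.labels == code))
            for code, name in config.LABEL_NAMES.items()
        }


@dataclass
class VesselInstances:
    """Labeled vessel cross-sections with per-instance records.

    ``instance_labels`` is 0 where there is no vessel and ``k`` on the pixels
    of instance ``k``; ids are contiguous from 1.  ``records`` has one row per
    instance with ``id``, ``area_um2``, ``centroid_row``, ``centroid_col`` and
    ``inside_villi`` (centroid lies on a villi-class pixel).
    """

    instance_labels: np.ndarray
    records: pd.DataFrame
    pixel_size_um: float

    @property
    def n_instances(self) -> int:
        return len(self.records)


@dataclass
class QCReport:
    """Slide-level staining quality verdict."""

    artifact_fraction: float
    stain_intensity_summary: dict = field(default_factory=dict)
    passed: bool = True
    reason: str = ""


# ---------------------------------------------------------------------------
# Tissue detection and exclusions
# ---------------------------------------------------------------------------


def _luminance(rgb: np.ndarray) -> np.ndarray:
    """Mean of R, G, B rounded half-up, as an integer image."""
    return np.floor(rgb.astype(np.float64).mean(axis=2) + 0.5).astype(np.int64)


def detect_tissue(image: SlideImage, threshold: int = TISSUE_INTENSITY_THRESHOLD) -> np.ndarray:
    """Binary tissue mask: pixels whose luminance is strictly below ``threshold``.

    Luminance is the arithmetic mean of the three channels rounded half-up,
    so a uniform (209, 209, 209) pixel is tissue and (210, 210, 210) is not.
    """
    if not isinstance(image, SlideImage):
        image = SlideImage(np.asarray(image), 1.0)
    return _luminance(image.rgb) < threshold


def apply_exclusions(
    labels: LabelMask, exclusion_polygons: Sequence[np.ndarray]
) -> LabelMask:
    """Mark pixels inside manually drawn polygons as ``excluded``.

    Polygons are ``(N, 2)`` arrays of ``(row, col)`` vertices in pixel
    coordinates.  Vertices outside the image are clipped (with a warning);
    an empty polygon list returns the labels unchanged (new object).
    """
    out = labels.labels.copy()
    h, w = out.shape
    for poly in exclusion_polygons:
        poly = np.asarray(poly, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
            raise ValidationError("each exclusion polygon needs >= 3 (row, col) vertices")
        if (poly[:, 0].min() < 0 or poly[:, 1].min() < 0
                or poly[:, 0].max() > h - 1 or poly[:, 1].max() > w - 1):
            warnings.warn("exclusion polygon extends outside image bounds; clipping")
        rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=out.shape)
        out[rr, cc] = LABEL_EXCLUDED
    return LabelMask(out, labels.pixel_size_um, labels.artifact_fraction_raw)


# ---------------------------------------------------------------------------
# Color deconvolution
# ---------------------------------------------------------------------------


def _check_stain_matrix(stain_matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(stain_matrix, dtype=float)
    if m.shape != (3, 3):
        raise ValidationError("stain matrix must be 3x3 (rows = stain OD vectors)")
    if np.linalg.cond(m) > 1e6:
        raise ValidationError("degenerate stain matrix: vectors are collinear")
    return m


def deconvolve_stains(
    image: SlideImage, stain_matrix: np.ndarray = STAIN_MATRIX
) -> np.ndarray:
    """Per-pixel stain concentrations via Beer-Lambert color deconvolution.

    Returns an ``(H, W, 3)`` float array whose channels are the hematoxylin,
    AEC and residual concentrations (optical-density multipliers of the
    configured unit vectors).  A pure white pixel maps to 0 in every channel.
    """
    m = _check_stain_matrix(stain_matrix)
    rgb = image.rgb.astype(np.float64)
    od = -np.log10(np.maximum(rgb, 1.0) / 255.0)
    return od @ np.linalg.inv(m)


def extract_stain_channel(
    image: SlideImage, stain_matrix: np.ndarray = STAIN_MATRIX
) -> np.ndarray:
    """AEC (CD34) optical-density field, clipped to be nonnegative."""
    conc = deconvolve_stains(image, stain_matrix)
    return np.maximum(conc[..., 1], 0.0)


# ---------------------------------------------------------------------------
# Pixel classification
# ---------------------------------------------------------------------------


class PixelClassifier(Protocol):
    def predict(self, features: np.ndarray) -> np.ndarray:
        """Map an (H, W, C) feature stack to an (H, W) label image."""


def _feature_stack(image: SlideImage, smoothing_px: int) -> np.ndarray:
    """Deconvolved stain channels plus luminance, boxcar-denoised."""
    conc = deconvolve_stains(image)
    lum = _luminance(image.rgb).astype(np.float64)[..., None] / 255.0
    feats = np.concatenate([conc, lum], axis=2)
    if smoothing_px > 1:
        for c in range(feats.shape[2]):
            feats[..., c] = ndi.uniform_filter(feats[..., c], size=smoothing_px)
    return feats


class RuleBasedPixelClassifier:
    """Deterministic decision rules on deconvolved stain concentrations.

    The thresholds were fitted once on labeled synthetic tiles and are frozen
    in :mod:`placentometry.config`.  Rules, in order of precedence for a
    tissue pixel: achromatic-dark material (high residual channel) is an
    artifact; strong AEC or strong hematoxylin is villous tissue (vessels sit
    on villi and are labeled villi); weak AEC with little hematoxylin is
    fibrin; anything else falls back to background.
    """

    def __init__(self, thresholds: dict | None = None):
        self.thresholds = dict(config.CLASSIFIER_THRESHOLDS)
        if thresholds:
            self.thresholds.update(thresholds)

    def predict(self, features: np.ndarray) -> np.ndarray:
        hema, aec, resid = (features[..., i] for i in range(3))
        t = self.thresholds
        out = np.full(features.shape[:2], LABEL_BACKGROUND, dtype=np.uint8)
        fib = aec >= t["aec_fibrin"]
        out[fib] = LABEL_FIBRIN
        vil = (aec >= t["aec_villi"]) | (hema >= t["hema_villi"])
        out[vil] = LABEL_VILLI
        art = resid >= t["residual_artifact"]
        out[art] = LABEL_ARTIFACT
        return out


class TrainablePixelClassifier:
    """Pixel classifier trainable on synthetic ground truth.

    A small random-forest on the same feature stack as the rule-based
    classifier, behind the same ``predict`` contract.  Useful when stain
    appearance drifts away from the frozen rule thresholds.
    """

    def __init__(self, n_estimators: int = 30, random_state: int = 0):
        from sklearn.ensemble import RandomForestClassifier

        self._clf = RandomForestClassifier(
            n_estimators=n_estimators, random_state=random_state, n_jobs=1
        )
        self._fitted = False

    def fit(self, images: Sequence[SlideImage], truths: Sequence[np.ndarray],
            max_pixels_per_slide: int = 20000, seed: int = 0) -> "TrainablePixelClassifier":
        rng = np.random.default_rng(seed)
        xs, ys = [], []
        for img, truth in zip(images, truths):
            feats = _feature_stack(img, config.CLASSIFIER_SMOOTHING_PX)
            flat = feats.reshape(-1, feats.shape[2])
            lab = np.asarray(truth).ravel()
            idx = rng.choice(len(lab), size=min(max_pixels_per_slide, len(lab)),
                             replace=False)
            xs.append(flat[idx])
            ys.append(lab[idx])
        self._clf.fit(np.concatenate(xs), np.concatenate(ys))
        self._fitted = True
        return self

    def predict(self, features: np.ndarray) -> np.ndarray:
        if not self._fitted:
            raise ValidationError("TrainablePixelClassifier.predict before fit")
        flat = features.reshape(-1, features.shape[2])
        return self._clf.predict(flat).reshape(features.shape[:2]).astype(np.uint8)


def _reassign_intervillous_artifacts(labels: np.ndarray) -> np.ndarray:
    """Merge artifact blobs surrounded by intervillous space into background.

    For each artifact connected component, the one-pixel dilation ring is
    inspected; if at least half of it is background the blob is reassigned.
    Artifacts embedded in villous tissue or fibrin are kept.
    """
    out = labels.copy()
    art = labels == LABEL_ARTIFACT
    if not art.any():
        return out
    comp, n = ndi.label(art)
    ring_struct = ndi.generate_binary_structure(2, 2)
    for i in range(1, n + 1):
        blob = comp == i
        ring = ndi.binary_dilation(blob, structure=ring_struct) & ~blob
        if ring.sum() == 0 or np.mean(labels[ring] == LABEL_BACKGROUND) >= 0.5:
            out[blob] = LABEL_BACKGROUND
    return out


def classify_villous_tissue(
    image: SlideImage,
    tissue_mask: np.ndarray | None = None,
    classifier: PixelClassifier | None = None,
) -> LabelMask:
    """Assign every pixel a tissue class.

    Non-tissue pixels (luminance >= the global threshold) are background.
    Tissue pixels are classified into villi / fibrin / artifact / background
    by the pixel classifier; artifact blobs that lie in the intervillous
    space are then merged into background, the convention used when
    quantifying CD34 sections.  The pre-merge artifact share of tissue is
    kept on the returned mask for QC.
    """
    if tissue_mask is None:
        tissue_mask = detect_tissue(image)
    if classifier is None:
        classifier = RuleBasedPixelClassifier()
    feats = _feature_stack(image, config.CLASSIFIER_SMOOTHING_PX)
    raw = classifier.predict(feats)
    raw = np.where(tissue_mask, raw, LABEL_BACKGROUND).astype(np.uint8)

    n_tissue = int(tissue_mask.sum())
    n_artifact = int(np.count_nonzero(raw == LABEL_ARTIFACT))
    artifact_fraction_raw = (n_artifact / n_tissue) if n_tissue else 0.0

    final = _reassign_intervillous_artifacts(raw)
    return LabelMask(final, image.pixel_size_um, artifact_fraction_raw)


# ---------------------------------------------------------------------------
# Vessel segmentation
# ---------------------------------------------------------------------------


def segment_vessels(
    stain_field: np.ndarray,
    labels: LabelMask,
    *,
    min_area_um2: float = config.MIN_VESSEL_AREA_UM2,
    min_radius_um: float = 3.0,
    stain_threshold: float | None = None,
) -> VesselInstances:
    """Turn the AEC stain field into labeled vessel cross-sections.

    The stain field is thresholded inside villous pixels (per-slide Otsu by
    default), lumina are filled, touching vessels are split by a
    distance-transform watershed seeded at local maxima separated by at least
    ``0.5 * min_radius_um``, and instances smaller than ``min_area_um2`` are
    dropped.  An instance is ``inside_villi`` iff its centroid pixel carries
    the villi label.
    """
    stain_field = np.asarray(stain_field, dtype=float)
    if stain_field.shape != labels.shape:
        raise ValidationError("stain field and labels must share shape")
    villi = labels.labels == LABEL_VILLI
    if not villi.any():
        raise NoVillousTissueError()

    px_um = labels.pixel_size_um
    if stain_threshold is None:
        vals = stain_field[villi]
        if np.ptp(vals) < 1e-9:
            # featureless stain field inside villi: nothing to segment
            return _empty_instances(labels)
        stain_threshold = threshold_otsu(vals)
    cand = (stain_field >= stain_threshold) & villi
    if not cand.any():
        return _empty_instances(labels)
    cand = ndi.binary_fill_holes(cand)

    distance = ndi.distance_transform_edt(cand)
    min_sep_px = max(
        1, int(round(config.WATERSHED_SEED_SEPARATION_FACTOR * min_radius_um / px_um))
    )
    blobs, _ = ndi.label(cand)
    coords = peak_local_max(distance, min_distance=min_sep_px, labels=blobs,
                            exclude_border=False)
    markers = np.zeros_like(blobs)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    markers, _ = ndi.label(markers > 0)
    seg = watershed(-distance, markers, mask=cand)

    # area filter + contiguous relabeling
    ids, counts = np.unique(seg[seg > 0], return_counts=True)
    px_area_um2 = px_um**2
    keep = ids[counts * px_area_um2 >= min_area_um2]
    lut = np.zeros(seg.max() + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1)
    seg = lut[seg]

    if seg.max() == 0:
        return _empty_instances(labels)
    recs = []
    centroids = ndi.center_of_mass(seg > 0, seg, index=np.arange(1, seg.max() + 1))
    areas = np.bincount(seg.ravel())[1:]
    for k, ((cr, cc), a) in enumerate(zip(centroids, areas), start=1):
        ir, ic = int(round(cr)), int(round(cc))
        ir = min(max(ir, 0), labels.shape[0] - 1)
        ic = min(max(ic, 0), labels.shape[1] - 1)
        recs.append(
            dict(
                id=k,
                area_um2=float(a * px_area_um2),
                centroid_row=float(cr),
                centroid_col=float(cc),
                inside_villi=bool(labels.labels[ir, ic] == LABEL_VILLI),
            )
        )
    return VesselInstances(seg.astype(np.int32), pd.DataFrame(recs), px_um)


def _empty_instances(labels: LabelMask) -> VesselInstances:
    empty = pd.DataFrame(
        columns=["id", "area_um2", "centroid_row", "centroid_col", "inside_villi"]
    )
    return VesselInstances(
        np.zeros(labels.shape, dtype=np.int32), empty, labels.pixel_size_um
    )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------


def qc_slide(
    labels: LabelMask,
    stain_field: np.ndarray,
    *,
    max_artifact_fraction: float = config.QC_MAX_ARTIFACT_FRACTION,
    min_median_villous_od: float = config.QC_MIN_MEDIAN_VILLOUS_OD,
) -> QCReport:
    """Flag slides with heavy artifact contamination or weak CD34 staining.

    The artifact fraction is taken from the classifier's pre-merge bookkeeping
    when available (artifacts merged into background would otherwise be
    invisible here); staining strength is the median AEC optical density over
    villous pixels.
    """
    lab = labels.labels
    villi = lab == LABEL_VILLI
    tissue = np.isin(lab, (LABEL_VILLI, LABEL_FIBRIN, LABEL_ARTIFACT))
    if labels.artifact_fraction_raw is not None:
        artifact_fraction = labels.artifact_fraction_raw
    else:
        n_t = int(tissue.sum())
        artifact_fraction = (
            int(np.count_nonzero(lab == LABEL_ARTIFACT)) / n_t if n_t else 0.0
        )
    med_od = float(np.median(np.asarray(stain_field)[villi])) if villi.any() else 0.0
    summary = {
        "median_villous_aec_od": med_od,
        "p90_villous_aec_od": float(np.percentile(np.asarray(stain_field)[villi], 90))
        if villi.any()
        else 0.0,
    }
    if artifact_fraction > max_artifact_fraction:
        return QCReport(artifact_fraction, summary, False,
                        f"artifact fraction {artifact_fraction:.3f} exceeds "
                        f"{max_artifact_fraction:.3f}")
    if med_od < min_median_villous_od:
        return QCReport(artifact_fraction, summary, False,
                        f"weak staining: median villous AEC OD {med_od:.4f} below "
                        f"{min_median_villous_od:.4f}")
    return QCReport(artifact_fraction, summary, True, "")
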