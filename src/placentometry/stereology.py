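"""Normalized structural metrics on whole sections and 1-mm circle probes.

Three dimensionless / area-normalized quantities make sections of different
size comparable:

* density of villi (%) = 100 * villi / (villi + fibrin + intervillous)
* vessel area (%)      = 100 * vessel pixels within villi / villi
* vessel count per mm² = instances whose centroid lies on villi / villous mm²

Excluded pixels are removed from every numerator and denominator.  Circle
probes ("regions") restrict every term to a 1-mm-diameter disc placed on
villous structures, emphasising peripheral villi.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from . import config
from .config import LABEL_BACKGROUND, LABEL_FIBRIN, LABEL_VILLI
from .errors import NoVillousTissueError, ValidationError
from .imaging import LabelMask, VesselInstances

__all__ = ["RegionSpec", "StereologyMetrics", "compute_metrics", "place_regions"]


@dataclass
class RegionSpec:
    """A circular probe in pixel coordinates."""

    center: tuple[float, float]  # (row, col)
    diameter_um: float = config.REGION_DIAMETER_UM

    def mask(self, shape: tuple[int, int], pixel_size_um: float) -> np.ndarray:
        r_px = 0.5 * self.diameter_um / pixel_size_um
        rr, cc = np.ogrid[: shape[0], : shape[1]]
        return (rr - self.center[0]) ** 2 + (cc - self.center[1]) ** 2 <= r_px**2


@dataclass
class StereologyMetrics:
    density_villi_pct: float
    vessel_area_pct: float
    vessel_count_per_mm2: float
    villous_area_mm2: float
    n_vessels: int
    scope: str = "whole_section"


def compute_metrics(
    labels: LabelMask,
    vessels: VesselInstances,
    region: RegionSpec | None = None,
) -> StereologyMetrics:
    """Evaluate the three normalized metrics in the given scope.

    Raises :class:`NoVillousTissueError` when the scope contains no villous
    pixels (the denominators would be undefined).
    """
    lab = labels.labels
    scope = np.ones(lab.shape, dtype=bool)
    if region is not None:
        scope = region.mask(lab.shape, labels.pixel_size_um)

    villi = (lab == LABEL_VILLI) & scope
    fibrin = (lab == LABEL_FIBRIN) & scope
    interv = (lab == LABEL_BACKGROUND) & scope

    n_villi = int(villi.sum())
    if n_villi == 0:
        raise NoVillousTissueError()
    denom = n_villi + int(fibrin.sum()) + int(interv.sum())
    density = 100.0 * n_villi / denom

    vessel_px = (vessels.instance_labels > 0) & villi
    vessel_area_pct = 100.0 * int(vessel_px.sum()) / n_villi

    px_um = labels.pixel_size_um
    villous_mm2 = n_villi * px_um**2 / 1e6
    recs = vessels.records
    if len(recs):
        inside = recs["inside_villi"].to_numpy(dtype=bool)
        if region is not None:
            ir = recs["centroid_row"].round().astype(int).clip(0, lab.shape[0] - 1)
            ic = recs["centroid_col"].round().astype(int).clip(0, lab.shape[1] - 1)
            inside = inside & scope[ir, ic]
        n_count = int(inside.sum())
    else:
        n_count = 0
    return StereologyMetrics(
        density_villi_pct=density,
        vessel_area_pct=vessel_area_pct,
        vessel_count_per_mm2=n_count / villous_mm2,
        villous_area_mm2=villous_mm2,
        n_vessels=n_count,
        scope="regions" if region is not None else "whole_section",
    )


def place_regions(
    labels: LabelMask,
    k: int = 3,
    diameter_um: float = config.REGION_DIAMETER_UM,
    seed: int = 0,
    *,
    min_villous_fraction: float = config.REGION_MIN_VILLOUS_FRACTION,
    stride_px: int | None = None,
) -> list[RegionSpec]:
    """Place up to ``k`` non-overlapping circles maximizing villous content.

    Candidate centers lie on a grid (stride defaulting to a quarter radius)
    with a seeded sub-stride offset; the villous fraction of every candidate
    circle is computed by convolution with a disc kernel, and circles are
    picked greedily by decreasing fraction (row, col as deterministic
    tie-break), skipping candidates that would overlap an accepted circle.
    Only circles meeting ``min_villous_fraction`` and lying fully inside the
    image are eligible.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    lab = labels.labels
    px_um = labels.pixel_size_um
    r_px = 0.5 * diameter_um / px_um
    h, w = lab.shape
    if 2 * r_px > min(h, w):
        raise ValidationError("image smaller than the probe circle")

    if stride_px is None:
        stride_px = max(1, int(round(r_px / 4)))
    rng = np.random.default_rng(seed)
    off_r = int(rng.integers(stride_px)) if stride_px > 1 else 0
    off_c = int(rng.integers(stride_px)) if stride_px > 1 else 0

    # villous pixel count under a disc centered at every pixel
    ry = np.arange(-int(np.ceil(r_px)), int(np.ceil(r_px)) + 1)
    kernel = (ry[:, None] ** 2 + ry[None, :] ** 2 <= r_px**2).astype(np.float32)
    counts = signal.fftconvolve((lab == LABEL_VILLI).astype(np.float32), kernel,
                                mode="same")
    frac = counts / kernel.sum()

    rmin = int(np.ceil(r_px))
    rows = np.arange(rmin + off_r, h - rmin, stride_px)
    cols = np.arange(rmin + off_c, w - rmin, stride_px)
    if len(rows) == 0 or len(cols) == 0:
        raise ValidationError("image smaller than the probe circle")
    cand_frac = frac[np.ix_(rows, cols)]
    order = np.argsort(
        np.rec.fromarrays(
            [-cand_frac.ravel(),
             np.repeat(rows, len(cols)),
             np.tile(cols, len(rows))],
            names=["negfrac", "r", "c"],
        ),
        order=("negfrac", "r", "c"),
    )

    chosen: list[RegionSpec] = []
    flat_rows = np.repeat(rows, len(cols))
    flat_cols = np.tile(cols, len(rows))
    flat_frac = cand_frac.ravel()
    for idx in order:
        f = flat_frac[idx]
        if f < min_villous_fraction - 1e-12:
            break
        r0, c0 = float(flat_rows[idx]), float(flat_cols[idx])
        if any((r0 - s.center[0]) ** 2 + (c0 - s.center[1]) ** 2 < (2 * r_px) ** 2
               for s in chosen):
            continue
        chosen.append(RegionSpec((r0, c0), diameter_um))
        if len(chosen) == k:
            break
    if not chosen:
        raise NoVillousTissueError("insufficient villous tissue")
    return chosen
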