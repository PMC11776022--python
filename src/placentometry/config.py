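"""Frozen numeric conventions shared by the slide generator and the imaging chain.

Everything the segmentation stage assumes about color is in one place so that
the generator (which renders stains forward through Beer-Lambert) and the
deconvolution (which inverts it) agree by construction.
"""

from __future__ import annotations

import numpy as np

# Optical-density unit vectors per stain (rows), Ruifrok-Johnston convention.
# Row 0: hematoxylin (nuclei, blue-purple); row 1: AEC (red chromogen marking
# CD34+ endothelium); row 2: residual axis completing the basis, onto which
# achromatic material (dirt, precipitate) projects strongly.
STAIN_MATRIX = np.array(
    [
        [0.650, 0.704, 0.286],
        [0.2743, 0.6796, 0.6803],
        [0.2845656, -0.3637452, 0.2486328],
    ]
)

#: Label codes used by every mask in the package.
LABEL_BACKGROUND = 0  # intervillous space / non-tissue
LABEL_VILLI = 1
LABEL_FIBRIN = 2
LABEL_ARTIFACT = 3
LABEL_EXCLUDED = 4

LABEL_NAMES = {
    LABEL_BACKGROUND: "background",
    LABEL_VILLI: "villi",
    LABEL_FIBRIN: "fibrin",
    LABEL_ARTIFACT: "artifact",
    LABEL_EXCLUDED: "excluded",
}

#: 8-bit intensity threshold separating tissue (strictly below) from
#: background, applied to the arithmetic mean of R, G, B rounded half-up.
TISSUE_INTENSITY_THRESHOLD = 210

# Mean stain concentrations (dimensionless OD multipliers) used when rendering
# each synthetic tissue class; the classifier thresholds below are fitted once
# against tiles rendered from these and then frozen.
RENDER_CONCENTRATIONS = {
    "villi": (0.55, 0.05),  # (hematoxylin, AEC)
    "vessel": (0.15, 0.90),
    "fibrin": (0.08, 0.18),
    "background": (0.005, 0.002),
}
#: Artifacts are rendered as achromatic speckles at this 8-bit gray level.
ARTIFACT_GRAY_LEVEL = 45
#: Multiplicative lognormal jitter (sigma of log) on rendered concentrations.
RENDER_CONCENTRATION_JITTER = 0.08

# Rule-based pixel classifier decision thresholds on the deconvolved
# (hematoxylin, AEC, residual) concentration channels.
CLASSIFIER_THRESHOLDS = {
    "residual_artifact": 0.15,  # achromatic-dark material
    "aec_villi": 0.40,  # strongly AEC-positive = vessel lumen/wall inside villi
    "hema_villi": 0.22,  # hematoxylin-rich stroma
    "aec_fibrin": 0.07,  # weakly eosinophilic pale-pink deposits
}
#: Half-width of the boxcar used to denoise channels before thresholding (px).
CLASSIFIER_SMOOTHING_PX = 3

# Vessel instance segmentation.
MIN_VESSEL_AREA_UM2 = 20.0  # lower bound on a capillary cross-section
#: Watershed seed separation, as a fraction of the smallest expected radius.
WATERSHED_SEED_SEPARATION_FACTOR = 0.5

# Slide-level quality control.
QC_MAX_ARTIFACT_FRACTION = 0.15
QC_MIN_MEDIAN_VILLOUS_OD = 0.02

# Region placement (circle probes of 1 mm diameter on villous structures).
REGION_DIAMETER_UM = 1000.0
REGION_MIN_VILLOUS_FRACTION = 0.30

# Freedson count cut-points (counts/min) and wear-time conventions.
SEDENTARY_MAX_COUNTS = 99  # sedentary: < 100 counts/min
LIGHT_MAX_COUNTS = 1951  # light: 100-1951; MVPA: > 1951
NONWEAR_ZERO_RUN_MIN = 60  # minutes of consecutive zeros flagged non-wear
VALID_DAY_WEAR_MIN = 600  # minimum wear minutes for a valid day
MIN_VALID_DAYS_PER_PERIOD = 3
MIN_VALID_PERIODS = 2

PERIODS = ("<20w", "24-28w", "35-37w")
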