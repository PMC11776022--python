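"""Imaging chain: tissue threshold, classification, deconvolution, vessels, QC."""

import numpy as np
import pytest

from placentometry import config
from placentometry.config import (LABEL_ARTIFACT, LABEL_BACKGROUND,
                                  LABEL_FIBRIN, LABEL_VILLI, STAIN_MATRIX)
from placentometry.errors import NoVillousTissueError, ValidationError
from placentometry.imaging import (LabelMask, SlideImage, apply_exclusions,
                                   classify_villous_tissue, deconvolve_stains,
                                   detect_tissue, extract_stain_channel,
                                   qc_slide, segment_vessels)
from placentometry.stereology import compute_metrics
from placentometry.synthetic_data import SlideParams, generate_slide


def render_pure(ch, ca, shape=(8, 8)):
    """Forward Beer-Lambert render of a uniform concentration patch."""
    od = ch * STAIN_MATRIX[0] + ca * STAIN_MATRIX[1]
    rgb = np.clip(np.round(255.0 * 10.0 ** (-od)), 0, 255).astype(np.uint8)
    return np.broadcast_to(rgb, shape + (3,)).copy()


# --- detect_tissue ---------------------------------------------------------


def test_white_image_has_no_tissue():
    img = SlideImage(np.full((16, 16, 3), 255, np.uint8), 1.0)
    assert not detect_tissue(img).any()


@pytest.mark.parametrize("gray,expected", [(209, True), (210, False)])
def test_intensity_threshold_boundary(gray, expected):
    img = SlideImage(np.full((4, 4, 3), gray, np.uint8), 1.0)
    assert detect_tissue(img).all() == expected


def test_tissue_mask_covers_stained_classes(default_slide):
    image, truth = default_slide
    tissue = detect_tissue(image)
    gt = truth.label_mask.labels
    stained = (gt == LABEL_VILLI) | (gt == LABEL_FIBRIN)
    assert tissue[stained].mean() >= 0.99


# --- exclusions ------------------------------------------------------------


def test_empty_polygon_list_is_identity(default_slide):
    _, truth = default_slide
    out = apply_exclusions(truth.label_mask, [])
    assert np.array_equal(out.labels, truth.label_mask.labels)


def test_full_image_exclusion_breaks_metrics(segmented_slide):
    _, _, labels, _, vessels = segmented_slide
    h, w = labels.shape
    poly = np.array([[0, 0], [0, w - 1], [h - 1, w - 1], [h - 1, 0]])
    out = apply_exclusions(labels, [poly])
    assert (out.labels == config.LABEL_EXCLUDED).all()
    with pytest.raises(NoVillousTissueError, match="no villous tissue"):
        compute_metrics(out, vessels)


def test_half_exclusion_removes_exactly_covered_villi(default_slide):
    _, truth = default_slide
    labels = truth.label_mask
    h, w = labels.shape
    poly = np.array([[0, 0], [0, w // 2 - 1], [h - 1, w // 2 - 1], [h - 1, 0]])
    out = apply_exclusions(labels, [poly])
    expected = int(np.count_nonzero(
        (labels.labels == LABEL_VILLI)[:, w // 2:]))
    assert int(np.count_nonzero(out.labels == LABEL_VILLI)) == expected


# --- classification --------------------------------------------------------


def test_classifier_accuracy_on_synthetic_slide(segmented_slide):
    _, truth, labels, _, _ = segmented_slide
    acc = np.mean(labels.labels == truth.label_mask.labels)
    assert acc >= 0.90


def test_intervillous_artifacts_merged_into_background():
    img, truth = generate_slide(SlideParams(seed=21, artifact_fraction=0.02))
    assert (truth.label_mask.labels == LABEL_ARTIFACT).any()
    labels = classify_villous_tissue(img)
    assert not (labels.labels == LABEL_ARTIFACT).any()
    assert labels.artifact_fraction_raw > 0


def test_blank_image_all_background():
    img = SlideImage(np.full((32, 32, 3), 255, np.uint8), 2.0)
    labels = classify_villous_tissue(img)
    assert (labels.labels == LABEL_BACKGROUND).all()


def test_rectangle_oracle_exact():
    """Axis-aligned rectangles of pure class colors classify exactly."""
    h = w = 60
    rgb = np.broadcast_to(render_pure(*config.RENDER_CONCENTRATIONS["background"],
                                      (1, 1))[0, 0], (h, w, 3)).copy()
    expected = np.full((h, w), LABEL_BACKGROUND, np.uint8)
    rgb[5:25, 5:25] = render_pure(*config.RENDER_CONCENTRATIONS["villi"], (20, 20))
    expected[5:25, 5:25] = LABEL_VILLI
    rgb[35:50, 10:30] = render_pure(*config.RENDER_CONCENTRATIONS["fibrin"], (15, 20))
    expected[35:50, 10:30] = LABEL_FIBRIN
    rgb[10:20, 40:52] = config.ARTIFACT_GRAY_LEVEL  # merged into background
    labels = classify_villous_tissue(SlideImage(rgb, 2.0))
    assert np.array_equal(labels.labels, expected)


# --- stain deconvolution ---------------------------------------------------


def test_white_pixel_zero_optical_density():
    img = SlideImage(np.full((4, 4, 3), 255, np.uint8), 1.0)
    assert np.allclose(extract_stain_channel(img), 0.0)


def test_deconvolution_matches_analytic_inversion():
    """Implementation equals a hand-written Beer-Lambert inversion to 1e-6,
    and recovers the rendered AEC concentration up to 8-bit quantization."""
    conc_true = 0.6
    img = SlideImage(render_pure(0.0, conc_true), 1.0)
    ours = deconvolve_stains(img)
    od = -np.log10(np.maximum(img.rgb.astype(float), 1.0) / 255.0)
    by_hand = np.linalg.solve(STAIN_MATRIX.T, od[0, 0])
    assert np.allclose(ours[0, 0], by_hand, atol=1e-6)
    assert abs(ours[0, 0, 1] - conc_true) < 0.01


def test_pure_hematoxylin_has_negligible_aec():
    img = SlideImage(render_pure(0.7, 0.0), 1.0)
    conc = deconvolve_stains(img)
    assert abs(conc[0, 0, 1]) <= 0.05 * conc[0, 0, 0]


def test_collinear_stain_matrix_rejected():
    bad = np.array([[0.65, 0.70, 0.29], [0.65, 0.70, 0.29], [0.0, 0.0, 1.0]])
    img = SlideImage(np.full((4, 4, 3), 200, np.uint8), 1.0)
    with pytest.raises(ValidationError):
        extract_stain_channel(img, bad)


# --- vessel segmentation ---------------------------------------------------


def _disc_field(shape, discs):
    """Stain field with value 1.0 on the union of (center, radius) discs."""
    field = np.zeros(shape)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    for (r0, c0), rad in discs:
        field[(rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2] = 1.0
    return field


def all_villi(shape, px=1.0):
    return LabelMask(np.full(shape, LABEL_VILLI, np.uint8), px)


def test_watershed_splits_two_touching_discs():
    # centers 1.9 radii apart: overlap of 10% of a radius
    field = _disc_field((64, 64), [((32, 20), 10.0), ((32, 39), 10.0)])
    v = segment_vessels(field, all_villi((64, 64)), stain_threshold=0.5,
                        min_radius_um=5.0)
    assert v.n_instances == 2


def test_annulus_lumen_is_filled():
    outer = _disc_field((48, 48), [((24, 24), 10.0)])
    lumen = _disc_field((48, 48), [((24, 24), 5.0)])
    annulus = outer - lumen
    v = segment_vessels(annulus, all_villi((48, 48)), stain_threshold=0.5)
    assert v.n_instances == 1
    assert v.records.area_um2.iloc[0] == pytest.approx(outer.sum(), abs=0.5)


def test_small_instances_filtered():
    field = _disc_field((32, 32), [((16, 16), 2.0)])  # ~13 um^2 < 20 um^2
    v = segment_vessels(field, all_villi((32, 32)), stain_threshold=0.5)
    assert v.n_instances == 0


def test_no_villous_tissue_raises():
    labels = LabelMask(np.zeros((16, 16), np.uint8), 1.0)
    with pytest.raises(NoVillousTissueError):
        segment_vessels(np.zeros((16, 16)), labels)


def test_detected_count_monotone_in_generated_density():
    counts = []
    for density in (300.0, 900.0, 1800.0):
        img, _ = generate_slide(SlideParams(width_px=384, height_px=384,
                                            vessel_density_per_mm2=density,
                                            seed=77))
        labels = classify_villous_tissue(img)
        v = segment_vessels(extract_stain_channel(img), labels)
        counts.append(v.n_instances)
    assert counts[0] < counts[1] < counts[2]


# --- QC --------------------------------------------------------------------


def test_clean_slide_passes_qc(segmented_slide):
    _, _, labels, stain, _ = segmented_slide
    assert qc_slide(labels, stain).passed


def test_heavy_artifacts_fail_qc():
    img, _ = generate_slide(SlideParams(seed=31, artifact_fraction=0.30))
    labels = classify_villous_tissue(img)
    rep = qc_slide(labels, extract_stain_channel(img))
    assert not rep.passed
    assert "artifact fraction" in rep.reason


def test_weak_staining_fails_qc():
    img, truth = generate_slide(SlideParams(seed=32, stain_intensity=0.10,
                                            artifact_fraction=0.0))
    # evaluate staining over the true villous mask: weak stain is no longer
    # detected as tissue at all, which is exactly the failure mode
    labels = classify_villous_tissue(img)
    stain = extract_stain_channel(img)
    rep = qc_slide(labels, stain)
    assert not rep.passed
    assert "staining" in rep.reason


def test_label_partition_conservation(segmented_slide):
    _, _, labels, _, _ = segmented_slide
    counts = labels.class_counts()
    assert sum(counts.values()) == labels.shape[0] * labels.shape[1]


def test_vessel_centroid_containment(segmented_slide):
    _, _, labels, _, vessels = segmented_slide
    recs = vessels.records[vessels.records.inside_villi]
    ir = recs.centroid_row.round().astype(int)
    ic = recs.centroid_col.round().astype(int)
    assert (labels.labels[ir, ic] == LABEL_VILLI).all()
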