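import numpy as np
import pytest

from placentometry.imaging import (classify_villous_tissue,
                                   extract_stain_channel, segment_vessels)
from placentometry.synthetic_data import SlideParams, generate_slide


@pytest.fixture(scope="session")
def default_slide():
    """One 512x512 slide at the generator defaults, with its ground truth."""
    return generate_slide(SlideParams(seed=11))


@pytest.fixture(scope="session")
def segmented_slide(default_slide):
    """The default slide pushed through the full imaging chain."""
    image, truth = default_slide
    labels = classify_villous_tissue(image)
    stain = extract_stain_channel(image)
    vessels = segment_vessels(stain, labels)
    return image, truth, labels, stain, vessels
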