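import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from osteomix.raster_core import BinaryMask, Channel, ChannelImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_image(pixels, channel=Channel.MOB_CYAN, px=1.0):
    return ChannelImage(np.asarray(pixels), channel, px)


def make_mask(bits, channel=Channel.MOB_CYAN, px=1.0):
    return BinaryMask(np.asarray(bits, dtype=bool), channel, px)


@pytest.fixture
def two_blob_masks():
    """Two well-separated single-color square blobs on a 40x40 grid."""
    cyan = np.zeros((40, 40), dtype=bool)
    red = np.zeros((40, 40), dtype=bool)
    cyan[5:10, 5:10] = True
    red[30:35, 30:35] = True
    return make_mask(cyan, Channel.MOB_CYAN), make_mask(red, Channel.MOC_RED)
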