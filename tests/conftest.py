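import numpy as np
import pytest

from vlstitch.fragment_io import RasterTile, fragment_from_array
from vlstitch.matting import choose_mask_factor, compute_alpha_mask, dilate_mask
from vlstitch.fragment_io import make_thumbnail
from vlstitch.synth import default_section_spec, generate_section


@pytest.fixture(scope="session")
def section():
    """The stock synthetic section: image, annotations, analytic truth."""
    spec = default_section_spec(seed=1)
    image, annotations, truth = generate_section(spec)
    return spec, image, annotations, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tile_of(arr) -> RasterTile:
    return RasterTile(origin=(0, 0), pixels=np.asarray(arr, dtype=np.uint8))


def render_masks(fragments, dilate_px=1):
    """Matting masks for a fragment list at an adequate scale."""
    masks = {}
    for f in fragments:
        mf = choose_mask_factor(f.width_l0, f.height_l0)
        m = compute_alpha_mask(make_thumbnail(f, mf), factor=mf)
        masks[f.fragment_id] = dilate_mask(m, px=dilate_px)
    return masks
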