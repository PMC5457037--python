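import numpy as np
import pytest

from biofilmquant.image_io import FieldImage
from biofilmquant.synthetic_imaging import SyntheticFieldSpec, generate_field


def make_field(arr, bit_depth=8, tile_index=0, pixel_scale_um=0.486):
    """Wrap a plain integer grid as a FieldImage (geometry kept consistent)."""
    arr = np.asarray(arr)
    rows, cols = arr.shape
    return FieldImage(
        pixels=arr.astype(np.uint8 if bit_depth == 8 else np.uint16),
        bit_depth=bit_depth,
        tile_index=tile_index,
        field_width_mm=cols * pixel_scale_um * 1e-3,
        field_height_mm=rows * pixel_scale_um * 1e-3,
        pixel_scale_um=pixel_scale_um,
    )


@pytest.fixture(scope="session")
def small_spec():
    """Small, fast synthetic field: 120x160 px, 2% coverage."""
    return SyntheticFieldSpec(raster=(120, 160), target_coverage_pct=2.0, seed=7)


@pytest.fixture(scope="session")
def small_field(small_spec):
    field, cell_mask, artefact_mask = generate_field(small_spec)
    return field, cell_mask, artefact_mask
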