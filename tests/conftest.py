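import numpy as np
import pytest
from skimage import measure
from skimage.draw import disk as draw_disk

import mechanoquant as mq


@pytest.fixture(scope="session")
def organoid_fixture():
    """One rendered organoid (mild noise) with its ground truth."""
    spec = mq.SyntheticOrganoidSpec(seed=1, noise_sd=2.0)
    img, gt = mq.gen_organoid_image(spec)
    return spec, img, gt


@pytest.fixture(scope="session")
def segmented_organoid(organoid_fixture):
    """Full segmentation chain run once on the shared organoid."""
    spec, img, gt = organoid_fixture
    org = mq.segment_organoid(img)[0]
    nuclei = mq.detect_nuclei(img["DAPI"], org)
    cells = mq.segment_cells(nuclei, img, org)
    return spec, img, gt, org, cells


@pytest.fixture(scope="session")
def disk_organoid():
    """Factory fixture: OrganoidMask for an exact disk."""
    return circular_organoid_mask


def circular_organoid_mask(shape, center, radius_px, pixel_size_um=1.0):
    """An OrganoidMask for an exact disk (helper for geometry tests)."""
    mask = np.zeros(shape, bool)
    rr, cc = draw_disk(center, radius_px, shape=shape)
    mask[rr, cc] = True
    contour = measure.find_contours(mask.astype(float), 0.5)[0]
    return mq.OrganoidMask(
        mask=mask,
        contour=contour,
        centroid=center,
        equivalent_radius_um=radius_px * pixel_size_um,
        pixel_size_um=pixel_size_um,
    )
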