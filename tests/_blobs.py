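"""Random connected blob masks for perimeter/hull property tests."""

import numpy as np
from scipy import ndimage as ndi


def random_blob_mask(seed, shape=(160, 160)):
    rng = np.random.default_rng(seed)
    field = ndi.gaussian_filter(rng.normal(size=shape), 8.0)
    mask = field > np.percentile(field, 70)
    labels, n = ndi.label(mask)
    if n == 0:
        return random_blob_mask(seed + 1000, shape)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    out = labels == counts.argmax()
    return out if out.sum() > 200 else random_blob_mask(seed + 1000, shape)
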