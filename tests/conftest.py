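import numpy as np
import pytest

from greenspot.preprocess import Blob


def blob_from_mask(mask: np.ndarray, offset=(0, 0)) -> Blob:
    """Wrap a boolean mask as a Blob, cropped to its bounding box."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    top, left = rows.min(), cols.min()
    bottom, right = rows.max() + 1, cols.max() + 1
    return Blob(mask=mask[top:bottom, left:right],
                bbox=(top + offset[0], left + offset[1],
                      bottom + offset[0], right + offset[1]))


def raster_disc(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def random_blob(rng: np.random.Generator) -> Blob:
    """Union of a few random rectangles and discs, for oracle comparisons."""
    size = int(rng.integers(20, 60))
    mask = np.zeros((size, size), dtype=bool)
    for _ in range(int(rng.integers(2, 6))):
        if rng.random() < 0.5:
            r0, c0 = rng.integers(0, size - 5, 2)
            h, w = rng.integers(3, 12, 2)
            mask[r0:r0 + h, c0:c0 + w] = True
        else:
            cy, cx = rng.integers(5, size - 5, 2)
            rad = int(rng.integers(2, 8))
            yy, xx = np.mgrid[:size, :size]
            mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= rad**2
    # keep the largest connected piece so it is a single blob
    from skimage.measure import label

    lab = label(mask, connectivity=2)
    if lab.max() == 0:
        mask[size // 2, size // 2] = True
        return blob_from_mask(mask)
    largest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
    return blob_from_mask(lab == largest)


@pytest.fixture(scope="session")
def small_dataset():
    """Six images per class, shared across tests that only read them."""
    from greenspot.synthgen import gen_dataset

    records, manifest = gen_dataset(6, seed=0)
    return records, manifest
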