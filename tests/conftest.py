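import numpy as np
import pytest

from blotkin import ArrayLayout, KineticConstants, get_layout


@pytest.fixture(scope="session")
def generic_layout():
    """Shipped 8x10 layout with reference spots in all four corners."""
    return get_layout("generic_8x10")


@pytest.fixture(scope="session")
def small_layout():
    """Small 4x5 grid for fast image-level tests."""
    return ArrayLayout(
        name="test-4x5", n_rows=4, n_cols=5, spot_box=20,
        reference_spots=((0, 0), (3, 0), (0, 4)),
        analytes={(1, 1): "A", (1, 2): "A", (2, 2): "B"},
    )


@pytest.fixture(scope="session")
def constants():
    return KineticConstants()


def gaussian_spot(shape, center, sigma, amplitude):
    """Render one isotropic Gaussian spot on a zero frame."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return amplitude * np.exp(-r2 / (2.0 * sigma ** 2))


def aligned_reference_centroid_errors(aligned, layout):
    """Background-subtracted intensity centroid of each reference-spot box
    vs its canonical center, on the mean of the first half of the frames
    (where fast reference spots are strongest).  Pixel units."""
    sb = layout.spot_box
    frame = aligned.frames[:max(1, aligned.n_frames // 2)].mean(axis=0)
    frame = frame - np.median(frame)
    errs = []
    for (r, c) in layout.alignment_reference_spots():
        box = np.clip(frame[r * sb:(r + 1) * sb, c * sb:(c + 1) * sb], 0,
                      None)
        if box.sum() <= 0:
            errs.append(np.nan)
            continue
        yy, xx = np.mgrid[0:sb, 0:sb]
        cy = (box * yy).sum() / box.sum() + r * sb
        cx = (box * xx).sum() / box.sum() + c * sb
        tr, tc = layout.spot_center((r, c))
        errs.append(float(np.hypot(cy - tr, cx - tc)))
    return np.array(errs)
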