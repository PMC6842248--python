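import numpy as np
import pytest

from mycoscreen import morphology, synthetic


@pytest.fixture(scope="session")
def culture_image():
    """One rendered culture image with its layout and ground truth."""
    spec = synthetic.example_image_spec(seed=11)
    image, truth = synthetic.render_culture_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def shape_suite():
    """>= 100 structures of varied size, elongation and roughness.

    Rendered across several images so pellets (smooth and rough ellipses of
    different aspect ratios) and dispersed fragments (elongated blobs down to
    the 95 µm² window) are all represented.
    """
    metrics = []
    for seed in range(4):
        spec = synthetic.example_image_spec(
            seed=20 + seed, n_pellets=10, n_fragments=16, image_px=1500
        )
        image, _ = synthetic.render_culture_image(spec)
        metrics.extend(morphology.measure_structures(image, spec.pixel_size_um))
    assert len(metrics) >= 100
    return metrics


def brute_force_feret(pixels: np.ndarray, pixel_size_um: float, n_angles: int = 3600):
    """Projection oracle: caliper widths over n_angles directions.

    Projects every pixel-corner point onto each direction; the max/min of the
    projected widths over the angle sweep brackets the Feret diameters
    independently of any hull construction.
    """
    base = np.asarray(pixels, dtype=float)
    corners = np.concatenate(
        [base + off for off in ((0, 0), (0, 1), (1, 0), (1, 1))]
    ) * pixel_size_um
    angles = np.linspace(0.0, np.pi, n_angles, endpoint=False)
    directions = np.column_stack([np.cos(angles), np.sin(angles)])
    proj = corners @ directions.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    return float(widths.max()), float(widths.min())
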