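from dataclasses import replace

import numpy as np
import pytest

from calnet.params import GeneratorParams, get_preset


@pytest.fixture
def small_params() -> GeneratorParams:
    """A fast, small culture: 60 ROIs, 2 min, bursting."""
    return replace(
        get_preset("WT-STR"),
        n_rois=60,
        frac_glia=0.1,
        frac_active=0.5,
        duration=120.0,
        mean_ibi=15.0,
        burst_participation=0.6,
        independent_rate=0.05,
        n_modules=2,
        seed=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def make_disk_movie(centers, image_size=(400, 400), radius=5, n_frames=30,
                    brightness=500.0, seed=0, extra_pixels=None):
    """Movie with bright disks in the dim zone of a vignette illumination
    field (the regime the percentile-normalizing ROI detector expects)."""
    import numpy as np

    from calnet.synthetic import render_movie, vignette_field

    dy, dx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    disk = np.argwhere(dy**2 + dx**2 <= radius**2) - radius
    layout = [disk + c for c in centers]
    if extra_pixels is not None:
        layout.append(extra_pixels)
    traces = np.full((len(layout), n_frames), brightness)
    field = vignette_field(image_size)
    return render_movie(traces, layout, image_size, seed=seed,
                        background=field, pixel_noise_sd=1.0), layout
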