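import numpy as np
import pytest

from endoseg import synth

# "clean" acquisition: strong border/interior contrast, no noise, mild blur
CLEAN_OVERRIDES = dict(
    noise_sigma=0.0,
    illumination_amplitude=10.0,
    blur_sigma=1.0,
    border_intensity=80.0,
    interior_intensity=150.0,
)


def clean_spec(seed: int, **extra) -> synth.SyntheticSpec:
    return synth.SyntheticSpec(seed=seed, **{**CLEAN_OVERRIDES, **extra})


@pytest.fixture(scope="session")
def clean_fixture():
    """One clean mosaic: (spec, truth, rendered image)."""
    spec = clean_spec(seed=1)
    truth = synth.generate_mosaic(spec)
    img = synth.render_specular(truth, spec)
    return spec, truth, img


@pytest.fixture(scope="session")
def clean_batch():
    """Three clean mosaics for count/quality statistics."""
    out = []
    for seed in (1, 2, 3):
        spec = clean_spec(seed=seed)
        truth = synth.generate_mosaic(spec)
        out.append((spec, truth, synth.render_specular(truth, spec)))
    return out


@pytest.fixture(scope="session")
def six_cell_fixture():
    """A tiny mosaic with very few cells for count sanity checks."""
    spec = clean_spec(seed=0, width=96, height=96, mean_cell_area=1500.0, jitter=0.2)
    truth = synth.generate_mosaic(spec)
    img = synth.render_specular(truth, spec)
    return spec, truth, img


def random_contour_map(rng: np.random.Generator, shape=(64, 64), density=0.05):
    """Seeded random nonempty binary contour map."""
    m = rng.random(shape) < density
    if not m.any():
        m[tuple(rng.integers(0, s) for s in shape)] = True
    return m
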