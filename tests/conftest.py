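import numpy as np
import pytest

from gestaliver import phantoms, segmentation

#: fast phantom geometry shared by unit tests (96x96x12 @ 2x2x6 mm)
SMALL_GEOMETRY = dict(
    shape=(96, 96, 12),
    spacing=(2.0, 2.0, 6.0),
    body_radii_mm=(85.0, 68.0),
    vat_blob_count=8,
    vat_blob_radius_mm=(6.0, 12.0),
)


def small_spec(**overrides) -> phantoms.PhantomSpec:
    params = dict(SMALL_GEOMETRY)
    params.update(overrides)
    return phantoms.PhantomSpec(**params)


@pytest.fixture(scope="session")
def clean_small_phantom():
    """Noise-free, bias-free small phantom."""
    return phantoms.make_abdomen_phantom(small_spec(seed=2))


@pytest.fixture(scope="session")
def plain_small_phantom():
    """Noise-free small phantom without the bright liver/uterus regions."""
    return phantoms.make_abdomen_phantom(
        small_spec(include_liver=False, include_uterus=False, seed=2)
    )


@pytest.fixture(scope="session")
def noisy_small_phantom():
    """SNR-10, 30%-bias small phantom."""
    return phantoms.make_abdomen_phantom(small_spec(noise_sd=20.0, bias_amplitude=0.30, seed=3))


@pytest.fixture(scope="session")
def acceptance_phantom():
    """The acceptance-scale phantom: 160x160x30, SNR 10, 30% bias."""
    return phantoms.make_abdomen_phantom(
        phantoms.PhantomSpec(noise_sd=20.0, bias_amplitude=0.30, seed=17)
    )


@pytest.fixture(scope="session")
def acceptance_pipeline(acceptance_phantom):
    """End-to-end pipeline result on the acceptance phantom (run once)."""
    ph = acceptance_phantom
    seeds = phantoms.make_seed_labels(ph.truth, np.linspace(2, 27, 11).astype(int))
    return segmentation.run_pipeline(ph.image, seeds, ph.exclusion.uterus, ph.exclusion.liver)
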