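import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, database=None, deadline=None)
settings.load_profile("repro")

from vertfract import phantom
from vertfract.interface import PipelineConfig, build_dataset, stage_seed


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_case():
    """One noisy phantom with two fractured levels."""
    spec = phantom.PhantomSpec(fracture_levels=frozenset({1, 3}), seed=7)
    return phantom.generate_case(spec)


@pytest.fixture(scope="session")
def clean_case():
    """Noise-, bias- and jitter-free phantom with one fractured level; every
    truth shape is convex, so hull regularization is lossless."""
    spec = phantom.PhantomSpec(fracture_levels=frozenset({2}),
                               noise_sd=0.0, bias_amplitude=0.0,
                               boundary_irregularity=0.0, seed=3)
    return phantom.generate_case(spec)


@pytest.fixture(scope="session")
def cohort():
    """The desk-scale study cohort: 63 cases x 5 VBs under the default
    phantom conditions, segmented and featurized once per session.

    Returns (dataset, per-VB dice scores)."""
    config = PipelineConfig(seed=0)
    spec = phantom.PhantomSpec(
        height_loss_fraction=config.height_loss_fraction,
        noise_sd=config.noise_sd,
        bias_amplitude=config.bias_amplitude,
    )
    cases, _ = phantom.generate_dataset(
        spec, n_cases=config.n_cases,
        fracture_prevalence=config.fracture_prevalence,
        seed=stage_seed(config.seed, "phantom"))
    dataset, dices = build_dataset(cases, config)
    return dataset, dices


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    n = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[0:n, 0:n]
    c = radius + pad
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def random_mask(rng, shape, p=0.4) -> np.ndarray:
    return rng.random(shape) < p
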