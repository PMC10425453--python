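import numpy as np
import pytest

import samdenoise as sd

# Benchmark condition: default phantom, noise at 10% and 15% of the clean
# peak, fixed noise seeds.  Session-scoped because the full evaluation runs
# the volumetric denoiser, which dominates suite runtime.


@pytest.fixture(scope="session")
def bench_spec():
    return sd.default_benchmark_spec()


@pytest.fixture(scope="session")
def clean_volume(bench_spec):
    return sd.simulate_clean_volume(bench_spec)


@pytest.fixture(scope="session")
def clean_amplitude(clean_volume):
    return sd.amplitude_image(clean_volume).values


@pytest.fixture(scope="session")
def noisy10(clean_volume):
    return sd.add_gaussian_noise(clean_volume, sd.NoiseModel(10.0), seed=42)


@pytest.fixture(scope="session")
def noisy15(clean_volume):
    return sd.add_gaussian_noise(clean_volume, sd.NoiseModel(15.0), seed=43)


@pytest.fixture(scope="session")
def report10(clean_volume, noisy10):
    cfg = sd.EvalConfig(bm4d=sd.BM4DParams(sigma=10.0))
    return sd.evaluate_filters(clean_volume, noisy10, cfg).as_dict()


@pytest.fixture(scope="session")
def report15(clean_volume, noisy15):
    cfg = sd.EvalConfig(bm4d=sd.BM4DParams(sigma=15.0))
    return sd.evaluate_filters(clean_volume, noisy15, cfg).as_dict()


@pytest.fixture
def small_spec():
    # small raster for fast unit tests; echo band still well inside the trace
    return sd.PhantomSpec(nx=20, ny=20, nt=48, seed=1)
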