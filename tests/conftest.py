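import numpy as np
import pytest

from ftirseed.preprocess import average_replicates, baseline_correct
from ftirseed.synth import GeneratorConfig, Spectrum, WavenumberGrid, generate_dataset, generate_spectrum


@pytest.fixture(scope="session")
def gen_config() -> GeneratorConfig:
    return GeneratorConfig()


@pytest.fixture(scope="session")
def small_dataset(gen_config):
    """Tiny benchmark: 2 specimens per (class x batch x split), 3 replicates."""
    return generate_dataset(gen_config, n_per_cell=2, seed=11)


@pytest.fixture(scope="session")
def specimen_spectrum(gen_config) -> Spectrum:
    """One baseline-corrected replicate-averaged class-1 spectrum."""
    reps = [generate_spectrum(gen_config, 1, "jinhua", 0, r) for r in (1, 2, 3)]
    return baseline_correct(average_replicates(reps))


def make_flat_spectrum(values, **meta) -> Spectrum:
    """Wrap a raw vector in a Spectrum on a matching synthetic grid."""
    values = np.asarray(values, dtype=float)
    grid = WavenumberGrid(start=float(2 * (values.size - 1)), stop=0.0, step=2.0)
    defaults = dict(class_id=1, batch_id="jinhua", specimen_id=0, replicate_id=1)
    defaults.update(meta)
    return Spectrum(grid=grid, absorbance=values, **defaults)
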