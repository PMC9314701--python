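import numpy as np
import pytest

from hssd import (
    HssdModel,
    ModelSpec,
    PosteriorSamples,
    SamplerConfig,
    SyntheticConfig,
    generate,
    preprocess_records,
)


@pytest.fixture(scope="session")
def paper_scale_data():
    """Synthetic dataset at the compiled-NMP-data regime (~30 obs, 15 refs)."""
    records, truth = generate(SyntheticConfig(seed=42))
    return preprocess_records(records), truth


@pytest.fixture(scope="session")
def fitted_size_media(paper_scale_data):
    """size+media model fitted with the fast profile (shared, read-only)."""
    data, _ = paper_scale_data
    model = HssdModel(data, ModelSpec.from_label("size+media"))
    return model.fit(SamplerConfig.fast(seed=7))


def make_samples(spec: ModelSpec, draws: dict, r: np.ndarray) -> PosteriorSamples:
    """Assemble a PosteriorSamples by hand (e.g. a single plug-in draw).

    ``draws`` maps parameter name -> (n_chains, n_kept) array; ``r`` has shape
    (n_chains, n_kept, n_refs).
    """
    config = SamplerConfig(
        n_chains=r.shape[0], n_burnin=0,
        n_draws=r.shape[1], thin=1, seed=0,
    )
    return PosteriorSamples(
        params={k: np.asarray(v, dtype=float) for k, v in draws.items()},
        r=np.asarray(r, dtype=float),
        spec=spec,
        config=config,
        rhat={},
    )
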