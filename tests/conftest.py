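import warnings

import pytest

import figground as fg

# per-sRF speed normalization can be degenerate when pursuit nulls a region;
# irrelevant noise for suite output
warnings.filterwarnings("ignore", message="degenerate speed range")


@pytest.fixture(scope="session")
def default_params():
    return fg.SceneGenParams()


@pytest.fixture(scope="session")
def small_dataset():
    """A handful of default scenes for cheap structural tests."""
    bundles, manifest = fg.generate_dataset(6, fg.SceneGenParams(), seed=101)
    return bundles, manifest


@pytest.fixture(scope="session")
def default_run():
    """Full study-scale run: 30 scenes, 200 sRFs per diameter, pursuit on.

    Shared across the sampler-invariant and sign-reproduction checks.
    """
    params = fg.SceneGenParams()
    bundles, _ = fg.generate_dataset(30, params, seed=11)
    samples, provenance = fg.build_srf_set(bundles, n_per_size=200, seed=12)
    diff = fg.srf_differences(bundles, samples)
    return {
        "params": params,
        "bundles": bundles,
        "samples": samples,
        "provenance": provenance,
        "differences": diff,
    }
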