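import pytest

import autospill as a


@pytest.fixture(scope="session")
def clean_small_panel():
    """Noise-free 4x4 panel without autofluorescence, debris or scatter use."""
    spec = a.SyntheticPanelSpec(
        n_dyes=4,
        n_detectors=4,
        autofluorescence=False,
        debris_fraction=0.0,
        shot_noise=0.0,
        noise_floor=0.0,
        n_events=3000,
        seed=7,
    )
    return a.generate_panel(spec)


@pytest.fixture(scope="session")
def noisy_small_panel():
    """Heteroskedastic 4-dye panel with autofluorescence on a free channel."""
    spec = a.SyntheticPanelSpec(
        n_dyes=4, n_detectors=5, debris_fraction=0.0, n_events=8000, seed=19
    )
    return a.generate_panel(spec)


@pytest.fixture(scope="session")
def standard_panel():
    """The standard condition: 7 dyes + AF on 8 detectors, 20k events, debris."""
    return a.generate_panel(a.SyntheticPanelSpec(seed=11))


@pytest.fixture(scope="session")
def standard_fit(standard_panel):
    model = a.SpilloverModel(standard_panel.controls, autofluorescence=True)
    return model.fit()
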