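import numpy as np
import pandas as pd
import pytest

from vibrotact.thresholds import default_model


@pytest.fixture(scope="session")
def model():
    return default_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_spectrum(rng, n_fft=32768, fs=10_000.0):
    """Smooth random dB spectrum on an FFT bin grid: a handful of
    Gaussian bumps in log-frequency over a sub-threshold noise floor."""
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    logf = np.log10(np.maximum(freqs, 1e-6))
    db = np.full_like(freqs, -60.0)
    for _ in range(rng.integers(2, 5)):
        center = rng.uniform(np.log10(1.0), np.log10(700.0))
        width = rng.uniform(0.1, 0.6)
        height = rng.uniform(20.0, 55.0)
        db = np.maximum(db, height * np.exp(-0.5 * ((logf - center) / width) ** 2) - 10.0)
    return freqs, db


@pytest.fixture(scope="session")
def planted_panel():
    """Two subject clusters with sign-flipped loadings, planted factor scores."""
    from vibrotact.simulate import PanelSpec, simulate_panel

    g = pd.DataFrame(
        np.random.default_rng(7).normal(0, 1.5, size=(8, 2)),
        index=[f"sample{i+1}" for i in range(8)],
    )
    panel, membership = simulate_panel(PanelSpec(noise_sd=0.5), g, seed=7)
    return panel, membership, g
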