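import numpy as np
import pytest

from neotheta.containers import EpochSet, GroupTFR


@pytest.fixture
def rng():
    return np.random.default_rng(20240705)


def epochs_with_sds(sds, n_samples=640, fs=500.0, condition="french"):
    """Single-channel epochs whose pooled SDs are exactly ``sds``.

    Each epoch alternates ±c, giving zero mean and SD exactly c.
    """
    data = np.stack([
        c * np.tile([1.0, -1.0], n_samples // 2)[None, :] for c in sds
    ])
    return EpochSet(data, fs, ["CZ"], np.array([condition] * len(sds),
                                               dtype=object), 400.0)


def toy_group(rng, n=8, n_freqs=6, n_times=40, effect=0.0,
              effect_loc=(2, slice(10, 25)), noise=1.0, fs_times=10.0):
    """Small two-condition group stack with an optional planted effect."""
    a = rng.normal(scale=noise, size=(n, n_freqs, n_times))
    b = rng.normal(scale=noise, size=(n, n_freqs, n_times))
    if effect:
        a[:, effect_loc[0], effect_loc[1]] += effect
    return GroupTFR({"french": a, "english": b}, ("french", "english"),
                    [f"P{i}" for i in range(n)],
                    np.arange(1.0, n_freqs + 1),
                    np.arange(n_times) * fs_times)
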