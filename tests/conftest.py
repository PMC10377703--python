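import numpy as np
import pytest

import fluoseries as fs


def series_arrays(series):
    """Unpack generate_series output into (images, masks, groups)."""
    images = [s[0] for s in series]
    masks = [fs.RoiMask(s[1].section_mask()) for s in series]
    groups = [s[2]["group_id"] for s in series]
    return images, masks, groups


def make_null_series(seed, n_internodes=2, size=64, internode_sd=0.0):
    """4-group null series (no group effect) of small phantom sections."""
    cfg = fs.small_phantom_config(size)
    scfg = fs.SeriesConfig(
        groups=("g1", "g2", "g3", "g4"),
        internodes_per_group=n_internodes,
        sections_per_internode=2,
        internode_sd=internode_sd,
        seed=seed,
    )
    return series_arrays(fs.generate_series(scfg, cfg))


def make_effect_series(seed, factor=1.5, n_internodes=2, size=64):
    """Series with a sheath visible-channel multiplier on the first group."""
    cfg = fs.small_phantom_config(size)
    scfg = fs.SeriesConfig(
        groups=("g1", "g2", "g3", "g4"),
        internodes_per_group=n_internodes,
        sections_per_internode=2,
        group_multipliers={"g1": fs.sheath_effect_multipliers(factor)},
        internode_sd=0.0,
        seed=seed,
    )
    return series_arrays(fs.generate_series(scfg, cfg))


@pytest.fixture(scope="session")
def small_series():
    """Six seeded 64×64 phantom sections with ground-truth masks."""
    cfg = fs.small_phantom_config(64)
    scfg = fs.SeriesConfig(
        groups=("a", "b"),
        internodes_per_group=3,
        sections_per_internode=1,
        internode_sd=0.1,
        seed=42,
    )
    return series_arrays(fs.generate_series(scfg, cfg))


@pytest.fixture(scope="session")
def fitted_model(small_series):
    images, masks, _ = small_series
    stats = [fs.accumulate_local_stats(i, m) for i, m in zip(images, masks)]
    return fs.fit_large_pca(stats)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
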