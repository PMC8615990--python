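import numpy as np
import pytest

import erpdecode as ed


def small_config(**kw):
    """Desk-scale StudyConfig with paper-like timing but few channels/trials."""
    defaults = dict(n_subjects=4, n_trials_per_condition=16, n_channels=8,
                    seed=5)
    defaults.update(kw)
    return ed.StudyConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_head():
    return ed.build_toy_headmodel(n_channels=8, n_sources=6, seed=5)


@pytest.fixture(scope="session")
def null_study(tiny_head):
    """Zero-effect study: conditions are exchangeable by construction."""
    cfg = small_config(effects=[])
    return ed.simulate_study(cfg, tiny_head)


@pytest.fixture(scope="session")
def null_epochs(null_study):
    return ed.preprocess_study(null_study, min_epochs=1)


@pytest.fixture(scope="session")
def effect_study():
    """Default two-effect study at desk scale (12 channels, 6 subjects)."""
    head = ed.build_toy_headmodel(n_channels=12, n_sources=8, seed=9)
    cfg = ed.StudyConfig(n_subjects=6, n_trials_per_condition=40,
                         n_channels=12, seed=9)
    return ed.simulate_study(cfg, head), head


@pytest.fixture(scope="session")
def effect_epochs(effect_study):
    study, _ = effect_study
    return ed.preprocess_study(study, min_epochs=30)


def make_epochs(data, sfreq=250.0, tmin_ms=-1500.0, labels=None,
                subjects=None):
    """Build an EpochSet directly from an array (test helper)."""
    n, c, s = data.shape
    times = tmin_ms + np.arange(s) * 1000.0 / sfreq
    return ed.EpochSet(
        data=data,
        times_ms=times,
        labels=np.asarray(labels if labels is not None else
                          [1, -1] * (n // 2) + [1] * (n % 2)),
        subject_ids=np.asarray(subjects if subjects is not None
                               else ["S00"] * n),
        sfreq_hz=sfreq,
        ch_names=[f"E{i+1}" for i in range(c)],
    )
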