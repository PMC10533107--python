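import numpy as np
import pytest

from painmon.descriptors import WindowSet
from painmon.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Four subjects, 3 phasic reps, full protocol otherwise — seconds to build."""
    cfg = GeneratorConfig(n_subjects=4, phasic_reps=3, seed=7)
    recordings, assignment = generate_cohort(cfg)
    return cfg, recordings, assignment


@pytest.fixture(scope="session")
def small_windows(small_cohort):
    from painmon.descriptors import featurize_cohort

    _, recordings, _ = small_cohort
    return featurize_cohort(recordings)


def make_window_set(codes, n_feature_cols=2, subject="S001"):
    """WindowSet with the given per-window label codes and dummy features."""
    codes = np.asarray(codes, dtype=np.int64)
    n = codes.shape[0]
    rng = np.random.default_rng(0)
    return WindowSet(
        subject_ids=np.full(n, subject, dtype=object),
        t_end=np.arange(10, 10 + n, dtype=np.int64),
        label_codes=codes,
        features={"eda": rng.standard_normal((n, 10, n_feature_cols)),
                  "facial": rng.standard_normal((n, 10, n_feature_cols))},
    )
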