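import numpy as np
import pytest

from shortcutaudit import CohortSpec, ShortcutSpec, SignalSpec, generate_cohort


@pytest.fixture(scope="session")
def tiny_spec():
    """A small, fast cohort: 2 groups, deterministic shortcut, crisp signal."""
    return CohortSpec(
        n_subjects=80,
        images_per_subject=1,
        image_shape=(32, 32),
        group_names=("g0", "g1"),
        group_proportions=(0.5, 0.5),
        label_names=("spot",),
        prevalence_per_group=((0.3,), (0.7,)),
        shortcut=ShortcutSpec(kind="corner_token", strength=0.4, token_size=5, margin=2,
                              leak_rate=1.0),
        disease_signal=SignalSpec(contrast=0.3, contrast_sd=0.0, mimic_contrast=0.0, visibility=1.0),
        noise_sigma=0.05,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
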