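import numpy as np
import pytest

from ldflim import (
    FLF_GATE,
    UNFILTERED_GATE,
    apply_gate,
    generate_worm,
    preset_config,
)


@pytest.fixture(scope="session")
def wt_worm():
    """One wild-type worm at 8 uM, shared across read-only tests."""
    return generate_worm(preset_config("WT", seed=11, concentration=8))


@pytest.fixture(scope="session")
def wt_gated(wt_worm):
    stack, labels = wt_worm
    return (apply_gate(stack, UNFILTERED_GATE).values,
            apply_gate(stack, FLF_GATE).values, labels)


def class_mask(labels, cls):
    return np.isin(labels.labels, labels.labels_of_class(cls))
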