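import numpy as np
import pytest

import edma


@pytest.fixture
def triangle_config():
    """The 3-4-5 right triangle in the z=0 plane."""
    return edma.LandmarkConfiguration(
        "tri",
        ("A", "B", "C"),
        np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 4.0, 0.0]]),
    )


@pytest.fixture
def small_dataset():
    """Two specimens x three landmarks, two groups."""
    labels = ("A", "B", "C")
    c1 = edma.LandmarkConfiguration(
        "S1", labels, np.array([[0.0, 0.0, 0.0], [3.0, 0.0, 0.0], [0.0, 4.0, 0.0]])
    )
    c2 = edma.LandmarkConfiguration(
        "S2", labels, np.array([[0.1, 0.0, 0.0], [3.1, 0.1, 0.0], [0.0, 4.1, 0.1]])
    )
    return edma.LandmarkDataset([c1, c2], {"S1": "wt", "S2": "mut"})


def make_two_groups(n=10, sigma=0.03, template_seed=11, seeds=(101, 202),
                    effect_labels=(), magnitude=0.0):
    """Two simulated groups around a 16-landmark template."""
    tmpl = edma.make_template_form("mandible_16", seed=template_seed)
    test_tmpl = tmpl
    if effect_labels and magnitude:
        test_tmpl = edma.apply_regional_effect(
            tmpl, effect_labels, "radial_scale", magnitude
        )
    a = edma.simulate_group(test_tmpl, n, sigma, "mutant", seed=seeds[0])
    b = edma.simulate_group(tmpl, n, sigma, "unaffected", seed=seeds[1])
    return a, b, tmpl


@pytest.fixture
def two_groups():
    return make_two_groups()
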