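import numpy as np
import pytest

import tmekit as tk


@pytest.fixture(scope="session")
def default_slide():
    """One deterministic synthetic slide with the default conditions."""
    return tk.simulate_slide(tk.SlideSimConfig(seed=7))


@pytest.fixture(scope="session")
def assigned_slide(default_slide):
    """The same slide with regions labelled and nuclei assigned."""
    annotation, mask, gt = default_slide
    regions = tk.label_tumor_regions(mask)
    assigned = tk.assign_nuclei_to_regions(annotation, regions)
    return assigned, mask, regions, gt


@pytest.fixture(scope="session")
def refined_slide(assigned_slide):
    assigned, mask, regions, gt = assigned_slide
    refined, n_changed = tk.reclassify_epithelial(assigned, regions)
    return refined, mask, regions, gt, n_changed


@pytest.fixture(scope="session")
def registry():
    return tk.build_default_registry()


def rng_for(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)
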