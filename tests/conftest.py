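import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from magicperf.phantom import LesionSpec, PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_spec():
    """64-px phantom with one core+penumbra lesion."""
    return PhantomSpec(
        image_size=64, n_ncct_slices=101, n_ctp_slices=10,
        lesions=(LesionSpec(center=(5, 28, 22), core_radius=5.0,
                            penumbra_radius=15.0),),
        seed=7)


@pytest.fixture(scope="session")
def small_case(small_spec):
    return generate_phantom(small_spec)


@pytest.fixture(scope="session")
def lesion_free_case():
    return generate_phantom(PhantomSpec(image_size=64, n_ncct_slices=101,
                                        n_ctp_slices=10, seed=7))


@pytest.fixture(scope="session")
def tiny_samples():
    """Fifty paired samples from five 64-px phantom cases, with per-sample
    brain masks (the desk-scale training set)."""
    from magicperf.phantom import generate_cohort
    from magicperf.preprocess import pair_slices
    cases = generate_cohort(5, seed=1, image_size=64, n_ncct_slices=101,
                            n_ctp_slices=10)
    samples, masks = [], []
    for i, case in enumerate(cases):
        ss = pair_slices(case.ncct, case.maps, case.ctp_z_mm, case_id=f"c{i}")
        samples.extend(ss)
        masks.extend(case.brain_mask[s.meta["ctp_index"]] for s in ss)
    return samples, masks


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
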