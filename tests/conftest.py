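import warnings

import numpy as np
import pytest

from wastunt import cleaning, growth, lms
from wastunt.simulate import SyntheticConfig, generate_cohort

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def refs():
    return lms.toy_reference()


@pytest.fixture(scope="session")
def small_cohort(refs):
    """A cleaned default-condition cohort shared by the unit tests."""
    lfa, wfl = refs
    cfg = SyntheticConfig(n_subjects=150, seed=11)
    visits, manifest = generate_cohort(cfg, refs=refs)
    visits = lms.add_zscores(visits, lfa, wfl)
    kept, excluded, report = cleaning.clean_cohort(visits)
    return {"visits": kept, "excluded": excluded, "report": report, "manifest": manifest}


@pytest.fixture(scope="session")
def small_growth_fit(small_cohort):
    frame = growth.build_design(small_cohort["visits"])
    return growth.fit_growth_model(frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
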