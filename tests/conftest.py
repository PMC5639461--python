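import numpy as np
import pytest

import somnotype as st


@pytest.fixture(scope="session")
def ld_cohort():
    """Small default LD cohort (6 WT vs 6 mutant, 7 days) reused across
    tests; session-scoped because generation is the expensive part."""
    spec = st.MouseCohortSpec(seed=11)
    return st.simulate_mouse_activity(spec, st.ld_schedule(7)), spec


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_trace(values, **kwargs):
    defaults = dict(subject_id="T", genotype="WT", bin_seconds=10)
    defaults.update(kwargs)
    return st.ActivityTrace(values=np.asarray(values, dtype=float), **defaults)


@pytest.fixture()
def toy_quartet():
    spec = st.PedigreeVcfSpec(
        n_background_variants=50,
        planted=(st.PlantedVariant(model="x_linked"),),
        seed=5,
    )
    return st.make_toy_pedigree_vcf(spec)
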