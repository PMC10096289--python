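import numpy as np
import pytest

from moadti import SyntheticConfig, gen_study


@pytest.fixture(scope="session")
def small_study():
    """Desk-scale synthetic study shared by read-only tests."""
    return gen_study(SyntheticConfig(n_targets=8, n_compounds=40, n_positives=60,
                                     seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def pair_features(records, study):
    """Concatenated compound (+) ground-truth target features for records."""
    return np.vstack(
        [
            np.concatenate(
                [study.compound_store.vector(r.compound_id),
                 study.truths[r.target_gene]]
            )
            for r in records
        ]
    )
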