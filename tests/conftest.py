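import numpy as np
import pytest

from threatlearn import DesignConfig, TrialSequence, generate_design


@pytest.fixture(scope="session")
def default_seq() -> TrialSequence:
    """One default 160-trial sequence (80 CS+ / 80 CS-, 50% reinforcement)."""
    return generate_design(DesignConfig(), seed=123, participant_id="p1")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_sequence(cs, us, participant_id="toy"):
    """Hand-rolled sequence for toy examples (single block)."""
    cs = np.asarray(cs, dtype=object)
    return TrialSequence(
        participant_id=participant_id,
        cs=cs,
        us=np.asarray(us, dtype=int),
        block=np.ones(len(cs), dtype=int),
    )
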