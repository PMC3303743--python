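import numpy as np
import pytest

from sdckit.fold import FoldEngine, RnaSequence
from sdckit.shape import MutantCollection, ReactivityProfile


@pytest.fixture(scope="session")
def engine():
    return FoldEngine()


def random_sequence(rng, n):
    return RnaSequence(id=f"r{n}", residues="".join(rng.choice(list("ACGU"), size=n)))


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_profile(values, variant="WT", replicate=1, state="raw", rna_id="rna"):
    values = np.asarray(values, dtype=float)
    return ReactivityProfile(
        rna_id=rna_id,
        variant_id=variant,
        replicate=replicate,
        positions=np.arange(1, len(values) + 1),
        reactivities=values,
        state=state,
    )


@pytest.fixture
def small_collection():
    """Three variants on a shared 30-position frame, raw state."""
    rng = np.random.default_rng(42)
    profiles = [
        make_profile(rng.gamma(2.0, 0.5, size=30), variant=v) for v in ("WT", "C7G", "U19A")
    ]
    return MutantCollection(rna_id="rna", profiles=profiles)
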