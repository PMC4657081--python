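import numpy as np
import pytest

from mirnaclassify import (
    GaussianBenchSpec,
    HairpinFold,
    HairpinRecord,
    gen_gaussian_bench,
)

#: Scalar defaults that make any fixture fold complete for extraction.
FOLD_SCALARS = dict(
    dG=-10.0, EFE=-9.5, Freq=0.8, Diversity=2.0, dS=-150.0, dH=-50.0,
    Tm=60.0, dQ=0.3, dF=0.9, dP=0.4, dD=0.1,
)


def make_fold(structure: str, **overrides) -> HairpinFold:
    """A fold with every thermodynamic scalar filled (fixture values)."""
    scalars = dict(FOLD_SCALARS)
    scalars.update(overrides)
    return HairpinFold(structure=structure, source="synthetic", **scalars)


@pytest.fixture
def stem_record():
    """Perfect 4-bp G:C stem with a 4-nt loop."""
    rec = HairpinRecord("stem", "GGGGAAAACCCC")
    fold = make_fold("((((....))))")
    return rec, fold


@pytest.fixture(scope="session")
def small_bench():
    """A quick imbalanced Gaussian benchmark for trainer tests."""
    spec = GaussianBenchSpec(
        n_pos=30, n_neg=300, dim=5, separation=2.5, neg_clusters=2, seed=7
    )
    return gen_gaussian_bench(spec)


@pytest.fixture
def separable_xy():
    """Linearly separable balanced toy data."""
    rng = np.random.default_rng(0)
    X = np.vstack([
        rng.normal(0.0, 0.3, size=(20, 2)),
        rng.normal(5.0, 0.3, size=(20, 2)),
    ])
    y = np.array([1] * 20 + [0] * 20)
    return X, y
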