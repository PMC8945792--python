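import numpy as np
import pandas as pd
import pytest

from lsea.registry import EnzymeClass, LipidRecord, LipidRegistry, Precursor
from lsea.synth import SynthConfig, generate


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study (seed 1), shared across tests."""
    return generate(SynthConfig(seed=1))


@pytest.fixture()
def tiny_registry():
    return LipidRegistry(
        [
            LipidRecord(
                canonical_id="maresin-1",
                display_name="Maresin-1",
                synonyms=("maresin 1", "MaR1"),
                precursor=Precursor.DHA,
                enzyme_class=EnzymeClass.LOX,
            ),
            LipidRecord(
                canonical_id="9(10)-epome",
                display_name="9(10)-EpOME",
                synonyms=("9,10-EpOME",),
                precursor=Precursor.LA,
                enzyme_class=EnzymeClass.CYP450,
            ),
            LipidRecord(
                canonical_id="ltb4",
                display_name="LTB4",
                synonyms=("Leukotriene B4",),
                precursor=Precursor.AA,
                enzyme_class=EnzymeClass.LOX,
            ),
        ]
    )


@pytest.fixture()
def small_meta():
    return pd.DataFrame(
        {
            "tissue": ["lung", "lung"],
            "treatment": ["CTRL", "DEP"],
            "protocol": ["acute", "acute"],
            "replicate": [1, 1],
        },
        index=pd.Index(["s1", "s2"], name="sample_id"),
    )


def nb_counts(rng, mean, alpha, size):
    """NB draws with variance mean + alpha * mean^2 (Poisson at alpha=0)."""
    if alpha == 0:
        return rng.poisson(mean, size=size).astype(float)
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + np.asarray(mean)), size=size).astype(
        float
    )
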