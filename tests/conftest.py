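import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ystrpop.alleles import AlleleValue
from ystrpop.core import Haplotype, PopulationDataset
from ystrpop.panel import LocusPanel, YFILER_17

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def panel():
    return YFILER_17


@pytest.fixture
def single_locus_panel():
    return LocusPanel(loci=("L1",))


def make_haplotype(sample_id, vec, population="P", loci=None):
    """Integer haplotype from a repeat vector (generic locus names)."""
    loci = loci or [f"L{i+1}" for i in range(len(vec))]
    return Haplotype(
        sample_id, population, {l: AlleleValue.integer(v) for l, v in zip(loci, vec)}
    )


def make_population(name, vectors, loci=None):
    return PopulationDataset(
        name,
        [make_haplotype(f"{name}{i}", v, name, loci) for i, v in enumerate(vectors)],
    )


@pytest.fixture
def modal_yfiler_haplotype(panel):
    from ystrpop.simulate import DEFAULT_FOUNDER

    def build(sample_id="s1", population="P", **overrides):
        calls = {l: AlleleValue.integer(DEFAULT_FOUNDER[l]) for l in panel.loci}
        calls.update(overrides)
        return Haplotype(sample_id, population, calls)

    return build
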