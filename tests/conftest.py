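import numpy as np
import pytest

from mrcorge import InstrumentRecord, VariantAssociation

ALLELE_PAIRS = [("A", "G"), ("T", "C"), ("G", "A"), ("C", "T")]


def make_instruments(rng: np.random.Generator, n: int,
                     beta_scale: float = 0.1) -> list[InstrumentRecord]:
    """Random harmonized instruments with well-behaved statistics."""
    records = []
    for j in range(n):
        ea, oa = ALLELE_PAIRS[j % len(ALLELE_PAIRS)]
        be = 0.0
        while be == 0.0:
            be = rng.normal(0.0, beta_scale)
        records.append(InstrumentRecord(
            variant_id=f"rs{j + 1:05d}",
            effect_allele=ea, other_allele=oa,
            beta_exposure=float(be),
            se_exposure=float(rng.uniform(0.005, 0.05)),
            beta_outcome=float(rng.normal(0.0, 0.05)),
            se_outcome=float(rng.uniform(0.005, 0.05)),
            eaf_exposure=float(rng.uniform(0.05, 0.95)),
            pval_exposure=float(rng.uniform(0, 1)),
            n_exposure=float(rng.integers(10_000, 500_000)),
            eaf_outcome=float(rng.uniform(0.05, 0.95)),
            n_outcome=float(rng.integers(10_000, 500_000)),
        ))
    return records


def make_association(variant_id="rs1", effect_allele="A", other_allele="G",
                     beta=0.1, se=0.01, eaf=0.3, pval=1e-8,
                     n=100_000.0) -> VariantAssociation:
    return VariantAssociation(variant_id, effect_allele, other_allele,
                              beta, se, eaf=eaf, pval=pval, n=n)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def instruments(rng):
    return make_instruments(rng, 30)
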