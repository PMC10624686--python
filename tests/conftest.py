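import random

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from spddpcr import published
from spddpcr.assay_design import AmpliconTemplate, VariantSpec


@pytest.fixture(scope="session")
def assays():
    """The seven packaged characterized assays."""
    return published.published_assays()


@pytest.fixture(scope="session")
def variants_table():
    """The seven prioritized variants with WES counts and ddPCR results."""
    return published.published_variants()


@pytest.fixture()
def apc_4128(assays):
    return next(a for a in assays if a.hgvs_c == "c.4128T>A")


@pytest.fixture()
def lamc3(assays):
    return next(a for a in assays if a.gene == "LAMC3")


def random_template(rng: random.Random, length: int, offset: int) -> AmpliconTemplate:
    seq = "".join(rng.choice("ACGT") for _ in range(length))
    ref = seq[offset]
    alt = rng.choice([b for b in "ACGT" if b != ref])
    return AmpliconTemplate(seq, offset, VariantSpec("TEST", "c.?", ref, alt))
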