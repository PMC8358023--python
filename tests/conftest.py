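import pytest

from ctdna.somatic_filter import FilterConfig
from ctdna.synthetic import SimParams, simulate_cohort
from ctdna.variant_io import (
    FunctionalClass,
    Material,
    SampleMeta,
    VariantCall,
    VariantKey,
)


def make_call(
    chrom="12",
    pos=25398284,
    ref="C",
    alt="A",
    gene="KRAS",
    fclass=FunctionalClass.MISSENSE,
    sample_id="S1",
    vaf=None,
    depth=2000,
    alt_reads=40,
    **kwargs,
):
    """Convenience constructor used across the suite."""
    if vaf is None:
        vaf = alt_reads / depth if depth else 0.0
    return VariantCall(
        key=VariantKey(chrom, pos, ref, alt),
        gene=gene,
        functional_class=fclass,
        sample_id=sample_id,
        vaf=vaf,
        depth=depth,
        alt_reads=alt_reads,
        **kwargs,
    )


@pytest.fixture
def cfdna_sample():
    return SampleMeta("S1", "P1", Material.CFDNA, "baseline", "v3")


@pytest.fixture
def tissue_sample():
    return SampleMeta("T1", "P1", Material.TISSUE_FFPE, "baseline", "v3")


@pytest.fixture
def pbmc_sample():
    return SampleMeta("B1", "P1", Material.PBMC, "baseline", "v3")


@pytest.fixture
def config():
    return FilterConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-patient synthetic cohort shared by the heavier tests."""
    return simulate_cohort(SimParams(n_patients=40, seed=7))
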