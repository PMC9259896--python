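import pytest

from uvtriage.models import (
    Consequence,
    VariantAnnotation,
    VariantCall,
    VariantKey,
    Zygosity,
)
from uvtriage.simulate import SimulationConfig, generate_cohort


def make_call(
    chrom="1",
    pos=1000,
    ref="A",
    alt="G",
    sample="S1",
    zygosity=Zygosity.HET,
    depth=50,
    alt_fraction=0.5,
    transcript="",
):
    return VariantCall(
        key=VariantKey(chrom, pos, ref, alt, transcript),
        sample_id=sample,
        zygosity=zygosity,
        read_depth=depth,
        alt_fraction=alt_fraction,
    )


def make_annotation(
    key=None,
    gene="GENE1",
    consequence=Consequence.MISSENSE,
    freqs=None,
    **key_kwargs,
):
    if key is None:
        key = make_call(**key_kwargs).key
    return VariantAnnotation(
        key=key,
        gene_symbol=gene,
        consequence=consequence,
        population_freqs=freqs or {},
    )


SMALL_CONFIG = SimulationConfig(
    n_patients=20,
    n_genes=300,
    asd_panel_size=40,
    ndd_panel_size=12,
    mean_kept_variants_per_patient=30.0,
    n_artifacts=4,
    artifact_carriers_min=6,
    artifact_carriers_max=10,
    n_polymorphisms=5,
    decoy_mean_per_patient=3.0,
    trio_fraction=0.5,
    sibling_pairs=2,
    twin_pairs=1,
    seed=7,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CONFIG)
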