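import numpy as np
import pytest

from sigselect import (
    Channel,
    CohortSpec,
    DriverSpec,
    MutationRecord,
    SignatureCatalog,
    generate_signatures,
)


@pytest.fixture(scope="session")
def cosmic():
    from sigselect import load_cosmic_v2

    return load_cosmic_v2()


@pytest.fixture
def disjoint_catalog():
    """Two signatures with disjoint channel supports (s1: channels 0-47,
    s2: channels 48-95), plus their names."""
    probs = np.zeros((2, 96))
    probs[0, :48] = 1 / 48
    probs[1, 48:] = 1 / 48
    return SignatureCatalog(names=["s1", "s2"], probs=probs)


@pytest.fixture(scope="session")
def synth_catalog():
    return generate_signatures(5, concentration=0.3, seed=11)


def make_record(
    sample="S1",
    ctype="CT",
    chrom="1",
    pos=100,
    ref="C",
    alt="A",
    context="ACA",
    gene="",
    effect="other",
):
    return MutationRecord(
        sample_id=sample,
        cancer_type=ctype,
        chromosome=chrom,
        position=pos,
        ref_allele=ref,
        alt_allele=alt,
        context=context,
        gene=gene,
        effect=effect,
    )


@pytest.fixture
def record_factory():
    return make_record


def equal_channel_cohort(r_true, n_samples=200, seed=0, catalog=None, burden=300):
    """Cohort with two same-channel drivers planted at relative risk r_true,
    oriented so the scan's sorted first label is the r_true driver."""
    cat = catalog if catalog is not None else generate_signatures(5, 0.3, seed=11)
    ch = Channel.from_label("A[C>A]A")
    drivers = [
        DriverSpec("G1:A", ch, "G1", float(r_true)),
        DriverSpec("G2:B", ch, "G2", 1.0),
    ]
    return CohortSpec(
        n_samples=n_samples,
        catalog=cat,
        burden_mean=burden,
        burden_dispersion=None,
        exposure_alpha=0.5,
        drivers=drivers,
        seed=seed,
    )
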