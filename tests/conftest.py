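import pytest

from varcalib import (
    ClinvarBin,
    CohortDataset,
    Consequence,
    VariantRecord,
    reclassify_consequence,
)


def make_record(
    chrom="1",
    pos=1000,
    ref="A",
    alt="T",
    gene="SOD1",
    consequence_term="missense_variant",
    clinvar_bin=ClinvarBin.VUS,
    revel=None,
    cadd=None,
    pop_af=None,
    pop_ac=None,
    case_ac=1,
    control_ac=0,
):
    """Record factory with the consequence class derived from the term."""
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        gene=gene,
        consequence_term=consequence_term,
        consequence_class=reclassify_consequence(consequence_term),
        clinvar_bin=clinvar_bin,
        revel=revel,
        cadd=cadd,
        pop_af=pop_af,
        pop_ac=pop_ac,
        case_ac=case_ac,
        control_ac=control_ac,
    )


@pytest.fixture
def six_record_cohort():
    """Two synonymous, one common missense, three rare PTV/missense records."""
    records = [
        make_record(pos=10, consequence_term="synonymous_variant", cadd=1.0, pop_af=0.001),
        make_record(pos=20, consequence_term="synonymous_variant", cadd=2.0, pop_af=None),
        make_record(pos=30, revel=0.5, cadd=22.0, pop_af=0.05),  # common missense
        make_record(pos=40, revel=0.7, cadd=25.0, pop_af=0.001),
        make_record(pos=50, consequence_term="stop_gained", cadd=35.0, pop_af=None),
        make_record(pos=60, consequence_term="frameshift_variant", cadd=30.0, pop_af=0.009),
    ]
    return CohortDataset(name="toy", n_cases=100, n_controls=100, records=records)
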