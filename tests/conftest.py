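import numpy as np
import pytest

from clonedivergence import (
    AlterationClass,
    ClinicalRecord,
    Cohort,
    GeneratorConfig,
    Lesion,
    MetastasisSubtype,
    PatientPair,
    Response,
    SampleProfile,
    Variant,
    assemble_cohort,
    generate_cohort,
)


def make_snv(patient, lesion, gene, chrom="1", pos=100, ref="C", alt="T",
             vaf=0.3, context=None):
    return Variant(
        patient_id=patient,
        lesion=Lesion(lesion),
        gene=gene,
        chrom=chrom,
        pos=pos,
        ref=ref,
        alt=alt,
        alteration_class=AlterationClass.SUBSTITUTION_INDEL,
        vaf=vaf,
        context=context,
    )


def make_clinical(patient, subtype="synchronous", response="PR", os_months=24.0,
                  os_event=True, **kw):
    return ClinicalRecord(
        patient_id=patient,
        metastasis_subtype=MetastasisSubtype(subtype),
        response=Response(response) if response else None,
        os_months=os_months,
        os_event=os_event,
        **kw,
    )


def make_pair(patient, primary_keys, metastasis_keys, clinical=None):
    """Pair whose SNVs are defined by (chrom, pos) site tuples per lesion."""
    def profile(lesion, sites):
        variants = tuple(
            make_snv(patient, lesion, gene=f"G{c}_{p}", chrom=str(c), pos=p)
            for c, p in sorted(sites)
        )
        return SampleProfile(patient, Lesion(lesion), variants)

    return PatientPair(
        patient_id=patient,
        clinical=clinical or make_clinical(patient),
        primary=profile("primary", primary_keys),
        metastasis=profile("metastasis", metastasis_keys),
    )


@pytest.fixture(scope="session")
def synthetic():
    """Default-condition synthetic cohort with truth, shared across tests."""
    config = GeneratorConfig(n_patients=64, seed=11)
    cohort, truth, matrix = generate_cohort(config)
    return {"config": config, "cohort": cohort, "truth": truth, "matrix": matrix}


@pytest.fixture(scope="session")
def big_synthetic():
    """Larger cohort for recovery-rate and calibration checks."""
    config = GeneratorConfig(n_patients=300, seed=23)
    cohort, truth, matrix = generate_cohort(config)
    return {"config": config, "cohort": cohort, "truth": truth, "matrix": matrix}
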