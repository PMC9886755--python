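import numpy as np
import pytest

from apoeld.data import GenotypeDataset, SampleRecord, VariantRecord


def make_variant(vid="rs1", chrom="1", pos=1000, r2=None, effect="alt"):
    ref, alt = "A", "G"
    return VariantRecord(
        variant_id=vid,
        chrom=chrom,
        pos=pos,
        ref_allele=ref,
        alt_allele=alt,
        effect_allele=alt if effect == "alt" else ref,
        imputation_r2=r2,
    )


def make_sample(sid, status="NAD", age=80.0, dataset="D1", family=None, pcs=None,
                sex="female", apoe=None):
    return SampleRecord(
        sample_id=sid,
        dataset_id=dataset,
        family_id=family or sid,
        sex=sex,
        ad_status=status,
        age_onset=age if status == "AD" else None,
        age_censor=age if status == "NAD" else None,
        pcs=tuple(pcs) if pcs is not None else (),
        apoe_genotype=apoe,
    )


@pytest.fixture
def small_dataset():
    """10 samples x 4 variants with deterministic dosages."""
    rng = np.random.default_rng(0)
    variants = [make_variant(f"rs{k}", chrom=str(k + 1), pos=1000 * (k + 1))
                for k in range(4)]
    dosages = rng.integers(0, 3, size=(10, 4)).astype(np.int8)
    samples = [make_sample(f"S{i}", status="AD" if i < 4 else "NAD",
                           age=70.0 + i) for i in range(10)]
    return GenotypeDataset(dosages, variants, samples, "D1")
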