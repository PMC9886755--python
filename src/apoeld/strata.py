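"""APOE epsilon genotype calls and the four analysis strata.

The epsilon alleles are defined by two exonic SNPs: the rs429358 minor
allele (C) marks ε4 and the rs7412 minor allele (T) marks ε2; ε3 carries
neither.  With the vanishingly rare ε1 allele excluded, the pair of minor
allele dosages at (rs429358, rs7412) determines the diplotype uniquely.

The analysis runs in two anchor-specific subsamples:

* anchor rs7412 → the ε4-negative stratum (ε2ε2, ε2ε3, ε3ε3), isolating
  the ε2 allele's effect;
* anchor rs429358 → the ε2-negative stratum (ε4ε4, ε3ε4, ε3ε3).

Each stratum is split into AD-affected (AD) and unaffected (NAD) groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .data import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

RS429358 = "rs429358"
RS7412 = "rs7412"

APOE_GENOTYPES = ("e2e2", "e2e3", "e2e4", "e3e3", "e3e4", "e4e4")

#: anchor SNP -> epsilon genotypes retained in its stratum
STRATUM_GENOTYPES = {
    RS7412: frozenset({"e2e2", "e2e3", "e3e3"}),  # ε4-negative
    RS429358: frozenset({"e4e4", "e3e4", "e3e3"}),  # ε2-negative
}

STRATUM_LABEL = {RS7412: "e4_negative", RS429358: "e2_negative"}

_CALL_TABLE = {
    (0, 0): "e3e3",
    (1, 0): "e3e4",
    (2, 0): "e4e4",
    (0, 1): "e2e3",
    (0, 2): "e2e2",
    (1, 1): "e2e4",
}


def call_apoe(d429358: int, d7412: int) -> str:
    """Call the APOE diplotype from minor-allele dosages at the two SNPs.

    ``d429358`` counts the C (ε4-defining) allele, ``d7412`` the T
    (ε2-defining) allele.  A combined dosage above 2 would require an ε1
    allele (both minor alleles on one haplotype) and raises.
    """
    if d429358 == MISSING or d7412 == MISSING:
        raise ValueError("call_apoe: missing dosage")
    key = (int(d429358), int(d7412))
    if key not in _CALL_TABLE:
        raise ValueError(
            f"call_apoe: dosage pair {key} implies an e1 allele "
            "(excluded as biologically implausible)"
        )
    return _CALL_TABLE[key]


@dataclass
class Stratum:
    """One AD or NAD group within an anchor-defined subsample."""

    anchor: str
    negative_for: str  # "e4" | "e2"
    group: str  # "AD" | "NAD"
    sample_ids: set[str] = field(default_factory=set)
    dataset_id: str = "pooled"

    def __post_init__(self) -> None:
        expected = "e4" if self.anchor == RS7412 else "e2"
        if self.negative_for != expected:
            raise ValueError(
                f"anchor {self.anchor} defines the {expected}-negative stratum, "
                f"not {self.negative_for}-negative"
            )


def apoe_calls(ds: GenotypeDataset) -> tuple[dict[str, str], list[str]]:
    """APOE genotype per sample; returns (calls, excluded sample ids).

    Directly reported genotypes in the phenotype record override derived
    calls; disagreements are logged.  Samples with missing dosages at either
    SNP (and no reported genotype) are excluded.
    """
    if not (ds.has_variant(RS429358) and ds.has_variant(RS7412)):
        raise ValueError("dataset lacks rs429358 and/or rs7412")
    d4 = ds.dosage_vector(RS429358)
    d2 = ds.dosage_vector(RS7412)
    calls: dict[str, str] = {}
    excluded: list[str] = []
    for s, a, b in zip(ds.samples, d4, d2):
        reported = s.apoe_genotype
        if reported is not None and reported not in APOE_GENOTYPES:
            raise ValueError(f"{s.sample_id}: unknown APOE genotype {reported!r}")
        if a == MISSING or b == MISSING:
            if reported is not None:
                calls[s.sample_id] = reported
            else:
                excluded.append(s.sample_id)
                logger.info("excluding %s: missing APOE dosage", s.sample_id)
            continue
        derived = call_apoe(int(a), int(b))
        if reported is not None and reported != derived:
            logger.warning(
                "%s: reported APOE genotype %s != derived %s; using reported",
                s.sample_id,
                reported,
                derived,
            )
        calls[s.sample_id] = reported if reported is not None else derived
    return calls, excluded


def build_strata(ds: GenotypeDataset, anchor: str) -> tuple[Stratum, Stratum]:
    """Build the (AD, NAD) strata for one anchor SNP.

    Keeps only subjects whose APOE genotype is in the anchor's allowed set
    (ε2ε4 carriers fall in neither stratum), then splits by AD status.
    """
    if anchor not in STRATUM_GENOTYPES:
        raise ValueError(f"anchor must be {RS7412} or {RS429358}, got {anchor!r}")
    allowed = STRATUM_GENOTYPES[anchor]
    negative_for = "e4" if anchor == RS7412 else "e2"
    calls, _ = apoe_calls(ds)
    ad = Stratum(anchor, negative_for, "AD", set(), ds.dataset_id)
    nad = Stratum(anchor, negative_for, "NAD", set(), ds.dataset_id)
    for s in ds.samples:
        g = calls.get(s.sample_id)
        if g is None or g not in allowed:
            continue
        (ad if s.ad_status == "AD" else nad).sample_ids.add(s.sample_id)
    for stratum in (ad, nad):
        if not stratum.sample_ids:
            raise ValueError(
                f"empty stratum: {STRATUM_LABEL[anchor]} {stratum.group} "
                f"in dataset {ds.dataset_id}"
            )
    return ad, nad


def stratum_dataset(ds: GenotypeDataset, stratum: Stratum) -> GenotypeDataset:
    """Restrict a dataset to one stratum's samples."""
    return ds.subset_samples(stratum.sample_ids)
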