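"""Synthetic multi-dataset cohorts with the structure the analysis assumes.

Two generation modes mirror the two halves of the pipeline:

* **LD mode** (:func:`gen_ld_mode`) simulates genotype-given-status: each
  AD/NAD group has its own two-locus haplotype pool for every
  (anchor, partner) pair, so the group-specific correlation r is an
  analytic property of the scenario.  Null SNPs are drawn from a common
  pool independent of the anchor (r = 0 in both groups).

* **Survival mode** (:func:`gen_survival_mode`) simulates
  status-given-genotype: one haplotype pool, compound-genotype effects on
  a Weibull proportional-hazards onset time (shape 4, scale 85 years by
  default, mimicking late-onset incidence), independent uniform censoring
  on [60, 95] years, and an optional shared log-normal family frailty.

Each dataset draws from its own pseudo-random stream derived from the
master seed by fixed offsets, so output is bit-identical given
(scenario, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeDataset, SampleRecord, VariantRecord
from .strata import RS429358, RS7412

__all__ = [
    "LDScenario",
    "SurvivalScenario",
    "hap_table_from_r",
    "implied_r",
    "gen_ld_mode",
    "gen_survival_mode",
]

# hg38 positions of the two epsilon-defining APOE SNPs
_APOE_VARIANTS = {
    RS429358: VariantRecord(RS429358, "19", 44908684, "T", "C", "C"),
    RS7412: VariantRecord(RS7412, "19", 44908822, "C", "T", "T"),
}


def hap_table_from_r(pA: float, pB: float, r: float) -> tuple[float, float, float, float]:
    """Haplotype frequencies (p11, p10, p01, p00) with given margins and r."""
    if not (0 < pA < 1 and 0 < pB < 1):
        raise ValueError("margins must be in (0,1)")
    p11 = pA * pB + r * np.sqrt(pA * (1 - pA) * pB * (1 - pB))
    table = (p11, pA - p11, pB - p11, 1 - pA - pB + p11)
    if any(t < -1e-12 or t > 1 + 1e-12 for t in table):
        raise ValueError(f"r={r} infeasible for margins pA={pA}, pB={pB}")
    return tuple(float(np.clip(t, 0.0, 1.0)) for t in table)  # type: ignore[return-value]


def implied_r(table: tuple[float, float, float, float]) -> float:
    p11, p10, p01, _ = table
    pA = p11 + p10
    pB = p11 + p01
    return float((p11 - pA * pB) / np.sqrt(pA * (1 - pA) * pB * (1 - pB)))


def _check_table(table: tuple[float, float, float, float], name: str) -> None:
    if len(table) != 4 or any(t < 0 for t in table):
        raise ValueError(f"{name}: haplotype frequencies must be non-negative")
    if abs(sum(table) - 1.0) > 1e-9:
        raise ValueError(f"{name}: haplotype frequencies must sum to 1")


@dataclass
class LDScenario:
    """Group-specific LD structure for the Δr analysis.

    ``partner_haps`` maps a partner variant id to per-group haplotype
    tables ``{"AD": (p11, p10, p01, p00), "NAD": ...}`` over the
    (anchor minor, partner minor) alleles.  All partner tables must agree
    on the anchor's per-group allele frequency (the anchor is drawn once
    per subject and partners are drawn conditional on it).  ``n_null``
    SNPs are independent of the anchor with MAF uniform in
    ``null_maf_range``, identical in both groups.

    Default sample sizes and frequencies follow the ε2 analysis setting:
    the anchor minor allele is rarer in the AD group (the ε2 allele is
    protective), and the AD group is the smaller one.
    """

    anchor: str = RS7412
    dataset_sizes: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"D1": (600, 1000)}
    )  # name -> (n_AD, n_NAD)
    anchor_freq: dict[str, float] = field(
        default_factory=lambda: {"AD": 0.04, "NAD": 0.08}
    )
    partner_haps: dict[str, dict[str, tuple[float, float, float, float]]] = field(
        default_factory=dict
    )
    n_null: int = 0
    null_maf_range: tuple[float, float] = (0.1, 0.4)
    seed: int = 0

    def validate(self) -> None:
        if self.anchor not in (RS7412, RS429358):
            raise ValueError(f"anchor must be {RS7412} or {RS429358}")
        for g in ("AD", "NAD"):
            if not 0 < self.anchor_freq[g] < 1:
                raise ValueError("anchor_freq must be in (0,1)")
        for vid, groups in self.partner_haps.items():
            for g in ("AD", "NAD"):
                table = groups[g]
                _check_table(table, f"{vid}/{g}")
                pA = table[0] + table[1]
                if abs(pA - self.anchor_freq[g]) > 1e-9:
                    raise ValueError(
                        f"{vid}/{g}: anchor margin {pA} != anchor_freq "
                        f"{self.anchor_freq[g]}"
                    )

    @classmethod
    def planted(
        cls,
        r_ad: float,
        r_nad: float,
        partner_id: str = "rs_planted",
        partner_freq: float = 0.3,
        **kwargs,
    ) -> "LDScenario":
        """Scenario with one partner SNP at target per-group r values."""
        sc = cls(**kwargs)
        sc.partner_haps[partner_id] = {
            "AD": hap_table_from_r(sc.anchor_freq["AD"], partner_freq, r_ad),
            "NAD": hap_table_from_r(sc.anchor_freq["NAD"], partner_freq, r_nad),
        }
        return sc


def _age_records(
    rng: np.random.Generator,
    ds_name: str,
    statuses: np.ndarray,
) -> list[SampleRecord]:
    n = statuses.shape[0]
    sexes = rng.choice(["female", "male"], size=n)
    onsets = np.clip(np.round(rng.normal(75.0, 7.0, size=n)), 60, 95)
    censors = np.round(rng.uniform(60.0, 95.0, size=n))
    pcs = rng.normal(0.0, 1.0, size=(n, 5))
    records = []
    for i in range(n):
        ad = statuses[i] == "AD"
        records.append(
            SampleRecord(
                sample_id=f"{ds_name}_S{i:05d}",
                dataset_id=ds_name,
                family_id=f"{ds_name}_F{i:05d}",
                sex=str(sexes[i]),
                ad_status="AD" if ad else "NAD",
                age_onset=float(onsets[i]) if ad else None,
                age_censor=None if ad else float(censors[i]),
                pcs=tuple(np.round(pcs[i], 6)),
            )
        )
    return records


def _partner_dosage(
    rng: np.random.Generator,
    anchor_hap: np.ndarray,  # (n, 2) anchor minor-allele indicators
    table: tuple[float, float, float, float],
) -> np.ndarray:
    """Partner minor-allele dosage conditional on the anchor haplotypes."""
    p11, p10, p01, p00 = table
    pA = p11 + p10
    p_given1 = p11 / pA if pA > 0 else 0.0
    p_given0 = p01 / (1 - pA) if pA < 1 else 0.0
    prob = np.where(anchor_hap == 1, p_given1, p_given0)
    alleles = rng.random(anchor_hap.shape) < prob
    return alleles.sum(axis=1).astype(np.int8)


def gen_ld_mode(sc: LDScenario) -> list[GenotypeDataset]:
    """Generate per-dataset cohorts under the group-specific LD scenario."""
    sc.validate()
    other_apoe = RS429358 if sc.anchor == RS7412 else RS7412
    partner_ids = sorted(sc.partner_haps)
    variants = [_APOE_VARIANTS[sc.anchor], _APOE_VARIANTS[other_apoe]]
    for k, vid in enumerate(partner_ids):
        chrom = str(1 + (k % 18))  # keep planted partners off chromosome 19
        variants.append(
            VariantRecord(vid, chrom, 10_000_000 + 1000 * k, "A", "G", "G")
        )
    null_ids = [f"rs_null{k:05d}" for k in range(sc.n_null)]
    for k, vid in enumerate(null_ids):
        chrom = str(1 + (k % 22))
        variants.append(
            VariantRecord(vid, chrom, 50_000_000 + 1000 * k, "A", "C", "C")
        )
    vindex = {v.variant_id: j for j, v in enumerate(variants)}

    datasets = []
    for d_idx, (name, (n_ad, n_nad)) in enumerate(sorted(sc.dataset_sizes.items())):
        rng = np.random.default_rng([sc.seed, d_idx])
        n = n_ad + n_nad
        statuses = np.array(["AD"] * n_ad + ["NAD"] * n_nad)
        # null-SNP MAFs are a property of the dataset stream
        null_mafs = rng.uniform(*sc.null_maf_range, size=sc.n_null)
        dosages = np.zeros((n, len(variants)), dtype=np.int8)
        for group in ("AD", "NAD"):
            rows = np.flatnonzero(statuses == group)
            pA = sc.anchor_freq[group]
            anchor_hap = (rng.random((rows.size, 2)) < pA).astype(np.int8)
            dosages[rows, vindex[sc.anchor]] = anchor_hap.sum(axis=1)
            for vid in partner_ids:
                dosages[rows, vindex[vid]] = _partner_dosage(
                    rng, anchor_hap, sc.partner_haps[vid][group]
                )
            for k, vid in enumerate(null_ids):
                dosages[rows, vindex[vid]] = rng.binomial(
                    2, null_mafs[k], size=rows.size
                ).astype(np.int8)
        samples = _age_records(rng, name, statuses)
        datasets.append(GenotypeDataset(dosages, variants, samples, name))
    return datasets


@dataclass
class SurvivalScenario:
    """Status-given-genotype scenario for the compound-genotype Cox model.

    One haplotype pool for the (anchor, partner) pair with margins
    ``anchor_freq``/``partner_freq`` and correlation ``r``; onset times are
    Weibull proportional hazards with log hazard ratios ``betas`` per
    CompG level (CompG1 reference).  Families of ``family_size`` share a
    normal log-frailty with variance ``frailty_var``.
    """

    anchor: str = RS7412
    partner_id: str = "rs_partner"
    anchor_freq: float = 0.08
    partner_freq: float = 0.25
    r: float = 0.0
    betas: dict[str, float] = field(
        default_factory=lambda: {"CompG2": 0.0, "CompG3": -0.73, "CompG4": -0.18}
    )
    weibull_shape: float = 4.0
    weibull_scale: float = 85.0
    censor_range: tuple[float, float] = (60.0, 95.0)
    family_size: int = 1
    frailty_var: float = 0.0
    dataset_sizes: dict[str, int] = field(default_factory=lambda: {"D1": 4000})
    seed: int = 0

    def validate(self) -> None:
        if self.weibull_shape <= 0 or self.weibull_scale <= 0:
            raise ValueError("Weibull shape and scale must be positive")
        if self.frailty_var < 0:
            raise ValueError("frailty_var must be >= 0")
        hap_table_from_r(self.anchor_freq, self.partner_freq, self.r)


def gen_survival_mode(sc: SurvivalScenario) -> list[GenotypeDataset]:
    """Generate per-dataset cohorts under the survival scenario."""
    from .survival import compg_code

    sc.validate()
    other_apoe = RS429358 if sc.anchor == RS7412 else RS7412
    table = hap_table_from_r(sc.anchor_freq, sc.partner_freq, sc.r)
    variants = [
        _APOE_VARIANTS[sc.anchor],
        _APOE_VARIANTS[other_apoe],
        VariantRecord(sc.partner_id, "11", 109_127_412, "A", "G", "G"),
    ]
    datasets = []
    for d_idx, (name, n) in enumerate(sorted(sc.dataset_sizes.items())):
        rng = np.random.default_rng([sc.seed + 1_000_003, d_idx])
        # two haplotypes per subject from the single pool
        haps = rng.choice(4, size=(n, 2), p=np.asarray(table))
        anchor_dos = (np.isin(haps, (0, 1))).sum(axis=1).astype(np.int8)  # p11,p10
        partner_dos = (np.isin(haps, (0, 2))).sum(axis=1).astype(np.int8)  # p11,p01
        levels = np.array(
            [compg_code(int(a), int(b)) for a, b in zip(anchor_dos, partner_dos)]
        )
        lp = np.array([sc.betas.get(lv, 0.0) for lv in levels])
        n_fam = int(np.ceil(n / sc.family_size))
        fam_ids = np.repeat(np.arange(n_fam), sc.family_size)[:n]
        if sc.frailty_var > 0:
            frailty = rng.normal(0.0, np.sqrt(sc.frailty_var), size=n_fam)
            lp = lp + frailty[fam_ids]
        u = rng.uniform(size=n)
        t_event = sc.weibull_scale * (-np.log(u) / np.exp(lp)) ** (1.0 / sc.weibull_shape)
        censor = rng.uniform(*sc.censor_range, size=n)
        event = t_event <= censor
        if event.sum() == 0:
            import warnings

            warnings.warn(
                f"{name}: no events realized under the scenario", stacklevel=2
            )
        onset = np.round(np.maximum(t_event, 1.0))
        censor = np.round(censor)
        sexes = rng.choice(["female", "male"], size=n)
        pcs = rng.normal(0.0, 1.0, size=(n, 5))
        samples = []
        for i in range(n):
            samples.append(
                SampleRecord(
                    sample_id=f"{name}_S{i:05d}",
                    dataset_id=name,
                    family_id=f"{name}_F{fam_ids[i]:05d}",
                    sex=str(sexes[i]),
                    ad_status="AD" if event[i] else "NAD",
                    age_onset=float(onset[i]) if event[i] else None,
                    age_censor=None if event[i] else float(censor[i]),
                    pcs=tuple(np.round(pcs[i], 6)),
                )
            )
        dosages = np.zeros((n, 3), dtype=np.int8)
        dosages[:, 0] = anchor_dos
        dosages[:, 2] = partner_dos
        datasets.append(GenotypeDataset(dosages, variants, samples, name))
    return datasets
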