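"""Genotype/phenotype containers, readers and quality-control filters.

Dosages are hard calls in ``{0, 1, 2}`` counting the declared effect allele;
missing values are encoded as ``-1`` throughout.  Imputed posterior dosages
must be hard-called upstream (a max-probability genotype call below 0.9
should be set missing before the data reach this module).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

MISSING = -1

__all__ = [
    "MISSING",
    "VariantRecord",
    "SampleRecord",
    "GenotypeDataset",
    "QCConfig",
    "QCReport",
    "read_genotypes",
    "read_phenotypes",
    "attach_phenotypes",
    "compute_maf",
    "hwe_test",
    "apply_qc",
    "write_dosage_table",
    "write_variant_table",
    "write_phenotype_table",
    "write_vcf",
]


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic autosomal variant.

    ``effect_allele`` is the allele counted by the dosage and must be one of
    ``ref_allele``/``alt_allele``.  ``imputation_r2`` is ``None`` for directly
    genotyped variants.
    """

    variant_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    effect_allele: str
    eaf: float | None = None
    imputation_r2: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in (self.ref_allele, self.alt_allele):
            raise ValueError(
                f"{self.variant_id}: effect allele {self.effect_allele!r} is "
                f"neither ref {self.ref_allele!r} nor alt {self.alt_allele!r}"
            )
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: position must be >= 1")


@dataclass(frozen=True)
class SampleRecord:
    """Phenotype record for one subject.

    AD cases carry ``age_onset``; unaffected (NAD) subjects carry
    ``age_censor`` (age last seen).  Exactly the age matching the status is
    required.
    """

    sample_id: str
    dataset_id: str
    family_id: str
    sex: str  # "male" | "female"
    ad_status: str  # "AD" | "NAD"
    age_onset: float | None = None
    age_censor: float | None = None
    pcs: tuple[float, ...] = ()
    cohort: str = ""
    apoe_genotype: str | None = None  # directly reported, overrides derived

    def __post_init__(self) -> None:
        if self.ad_status not in ("AD", "NAD"):
            raise ValueError(f"{self.sample_id}: ad_status must be AD or NAD")
        if self.sex not in ("male", "female"):
            raise ValueError(f"{self.sample_id}: sex must be male or female")
        if self.ad_status == "AD":
            if self.age_onset is None:
                raise ValueError(f"{self.sample_id}: AD case without age_onset")
            if self.age_onset <= 0:
                raise ValueError(f"{self.sample_id}: age_onset must be > 0")
        else:
            if self.age_censor is None:
                raise ValueError(f"{self.sample_id}: NAD subject without age_censor")
            if self.age_censor <= 0:
                raise ValueError(f"{self.sample_id}: age_censor must be > 0")

    @property
    def time(self) -> float:
        """Analysis time: age at onset for cases, censoring age otherwise."""
        return self.age_onset if self.ad_status == "AD" else self.age_censor  # type: ignore[return-value]

    @property
    def event(self) -> int:
        return 1 if self.ad_status == "AD" else 0


class GenotypeDataset:
    """Samples x variants hard-call dosage matrix with metadata.

    Parameters
    ----------
    dosages
        Integer matrix of shape ``(n_samples, n_variants)`` with entries in
        ``{0, 1, 2, -1}``; ``-1`` marks a missing call.
    variants, samples
        Per-column / per-row metadata; lengths must match the matrix.
    dataset_id
        Cohort label (e.g. ``"ADGC"``).
    """

    def __init__(
        self,
        dosages: np.ndarray,
        variants: Sequence[VariantRecord],
        samples: Sequence[SampleRecord],
        dataset_id: str = "dataset",
    ) -> None:
        dosages = np.asarray(dosages, dtype=np.int8)
        if dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D (samples x variants)")
        if dosages.shape != (len(samples), len(variants)):
            raise ValueError(
                f"dosage matrix {dosages.shape} does not match "
                f"{len(samples)} samples x {len(variants)} variants"
            )
        bad = ~np.isin(dosages, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"dosage {dosages[i, j]} at sample {samples[i].sample_id}, "
                f"variant {variants[j].variant_id} not in {{0,1,2,missing}}"
            )
        self.dosages = dosages
        self.variants = list(variants)
        self.samples = list(samples)
        self.dataset_id = dataset_id
        self._vindex = {v.variant_id: k for k, v in enumerate(self.variants)}
        self._sindex = {s.sample_id: k for k, s in enumerate(self.samples)}
        if len(self._vindex) != len(self.variants):
            raise ValueError("duplicate variant ids")
        if len(self._sindex) != len(self.samples):
            dupes = pd.Series([s.sample_id for s in self.samples])
            raise ValueError(
                "duplicate sample ids: "
                + ", ".join(sorted(dupes[dupes.duplicated()].unique()))
            )

    # -- accessors -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def has_variant(self, variant_id: str) -> bool:
        return variant_id in self._vindex

    def variant(self, variant_id: str) -> VariantRecord:
        return self.variants[self._vindex[variant_id]]

    def dosage_vector(self, variant_id: str) -> np.ndarray:
        """Dosages of one variant across all samples (missing = -1)."""
        return self.dosages[:, self._vindex[variant_id]]

    # -- subsetting ----------------------------------------------------
    def subset_samples(self, keep: Iterable[str] | np.ndarray) -> "GenotypeDataset":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep)
            idx = np.array(
                [k for k, s in enumerate(self.samples) if s.sample_id in wanted],
                dtype=int,
            )
        return GenotypeDataset(
            self.dosages[idx],
            self.variants,
            [self.samples[k] for k in idx],
            self.dataset_id,
        )

    def subset_variants(self, keep: Iterable[str] | np.ndarray) -> "GenotypeDataset":
        if isinstance(keep, np.ndarray) and keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            wanted = set(keep)
            idx = np.array(
                [k for k, v in enumerate(self.variants) if v.variant_id in wanted],
                dtype=int,
            )
        return GenotypeDataset(
            self.dosages[:, idx],
            [self.variants[k] for k in idx],
            self.samples,
            self.dataset_id,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GenotypeDataset({self.dataset_id!r}: {self.n_samples} samples x "
            f"{self.n_variants} variants)"
        )


@dataclass(frozen=True)
class QCConfig:
    """Variant/sample quality-control thresholds.

    Defaults: missing rate 5%, MAF 5%, Hardy-Weinberg p-value floor 1e-6,
    imputation quality r^2 >= 0.7.
    """

    max_missing_rate: float = 0.05
    min_maf: float = 0.05
    hwe_p_floor: float = 1e-6
    min_imputation_r2: float = 0.7

    def __post_init__(self) -> None:
        for name in ("max_missing_rate", "min_maf", "hwe_p_floor", "min_imputation_r2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0,1]")


@dataclass
class QCReport:
    """Counts of records dropped per QC rule, in application order."""

    n_variants_imputation: int = 0
    n_variants_missing: int = 0
    n_samples_missing: int = 0
    n_variants_maf: int = 0
    n_variants_hwe: int = 0
    dropped_variants: dict[str, str] = field(default_factory=dict)
    dropped_samples: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rule": [
                    "imputation_r2",
                    "variant_missing_rate",
                    "sample_missing_rate",
                    "maf",
                    "hwe",
                ],
                "n_dropped": [
                    self.n_variants_imputation,
                    self.n_variants_missing,
                    self.n_samples_missing,
                    self.n_variants_maf,
                    self.n_variants_hwe,
                ],
            }
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_variant_table(path: str | Path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"variant_id", "chrom", "pos", "ref_allele", "alt_allele", "effect_allele"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"variant table {path} lacks columns: {sorted(missing_cols)}")
    records = []
    for row in df.itertuples(index=False):
        r2 = getattr(row, "imputation_r2", None)
        eaf = getattr(row, "eaf", None)
        records.append(
            VariantRecord(
                variant_id=str(row.variant_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=str(row.ref_allele),
                alt_allele=str(row.alt_allele),
                effect_allele=str(row.effect_allele),
                eaf=None if eaf is None or pd.isna(eaf) else float(eaf),
                imputation_r2=None if r2 is None or pd.isna(r2) else float(r2),
            )
        )
    return records


def read_genotypes(
    path: str | Path,
    format: str = "vcf",
    variant_table: str | Path | None = None,
    effect_alleles: dict[str, str] | None = None,
    dataset_id: str = "dataset",
) -> GenotypeDataset:
    """Read hard-call genotypes from a VCF or a tab-delimited dosage table.

    Parameters
    ----------
    format
        ``"vcf"`` (VCF v4.x, parsed with cyvcf2) or ``"dosage_table"``
        (rows = samples, header row of variant ids, first column
        ``sample_id``; a companion ``variant_table`` TSV is then required).
    effect_alleles
        Optional ``variant_id -> allele`` mapping.  For VCF input the default
        effect allele is ALT; dosages are flipped to ``2 - dosage`` when the
        declared effect allele is REF.

    Notes
    -----
    Sample records are placeholders until :func:`attach_phenotypes` joins the
    phenotype table; only ``sample_id`` is meaningful on return.
    """
    if format == "vcf":
        return _read_vcf(path, effect_alleles or {}, dataset_id)
    if format == "dosage_table":
        if variant_table is None:
            raise ValueError("dosage_table format requires variant_table")
        return _read_dosage_table(path, variant_table, dataset_id)
    raise ValueError(f"unknown genotype format {format!r}")


def _placeholder_sample(sample_id: str, dataset_id: str) -> SampleRecord:
    return SampleRecord(
        sample_id=sample_id,
        dataset_id=dataset_id,
        family_id=sample_id,
        sex="female",
        ad_status="NAD",
        age_censor=1.0,  # placeholder, replaced on phenotype join
    )


def _read_vcf(
    path: str | Path, effect_alleles: dict[str, str], dataset_id: str
) -> GenotypeDataset:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # pragma: no cover - cyvcf2 error text varies
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) != 1:
            raise ValueError(
                f"{path}: variant at {rec.CHROM}:{rec.POS} is not biallelic; "
                "split multi-allelic sites upstream"
            )
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        ea = effect_alleles.get(vid, rec.ALT[0])
        r2 = rec.INFO.get("R2", rec.INFO.get("DR2"))
        # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(rec.gt_types)
        alt_dosage = np.select(
            [gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING
        ).astype(np.int8)
        if ea == rec.REF:
            dos = np.where(alt_dosage == MISSING, MISSING, 2 - alt_dosage)
        else:
            dos = alt_dosage
        variants.append(
            VariantRecord(
                variant_id=vid,
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                ref_allele=rec.REF,
                alt_allele=rec.ALT[0],
                effect_allele=ea,
                imputation_r2=None if r2 is None else float(r2),
            )
        )
        columns.append(dos.astype(np.int8))
    if not variants:
        raise ValueError(f"{path}: VCF contains no variants")
    dosages = np.column_stack(columns)
    samples = [_placeholder_sample(s, dataset_id) for s in sample_ids]
    return GenotypeDataset(dosages, variants, samples, dataset_id)


def _read_dosage_table(
    path: str | Path, variant_table: str | Path, dataset_id: str
) -> GenotypeDataset:
    variants = _read_variant_table(variant_table)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA", "."])
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: dosage table must have a sample_id column")
    vids = [c for c in df.columns if c != "sample_id"]
    byid = {v.variant_id: v for v in variants}
    unknown = [v for v in vids if v not in byid]
    if unknown:
        raise ValueError(f"{path}: variants absent from variant table: {unknown[:5]}")
    mat = df[vids].to_numpy(dtype=float)
    valid = np.isnan(mat) | np.isin(mat, (0.0, 1.0, 2.0))
    if not valid.all():
        i, j = np.argwhere(~valid)[0]
        raise ValueError(
            f"{path}: line {i + 2}: dosage {mat[i, j]!r} for variant "
            f"{vids[j]} not in {{0,1,2,missing}}"
        )
    dosages = np.where(np.isnan(mat), MISSING, mat).astype(np.int8)
    samples = [_placeholder_sample(s, dataset_id) for s in df["sample_id"]]
    return GenotypeDataset(dosages, [byid[v] for v in vids], samples, dataset_id)


_PHENO_NUMERIC = ("age_onset", "age_censor")


def read_phenotypes(path: str | Path) -> list[SampleRecord]:
    """Read a tab-delimited phenotype table into sample records.

    Required columns: ``sample_id``, ``dataset_id``, ``family_id``, ``sex``,
    ``ad_status``, ``age_onset``, ``age_censor``; optional: ``pc1``..``pc5``,
    ``cohort``, ``apoe_genotype``.  Raises on duplicated sample ids and on
    cases lacking an onset age.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", "."])
    required = {"sample_id", "dataset_id", "family_id", "sex", "ad_status"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ValueError(f"phenotype table lacks columns: {sorted(missing_cols)}")
    dupes = df["sample_id"][df["sample_id"].duplicated()]
    if len(dupes):
        raise ValueError(
            "duplicate sample ids in phenotype table: "
            + ", ".join(sorted(dupes.unique()))
        )
    pc_cols = [c for c in df.columns if c.startswith("pc")]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        ages = {
            k: (None if pd.isna(d.get(k)) else float(d[k])) for k in _PHENO_NUMERIC
        }
        pcs = tuple(float(d[c]) for c in pc_cols if not pd.isna(d[c]))
        records.append(
            SampleRecord(
                sample_id=d["sample_id"],
                dataset_id=d["dataset_id"],
                family_id=d["family_id"],
                sex=d["sex"],
                ad_status=d["ad_status"],
                age_onset=ages["age_onset"],
                age_censor=ages["age_censor"],
                pcs=pcs,
                cohort=d.get("cohort") if not pd.isna(d.get("cohort", np.nan)) else "",
                apoe_genotype=(
                    d.get("apoe_genotype")
                    if not pd.isna(d.get("apoe_genotype", np.nan))
                    else None
                ),
            )
        )
    return records


def attach_phenotypes(
    ds: GenotypeDataset, phenotypes: Sequence[SampleRecord]
) -> tuple[GenotypeDataset, list[str]]:
    """Join phenotype records onto a genotype dataset by sample id.

    Returns the dataset restricted to phenotyped samples plus the list of
    genotyped sample ids that had no phenotype record.
    """
    byid = {p.sample_id: p for p in phenotypes}
    matched = [s.sample_id for s in ds.samples if s.sample_id in byid]
    unmatched = [s.sample_id for s in ds.samples if s.sample_id not in byid]
    sub = ds.subset_samples(matched)
    sub.samples = [replace(byid[sid], dataset_id=ds.dataset_id) for sid in matched]
    sub._sindex = {s.sample_id: k for k, s in enumerate(sub.samples)}
    return sub, unmatched


def write_dosage_table(ds: GenotypeDataset, path: str | Path) -> None:
    df = pd.DataFrame(
        ds.dosages.astype(object), columns=ds.variant_ids, index=ds.sample_ids
    )
    df = df.where(df != MISSING, "NA")
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def write_variant_table(variants: Sequence[VariantRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref_allele": [v.ref_allele for v in variants],
            "alt_allele": [v.alt_allele for v in variants],
            "effect_allele": [v.effect_allele for v in variants],
            "eaf": [v.eaf if v.eaf is not None else "NA" for v in variants],
            "imputation_r2": [
                v.imputation_r2 if v.imputation_r2 is not None else "NA"
                for v in variants
            ],
        }
    ).to_csv(path, sep="\t", index=False)


def write_phenotype_table(samples: Sequence[SampleRecord], path: str | Path) -> None:
    n_pcs = max((len(s.pcs) for s in samples), default=0)
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "dataset_id": s.dataset_id,
            "family_id": s.family_id,
            "sex": s.sex,
            "ad_status": s.ad_status,
            "age_onset": s.age_onset if s.age_onset is not None else "NA",
            "age_censor": s.age_censor if s.age_censor is not None else "NA",
            "cohort": s.cohort or "NA",
        }
        for k in range(n_pcs):
            row[f"pc{k + 1}"] = s.pcs[k] if k < len(s.pcs) else "NA"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_vcf(ds: GenotypeDataset, path: str | Path) -> None:
    """Write hard calls as an uncompressed VCF v4.2 with GT fields only."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation r2">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dict.fromkeys(v.chrom for v in ds.variants)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.sample_ids)
            + "\n"
        )
        order = sorted(
            range(ds.n_variants),
            key=lambda k: (ds.variants[k].chrom, ds.variants[k].pos),
        )
        for k in order:
            v = ds.variants[k]
            # VCF genotypes count ALT alleles; flip if effect allele is REF
            col = ds.dosages[:, k]
            if v.effect_allele == v.ref_allele:
                col = np.where(col == MISSING, MISSING, 2 - col)
            info = "." if v.imputation_r2 is None else f"R2={v.imputation_r2:g}"
            gts = "\t".join(gt_map[int(g)] for g in col)
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref_allele}\t"
                f"{v.alt_allele}\t.\tPASS\t{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# QC statistics
# ---------------------------------------------------------------------------


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency from hard-call dosages (missing = -1 ignored)."""
    d = np.asarray(dosages)
    d = d[d != MISSING]
    if d.size == 0:
        raise ValueError("compute_maf: all dosages missing")
    p = float(d.sum()) / (2.0 * d.size)
    return min(p, 1.0 - p)


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "chisq") -> float:
    """Hardy-Weinberg equilibrium test p-value from genotype counts.

    ``method="chisq"`` (default) is the 1-df goodness-of-fit test against the
    p^2 / 2pq / q^2 expectations; ``method="exact"`` is the conditional exact
    test on the heterozygote count with the mid-p correction.  Monomorphic
    input returns 1.0 by convention.
    """
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("hwe_test: no subjects")
    n_a = 2 * n_aa + n_Aa  # minor-allele count if a is minor; symmetric anyway
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    if method == "chisq":
        p = n_a / (2.0 * n)
        exp = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
        obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        return float(stats.chi2.sf(chi2, df=1))
    if method == "exact":
        return _hwe_exact_midp(n_AA, n_Aa, n_aa)
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_exact_midp(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE test conditional on allele counts, mid-p variant."""
    n = n_AA + n_Aa + n_aa
    n_a = 2 * n_aa + n_Aa
    n_a = min(n_a, 2 * n - n_a)
    het_obs = n_Aa
    hets = np.arange(n_a % 2, n_a + 1, 2)
    # log probability of each possible heterozygote count given allele counts
    from scipy.special import gammaln

    n_A = 2 * n - n_a

    def logprob(h):
        rare_hom = (n_a - h) // 2
        com_hom = (n_A - h) // 2
        return (
            h * math.log(2)
            + gammaln(n + 1)
            - gammaln(rare_hom + 1)
            - gammaln(h + 1)
            - gammaln(com_hom + 1)
            - (gammaln(2 * n + 1) - gammaln(n_a + 1) - gammaln(n_A + 1))
        )

    logp = np.array([logprob(int(h)) for h in hets])
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    p_obs = prob[hets == het_obs][0]
    p = prob[prob <= p_obs + 1e-12].sum() - 0.5 * p_obs
    return float(min(1.0, max(p, np.nextafter(0, 1))))


def apply_qc(
    ds: GenotypeDataset,
    cfg: QCConfig | None = None,
    exempt: set[str] | None = None,
) -> tuple[GenotypeDataset, QCReport]:
    """Apply variant/sample QC filters in a fixed order.

    Order: (1) imputed variants with r^2 below threshold; (2) variants, then
    samples, with missing rate above threshold; (3) variants with MAF below
    threshold; (4) variants failing Hardy-Weinberg.  The order is part of the
    contract — missingness interacts with MAF, so filter order matters.

    ``exempt`` variant ids (e.g. the two APOE anchor SNPs, which are
    deliberately monomorphic within an ε-negative stratum) bypass all
    variant-level filters.
    """
    cfg = cfg or QCConfig()
    exempt = exempt or set()
    report = QCReport()

    def _keep(keep: np.ndarray, variants) -> np.ndarray:
        return keep | np.array([v.variant_id in exempt for v in variants])

    # rule 1: imputation quality
    keep = np.array(
        [
            v.imputation_r2 is None or v.imputation_r2 >= cfg.min_imputation_r2
            for v in ds.variants
        ]
    )
    keep = _keep(keep, ds.variants)
    for v, k in zip(ds.variants, keep):
        if not k:
            report.dropped_variants[v.variant_id] = "imputation_r2"
    report.n_variants_imputation = int((~keep).sum())
    ds = ds.subset_variants(keep)

    # rule 2a: variant missing rate
    miss = (ds.dosages == MISSING).mean(axis=0)
    keep = _keep(miss <= cfg.max_missing_rate, ds.variants)
    for v, k in zip(ds.variants, keep):
        if not k:
            report.dropped_variants[v.variant_id] = "missing_rate"
    report.n_variants_missing = int((~keep).sum())
    ds = ds.subset_variants(keep)

    # rule 2b: sample missing rate
    if ds.n_variants:
        smiss = (ds.dosages == MISSING).mean(axis=1)
        keep_s = smiss <= cfg.max_missing_rate
        report.dropped_samples = [
            s.sample_id for s, k in zip(ds.samples, keep_s) if not k
        ]
        report.n_samples_missing = int((~keep_s).sum())
        ds = ds.subset_samples(keep_s)

    # rule 3: MAF
    mafs = []
    for j in range(ds.n_variants):
        col = ds.dosages[:, j]
        col = col[col != MISSING]
        mafs.append(compute_maf(col) if col.size else 0.0)
    keep = _keep(np.array([m >= cfg.min_maf for m in mafs]), ds.variants)
    for v, k in zip(ds.variants, keep):
        if not k:
            report.dropped_variants[v.variant_id] = "maf"
    report.n_variants_maf = int((~keep).sum())
    ds = ds.subset_variants(keep)

    # rule 4: HWE
    keep = np.ones(ds.n_variants, dtype=bool)
    for j in range(ds.n_variants):
        if ds.variants[j].variant_id in exempt:
            continue
        col = ds.dosages[:, j]
        col = col[col != MISSING]
        p = hwe_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
        if p < cfg.hwe_p_floor:
            keep[j] = False
            report.dropped_variants[ds.variants[j].variant_id] = "hwe"
    report.n_variants_hwe = int((~keep).sum())
    ds = ds.subset_variants(keep)

    if ds.n_variants == 0 or ds.n_samples == 0:
        raise ValueError("apply_qc: dataset empty after filtering")
    return ds, report
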