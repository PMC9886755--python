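"""Compound-genotype coding and proportional-hazards age-at-onset models.

A compound genotype (CompG) crosses the anchor APOE SNP's genotype with a
partner SNP's genotype into four levels:

========  ==============  ===============
anchor    partner SNP     level
========  ==============  ===============
0         0               CompG1 (reference)
0         1 or 2          CompG2
1 or 2    0               CompG3
1 or 2    1 or 2          CompG4
========  ==============  ===============

CompG2 isolates the partner SNP's minor allele from the ε allele, CompG3
isolates the ε allele, and CompG4 carries both; all share the CompG1
reference, so the CompG3-vs-CompG4 contrast measures how the partner SNP's
minor allele modulates the ε allele's effect on AD risk.

Fits use the Cox partial likelihood with Efron tie handling (onset ages in
integer years are heavily tied).  Family clustering is absorbed through a
cluster-robust (sandwich) variance by family id; the point estimates equal
the independence fit, which is exact when the between-family frailty
variance is zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import MISSING, GenotypeDataset

logger = logging.getLogger(__name__)

COMPG_LEVELS = ("CompG1", "CompG2", "CompG3", "CompG4")

__all__ = [
    "COMPG_LEVELS",
    "CoxFit",
    "compg_code",
    "build_frame",
    "fit_cox",
    "contrast_chi2",
]


def compg_code(anchor_dosage: int, snp_dosage: int) -> str:
    """Map an (anchor, partner SNP) dosage pair to its CompG level."""
    if anchor_dosage == MISSING or snp_dosage == MISSING:
        raise ValueError("compg_code: missing dosage")
    if anchor_dosage not in (0, 1, 2) or snp_dosage not in (0, 1, 2):
        raise ValueError("compg_code: dosages must be in {0,1,2}")
    if anchor_dosage == 0:
        return "CompG1" if snp_dosage == 0 else "CompG2"
    return "CompG3" if snp_dosage == 0 else "CompG4"


@dataclass
class CoxFit:
    """Cox model estimates for CompG2/3/4 vs the CompG1 reference."""

    betas: dict[str, float]  # level -> log hazard ratio
    ses: dict[str, float]
    pvalues: dict[str, float]
    covariates: dict[str, float] = field(default_factory=dict)
    n: int = 0
    n_events: int = 0
    converged: bool = False
    cluster_robust: bool = False
    frailty_variance: float | None = None
    level_counts: dict[str, int] = field(default_factory=dict)


def build_frame(
    ds: GenotypeDataset,
    anchor: str,
    variant_id: str,
) -> pd.DataFrame:
    """Per-subject survival frame for one anchor/partner pair.

    ``ds`` must already be restricted to the anchor's ε-negative stratum
    (both AD and NAD subjects).  AD cases contribute (age at onset,
    event=1); NAD subjects contribute (censoring age, event=0).  Subjects
    missing either dosage are excluded with a logged reason.
    """
    a = ds.dosage_vector(anchor)
    v = ds.dosage_vector(variant_id)
    rows = []
    for s, da, dv in zip(ds.samples, a, v):
        if da == MISSING or dv == MISSING:
            logger.info("excluding %s: missing dosage for CompG", s.sample_id)
            continue
        row = {
            "sample_id": s.sample_id,
            "time": float(s.time),
            "event": s.event,
            "compg": compg_code(int(da), int(dv)),
            "sex": 1.0 if s.sex == "male" else 0.0,
            "family_id": s.family_id,
            "dataset_id": s.dataset_id,
            "cohort": s.cohort or "",
        }
        for k in range(5):
            row[f"pc{k + 1}"] = s.pcs[k] if k < len(s.pcs) else 0.0
        rows.append(row)
    if not rows:
        raise ValueError(f"build_frame: no usable subjects for {variant_id}")
    frame = pd.DataFrame(rows)
    counts = frame["compg"].value_counts()
    for level in COMPG_LEVELS:
        if counts.get(level, 0) == 0:
            logger.warning("%s: CompG level %s has zero subjects", variant_id, level)
    return frame


def fit_cox(
    frame: pd.DataFrame,
    use_frailty: bool = True,
    covariates: tuple[str, ...] = ("sex", "pc1", "pc2", "pc3", "pc4", "pc5"),
) -> CoxFit:
    """Fit the Cox model of AD onset on CompG indicators plus covariates.

    CompG2/3/4 enter as indicators against the CompG1 reference; sex and
    the top five principal components are fixed effects, plus cohort
    dummies when the frame has more than one cohort.  With ``use_frailty``
    and any multi-member family present, within-family correlation is
    handled by a cluster-robust variance with family id as the cluster
    (point estimates are the independence estimates); ``cluster_robust``
    is flagged in the result.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    counts = frame["compg"].value_counts()
    if counts.get("CompG1", 0) == 0:
        raise ValueError("fit_cox: CompG1 (reference) level is empty")
    present = [lv for lv in COMPG_LEVELS[1:] if counts.get(lv, 0) > 0]
    if not present:
        raise ValueError("fit_cox: fewer than 2 populated CompG levels")
    if int(frame["event"].sum()) < len(present) + len(covariates):
        raise ValueError("fit_cox: fewer events than parameters")

    df = frame.copy()
    cols = []
    for lv in present:
        df[lv] = (df["compg"] == lv).astype(float)
        cols.append(lv)
    for c in covariates:
        if c in df.columns and df[c].nunique() > 1:
            cols.append(c)
    cohorts = sorted(df["cohort"].unique())
    if len(cohorts) > 1:
        for c in cohorts[1:]:
            name = f"cohort_{c}"
            df[name] = (df["cohort"] == c).astype(float)
            cols.append(name)

    families = df["family_id"]
    clustered = bool(use_frailty and families.duplicated().any())
    fit_cols = ["time", "event"] + cols + (["family_id"] if clustered else [])

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df[fit_cols],
                duration_col="time",
                event_col="event",
                cluster_col="family_id" if clustered else None,
                robust=clustered,
            )
    except ConvergenceError as exc:
        msg = str(exc)
        if "complete separation" in msg or "monotone" in msg.lower():
            raise RuntimeError(
                "fit_cox: monotone partial likelihood (complete separation); "
                "consider a Firth-style penalized fit"
            ) from exc
        raise RuntimeError(f"fit_cox: Cox model did not converge: {msg}") from exc

    summary = cph.summary
    betas, ses, pvals = {}, {}, {}
    for lv in present:
        betas[lv] = float(summary.loc[lv, "coef"])
        ses[lv] = float(summary.loc[lv, "se(coef)"])
        pvals[lv] = float(summary.loc[lv, "p"])
    covs = {
        c: float(summary.loc[c, "coef"]) for c in cols if c not in present
    }
    return CoxFit(
        betas=betas,
        ses=ses,
        pvalues=pvals,
        covariates=covs,
        n=len(df),
        n_events=int(df["event"].sum()),
        converged=True,
        cluster_robust=clustered,
        frailty_variance=None,
        level_counts={lv: int(counts.get(lv, 0)) for lv in COMPG_LEVELS},
    )


def contrast_chi2(
    b3: float, se3: float, b4: float, se4: float
) -> tuple[float, float, float]:
    """1-df chi-square contrast of the CompG3 and CompG4 effects.

    ``chi2 = (b3 - b4)^2 / (se3^2 + se4^2)``; ``abs_diff = |b4| - |b3|``
    (the change in effect magnitude when the partner SNP's minor allele
    joins the ε allele).
    """
    if se3 <= 0 or se4 <= 0:
        raise ValueError("contrast_chi2: standard errors must be positive")
    chi2 = (b3 - b4) ** 2 / (se3**2 + se4**2)
    p = float(stats.chi2.sf(chi2, df=1))
    abs_diff = abs(b4) - abs(b3)
    return float(chi2), p, float(abs_diff)
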