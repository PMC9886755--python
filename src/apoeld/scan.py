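"""Genome scan for LD with an APOE anchor SNP and the group-specific test.

Stage 1 screens every variant for LD with the anchor (rs7412 in the
ε4-negative stratum, rs429358 in the ε2-negative stratum), separately in
the AD and NAD groups, per dataset and in the pooled sample.  Hits are kept
either by a discovery–replication rule (suggestive significance in one
dataset, Bonferroni-adjusted replication in another) or by suggestive
significance in the pooled sample.

Stage 2 asks whether a stage-1 SNP's LD differs between the AD and NAD
groups: Δr = r_AD − r_NAD, with significance from a permutation test that
reshuffles AD/NAD labels (within dataset by default, preserving per-dataset
group sizes) and recomputes Δr from group-wise EM haplotype frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MISSING, GenotypeDataset
from .ld import (
    em_hapfreqs_batch,
    r_from_freqs_batch,
    tabulate_counts_matrix,
)
from .strata import build_strata, stratum_dataset

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenThresholds",
    "Stage1Hit",
    "DeltaRResult",
    "stage1_scan",
    "classify_stage1",
    "delta_r_permutation",
    "stage2_select",
]


@dataclass(frozen=True)
class ScreenThresholds:
    """Multi-stage screening p-value thresholds.

    ``replication_p`` is 0.05/4 — Bonferroni over the four potential
    replication datasets.
    """

    genomewide_p: float = 5e-8
    suggestive_p: float = 5e-6
    replication_p: float = 0.0125
    stage2_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not self.genomewide_p < self.suggestive_p < self.replication_p:
            raise ValueError("thresholds must satisfy genomewide < suggestive < replication")


@dataclass
class Stage1Hit:
    variant_id: str
    set_label: str  # "replication" | "pooled"
    group: str  # "AD" | "NAD" | "both"
    per_dataset: dict[str, dict] = field(default_factory=dict)
    pooled: dict | None = None


@dataclass(frozen=True)
class DeltaRResult:
    r_AD: float
    r_NAD: float
    delta: float
    B: int
    p_perm: float
    seed: int
    n_redrawn: int = 0


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------


def _group_counts(
    ds: GenotypeDataset, anchor: str, group_ids: set[str], variant_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    """(n_variants, 9) anchor-vs-variant counts over one group's subjects."""
    sub = ds.subset_samples(group_ids)
    a = sub.dosage_vector(anchor)
    cols = [sub._vindex[v] for v in variant_ids]
    mat = sub.dosages[:, cols]
    counts = tabulate_counts_matrix(a, mat)
    return counts, counts.sum(axis=1)


def _ld_rows(counts: np.ndarray) -> pd.DataFrame:
    """LD statistics for a batch of count tables (NaN-safe)."""
    from scipy import stats as sps

    p, ll, it, cv = em_hapfreqs_batch(counts)
    r = r_from_freqs_batch(p)
    n = counts.sum(axis=1)
    chi2 = r * r * n
    with np.errstate(invalid="ignore"):
        pval = sps.chi2.sf(chi2, df=1)
    return pd.DataFrame(
        {"r": r, "chi2": chi2, "p": pval, "n": n, "converged": cv}
    )


def stage1_scan(
    datasets: list[GenotypeDataset],
    anchor: str,
    group: str,
) -> pd.DataFrame:
    """LD of every non-anchor variant with the anchor, per dataset + pooled.

    Subjects are restricted to the anchor's ε-negative stratum and the
    requested AD/NAD group.  Pooling concatenates subjects, which for the
    9-cell tables is simply the sum of per-dataset counts; variants absent
    from a dataset contribute nothing to the pool.

    Returns a tidy frame with columns ``variant_id, chrom, pos, dataset,
    group, r, chi2, p, n, converged``; ``dataset == "pooled"`` rows carry
    the combined estimate.
    """
    if not datasets:
        raise ValueError("stage1_scan: no datasets")
    if group not in ("AD", "NAD"):
        raise ValueError("group must be AD or NAD")
    # union of scannable variants (everything but the two APOE SNPs)
    meta: dict[str, tuple[str, int]] = {}
    for ds in datasets:
        if not ds.has_variant(anchor):
            raise ValueError(f"dataset {ds.dataset_id} lacks anchor {anchor}")
        for v in ds.variants:
            if v.variant_id not in ("rs7412", "rs429358"):
                meta.setdefault(v.variant_id, (v.chrom, v.pos))
    all_vids = sorted(meta, key=lambda v: (meta[v][0], meta[v][1]))

    rows = []
    pooled_counts = np.zeros((len(all_vids), 9), dtype=np.int64)
    pooled_seen = np.zeros(len(all_vids), dtype=bool)
    vid_pos = {v: k for k, v in enumerate(all_vids)}
    for ds in datasets:
        ad, nad = build_strata(ds, anchor)
        ids = (ad if group == "AD" else nad).sample_ids
        present = [v for v in all_vids if ds.has_variant(v)]
        counts, n = _group_counts(ds, anchor, ids, present)
        # anchor must be polymorphic within the stratum group
        pA = (
            counts.reshape(-1, 3, 3).sum(axis=2) * np.array([0.0, 1.0, 2.0])
        ).sum(axis=1) / (2 * np.maximum(n, 1))
        if counts.shape[0] and not ((pA > 0) & (pA < 1)).any():
            raise ValueError(
                f"anchor {anchor} monomorphic in {ds.dataset_id} {group} stratum"
            )
        stats_df = _ld_rows(counts)
        stats_df.insert(0, "variant_id", present)
        stats_df.insert(1, "dataset", ds.dataset_id)
        rows.append(stats_df)
        idx = np.array([vid_pos[v] for v in present])
        pooled_counts[idx] += counts
        pooled_seen[idx] = True

    pooled_df = _ld_rows(pooled_counts[pooled_seen])
    pooled_df.insert(0, "variant_id", list(np.array(all_vids)[pooled_seen]))
    pooled_df.insert(1, "dataset", "pooled")
    rows.append(pooled_df)

    out = pd.concat(rows, ignore_index=True)
    out.insert(1, "chrom", [meta[v][0] for v in out["variant_id"]])
    out.insert(2, "pos", [meta[v][1] for v in out["variant_id"]])
    out.insert(3, "group", group)
    return out


def classify_stage1(
    scan: pd.DataFrame, th: ScreenThresholds | None = None
) -> list[Stage1Hit]:
    """Select stage-1 hits from a scan table (AD and/or NAD rows).

    Replication set: p below the suggestive threshold in any single dataset
    (discovery) and below the replication threshold in at least one other
    dataset.  Pooled set: pooled p below the suggestive threshold, excluding
    variants already in the replication set.  A variant qualifying in both
    AD and NAD scans is recorded once with ``group="both"``.
    """
    th = th or ScreenThresholds()
    hits: dict[str, Stage1Hit] = {}
    for (vid, group), sub in scan.groupby(["variant_id", "group"], sort=True):
        per_ds = sub[sub["dataset"] != "pooled"].dropna(subset=["p"])
        pooled = sub[sub["dataset"] == "pooled"].dropna(subset=["p"])
        label = None
        pvals = per_ds.set_index("dataset")["p"]
        discovery = pvals[pvals < th.suggestive_p]
        for d in discovery.index:
            others = pvals.drop(d)
            if (others < th.replication_p).any():
                label = "replication"
                break
        if label is None and len(pooled) and pooled["p"].iloc[0] < th.suggestive_p:
            label = "pooled"
        if label is None:
            continue
        record = {
            r.dataset: {"r": r.r, "chi2": r.chi2, "p": r.p, "n": int(r.n)}
            for r in per_ds.itertuples()
        }
        pooled_rec = (
            {
                "r": pooled["r"].iloc[0],
                "chi2": pooled["chi2"].iloc[0],
                "p": pooled["p"].iloc[0],
                "n": int(pooled["n"].iloc[0]),
            }
            if len(pooled)
            else None
        )
        if vid in hits:
            prev = hits[vid]
            if prev.group != group:
                prev.group = "both"
            # replication membership dominates the pooled label
            if label == "replication":
                prev.set_label = "replication"
        else:
            hits[vid] = Stage1Hit(
                variant_id=vid,
                set_label=label,
                group=group,
                per_dataset=record,
                pooled=pooled_rec,
            )
    return sorted(hits.values(), key=lambda h: h.variant_id)


# ---------------------------------------------------------------------------
# Stage 2: Δr permutation test
# ---------------------------------------------------------------------------


def _cells_by_dataset(
    anchor_dos: np.ndarray, var_dos: np.ndarray, dataset: np.ndarray
) -> tuple[list[np.ndarray], np.ndarray]:
    ok = (anchor_dos != MISSING) & (var_dos != MISSING)
    code = 3 * anchor_dos[ok].astype(np.int64) + var_dos[ok]
    ds = np.asarray(dataset)[ok]
    labels = np.unique(ds)
    per = [np.bincount(code[ds == d], minlength=9) for d in labels]
    return per, labels


def _r_of_counts(counts: np.ndarray) -> float:
    p, _, _, _ = em_hapfreqs_batch(counts[None, :])
    r = r_from_freqs_batch(p)[0]
    return float(r)


def delta_r_permutation(
    ad: tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray],
    nad: tuple[np.ndarray, np.ndarray] | tuple[np.ndarray, np.ndarray, np.ndarray],
    B_max: int = 1_000_000,
    seed: int = 0,
    alpha: float | None = None,
    within_dataset: bool = True,
    block_size: int = 2000,
) -> DeltaRResult:
    """Permutation test of Δr = r_AD − r_NAD for one anchor/variant pair.

    ``ad`` and ``nad`` are per-group tuples ``(anchor dosages, variant
    dosages[, dataset labels])``, as returned by :func:`group_pair_arrays`.

    The null is built by reshuffling AD/NAD labels — within each dataset
    when ``within_dataset`` (the default, preserving per-dataset group
    sizes), or over the pooled sample otherwise.  Label permutation only
    moves subjects between the two groups' 9-cell genotype tables, so each
    replicate is drawn directly as a multivariate hypergeometric split of
    the per-dataset cell counts; group-wise EM then yields Δr*.

    The two-sided p-value is ``(1 + #{|Δr*| >= |Δr_obs|}) / (B + 1)``.
    When ``alpha`` is given, permutation proceeds in blocks with adaptive
    early stopping once a 99.99% Clopper–Pearson interval for the
    exceedance probability excludes ``alpha``; otherwise exactly ``B_max``
    permutations are used.  Replicates in which a permuted group goes
    monomorphic (EM undefined) are redrawn and counted.
    """
    anchor_ad, var_ad = np.asarray(ad[0]), np.asarray(ad[1])
    anchor_nad, var_nad = np.asarray(nad[0]), np.asarray(nad[1])
    dataset_ad = np.asarray(ad[2]) if len(ad) > 2 else None
    dataset_nad = np.asarray(nad[2]) if len(nad) > 2 else None
    if anchor_ad.size == 0 or anchor_nad.size == 0:
        raise ValueError("delta_r_permutation: empty group")
    if dataset_ad is None or not within_dataset:
        dataset_ad = np.zeros(anchor_ad.shape[0], dtype=np.int64)
    if dataset_nad is None or not within_dataset:
        dataset_nad = np.zeros(anchor_nad.shape[0], dtype=np.int64)

    per_ad, labels_ad = _cells_by_dataset(anchor_ad, var_ad, dataset_ad)
    per_nad, labels_nad = _cells_by_dataset(anchor_nad, var_nad, dataset_nad)
    labels = sorted(set(labels_ad.tolist()) | set(labels_nad.tolist()))
    ad_by = dict(zip(labels_ad.tolist(), per_ad))
    nad_by = dict(zip(labels_nad.tolist(), per_nad))
    totals = []
    n_ad_per = []
    for d in labels:
        a = ad_by.get(d, np.zeros(9, dtype=np.int64))
        b = nad_by.get(d, np.zeros(9, dtype=np.int64))
        totals.append(a + b)
        n_ad_per.append(int(a.sum()))
    totals = [t.astype(np.int64) for t in totals]

    obs_ad = sum(ad_by.values())
    obs_nad = sum(nad_by.values())
    r_ad = _r_of_counts(obs_ad)
    r_nad = _r_of_counts(obs_nad)
    if not (np.isfinite(r_ad) and np.isfinite(r_nad)):
        raise ValueError("delta_r_permutation: variant monomorphic in a group")
    delta_obs = r_ad - r_nad

    rng = np.random.default_rng(seed)
    total_all = sum(totals)
    exceed = 0
    done = 0
    redrawn = 0
    while done < B_max:
        b = min(block_size, B_max - done)
        ad_counts = np.zeros((b, 9), dtype=np.int64)
        for t, n_ad in zip(totals, n_ad_per):
            ad_counts += rng.multivariate_hypergeometric(t, n_ad, size=b)
        nad_counts = total_all[None, :] - ad_counts
        p_ad, _, _, _ = em_hapfreqs_batch(ad_counts)
        p_nad, _, _, _ = em_hapfreqs_batch(nad_counts)
        deltas = r_from_freqs_batch(p_ad) - r_from_freqs_batch(p_nad)
        bad = ~np.isfinite(deltas)
        while bad.any():
            # degenerate splits (a permuted group went monomorphic): redraw
            nb = int(bad.sum())
            redrawn += nb
            logger.info("redrawing %d degenerate permutation replicates", nb)
            repl = np.zeros((nb, 9), dtype=np.int64)
            for t, n_ad in zip(totals, n_ad_per):
                repl += rng.multivariate_hypergeometric(t, n_ad, size=nb)
            p_ad, _, _, _ = em_hapfreqs_batch(repl)
            p_nad, _, _, _ = em_hapfreqs_batch(total_all[None, :] - repl)
            new = r_from_freqs_batch(p_ad) - r_from_freqs_batch(p_nad)
            deltas[bad] = new
            bad = ~np.isfinite(deltas)
        exceed += int((np.abs(deltas) >= abs(delta_obs) - 1e-12).sum())
        done += b
        if alpha is not None and done >= 200:
            from scipy.stats import beta as beta_dist

            lo = (
                beta_dist.ppf(5e-5, exceed, done - exceed + 1) if exceed > 0 else 0.0
            )
            hi = (
                beta_dist.ppf(1 - 5e-5, exceed + 1, done - exceed)
                if exceed < done
                else 1.0
            )
            if hi < alpha or lo > alpha:
                break
    p_perm = (1 + exceed) / (done + 1)
    return DeltaRResult(
        r_AD=r_ad,
        r_NAD=r_nad,
        delta=delta_obs,
        B=done,
        p_perm=p_perm,
        seed=seed,
        n_redrawn=redrawn,
    )


def stage2_select(
    results: dict[str, DeltaRResult], m: int, alpha: float = 0.05
) -> list[str]:
    """Variants whose permutation p beats the Bonferroni threshold alpha/m.

    ``m`` is the number of stage-1 SNPs tested for this anchor; selection
    uses a strict inequality, so p exactly at the threshold is excluded.
    """
    if m < 1:
        raise ValueError("stage2_select: m must be >= 1")
    thr = alpha / m
    return sorted(v for v, res in results.items() if res.p_perm < thr)


def group_pair_arrays(
    datasets: list[GenotypeDataset], anchor: str, variant_id: str
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Pooled per-group (anchor dosages, variant dosages, dataset labels)
    for the anchor's stratum, ready for :func:`delta_r_permutation`."""
    out: dict[str, list] = {"AD": [[], [], []], "NAD": [[], [], []]}
    for ds in datasets:
        if not ds.has_variant(variant_id):
            continue
        ad, nad = build_strata(ds, anchor)
        for group, stratum in (("AD", ad), ("NAD", nad)):
            sub = stratum_dataset(ds, stratum)
            out[group][0].append(sub.dosage_vector(anchor))
            out[group][1].append(sub.dosage_vector(variant_id))
            out[group][2].append(np.repeat(ds.dataset_id, sub.n_samples))
    return {
        g: (
            np.concatenate(v[0]),
            np.concatenate(v[1]),
            np.concatenate(v[2]),
        )
        for g, v in out.items()
    }
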