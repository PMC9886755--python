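"""Two-locus haplotype-frequency EM and linkage-disequilibrium statistics.

Unphased genotypes leave only the double heterozygote phase-ambiguous: a
subject with dosage (1, 1) carries either the cis pair (minor,minor) +
(major,major) or the trans pair (minor,major) + (major,minor).  The EM
algorithm splits that cell between the two phase configurations in
proportion to ``2*p11*p00`` vs ``2*p10*p01`` (E-step) and re-estimates the
four haplotype frequencies from expected haplotype counts (M-step),
maximizing the 9-cell genotype multinomial likelihood under random mating.

LD is summarized by ``D = p11 - pA*pB`` and the correlation
``r = D / sqrt(pA(1-pA) pB(1-pB))`` between the minor (effect) alleles.
Significance uses the conservative test ``chi2 = r^2 * n`` with *n* the
number of subjects — not 2n gametes — acknowledging the phase uncertainty;
``var(r)`` is a delta-method variance used only for confidence intervals.

All estimation routines have a batch form operating on ``(B, 9)`` count
arrays; the scalar API wraps the batch one so both share a single code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import xlogy

from .data import MISSING

EM_TOL = 1e-10
EM_MAX_ITER = 1000

__all__ = [
    "GenotypeCounts9",
    "HapFreqs",
    "LDResult",
    "tabulate_counts",
    "tabulate_counts_matrix",
    "em_hapfreqs",
    "em_hapfreqs_batch",
    "ld_from_hapfreqs",
    "ld_pair",
    "r_from_freqs_batch",
    "r_variance",
]


@dataclass(frozen=True)
class GenotypeCounts9:
    """3x3 table of subjects by dosage at two SNPs (rows: SNP-1 dosage)."""

    counts: np.ndarray  # shape (3, 3), int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("counts must be a non-negative 3x3 table")
        if c.sum() < 1:
            raise ValueError("counts must include at least one subject")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def flat(self) -> np.ndarray:
        return self.counts.reshape(9)


@dataclass(frozen=True)
class HapFreqs:
    """ML two-locus haplotype frequencies.

    ``p11``: (minor, minor); ``p10``: (minor at SNP-1, major at SNP-2);
    ``p01``: (major, minor); ``p00``: (major, major).
    """

    p11: float
    p10: float
    p01: float
    p00: float
    loglik: float
    iterations: int
    converged: bool

    def __post_init__(self) -> None:
        total = self.p11 + self.p10 + self.p01 + self.p00
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"haplotype frequencies sum to {total}, not 1")

    @property
    def pA(self) -> float:
        """Minor-allele frequency at SNP-1."""
        return self.p11 + self.p10

    @property
    def pB(self) -> float:
        """Minor-allele frequency at SNP-2."""
        return self.p11 + self.p01


@dataclass(frozen=True)
class LDResult:
    D: float
    r: float
    var_r: float  # NaN until r_variance fills it in
    chi2: float
    p: float
    n: int


def tabulate_counts(dosages1: np.ndarray, dosages2: np.ndarray) -> GenotypeCounts9:
    """Cross-tabulate two dosage vectors over pairwise-complete subjects."""
    d1 = np.asarray(dosages1)
    d2 = np.asarray(dosages2)
    if d1.shape != d2.shape:
        raise ValueError("dosage vectors differ in length")
    ok = (d1 != MISSING) & (d2 != MISSING)
    if not ok.any():
        raise ValueError("no pairwise-complete subjects")
    flat = np.bincount(3 * d1[ok].astype(np.int64) + d2[ok], minlength=9)
    return GenotypeCounts9(flat.reshape(3, 3))


def tabulate_counts_matrix(anchor: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """9-cell counts of an anchor vector against every column of a matrix.

    Returns an ``(n_variants, 9)`` int array; cell index is
    ``3 * anchor_dosage + variant_dosage``.  Pairs with a missing value on
    either side are dropped per variant.
    """
    a = np.asarray(anchor, dtype=np.int64)
    m = np.asarray(mat, dtype=np.int64)
    if m.ndim != 2 or m.shape[0] != a.shape[0]:
        raise ValueError("matrix rows must match anchor length")
    nv = m.shape[1]
    valid = (a[:, None] != MISSING) & (m != MISSING)
    code = (3 * a[:, None] + m) + 9 * np.arange(nv)[None, :]
    flat = np.bincount(code[valid], minlength=9 * nv)
    return flat.reshape(nv, 9)


# ---------------------------------------------------------------------------
# EM core (batch)
# ---------------------------------------------------------------------------

# Haplotype composition of each unambiguous genotype cell, flattened as
# 3*i + j.  Cell 4 (the double heterozygote) is handled separately.
_CELL_HAPS = {
    0: ("00", "00"),
    1: ("00", "01"),
    2: ("01", "01"),
    3: ("00", "10"),
    5: ("11", "01"),
    6: ("10", "10"),
    7: ("11", "10"),
    8: ("11", "11"),
}


def _fixed_hap_counts(counts: np.ndarray) -> np.ndarray:
    """Haplotype counts contributed by phase-unambiguous cells.

    ``counts``: (B, 9).  Returns (B, 4) in order (p11, p10, p01, p00).
    """
    c = counts
    h11 = 2 * c[:, 8] + c[:, 7] + c[:, 5]
    h10 = 2 * c[:, 6] + c[:, 7] + c[:, 3]
    h01 = 2 * c[:, 2] + c[:, 5] + c[:, 1]
    h00 = 2 * c[:, 0] + c[:, 1] + c[:, 3]
    return np.stack([h11, h10, h01, h00], axis=1).astype(float)


def _loglik(counts: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Genotype multinomial log-likelihood (constant term dropped).

    ``counts``: (B, 9); ``p``: (B, 4) haplotype frequencies.
    """
    p11, p10, p01, p00 = p[:, 0], p[:, 1], p[:, 2], p[:, 3]
    cell = np.empty_like(counts, dtype=float)
    cell[:, 0] = p00**2
    cell[:, 1] = 2 * p00 * p01
    cell[:, 2] = p01**2
    cell[:, 3] = 2 * p00 * p10
    cell[:, 4] = 2 * p11 * p00 + 2 * p10 * p01
    cell[:, 5] = 2 * p11 * p01
    cell[:, 6] = p10**2
    cell[:, 7] = 2 * p11 * p10
    cell[:, 8] = p11**2
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = xlogy(counts, cell).sum(axis=1)
    return ll


def _marginals(counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = counts.sum(axis=1)
    row = counts.reshape(-1, 3, 3)
    pA = (row.sum(axis=2) * np.array([0.0, 1.0, 2.0])).sum(axis=1) / (2 * n)
    pB = (row.sum(axis=1) * np.array([0.0, 1.0, 2.0])).sum(axis=1) / (2 * n)
    return pA, pB


def _starts(pA: np.ndarray, pB: np.ndarray) -> list[np.ndarray]:
    """Equilibrium start plus near-extreme-D starts (escape the trans/cis
    saddle when double heterozygotes dominate)."""
    eq_p11 = pA * pB
    d_max = np.minimum(pA, pB) - pA * pB
    d_min = np.maximum(-pA * pB, -(1 - pA) * (1 - pB))
    out = []
    for p11 in (eq_p11, eq_p11 + 0.98 * d_max, eq_p11 + 0.98 * d_min):
        p10 = pA - p11
        p01 = pB - p11
        p00 = 1.0 - pA - pB + p11
        out.append(np.stack([p11, p10, p01, p00], axis=1))
    return out


def _em_one_start(
    counts: np.ndarray,
    p0: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Run EM from one start.  Returns (p, loglik, iterations, converged)."""
    fixed = _fixed_hap_counts(counts)
    n11 = counts[:, 4].astype(float)
    two_n = 2.0 * counts.sum(axis=1)
    p = np.clip(p0, 0.0, 1.0)
    p /= p.sum(axis=1, keepdims=True)
    iters = np.zeros(counts.shape[0], dtype=np.int64)
    active = np.ones(counts.shape[0], dtype=bool)
    for it in range(1, max_iter + 1):
        cis = p[:, 0] * p[:, 3]
        trans = p[:, 1] * p[:, 2]
        denom = cis + trans
        x = np.where(denom > 0, cis / np.where(denom > 0, denom, 1.0), 0.5)
        new = fixed.copy()
        new[:, 0] += x * n11
        new[:, 3] += x * n11
        new[:, 1] += (1.0 - x) * n11
        new[:, 2] += (1.0 - x) * n11
        new /= two_n[:, None]
        delta = np.abs(new - p).max(axis=1)
        p = np.where(active[:, None], new, p)
        iters[active] = it
        active = active & (delta >= tol)
        if not active.any():
            break
    converged = ~active
    ll = _loglik(counts, p)
    return p, ll, iters, converged


def em_hapfreqs_batch(
    counts: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Batch EM over many 9-cell tables.

    Parameters
    ----------
    counts
        ``(B, 9)`` array of genotype cell counts (flattened 3x3, row =
        SNP-1 dosage).

    Returns
    -------
    p, loglik, iterations, converged
        ``p`` is ``(B, 4)`` in order (p11, p10, p01, p00).  Tables
        monomorphic at either locus yield NaN frequencies.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    pA, pB = _marginals(counts)
    poly = (pA > 0) & (pA < 1) & (pB > 0) & (pB < 1)
    out_p = np.full((counts.shape[0], 4), np.nan)
    out_ll = np.full(counts.shape[0], np.nan)
    out_it = np.zeros(counts.shape[0], dtype=np.int64)
    out_cv = np.zeros(counts.shape[0], dtype=bool)
    if poly.any():
        sub = counts[poly]
        best = None
        for p0 in _starts(pA[poly], pB[poly]):
            res = _em_one_start(sub, p0, tol, max_iter)
            if best is None:
                best = list(res)
            else:
                better = res[1] > best[1] + 1e-12
                for k in range(4):
                    best[k] = np.where(
                        better[:, None] if best[k].ndim == 2 else better,
                        res[k],
                        best[k],
                    )
        out_p[poly] = best[0]
        out_ll[poly] = best[1]
        out_it[poly] = best[2]
        out_cv[poly] = best[3]
    return out_p, out_ll, out_it, out_cv


def em_hapfreqs(
    c: GenotypeCounts9,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> HapFreqs:
    """ML haplotype frequencies for one 9-cell genotype table.

    Multiple EM starts (equilibrium plus two near-extreme-|D| points) are
    run and the best log-likelihood wins.  Raises on tables monomorphic at
    either locus.
    """
    flat = c.flat[None, :]
    pA, pB = _marginals(flat)
    if not (0 < pA[0] < 1 and 0 < pB[0] < 1):
        raise ValueError("em_hapfreqs: monomorphic input")
    p, ll, it, cv = em_hapfreqs_batch(flat, tol=tol, max_iter=max_iter)
    return HapFreqs(
        p11=float(p[0, 0]),
        p10=float(p[0, 1]),
        p01=float(p[0, 2]),
        p00=float(p[0, 3]),
        loglik=float(ll[0]),
        iterations=int(it[0]),
        converged=bool(cv[0]),
    )


# ---------------------------------------------------------------------------
# LD statistics
# ---------------------------------------------------------------------------


def r_from_freqs_batch(p: np.ndarray) -> np.ndarray:
    """Correlation r from ``(B, 4)`` haplotype frequencies; NaN where a
    locus is monomorphic."""
    pA = p[:, 0] + p[:, 1]
    pB = p[:, 0] + p[:, 2]
    D = p[:, 0] - pA * pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, D / np.sqrt(np.where(denom > 0, denom, 1.0)), np.nan)


def ld_from_hapfreqs(h: HapFreqs, n: int) -> LDResult:
    """D, r and the conservative subject-count chi-square test.

    ``chi2 = r^2 * n`` with *n* subjects; p is the 1-df chi-square upper
    tail (a two-sided test of r = 0).
    """
    pA, pB = h.pA, h.pB
    if not (0 < pA < 1 and 0 < pB < 1):
        raise ValueError("ld_from_hapfreqs: monomorphic margin")
    D = h.p11 - pA * pB
    r = D / np.sqrt(pA * (1 - pA) * pB * (1 - pB))
    r = float(np.clip(r, -1.0, 1.0))
    chi2 = r * r * n
    p = float(stats.chi2.sf(chi2, df=1))
    return LDResult(D=float(D), r=r, var_r=float("nan"), chi2=chi2, p=p, n=int(n))


def ld_pair(
    dosages1: np.ndarray,
    dosages2: np.ndarray,
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> LDResult:
    """Convenience: tabulate, EM and LD statistics for one SNP pair."""
    c = tabulate_counts(dosages1, dosages2)
    h = em_hapfreqs(c, tol=tol, max_iter=max_iter)
    return ld_from_hapfreqs(h, c.n)


# ---------------------------------------------------------------------------
# asymptotic variance of r
# ---------------------------------------------------------------------------


def _theta_loglik(theta: np.ndarray, counts: np.ndarray) -> float:
    p = np.array([theta[0], theta[1], theta[2], 1.0 - theta.sum()])
    if (p < 0).any():
        return -np.inf
    return float(_loglik(counts[None, :], p[None, :])[0])


def _theta_r(theta: np.ndarray) -> float:
    p11, p10, p01 = theta
    pA = p11 + p10
    pB = p11 + p01
    return (p11 - pA * pB) / np.sqrt(pA * (1 - pA) * pB * (1 - pB))


def r_variance(
    h: HapFreqs,
    counts: GenotypeCounts9,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Delta-method variance of r from the observed Fisher information.

    The information matrix of the three free haplotype frequencies is the
    negative Hessian of the genotype multinomial log-likelihood at the EM
    estimate (central finite differences); the gradient of r is propagated
    through its inverse.  If the estimate sits on the simplex boundary or
    the information is singular, falls back to a seeded nonparametric
    bootstrap over subjects (``n_boot`` multinomial resamples of the 9-cell
    table, re-running EM on each).
    """
    theta = np.array([h.p11, h.p10, h.p01])
    flat = counts.flat.astype(np.int64)
    step = 1e-5
    on_boundary = (np.append(theta, 1.0 - theta.sum()) < 10 * step).any()
    if not on_boundary:
        hess = np.empty((3, 3))
        f0 = _theta_loglik(theta, flat)
        for i in range(3):
            for j in range(i, 3):
                ei = np.eye(3)[i] * step
                ej = np.eye(3)[j] * step
                fpp = _theta_loglik(theta + ei + ej, flat)
                fpm = _theta_loglik(theta + ei - ej, flat)
                fmp = _theta_loglik(theta - ei + ej, flat)
                fmm = _theta_loglik(theta - ei - ej, flat)
                hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * step**2)
        info = -hess
        grad = np.empty(3)
        for i in range(3):
            ei = np.eye(3)[i] * step
            grad[i] = (_theta_r(theta + ei) - _theta_r(theta - ei)) / (2 * step)
        try:
            cov = np.linalg.inv(info)
            var = float(grad @ cov @ grad)
            if np.isfinite(var) and var > 0 and np.isfinite(f0):
                return var
        except np.linalg.LinAlgError:
            pass
    # bootstrap fallback (boundary estimate or singular information)
    rng = np.random.default_rng(seed)
    n = counts.n
    probs = flat / n
    tables = rng.multinomial(n, probs, size=n_boot)
    p, _, _, _ = em_hapfreqs_batch(tables)
    rs = r_from_freqs_batch(p)
    rs = rs[np.isfinite(rs)]
    if rs.size < 2:
        raise ValueError("r_variance: bootstrap produced no usable replicates")
    return float(rs.var(ddof=1))
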