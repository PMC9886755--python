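"""Inverse-variance fixed-effect meta-analysis of per-dataset Cox effects.

The pooled estimate weights each dataset by the reciprocal of its squared
standard error:  beta = sum(w_i b_i)/sum(w_i),  se = 1/sqrt(sum(w_i)),
w_i = 1/se_i^2.  Cochran's Q and I^2 are reported for information but never
gate results.  Direction strings summarize per-dataset effect signs in a
fixed dataset order ('?' where a dataset is missing or unfit).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

#: dataset order used in direction strings
DATASET_ORDER = ("LOAD_FBS", "ADGC", "FHS", "CHS", "ADSP_WGS")

__all__ = [
    "DATASET_ORDER",
    "MetaResult",
    "meta_fixed",
    "direction_string",
    "bonferroni_classify",
]


@dataclass(frozen=True)
class MetaResult:
    beta_meta: float
    se_meta: float
    p: float
    k: int
    q: float  # Cochran's Q heterogeneity statistic
    i2: float  # I^2 in [0, 1]
    directions: str = ""


def meta_fixed(
    estimates: list[tuple[float, float]],
    directions: str = "",
) -> MetaResult:
    """Combine (beta, se) pairs by inverse-variance fixed-effect weighting."""
    if not estimates:
        raise ValueError("meta_fixed: no estimates")
    b = np.array([e[0] for e in estimates], dtype=float)
    s = np.array([e[1] for e in estimates], dtype=float)
    if (s <= 0).any():
        raise ValueError("meta_fixed: standard errors must be positive")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(1.0 / np.sqrt(w.sum()))
    z = beta / se
    p = float(2 * stats.norm.sf(abs(z)))
    q = float((w * (b - beta) ** 2).sum())
    k = len(estimates)
    i2 = max(0.0, (q - (k - 1)) / q) if k > 1 and q > 0 else 0.0
    return MetaResult(beta_meta=beta, se_meta=se, p=p, k=k, q=q, i2=i2,
                      directions=directions)


def direction_string(
    estimates: dict[str, float | None],
    order: tuple[str, ...] = DATASET_ORDER,
) -> str:
    """Per-dataset effect signs in the configured order.

    ``estimates`` maps dataset label to beta (``None``/absent -> '?').
    The output depends only on ``order``, never on input ordering.
    """
    out = []
    for d in order:
        b = estimates.get(d)
        if b is None or not np.isfinite(b):
            out.append("?")
        elif b > 0:
            out.append("+")
        elif b < 0:
            out.append("-")
        else:
            out.append("?")
    return "".join(out)


def bonferroni_classify(p: float, m: int, alpha: float = 0.05) -> str:
    """Classify a p-value against the Bonferroni level alpha/m.

    Returns ``"significant"`` (p < alpha/m), ``"nominal"``
    (alpha/m <= p < alpha) or ``"null"``.
    """
    if m < 1:
        raise ValueError("bonferroni_classify: m must be >= 1")
    if p < alpha / m:
        return "significant"
    if p < alpha:
        return "nominal"
    return "null"
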