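"""Rank-based tests implemented from their defining formulas.

One shared implementation serves every stage that compares distributions:
Mann-Whitney U (two groups), Kruskal-Wallis (more than two), Dunn's
post-hoc z tests with Bonferroni correction, and Spearman's rank
correlation.  All use midranks for ties and tie-corrected variances.

Conventions
-----------
* ``mann_whitney_u`` reports U for the *first* sample
  (U1 = R1 - n1(n1+1)/2); the complementary orientation is n1*n2 - U.
  The p-value uses the normal approximation with tie-corrected variance
  and a 0.5 continuity correction; an exact-enumeration p is available
  for small samples via ``method="exact"``.
* Dunn's z for groups i, j is (meanrank_i - meanrank_j) / SE with the
  pooled-midrank tie term, so the sign follows the group ordering given.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist


def _tie_term(pooled_ranks_source: np.ndarray) -> float:
    """Sum of (t^3 - t) over groups of tied values."""
    _, counts = np.unique(pooled_ranks_source, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def mann_whitney_u(x, y, method: str = "normal") -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns (U, p) with U computed for ``x``.  ``method="exact"`` switches
    to full enumeration of rank assignments (intended for n1 + n2 <= 20,
    no ties handled specially beyond midranks in the statistic).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    if method == "exact":
        if n1 + n2 > 20:
            raise ValueError("exact method supported for n1 + n2 <= 20")
        idx = np.arange(n1 + n2)
        devs = []
        mean_u = n1 * n2 / 2.0
        for chosen in combinations(idx, n1):
            u_perm = ranks[list(chosen)].sum() - n1 * (n1 + 1) / 2.0
            devs.append(abs(u_perm - mean_u))
        devs = np.asarray(devs)
        p = float(np.mean(devs >= abs(u - mean_u) - 1e-12))
        return float(u), min(1.0, p)

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie = _tie_term(pooled)
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1)))
    if var_u <= 0:
        return float(u), 1.0
    diff = u - mean_u
    if diff > 0:
        z = (diff - 0.5) / np.sqrt(var_u)
    elif diff < 0:
        z = (diff + 0.5) / np.sqrt(var_u)
    else:
        z = 0.0
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return float(u), float(p)


def _groups(values, labels):
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    names = sorted(pd.unique(labels).tolist())
    split = {g: values[labels == g] for g in names}
    for g, v in split.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    return values, labels, names, split


def kruskal_wallis(values, group_labels) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-squared (k-1 df) p-value."""
    values, labels, names, split = _groups(values, group_labels)
    if len(names) < 2:
        raise ValueError("Kruskal-Wallis requires at least 2 groups")
    n = values.size
    ranks = rankdata(values)
    h = 0.0
    for g in names:
        rg = ranks[labels == g]
        h += rg.sum() ** 2 / rg.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    tie = _tie_term(values)
    correction = 1.0 - tie / (n ** 3 - n)
    if correction <= 0:
        return 0.0, 1.0  # all values identical
    h /= correction
    p = float(chi2_dist.sf(h, df=len(names) - 1))
    return float(h), p


def dunn_posthoc(values, group_labels,
                 correction: str = "bonferroni") -> pd.DataFrame:
    """Pairwise Dunn z tests following a Kruskal-Wallis test.

    For groups i, j:  z = (meanrank_i - meanrank_j) / SE  with
    SE^2 = [N(N+1)/12 - sum(t^3 - t)/(12(N-1))] * (1/n_i + 1/n_j),
    midranks over the pooled sample.  Two-sided p = 2*(1 - Phi(|z|)),
    multiplied by C(k, 2) under Bonferroni correction and capped at 1.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    values, labels, names, split = _groups(values, group_labels)
    if len(names) < 2:
        raise ValueError("Dunn's test requires at least 2 groups")
    n = values.size
    ranks = rankdata(values)
    mean_ranks = {g: ranks[labels == g].mean() for g in names}
    sizes = {g: int((labels == g).sum()) for g in names}
    tie = _tie_term(values)
    base_var = n * (n + 1) / 12.0 - tie / (12.0 * (n - 1))
    k = len(names)
    multiplier = comb(k, 2) if correction == "bonferroni" else 1
    rows = []
    for gi, gj in combinations(names, 2):
        se = np.sqrt(base_var * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
        z = 0.0 if se == 0 else (mean_ranks[gi] - mean_ranks[gj]) / se
        p = min(1.0, 2.0 * norm.sf(abs(z)) * multiplier)
        rows.append({"group_i": gi, "group_j": gj, "z": float(z),
                     "p_corrected": float(p)})
    return pd.DataFrame(rows)


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman's rank correlation with a t-approximation p (n-2 df).

    Midranked Pearson correlation of the two rank vectors.  A constant
    vector makes rho undefined: returns (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return float("nan"), float("nan")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    n = x.size
    if abs(rho) >= 1.0:
        return float(np.sign(rho)), 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = float(min(1.0, 2.0 * t_dist.sf(abs(t), df=n - 2)))
    return rho, p
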