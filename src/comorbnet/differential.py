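"""Stratified case-control differential comorbidity analysis.

For every phenotype tested within a stratum a 2x2 contingency table is
formed (cases with/without, controls with/without).  Test selection
follows the small-cell rule: a two-sided Fisher's exact test when any
cell is below 5, otherwise a Pearson chi-squared test (1 df, no
continuity correction — small cells are already routed to Fisher).
Significance is a Bonferroni-corrected p below alpha, with the family
defined as the phenotypes tested within that stratum.

The two-sided Fisher p-value is the point-probability definition: the sum
of hypergeometric probabilities, over all tables with the observed
margins, that do not exceed the observed table's probability (within a
small relative tolerance guarding floating-point ties).  It is computed
here by full enumeration over the feasible range of the top-left cell.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .errors import ContractError, IntegrityError

#: Relative tolerance when comparing hypergeometric point probabilities.
_FISHER_RTOL = 1e-7

RESULT_COLUMNS = ["phenotype", "stratum", "a", "b", "c", "d", "test_used",
                  "p_value", "p_bonferroni", "odds_ratio", "significant"]


@dataclass(frozen=True)
class ContingencyResult:
    """One phenotype's 2x2 test within one stratum."""

    phenotype: str
    stratum: str
    a: int  # cases with phenotype
    b: int  # cases without
    c: int  # controls with
    d: int  # controls without
    test_used: str
    p_value: float
    p_bonferroni: float
    odds_ratio: float
    significant: bool


def select_test(a: int, b: int, c: int, d: int) -> str:
    """'fisher' iff any of the four cells is below 5, else 'chi2'."""
    return "fisher" if min(a, b, c, d) < 5 else "chi2"


def _log_hypergeom_pmf(ks: np.ndarray, n1: int, n2: int, m: int) -> np.ndarray:
    """log P(X = k) for X ~ Hypergeom(row1=n1, row2=n2, col1=m)."""
    ks = np.asarray(ks)
    return (gammaln(n1 + 1) - gammaln(ks + 1) - gammaln(n1 - ks + 1)
            + gammaln(n2 + 1) - gammaln(m - ks + 1) - gammaln(n2 - m + ks + 1)
            - (gammaln(n1 + n2 + 1) - gammaln(m + 1)
               - gammaln(n1 + n2 - m + 1)))


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full enumeration (point-probability rule).

    Convention: a zero margin on either axis gives p = 1 (only one table is
    possible).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n1, n2 = a + b, c + d           # row margins
    m = a + c                       # first column margin
    if n1 == 0 or n2 == 0 or m == 0 or (b + d) == 0:
        return 1.0
    lo, hi = max(0, m - n2), min(n1, m)
    ks = np.arange(lo, hi + 1)
    logp = _log_hypergeom_pmf(ks, n1, n2, m)
    log_obs = _log_hypergeom_pmf(np.array([a]), n1, n2, m)[0]
    mask = logp <= log_obs + np.log1p(_FISHER_RTOL)
    return float(min(1.0, np.exp(logp[mask]).sum()))


def chi2_test(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-squared test on a 2x2 table, 1 df, no continuity
    correction; upper-tail p.  Zero expected counts must have been routed
    to Fisher by :func:`select_test`; reaching them here is an error."""
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ContractError(
            "zero expected count: this table must be tested with Fisher")
    stat = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return float(chi2_dist.sf(stat, df=1))


def chi2_statistic(a: int, b: int, c: int, d: int) -> float:
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    return n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)


def odds_ratio(a: int, b: int, c: int, d: int) -> float:
    """Sample odds ratio (a*d)/(b*c); Haldane–Anscombe correction (+0.5 to
    every cell) whenever any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (a * d) / (b * c)


def contingency_tables(matrix: pd.DataFrame, case_ids, control_ids,
                       tested_phenotypes: Iterable[str] | None = None,
                       exclude_phenotypes: Iterable[str] = ()) -> pd.DataFrame:
    """Per-phenotype 2x2 cell counts for one stratum.

    By default the tested set is every phenotype with at least one carrier
    in the stratum cohort, minus the configured exclusions (the
    case-defining phenotype).  The number of rows returned defines the
    Bonferroni family size for the stratum.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    if set(case_ids) & set(control_ids):
        raise IntegrityError("case and control ids overlap")
    cases = matrix.loc[case_ids]
    controls = matrix.loc[control_ids]
    a = cases.sum(axis=0)
    c = controls.sum(axis=0)
    if tested_phenotypes is None:
        tested = (a + c) > 0
        tested &= ~matrix.columns.isin(set(exclude_phenotypes))
        phenos = matrix.columns[tested]
    else:
        phenos = pd.Index([p for p in tested_phenotypes
                           if p not in set(exclude_phenotypes)])
    out = pd.DataFrame({
        "phenotype": phenos,
        "a": a[phenos].to_numpy(int),
        "b": len(case_ids) - a[phenos].to_numpy(int),
        "c": c[phenos].to_numpy(int),
        "d": len(control_ids) - c[phenos].to_numpy(int),
    })
    return out.reset_index(drop=True)


def bonferroni_flag(results: pd.DataFrame, family_size: int,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Add p_bonferroni = min(1, p * family_size) and the significance flag."""
    if family_size < len(results):
        raise IntegrityError(
            f"family_size {family_size} smaller than number of results "
            f"{len(results)}")
    out = results.copy()
    out["p_bonferroni"] = np.minimum(1.0, out["p_value"] * family_size)
    out["significant"] = out["p_bonferroni"] < alpha
    return out


def _vectorized_chi2_p(a, b, c, d):
    n = a + b + c + d
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return chi2_dist.sf(stat, df=1)


def stratum_differential(matrix: pd.DataFrame, case_ids, control_ids,
                         stratum: str = "",
                         exclude_phenotypes: Iterable[str] = (),
                         alpha: float = 0.05) -> pd.DataFrame:
    """Full differential analysis for one stratum.

    Returns one row per tested phenotype with cells, test choice, raw and
    Bonferroni-corrected p, odds ratio and significance flag.  The
    chi-squared branch is evaluated vectorized; Fisher tables are
    enumerated individually.
    """
    tables = contingency_tables(matrix, case_ids, control_ids,
                                exclude_phenotypes=exclude_phenotypes)
    a = tables["a"].to_numpy(float)
    b = tables["b"].to_numpy(float)
    c = tables["c"].to_numpy(float)
    d = tables["d"].to_numpy(float)
    use_fisher = np.minimum.reduce([a, b, c, d]) < 5
    p = np.ones(len(tables))
    if (~use_fisher).any():
        p[~use_fisher] = _vectorized_chi2_p(a[~use_fisher], b[~use_fisher],
                                            c[~use_fisher], d[~use_fisher])
    for i in np.nonzero(use_fisher)[0]:
        p[i] = fisher_exact_two_sided(int(a[i]), int(b[i]),
                                      int(c[i]), int(d[i]))
    ors = np.array([odds_ratio(int(ai), int(bi), int(ci), int(di))
                    for ai, bi, ci, di in zip(a, b, c, d)])
    out = tables.assign(
        stratum=stratum,
        test_used=np.where(use_fisher, "fisher", "chi2"),
        p_value=p,
        odds_ratio=ors,
    )
    out = bonferroni_flag(out, family_size=len(out), alpha=alpha)
    return out[RESULT_COLUMNS]


def intersect_significant(significant_sets: Mapping[str, set]) -> dict[frozenset, set]:
    """Exact-subset partition of significant phenotypes across strata
    (UpSet semantics): a phenotype significant in exactly strata {A, B}
    appears only in the {A, B} block.  Empty blocks are omitted."""
    strata = sorted(significant_sets)
    membership: dict[str, set] = {}
    for stratum in strata:
        for pheno in significant_sets[stratum]:
            membership.setdefault(pheno, set()).add(stratum)
    partition: dict[frozenset, set] = {}
    for pheno, where in membership.items():
        partition.setdefault(frozenset(where), set()).add(pheno)
    return partition


def upset_counts(partition: Mapping[frozenset, set]) -> pd.DataFrame:
    """Tabulate the intersection partition for UpSet-style plotting."""
    rows = [{"strata": "&".join(sorted(block)), "n": len(phenos),
             "phenotypes": sorted(phenos)}
            for block, phenos in partition.items()]
    rows.sort(key=lambda r: (-r["n"], r["strata"]))
    return pd.DataFrame(rows, columns=["strata", "n", "phenotypes"])
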