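"""Propensity-score estimation and 1:2 nearest-neighbor matching.

The design follows the conventional case-control workflow: fit a
main-effects logistic regression of case status on the matching
covariates, optionally trim to the region of common support (the
overlapping propensity-score range of cases and controls), then match
greedily without replacement, one round per control-per-case ratio unit,
processing cases in descending propensity-score order.  A second,
stratum-wise round re-estimates scores within each racialized stratum
(dropping the stratum label from the covariates) and optionally
equalizes stratum sizes by seeded subsampling to the smallest stratum's
complete-match case count.

Balance is reported as standardized mean differences (SMD); |SMD| < 0.1 is
the conventional threshold for acceptable balance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .errors import ConfigError, MatchingError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MatchSpec:
    """Specification of one matching round."""

    covariates: tuple[str, ...] = ("sex", "estimated_age", "death_status")
    ratio: int = 2
    method: str = "nearest_neighbor"
    common_support: bool = False
    #: which group loses patients outside the overlap region: trimming
    #: "both" groups, or only the candidate "control" pool (which keeps the
    #: case cohort — and hence the estimand — intact)
    common_support_discard: str = "both"
    seed: int = 0

    def validate(self) -> None:
        if self.ratio < 1:
            raise ConfigError("ratio must be >= 1")
        if not self.covariates:
            raise ConfigError("covariates must be non-empty")
        if self.method != "nearest_neighbor":
            raise ConfigError(f"unsupported matching method: {self.method}")
        if self.common_support_discard not in ("both", "control"):
            raise ConfigError(
                "common_support_discard must be 'both' or 'control'")


@dataclass
class MatchedCohort:
    """Result of one matching round.

    ``links`` maps each matched case to its matched controls (at most
    ``ratio``, fewer only when the pool ran short).  Controls are used
    without replacement.
    """

    case_ids: list[str]
    control_ids: list[str]
    links: dict[str, list[str]]
    stratum: str | None = None
    balance: pd.DataFrame | None = None
    n_dropped_common_support: dict[str, int] = field(
        default_factory=lambda: {"cases": 0, "controls": 0})

    def complete_cases(self, ratio: int) -> list[str]:
        return [c for c in self.case_ids if len(self.links[c]) == ratio]


def _design_matrix(persons: pd.DataFrame,
                   covariates: tuple[str, ...]) -> pd.DataFrame:
    """One-hot expand categoricals (first level as reference), drop
    constant columns with a warning."""
    parts = []
    for cov in covariates:
        col = persons[cov]
        if col.dtype.kind in "biufc" and cov != "sex":
            parts.append(col.astype(float).rename(cov))
        else:
            levels = sorted(col.astype(str).unique())
            for level in levels[1:]:  # first level = reference
                parts.append((col.astype(str) == level)
                             .astype(float).rename(f"{cov}[{level}]"))
    X = pd.concat(parts, axis=1) if parts else pd.DataFrame(index=persons.index)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping constant covariate column(s): {constant}",
                      stacklevel=2)
        X = X.drop(columns=constant)
    return X


def estimate_propensity(persons: pd.DataFrame,
                        covariates: tuple[str, ...]) -> pd.Series:
    """Fitted case-status probabilities from a maximum-likelihood logistic
    regression with intercept.  Returns a Series indexed by person_id."""
    y = persons["is_case"].astype(int).to_numpy()
    if y.sum() == 0 or y.sum() == len(y):
        raise MatchingError("need at least one case and one control")
    X = _design_matrix(persons, tuple(covariates))
    exog = sm.add_constant(X.to_numpy(), has_constant="add")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # IRLS via GLM: maximum-likelihood logistic fit that degrades
            # gracefully under quasi-separation (pinv instead of inv)
            fit = sm.GLM(y, exog, family=sm.families.Binomial()).fit(
                maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise MatchingError(
            "propensity model failed (perfect separation?); consider "
            "common-support trimming or reviewing the covariate list"
        ) from exc
    scores = np.asarray(fit.predict(exog))
    if X.shape[1] and scores[y == 1].min() > scores[y == 0].max():
        raise MatchingError(
            "perfect separation: every case outscores every control; "
            "consider common-support trimming or reviewing the covariate list")
    return pd.Series(scores, index=persons["person_id"].to_numpy(),
                     name="propensity")


def _common_support_trim(case_ids, control_ids, scores, discard="both"):
    s_case = scores.loc[case_ids]
    s_ctrl = scores.loc[control_ids]
    lo = max(s_case.min(), s_ctrl.min())
    hi = min(s_case.max(), s_ctrl.max())
    if discard == "both":
        keep_case = [i for i in case_ids if lo <= scores[i] <= hi]
    else:
        keep_case = list(case_ids)
    keep_ctrl = [i for i in control_ids if lo <= scores[i] <= hi]
    dropped = {"cases": len(case_ids) - len(keep_case),
               "controls": len(control_ids) - len(keep_ctrl)}
    return keep_case, keep_ctrl, dropped


def nearest_neighbor_match(case_ids, control_ids, scores: pd.Series,
                           spec: MatchSpec) -> MatchedCohort:
    """Greedy nearest-neighbor matching without replacement.

    Cases are processed in descending propensity-score order; one control
    is assigned per case per round, ``spec.ratio`` rounds in total.  Each
    case takes the remaining control closest in |score difference|; ties
    are broken by (score, person_id) for determinism.  With
    ``common_support``, patients outside the overlapping score range of
    the two groups are discarded first (counts logged).
    """
    spec.validate()
    case_ids = list(case_ids)
    control_ids = list(control_ids)
    if set(case_ids) & set(control_ids):
        raise MatchingError("case and control id sets overlap")
    missing = (set(case_ids) | set(control_ids)) - set(scores.index)
    if missing:
        raise MatchingError(f"scores missing for {len(missing)} id(s)")

    dropped = {"cases": 0, "controls": 0}
    if spec.common_support:
        case_ids, control_ids, dropped = _common_support_trim(
            case_ids, control_ids, scores, spec.common_support_discard)
        if dropped["cases"] or dropped["controls"]:
            logger.info("common support dropped %d cases, %d controls",
                        dropped["cases"], dropped["controls"])

    # controls sorted by (score, id); doubly linked list over that order
    ctrl = sorted(control_ids, key=lambda i: (scores[i], i))
    s_ctrl = np.array([scores[i] for i in ctrl])
    n = len(ctrl)
    left = np.arange(-1, n - 1)
    right = np.arange(1, n + 1)
    alive = np.ones(n, dtype=bool)

    def take_nearest(target: float) -> int | None:
        if not alive.any():
            return None
        pos = int(np.searchsorted(s_ctrl, target))
        li = pos - 1
        while li >= 0 and not alive[li]:
            li = left[li]
        ri = pos
        while ri < n and not alive[ri]:
            ri = right[ri]
        best = None
        for idx in (li, ri):
            if idx is None or idx < 0 or idx >= n:
                continue
            key = (abs(s_ctrl[idx] - target), s_ctrl[idx], ctrl[idx])
            if best is None or key < best[0]:
                best = (key, idx)
        idx = best[1]
        alive[idx] = False
        if left[idx] >= 0:
            right[left[idx]] = right[idx]
        if right[idx] < n:
            left[right[idx]] = left[idx]
        return idx

    # descending score, ties by ascending person_id
    ordered_cases = sorted(case_ids, key=lambda i: (-scores[i], i))
    links: dict[str, list[str]] = {c: [] for c in ordered_cases}
    short = False
    for _round in range(spec.ratio):
        for case in ordered_cases:
            idx = take_nearest(scores[case])
            if idx is None:
                short = True
                continue
            links[case].append(ctrl[idx])
    if short:
        warnings.warn("control pool exhausted; some cases matched to fewer "
                      f"than {spec.ratio} controls", stacklevel=2)
    matched_cases = [c for c in ordered_cases if links[c]]
    matched_controls = [i for c in matched_cases for i in links[c]]
    return MatchedCohort(case_ids=matched_cases,
                         control_ids=matched_controls,
                         links={c: links[c] for c in matched_cases},
                         n_dropped_common_support=dropped)


def match_cohort(persons: pd.DataFrame, spec: MatchSpec) -> MatchedCohort:
    """Estimate scores on the full table and run one matching round."""
    scores = estimate_propensity(persons, spec.covariates)
    case_ids = persons.loc[persons["is_case"], "person_id"].tolist()
    control_ids = persons.loc[~persons["is_case"], "person_id"].tolist()
    return nearest_neighbor_match(case_ids, control_ids, scores, spec)


def stratified_match(persons: pd.DataFrame, spec: MatchSpec,
                     equalize: bool = True,
                     seed: int | None = None,
                     stratum_col: str = "race_ethnicity") -> dict[str, MatchedCohort]:
    """Per-stratum matching with propensity scores re-estimated within each
    stratum (the stratum label itself is never a covariate here).

    With ``equalize``, every stratum's matched case set is subsampled
    (seeded) to the minimum complete-match case count across strata, and
    controls restricted to the retained cases' links, so all strata end up
    with equal case and control counts.
    """
    spec.validate()
    covariates = tuple(c for c in spec.covariates if c != stratum_col)
    spec_in_stratum = replace(spec, covariates=covariates)
    strata = sorted(persons[stratum_col].unique())
    results: dict[str, MatchedCohort] = {}
    for stratum in strata:
        sub = persons[persons[stratum_col] == stratum]
        if sub["is_case"].all() or not sub["is_case"].any():
            raise MatchingError(
                f"stratum {stratum!r} lacks cases or controls")
        matched = match_cohort(sub, spec_in_stratum)
        matched.stratum = stratum
        results[stratum] = matched

    if equalize:
        n_min = min(len(m.complete_cases(spec.ratio)) for m in results.values())
        rng = np.random.default_rng(spec.seed if seed is None else seed)
        for stratum in strata:
            m = results[stratum]
            complete = m.complete_cases(spec.ratio)
            keep = sorted(rng.choice(np.asarray(complete, dtype=object),
                                     size=n_min, replace=False).tolist())
            links = {c: m.links[c] for c in keep}
            results[stratum] = MatchedCohort(
                case_ids=keep,
                control_ids=[i for c in keep for i in links[c]],
                links=links, stratum=stratum,
                n_dropped_common_support=m.n_dropped_common_support)
    return results


def _smd_continuous(x: np.ndarray, y: np.ndarray) -> float:
    vx, vy = x.var(ddof=1) if len(x) > 1 else 0.0, y.var(ddof=1) if len(y) > 1 else 0.0
    denom = np.sqrt((vx + vy) / 2.0)
    if denom == 0:
        return 0.0
    return abs(x.mean() - y.mean()) / denom


def _smd_proportion(p1: float, p2: float) -> float:
    denom = np.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)
    if denom == 0:
        return 0.0
    return abs(p1 - p2) / denom


def standardized_mean_difference(case_vals: pd.Series,
                                 control_vals: pd.Series) -> float:
    """SMD between two groups for one covariate.

    Continuous covariates use the pooled-variance formula; categorical
    covariates are expanded level-wise into proportions and aggregated as
    the maximum level-wise SMD.  Zero variance in both groups gives 0.
    """
    if case_vals.dtype.kind in "biufc" and case_vals.dtype.kind != "b":
        return _smd_continuous(case_vals.to_numpy(float),
                               control_vals.to_numpy(float))
    levels = sorted(set(case_vals.astype(str)) | set(control_vals.astype(str)))
    if len(levels) <= 1:
        return 0.0
    smds = []
    for level in levels:
        p1 = float((case_vals.astype(str) == level).mean())
        p2 = float((control_vals.astype(str) == level).mean())
        smds.append(_smd_proportion(p1, p2))
    return max(smds)


def balance_table(persons: pd.DataFrame, matched: MatchedCohort,
                  covariates, pool_control_ids=None) -> pd.DataFrame:
    """Per-covariate SMD before vs after matching.

    'Before' compares the matched cases against the candidate-control pool
    (all controls by default); 'after' compares them against the matched
    controls.
    """
    if not matched.case_ids:
        raise MatchingError("matched cohort is empty")
    persons = persons.set_index("person_id", drop=False)
    cases = persons.loc[matched.case_ids]
    if pool_control_ids is None:
        pool_control_ids = persons.loc[~persons["is_case"], "person_id"].tolist()
    pool = persons.loc[list(pool_control_ids)]
    after = persons.loc[matched.control_ids]
    rows = []
    for cov in covariates:
        rows.append({
            "covariate": cov,
            "smd_before": standardized_mean_difference(cases[cov], pool[cov]),
            "smd_after": standardized_mean_difference(cases[cov], after[cov]),
        })
    return pd.DataFrame(rows).set_index("covariate")


def cohort_summary(persons: pd.DataFrame, matched: MatchedCohort,
                   covariates) -> pd.DataFrame:
    """Demographic summary of the matched cohort: counts and percentages
    per categorical level, mean (SD) for continuous covariates."""
    persons = persons.set_index("person_id", drop=False)
    rows = []
    for group, ids in (("AD", matched.case_ids), ("control", matched.control_ids)):
        sub = persons.loc[ids]
        for cov in covariates:
            col = sub[cov]
            if col.dtype.kind in "biufc" and col.dtype.kind != "b":
                rows.append({"group": group, "covariate": cov, "level": "",
                             "value": f"{col.mean():.1f} ({col.std():.1f})"})
            else:
                for level, n in col.astype(str).value_counts().items():
                    rows.append({"group": group, "covariate": cov,
                                 "level": level,
                                 "value": f"{n} ({100 * n / len(sub):.1f}%)"})
    return pd.DataFrame(rows)
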