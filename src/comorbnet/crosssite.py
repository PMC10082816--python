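"""Two-site validation: replication, OR concordance, metric concordance.

Significant phenotypes from the discovery site are looked up at the
validation site; a finding replicates when it is also significant there.
Effect-size concordance is quantified as Spearman's rank correlation of
log odds ratios — computed separately for the replicated subset and the
discovery-only subset (the contrast between the two is the qualitative
validation signal).  Network-metric concordance reduces each network to
one summary value per metric (median over nodes by default), z-scores
the summaries within site across the 8 networks per metric, and
correlates the paired cells across sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .ranktests import spearman_rho


@dataclass
class SitePairedResult:
    """Discovery-significant phenotypes paired with validation results."""

    pairs: pd.DataFrame
    # columns: stratum, phenotype, or_discovery, or_validation,
    #          significant_discovery, significant_validation
    summary: pd.DataFrame
    # per stratum: n_sig_discovery, n_replicated, replication_fraction


def pair_site_results(discovery: pd.DataFrame,
                      validation: pd.DataFrame) -> SitePairedResult:
    """Pair per-stratum differential results across the two sites.

    Pairs are restricted to phenotypes significant at the discovery site
    and tested at both sites.  Strata must agree between sites.  A stratum
    with no discovery-significant phenotypes has an undefined replication
    fraction (reported as NaN with a warning).
    """
    strata_d = set(discovery["stratum"])
    strata_v = set(validation["stratum"])
    if strata_d != strata_v:
        raise ContractError(
            f"strata differ between sites: {sorted(strata_d ^ strata_v)}")
    val = validation.set_index(["stratum", "phenotype"])
    rows, summary_rows = [], []
    for stratum in sorted(strata_d):
        disc = discovery[(discovery["stratum"] == stratum)
                         & discovery["significant"]]
        n_sig, n_rep = 0, 0
        for _, row in disc.iterrows():
            key = (stratum, row["phenotype"])
            if key not in val.index:
                continue  # not tested at validation site
            vrow = val.loc[key]
            n_sig += 1
            replicated = bool(vrow["significant"])
            n_rep += int(replicated)
            rows.append({
                "stratum": stratum, "phenotype": row["phenotype"],
                "or_discovery": float(row["odds_ratio"]),
                "or_validation": float(vrow["odds_ratio"]),
                "significant_discovery": True,
                "significant_validation": replicated,
            })
        if n_sig == 0:
            warnings.warn(f"stratum {stratum!r}: no discovery-significant "
                          "phenotypes; replication fraction undefined",
                          stacklevel=2)
        summary_rows.append({
            "stratum": stratum,
            "n_sig_discovery": n_sig,
            "n_replicated": n_rep,
            "replication_fraction": (n_rep / n_sig) if n_sig else float("nan"),
        })
    pairs = pd.DataFrame(rows, columns=[
        "stratum", "phenotype", "or_discovery", "or_validation",
        "significant_discovery", "significant_validation"])
    summary = pd.DataFrame(summary_rows).set_index("stratum")
    return SitePairedResult(pairs=pairs, summary=summary)


def or_concordance(paired: SitePairedResult,
                   subset: str = "replicated") -> pd.DataFrame:
    """Per-stratum Spearman correlation of log odds-ratio pairs.

    ``subset`` selects ``"replicated"`` (significant at both sites) or
    ``"discovery_only"`` pairs.  Strata with fewer than 3 pairs are
    reported as not computable (NaN).
    """
    if subset not in ("replicated", "discovery_only"):
        raise ContractError(f"unknown subset {subset!r}")
    rows = []
    for stratum, grp in paired.pairs.groupby("stratum"):
        if subset == "replicated":
            sel = grp[grp["significant_validation"]]
        else:
            sel = grp[~grp["significant_validation"]]
        if len(sel) < 3:
            rows.append({"stratum": stratum, "n": len(sel),
                         "rho": float("nan"), "p_value": float("nan")})
            continue
        rho, p = spearman_rho(np.log(sel["or_discovery"].to_numpy()),
                              np.log(sel["or_validation"].to_numpy()))
        rows.append({"stratum": stratum, "n": len(sel),
                     "rho": rho, "p_value": p})
    return pd.DataFrame(rows).set_index("stratum")


def loglog_plot_data(paired: SitePairedResult) -> pd.DataFrame:
    """Data table behind the log-log OR correlation plots."""
    out = paired.pairs.copy()
    out["log_or_discovery"] = np.log(out["or_discovery"])
    out["log_or_validation"] = np.log(out["or_validation"])
    return out


@dataclass
class MetricConcordance:
    per_network: pd.DataFrame   # (network, metric) summary + z per site
    rho: float
    p_value: float
    summary_statistic: str = "median"


def _summarize(table: pd.DataFrame, statistic: str) -> pd.Series:
    if statistic == "median":
        return table.median(axis=0)
    if statistic == "mean":
        return table.mean(axis=0)
    raise ContractError(f"unknown summary statistic {statistic!r}")


def metric_concordance(metric_tables_site1: dict[str, pd.DataFrame],
                       metric_tables_site2: dict[str, pd.DataFrame],
                       statistic: str = "median") -> MetricConcordance:
    """Cross-site concordance of network-level metric summaries.

    Each network contributes one summary value per metric (median over
    nodes by default).  Summaries are z-scored within each site across
    the networks, separately per metric, then the paired
    (network, metric) cells are correlated across sites with Spearman's
    rank correlation.
    """
    if set(metric_tables_site1) != set(metric_tables_site2):
        missing = set(metric_tables_site1) ^ set(metric_tables_site2)
        raise ContractError(f"network labels differ between sites: "
                            f"{sorted(missing)}")
    labels = sorted(metric_tables_site1)
    summaries = {}
    for site, tables in (("site1", metric_tables_site1),
                         ("site2", metric_tables_site2)):
        frame = pd.DataFrame({lab: _summarize(tables[lab], statistic)
                              for lab in labels}).T  # networks x metrics
        mean = frame.mean(axis=0)
        sd = frame.std(axis=0, ddof=0)
        z = (frame - mean).div(sd.replace(0.0, np.nan), axis=1)
        summaries[site] = (frame, z.fillna(0.0))
    cells = []
    for lab in labels:
        for metric in summaries["site1"][0].columns:
            cells.append({
                "network": lab, "metric": metric,
                "value_site1": summaries["site1"][0].loc[lab, metric],
                "value_site2": summaries["site2"][0].loc[lab, metric],
                "z_site1": summaries["site1"][1].loc[lab, metric],
                "z_site2": summaries["site2"][1].loc[lab, metric],
            })
    per_network = pd.DataFrame(cells)
    rho, p = spearman_rho(per_network["z_site1"].to_numpy(),
                          per_network["z_site2"].to_numpy())
    return MetricConcordance(per_network=per_network, rho=rho, p_value=p,
                             summary_statistic=statistic)
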