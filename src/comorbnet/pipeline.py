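"""End-to-end orchestration: simulate/load -> map -> match -> analyse.

Every stage writes plain files into the run directory so any stage can be
re-run or inspected in isolation; a manifest records the configuration
hash, the seed, package versions and every artifact produced.  Stage
logging includes patient and phenotype counts so filter attrition is
auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .crosssite import metric_concordance, or_concordance, pair_site_results
from .differential import intersect_significant, stratum_differential, upset_counts
from .embedding import comparisons_frame, compare_embedding, embed_2d
from .errors import ConfigError
from .matching import MatchSpec, balance_table, cohort_summary, stratified_match
from .network import (build_network, compare_ad_vs_control, compare_networks_kw,
                      export_graphml, node_metrics, visualization_subnetwork)
from .phecodes import (build_phenotype_matrix, fixture_map_path, load_phecode_map,
                       map_diagnoses, phenotype_categories)
from .simulate import (AD_PHENOTYPE, STRATA, SimulationConfig, generate_cohort,
                       generate_diagnoses, read_omop_lite, synthetic_phecode_map,
                       write_omop_lite)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of one pipeline run."""

    mode: str = "synthetic"                 # or "omop_lite_files"
    input_dir: str | None = None            # for omop_lite_files mode
    phecode_map: str = "fixture"            # path or "fixture"
    output_dir: str = "comorbnet_run"
    seed: int = 0
    alpha: float = 0.05
    ratio: int = 2
    covariates: tuple[str, ...] = ("sex", "estimated_age", "race_ethnicity",
                                   "death_status")
    common_support: bool = False
    node_threshold: float = 0.05
    edge_threshold: float = 0.05
    visualization_threshold: float = 0.25
    exclude_phenotypes: tuple[str, ...] = (AD_PHENOTYPE,)
    run_embedding: bool = True
    two_site: bool = False
    shared_effects: bool = True             # validation site shares effects
    # synthetic-mode generator settings
    n_cases_per_stratum: int = 150
    control_pool_multiplier: int = 5
    n_phenotypes: int = 60
    fraction_null: float = 0.7
    confounding_strength: float = 0.5
    validation_sites: tuple[str, ...] = ("UCD", "UCI", "UCLA", "UCSD")

    def validate(self) -> list[str]:
        errors = []
        if self.mode not in ("synthetic", "omop_lite_files"):
            errors.append(f"mode: unknown value {self.mode!r}")
        if self.mode == "omop_lite_files" and not self.input_dir:
            errors.append("input_dir: required in omop_lite_files mode")
        if not 0 < self.alpha < 1:
            errors.append(f"alpha: must be in (0, 1), got {self.alpha}")
        if self.ratio < 1:
            errors.append(f"ratio: must be >= 1, got {self.ratio}")
        for name in ("node_threshold", "edge_threshold",
                     "visualization_threshold"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                errors.append(f"{name}: must be in [0, 1), got {v}")
        if not isinstance(self.seed, int):
            errors.append("seed: must be an integer")
        return errors


def validate_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config file, fill defaults, and validate.

    Raises :class:`ConfigError` with the aggregated error list if any
    invariant fails; unknown keys are rejected.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    errors = [f"unknown config key: {k}" for k in sorted(unknown)]
    kwargs = {k: tuple(v) if isinstance(v, list) else v
              for k, v in raw.items() if k in known}
    if "seed" not in raw:
        logger.info("no seed in config; defaulting to 0")
    config = PipelineConfig(**kwargs)
    errors.extend(config.validate())
    if errors:
        raise ConfigError("; ".join(errors))
    return config


@dataclass
class ReportBundle:
    """Handles to everything a run produced."""

    config: PipelineConfig
    output_dir: Path
    manifest: dict
    matched: dict
    differential: dict[str, pd.DataFrame]
    networks: dict[tuple[str, str], object]
    metric_tables: dict[tuple[str, str], pd.DataFrame]
    crosssite: dict | None = None


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_map(config: PipelineConfig) -> pd.DataFrame:
    if config.phecode_map == "fixture":
        if config.mode == "synthetic":
            # synthetic cohorts may use more phenotypes than the bundled file
            return synthetic_phecode_map(config.n_phenotypes)
        return load_phecode_map(fixture_map_path())
    return load_phecode_map(config.phecode_map)


def _analyse_site(persons, diagnoses, map_table, config: PipelineConfig,
                  site_tag: str, outdir: Path, artifacts: list[str]):
    """Map, match, and run all per-site analyses.  Returns a dict of
    per-site results used by the cross-site stage."""
    assignments, report = map_diagnoses(diagnoses, map_table)
    logger.info("%s: %d diagnosis events -> %d assignments (%d unmapped, "
                "%d excluded w/o category)", site_tag, len(diagnoses),
                len(assignments), report.n_unmapped_events,
                report.n_excluded_events)

    spec = MatchSpec(covariates=tuple(config.covariates), ratio=config.ratio,
                     common_support=config.common_support, seed=config.seed)
    matched = stratified_match(persons, spec, equalize=True, seed=config.seed)
    all_case_ids = sorted(i for m in matched.values() for i in m.case_ids)
    all_control_ids = sorted(i for m in matched.values() for i in m.control_ids)
    cohort_ids = all_case_ids + all_control_ids
    logger.info("%s: matched %d cases / %d controls", site_tag,
                len(all_case_ids), len(all_control_ids))

    balance_covs = [c for c in config.covariates if c != "race_ethnicity"]
    balance_rows = []
    persons_idx = persons.set_index("person_id", drop=False)
    for stratum, m in matched.items():
        pool = persons_idx.loc[(persons_idx["race_ethnicity"] == stratum)
                               & ~persons_idx["is_case"], "person_id"]
        bt = balance_table(persons, m, balance_covs, pool_control_ids=pool)
        bt["stratum"] = stratum
        balance_rows.append(bt.reset_index())
        summary = cohort_summary(persons, m, config.covariates)
        summary.to_csv(outdir / f"{site_tag}_table1_{stratum}.csv", index=False)
        artifacts.append(f"{site_tag}_table1_{stratum}.csv")
    balance = pd.concat(balance_rows, ignore_index=True)
    balance.to_csv(outdir / f"{site_tag}_balance.csv", index=False)
    artifacts.append(f"{site_tag}_balance.csv")

    matrix = build_phenotype_matrix(
        assignments[assignments["person_id"].isin(cohort_ids)],
        cohort_ids, exclude_phenotypes=config.exclude_phenotypes)
    logger.info("%s: phenotype matrix %d patients x %d phenotypes",
                site_tag, *matrix.shape)

    if config.run_embedding and len(matrix) >= 10 and matrix.shape[1] >= 2:
        emb = embed_2d(matrix, seed=config.seed)
        labels_ad = pd.Series(
            persons_idx.loc[matrix.index, "is_case"].map(
                {True: "AD", False: "control"}).to_numpy(),
            index=matrix.index)
        labels_re = pd.Series(
            persons_idx.loc[matrix.index, "race_ethnicity"].to_numpy(),
            index=matrix.index)
        comparisons = (compare_embedding(emb, labels_ad, "AD_status")
                       + compare_embedding(emb, labels_re, "stratum"))
        if persons["site"].nunique() > 1:
            labels_site = pd.Series(
                persons_idx.loc[matrix.index, "site"].to_numpy(),
                index=matrix.index)
            comparisons += compare_embedding(emb, labels_site, "site")
        coords = emb.coordinates.copy()
        coords["AD_status"] = labels_ad
        coords["stratum"] = labels_re
        coords.to_csv(outdir / f"{site_tag}_umap.csv")
        comparisons_frame(comparisons).to_json(
            outdir / f"{site_tag}_umap_comparisons.json", orient="records")
        artifacts += [f"{site_tag}_umap.csv", f"{site_tag}_umap_comparisons.json"]

    categories = phenotype_categories(map_table)
    differential = {}
    manhattan_rows = []
    for stratum, m in matched.items():
        res = stratum_differential(matrix, m.case_ids, m.control_ids,
                                   stratum=stratum, alpha=config.alpha)
        res["category"] = res["phenotype"].map(categories).fillna("")
        res.to_csv(outdir / f"{site_tag}_differential_{stratum}.csv",
                   index=False)
        artifacts.append(f"{site_tag}_differential_{stratum}.csv")
        differential[stratum] = res
        manhattan_rows.append(res.assign(
            neg_log10_p=-np.log10(np.maximum(res["p_value"], 1e-300))))
    manhattan = pd.concat(manhattan_rows, ignore_index=True)
    manhattan[["stratum", "phenotype", "category", "neg_log10_p",
               "significant"]].to_csv(
        outdir / f"{site_tag}_manhattan.csv", index=False)
    artifacts.append(f"{site_tag}_manhattan.csv")

    sig_sets = {s: set(r.loc[r["significant"], "phenotype"])
                for s, r in differential.items()}
    partition = intersect_significant(sig_sets)
    upset = upset_counts(partition)
    upset.to_json(outdir / f"{site_tag}_upset.json", orient="records")
    artifacts.append(f"{site_tag}_upset.json")

    networks, metric_tables = {}, {}
    for stratum, m in matched.items():
        for status, ids in (("AD", m.case_ids), ("control", m.control_ids)):
            label = f"{stratum}_{status}"
            net = build_network(matrix, ids,
                                node_threshold=config.node_threshold,
                                edge_threshold=config.edge_threshold,
                                label=label)
            networks[(stratum, status)] = net
            metrics = node_metrics(net)
            metrics.to_csv(outdir / f"{site_tag}_metrics_{label}.csv")
            export_graphml(net, outdir / f"{site_tag}_network_{label}.graphml",
                           categories=categories)
            artifacts += [f"{site_tag}_metrics_{label}.csv",
                          f"{site_tag}_network_{label}.graphml"]
            metric_tables[(stratum, status)] = metrics
            visualization_subnetwork(
                matrix, ids, threshold=config.visualization_threshold,
                label=label, categories=categories,
                graphml_path=outdir / f"{site_tag}_viz_{label}.graphml")
            artifacts.append(f"{site_tag}_viz_{label}.graphml")
    logger.info("%s: built %d networks", site_tag, len(networks))

    comparisons = {}
    for status in ("AD", "control"):
        tables = {s: metric_tables[(s, status)] for s in matched}
        per_metric = {}
        for metric in tables[next(iter(tables))].columns:
            if all(len(t) for t in tables.values()):
                h, p, _pairs = compare_networks_kw(tables, metric)
                per_metric[metric] = {"H": h, "p": p}
        comparisons[f"between_{status}_networks"] = per_metric
    ad_vs_ctrl = {}
    for stratum in matched:
        per_metric = {}
        t_ad = metric_tables[(stratum, "AD")]
        t_ct = metric_tables[(stratum, "control")]
        if len(t_ad) and len(t_ct):
            for metric in t_ad.columns:
                u, p = compare_ad_vs_control(t_ad, t_ct, metric)
                per_metric[metric] = {"U": u, "p": p}
        ad_vs_ctrl[stratum] = per_metric
    comparisons["ad_vs_control"] = ad_vs_ctrl
    with open(outdir / f"{site_tag}_network_comparisons.json", "w") as fh:
        json.dump(comparisons, fh, indent=1)
    artifacts.append(f"{site_tag}_network_comparisons.json")

    return {"matched": matched, "matrix": matrix,
            "differential": differential, "networks": networks,
            "metric_tables": metric_tables, "balance": balance,
            "partition": partition}


def run_full(config: PipelineConfig) -> ReportBundle:
    """Execute the whole pipeline and write all artifacts."""
    errors = config.validate()
    if errors:
        raise ConfigError("; ".join(errors))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    map_table = _load_map(config)

    if config.mode == "synthetic":
        sim = SimulationConfig(
            n_cases_per_stratum=config.n_cases_per_stratum,
            control_pool_multiplier=config.control_pool_multiplier,
            n_phenotypes=config.n_phenotypes,
            fraction_null=config.fraction_null,
            confounding_strength=config.confounding_strength,
            seed=config.seed)
        persons, effects = generate_cohort(sim)
        diagnoses = generate_diagnoses(persons, effects, sim, map_table)
        write_omop_lite(persons, diagnoses, outdir / "omop_lite")
        effects.to_json(outdir / "ground_truth_effects.json")
        artifacts += ["omop_lite/person.csv",
                      "omop_lite/condition_occurrence.csv",
                      "ground_truth_effects.json"]
    else:
        persons, diagnoses = read_omop_lite(config.input_dir)
        effects = None

    site1 = _analyse_site(persons, diagnoses, map_table, config,
                          "discovery", outdir, artifacts)

    crosssite_report = None
    if config.two_site:
        if config.mode != "synthetic":
            raise ConfigError(
                "two_site: only supported in synthetic mode (real "
                "validation data must be run as a separate site)")
        sim_val = SimulationConfig(
            n_cases_per_stratum=config.n_cases_per_stratum,
            control_pool_multiplier=config.control_pool_multiplier,
            n_phenotypes=config.n_phenotypes,
            fraction_null=config.fraction_null,
            confounding_strength=config.confounding_strength,
            sites=tuple(config.validation_sites),
            seed=config.seed + 1)
        persons_v, _ = generate_cohort(sim_val)
        effects_v = effects if config.shared_effects else effects.for_validation_site()
        diagnoses_v = generate_diagnoses(persons_v, effects_v, sim_val,
                                         map_table)
        site2 = _analyse_site(persons_v, diagnoses_v, map_table, config,
                              "validation", outdir, artifacts)
        disc = pd.concat(site1["differential"].values(), ignore_index=True)
        vali = pd.concat(site2["differential"].values(), ignore_index=True)
        paired = pair_site_results(disc, vali)
        conc_rep = or_concordance(paired, "replicated")
        conc_only = or_concordance(paired, "discovery_only")
        labels = {f"{s}_{st}": t for (s, st), t in site1["metric_tables"].items()}
        labels_v = {f"{s}_{st}": t for (s, st), t in site2["metric_tables"].items()}
        mc = metric_concordance(labels, labels_v)
        crosssite_report = {
            "replication": paired.summary.to_dict(orient="index"),
            "or_concordance_replicated": conc_rep.to_dict(orient="index"),
            "or_concordance_discovery_only": conc_only.to_dict(orient="index"),
            "metric_concordance": {"rho": mc.rho, "p_value": mc.p_value},
        }
        paired.pairs.to_csv(outdir / "crosssite_pairs.csv", index=False)
        with open(outdir / "crosssite_report.json", "w") as fh:
            json.dump(crosssite_report, fh, indent=1, default=float)
        artifacts += ["crosssite_pairs.csv", "crosssite_report.json"]
    else:
        logger.info("single-site configuration; cross-site stage skipped")

    manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "comorbnet_version": __version__,
        "n_networks": len(site1["networks"]) * (2 if config.two_site else 1),
        "artifacts": sorted(artifacts),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return ReportBundle(config=config, output_dir=outdir, manifest=manifest,
                        matched=site1["matched"],
                        differential=site1["differential"],
                        networks=site1["networks"],
                        metric_tables=site1["metric_tables"],
                        crosssite=crosssite_report)
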