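"""Synthetic OMOP-lite EMR cohorts with known comorbidity effects.

This module emulates the structure of a de-identified hospital EMR extract:
a person table (demographics, vital status, care site, case status for
Alzheimer's dementia) and a condition table of raw ICD-9-CM / ICD-10-CM
billing codes.  Every phenotype effect is injected on the logit scale with a
known odds ratio, so the differential-analysis, network and cross-site
stages downstream can be validated against ground truth.

The generative model, per (phenotype, stratum):

    P(phenotype | patient) = logit^-1( logit(baseline)
                                       + is_case * log(OR)
                                       + confounding * z(covariates) )

where ``z`` is a mean-centred score of age, sex and death status.  With
``confounding_strength = 0`` the injected OR is exactly the marginal
case/control odds ratio being estimated downstream; with positive
confounding the covariates shift both case probability and phenotype
prevalence, so an unmatched analysis is biased and matching demonstrably
removes the bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, GenerationError

#: The four racialized strata analysed throughout the pipeline.
STRATA = ("Asian", "Black", "Latine", "White")

#: Phenotype name used for the case-defining condition (always excluded
#: from differential testing and embedding downstream).
AD_PHENOTYPE = "Alzheimer's disease"

PERSON_COLUMNS = [
    "person_id", "sex", "estimated_age", "race_ethnicity",
    "death_status", "site", "is_case",
]
CONDITION_COLUMNS = ["person_id", "code_system", "code"]

_PHECODE_CATEGORIES = [
    "circulatory system", "mental disorders", "endocrine/metabolic",
    "genitourinary", "neurological", "symptoms", "musculoskeletal",
    "hematopoietic", "digestive", "respiratory", "sense organs",
    "dermatologic",
]

# Clinically plausible phenotype names for the first synthetic phenotypes;
# anything beyond this list gets a systematic name.
_NAMED_PHENOTYPES = [
    ("Essential hypertension", "circulatory system"),
    ("Hyperlipidemia", "endocrine/metabolic"),
    ("Type 2 diabetes", "endocrine/metabolic"),
    ("Major depressive disorder", "mental disorders"),
    ("Anxiety disorder", "mental disorders"),
    ("Urinary tract infection", "genitourinary"),
    ("Memory loss", "neurological"),
    ("Vascular dementia", "mental disorders"),
    ("Psychosis", "mental disorders"),
    ("Cerebrovascular disease", "circulatory system"),
    ("Osteoporosis", "musculoskeletal"),
    ("Osteoarthrosis", "musculoskeletal"),
    ("Pain in joint", "symptoms"),
    ("Malaise and fatigue", "symptoms"),
    ("Other anemias", "hematopoietic"),
    ("Atrial fibrillation", "circulatory system"),
    ("Gastroesophageal reflux disease", "digestive"),
    ("Acute renal failure", "genitourinary"),
    ("Acquired hypothyroidism", "endocrine/metabolic"),
    ("Bipolar", "mental disorders"),
    ("Other upper respiratory disease", "respiratory"),
    ("Inflammation of eyelids", "sense organs"),
    ("Tinnitus", "sense organs"),
    ("Parasomnia", "neurological"),
    ("Cough", "respiratory"),
    ("Hyperhidrosis", "dermatologic"),
]

_ICD10_LETTERS = "ABCDEFGHIJKLMNR"


def synthetic_phecode_map(n_phenotypes: int) -> pd.DataFrame:
    """Build a synthetic phecode map covering ``n_phenotypes`` phenotypes.

    Each phenotype receives one ICD-9-CM and one ICD-10-CM code plus a
    phecode and a phecode category.  Two extra entries are always appended:
    the Alzheimer's dementia phenotype (real ICD-10-CM codes G30.1/G30.8/
    G30.9) and one deliberately category-less phenotype, so the downstream
    category-exclusion rule is exercised end to end.

    The map is deterministic — no randomness — and its layout matches the
    schema consumed by :func:`comorbnet.phecodes.load_phecode_map`.
    """
    if n_phenotypes < 0:
        raise ConfigError("n_phenotypes must be >= 0")
    rows = []
    for i in range(n_phenotypes):
        if i < len(_NAMED_PHENOTYPES):
            name, category = _NAMED_PHENOTYPES[i]
        else:
            name = f"Synthetic phenotype {i + 1:03d}"
            category = _PHECODE_CATEGORIES[i % len(_PHECODE_CATEGORIES)]
        phecode = f"{900 + i // 10}.{i % 10}"
        letter = _ICD10_LETTERS[i % len(_ICD10_LETTERS)]
        icd10 = f"{letter}{i // len(_ICD10_LETTERS):02d}.{i % 10}"
        icd9 = f"{100 + i}.{i % 10}"
        rows.append(("ICD10CM", icd10, phecode, name, category))
        rows.append(("ICD9CM", icd9, phecode, name, category))
    for code in ("G30.1", "G30.8", "G30.9"):
        rows.append(("ICD10CM", code, "290.11", AD_PHENOTYPE,
                     "mental disorders"))
    rows.append(("ICD10CM", "Z99.9", "999.9",
                 "Synthetic uncategorized condition", ""))
    return pd.DataFrame(
        rows, columns=["code_system", "icd_code", "phecode",
                       "phenotype", "category"],
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the discovery-cohort geometry the pipeline targets:
    422 cases per stratum, a five-fold candidate-control pool, and a
    1:2 match ratio applied later by the matching stage.
    """

    n_cases_per_stratum: int = 422
    control_pool_multiplier: int = 5
    n_phenotypes: int = 200
    fraction_null: float = 0.8
    effect_or_range: tuple[float, float] = (3.0, 6.0)
    baseline_prevalence_range: tuple[float, float] = (0.05, 0.40)
    confounding_strength: float = 0.0
    stratum_specific_effects: bool = False
    sites: tuple[str, ...] = ("siteA",)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases_per_stratum <= 0:
            raise ConfigError("n_cases_per_stratum must be positive")
        if self.control_pool_multiplier < 3:
            raise ConfigError("control_pool_multiplier must be >= 3")
        if self.n_phenotypes < 0:
            raise ConfigError("n_phenotypes must be >= 0")
        if not 0.0 <= self.fraction_null <= 1.0:
            raise ConfigError("fraction_null must be in [0, 1]")
        lo, hi = self.effect_or_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ConfigError("effect_or_range must be positive with lo <= hi")
        plo, phi = self.baseline_prevalence_range
        if not (0.0 < plo <= phi < 1.0):
            raise ConfigError(
                "baseline_prevalence_range must lie strictly inside (0, 1)")
        if self.confounding_strength < 0:
            raise ConfigError("confounding_strength must be >= 0")
        if not self.sites:
            raise ConfigError("sites must be non-empty")


@dataclass
class GroundTruthEffects:
    """Injected effect table: one row per (phenotype, stratum).

    ``shared_across_sites`` marks phenotypes whose effect replicates at a
    second site; phenotypes with ``False`` revert to OR = 1 there.
    """

    table: pd.DataFrame  # columns: phenotype, stratum, baseline_prevalence, odds_ratio
    shared_across_sites: dict[str, bool] = field(default_factory=dict)

    def validate(self) -> None:
        t = self.table
        if ((t["baseline_prevalence"] <= 0) | (t["baseline_prevalence"] >= 1)).any():
            raise ConfigError("baseline_prevalence must lie in (0, 1)")
        if (t["odds_ratio"] <= 0).any():
            raise ConfigError("odds_ratio must be > 0")

    def nonnull_phenotypes(self) -> set[str]:
        t = self.table
        return set(t.loc[t["odds_ratio"] != 1.0, "phenotype"])

    def null_phenotypes(self) -> set[str]:
        return set(self.table["phenotype"]) - self.nonnull_phenotypes()

    def for_validation_site(self) -> "GroundTruthEffects":
        """Effects as they apply at a second EMR site: non-shared
        phenotypes lose their case effect (OR -> 1)."""
        t = self.table.copy()
        shared = t["phenotype"].map(lambda p: self.shared_across_sites.get(p, True))
        t.loc[~shared.astype(bool), "odds_ratio"] = 1.0
        return GroundTruthEffects(t, dict(self.shared_across_sites))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "effects": self.table.to_dict(orient="records"),
            "shared_across_sites": self.shared_across_sites,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruthEffects":
        payload = json.loads(Path(path).read_text())
        return cls(pd.DataFrame(payload["effects"]),
                   dict(payload["shared_across_sites"]))


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def _effect_phenotype_names(n: int) -> list[str]:
    m = synthetic_phecode_map(n)
    names = m.loc[(m["category"] != "") & (m["phenotype"] != AD_PHENOTYPE),
                  "phenotype"].drop_duplicates().tolist()
    return names[:n]


def generate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruthEffects]:
    """Generate the person table plus the ground-truth effect table.

    Each of the four strata receives ``n_cases_per_stratum`` cases and
    ``n_cases_per_stratum * control_pool_multiplier`` candidate controls.
    With ``confounding_strength > 0`` cases are drawn from a covariate
    distribution tilted towards older age, male sex and death, so matching
    is non-trivial.
    """
    config.validate()
    rng_cov, rng_eff = _child_rngs(config.seed, 2)
    c = config.confounding_strength
    n_cases = config.n_cases_per_stratum
    n_ctrl = n_cases * config.control_pool_multiplier

    frames = []
    pid = 0
    for stratum in STRATA:
        for is_case, n in ((True, n_cases), (False, n_ctrl)):
            age_mean = 85.0 + (3.0 * c if is_case else 0.0)
            # ages above 90 are capped at 90, mirroring the de-identification
            # convention for elderly patients in EMR extracts
            age = np.clip(np.round(rng_cov.normal(age_mean, 6.0, n)), 65, 90)
            p_female = np.clip(0.70 - (0.08 * c if is_case else 0.0), 0.05, 0.95)
            sex = np.where(rng_cov.random(n) < p_female, "female", "male")
            p_dead = np.clip(0.12 + (0.25 * c if is_case else 0.0), 0.0, 0.95)
            death = np.where(rng_cov.random(n) < p_dead, "deceased", "alive")
            site = rng_cov.choice(np.asarray(config.sites, dtype=object), size=n)
            ids = [f"P{pid + k:07d}" for k in range(n)]
            pid += n
            frames.append(pd.DataFrame({
                "person_id": ids,
                "sex": sex,
                "estimated_age": age.astype(int),
                "race_ethnicity": stratum,
                "death_status": death,
                "site": site,
                "is_case": is_case,
            }))
    persons = pd.concat(frames, ignore_index=True)

    names = _effect_phenotype_names(config.n_phenotypes)
    n_null = int(round(config.fraction_null * len(names)))
    null_mask = np.zeros(len(names), dtype=bool)
    if n_null:
        null_mask[rng_eff.choice(len(names), size=n_null, replace=False)] = True
    plo, phi = config.baseline_prevalence_range
    olo, ohi = config.effect_or_range
    rows = []
    for i, name in enumerate(names):
        base_or = 1.0 if null_mask[i] else float(rng_eff.uniform(olo, ohi))
        baseline = float(rng_eff.uniform(plo, phi))
        for stratum in STRATA:
            or_s = base_or
            if config.stratum_specific_effects and not null_mask[i]:
                or_s = float(rng_eff.uniform(olo, ohi))
            rows.append((name, stratum, baseline, or_s))
    effects = GroundTruthEffects(
        pd.DataFrame(rows, columns=["phenotype", "stratum",
                                    "baseline_prevalence", "odds_ratio"]),
        {name: True for name in names},
    )
    effects.validate()
    return persons, effects


def _covariate_score(persons: pd.DataFrame) -> np.ndarray:
    """Mean-centred confounder score linking demographics to prevalence."""
    z = (0.4 * (persons["estimated_age"].to_numpy(float) - 85.0) / 6.0
         + 0.6 * (persons["death_status"].to_numpy() == "deceased")
         + 0.2 * (persons["sex"].to_numpy() == "male"))
    return z - z.mean()


def phenotype_probabilities(persons: pd.DataFrame,
                            effects: GroundTruthEffects,
                            confounding_strength: float = 0.0) -> pd.DataFrame:
    """Per-patient, per-phenotype acquisition probabilities (logit model)."""
    effects.validate()
    if effects.table.empty:
        return pd.DataFrame(index=persons["person_id"].to_numpy())
    z = confounding_strength * _covariate_score(persons)
    is_case = persons["is_case"].to_numpy(bool)
    piv_base = effects.table.pivot(index="phenotype", columns="stratum",
                                   values="baseline_prevalence")
    piv_or = effects.table.pivot(index="phenotype", columns="stratum",
                                 values="odds_ratio")
    strata = persons["race_ethnicity"].to_numpy()
    base = piv_base[strata].to_numpy()          # (phenotype, patient)
    logor = np.log(piv_or[strata].to_numpy())
    eta = (np.log(base / (1.0 - base))
           + logor * is_case[None, :]
           + z[None, :])
    probs = 1.0 / (1.0 + np.exp(-eta))
    return pd.DataFrame(probs.T, index=persons["person_id"].to_numpy(),
                        columns=piv_base.index)


def simulate_phenotype_matrix(persons: pd.DataFrame,
                              effects: GroundTruthEffects,
                              seed: int,
                              confounding_strength: float = 0.0) -> pd.DataFrame:
    """Draw the boolean patient x phenotype incidence matrix directly.

    This is the Bernoulli layer of the generator without the ICD-code
    round-trip; :func:`generate_diagnoses` emits codes from the same draw.
    Axes are sorted for deterministic downstream serialization.
    """
    rng = np.random.default_rng(seed)
    probs = phenotype_probabilities(persons, effects, confounding_strength)
    draws = rng.random(probs.shape) < probs.to_numpy()
    out = pd.DataFrame(draws, index=probs.index, columns=probs.columns)
    return out.sort_index(axis=0).sort_index(axis=1)


def generate_diagnoses(persons: pd.DataFrame,
                       effects: GroundTruthEffects,
                       config: SimulationConfig,
                       map_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Emit the ICD condition table implied by the effect model.

    Every acquired phenotype emits 1–3 of its mapped ICD codes (sampled with
    replacement, so duplicate events occur and exercise downstream
    de-duplication).  Cases additionally receive one case-defining
    Alzheimer's code.  Raises :class:`GenerationError` if a phenotype under
    effects has no ICD code in the map.
    """
    config.validate()
    if map_table is None:
        map_table = synthetic_phecode_map(config.n_phenotypes)
    codes_by_pheno = {
        name: list(zip(grp["code_system"], grp["icd_code"]))
        for name, grp in map_table.groupby("phenotype")
    }
    missing = sorted(set(effects.table["phenotype"]) - set(codes_by_pheno))
    if missing:
        raise GenerationError(
            "phenotypes without ICD codes in the map: " + ", ".join(missing))

    rng_draw, rng_codes = _child_rngs(config.seed + 1, 2)
    if effects.table.empty:
        return pd.DataFrame(columns=CONDITION_COLUMNS)
    matrix = simulate_phenotype_matrix(
        persons, effects, seed=int(rng_draw.integers(2**31)),
        confounding_strength=config.confounding_strength)

    person_idx, pheno_idx = np.nonzero(matrix.to_numpy())
    persons_arr = matrix.index.to_numpy()
    phenos_arr = matrix.columns.to_numpy()
    n_codes = rng_codes.integers(1, 4, size=person_idx.size)
    rows: list[tuple[str, str, str]] = []
    for pi, fi, k in zip(person_idx, pheno_idx, n_codes):
        options = codes_by_pheno[phenos_arr[fi]]
        picks = rng_codes.integers(0, len(options), size=k)
        pid = persons_arr[pi]
        for j in picks:
            system, code = options[j]
            rows.append((pid, system, code))
    # case-defining AD codes
    for pid in persons.loc[persons["is_case"], "person_id"]:
        rows.append((pid, "ICD10CM", "G30.9"))
    out = pd.DataFrame(rows, columns=CONDITION_COLUMNS)
    return out.sort_values(CONDITION_COLUMNS, kind="stable").reset_index(drop=True)


def write_omop_lite(persons: pd.DataFrame, diagnoses: pd.DataFrame,
                    directory: str | Path,
                    deduplicate: bool = False) -> dict[str, Path]:
    """Write person and condition_occurrence CSVs; returns the file paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    if deduplicate:
        diagnoses = diagnoses.drop_duplicates(CONDITION_COLUMNS)
    paths = {
        "person": directory / "person.csv",
        "condition_occurrence": directory / "condition_occurrence.csv",
    }
    persons[PERSON_COLUMNS].to_csv(paths["person"], index=False)
    diagnoses[CONDITION_COLUMNS].to_csv(paths["condition_occurrence"], index=False)
    return paths


def read_omop_lite(directory: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read tables written by :func:`write_omop_lite` (lossless round-trip)."""
    directory = Path(directory)
    persons = pd.read_csv(directory / "person.csv",
                          dtype={"person_id": str})
    if persons.empty:
        persons = persons.astype({"is_case": bool}, errors="ignore")
    diagnoses = pd.read_csv(directory / "condition_occurrence.csv",
                            dtype={"person_id": str, "code_system": str,
                                   "code": str})
    return persons, diagnoses
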