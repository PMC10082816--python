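"""Synthetic EMR generator: arithmetic, determinism, calibration, I/O."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from comorbnet.errors import ConfigError, GenerationError
from comorbnet.matching import standardized_mean_difference
from comorbnet.simulate import (STRATA, GroundTruthEffects, SimulationConfig,
                                generate_cohort, generate_diagnoses,
                                read_omop_lite, simulate_phenotype_matrix,
                                synthetic_phecode_map, write_omop_lite)


def _effects(phenotypes, baseline, odds_ratio):
    rows = [(p, s, baseline, odds_ratio) for p in phenotypes for s in STRATA]
    return GroundTruthEffects(
        pd.DataFrame(rows, columns=["phenotype", "stratum",
                                    "baseline_prevalence", "odds_ratio"]),
        {p: True for p in phenotypes})


def test_cohort_counts_follow_config():
    config = SimulationConfig(n_cases_per_stratum=422,
                              control_pool_multiplier=5, n_phenotypes=5,
                              seed=7)
    persons, _ = generate_cohort(config)
    assert int(persons["is_case"].sum()) == 1688
    assert int((~persons["is_case"]).sum()) == 8440
    by_stratum = persons.groupby("race_ethnicity")["is_case"].agg(["sum", "count"])
    assert (by_stratum["sum"] == 422).all()
    assert (by_stratum["count"] == 422 * 6).all()


def test_cohort_invariants(small_cohort):
    persons, effects = small_cohort
    assert persons["person_id"].is_unique
    assert (persons["estimated_age"] >= 65).all()
    assert set(persons["race_ethnicity"]) == set(STRATA)
    effects.validate()


def test_seeded_determinism(small_config):
    p1, e1 = generate_cohort(small_config)
    p2, e2 = generate_cohort(small_config)
    pd.testing.assert_frame_equal(p1, p2)
    pd.testing.assert_frame_equal(e1.table, e2.table)
    d1 = generate_diagnoses(p1, e1, small_config)
    d2 = generate_diagnoses(p2, e2, small_config)
    pd.testing.assert_frame_equal(d1, d2)


@pytest.mark.parametrize("field, value", [
    ("n_cases_per_stratum", 0),
    ("control_pool_multiplier", 2),
    ("fraction_null", 1.5),
    ("effect_or_range", (-1.0, 2.0)),
    ("baseline_prevalence_range", (0.0, 0.5)),
])
def test_invalid_config_names_field(field, value):
    config = SimulationConfig(**{field: value})
    with pytest.raises(ConfigError, match=field.split("_")[0]):
        config.validate()


def test_no_confounding_gives_balanced_pool():
    config = SimulationConfig(n_cases_per_stratum=422,
                              control_pool_multiplier=5, n_phenotypes=3,
                              confounding_strength=0.0, seed=5)
    persons, _ = generate_cohort(config)
    cases = persons[persons["is_case"]]
    pool = persons[~persons["is_case"]]
    for cov in ("sex", "estimated_age", "death_status"):
        assert standardized_mean_difference(cases[cov], pool[cov]) < 0.1


def test_confounding_shifts_case_covariates():
    config = SimulationConfig(n_cases_per_stratum=422,
                              control_pool_multiplier=3, n_phenotypes=3,
                              confounding_strength=1.0, seed=5)
    persons, _ = generate_cohort(config)
    cases = persons[persons["is_case"]]
    pool = persons[~persons["is_case"]]
    assert standardized_mean_difference(
        cases["estimated_age"], pool["estimated_age"]) > 0.2


def test_null_prevalence_within_binomial_interval():
    """With OR = 1 both case and control prevalences sit in the exact
    binomial 99% interval around the configured baseline."""
    phenos = ["Essential hypertension"]
    effects = _effects(phenos, baseline=0.3, odds_ratio=1.0)
    persons = pd.DataFrame({
        "person_id": [f"x{i}" for i in range(400)],
        "sex": "female", "estimated_age": 80, "race_ethnicity": "Asian",
        "death_status": "alive", "site": "siteA",
        "is_case": [True] * 200 + [False] * 200,
    })
    matrix = simulate_phenotype_matrix(persons, effects, seed=1)
    lo, hi = binom.ppf([0.005, 0.995], 200, 0.3)
    for group in (persons["is_case"], ~persons["is_case"]):
        count = matrix.loc[persons.loc[group.to_numpy(), "person_id"]].sum().iloc[0]
        assert lo <= count <= hi


def test_case_prevalence_matches_logistic_arithmetic():
    """baseline 0.1, OR 4 -> case prevalence logit^-1(logit(.1)+ln4) ~ .3077."""
    effects = _effects(["Essential hypertension"], baseline=0.1, odds_ratio=4.0)
    n = 4000
    persons = pd.DataFrame({
        "person_id": [f"x{i}" for i in range(n)],
        "sex": "female", "estimated_age": 80, "race_ethnicity": "Black",
        "death_status": "alive", "site": "siteA", "is_case": True,
    })
    matrix = simulate_phenotype_matrix(persons, effects, seed=2)
    expected = 1 / (1 + np.exp(-(np.log(0.1 / 0.9) + np.log(4.0))))
    lo, hi = binom.ppf([0.005, 0.995], n, expected)
    assert lo <= matrix.to_numpy().sum() <= hi
    assert abs(expected - 0.3077) < 5e-4


def test_prevalence_calibration_at_depth():
    """Empirical prevalence converges to the logistic model within 3
    binomial standard errors at n = 5000, per (phenotype, stratum)."""
    effects = _effects(["Hyperlipidemia", "Psychosis"], baseline=0.2,
                       odds_ratio=3.0)
    n = 5000
    persons = pd.DataFrame({
        "person_id": [f"c{i}" for i in range(n)],
        "sex": "male", "estimated_age": 82, "race_ethnicity": "Latine",
        "death_status": "alive", "site": "siteA",
        "is_case": [True] * (n // 2) + [False] * (n // 2),
    })
    matrix = simulate_phenotype_matrix(persons, effects, seed=3)
    case_p = 1 / (1 + np.exp(-(np.log(0.2 / 0.8) + np.log(3.0))))
    for is_case, p in ((True, case_p), (False, 0.2)):
        ids = persons.loc[persons["is_case"] == is_case, "person_id"]
        emp = matrix.loc[ids].mean()
        se = np.sqrt(p * (1 - p) / len(ids))
        assert (np.abs(emp - p) <= 3 * se).all()


def test_zero_phenotypes_gives_empty_diagnoses(small_config):
    from dataclasses import replace
    config = replace(small_config, n_phenotypes=0)
    persons, effects = generate_cohort(config)
    diagnoses = generate_diagnoses(persons, effects, config)
    assert list(diagnoses.columns) == ["person_id", "code_system", "code"]
    # cases still receive their case-defining code, nothing else
    assert set(diagnoses["code"]) <= {"G30.9"} or diagnoses.empty


def test_missing_icd_codes_raise(small_cohort, small_config):
    persons, effects = small_cohort
    tiny_map = synthetic_phecode_map(2)  # covers only 2 of 12 phenotypes
    with pytest.raises(GenerationError, match="Synthetic phenotype|Urinary"):
        generate_diagnoses(persons, effects, small_config, map_table=tiny_map)


def test_omop_lite_round_trip(tmp_path, small_cohort, small_config):
    persons, effects = small_cohort
    diagnoses = generate_diagnoses(persons, effects, small_config)
    write_omop_lite(persons, diagnoses, tmp_path)
    p2, d2 = read_omop_lite(tmp_path)
    pd.testing.assert_frame_equal(persons.reset_index(drop=True), p2)
    pd.testing.assert_frame_equal(diagnoses.reset_index(drop=True), d2)


def test_omop_lite_empty_tables(tmp_path):
    persons = pd.DataFrame(columns=["person_id", "sex", "estimated_age",
                                    "race_ethnicity", "death_status", "site",
                                    "is_case"])
    diagnoses = pd.DataFrame(columns=["person_id", "code_system", "code"])
    paths = write_omop_lite(persons, diagnoses, tmp_path)
    assert paths["person"].read_text().strip() == (
        "person_id,sex,estimated_age,race_ethnicity,death_status,site,is_case")


def test_deduplicated_write(tmp_path, small_cohort, small_config):
    persons, effects = small_cohort
    diagnoses = generate_diagnoses(persons, effects, small_config)
    write_omop_lite(persons, diagnoses, tmp_path, deduplicate=True)
    _, d2 = read_omop_lite(tmp_path)
    assert not d2.duplicated(["person_id", "code_system", "code"]).any()


def test_validation_site_effects_null_out_non_shared():
    effects = _effects(["A", "B"], baseline=0.2, odds_ratio=4.0)
    effects.shared_across_sites = {"A": True, "B": False}
    val = effects.for_validation_site()
    t = val.table.set_index("phenotype")
    assert (t.loc["A", "odds_ratio"] == 4.0).all()
    assert (t.loc["B", "odds_ratio"] == 1.0).all()
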