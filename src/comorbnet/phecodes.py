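"""ICD-to-phecode phenotype mapping and the binary phenotype matrix.

Phecodes aggregate ICD-9-CM / ICD-10-CM billing codes into clinically
meaningful phenotype groups, each assigned to a category (circulatory
system, mental disorders, ...).  Phecodes with no category are excluded
from all analyses.  ICD codes are matched exactly (string equality after
trimming); the published map files enumerate codes explicitly, so no
prefix rollup is performed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)

MAP_COLUMNS = ["code_system", "icd_code", "phecode", "phenotype", "category"]
VALID_CODE_SYSTEMS = {"ICD9CM", "ICD10CM"}


def fixture_map_path() -> Path:
    """Path of the bundled miniature synthetic phecode map (CSV)."""
    return Path(resources.files("comorbnet").joinpath(
        "data/synthetic_phecode_map.csv"))


@dataclass
class UnmappedReport:
    """Diagnoses that produced no phenotype assignment, and why."""

    unmapped: dict[tuple[str, str], int] = field(default_factory=dict)
    excluded_no_category: dict[tuple[str, str], int] = field(default_factory=dict)

    @property
    def n_unmapped_events(self) -> int:
        return sum(self.unmapped.values())

    @property
    def n_excluded_events(self) -> int:
        return sum(self.excluded_no_category.values())


def load_phecode_map(paths: str | Path | Sequence[str | Path],
                     column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Load one or more phecode map CSVs into the normalized schema.

    Parameters
    ----------
    paths
        CSV file(s).  Multiple files (e.g. separate ICD-9 and ICD-10 maps)
        are concatenated.
    column_map
        Optional mapping from the file's column names to the canonical
        ``code_system, icd_code, phecode, phenotype, category`` names, to
        tolerate dialect differences between published map layouts.

    Identical duplicate rows are dropped (logged); ICD codes are stripped of
    surrounding whitespace with decimal points preserved; missing categories
    become empty strings.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames = []
    for path in paths:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        if column_map:
            df = df.rename(columns=dict(column_map))
        missing = [c for c in MAP_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(
                f"{path}: missing required column(s) {', '.join(missing)}")
        frames.append(df[MAP_COLUMNS])
    table = pd.concat(frames, ignore_index=True)
    for col in ("code_system", "icd_code", "phecode", "phenotype"):
        table[col] = table[col].str.strip()
    table["category"] = table["category"].fillna("").str.strip()
    bad = set(table["code_system"]) - VALID_CODE_SYSTEMS
    if bad:
        raise SchemaError(
            f"unknown code_system value(s): {', '.join(sorted(bad))}")
    n_before = len(table)
    table = table.drop_duplicates().reset_index(drop=True)
    if len(table) < n_before:
        logger.info("phecode map: dropped %d duplicate rows",
                    n_before - len(table))
    # one phenotype name per phecode
    names_per_phecode = table.groupby("phecode")["phenotype"].nunique()
    conflicting = names_per_phecode[names_per_phecode > 1]
    if not conflicting.empty:
        raise SchemaError(
            "phecode(s) mapped to multiple phenotype names: "
            + ", ".join(conflicting.index[:5]))
    return table


def map_diagnoses(diagnoses: pd.DataFrame,
                  map_table: pd.DataFrame) -> tuple[pd.DataFrame, UnmappedReport]:
    """Map ICD diagnosis events to (person_id, phenotype) assignments.

    Each (person, phenotype) pair appears once regardless of how many ICD
    events support it.  Phecodes with an empty category are excluded and
    counted in the report; ICD codes absent from the map are counted as
    unmapped.  Never fatal: an empty map yields empty assignments plus a
    full unmapped report.
    """
    report = UnmappedReport()
    if diagnoses.empty:
        return (pd.DataFrame(columns=["person_id", "phenotype"]), report)
    events = diagnoses.copy()
    events["code"] = events["code"].str.strip()

    usable = map_table[map_table["category"] != ""]
    merged = events.merge(
        map_table.rename(columns={"icd_code": "code"}),
        on=["code_system", "code"], how="left")

    unmatched = merged["phenotype"].isna()
    for (system, code), n in (merged.loc[unmatched]
                              .groupby(["code_system", "code"]).size().items()):
        report.unmapped[(system, code)] = int(n)
    no_cat = (~unmatched) & (merged["category"] == "")
    for (system, code), n in (merged.loc[no_cat]
                              .groupby(["code_system", "code"]).size().items()):
        report.excluded_no_category[(system, code)] = int(n)

    kept = merged.loc[(~unmatched) & (merged["category"] != ""),
                      ["person_id", "phenotype"]]
    assignments = (kept.drop_duplicates()
                   .sort_values(["person_id", "phenotype"], kind="stable")
                   .reset_index(drop=True))
    # keep the usable-map reference for callers that want categories
    assignments.attrs["n_usable_map_rows"] = len(usable)
    return assignments, report


def phenotype_categories(map_table: pd.DataFrame) -> dict[str, str]:
    """Phenotype name -> phecode category (first non-empty per phenotype)."""
    usable = map_table[map_table["category"] != ""]
    return dict(usable.drop_duplicates("phenotype")
                .set_index("phenotype")["category"])


def build_phenotype_matrix(assignments: pd.DataFrame,
                           patients: Iterable[str],
                           exclude_phenotypes: Iterable[str] = ()) -> pd.DataFrame:
    """Binary patient x phenotype matrix over all listed patients.

    Patients with no assignment get all-zero rows.  Phenotypes listed in
    ``exclude_phenotypes`` (e.g. the case-defining Alzheimer's phenotype)
    are removed from the column axis.  Axes are sorted lexicographically
    for deterministic serialization.
    """
    patients = pd.Index(sorted(set(patients)), name="person_id")
    exclude = set(exclude_phenotypes)
    if not assignments.empty:
        unknown = set(assignments["person_id"]) - set(patients)
        if unknown:
            raise IntegrityError(
                f"assignments reference unknown person_id(s): "
                f"{', '.join(sorted(unknown)[:5])}")
    kept = assignments[~assignments["phenotype"].isin(exclude)]
    if kept.empty:
        return pd.DataFrame(False, index=patients, columns=[])
    wide = (kept.assign(value=True)
            .pivot_table(index="person_id", columns="phenotype",
                         values="value", aggfunc="any", fill_value=False))
    matrix = wide.reindex(index=patients, fill_value=False)
    matrix = matrix.sort_index(axis=1)
    matrix.columns.name = "phenotype"
    return matrix.astype(bool)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Serialize the phenotype matrix as wide TSV (0/1 cells)."""
    matrix.astype(int).to_csv(path, sep="\t")


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns.name = "phenotype"
    return df.astype(bool)
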