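"""2-D embedding of one-hot phenotype profiles and group comparisons.

Patients are represented by the rows of the binary phenotype matrix (the
case-defining Alzheimer's phenotype must already be excluded from the
columns — enforced here) and embedded with UMAP.  The embedding algorithm
is consumed as published via ``umap-learn``; the contribution of this
module is the feature construction contract and the distributional
comparisons of the resulting components: Mann-Whitney U for two-level
groupings (AD status), Kruskal-Wallis plus Dunn's Bonferroni-corrected
post-hoc tests for more than two levels (stratum, care site).

Determinism note: passing a seed forces umap-learn into single-threaded
mode, which is what makes repeated runs byte-identical.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ContractError
from .ranktests import dunn_posthoc, kruskal_wallis, mann_whitney_u

#: Phenotype names that must never enter the embedded feature set.
DEFAULT_EXCLUDED = ("Alzheimer's disease",)


@dataclass
class EmbeddingResult:
    coordinates: pd.DataFrame  # index person_id, columns ["component1", "component2"]
    feature_count: int
    n_neighbors: int
    min_dist: float
    seed: int


@dataclass
class GroupComparison:
    """Rank-test results for one embedding component under one grouping."""

    grouping: str
    component: str
    test: str                      # "MWU" or "KW"
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None = None  # Dunn pairs when test == "KW"


def embed_2d(matrix: pd.DataFrame, n_neighbors: int = 15,
             min_dist: float = 0.1, seed: int = 0,
             forbidden_phenotypes=DEFAULT_EXCLUDED) -> EmbeddingResult:
    """Embed the phenotype matrix rows into two UMAP components."""
    present = set(matrix.columns) & set(forbidden_phenotypes)
    if present:
        raise ContractError(
            "case-defining phenotype(s) present in the feature matrix: "
            + ", ".join(sorted(present)))
    if len(matrix) < 10:
        raise ContractError("embedding requires at least 10 patients")
    import umap  # deferred: numba compilation is expensive

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            min_dist=min_dist, random_state=seed)
        coords = reducer.fit_transform(matrix.to_numpy(float))
    frame = pd.DataFrame(coords, index=matrix.index,
                         columns=["component1", "component2"])
    return EmbeddingResult(coordinates=frame,
                           feature_count=matrix.shape[1],
                           n_neighbors=n_neighbors, min_dist=min_dist,
                           seed=seed)


def compare_embedding(embedding: EmbeddingResult, labels: pd.Series,
                      grouping: str) -> list[GroupComparison]:
    """Compare component distributions across the label's levels.

    Two levels: Mann-Whitney U.  More than two: Kruskal-Wallis followed by
    Dunn's Bonferroni-corrected pairwise tests.  Levels with zero patients
    are dropped with a warning.
    """
    coords = embedding.coordinates
    labels = labels.reindex(coords.index)
    if labels.isna().any():
        raise ContractError("labels must cover every embedded patient")
    counts = labels.value_counts()
    empty = [str(level) for level, n in counts.items() if n == 0]
    if empty:
        warnings.warn(f"dropping empty grouping level(s): {empty}",
                      stacklevel=2)
    levels = sorted(counts[counts > 0].index.tolist())
    if len(levels) < 2:
        raise ContractError(f"grouping {grouping!r} has fewer than 2 levels")
    results = []
    for component in coords.columns:
        values = coords[component].to_numpy()
        if len(levels) == 2:
            x = values[(labels == levels[0]).to_numpy()]
            y = values[(labels == levels[1]).to_numpy()]
            u, p = mann_whitney_u(x, y)
            results.append(GroupComparison(grouping, component, "MWU",
                                           u, p, None))
        else:
            h, p = kruskal_wallis(values, labels.to_numpy())
            pairs = dunn_posthoc(values, labels.to_numpy())
            results.append(GroupComparison(grouping, component, "KW",
                                           h, p, pairs))
    return results


def comparisons_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten comparison results for serialization."""
    rows = []
    for comparison in comparisons:
        rows.append({"grouping": comparison.grouping,
                     "component": comparison.component,
                     "test": comparison.test,
                     "statistic": comparison.statistic,
                     "p_value": comparison.p_value})
    return pd.DataFrame(rows)
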