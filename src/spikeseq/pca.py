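"""Temporal-profile PCA and Fisher-exact gene-set enrichment.

Each gene's expression series is first normalized to its own mean over the
included samples, so PCA operates on *temporal shape* rather than absolute
abundance.  The steady-state replicates enter as separate "time points",
which lets a component's stability across replicates be inspected directly.
Columns (time points) are mean-centered before the decomposition; without
centering the leading component would be the trivial all-ones direction.

Component signs are fixed by convention so plots and scores are reproducible:
PC1 points "up in starvation" (its value at the last starvation time point
exceeds its steady-state mean), PC2 points "up in the early surge" (positive
at the first starvation time point), and any further component has its
largest-magnitude loading positive.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .normalize import NormalizedMatrix


@dataclasses.dataclass
class ProfileMatrix:
    """Genes x samples matrix of mean-1 temporal profiles."""

    values: pd.DataFrame
    samples: pd.DataFrame
    dropped_genes: list[str]  # zero-mean rows excluded from the analysis


def profile_normalize(
    norm: NormalizedMatrix,
    include_samples: Sequence[str] | None = None,
) -> ProfileMatrix:
    """Divide each gene's series by its own mean over the included samples.

    By default the steady-state and starvation samples are included and
    outlier-flagged samples are excluded.  Genes whose mean over the included
    samples is zero carry no shape information and are dropped (reported in
    ``dropped_genes``).
    """
    if include_samples is None:
        meta = norm.samples
        mask = meta["condition"].isin(["steady_state", "starvation"]) & ~meta[
            "is_outlier"
        ].astype(bool)
        include_samples = meta.index[mask].tolist()
    else:
        include_samples = list(include_samples)
        missing = set(include_samples) - set(norm.samples.index)
        if missing:
            raise ValueError(f"unknown samples requested: {sorted(missing)}")
    if len(include_samples) < 2:
        raise ValueError("need at least 2 included samples for a profile")
    values = norm.values[include_samples]
    means = values.mean(axis=1)
    nonzero = means > 0
    dropped = values.index[~nonzero].tolist()
    profiles = values.loc[nonzero].div(means[nonzero], axis=0)
    return ProfileMatrix(
        values=profiles,
        samples=norm.samples.loc[include_samples].copy(),
        dropped_genes=dropped,
    )


@dataclasses.dataclass
class PCAResult:
    """Explained-variance fractions, per-gene scores and component vectors."""

    explained_fraction: pd.Series  # index PC1, PC2, ...
    scores: pd.DataFrame  # genes x components
    components: pd.DataFrame  # components x samples
    samples: pd.DataFrame


def _fix_signs(
    components: np.ndarray, scores: np.ndarray, samples: pd.DataFrame
) -> None:
    """Apply the sign convention in place (components are rows)."""
    steady = samples["condition"].to_numpy() == "steady_state"
    starving = samples["condition"].to_numpy() == "starvation"
    times = samples["time_min"].to_numpy(float)
    for k in range(components.shape[0]):
        vec = components[k]
        flip = False
        if k == 0 and starving.any() and steady.any():
            last = np.argmax(np.where(starving, times, -np.inf))
            flip = (vec[last] - vec[steady].mean()) < 0
        elif k == 1 and starving.any():
            first = np.argmin(np.where(starving, times, np.inf))
            flip = vec[first] < 0
        else:
            flip = vec[np.argmax(np.abs(vec))] < 0
        if flip:
            components[k] = -vec
            scores[:, k] = -scores[:, k]


def run_pca(profiles: ProfileMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of the centered profile matrix (genes as observations).

    All non-trivial components are retained by default; explained fractions
    are eigenvalue shares and sum to 1 over the full decomposition.
    """
    X = profiles.values.to_numpy(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 genes and 2 samples for PCA")
    if not np.any(np.std(X, axis=0) > 0):
        raise ValueError("degenerate (rank-0) profile matrix")
    max_rank = min(X.shape[0], X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    components = pca.components_.copy()
    _fix_signs(components, scores, profiles.samples)
    names = [f"PC{i + 1}" for i in range(k)]
    return PCAResult(
        explained_fraction=pd.Series(
            pca.explained_variance_ratio_, index=names, name="explained_fraction"
        ),
        scores=pd.DataFrame(scores, index=profiles.values.index, columns=names),
        components=pd.DataFrame(
            components, index=names, columns=profiles.values.columns
        ),
        samples=profiles.samples.copy(),
    )


def select_extremes(
    result: PCAResult, component: str = "PC1", fraction: float = 0.1
) -> tuple[list[str], list[str]]:
    """Top and bottom ``ceil(fraction * N)`` genes by component score.

    Ties at the boundary resolve lexicographically by gene id, so the subsets
    are deterministic.
    """
    if component not in result.scores.columns:
        raise KeyError(f"unknown component: {component}")
    if not 0 < fraction <= 0.5:
        raise ValueError("fraction must lie in (0, 0.5]")
    scores = result.scores[component]
    n = math.ceil(fraction * len(scores))
    by_id = scores.sort_index()
    top = by_id.sort_values(ascending=False, kind="stable").index[:n].tolist()
    bottom = by_id.sort_values(ascending=True, kind="stable").index[:n].tolist()
    return top, bottom


def enrich(
    subset: Sequence[str],
    gene_sets: Mapping[str, Iterable[str]],
    universe: Sequence[str],
) -> pd.DataFrame:
    """One-sided Fisher-exact enrichment of ``subset`` in each gene set.

    Sets are intersected with the universe; p-values are adjusted across all
    tested sets with the Benjamini-Hochberg step-up rule.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    subset_set = set(subset)
    stray = subset_set - universe_set
    if stray:
        raise ValueError(f"subset genes outside the universe: {sorted(stray)[:5]}")
    rows = []
    for set_id, members in gene_sets.items():
        members_set = set(members) & universe_set
        a = len(subset_set & members_set)  # in subset, in set
        b = len(subset_set) - a  # in subset, not in set
        c = len(members_set) - a  # not in subset, in set
        d = len(universe_set) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append(
            {
                "set_id": set_id,
                "overlap": a,
                "set_size": len(members_set),
                "subset_size": len(subset_set),
                "universe_size": len(universe_set),
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adjusted"] = multipletests(table["p_value"], method="fdr_bh")[1]
    else:
        table["p_adjusted"] = pd.Series(dtype=float)
    return table
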