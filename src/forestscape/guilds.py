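"""Empirical habitat-guild classification from cumulative accumulation curves.

A species' habitat association is read off the way its individuals accumulate
across survey locations ranked by surrounding forest amount.  At each scale,
locations are sorted by forest amount (ascending, ties by location id) and two
cumulative-share curves are compared:

* ``F_species(k)`` — share of the species' individuals in the first k ranks;
* ``F_forest(k)``  — share of total forest amount in the first k ranks.

The Kolmogorov–Smirnov statistic ``D = max_k |F_species − F_forest|`` with the
signed gap at its (first) argmax carries the direction: a negative gap means
individuals lag forest accumulation (concentrated in the most-forested
landscapes → *forest-area sensitive*), a positive gap means they run ahead of
it (concentrated where forest is scarce → *edge/open*).  Because counts over
locations are not exchangeable draws from a continuous distribution, the
classical KS null does not apply; significance comes from a permutation test
that shuffles the count vector over locations, preserving the count multiset
exactly.  Species with no significant gap accumulate individuals at the rate
forest accumulates: *forest generalists*.

Per-scale labels are combined by majority vote across scales, ties resolved
to generalist.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "AREA_SENSITIVE",
    "GENERALIST",
    "EDGE_OPEN",
    "cumulative_curves",
    "ks_compare",
    "classify_scale",
    "classify_species",
    "filter_species",
    "KSGuildClassifier",
]

AREA_SENSITIVE = "area-sensitive"
GENERALIST = "generalist"
EDGE_OPEN = "edge-open"

#: Exclusion flags honoured by :func:`filter_species`.
EXCLUSION_FLAGS = frozenset({"hybrid", "irregular", "raptor", "waterfowl"})


def cumulative_curves(
    counts: np.ndarray, forest: np.ndarray, location_ids: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative species-share and forest-share curves over ranked locations.

    Locations are ranked by forest amount ascending, ties broken by location
    id; both curves are nondecreasing prefix shares ending at 1.
    """
    counts = np.asarray(counts, dtype=float)
    forest = np.asarray(forest, dtype=float)
    if counts.shape != forest.shape or counts.ndim != 1:
        raise ValueError("counts and forest must be 1-D arrays of equal length")
    if len(counts) < 2:
        raise ValueError("need at least two locations")
    total = counts.sum()
    if total <= 0:
        raise ValueError("species total count is zero; curves undefined")
    if location_ids is None:
        location_ids = np.arange(len(counts))
    order = np.lexsort((np.asarray(location_ids), forest))
    f_species = np.cumsum(counts[order]) / total
    forest_total = forest.sum()
    if forest_total > 0:
        f_forest = np.cumsum(forest[order]) / forest_total
    else:
        f_forest = np.arange(1, len(forest) + 1) / len(forest)
    return f_species, f_forest


def _d_and_gap(f_species: np.ndarray, f_forest: np.ndarray) -> tuple[float, float]:
    gaps = f_species - f_forest
    k = int(np.argmax(np.abs(gaps)))  # first argmax on ties
    return float(abs(gaps[k])), float(gaps[k])


def ks_compare(
    counts: np.ndarray,
    forest: np.ndarray,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
    location_ids: np.ndarray | None = None,
) -> tuple[float, float, float]:
    """KS statistic, signed gap at the argmax, and permutation p-value.

    The null shuffles the count vector over locations; ``p = (1 + #{D_perm
    >= D}) / (n_permutations + 1)``.
    """
    if n_permutations < 99:
        raise ValueError("at least 99 permutations are required")
    f_species, f_forest = cumulative_curves(counts, forest, location_ids)
    d_obs, gap = _d_and_gap(f_species, f_forest)

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = np.asarray(counts, dtype=float)
    if location_ids is None:
        location_ids = np.arange(len(counts))
    order = np.lexsort((np.asarray(location_ids), np.asarray(forest, dtype=float)))
    sorted_counts = counts[order]
    total = counts.sum()
    n = len(counts)
    # batch permutations: independent shuffles of the count vector
    keys = rng.random((n_permutations, n))
    idx = np.argsort(keys, axis=1)
    perm = sorted_counts[idx]
    f_perm = np.cumsum(perm, axis=1) / total
    d_perm = np.abs(f_perm - f_forest[None, :]).max(axis=1)
    p = (1.0 + (d_perm >= d_obs - 1e-12).sum()) / (n_permutations + 1.0)
    return d_obs, gap, float(p)


def classify_scale(p: float, gap: float, alpha: float = 0.05) -> str:
    """Per-scale guild label from the permutation test outcome."""
    if p < alpha and gap < 0:
        return AREA_SENSITIVE
    if p < alpha and gap > 0:
        return EDGE_OPEN
    return GENERALIST


def classify_species(scale_labels: list[str]) -> str:
    """Majority vote over per-scale labels; ties go to generalist."""
    tally = Counter(scale_labels)
    top = max(tally.values())
    winners = [lab for lab, k in tally.items() if k == top]
    return winners[0] if len(winners) == 1 else GENERALIST


def filter_species(
    counts: pd.DataFrame,
    min_locations: int = 30,
    exclusion_flags: dict[str, set[str]] | None = None,
) -> list[str]:
    """Species retained for analysis.

    Keeps species occurring (count > 0) at ``min_locations`` or more
    locations and drops species whose flag set intersects the exclusion
    flags (hybrid / irregular / raptor / waterfowl).
    """
    occ = (
        counts.loc[counts["count"] > 0]
        .groupby("species")["location_id"]
        .nunique()
    )
    keep = occ[occ >= min_locations].index.tolist()
    if exclusion_flags:
        keep = [
            sp
            for sp in keep
            if not (set(exclusion_flags.get(sp, ())) & EXCLUSION_FLAGS)
        ]
    return sorted(keep)


@dataclass
class GuildEvidence:
    """Per-species classification evidence across scales."""

    species: str
    per_scale: pd.DataFrame  # radius, D, gap, p, label
    final_label: str


class KSGuildClassifier(BaseEstimator):
    """Classify species into habitat guilds from counts and forest amounts.

    Parameters
    ----------
    alpha : significance level of the permutation test per scale.
    n_permutations : permutations per species × scale (≥ 99).
    random_state : seed for the permutation stream.

    Attributes (after ``fit``)
    --------------------------
    labels_ : dict species -> final guild label.
    evidence_ : tidy frame (species, radius, D, gap, p, label).
    """

    def __init__(
        self, alpha: float = 0.05, n_permutations: int = 999, random_state: int = 0
    ):
        self.alpha = alpha
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, counts: pd.DataFrame, forest_by_scale: pd.DataFrame):
        """Fit on a long count table and per-scale forest amounts.

        ``counts``: columns location_id, species, count (zero rows optional).
        ``forest_by_scale``: columns location_id, radius, FA covering every
        location — classification uses the full location set, before any
        downstream landscape filtering.
        """
        rng = np.random.default_rng(self.random_state)
        radii = np.sort(forest_by_scale["radius"].unique())
        loc_ids = np.sort(forest_by_scale["location_id"].unique())
        fa = {
            float(r): (
                forest_by_scale[forest_by_scale["radius"] == r]
                .set_index("location_id")["FA"]
                .reindex(loc_ids)
                .to_numpy(dtype=float)
            )
            for r in radii
        }
        wide = (
            counts.pivot_table(
                index="location_id", columns="species", values="count",
                aggfunc="sum", fill_value=0,
            )
            .reindex(loc_ids, fill_value=0)
        )
        rows = []
        labels = {}
        for sp in wide.columns:
            c = wide[sp].to_numpy(dtype=float)
            per_scale_labels = []
            for r in radii:
                d, gap, p = ks_compare(
                    c, fa[float(r)], self.n_permutations, rng, loc_ids
                )
                lab = classify_scale(p, gap, self.alpha)
                per_scale_labels.append(lab)
                rows.append(
                    {"species": sp, "radius": float(r), "D": d, "gap": gap,
                     "p": p, "label": lab}
                )
            labels[sp] = classify_species(per_scale_labels)
        self.evidence_ = pd.DataFrame(rows)
        self.labels_ = labels
        self.radii_ = [float(r) for r in radii]
        return self

    def predict(self, species: list[str]) -> list[str]:
        """Final guild labels for the given species (must have been fit)."""
        return [self.labels_[sp] for sp in species]
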