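"""Relative importance of landscape-structure components by placement counts.

Standardized effects from the best-scale model of each diversity measure are
grouped into three components of landscape structure:

* **amount** — forest amount (FA);
* **configuration** — forest patch density (FPD) and clumpiness (FCI);
* **matrix quality** — urbanization (URB, URBHI) and agriculture amount (AG).

Per measure, each component is represented by its *meaningful* effect (95% CI
strictly excluding 0) of largest absolute size; components with
representatives are placed first/second/third by |beta|.  When exactly two
components have meaningful effects, the remaining component is placed third;
a measure with no meaningful landscape effect contributes nothing.  The
overall ordering assigns components to ranks so as to agree with the
placement counts as much as possible — the component placed first most often
is deemed most important, the one placed second most often second, and the
one placed third most often least important — resolved jointly as the
maximum-agreement assignment, with exact ties broken toward
amount > matrix quality > configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from itertools import permutations

import pandas as pd

__all__ = [
    "COMPONENT_OF",
    "COMPONENTS",
    "meaningful",
    "rank_components",
    "tally_and_order",
    "PlacementTally",
    "load_example_effects",
]

COMPONENT_OF = {
    "FA": "amount",
    "FPD": "configuration",
    "FCI": "configuration",
    "URB": "matrix quality",
    "URBHI": "matrix quality",
    "AG": "matrix quality",
}

#: Fixed priority used only to break exact ties.
COMPONENTS = ("amount", "matrix quality", "configuration")


def meaningful(lo: float, hi: float) -> bool:
    """True iff the 95% CI strictly excludes zero (a bound at 0 does not)."""
    if lo > hi:
        raise ValueError(f"invalid interval ({lo}, {hi})")
    return (lo > 0 and hi > 0) or (lo < 0 and hi < 0)


def rank_components(effects: pd.DataFrame) -> dict[str, int]:
    """Placements (component -> rank 1/2/3) for one diversity measure.

    ``effects`` has columns predictor, beta, lo, hi for the measure's
    best-scale model; predictors outside :data:`COMPONENT_OF` are ignored.
    """
    reps: dict[str, float] = {}
    for row in effects.itertuples(index=False):
        comp = COMPONENT_OF.get(row.predictor)
        if comp is None or not meaningful(row.lo, row.hi):
            continue
        mag = abs(row.beta)
        if comp not in reps or mag > reps[comp]:
            reps[comp] = mag
    if not reps:
        return {}
    order = sorted(
        reps, key=lambda c: (-reps[c], COMPONENTS.index(c))
    )
    mags = sorted(reps.values(), reverse=True)
    if len(mags) > len(set(mags)):
        warnings.warn(
            "tied |beta| across components; tie broken toward "
            "amount > matrix quality > configuration",
            stacklevel=2,
        )
    placements = {comp: i + 1 for i, comp in enumerate(order)}
    if len(reps) == 2:
        # two meaningful components: the meaningless one is ranked third
        (rest,) = set(COMPONENTS) - set(reps)
        placements[rest] = 3
    return placements


@dataclass
class PlacementTally:
    """First/second/third placement counts per component and overall order."""

    counts: pd.DataFrame  # index component, columns first/second/third
    order: tuple[str, str, str]
    per_measure: dict[str, dict[str, int]] = field(default_factory=dict)


def tally_and_order(
    effect_table: pd.DataFrame, measures: list[str] | None = None
) -> PlacementTally:
    """Accumulate placements over diversity measures and order components.

    ``effect_table`` has columns measure, predictor, beta, lo, hi; a measure
    listed in ``measures`` but absent from the table has no meaningful
    effects and contributes no placements.
    """
    if measures is None:
        measures = list(pd.unique(effect_table["measure"]))
    counts = pd.DataFrame(
        0, index=list(COMPONENTS), columns=["first", "second", "third"]
    )
    per_measure = {}
    for m in measures:
        sub = effect_table[effect_table["measure"] == m]
        placements = rank_components(sub) if len(sub) else {}
        per_measure[m] = placements
        for comp, rank in placements.items():
            counts.loc[comp, ["first", "second", "third"][rank - 1]] += 1

    # maximum-agreement assignment of components to ranks; candidate
    # permutations are scanned in tie-break priority order so the first
    # best-scoring assignment wins exact ties
    best_score, best_perm = -1, None
    for perm in permutations(COMPONENTS):
        score = sum(
            counts.loc[comp, ["first", "second", "third"][rank]]
            for rank, comp in enumerate(perm)
        )
        if score > best_score:
            best_score, best_perm = score, perm
    return PlacementTally(counts=counts, order=best_perm, per_measure=per_measure)


def load_example_effects() -> pd.DataFrame:
    """Best-scale standardized effects from a statewide forest-bird analysis.

    A worked example table (measure, predictor, beta, lo, hi) of meaningful
    coefficients across nine diversity measures — relative abundance (RA),
    Chao1 richness (SR), and Pielou evenness (J) for the all-forest (AF),
    forest-area sensitive (AS), and forest generalist (FG) guilds.  Measures
    with no meaningful landscape effect (AF_SR, AS_SR) have no rows.
    """
    with resources.files("forestscape.data").joinpath(
        "example_effects.csv"
    ).open() as fh:
        return pd.read_csv(fh)


#: Names of the nine diversity measures in the example table's notation.
EXAMPLE_MEASURES = [
    "AF_RA", "AF_SR", "AF_J",
    "AS_RA", "AS_SR", "AS_J",
    "FG_RA", "FG_SR", "FG_J",
]
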