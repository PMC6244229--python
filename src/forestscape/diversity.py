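"""Per-location diversity measures: relative abundance, Chao1, Pielou.

Nine responses are computed per location: relative abundance (RA), Chao1
estimated richness (SR), and Pielou evenness (J) for each of three guilds —
forest-area sensitive, forest generalist, and their union ("all-forest").

Chao1 uses the classic estimator ``S_obs + F1^2 / (2 F2)`` with the
bias-corrected fallback ``S_obs + F1 (F1 - 1) / 2`` when no doubletons are
observed, so it is finite for every sample.  Pielou evenness is Shannon
entropy (natural log) divided by ``ln S_obs`` and is undefined (NaN) for
locations with fewer than two species — such locations are dropped only from
models using that response.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .guilds import AREA_SENSITIVE, GENERALIST

__all__ = [
    "ALL_FOREST",
    "relative_abundance",
    "chao1",
    "shannon_entropy",
    "pielou",
    "diversity_table",
]

ALL_FOREST = "all-forest"


def _check_counts(counts) -> np.ndarray:
    a = np.asarray(counts)
    if a.size and not np.all(np.equal(np.mod(a, 1), 0)):
        raise ValueError("abundances must be nonnegative integers")
    a = a.astype(np.int64) if a.size else a.reshape(0).astype(np.int64)
    if (a < 0).any():
        raise ValueError("abundances must be nonnegative integers")
    return a[a > 0]


def relative_abundance(counts) -> int:
    """Total individuals: the sum of species counts."""
    a = np.asarray(counts)
    return int(a.sum()) if a.size else 0


def chao1(counts) -> float:
    """Chao1 estimated species richness.

    ``S_obs + F1^2/(2 F2)`` when doubletons exist; the bias-corrected
    ``S_obs + F1 (F1 - 1)/2`` when ``F2 = 0``; 0 with no species observed.
    """
    a = _check_counts(counts)
    s_obs = a.size
    if s_obs == 0:
        return 0.0
    f1 = int((a == 1).sum())
    f2 = int((a == 2).sum())
    if f2 > 0:
        return s_obs + f1 * f1 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def shannon_entropy(counts) -> float:
    """Shannon index H' (nats) over species with positive counts."""
    a = _check_counts(counts).astype(float)
    if a.size == 0:
        return 0.0
    p = a / a.sum()
    return float(-(p * np.log(p)).sum())


def pielou(counts) -> float:
    """Pielou evenness J = H'/ln(S_obs); NaN when fewer than two species."""
    a = _check_counts(counts)
    if a.size <= 1:
        return float("nan")
    return shannon_entropy(a) / np.log(a.size)


def diversity_table(
    counts: pd.DataFrame,
    guild_of: dict[str, str],
    location_ids=None,
) -> pd.DataFrame:
    """All nine diversity measures per location.

    ``counts`` is the long table (location_id, species, count); ``guild_of``
    maps species to guild labels.  Species labelled edge/open are outside all
    three modelled guilds.  Returns one row per location × guild with RA,
    S_obs, F1, F2, SR (Chao1), H, and J.  Locations in ``location_ids``
    (default: those present in ``counts``) appear for every guild even when
    no guild member was recorded there.
    """
    guilds = {
        AREA_SENSITIVE: {s for s, g in guild_of.items() if g == AREA_SENSITIVE},
        GENERALIST: {s for s, g in guild_of.items() if g == GENERALIST},
    }
    guilds[ALL_FOREST] = guilds[AREA_SENSITIVE] | guilds[GENERALIST]
    if location_ids is None:
        location_ids = np.sort(counts["location_id"].unique())

    rows = []
    by_loc = dict(tuple(counts.groupby("location_id"))) if len(counts) else {}
    for loc in location_ids:
        sub = by_loc.get(loc)
        for guild, members in guilds.items():
            if sub is not None and len(members):
                vals = (
                    sub.loc[sub["species"].isin(members)]
                    .groupby("species")["count"].sum().to_numpy()
                )
            else:
                vals = np.array([], dtype=np.int64)
            vals = vals[vals > 0]
            rows.append(
                {
                    "location_id": loc,
                    "guild": guild,
                    "RA": relative_abundance(vals),
                    "S_obs": int(vals.size),
                    "F1": int((vals == 1).sum()),
                    "F2": int((vals == 2).sum()),
                    "SR": chao1(vals),
                    "H": shannon_entropy(vals),
                    "J": pielou(vals),
                }
            )
    return pd.DataFrame(rows)
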