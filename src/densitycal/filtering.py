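"""Stringent filtering and geographic subsampling of community checklists.

Mirrors the standard semi-structured data-preparation recipe: keep complete,
stationary counts at personal locations, restrict start times to the seven
hours after nautical dawn and durations to 3-30 min, drop presence-only "X"
records, then retain one checklist per cell of a 200-m grid to reduce
overrepresentation of popular birding locations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

#: reporting order of the filtering rules
RULE_ORDER = ("protocol", "location_type", "time", "duration", "presence_only", "completeness")


def filter_checklists(
    checklists: pd.DataFrame,
    max_hours_after_dawn: float = 7.0,
    duration_range: tuple[float, float] = (3.0, 30.0),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the stringent filtering rules; return (filtered, removal tally).

    Retains checklists that are stationary, at a personal location, started
    within ``max_hours_after_dawn`` hours of nautical dawn (and not before
    dawn), lasted within ``duration_range`` minutes, report a numeric count
    (no "X"), and are complete.  The tally counts removals rule-by-rule in
    :data:`RULE_ORDER`; the retained set is the intersection of the
    predicates, so rule order affects the tally only.
    """
    df = checklists
    max_min = max_hours_after_dawn * 60.0
    lo, hi = duration_range
    predicates = {
        "protocol": df["protocol"] == "stationary",
        "location_type": df["location_type"] == "personal",
        "time": (df["min_since_dawn"] >= 0) & (df["min_since_dawn"] <= max_min),
        "duration": (df["duration_min"] >= lo) & (df["duration_min"] <= hi),
        "presence_only": ~df["is_x"].astype(bool),
        "completeness": df["complete"].astype(bool),
    }
    tally: dict[str, int] = {}
    keep = pd.Series(True, index=df.index)
    for rule in RULE_ORDER:
        newkeep = keep & predicates[rule]
        tally[rule] = int(keep.sum() - newkeep.sum())
        keep = newkeep
    return df.loc[keep].copy(), tally


def geographic_sample(checklists: pd.DataFrame, grid_m: float = 200.0, seed=None) -> pd.DataFrame:
    """Retain one uniformly chosen checklist per occupied grid cell.

    Cells are half-open ``[k*grid, (k+1)*grid)``, so a coordinate exactly on
    a boundary belongs to the right/upper cell.  Selection is independent of
    whether the species was detected.
    """
    if grid_m <= 0:
        raise InvalidArgumentError("grid size must be positive")
    if checklists.empty:
        return checklists.copy()
    rng = np.random.default_rng(seed)
    cx = np.floor(checklists["x_m"].to_numpy() / grid_m).astype(int)
    cy = np.floor(checklists["y_m"].to_numpy() / grid_m).astype(int)
    order = rng.permutation(len(checklists))
    cells = pd.DataFrame({"cx": cx[order], "cy": cy[order]},
                         index=checklists.index[order])
    first = ~cells.duplicated(["cx", "cy"])
    chosen = cells.index[first]
    return checklists.loc[checklists.index.intersection(chosen, sort=False)].copy()
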