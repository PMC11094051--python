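"""Fixed covariate transforms shared by the simulator and the detection models.

Detection-model design matrices are built from named survey covariates with
*fixed* affine/log transforms (no data-dependent standardization), so that a
model fitted on one dataset produces identical offsets when applied to
another.  Centering constants correspond to the midpoints of the simulated
season (Julian day 120-190) and morning window (0-420 min after dawn).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

JDAY_CENTER, JDAY_SCALE = 155.0, 35.0
TOD_CENTER, TOD_SCALE = 210.0, 210.0
DIST_SCALE_M = 1000.0  # d_river / d_highway rescaling


def jday_c(jday) -> np.ndarray:
    return (np.asarray(jday, dtype=float) - JDAY_CENTER) / JDAY_SCALE


def tod_c(tod) -> np.ndarray:
    return (np.asarray(tod, dtype=float) - TOD_CENTER) / TOD_SCALE


#: term name -> function of a covariate DataFrame returning one design column
TERM_BUILDERS = {
    "jday": lambda d: jday_c(d["jday"]),
    "jday2": lambda d: jday_c(d["jday"]) ** 2,
    "tod": lambda d: tod_c(d["min_since_dawn"]),
    "tod2": lambda d: tod_c(d["min_since_dawn"]) ** 2,
    "d_river": lambda d: np.asarray(d["d_river"], dtype=float) / DIST_SCALE_M,
    "d_river2": lambda d: (np.asarray(d["d_river"], dtype=float) / DIST_SCALE_M) ** 2,
    "log_d_river": lambda d: np.log(np.asarray(d["d_river"], dtype=float) / DIST_SCALE_M),
    "d_highway": lambda d: np.asarray(d["d_highway"], dtype=float) / DIST_SCALE_M,
    "d_highway2": lambda d: (np.asarray(d["d_highway"], dtype=float) / DIST_SCALE_M) ** 2,
    "log_d_highway": lambda d: np.log(np.asarray(d["d_highway"], dtype=float) / DIST_SCALE_M),
    "canopy": lambda d: np.asarray(d["canopy_75"], dtype=float),
    "urban_hd_md": lambda d: np.asarray(d["urban_hd_md_75"], dtype=float),
    "urban_total": lambda d: np.asarray(d["urban_total_75"], dtype=float),
}


def build_design(covariates: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    """Design matrix [1, terms...] for the given covariate table."""
    n = len(covariates)
    cols = [np.ones(n)]
    for t in terms:
        cols.append(np.asarray(TERM_BUILDERS[t](covariates), dtype=float))
    return np.column_stack(cols)
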