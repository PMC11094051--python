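"""Detection models: availability (removal) and perceptibility (distance).

Point-count detection is decomposed into availability -- the probability a
bird present at the survey gives a detectable cue within the count, modelled
from removal (first-interval-of-detection) data with a per-minute cue rate
``phi`` -- and perceptibility -- the probability an available bird is
perceived, modelled from binned distance data with a half-normal detection
function ``g(r) = exp(-r^2/tau^2)``.

Both are conditional multinomial likelihoods over observed cells:

* removal: ``pi_j = (e^{-phi t_{j-1}} - e^{-phi t_j}) / (1 - e^{-phi T})``
* distance (unlimited last bin): ``pi_k = e^{-r_{k-1}^2/tau^2} - e^{-r_k^2/tau^2}``

with log-linear covariate effects on ``phi`` and ``tau``.  Candidate models
are ranked by small-sample AICc; the top models yield per-survey correction
factors ``C = A * p * q`` (effective area x availability x perceptibility,
with q = 1 inside the effective detection radius by definition), whose log
enters downstream count models as an offset.

The model/results split follows the statsmodels convention: a model object
holds data and a candidate structure, ``fit()`` returns a results object
with coefficients, AICc and prediction methods.
"""

from __future__ import annotations

import math
import warnings
from itertools import product

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq, minimize

from .design import build_design
from .errors import EstimationError, InvalidArgumentError
from .landscape import Landscape

_LINPRED_CLIP = 15.0  # keeps exp(linpred) finite without affecting interior optima


# ---------------------------------------------------------------------------
# elementary probabilities
# ---------------------------------------------------------------------------

def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected AIC: -2 loglik + 2k + 2k(k+1)/(n-k-1)."""
    if n <= k + 1:
        raise InvalidArgumentError(f"AICc undefined for n={n}, k={k} (need n > k+1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def removal_cell_probs(phi: float, boundaries) -> np.ndarray:
    """Conditional probabilities of first detection in each removal interval."""
    t = np.asarray(boundaries, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidArgumentError("interval boundaries must be strictly increasing")
    if phi <= 0:
        raise InvalidArgumentError("phi must be positive")
    e = np.exp(-phi * t)
    return (e[:-1] - e[1:]) / (1.0 - e[-1])


def distance_cell_probs(tau: float, bin_edges) -> np.ndarray:
    """Conditional probabilities of detection in each distance bin.

    Equals the integral of ``2 pi r g(r)`` over the bin divided by
    ``pi tau^2``, for half-normal ``g``; the last edge must be infinite.
    """
    r = np.asarray(bin_edges, dtype=float)
    if np.any(np.diff(r) <= 0):
        raise InvalidArgumentError("bin edges must be strictly increasing")
    if not np.isinf(r[-1]):
        raise InvalidArgumentError("last bin edge must be infinite (unlimited-distance)")
    if tau <= 0:
        raise InvalidArgumentError("tau must be positive")
    a = np.exp(-(r**2) / tau**2)  # exp(-inf) = 0 handles the last edge
    return a[:-1] - a[1:]


def availability(phi, duration) -> np.ndarray:
    """Availability p = 1 - e^{-phi T} for a count of duration T minutes."""
    if np.any(np.asarray(duration) <= 0):
        raise InvalidArgumentError("duration must be positive")
    return -np.expm1(-np.asarray(phi, dtype=float) * np.asarray(duration, dtype=float))


def edr(tau: float) -> float:
    """Effective detection radius; equals tau for half-normal g."""
    return float(tau)


def edr_from_balance(tau: float, tol: float = 1e-10) -> float:
    """Solve the EDR's defining balance integral numerically.

    The EDR rho satisfies: birds missed inside rho equal birds detected
    outside rho, i.e. ``int_0^rho (1-g) 2 pi r dr = int_rho^inf g 2 pi r dr``.
    Provided as an independent check of the closed form ``rho = tau``.
    """
    def g(r):
        return math.exp(-(r**2) / tau**2)

    def balance(rho):
        missed_inside = quad(lambda r: (1.0 - g(r)) * 2 * math.pi * r, 0, rho)[0]
        detected_outside = quad(lambda r: g(r) * 2 * math.pi * r, rho, np.inf)[0]
        return missed_inside - detected_outside

    return brentq(balance, 1e-6 * tau, 20.0 * tau, xtol=tol * tau)


# ---------------------------------------------------------------------------
# model / results classes
# ---------------------------------------------------------------------------

class _CellModel:
    """Shared machinery for conditional-multinomial detection models."""

    #: subclass: name of the log-linear parameter ("phi" or "tau")
    _param_name = ""

    def __init__(self, cells: np.ndarray, covariates: pd.DataFrame, terms: tuple[str, ...]):
        self.cells = np.asarray(cells, dtype=int)
        self.n = self.cells.size
        if self.n < 1:
            raise InvalidArgumentError("need at least one detected individual")
        self.terms = tuple(terms)
        self.exog = build_design(covariates, self.terms)
        self.k = self.exog.shape[1]

    def _rates(self, params: np.ndarray) -> np.ndarray:
        lin = np.clip(self.exog @ params, -_LINPRED_CLIP, _LINPRED_CLIP)
        return np.exp(lin)

    def _cell_prob_matrix(self, rates: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def loglike(self, params) -> float:
        probs = self._cell_prob_matrix(self._rates(np.asarray(params, dtype=float)))
        p_obs = probs[np.arange(self.n), self.cells - 1]
        return float(np.sum(np.log(np.clip(p_obs, 1e-300, None))))

    def default_start(self) -> np.ndarray:
        return np.zeros(self.k)

    def fit(self, start_params=None, seed: int = 0, gtol: float = 1e-8,
            ridge: float = 0.5):
        """Maximize the likelihood by BFGS from a scale-aware (then jittered) start.

        A weak ridge penalty (``ridge`` x sum of squared covariate slopes,
        intercept excluded) guards against quasi-separation in small samples;
        it is negligible whenever slopes are actually estimable.  Reported
        log-likelihoods (and hence AICc) are unpenalized.
        """
        x0 = self.default_start() if start_params is None else np.asarray(start_params, float)

        def objective(b):
            return -self.loglike(b) + ridge * float(np.sum(np.square(b[1:])))

        rng = np.random.default_rng(seed)
        best = None
        for attempt in range(4):
            start = x0 if attempt == 0 else x0 + rng.normal(0, 0.5, size=self.k)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = minimize(objective, start, method="BFGS",
                               options={"gtol": gtol, "maxiter": 500})
            if np.all(np.isfinite(res.x)) and np.isfinite(res.fun):
                if best is None or res.fun < best.fun:
                    best = res
                if res.success or np.linalg.norm(res.jac) < 1e-4:
                    break
        if best is None:
            raise EstimationError(f"{type(self).__name__} failed to converge "
                                  f"for terms {self.terms}")
        return self._results_class(self, best.x, self.loglike(best.x))


class DetectionResults:
    """Fitted coefficients, fit statistics and predictors for one candidate."""

    def __init__(self, model: _CellModel, params: np.ndarray, loglik: float):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.loglik = float(loglik)
        self.k = model.k
        self.n = model.n
        # AICc is undefined when n <= k+1; such candidates cannot be ranked
        self.aicc = aicc(self.loglik, self.k, self.n) if self.n > self.k + 1 else math.inf

    @property
    def terms(self) -> tuple[str, ...]:
        return self.model.terms

    @property
    def param_names(self) -> list[str]:
        return ["intercept", *self.model.terms]

    def _predict_rate(self, covariates: pd.DataFrame) -> np.ndarray:
        try:
            x = build_design(covariates, self.model.terms)
        except KeyError as exc:
            raise InvalidArgumentError(f"missing covariate column: {exc}") from exc
        return np.exp(np.clip(x @ self.params, -_LINPRED_CLIP, _LINPRED_CLIP))

    def summary(self) -> dict:
        return {
            "model": type(self.model).__name__,
            "terms": list(self.model.terms),
            "coefficients": dict(zip(self.param_names, self.params.tolist())),
            "loglik": self.loglik,
            "aicc": self.aicc,
            "n_individuals": self.n,
        }


class RemovalModel(_CellModel):
    """Availability model: removal intervals with log-linear cue rate phi."""

    _param_name = "phi"

    def __init__(self, intervals, covariates: pd.DataFrame, boundaries, terms: tuple[str, ...] = ()):
        t = np.asarray(boundaries, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise InvalidArgumentError("interval boundaries must be strictly increasing")
        self.boundaries = t
        super().__init__(intervals, covariates, terms)
        if self.cells.min() < 1 or self.cells.max() > len(t) - 1:
            raise InvalidArgumentError("removal interval out of range")

    def _cell_prob_matrix(self, phi: np.ndarray) -> np.ndarray:
        e = np.exp(-np.outer(phi, self.boundaries))
        return (e[:, :-1] - e[:, 1:]) / (1.0 - e[:, -1:])


class RemovalResults(DetectionResults):
    def phi(self, covariates: pd.DataFrame) -> np.ndarray:
        """Per-survey cue rate (per minute)."""
        return self._predict_rate(covariates)

    def availability(self, covariates: pd.DataFrame, duration) -> np.ndarray:
        """p = 1 - e^{-phi T} at each survey's own duration (min)."""
        return availability(self.phi(covariates), duration)


class DistanceModel(_CellModel):
    """Perceptibility model: distance bins with log-linear half-normal tau."""

    _param_name = "tau"

    def __init__(self, bins, covariates: pd.DataFrame, bin_edges, terms: tuple[str, ...] = ()):
        r = np.asarray(bin_edges, dtype=float)
        if np.any(np.diff(r) <= 0) or not np.isinf(r[-1]):
            raise InvalidArgumentError("bin edges must be strictly increasing and end at inf")
        self.bin_edges = r
        super().__init__(bins, covariates, terms)
        if self.cells.min() < 1 or self.cells.max() > len(r) - 1:
            raise InvalidArgumentError("distance bin out of range")

    def _cell_prob_matrix(self, tau: np.ndarray) -> np.ndarray:
        with np.errstate(over="ignore"):
            edges2 = np.where(np.isinf(self.bin_edges), np.inf, self.bin_edges**2)
            a = np.exp(-edges2[None, :] / tau[:, None] ** 2)
        return a[:, :-1] - a[:, 1:]

    def default_start(self) -> np.ndarray:
        # start tau at half the largest finite bin edge so the likelihood is
        # informative (a 1-m start puts all mass in the first bin and leaves
        # the surface numerically flat)
        x0 = np.zeros(self.k)
        x0[0] = math.log(0.5 * self.bin_edges[-2]) if self.bin_edges[-2] > 0 else 0.0
        return x0


class DistanceResults(DetectionResults):
    def tau(self, covariates: pd.DataFrame) -> np.ndarray:
        """Per-survey half-normal scale (m)."""
        return self._predict_rate(covariates)

    def edr(self, covariates: pd.DataFrame) -> np.ndarray:
        """Effective detection radius (m); tau itself for half-normal g."""
        return self.tau(covariates)


RemovalModel._results_class = RemovalResults
DistanceModel._results_class = DistanceResults


# ---------------------------------------------------------------------------
# candidate sets and AICc selection
# ---------------------------------------------------------------------------

#: all combinations of Julian day and time of day with optional quadratic
#: per included linear term, plus the null model (9 candidates)
REMOVAL_CANDIDATES: tuple[tuple[str, ...], ...] = (
    (),
    ("jday",),
    ("jday", "jday2"),
    ("tod",),
    ("tod", "tod2"),
    ("jday", "tod"),
    ("jday", "jday2", "tod"),
    ("jday", "tod", "tod2"),
    ("jday", "jday2", "tod", "tod2"),
)

_DIST_FORMS = {
    "d_river": (("d_river",), ("d_river", "d_river2"), ("log_d_river",)),
    "d_highway": (("d_highway",), ("d_highway", "d_highway2"), ("log_d_highway",)),
}


def distance_stage1_candidates() -> tuple[tuple[str, ...], ...]:
    """Null + noise-source (river/highway distance) structures.

    Each variable enters as linear, linear+quadratic, or log-transformed;
    both-variable candidates combine one form of each (16 candidates).
    """
    singles = [f for forms in _DIST_FORMS.values() for f in forms]
    both = [fr + fh for fr, fh in product(*_DIST_FORMS.values())]
    return ((), *singles, *both)


STAGE2_EXTRAS: tuple[tuple[str, ...], ...] = (
    ("canopy",),
    ("urban_hd_md",),
    ("urban_total",),
    ("canopy", "urban_hd_md"),
    ("canopy", "urban_total"),
)


def _fit_candidates(model_cls, cells, covariates, structure, candidates, seed):
    results = []
    for terms in candidates:
        model = model_cls(cells, covariates, structure, terms=terms)
        if model.n <= model.k + 1:
            warnings.warn(f"skipping candidate {terms}: n={model.n} <= k+1={model.k + 1}")
            continue
        try:
            results.append(model.fit(seed=seed))
        except EstimationError as exc:
            warnings.warn(f"candidate {terms} failed: {exc}")
    if not results:
        raise EstimationError("no detection-model candidate could be fitted")
    return sorted(results, key=lambda r: r.aicc)


def fit_removal_set(intervals, covariates: pd.DataFrame, boundaries,
                    candidates=REMOVAL_CANDIDATES, seed: int = 0) -> list[RemovalResults]:
    """Fit the removal candidate set; return results ranked by AICc."""
    return _fit_candidates(RemovalModel, intervals, covariates, boundaries,
                           candidates, seed)


def fit_distance_set(bins, covariates: pd.DataFrame, bin_edges,
                     stage1_candidates=None, stage2_extras=STAGE2_EXTRAS,
                     seed: int = 0) -> list[DistanceResults]:
    """Two-stage distance-model selection, ranked by AICc.

    Stage 1 screens noise-source structures (distance to river/highway) and
    perpetuates the top AICc structure; stage 2 adds canopy/urban land-cover
    terms to that structure.  The stage-1 winner remains a stage-2 candidate.
    """
    stage1 = distance_stage1_candidates() if stage1_candidates is None else stage1_candidates
    ranked1 = _fit_candidates(DistanceModel, bins, covariates, bin_edges, stage1, seed)
    winner = ranked1[0].terms
    stage2 = [winner] + [winner + extra for extra in stage2_extras]
    return _fit_candidates(DistanceModel, bins, covariates, bin_edges, stage2, seed)


# ---------------------------------------------------------------------------
# survey covariates and offsets
# ---------------------------------------------------------------------------

#: columns the detection designs may draw on
SURVEY_COVARIATE_COLUMNS = [
    "jday", "min_since_dawn", "d_river", "d_highway",
    "canopy_75", "urban_hd_md_75", "urban_total_75",
]


def survey_covariate_table(landscape: Landscape, checklists: pd.DataFrame) -> pd.DataFrame:
    """Detection-model covariates for each survey.

    Date/time come from the checklist; noise-source distances are taken at
    the survey's cell, land-cover terms as 75-m focal means.
    """
    x, y = checklists["x_m"].to_numpy(), checklists["y_m"].to_numpy()
    out = pd.DataFrame({
        "survey_id": checklists["survey_id"].to_numpy(),
        "jday": checklists["jday"].to_numpy(),
        "min_since_dawn": checklists["min_since_dawn"].to_numpy(),
    }, index=checklists.index)
    for name, col in (("d_river", "d_river"), ("d_highway", "d_highway"),
                      ("canopy_75", "canopy_75"), ("urban_hd_md_75", "urban_hd_md_75"),
                      ("urban_total_75", "urban_total_75")):
        try:
            out[col] = landscape.values_at(name, x, y)
        except KeyError as exc:
            raise InvalidArgumentError(f"landscape lacks covariate {exc}") from exc
    return out


def compute_offsets(
    checklists: pd.DataFrame,
    removal: RemovalResults,
    distance: DistanceResults,
    landscape: Landscape,
    covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-survey QPAD correction factors C = A * p * q.

    ``A = pi rho^2`` is the effective area in hectares (rho the EDR), ``p``
    availability at the survey's own duration, and ``q = 1`` within the EDR
    by definition.  Returns columns (survey_id, p, q, edr_m, area_ha, C, logC).
    """
    cov = survey_covariate_table(landscape, checklists) if covariates is None else covariates
    p = removal.availability(cov, checklists["duration_min"].to_numpy())
    rho = distance.edr(cov)
    area_ha = math.pi * rho**2 / 1e4
    c = area_ha * p
    return pd.DataFrame({
        "survey_id": checklists["survey_id"].to_numpy(),
        "p": p, "q": 1.0, "edr_m": rho, "area_ha": area_ha,
        "C": c, "logC": np.log(c),
    }, index=checklists.index)


def fixed_offsets(checklists: pd.DataFrame, radius_m: float = 200.0) -> pd.DataFrame:
    """Fixed-radius offsets: C = pi r^2 (ha) with perfect detection p = q = 1."""
    if radius_m <= 0:
        raise InvalidArgumentError("radius must be positive")
    area_ha = math.pi * radius_m**2 / 1e4
    n = len(checklists)
    return pd.DataFrame({
        "survey_id": checklists["survey_id"].to_numpy(),
        "p": np.ones(n), "q": 1.0, "edr_m": radius_m,
        "area_ha": area_ha, "C": area_ha, "logC": math.log(area_ha),
    }, index=checklists.index)


def oracle_offsets(checklists: pd.DataFrame, truth, landscape: Landscape) -> pd.DataFrame:
    """Offsets from the simulator's true phi and tau (for oracle checks)."""
    phi = truth.phi(checklists["jday"].to_numpy(), checklists["min_since_dawn"].to_numpy())
    p = availability(phi, checklists["duration_min"].to_numpy())
    rho = truth.tau(landscape, checklists["x_m"].to_numpy(), checklists["y_m"].to_numpy())
    area_ha = math.pi * rho**2 / 1e4
    c = area_ha * p
    return pd.DataFrame({
        "survey_id": checklists["survey_id"].to_numpy(),
        "p": p, "q": 1.0, "edr_m": rho, "area_ha": area_ha,
        "C": c, "logC": np.log(c),
    }, index=checklists.index)
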