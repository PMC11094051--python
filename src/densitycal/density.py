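"""Zero-inflated density modelling with detection offsets.

Stage 1 (zero-inflation): a probability-of-occurrence learner is fitted to
detection/non-detection labels over multi-scale covariates, evaluated by AUC
on an independent test set, and thresholded at the training-sample prevalence
to define binary suitable/unsuitable habitat.

Stage 2 (density): a count learner with Poisson loss and per-survey exposure
``C`` (the detection offset, in hectares) is fitted to counts from suitable
habitat only.  The exposure contract is ``E[count] = C x density``, so
predictions are densities in birds/ha; summing density x cell area over
suitable cells yields the population estimate.

Two learner families honour the same contract: a boosted-tree ensemble
(interaction depth 3, bag fraction 0.75, learning rate tuned so the selected
tree count falls in a target range) and a deterministic penalized-GLM
fallback that is exact and fast, used throughout the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import rankdata
from sklearn.ensemble import GradientBoostingClassifier, HistGradientBoostingRegressor
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from .errors import EstimationError, InvalidArgumentError, UndefinedResultWarning
from .landscape import Landscape


# ---------------------------------------------------------------------------
# learner configuration
# ---------------------------------------------------------------------------

@dataclass
class LearnerConfig:
    """Hyperparameters shared by the occurrence and count learners.

    ``kind="fallback"`` selects the deterministic GLM-family learners;
    ``kind="boosted"`` selects boosted-tree ensembles with interaction depth
    ``depth``, row subsampling ``bag_fraction`` and a learning rate halved
    (up to ``max_halvings`` times) until the selected number of trees falls
    inside ``tree_range``.
    """

    kind: str = "fallback"
    depth: int = 3
    bag_fraction: float = 0.75
    tree_range: tuple[int, int] = (1000, 5000)
    folds: int = 10
    learning_rate: float = 0.1
    max_halvings: int = 6

    def __post_init__(self) -> None:
        if self.kind not in ("fallback", "boosted"):
            raise InvalidArgumentError("learner kind must be 'fallback' or 'boosted'")


# ---------------------------------------------------------------------------
# evaluation statistics
# ---------------------------------------------------------------------------

def auc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney rank statistic.

    Ties in scores count one half; requires both classes present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    if n1 == 0 or n0 == 0:
        raise InvalidArgumentError("AUC requires both classes present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def predictive_correlation(predicted_counts, observed_counts) -> float:
    """Pearson correlation between offset-scaled predictions and counts.

    Returns NaN (with :class:`UndefinedResultWarning`) when either vector has
    zero variance, or when fewer than 3 pairs are available.
    """
    p = np.asarray(predicted_counts, dtype=float)
    o = np.asarray(observed_counts, dtype=float)
    if p.size < 3 or p.std() == 0.0 or o.std() == 0.0:
        warnings.warn("predictive correlation undefined (zero variance or n < 3)",
                      UndefinedResultWarning)
        return float("nan")
    return float(np.corrcoef(p, o)[0, 1])


# ---------------------------------------------------------------------------
# occurrence stage
# ---------------------------------------------------------------------------

def _tune_boosted_classifier(x, y, config: LearnerConfig, seed: int):
    lo, hi = config.tree_range
    lr = config.learning_rate
    rng_state = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    for halving in range(config.max_halvings + 1):
        losses = np.zeros(hi)
        kf = KFold(config.folds, shuffle=True, random_state=rng_state)
        for tr, va in kf.split(x):
            gbm = GradientBoostingClassifier(
                n_estimators=hi, learning_rate=lr, max_depth=config.depth,
                subsample=config.bag_fraction, random_state=rng_state)
            gbm.fit(x[tr], y[tr])
            for i, proba in enumerate(gbm.staged_predict_proba(x[va])):
                p = np.clip(proba[:, 1], 1e-12, 1 - 1e-12)
                losses[i] += -np.mean(y[va] * np.log(p) + (1 - y[va]) * np.log(1 - p))
        best = int(np.argmin(losses)) + 1
        if best >= lo:
            break
        lr /= 2.0
    else:
        warnings.warn(f"optimal tree count {best} below {lo} after "
                      f"{config.max_halvings} halvings of the learning rate")
    n_trees = min(best, hi)
    final = GradientBoostingClassifier(
        n_estimators=n_trees, learning_rate=lr, max_depth=config.depth,
        subsample=config.bag_fraction, random_state=rng_state)
    final.fit(x, y)
    return final


@dataclass
class OccurrenceFit:
    """Fitted occurrence stage: probability predictor, prevalence threshold, AUC."""

    learner: object
    prevalence: float
    auc: float | None = None
    config: LearnerConfig = field(default_factory=LearnerConfig)

    @property
    def threshold(self) -> float:
        """Suitability threshold = training-sample prevalence."""
        return self.prevalence

    def predict_prob(self, features) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        return self.learner.predict_proba(x)[:, 1]


def fit_occurrence(
    train_features,
    train_labels,
    config: LearnerConfig | None = None,
    seed: int = 0,
    test_features=None,
    test_labels=None,
) -> OccurrenceFit:
    """Fit the occurrence learner; evaluate AUC on the independent test set."""
    config = config or LearnerConfig()
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels).astype(int)
    if y.min() == y.max():
        raise EstimationError("occurrence training data contain a single class")
    if config.kind == "boosted":
        learner = _tune_boosted_classifier(x, y, config, seed)
    else:
        learner = make_pipeline(StandardScaler(),
                                LogisticRegression(C=1.0, max_iter=5000))
        learner.fit(x, y)
    fit = OccurrenceFit(learner=learner, prevalence=float(y.mean()), config=config)
    if test_features is not None and test_labels is not None:
        fit.auc = auc(fit.predict_prob(test_features), test_labels)
    return fit


@dataclass
class SuitabilityMask:
    """Binary suitable/unsuitable habitat over landscape cells."""

    mask: np.ndarray  # (n_y, n_x) boolean
    cell_area_ha: float
    threshold: float

    @property
    def area_ha(self) -> float:
        return float(self.mask.sum() * self.cell_area_ha)


def threshold_by_prevalence(fit: OccurrenceFit, landscape: Landscape) -> SuitabilityMask:
    """Suitable habitat: cells whose predicted probability >= prevalence.

    Predictions exactly at the threshold count as suitable.
    """
    prob = fit.predict_prob(landscape.cell_features()).reshape(landscape.shape)
    return SuitabilityMask(mask=prob >= fit.threshold,
                           cell_area_ha=landscape.cell_area_ha,
                           threshold=fit.threshold)


# ---------------------------------------------------------------------------
# density stage
# ---------------------------------------------------------------------------

def _tune_boosted_poisson(x, rate, weight, config: LearnerConfig, seed: int):
    lo, hi = config.tree_range
    lr = config.learning_rate
    rng_state = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31))
    for halving in range(config.max_halvings + 1):
        gbm = HistGradientBoostingRegressor(
            loss="poisson", max_iter=hi, learning_rate=lr,
            max_depth=config.depth, early_stopping=True,
            validation_fraction=0.15, n_iter_no_change=25,
            random_state=rng_state)
        gbm.fit(x, rate, sample_weight=weight)
        if gbm.n_iter_ >= lo:
            break
        lr /= 2.0
    else:
        warnings.warn(f"selected iteration count {gbm.n_iter_} below {lo} after "
                      f"{config.max_halvings} halvings of the learning rate")
    return gbm


@dataclass
class DensityFit:
    """Fitted count stage predicting density (birds/ha) over covariates."""

    learner: object
    config: LearnerConfig
    kind: str
    params: np.ndarray | None = None  # fallback GLM coefficients [const, features...]

    def predict_density(self, features) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if self.kind == "boosted":
            return np.clip(self.learner.predict(x), 0.0, None)
        exog = sm.add_constant(x, has_constant="add")
        return np.exp(np.clip(exog @ self.params, -30.0, 30.0))


def fit_density(
    train_features,
    counts,
    offsets_c,
    config: LearnerConfig | None = None,
    seed: int = 0,
) -> DensityFit:
    """Fit the Poisson count learner with per-survey exposure ``C`` (ha).

    The exposure contract ``E[count] = C x density`` is realized either by an
    explicit ``log C`` offset in a Poisson GLM (fallback) or by fitting the
    rate ``count / C`` with Poisson deviance and sample weights ``C``
    (boosted learner) -- the two are equivalent at the optimum.
    """
    config = config or LearnerConfig()
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(counts, dtype=float)
    c = np.asarray(offsets_c, dtype=float)
    if x.shape[0] == 0:
        raise EstimationError("no training surveys in suitable habitat")
    if np.any(c <= 0):
        raise InvalidArgumentError("all offsets C must be positive")
    if config.kind == "boosted":
        learner = _tune_boosted_poisson(x, y / c, c, config, seed)
        return DensityFit(learner=learner, config=config, kind="boosted")
    exog = sm.add_constant(x, has_constant="add")
    if y.sum() == 0:
        # all-zero counts: the MLE density is 0; represent by a large negative
        # intercept rather than a divergent IRLS path
        params = np.zeros(exog.shape[1])
        params[0] = -30.0
        return DensityFit(learner=None, config=config, kind="fallback", params=params)
    model = sm.GLM(y, exog, family=sm.families.Poisson(), offset=np.log(c))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(maxiter=200)
        params = np.asarray(res.params, dtype=float)
    except Exception:
        res = model.fit_regularized(alpha=1e-4, L1_wt=0.0, maxiter=200)
        params = np.asarray(res.params, dtype=float)
    return DensityFit(learner=res, config=config, kind="fallback", params=params)


def predict_density_grid(fit: DensityFit, landscape: Landscape,
                         mask: SuitabilityMask,
                         feature_radii: tuple[float, ...] | None = None) -> np.ndarray:
    """Per-cell density surface (birds/ha); zero outside suitable habitat."""
    feats = landscape.cell_features(feature_radii)
    dens = fit.predict_density(feats).reshape(landscape.shape)
    dens = np.where(mask.mask, dens, 0.0)
    return dens


def mean_density(density_grid: np.ndarray, mask: SuitabilityMask) -> float:
    """Mean density over suitable cells (birds/ha); 0 for an empty mask."""
    n = int(mask.mask.sum())
    return float(density_grid[mask.mask].mean()) if n else 0.0


def estimate_population(density_grid: np.ndarray, mask: SuitabilityMask) -> float:
    """Population = sum over suitable cells of density x cell area."""
    if density_grid.shape != mask.mask.shape:
        raise InvalidArgumentError("density grid and mask are misaligned")
    return float(density_grid[mask.mask].sum() * mask.cell_area_ha)
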