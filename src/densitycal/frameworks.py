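"""Benchmark, Fixed, Independent and Calibration analysis frameworks.

Each framework runs the same zero-inflated density pipeline -- occurrence
model, prevalence threshold, detection offsets, offset-adjusted Poisson count
model, landscape prediction -- but differs in where its detection information
comes from:

* benchmark: structured surveys model everything (best practice);
* fixed: community counts with a fixed survey radius and perfect detection;
* independent: detection models from the full structured dataset, density
  from community data only;
* calibration: detection models from a small structured subset sampled until
  ``n_occ`` surveys with a detection, optionally pooled into the community
  training data.

Ten seeded iterations per framework quantify stochastic variability; each
endpoint (AUC, suitable area, mean density, population) is summarized as a
percent of the benchmark's median.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import density as dn
from . import detection as det
from .errors import InfeasibleError, InvalidArgumentError, UndefinedResultWarning
from .landscape import Landscape

ENDPOINTS = ("auc", "suitable_area_ha", "mean_density", "population")
FRAMEWORK_NAMES = ("benchmark", "fixed", "independent", "calibration")
CALIBRATION_SIZES = (10, 30, 100, 250)


@dataclass
class FrameworkSpec:
    """Configuration of one framework run."""

    name: str
    fixed_radius_m: float = 200.0
    n_occ: int | None = None
    pooling: bool = False
    iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in FRAMEWORK_NAMES:
            raise InvalidArgumentError(f"unknown framework {self.name!r}")
        if self.name == "calibration" and self.n_occ is None:
            raise InvalidArgumentError("calibration framework requires n_occ")
        if self.name != "calibration" and self.n_occ is not None:
            raise InvalidArgumentError("n_occ is only valid for the calibration framework")


@dataclass
class IterationResult:
    framework: str
    iteration: int
    auc: float
    suitable_area_ha: float
    mean_density: float
    population: float
    predictive_r: float = float("nan")
    offsets_summary: dict = field(default_factory=dict)
    n_occurrence_train: int = 0

    @property
    def endpoints(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ENDPOINTS}


@dataclass
class ComparisonSummary:
    """Per-endpoint percent-of-benchmark summaries."""

    benchmark_median: dict[str, float]
    percents: dict[str, list[float]]
    median_percent: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ep in self.benchmark_median:
            rows.append({
                "endpoint": ep,
                "benchmark_median": self.benchmark_median[ep],
                "median_percent": self.median_percent[ep],
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def make_benchmark_dataset(structured: pd.DataFrame, n_match: int, seed):
    """Uniform sample without replacement; remainder is the test set."""
    n = len(structured)
    if n_match > n:
        raise InvalidArgumentError(f"n_match={n_match} exceeds {n} structured surveys")
    if n_match == n:
        warnings.warn("benchmark uses all structured surveys; test set is empty")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(n)
    bench = structured.iloc[idx[:n_match]].copy()
    test = structured.iloc[idx[n_match:]].copy()
    return bench, test


def sample_calibration(benchmark: pd.DataFrame, n_occ: int, seed) -> pd.DataFrame:
    """Shuffle and accumulate surveys until exactly n_occ have a detection.

    The returned subset includes the non-detection surveys drawn en route.
    """
    positives = int((benchmark["count"] > 0).sum())
    if positives < n_occ:
        raise InfeasibleError(
            f"requested {n_occ} surveys with detections but only {positives} available")
    rng = np.random.default_rng(seed)
    shuffled = benchmark.iloc[rng.permutation(len(benchmark))]
    cum_pos = (shuffled["count"] > 0).cumsum()
    stop = int(np.argmax(cum_pos.to_numpy() >= n_occ))
    return shuffled.iloc[:stop + 1].copy()


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------

def _survey_cell_rows(landscape: Landscape, df: pd.DataFrame) -> np.ndarray:
    row, col = landscape.cell_index(df["x_m"].to_numpy(), df["y_m"].to_numpy())
    return row * landscape.n_x + col


def survey_features(landscape: Landscape, df: pd.DataFrame,
                    radii: tuple[float, ...] | None = None) -> np.ndarray:
    """Multi-scale covariates of each survey's containing cell."""
    cells = landscape.cell_features(radii)
    return cells[_survey_cell_rows(landscape, df)]


DENSITY_RADII = (75.0,)  # count-stage covariates: 75-m focal means only


def _occurrence_stage(train: pd.DataFrame, test: pd.DataFrame,
                      landscape: Landscape, config: dn.LearnerConfig, seed):
    fit = dn.fit_occurrence(
        survey_features(landscape, train), (train["count"] > 0).to_numpy(),
        config=config, seed=seed,
        test_features=survey_features(landscape, test),
        test_labels=(test["count"] > 0).to_numpy())
    mask = dn.threshold_by_prevalence(fit, landscape)
    return fit, mask


def _in_mask(landscape: Landscape, mask: dn.SuitabilityMask, df: pd.DataFrame) -> np.ndarray:
    return mask.mask.ravel()[_survey_cell_rows(landscape, df)]


def _detection_stage(surveys: pd.DataFrame, detections: pd.DataFrame,
                     landscape: Landscape, mask: dn.SuitabilityMask, seed,
                     allow_unrestricted_fallback: bool = False,
                     boundaries=(0.0, 1.0, 2.0, 3.0, 4.0, 5.0),
                     bin_edges=(0.0, 50.0, 100.0, 150.0, 200.0, np.inf)):
    """Fit removal + distance model sets on structured surveys in the mask."""
    inside = surveys.loc[_in_mask(landscape, mask, surveys)]
    if inside.empty or not detections["survey_id"].isin(inside["survey_id"]).any():
        if not allow_unrestricted_fallback:
            raise InfeasibleError("no structured surveys with detections inside "
                                  "predicted-suitable habitat")
        warnings.warn("calibration sample has no detections inside suitable habitat; "
                      "falling back to the unrestricted calibration sample")
        inside = surveys
    cov = det.survey_covariate_table(landscape, inside).set_index("survey_id")
    dets = detections[detections["survey_id"].isin(inside["survey_id"])]
    ind_cov = cov.loc[dets["survey_id"]].reset_index(drop=True)
    removal = det.fit_removal_set(dets["removal_interval"].to_numpy(), ind_cov,
                                  boundaries, seed=int(seed))[0]
    distance = det.fit_distance_set(dets["distance_bin_index"].to_numpy(), ind_cov,
                                    bin_edges, seed=int(seed))[0]
    return removal, distance


def _count_stage(train: pd.DataFrame, offsets: pd.DataFrame, landscape: Landscape,
                 mask: dn.SuitabilityMask, config: dn.LearnerConfig, seed):
    suitable = _in_mask(landscape, mask, train)
    train_in = train.loc[suitable]
    off_in = offsets.loc[suitable]
    fit = dn.fit_density(
        survey_features(landscape, train_in, DENSITY_RADII),
        train_in["count"].to_numpy(), off_in["C"].to_numpy(),
        config=config, seed=seed)
    grid = dn.predict_density_grid(fit, landscape, mask, DENSITY_RADII)
    return fit, grid


def _predictive_r(fit: dn.DensityFit, grid: np.ndarray, landscape: Landscape,
                  mask: dn.SuitabilityMask, test: pd.DataFrame,
                  test_offsets: pd.DataFrame) -> float:
    dens_at_test = grid.ravel()[_survey_cell_rows(landscape, test)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UndefinedResultWarning)
        return dn.predictive_correlation(dens_at_test * test_offsets["C"].to_numpy(),
                                         test["count"].to_numpy())


def _offsets_summary(offsets: pd.DataFrame) -> dict:
    return {
        "median_C_ha": float(offsets["C"].median()),
        "median_p": float(offsets["p"].median()),
        "median_edr_m": float(offsets["edr_m"].median()),
    }


def _iteration_seeds(seed, iterations: int):
    return np.random.SeedSequence(seed).spawn(iterations)


# ---------------------------------------------------------------------------
# framework runners
# ---------------------------------------------------------------------------

def run_benchmark(benchmark: pd.DataFrame, detections: pd.DataFrame,
                  test: pd.DataFrame, landscape: Landscape,
                  config: dn.LearnerConfig | None = None, seed=0,
                  iterations: int = 10) -> list[IterationResult]:
    """Best-practice pipeline on the structured benchmark dataset."""
    config = config or dn.LearnerConfig()
    results = []
    for i, child in enumerate(_iteration_seeds(seed, iterations)):
        s_occ, s_det, s_dens = child.spawn(3)
        occ, mask = _occurrence_stage(benchmark, test, landscape, config, s_occ)
        removal, distance = _detection_stage(benchmark, detections, landscape, mask,
                                             s_det.generate_state(1)[0] % 2**31)
        offsets = det.compute_offsets(benchmark, removal, distance, landscape)
        fit, grid = _count_stage(benchmark, offsets, landscape, mask, config, s_dens)
        test_off = det.compute_offsets(test, removal, distance, landscape)
        results.append(IterationResult(
            "benchmark", i, occ.auc, mask.area_ha, dn.mean_density(grid, mask),
            dn.estimate_population(grid, mask),
            _predictive_r(fit, grid, landscape, mask, test, test_off),
            _offsets_summary(offsets), n_occurrence_train=len(benchmark)))
    return results


def run_fixed(cs: pd.DataFrame, test: pd.DataFrame, landscape: Landscape,
              radius_m: float = 200.0, config: dn.LearnerConfig | None = None,
              seed=0, iterations: int = 10) -> list[IterationResult]:
    """Fixed-radius framework: perfect detection within ``radius_m``."""
    config = config or dn.LearnerConfig()
    results = []
    for i, child in enumerate(_iteration_seeds(seed, iterations)):
        s_occ, s_det, s_dens = child.spawn(3)
        occ, mask = _occurrence_stage(cs, test, landscape, config, s_occ)
        offsets = det.fixed_offsets(cs, radius_m)
        fit, grid = _count_stage(cs, offsets, landscape, mask, config, s_dens)
        test_off = det.fixed_offsets(test, radius_m)
        results.append(IterationResult(
            "fixed", i, occ.auc, mask.area_ha, dn.mean_density(grid, mask),
            dn.estimate_population(grid, mask),
            _predictive_r(fit, grid, landscape, mask, test, test_off),
            _offsets_summary(offsets), n_occurrence_train=len(cs)))
    return results


def run_independent(cs: pd.DataFrame, structured_full: pd.DataFrame,
                    detections_full: pd.DataFrame, test: pd.DataFrame,
                    landscape: Landscape, config: dn.LearnerConfig | None = None,
                    seed=0, iterations: int = 10) -> list[IterationResult]:
    """Offsets from detection models fitted to the full structured dataset."""
    if structured_full.empty or detections_full.empty:
        raise InvalidArgumentError("independent framework requires a structured "
                                   "dataset with detection records")
    config = config or dn.LearnerConfig()
    results = []
    for i, child in enumerate(_iteration_seeds(seed, iterations)):
        s_occ, s_det, s_dens = child.spawn(3)
        occ, mask = _occurrence_stage(cs, test, landscape, config, s_occ)
        removal, distance = _detection_stage(structured_full, detections_full,
                                             landscape, mask,
                                             s_det.generate_state(1)[0] % 2**31)
        offsets = det.compute_offsets(cs, removal, distance, landscape)
        fit, grid = _count_stage(cs, offsets, landscape, mask, config, s_dens)
        test_off = det.compute_offsets(test, removal, distance, landscape)
        results.append(IterationResult(
            "independent", i, occ.auc, mask.area_ha, dn.mean_density(grid, mask),
            dn.estimate_population(grid, mask),
            _predictive_r(fit, grid, landscape, mask, test, test_off),
            _offsets_summary(offsets), n_occurrence_train=len(cs)))
    return results


def run_calibration(cs: pd.DataFrame, benchmark: pd.DataFrame,
                    detections: pd.DataFrame, test: pd.DataFrame,
                    landscape: Landscape, n_occ: int, pooling: bool = False,
                    config: dn.LearnerConfig | None = None, seed=0,
                    iterations: int = 10) -> list[IterationResult]:
    """Calibration framework: a fresh calibration sample per iteration.

    With pooling, the occurrence and count stages train on the union of
    community and calibration surveys (calibration surveys carry their own
    offsets); without pooling, on community surveys only.
    """
    config = config or dn.LearnerConfig()
    results = []
    for i, child in enumerate(_iteration_seeds(seed, iterations)):
        s_occ, s_det, s_dens, s_cal = child.spawn(4)
        calib = sample_calibration(benchmark, n_occ, s_cal)
        occ_train = pd.concat([cs, calib], ignore_index=True) if pooling else cs
        occ, mask = _occurrence_stage(occ_train, test, landscape, config, s_occ)
        removal, distance = _detection_stage(
            calib, detections[detections["survey_id"].isin(calib["survey_id"])],
            landscape, mask, s_det.generate_state(1)[0] % 2**31,
            allow_unrestricted_fallback=True)
        if pooling:
            count_train = pd.concat([cs, calib], ignore_index=True)
        else:
            count_train = cs
        offsets = det.compute_offsets(count_train, removal, distance, landscape)
        fit, grid = _count_stage(count_train, offsets, landscape, mask, config, s_dens)
        test_off = det.compute_offsets(test, removal, distance, landscape)
        results.append(IterationResult(
            "calibration", i, occ.auc, mask.area_ha, dn.mean_density(grid, mask),
            dn.estimate_population(grid, mask),
            _predictive_r(fit, grid, landscape, mask, test, test_off),
            _offsets_summary(offsets), n_occurrence_train=len(occ_train)))
    return results


# ---------------------------------------------------------------------------
# comparison
# ---------------------------------------------------------------------------

def compare(framework_results: list[IterationResult],
            benchmark_results: list[IterationResult]) -> ComparisonSummary:
    """Percent-of-benchmark per endpoint; benchmark = median of its iterations."""
    if not framework_results or not benchmark_results:
        raise InvalidArgumentError("both result lists must be non-empty")
    bench_median, percents, med_pct = {}, {}, {}
    for ep in ENDPOINTS:
        bm = float(np.median([getattr(r, ep) for r in benchmark_results]))
        bench_median[ep] = bm
        if bm == 0:
            warnings.warn(f"benchmark median for {ep} is zero; percent undefined",
                          UndefinedResultWarning)
            percents[ep] = [float("nan")] * len(framework_results)
            med_pct[ep] = float("nan")
            continue
        vals = [100.0 * getattr(r, ep) / bm for r in framework_results]
        percents[ep] = vals
        med_pct[ep] = float(np.median(vals))
    return ComparisonSummary(bench_median, percents, med_pct)
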