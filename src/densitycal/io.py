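"""Readers/writers, run configuration, and the top-level experiment runner.

Checklist CSV column dictionary (comma-separated, UTF-8, "." decimal):

==================  =====================================================
survey_id           unique string id
x_m, y_m            planar coordinates in metres (landscape origin corner)
jday                Julian day of the survey
min_since_dawn      start time in minutes since nautical dawn (may be < 0
                    in raw community data; removed by filtering)
duration_min        count duration in minutes (> 0)
protocol            stationary | traveling | incidental
location_type       personal | hotspot
observer_id         string id
complete            True/False: all detected species were reported
count_or_X          non-negative integer count, or "X" for presence-only
==================  =====================================================

Individual-detection CSV: survey_id, removal_interval, distance_bin_index.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import detection as det
from . import filtering
from . import frameworks as fw
from .density import LearnerConfig
from .errors import InvalidArgumentError, SchemaError
from .synthetic import (CHECKLIST_COLUMNS, SCENARIO_NAMES, Scenario,
                        make_fixture_scenario)

log = logging.getLogger("densitycal")

CSV_COLUMNS = ["survey_id", "x_m", "y_m", "jday", "min_since_dawn", "duration_min",
               "protocol", "location_type", "observer_id", "complete", "count_or_X"]
DETECTION_CSV_COLUMNS = ["survey_id", "removal_interval", "distance_bin_index"]


# ---------------------------------------------------------------------------
# checklist and detection CSV round trip
# ---------------------------------------------------------------------------

def write_checklists(checklists: pd.DataFrame, path) -> None:
    out = checklists.copy()
    count_or_x = out["count"].map(
        lambda v: "" if pd.isna(v) else str(int(v)))
    count_or_x[out["is_x"].astype(bool)] = "X"
    out["count_or_X"] = count_or_x
    out[CSV_COLUMNS].to_csv(path, index=False)


def read_checklists(path) -> pd.DataFrame:
    """Read and validate a checklist CSV into the in-memory schema."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"checklist file not found: {path}")
    df = pd.read_csv(path, dtype={"count_or_X": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    raw = df["count_or_X"].fillna("").str.strip()
    is_x = raw.str.upper() == "X"
    counts = pd.Series(np.nan, index=df.index, dtype=float)
    numeric = pd.to_numeric(raw.where(~is_x), errors="coerce")
    bad = (~is_x) & numeric.isna()
    if bad.any():
        rows = ", ".join(str(i + 2) for i in df.index[bad][:5])  # +2: header + 0-base
        raise SchemaError(f"unparseable count_or_X at file row(s) {rows}")
    counts[~is_x] = numeric[~is_x]
    if (df["duration_min"] <= 0).any():
        rows = ", ".join(str(i + 2) for i in df.index[df["duration_min"] <= 0][:5])
        raise SchemaError(f"non-positive duration at file row(s) {rows}")
    out = df.drop(columns=["count_or_X"]).copy()
    out["count"] = counts
    out["is_x"] = is_x.to_numpy()
    out["complete"] = out["complete"].astype(bool)
    return out[CHECKLIST_COLUMNS]


def write_detections(detections: pd.DataFrame, path) -> None:
    detections[DETECTION_CSV_COLUMNS].to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DETECTION_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    return df[DETECTION_CSV_COLUMNS]


def write_offsets(offsets: pd.DataFrame, path) -> None:
    offsets[["survey_id", "p", "edr_m", "area_ha", "C", "logC"]].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration of one experiment run."""

    scenario: str = "common"
    framework: str = "benchmark"
    n_occ: int | None = None
    pooling: bool = False
    iterations: int = 10
    seed: int = 1
    fixed_radius_m: float = 200.0
    grid_m: float = 200.0
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    out_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIO_NAMES:
            raise SchemaError(f"unknown scenario {self.scenario!r}")
        if self.framework not in fw.FRAMEWORK_NAMES:
            raise SchemaError(f"unknown framework {self.framework!r}")
        if self.framework == "calibration" and self.n_occ is None:
            raise SchemaError("calibration framework requires n_occ")
        if self.iterations < 1 or self.grid_m <= 0 or self.fixed_radius_m <= 0:
            raise SchemaError("iterations, grid_m and fixed_radius_m must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        learner = LearnerConfig(**raw.pop("learner", {}))
        try:
            return cls(learner=learner, **raw)
        except TypeError as exc:
            raise SchemaError(f"invalid config key: {exc}") from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


# ---------------------------------------------------------------------------
# experiment runner
# ---------------------------------------------------------------------------

def prepare_datasets(scenario: Scenario, seed, grid_m: float = 200.0) -> dict:
    """Filter + geographically sample community data; split the benchmark."""
    filtered, tally = filtering.filter_checklists(scenario.community)
    cs = filtering.geographic_sample(filtered, grid_m=grid_m, seed=seed)
    n_match = min(len(cs), len(scenario.structured))
    bench, test = fw.make_benchmark_dataset(scenario.structured, n_match, seed)
    return {
        "cs": cs, "benchmark": bench, "test": test,
        "structured_full": scenario.structured,
        "detections": scenario.detections,
        "filter_tally": tally,
    }


def run_framework(config: RunConfig, scenario: Scenario, data: dict) -> list[fw.IterationResult]:
    landscape = scenario.landscape
    if config.framework == "benchmark":
        return fw.run_benchmark(data["benchmark"], data["detections"], data["test"],
                                landscape, config.learner, config.seed, config.iterations)
    if config.framework == "fixed":
        return fw.run_fixed(data["cs"], data["test"], landscape, config.fixed_radius_m,
                            config.learner, config.seed, config.iterations)
    if config.framework == "independent":
        return fw.run_independent(data["cs"], data["structured_full"], data["detections"],
                                  data["test"], landscape, config.learner,
                                  config.seed, config.iterations)
    return fw.run_calibration(data["cs"], data["benchmark"], data["detections"],
                              data["test"], landscape, config.n_occ, config.pooling,
                              config.learner, config.seed, config.iterations)


def results_frame(results: list[fw.IterationResult]) -> pd.DataFrame:
    """Tidy results: one row per iteration x endpoint."""
    rows = []
    for r in results:
        for ep, val in r.endpoints.items():
            rows.append({"framework": r.framework, "iteration": r.iteration,
                         "endpoint": ep, "value": val})
    return pd.DataFrame(rows)


def run_experiment(config: RunConfig) -> Path:
    """Run one configured framework end to end and write artifacts.

    Writes ``iterations.csv`` (tidy per-iteration endpoints), ``summary.json``
    (endpoint medians and diagnostics) and ``manifest.json`` (config hash,
    package version, seed) to the output directory; returns that directory.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    log.info("scenario=%s framework=%s seed=%d", config.scenario, config.framework,
             config.seed)
    scenario = make_fixture_scenario(config.scenario, config.seed)
    log.info("scenario built in %.1fs; true population %.1f birds",
             time.time() - t0, scenario.true_population)
    data = prepare_datasets(scenario, config.seed, config.grid_m)
    log.info("community: %d raw -> %d filtered+sampled; benchmark %d, test %d",
             len(scenario.community), len(data["cs"]), len(data["benchmark"]),
             len(data["test"]))
    try:
        results = run_framework(config, scenario, data)
    except Exception:
        log.exception("framework stage failed")
        raise
    results_frame(results).to_csv(out / "iterations.csv", index=False)
    medians = {ep: float(np.median([getattr(r, ep) for r in results]))
               for ep in fw.ENDPOINTS}
    summary = {
        "config": config.to_dict(),
        "true_population": scenario.true_population,
        "endpoint_medians": medians,
        "filter_tally": data["filter_tally"],
        "n_community": int(len(data["cs"])),
        "runtime_s": round(time.time() - t0, 2),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "config": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log.info("done in %.1fs -> %s", time.time() - t0, out)
    return out


def compare_result_dirs(benchmark_dir, framework_dir) -> dict:
    """Percent-of-benchmark comparison from two ``iterations.csv`` artifacts."""
    def load(d):
        df = pd.read_csv(Path(d) / "iterations.csv")
        return df.pivot(index="iteration", columns="endpoint", values="value")

    bench, frame = load(benchmark_dir), load(framework_dir)
    out = {}
    for ep in fw.ENDPOINTS:
        bm = float(bench[ep].median())
        if bm == 0:
            out[ep] = {"benchmark_median": bm, "median_percent": None}
            continue
        pct = (100.0 * frame[ep] / bm)
        out[ep] = {"benchmark_median": bm, "median_percent": float(pct.median())}
    return out
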