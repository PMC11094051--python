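"""Gridded landscapes with multi-scale (focal-mean) environmental covariates.

A :class:`Landscape` is a regular grid of square cells in planar metre
coordinates (origin at the lower-left corner, cells half-open
``[x, x + cell) x [y, y + cell)``).  Each named covariate is stored as a base
layer plus focal-mean versions at the five radii used throughout the package:
75, 165, 315, 615 and 1215 m.  A focal mean at radius ``r`` averages the cells
whose centres fall within ``r`` of the focal cell's centre, truncated at the
landscape edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.signal import fftconvolve

from .errors import InvalidArgumentError

FOCAL_RADII_M: tuple[float, ...] = (75.0, 165.0, 315.0, 615.0, 1215.0)


def _disc_kernel(radius_m: float, cell_m: float) -> np.ndarray:
    """0/1 kernel selecting cells whose centres lie within radius_m."""
    k = int(np.floor(radius_m / cell_m))
    di = np.arange(-k, k + 1)
    dist2 = (di[:, None] ** 2 + di[None, :] ** 2) * cell_m**2
    return (dist2 <= radius_m**2).astype(float)


def focal_mean(layer: np.ndarray, radius_m: float, cell_m: float) -> np.ndarray:
    """Edge-truncated focal mean of ``layer`` within ``radius_m``."""
    kernel = _disc_kernel(radius_m, cell_m)
    num = fftconvolve(layer, kernel, mode="same")
    den = fftconvolve(np.ones_like(layer), kernel, mode="same")
    return num / den


@dataclass
class Landscape:
    cell_m: float
    covariates: dict[str, np.ndarray]  # name -> (n_y, n_x) base layer
    focal: dict[str, np.ndarray] = field(default_factory=dict)  # "name_radius"
    radii: tuple[float, ...] = FOCAL_RADII_M

    def __post_init__(self) -> None:
        if self.cell_m <= 0:
            raise InvalidArgumentError("cell side length must be positive")
        for name, layer in list(self.covariates.items()):
            if not self._has_focal(name):
                self._compute_focal(name, layer)

    # -- construction -----------------------------------------------------
    def _has_focal(self, name: str) -> bool:
        return all(f"{name}_{int(r)}" in self.focal for r in self.radii)

    def _compute_focal(self, name: str, layer: np.ndarray) -> None:
        for r in self.radii:
            self.focal[f"{name}_{int(r)}"] = focal_mean(layer, r, self.cell_m)

    def add_covariate(self, name: str, layer: np.ndarray) -> None:
        """Add (or replace) a base layer and recompute its focal means."""
        if layer.shape != self.shape:
            raise InvalidArgumentError("layer shape does not match landscape")
        self.covariates[name] = layer
        self._compute_focal(name, layer)

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        first = next(iter(self.covariates.values()))
        return first.shape

    @property
    def n_y(self) -> int:
        return self.shape[0]

    @property
    def n_x(self) -> int:
        return self.shape[1]

    @property
    def extent_m(self) -> tuple[float, float]:
        """(width, height) in metres."""
        return self.n_x * self.cell_m, self.n_y * self.cell_m

    @property
    def cell_area_ha(self) -> float:
        return self.cell_m**2 / 1e4

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    def cell_index(self, x_m, y_m) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the half-open cell containing each point."""
        col = np.floor(np.asarray(x_m) / self.cell_m).astype(int)
        row = np.floor(np.asarray(y_m) / self.cell_m).astype(int)
        return row, col

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        xs = (np.arange(self.n_x) + 0.5) * self.cell_m
        ys = (np.arange(self.n_y) + 0.5) * self.cell_m
        return np.meshgrid(xs, ys)

    # -- feature extraction ----------------------------------------------
    def feature_names(self, radii: tuple[float, ...] | None = None) -> list[str]:
        radii = self.radii if radii is None else radii
        return [f"{n}_{int(r)}" for n in self.covariates for r in radii]

    def cell_features(self, radii: tuple[float, ...] | None = None) -> np.ndarray:
        """(n_cells, n_features) matrix of focal-mean covariates, row-major."""
        names = self.feature_names(radii)
        return np.column_stack([self.focal[n].ravel() for n in names])

    def layer(self, name: str) -> np.ndarray:
        """Base layer or focal layer ('name' or 'name_75')."""
        if name in self.covariates:
            return self.covariates[name]
        return self.focal[name]

    def values_at(self, name: str, x_m, y_m) -> np.ndarray:
        row, col = self.cell_index(x_m, y_m)
        return self.layer(name)[row, col]

    # -- serialization ----------------------------------------------------
    def save(self, path: str) -> None:
        """Write layers to <path>.npz with a JSON sidecar <path>.json."""
        arrays = {f"base__{k}": v for k, v in self.covariates.items()}
        arrays.update({f"focal__{k}": v for k, v in self.focal.items()})
        np.savez(path + ".npz", **arrays)
        meta = {
            "cell_m": self.cell_m,
            "covariates": list(self.covariates),
            "radii": list(self.radii),
            "shape": list(self.shape),
        }
        with open(path + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path: str) -> "Landscape":
        with open(path + ".json") as fh:
            meta = json.load(fh)
        data = np.load(path + ".npz")
        cov = {k[len("base__"):]: data[k] for k in data.files if k.startswith("base__")}
        foc = {k[len("focal__"):]: data[k] for k in data.files if k.startswith("focal__")}
        return cls(cell_m=meta["cell_m"], covariates=cov, focal=foc,
                   radii=tuple(meta["radii"]))


def generate_landscape(
    n_x: int,
    n_y: int,
    cell_m: float,
    n_covariates: int,
    smoothness_m: float,
    seed,
    covariate_names: list[str] | None = None,
) -> Landscape:
    """Simulate spatially autocorrelated, standardized covariate layers.

    Each layer is white Gaussian noise convolved with an isotropic Gaussian
    kernel of scale ``smoothness_m`` (in metres), then standardized to mean 0
    and standard deviation 1 across cells.  Focal means at the five standard
    radii are computed on the standardized layers.

    Parameters
    ----------
    n_x, n_y
        Grid dimensions (>= 8).
    cell_m
        Cell side length in metres.
    n_covariates
        Number of independent layers to draw.
    smoothness_m
        Gaussian autocorrelation scale; the limit ``smoothness_m -> 0``
        recovers spatially independent noise.
    seed
        Anything accepted by :func:`numpy.random.default_rng`.
    covariate_names
        Optional names; defaults to ``cov1..covN``.
    """
    if n_x < 8 or n_y < 8:
        raise InvalidArgumentError("grid must be at least 8 x 8 cells")
    if cell_m <= 0 or smoothness_m <= 0:
        raise InvalidArgumentError("cell_m and smoothness_m must be positive")
    if n_covariates < 1:
        raise InvalidArgumentError("need at least one covariate")
    names = covariate_names or [f"cov{i + 1}" for i in range(n_covariates)]
    if len(names) != n_covariates:
        raise InvalidArgumentError("covariate_names length mismatch")

    rng = np.random.default_rng(seed)
    sigma_cells = smoothness_m / cell_m
    pad = int(np.ceil(4 * sigma_cells))
    cov: dict[str, np.ndarray] = {}
    for name in names:
        noise = rng.standard_normal((n_y + 2 * pad, n_x + 2 * pad))
        smooth = gaussian_filter(noise, sigma=sigma_cells, mode="constant")
        layer = smooth[pad:pad + n_y, pad:pad + n_x] if pad else smooth
        layer = (layer - layer.mean()) / layer.std()
        cov[name] = layer
    return Landscape(cell_m=cell_m, covariates=cov)
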