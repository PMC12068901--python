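"""Replicated neutral landscapes for habitat-selection simulations.

Each landscape replicate carries three square raster covariates on the same
grid:

* ``elev`` — a continuous surface in [0, 1], generated as two-dimensional
  fractional Brownian motion (fBm) whose roughness is controlled by the
  fractional dimension ``fract_dim``;
* ``hab`` — a binary habitat indicator obtained by thresholding a second,
  independent fBm surface at 0.5 (strictly greater-than), which leaves about
  half of the cells as "habitat";
* ``dist_center`` — Euclidean distance (cell units, not standardized) to the
  landscape center, used as the homing covariate.

fBm fields are synthesised by circulant embedding: the intrinsic variogram
``gamma(h) = h ** fract_dim`` is turned into a stationary covariance on the
periodic doubled grid, its FFT gives the spectral weights, and one inverse
FFT of spectrally-weighted white noise yields the field, which is cropped to
remove wrap-around and min-max rescaled to [0, 1].  Small ``fract_dim``
(0.01) gives an essentially uncorrelated surface, large (1) a smooth, highly
autocorrelated one; rook-weight Moran's I is the diagnostic for this
ordering.

Coordinates are 0-based with ``x`` = column index and ``y`` = row index,
cell width 1; covariates are read by integer cell lookup (nearest cell, no
interpolation).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .seeding import substream

logger = logging.getLogger(__name__)

__all__ = [
    "LandscapeLayer",
    "LandscapeSet",
    "generate_fbm",
    "binarize",
    "distance_to_center",
    "morans_i",
    "make_landscape_set",
    "uniform_landscape_set",
    "extract_covariates",
    "write_ascii_grid",
    "read_ascii_grid",
    "write_landscape_set",
    "read_landscape_set",
]

#: minimum supported grid side for generated fBm layers
MIN_SIZE = 8


@dataclasses.dataclass
class LandscapeLayer:
    """One square raster covariate.

    kind is one of ``continuous`` (values in [0, 1]), ``binary`` (0/1) or
    ``distance`` (nonnegative, zero at the center cell).
    """

    name: str
    values: np.ndarray  # shape (size, size); values[y, x]
    kind: str
    fract_dim: Optional[float] = None
    seed: Optional[int] = None

    @property
    def size(self) -> int:
        return self.values.shape[0]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("layer values must be a square 2-D array")
        if self.kind not in ("continuous", "binary", "distance"):
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclasses.dataclass
class LandscapeSet:
    """The three covariate layers of one landscape replicate."""

    elev: LandscapeLayer
    hab: LandscapeLayer
    dist_center: LandscapeLayer
    replicate_id: int = 0

    @property
    def size(self) -> int:
        return self.elev.size

    def __post_init__(self) -> None:
        sizes = {self.elev.size, self.hab.size, self.dist_center.size}
        if len(sizes) != 1:
            raise ValueError("all layers of a landscape set must share one size")

    def layer(self, name: str) -> LandscapeLayer:
        try:
            return {"elev": self.elev, "hab": self.hab,
                    "dist_center": self.dist_center}[name]
        except KeyError:
            raise KeyError(f"no layer named {name!r}") from None


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_fbm(size: int, fract_dim: float, seed: int, name: str = "fbm") -> LandscapeLayer:
    """Generate a min-max-rescaled 2-D fractional Brownian surface.

    Parameters
    ----------
    size : int
        Cells per side, at least 8.
    fract_dim : float
        Variogram exponent in (0, 2]; larger values give smoother, more
        spatially autocorrelated surfaces.
    seed : int
        Seed of the layer's random stream; same (size, fract_dim, seed)
        always yields the same grid.
    """
    if size < MIN_SIZE:
        raise ValueError(f"size must be >= {MIN_SIZE}, got {size}")
    if not (0.0 < fract_dim <= 2.0):
        raise ValueError(f"fract_dim must be in (0, 2], got {fract_dim}")
    rng = substream(seed, "fbm")
    n_embed = 2 * size
    ax = np.minimum(np.arange(n_embed), n_embed - np.arange(n_embed)).astype(float)
    h = np.hypot(ax[:, None], ax[None, :])  # torus distances
    # stationarized covariance of the intrinsic field; additive constants are
    # irrelevant after rescaling
    cov = h.max() ** fract_dim - h**fract_dim
    lam = np.fft.fft2(cov).real
    # circulant embedding of an intrinsic model need not be exactly PSD;
    # clip the (tiny) negative eigenvalues
    np.clip(lam, 0.0, None, out=lam)
    noise = np.fft.fft2(rng.normal(size=(n_embed, n_embed)))
    field = np.fft.ifft2(np.sqrt(lam) * noise).real[:size, :size]
    lo, hi = field.min(), field.max()
    if hi <= lo:  # pragma: no cover - cannot occur for fract_dim > 0
        raise RuntimeError("degenerate constant field")
    values = (field - lo) / (hi - lo)
    return LandscapeLayer(name=name, values=values, kind="continuous",
                          fract_dim=float(fract_dim), seed=int(seed))


def binarize(layer: LandscapeLayer, threshold: float = 0.5) -> LandscapeLayer:
    """Threshold a continuous layer: values strictly greater than
    ``threshold`` become 1, all others (including exact ties) 0."""
    if layer.kind != "continuous":
        raise TypeError(f"binarize expects a continuous layer, got {layer.kind!r}")
    values = (layer.values > threshold).astype(float)
    return LandscapeLayer(name=layer.name, values=values, kind="binary",
                          fract_dim=layer.fract_dim, seed=layer.seed)


def distance_to_center(size: int, name: str = "dist_center") -> LandscapeLayer:
    """Euclidean distance (cell units) from each cell center to the landscape
    center.

    For even sizes the center is the point (size/2 - 0.5, size/2 - 0.5) in
    0-based cell-center coordinates, i.e. the corner shared by the four
    central cells; for odd sizes it is the central cell, whose distance is
    exactly zero.
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    c = (size - 1) / 2.0
    ax = np.arange(size, dtype=float) - c
    values = np.hypot(ax[:, None], ax[None, :])
    return LandscapeLayer(name=name, values=values, kind="distance")


def center_of(size: int) -> tuple[float, float]:
    """(x, y) of the homing center for a grid of the given size."""
    c = (size - 1) / 2.0
    return c, c


def morans_i(layer: LandscapeLayer) -> float:
    """Moran's I with rook contiguity weights (shared-edge neighbours).

    Raises on a constant layer, where spatial autocorrelation is undefined.
    """
    v = layer.values
    if v.shape[0] < 3:
        raise ValueError("Moran's I needs size >= 3")
    z = v - v.mean()
    denom = (z * z).sum()
    if denom == 0.0:
        raise ValueError("Moran's I is undefined for a constant layer")
    # each unordered rook pair counted once; symmetric weights double both
    # the cross-product sum and W, so the factor cancels
    cross = (z[:-1, :] * z[1:, :]).sum() + (z[:, :-1] * z[:, 1:]).sum()
    n_pairs = (v.shape[0] - 1) * v.shape[1] + v.shape[0] * (v.shape[1] - 1)
    n = v.size
    return float((n / n_pairs) * cross / denom)


def make_landscape_set(
    size: int,
    fract_dim_elev: float,
    fract_dim_hab: float,
    replicate_id: int = 0,
    seed: int = 0,
) -> LandscapeSet:
    """Generate one landscape replicate.

    ``elev`` and ``hab`` come from independent named substreams of the master
    seed, so changing one layer's fractional dimension leaves the other
    layer's realization untouched.
    """
    from .seeding import child_seed

    elev = generate_fbm(size, fract_dim_elev,
                        child_seed(seed, "elev", replicate_id), name="elev")
    hab_cont = generate_fbm(size, fract_dim_hab,
                            child_seed(seed, "hab", replicate_id), name="hab")
    hab = binarize(hab_cont)
    return LandscapeSet(elev=elev, hab=hab, dist_center=distance_to_center(size),
                        replicate_id=replicate_id)


def uniform_landscape_set(size: int, elev_value: float = 0.5,
                          hab_value: float = 0.0) -> LandscapeSet:
    """A spatially homogeneous landscape (constant elev/hab).

    Selection weights cancel on such a landscape, so movement reduces to an
    unbiased stepping-stone walk; used for move-probability diagnostics.
    """
    elev = LandscapeLayer("elev", np.full((size, size), float(elev_value)), "continuous")
    hab = LandscapeLayer("hab", np.full((size, size), float(hab_value)), "binary")
    return LandscapeSet(elev=elev, hab=hab, dist_center=distance_to_center(size))


def extract_covariates(landscape: LandscapeSet, x, y) -> dict[str, np.ndarray]:
    """Covariate values at (possibly continuous) coordinates by nearest-cell
    lookup, clipped to the grid."""
    size = landscape.size
    col = np.clip(np.rint(np.asarray(x, dtype=float)).astype(int), 0, size - 1)
    row = np.clip(np.rint(np.asarray(y, dtype=float)).astype(int), 0, size - 1)
    return {
        "elev": landscape.elev.values[row, col],
        "hab": landscape.hab.values[row, col],
        "dist_center": landscape.dist_center.values[row, col],
    }


# ---------------------------------------------------------------------------
# raster I/O (ESRI ASCII grid + YAML metadata sidecar)
# ---------------------------------------------------------------------------

def write_ascii_grid(layer: LandscapeLayer, path) -> None:
    """Write a layer as a single-band ESRI ASCII grid (north-up: the first
    file row is the highest y), with generation metadata in
    ``<path>.meta.yaml``."""
    path = Path(path)
    n = layer.size
    header = (
        f"ncols {n}\nnrows {n}\nxllcorner -0.5\nyllcorner -0.5\n"
        f"cellsize 1.0\nNODATA_value -9999\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, layer.values[::-1], fmt="%.10g")
    meta = {"name": layer.name, "kind": layer.kind,
            "fract_dim": layer.fract_dim, "seed": layer.seed}
    Path(str(path) + ".meta.yaml").write_text(yaml.safe_dump(meta))


def read_ascii_grid(path) -> LandscapeLayer:
    path = Path(path)
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    values = values[::-1]  # back to values[y, x] with y increasing upward
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("grid shape does not match header")
    meta_path = Path(str(path) + ".meta.yaml")
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    return LandscapeLayer(
        name=meta.get("name", path.stem),
        values=values,
        kind=meta.get("kind", "continuous"),
        fract_dim=meta.get("fract_dim"),
        seed=meta.get("seed"),
    )


def write_landscape_set(lset: LandscapeSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("elev", "hab", "dist_center"):
        write_ascii_grid(lset.layer(name), directory / f"{name}.asc")
    (directory / "set.meta.yaml").write_text(
        yaml.safe_dump({"replicate_id": lset.replicate_id}))


def read_landscape_set(directory) -> LandscapeSet:
    directory = Path(directory)
    layers = {name: read_ascii_grid(directory / f"{name}.asc")
              for name in ("elev", "hab", "dist_center")}
    meta_path = directory / "set.meta.yaml"
    meta = yaml.safe_load(meta_path.read_text()) if meta_path.exists() else {}
    return LandscapeSet(elev=layers["elev"], hab=layers["hab"],
                        dist_center=layers["dist_center"],
                        replicate_id=meta.get("replicate_id", 0))
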