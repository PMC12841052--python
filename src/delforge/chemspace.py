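"""Chemical-space embedding and density-based occupancy analysis.

Compound sets are fingerprinted with functional-class (FCFP-style) circular
fingerprints (radius 2, 1024 bits), embedded into 2-D with UMAP fitted on a
reference population only (n_neighbors=50, jaccard metric), and compared by
Gaussian kernel density estimation on a shared grid: the occupied region of
a set is the superlevel set {density > threshold} of its KDE (Scott's-rule
bandwidth, threshold 0.01 on the raw normalized density), and the occupancy
rate of a library against a reference is the fraction of the reference's
occupied cells also occupied by the library.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator
from scipy.stats import gaussian_kde

from .errors import GridMismatchError, ParseError

logger = logging.getLogger(__name__)

__all__ = [
    "fcfp_fp",
    "fingerprint_matrix",
    "EmbeddingModel",
    "fit_embedding",
    "project",
    "DensityMap",
    "OccupancyReport",
    "shared_grid",
    "kde_map",
    "occupancy",
]

DEFAULT_THRESHOLD = 0.01
DEFAULT_RESOLUTION = 512
DEFAULT_PADDING = 0.05

_FCFP_GEN: dict[tuple[int, int], object] = {}


def _fcfp_generator(nbits: int, radius: int):
    key = (nbits, radius)
    if key not in _FCFP_GEN:
        inv = rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
        _FCFP_GEN[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=nbits, atomInvariantsGenerator=inv)
    return _FCFP_GEN[key]


def fcfp_fp(structure: str | Chem.Mol, nbits: int = 1024,
            radius: int = 2) -> np.ndarray:
    """Functional-class circular fingerprint (FCFP4-style) as 0/1 uint8."""
    if isinstance(structure, Chem.Mol):
        mol = structure
    else:
        mol = Chem.MolFromSmiles(structure)
        if mol is None:
            raise ParseError(f"unparsable SMILES: {structure!r}")
    return _fcfp_generator(nbits, radius).GetFingerprintAsNumPy(mol).astype(
        np.uint8)


def fingerprint_matrix(structures: Iterable[str], nbits: int = 1024,
                       radius: int = 2) -> tuple[np.ndarray, list[int]]:
    """Fingerprint a collection; returns (matrix, kept input indices).

    Unparsable entries are skipped with a log record.
    """
    rows, kept = [], []
    for i, s in enumerate(structures):
        try:
            rows.append(fcfp_fp(s, nbits=nbits, radius=radius))
        except ParseError:
            logger.info("fingerprint skip: %r", s)
            continue
        kept.append(i)
    if rows:
        return np.vstack(rows), kept
    return np.empty((0, nbits), dtype=np.uint8), kept


@dataclass
class EmbeddingModel:
    """A fitted fingerprint+UMAP embedding.

    ``reference_coords`` are the 2-D coordinates of the reference set the
    model was fitted on.  Transforms are deterministic for a fixed seed.
    """

    n_neighbors: int
    metric: str
    seed: int
    nbits: int
    radius: int
    reference_coords: np.ndarray
    _reducer: object = field(repr=False, default=None)


def fit_embedding(reference: Sequence[str] | np.ndarray,
                  n_neighbors: int = 50, metric: str = "jaccard",
                  seed: int = 42, nbits: int = 1024,
                  radius: int = 2) -> EmbeddingModel:
    """Fit the 2-D embedding on the reference population only.

    ``reference`` is either a list of SMILES or a precomputed 0/1
    fingerprint matrix.
    """
    import umap

    if isinstance(reference, np.ndarray):
        X = reference
    else:
        reference = list(reference)
        if not reference:
            raise ValueError("reference must be nonempty")
        X, _ = fingerprint_matrix(reference, nbits=nbits, radius=radius)
    if X.shape[0] == 0:
        raise ValueError("reference must be nonempty")
    if X.shape[0] < n_neighbors:
        raise ValueError(
            f"n={X.shape[0]} reference compounds is fewer than "
            f"n_neighbors={n_neighbors}; lower n_neighbors to at most n")
    reducer = umap.UMAP(n_neighbors=n_neighbors, n_components=2,
                        metric=metric, random_state=seed)
    coords = reducer.fit_transform(X)
    return EmbeddingModel(n_neighbors=n_neighbors, metric=metric, seed=seed,
                          nbits=nbits, radius=radius,
                          reference_coords=np.asarray(coords),
                          _reducer=reducer)


def project(model: EmbeddingModel,
            structures: Sequence[str] | np.ndarray) -> np.ndarray:
    """Project structures through a fitted model; one coordinate pair per
    sanitizable input, input order preserved (unparsable inputs skipped
    with a log record)."""
    if model._reducer is None:
        raise ValueError("model is not fitted")
    if isinstance(structures, np.ndarray):
        X = structures
    else:
        if len(structures) == 0:
            return np.empty((0, 2))
        X, _ = fingerprint_matrix(structures, nbits=model.nbits,
                                  radius=model.radius)
    if X.shape[0] == 0:
        return np.empty((0, 2))
    return np.asarray(model._reducer.transform(X))


@dataclass
class DensityMap:
    """Gridded 2-D KDE of an embedded compound set."""

    grid_x: np.ndarray  # (R,) cell-center x coordinates
    grid_y: np.ndarray  # (R,) cell-center y coordinates
    density: np.ndarray  # (R, R), indexed [iy, ix]
    threshold: float
    bandwidth_factor: float

    @property
    def cell_area(self) -> float:
        return float((self.grid_x[1] - self.grid_x[0])
                     * (self.grid_y[1] - self.grid_y[0]))

    @property
    def occupied_mask(self) -> np.ndarray:
        return self.density > self.threshold

    @property
    def area(self) -> float:
        return float(self.occupied_mask.sum()) * self.cell_area

    @property
    def integral(self) -> float:
        return float(self.density.sum()) * self.cell_area

    def same_grid(self, other: "DensityMap") -> bool:
        return (self.grid_x.shape == other.grid_x.shape
                and np.allclose(self.grid_x, other.grid_x)
                and np.allclose(self.grid_y, other.grid_y))


@dataclass
class OccupancyReport:
    name: str
    kde_area: float
    occupancy_rate: float
    mean_qed: float | None = None

    def as_dict(self) -> dict:
        return {"name": self.name, "kde_area": self.kde_area,
                "occupancy_rate": self.occupancy_rate,
                "mean_qed": self.mean_qed}


def shared_grid(coord_sets: Sequence[np.ndarray],
                resolution: int = DEFAULT_RESOLUTION,
                padding: float = DEFAULT_PADDING
                ) -> tuple[np.ndarray, np.ndarray]:
    """One global lattice spanning the union bounding box of all sets,
    padded by ``padding`` per side.  Comparing areas across sets requires
    every map to be built on this shared grid."""
    allpts = np.vstack([np.asarray(c) for c in coord_sets if len(c)])
    lo = allpts.min(axis=0)
    hi = allpts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    lo = lo - padding * span
    hi = hi + padding * span
    return (np.linspace(lo[0], hi[0], resolution),
            np.linspace(lo[1], hi[1], resolution))


def kde_map(coords: np.ndarray,
            grid: tuple[np.ndarray, np.ndarray] | None = None,
            resolution: int = DEFAULT_RESOLUTION,
            threshold: float = DEFAULT_THRESHOLD) -> DensityMap:
    """Gaussian KDE (Scott's-rule bandwidth) of 2-D coordinates on a grid.

    Needs at least 3 non-collinear points; a singular covariance raises
    with advice to jitter the coordinates.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 two-dimensional points")
    # collapse exact duplicates into weights so the map (including the
    # Scott's-rule effective sample size) is invariant to duplication
    uniq, counts = np.unique(pts, axis=0, return_counts=True)
    try:
        kde = gaussian_kde(uniq.T, bw_method="scott",
                           weights=counts.astype(float))
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular covariance (collinear points); add a small random "
            "jitter to the coordinates") from exc
    if grid is None:
        grid = shared_grid([pts], resolution=resolution)
    gx, gy = grid
    xx, yy = np.meshgrid(gx, gy)
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(len(gy), len(gx))
    return DensityMap(grid_x=np.asarray(gx), grid_y=np.asarray(gy),
                      density=dens, threshold=threshold,
                      bandwidth_factor=float(kde.factor))


def occupancy(library_map: DensityMap, reference_map: DensityMap,
              name: str = "", mean_qed: float | None = None
              ) -> OccupancyReport:
    """Fraction of the reference's occupied cells also occupied by the
    library, plus the library's own occupied area."""
    if not library_map.same_grid(reference_map):
        raise GridMismatchError(
            "density maps must be built on a shared grid; use shared_grid()")
    ref_mask = reference_map.occupied_mask
    n_ref = int(ref_mask.sum())
    if n_ref == 0:
        raise ValueError("reference occupied region is empty; lower the "
                         "threshold or check the reference coordinates")
    inter = int((library_map.occupied_mask & ref_mask).sum())
    return OccupancyReport(name=name, kde_area=library_map.area,
                           occupancy_rate=inter / n_ref, mean_qed=mean_qed)
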