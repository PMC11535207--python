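"""Natal-habitat characterisation: buffer composition, scaled PCA, clustering.

Each natal territory is summarised by seven descriptors — mean elevation
and the proportions of the six land-cover classes — computed over a
2 km buffer around the nest.  A PCA on the scaled descriptors defines a
shared low-dimensional habitat space; natal areas are grouped into
habitat types by furthest-neighbour (complete-linkage) hierarchical
clustering of their PC scores, and arbitrary locations can be projected
into the same space to measure habitat dissimilarity.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.signal import oaconvolve

from .landscape import LAND_COVER_CLASSES, LandscapeRaster

#: Order of the natal habitat descriptors.
HABITAT_VARIABLES: tuple[str, ...] = ("elevation",) + tuple(
    f"prop_{c}" for c in LAND_COVER_CLASSES
)

DEFAULT_BUFFER_RADIUS = 2000.0  # m, the standard territory radius


class ExtractionError(ValueError):
    """No raster cell centre falls inside the requested buffer."""


class ProjectionError(ValueError):
    """A vector is incomplete on the PCA model's variable set."""


@dataclass
class HabitatVector:
    """Buffer composition: mean elevation + land-cover proportions.

    Proportions are over in-buffer cells only and sum to 1 (the buffer
    is renormalised where it is clipped by the raster edge).
    """

    elevation: float
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        missing = [c for c in LAND_COVER_CLASSES if c not in self.proportions]
        if missing:
            raise ValueError(f"missing land-cover classes: {missing}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")
        if not np.isfinite(self.elevation):
            raise ValueError("elevation not finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.elevation] + [self.proportions[c] for c in LAND_COVER_CLASSES]
        )

    @classmethod
    def from_array(cls, values: np.ndarray) -> "HabitatVector":
        values = np.asarray(values, dtype=float)
        return cls(
            elevation=float(values[0]),
            proportions={c: float(v) for c, v in zip(LAND_COVER_CLASSES, values[1:])},
        )


def extract_buffer_composition(
    landscape: LandscapeRaster, point: tuple[float, float], radius: float = DEFAULT_BUFFER_RADIUS
) -> HabitatVector:
    """Composition of the disc of given radius around ``point``.

    A cell belongs to the buffer iff its *centre* lies within ``radius``
    of the point.  Proportions are fractions of in-buffer cells per
    class; elevation is their mean.
    """
    x, y = point
    cs = landscape.cell_size
    # bounding box of candidate cells
    row_lo = max(int(np.floor((y - radius - landscape.y0) / cs)), 0)
    row_hi = min(int(np.ceil((y + radius - landscape.y0) / cs)) + 1, landscape.n_rows)
    col_lo = max(int(np.floor((x - radius - landscape.x0) / cs)), 0)
    col_hi = min(int(np.ceil((x + radius - landscape.x0) / cs)) + 1, landscape.n_cols)
    if row_lo >= row_hi or col_lo >= col_hi:
        raise ExtractionError(f"buffer around {point} misses the raster")
    rows = np.arange(row_lo, row_hi)
    cols = np.arange(col_lo, col_hi)
    cx, cy = landscape.cell_center(*np.meshgrid(rows, cols, indexing="ij"))
    inside = (cx - x) ** 2 + (cy - y) ** 2 <= radius**2
    n = int(inside.sum())
    if n == 0:
        raise ExtractionError(f"no cell centre within {radius} m of {point}")
    elev = landscape.elevation[row_lo:row_hi, col_lo:col_hi][inside]
    lc = landscape.land_cover[row_lo:row_hi, col_lo:col_hi][inside]
    counts = np.bincount(lc, minlength=len(LAND_COVER_CLASSES))
    props = counts / n
    return HabitatVector(
        elevation=float(elev.mean()),
        proportions={c: float(p) for c, p in zip(LAND_COVER_CLASSES, props)},
    )


# ---------------------------------------------------------------------------
# PCA on the scaled descriptors


@dataclass
class PCAModel:
    """Scaling parameters + loadings of the natal-habitat PCA.

    ``loadings`` holds all principal axes (columns, orthonormal
    eigenvectors of the correlation matrix, descending eigenvalue);
    projection uses the first ``k_retained``.  ``variable_names``
    records the variable set actually fitted (zero-variance variables
    are dropped at fit time).
    """

    variable_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    loadings: np.ndarray
    explained_variance_fraction: np.ndarray
    k_retained: int = 2

    def project(self, v) -> np.ndarray:
        """Scores of one vector (or an (n, p) matrix) on the retained axes."""
        if isinstance(v, HabitatVector):
            arr = _subset(v, self.variable_names)
        else:
            arr = np.asarray(v, dtype=float)
            if arr.shape[-1] != len(self.variable_names):
                raise ProjectionError(
                    f"expected {len(self.variable_names)} variables, got {arr.shape[-1]}"
                )
        if not np.all(np.isfinite(arr)):
            raise ProjectionError("non-finite value in vector to project")
        z = (arr - self.means) / self.sds
        return z @ self.loadings[:, : self.k_retained]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "variable_names": list(self.variable_names),
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_fraction": self.explained_variance_fraction.tolist(),
            "k_retained": self.k_retained,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            variable_names=tuple(d["variable_names"]),
            means=np.array(d["means"]),
            sds=np.array(d["sds"]),
            loadings=np.array(d["loadings"]),
            explained_variance_fraction=np.array(d["explained_variance_fraction"]),
            k_retained=int(d["k_retained"]),
        )


def _subset(v: HabitatVector, names: tuple[str, ...]) -> np.ndarray:
    full = dict(zip(HABITAT_VARIABLES, v.as_array()))
    try:
        return np.array([full[n] for n in names])
    except KeyError as exc:  # pragma: no cover - names always from HABITAT_VARIABLES
        raise ProjectionError(f"missing variable {exc}") from exc


def fit_natal_pca(vectors: list[HabitatVector], k_retained: int = 2) -> PCAModel:
    """PCA of the scaled natal descriptors.

    Variables are centred and scaled by their SD (n−1 denominator);
    loadings are the eigenvectors of the correlation matrix sorted by
    descending eigenvalue.  Zero-variance variables are dropped with a
    warning.  Each axis is oriented so its largest-magnitude loading is
    positive (downstream distances are sign-invariant).
    """
    if len(vectors) < 3:
        raise ValueError("need at least 3 vectors to fit the PCA")
    X = np.array([v.as_array() for v in vectors])
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise ValueError("all variables have zero variance")
    dropped = [n for n, k in zip(HABITAT_VARIABLES, keep) if not k]
    if dropped:
        warnings.warn(f"dropping zero-variance variables: {dropped}", stacklevel=2)
    names = tuple(n for n, k in zip(HABITAT_VARIABLES, keep) if k)
    X = X[:, keep]
    means = X.mean(axis=0)
    sds = sds[keep]
    Z = (X - means) / sds
    corr = (Z.T @ Z) / (len(vectors) - 1)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    # sign convention: dominant loading positive per axis
    for j in range(eigvec.shape[1]):
        i = np.argmax(np.abs(eigvec[:, j]))
        if eigvec[i, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    return PCAModel(
        variable_names=names,
        means=means,
        sds=sds,
        loadings=eigvec,
        explained_variance_fraction=eigval / eigval.sum(),
        k_retained=min(k_retained, len(names)),
    )


def project(pca: PCAModel, v) -> np.ndarray:
    """Functional alias for :meth:`PCAModel.project`."""
    return pca.project(v)


# ---------------------------------------------------------------------------
# Furthest-neighbour clustering of natal habitats


def cluster_natal_habitats(scores: np.ndarray, k: int | str = "auto") -> tuple[np.ndarray, np.ndarray]:
    """Complete-linkage clustering of PC scores into natal habitat types.

    Parameters
    ----------
    scores
        ``(n, K)`` matrix of retained PC scores.
    k
        Number of clusters, or ``"auto"`` to pick the cut with the
        largest relative loss of within-cluster inertia among
        consecutive cuts scanning k in [2, min(10, n−1)].

    Returns
    -------
    labels, merge_heights
        Integer labels 0..k−1 relabelled by descending cluster size,
        and the (n−1) linkage merge heights (non-decreasing).
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    n = scores.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points to cluster")
    Z = linkage(scores, method="complete", metric="euclidean")
    heights = Z[:, 2]
    if k == "auto":
        k = _auto_k(scores, Z, k_max=min(10, n - 1))
    k = int(k)
    if not (2 <= k <= n) and n > 1:
        raise ValueError(f"k={k} outside [2, {n}]")
    raw = fcluster(Z, t=k, criterion="maxclust")
    return _relabel_by_size(raw), heights


def _within_inertia(scores: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for lab in np.unique(labels):
        pts = scores[labels == lab]
        total += ((pts - pts.mean(axis=0)) ** 2).sum()
    return total


def _auto_k(scores: np.ndarray, Z: np.ndarray, k_max: int) -> int:
    """Cut with the largest relative inertia loss between consecutive cuts."""
    ks = range(2, max(k_max, 2) + 1)
    inertia = {1: _within_inertia(scores, np.zeros(len(scores)))}
    for k in ks:
        inertia[k] = _within_inertia(scores, fcluster(Z, t=k, criterion="maxclust"))
    best_k, best_gain = 2, -np.inf
    for k in ks:
        prev = inertia[k - 1]
        gain = (prev - inertia[k]) / prev if prev > 0 else 0.0
        if gain > best_gain:
            best_k, best_gain = k, gain
    return best_k


def _relabel_by_size(raw: np.ndarray) -> np.ndarray:
    """Map raw labels to 0..k−1 by descending cluster size (ties: first seen)."""
    uniq, counts = np.unique(raw, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    mapping = {int(uniq[o]): rank for rank, o in enumerate(order)}
    return np.array([mapping[int(r)] for r in raw])


# ---------------------------------------------------------------------------
# Natal assignments and the precomputed score grid


@dataclass
class NatalAssignment:
    """One individual's natal habitat: composition, PC scores, cluster."""

    individual: str
    nest: tuple[float, float]
    habitat: HabitatVector
    scores: np.ndarray
    cluster: int = -1


def assign_natal_habitats(
    landscape: LandscapeRaster,
    nests: dict[str, tuple[float, float]],
    radius: float = DEFAULT_BUFFER_RADIUS,
    k: int | str = "auto",
    k_retained: int = 2,
) -> tuple[list[NatalAssignment], PCAModel]:
    """Full natal stage: buffers → PCA → clustering, in nest-id order."""
    ids = list(nests)
    vectors = [extract_buffer_composition(landscape, nests[i], radius) for i in ids]
    pca = fit_natal_pca(vectors, k_retained=k_retained)
    scores = np.array([pca.project(v) for v in vectors])
    labels, _ = cluster_natal_habitats(scores, k=k)
    return (
        [
            NatalAssignment(i, nests[i], v, s, int(lab))
            for i, v, s, lab in zip(ids, vectors, scores, labels)
        ],
        pca,
    )


@dataclass
class ScoreGrid:
    """Per-cell PC scores of the buffer composition at each cell centre.

    Precomputing the buffered composition for every cell centre (by
    convolving the class-indicator and elevation grids with a disc
    kernel) makes step-covariate extraction O(1) per location: a step
    end-location takes the scores of the cell containing it.  Values
    agree exactly with :func:`extract_buffer_composition` evaluated at
    the cell centre.
    """

    landscape: LandscapeRaster
    pc1: np.ndarray
    pc2: np.ndarray

    def scores_at(self, x, y) -> np.ndarray:
        """``(n, 2)`` PC scores of the cells containing the points."""
        row, col = self.landscape.cell_index(x, y)
        return np.stack([self.pc1[row, col], self.pc2[row, col]], axis=-1)


def compute_score_grid(
    landscape: LandscapeRaster, pca: PCAModel, radius: float = DEFAULT_BUFFER_RADIUS
) -> ScoreGrid:
    """Convolve the landscape with a disc kernel and project every cell."""
    cs = landscape.cell_size
    r_cells = int(np.floor(radius / cs))
    d = np.arange(-r_cells, r_cells + 1)
    dj, di = np.meshgrid(d, d)
    kernel = ((di * cs) ** 2 + (dj * cs) ** 2 <= radius**2).astype(float)

    def conv(grid: np.ndarray) -> np.ndarray:
        return oaconvolve(grid, kernel, mode="same")

    count = conv(np.ones_like(landscape.elevation))
    layers = {"elevation": conv(landscape.elevation) / count}
    for code, cls in enumerate(LAND_COVER_CLASSES):
        layers[f"prop_{cls}"] = conv((landscape.land_cover == code).astype(float)) / count
    X = np.stack([layers[n] for n in pca.variable_names], axis=-1)
    flat = X.reshape(-1, X.shape[-1])
    scores = ((flat - pca.means) / pca.sds) @ pca.loadings[:, :2]
    shape = landscape.elevation.shape
    return ScoreGrid(
        landscape=landscape,
        pc1=scores[:, 0].reshape(shape),
        pc2=scores[:, 1].reshape(shape),
    )
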