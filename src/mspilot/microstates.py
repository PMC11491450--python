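"""Microstate map fitting: GFP, peak selection, and the modified k-means.

The fit operates on the scalp topographies at GFP peaks only (moments of
maximal topographic signal-to-noise).  The modified k-means is polarity
invariant: a sample is assigned to the class whose unit-norm map Γ_k
maximises the squared projection (Γ_k·V_t)², and each map is updated as
the first principal eigenvector of its assigned samples' scatter matrix,
which minimises the residual cost

    F = (1/(N_T (N_S - 1))) Σ_t || V_t − a_kt Γ_k ||²,   a_kt = Γ_k·V_t

under the unit-norm constraint.  Model order is scored by the predictive
cross-validation criterion

    CV = F · ((N_S − 1)/(N_S − 1 − N_K))²

and the best of ``n_init`` random restarts (lowest CV) is returned.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .recording import Recording, spatial_correlation

logger = logging.getLogger(__name__)

__all__ = [
    "GfpSeries",
    "MicrostateSolution",
    "compute_gfp",
    "find_gfp_peaks",
    "modified_kmeans",
    "cross_validation",
    "global_explained_variance",
]


@dataclass
class GfpSeries:
    """Global Field Power: the spatial SD of the potential at each sample."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("GFP is non-negative by definition")


@dataclass
class MicrostateSolution:
    """Result of one modified k-means fit on GFP-peak topographies."""

    maps: np.ndarray  # (K, n_channels), unit-norm rows
    assignments: np.ndarray  # (n_peaks,) class index per peak sample
    intensities: np.ndarray  # (n_peaks,) a_kt of the assigned class, µV
    cost_f: float  # residual cost, µV²
    cv: float  # cross-validation criterion, µV²
    gev: float  # global explained variance, fraction
    n_init: int
    seed: int

    @property
    def n_classes(self) -> int:
        return self.maps.shape[0]


def compute_gfp(rec: Recording) -> GfpSeries:
    """GFP(t) = standard deviation across channels of the potentials at t."""
    return GfpSeries(values=rec.data.std(axis=0, ddof=0), fs=rec.fs)


def find_gfp_peaks(gfp: GfpSeries, min_distance_ms: float = 10.0) -> np.ndarray:
    """Indices of strict local GFP maxima at least ``min_distance_ms`` apart.

    Plateaus contribute their centre sample once.  Raises if the series
    has no interior local maximum (e.g. strictly monotone input).
    """
    v = gfp.values
    if v.size < 3:
        raise ValueError("need at least 3 samples to find peaks")
    distance = max(int(round(min_distance_ms / 1000.0 * gfp.fs)), 1)
    peaks, props = find_peaks(v, distance=distance, plateau_size=1)
    if peaks.size == 0:
        raise ValueError("no GFP peaks found (degenerate input)")
    # centre of each plateau rather than its left edge
    centres = (props["left_edges"] + props["right_edges"]) // 2
    return centres.astype(int)


def _assign(maps: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Polarity-ignoring winner-take-all assignment.

    Ties go to the lowest class index (np.argmax convention), which keeps
    replays deterministic.
    """
    proj = X @ maps.T  # (n, K)
    assign = np.argmax(proj**2, axis=1)
    a = proj[np.arange(X.shape[0]), assign]
    return assign, a


def _cost_f(X: np.ndarray, a: np.ndarray, n_channels: int) -> float:
    # ||V_t - a Γ||² = V·V − a² for unit-norm Γ with a = Γ·V
    resid = np.sum(X**2) - np.sum(a**2)
    return float(resid / (X.shape[0] * (n_channels - 1)))


def modified_kmeans(
    peak_maps: np.ndarray,
    n_classes: int,
    n_init: int = 100,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
) -> MicrostateSolution:
    """Fit K microstate maps to GFP-peak topographies.

    Parameters
    ----------
    peak_maps : ndarray, shape (n_peaks, n_channels)
        Topographies at GFP peaks (µV).
    n_classes : int
        Number of microstate classes K.
    n_init : int
        Random restarts; the restart with the lowest CV wins.
    max_iter, tol : int, float
        Per-restart convergence: stop when the relative change of the cost
        falls below ``tol`` or after ``max_iter`` iterations (with a
        logged warning).
    seed : int
        Master seed; restart r uses ``default_rng([seed, r])``.
    """
    X = np.asarray(peak_maps, dtype=float)
    n, n_ch = X.shape
    if n <= n_classes:
        raise ValueError("need more peak samples than classes")
    if n_ch <= n_classes + 1:
        raise ValueError("need n_channels > n_classes + 1 for the CV criterion")

    best: MicrostateSolution | None = None
    for r in range(n_init):
        rng = np.random.default_rng([seed, r])
        idx = rng.choice(n, size=n_classes, replace=False)
        maps = X[idx].copy()
        norms = np.linalg.norm(maps, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        maps /= norms

        prev_cost = np.inf
        for it in range(max_iter):
            assign, a = _assign(maps, X)
            for k in range(n_classes):
                members = X[assign == k]
                if members.shape[0] == 0:
                    # empty cluster: re-seed from a random sample
                    cand = X[int(rng.integers(n))]
                    nrm = np.linalg.norm(cand)
                    maps[k] = cand / nrm if nrm > 0 else maps[k]
                    continue
                # principal eigenvector of the member scatter matrix
                scatter = members.T @ members
                _, vecs = np.linalg.eigh(scatter)
                maps[k] = vecs[:, -1]
            assign, a = _assign(maps, X)
            cost = _cost_f(X, a, n_ch)
            if np.isfinite(prev_cost) and prev_cost - cost <= tol * max(prev_cost, 1e-300):
                break
            prev_cost = cost
        else:
            logger.warning(
                "modified k-means restart %d did not converge in %d iterations",
                r,
                max_iter,
            )

        sol = MicrostateSolution(
            maps=maps.copy(),
            assignments=assign,
            intensities=a,
            cost_f=cost,
            cv=float("nan"),
            gev=float("nan"),
            n_init=n_init,
            seed=seed,
        )
        sol.cv = cross_validation(sol, X)
        if best is None or sol.cv < best.cv:
            best = sol

    assert best is not None
    best.gev = global_explained_variance(best, X)
    return best


def cross_validation(solution: MicrostateSolution, peak_maps: np.ndarray) -> float:
    """Predictive cross-validation criterion of a fitted solution.

    CV = [Σ_t (V_t·V_t − (V_t·Γ_{k(t)})²)] / (N_T (N_S−1)) ·
         ((N_S−1)/(N_S−1−N_K))²

    with k(t) the class assigned to sample t.  Ill-posed when
    N_K >= N_S − 1.
    """
    X = np.asarray(peak_maps, dtype=float)
    n, n_ch = X.shape
    n_k = solution.n_classes
    if n_k >= n_ch - 1:
        raise ValueError("CV requires n_classes < n_channels - 1")
    gamma = solution.maps[solution.assignments]  # (n, n_ch)
    proj = np.einsum("ij,ij->i", X, gamma)
    resid = np.sum(X**2) - np.sum(proj**2)
    sigma2 = resid / (n * (n_ch - 1))
    return float(sigma2 * ((n_ch - 1) / (n_ch - 1 - n_k)) ** 2)


def global_explained_variance(
    solution: MicrostateSolution, peak_maps: np.ndarray
) -> float:
    """GFP²-weighted mean squared spatial correlation with the winning map.

    GEV = Σ_t GFP(t)² corr(V_t, Γ_{k(t)})² / Σ_t GFP(t)²
    """
    X = np.asarray(peak_maps, dtype=float)
    gfp = X.std(axis=1, ddof=0)
    denom = float(np.sum(gfp**2))
    if denom == 0:
        raise ValueError("zero total GFP: GEV undefined")
    gamma = solution.maps[solution.assignments]
    Xc = X - X.mean(axis=1, keepdims=True)
    Gc = gamma - gamma.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", Xc, Gc)
    nx = np.linalg.norm(Xc, axis=1)
    ng = np.linalg.norm(Gc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where((nx > 0) & (ng > 0), num / (nx * ng), 0.0)
    return float(np.sum(gfp**2 * corr**2) / denom)
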