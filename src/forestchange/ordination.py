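"""Ordination: NMDS of pooled pre-colonial + modern compositions on Sørensen
distances of Wisconsin-standardized abundances, with environmental vector
fitting and an era-separation readout.

The embedding is found by SMACOF with isotonic (monotone, ties-averaged)
regression of configuration distances on dissimilarities (scikit-learn's
non-metric MDS), best of ``n_starts`` random starts. Goodness of fit is
Kruskal stress-1,

    stress = sqrt( Σ (d_ij − d̂_ij)² / Σ d_ij² ),

recomputed here from the final configuration so values are comparable
across dimensionalities. Coordinates are centered and rotated onto their
principal components so axis 1 carries maximal variance; half-change
scaling (a presentation-only rescaling) is not applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof
from scipy.spatial.distance import pdist

from .datamodel import DataError
from .spatial import DistanceMatrix

logger = logging.getLogger(__name__)


def wisconsin(matrix: np.ndarray) -> np.ndarray:
    """Wisconsin double standardization: columns divided by their maxima,
    then rows by their sums. All-zero columns are dropped with a warning."""
    m = np.asarray(matrix, dtype=float)
    if np.any(m < 0):
        raise DataError("Wisconsin standardization needs nonnegative input")
    col_max = m.max(axis=0)
    dead = col_max == 0
    if dead.any():
        logger.warning("wisconsin: dropping %d all-zero columns", int(dead.sum()))
        m = m[:, ~dead]
        col_max = col_max[~dead]
    m = m / col_max
    row_sum = m.sum(axis=1, keepdims=True)
    if np.any(row_sum == 0):
        raise DataError("Wisconsin standardization hit an all-zero row")
    return m / row_sum


def kruskal_stress(dissim_tri: np.ndarray, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against dissimilarities, with
    disparities from ties-averaged isotonic regression."""
    d = pdist(coords)
    iso = IsotonicRegression(increasing=True)
    dhat = iso.fit_transform(dissim_tri, d)
    denom = float((d ** 2).sum())
    if denom == 0:
        return 1.0
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _pc_rotate(coords: np.ndarray) -> np.ndarray:
    """Center and rotate so axis 1 has maximal variance (PC rotation)."""
    x = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    return x @ vt.T


@dataclass
class OrdinationResult:
    ids: list[str]
    coords: np.ndarray          # (n, k), centered and PC-rotated
    stress: float               # Kruskal stress-1 in [0, 1]
    k: int
    n_starts: int
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        cols = {f"axis{a + 1}": self.coords[:, a] for a in range(self.k)}
        return pd.DataFrame({"id": self.ids, **cols})


def nmds(dist: DistanceMatrix, k: int = 2, n_starts: int = 50,
         max_iter: int = 500, tol: float = 1e-9,
         seed: int = 0) -> OrdinationResult:
    """Non-metric multidimensional scaling of a distance matrix.

    Best of ``n_starts`` random configurations is retained; the reported
    stress is Kruskal stress-1 of the final (rotated) configuration.
    """
    n = len(dist.ids)
    if n < k + 2:
        raise DataError(f"NMDS with k={k} needs at least {k + 2} points")
    tri = dist.triangle()
    if np.allclose(tri, tri[0]):
        raise DataError("all dissimilarities equal; NMDS undefined")
    coords, _, n_iter = smacof(
        dist.values, metric=False, n_components=k, n_init=n_starts,
        max_iter=max_iter, eps=tol,
        random_state=np.random.RandomState(seed),
        return_n_iter=True, normalized_stress=True)
    converged = bool(n_iter < max_iter)
    if not converged:
        logger.warning("NMDS hit the iteration cap; best iterate returned")
    coords = _pc_rotate(coords)
    stress = kruskal_stress(tri, coords)
    return OrdinationResult(ids=list(dist.ids), coords=coords, stress=stress,
                            k=k, n_starts=n_starts, converged=converged)


@dataclass
class EnvFitResult:
    table: pd.DataFrame   # covariate, r2, p, direction_axis1..k


def envfit(result: OrdinationResult, covariates: pd.DataFrame,
           n_perm: int = 999, seed: int = 0) -> EnvFitResult:
    """Fit environmental vectors onto ordination axes.

    Each covariate is regressed on the axis scores; the direction cosines
    are the unit-norm coefficient vector, R² the variance explained, and p
    comes from permuting the covariate over rows. Constant covariates are
    skipped."""
    rng = np.random.default_rng(seed)
    X = result.coords
    Xc = X - X.mean(axis=0)
    rows = []
    for cov in covariates.columns:
        y = covariates[cov].to_numpy(dtype=float)
        if np.allclose(y, y[0]) or np.isnan(y).any():
            logger.warning("envfit: covariate %s constant or missing; skipped", cov)
            continue
        yc = y - y.mean()

        def r2_of(yv: np.ndarray) -> tuple[float, np.ndarray]:
            beta, *_ = np.linalg.lstsq(Xc, yv, rcond=None)
            fitted = Xc @ beta
            tot = float(yv @ yv)
            return (float(fitted @ fitted) / tot if tot > 0 else 0.0), beta

        r2, beta = r2_of(yc)
        null = np.empty(n_perm)
        for r in range(n_perm):
            null[r], _ = r2_of(yc[rng.permutation(len(yc))])
        p = (1 + int((null >= r2 - 1e-15).sum())) / (1 + n_perm)
        norm = np.linalg.norm(beta)
        direction = beta / norm if norm > 0 else beta
        row = {"covariate": cov, "r2": r2, "p": p}
        row.update({f"direction_axis{a + 1}": direction[a]
                    for a in range(result.k)})
        rows.append(row)
    return EnvFitResult(table=pd.DataFrame(rows))


@dataclass
class EraSeparation:
    axis: int                  # 1-based index of the separating axis
    frac_pre_below: float      # pre-colonial rows with score < 0
    frac_mod_above: float      # modern rows with score > 0


def era_axis_separation(result: OrdinationResult,
                        eras: np.ndarray) -> EraSeparation:
    """Era separation on the data-chosen axis.

    The separating axis maximizes the standardized between-era mean
    difference; its sign is fixed so the pre-colonial mean is negative.
    Returns the fractions of pre-colonial scores below zero and modern
    scores above zero on that axis.
    """
    eras = np.asarray(eras)
    pre = eras == "precolonial"
    mod = eras == "modern"
    if not pre.any() or not mod.any():
        raise DataError("need rows from both eras")
    X = result.coords - result.coords.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    sep = np.abs(X[pre].mean(axis=0) - X[mod].mean(axis=0)) / sd
    ax = int(np.argmax(sep))
    scores = X[:, ax].copy()
    if scores[pre].mean() > 0:
        scores = -scores
    return EraSeparation(
        axis=ax + 1,
        frac_pre_below=float((scores[pre] < 0).mean()),
        frac_mod_above=float((scores[mod] > 0).mean()),
    )
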