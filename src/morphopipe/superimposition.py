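"""Generalized Procrustes Analysis (GPA) of 3D landmark configurations.

Superimposition removes translation, scale and rotation so that only shape
differences remain.  Each configuration is centered, scaled to unit centroid
size (full Procrustes fit) and rotated to the running consensus; the
consensus is the mean of the aligned shapes re-scaled to unit size, iterated
to convergence.  Reflections are never allowed (specimens share anatomical
handedness), so every rotation has determinant +1.

Shapes may optionally be projected orthogonally onto the tangent space at
the consensus (on by default), the linearization under which ordinary
multivariate statistics are valid.  Centroid sizes are recorded from the raw
configurations and log-transformed for use as the allometry covariate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .landmark_io import LandmarkDataset

__all__ = [
    "AlignedDataset",
    "OutlierReport",
    "LandmarkVariabilityReport",
    "centroid_size",
    "opa_align",
    "gpa",
    "procrustes_distance",
    "flag_specimen_outliers",
    "landmark_variability",
]


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark deviations from the centroid.

    The standard geometric size measure; scale-equivariant
    (``centroid_size(c*X) == c*centroid_size(X)``).  Returns 0 for a fully
    degenerate (all-coincident) configuration — callers must reject such
    configurations before GPA.
    """
    config = np.asarray(config, dtype=float)
    centered = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def opa_align(
    source: np.ndarray, target: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Ordinary (pairwise) Procrustes alignment of ``source`` onto ``target``.

    Returns ``(rotation, scale, residual)`` minimizing
    ``|| scale * centered(source) @ rotation - centered(target) ||`` over
    proper rotations (det +1; reflections blocked by sign-correcting the
    smallest singular value).  ``residual`` is the minimized root summed
    squared difference.

    When the smallest singular value of the cross-covariance is numerically
    zero the optimum rotation is not unique; a deterministic tie-break
    (trace-maximizing sign choice on the SVD factors as returned) is applied
    and a warning emitted.
    """
    X = np.asarray(source, float)
    Y = np.asarray(target, float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {Y.shape}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    M = Xc.T @ Yc
    U, s, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    if s[-1] <= 1e-12 * max(s[0], 1.0):
        warnings.warn(
            "rank-deficient cross-covariance: rotation not unique, "
            "using deterministic trace-maximizing tie-break",
            RuntimeWarning,
            stacklevel=2,
        )
    sign = np.ones(3)
    sign[-1] = d if d != 0 else 1.0
    R = U @ np.diag(sign) @ Vt
    traced = float(np.sum(s[:-1]) + sign[-1] * s[-1])
    scale = traced / float(np.sum(Xc**2))
    # explicit evaluation (the closed form ||Y||^2 - tr^2/||X||^2 cancels
    # catastrophically for near-perfect fits)
    residual = float(np.linalg.norm(scale * (Xc @ R) - Yc))
    return R, scale, residual


@dataclass
class AlignedDataset:
    """GPA output: superimposed shapes plus size and convergence metadata.

    ``shapes`` are dimensionless (unit centroid size before optional tangent
    projection); ``centroid_sizes`` keep the original length units and
    ``log_centroid_sizes`` their natural logs.  ``consensus`` is the mean
    aligned shape re-scaled to unit centroid size.
    """

    shapes: np.ndarray  # (n, p, 3)
    centroid_sizes: np.ndarray  # (n,)
    log_centroid_sizes: np.ndarray  # (n,)
    consensus: np.ndarray  # (p, 3)
    iterations: int
    converged: bool
    tangent_projected: bool
    specimen_ids: list[str]
    landmark_labels: list[str]
    factors: pd.DataFrame | None = None

    @property
    def n_specimens(self) -> int:
        return self.shapes.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.shapes.shape[1]

    def flat(self) -> np.ndarray:
        """Shapes vectorized to (n, 3p) for multivariate statistics."""
        return self.shapes.reshape(self.n_specimens, -1)


def gpa(
    ds: LandmarkDataset,
    tol: float = 1e-8,
    max_iter: int = 100,
    tangent: bool = True,
) -> AlignedDataset:
    """Generalized Procrustes superimposition of all configurations.

    Iterates rotation-to-consensus / consensus-update until the summed
    squared change in consensus coordinates drops below ``tol``.
    Non-convergence within ``max_iter`` is flagged on the result, not raised.
    """
    n = ds.n_specimens
    if n < 2:
        raise ValueError("GPA needs at least 2 specimens")
    sizes = np.array([centroid_size(c) for c in ds.coords])
    if np.any(sizes <= 0):
        bad = [ds.specimen_ids[i] for i in np.flatnonzero(sizes <= 0)]
        raise ValueError(f"degenerate (zero-size) configurations: {bad}")
    X = ds.coords - ds.coords.mean(axis=1, keepdims=True)
    X = X / sizes[:, None, None]

    consensus = X[0].copy()
    iterations = 0
    converged = False
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            R, _, _ = opa_align(X[i], consensus)
            X[i] = X[i] @ R
        new_consensus = X.mean(axis=0)
        new_consensus = new_consensus / centroid_size(new_consensus)
        delta = float(np.sum((new_consensus - consensus) ** 2))
        consensus = new_consensus
        if delta < tol:
            converged = True
            break

    # canonical orientation: principal axes of the consensus, with a
    # deterministic sign convention, so the aligned frame does not depend on
    # the (arbitrary) orientation of the first configuration
    _, _, Vt = np.linalg.svd(consensus, full_matrices=False)
    R_can = Vt.T
    # sign convention on the rotated consensus (frame-invariant): the
    # largest-|coordinate| landmark on each of the first two principal axes
    # is positive; the third axis sign then follows from det(+1)
    C = consensus @ R_can
    for j in range(2):
        if C[np.argmax(np.abs(C[:, j])), j] < 0:
            R_can[:, j] = -R_can[:, j]
    if np.linalg.det(R_can) < 0:
        R_can[:, 2] = -R_can[:, 2]
    consensus = consensus @ R_can
    X = X @ R_can

    if tangent:
        c = consensus.reshape(-1)
        c = c / np.linalg.norm(c)
        V = X.reshape(n, -1)
        # orthogonal projection onto the tangent plane {y : y.c = |c|} at c
        V = V + np.outer(1.0 - V @ c, c)
        X = V.reshape(n, -1, 3)

    return AlignedDataset(
        shapes=X,
        centroid_sizes=sizes,
        log_centroid_sizes=np.log(sizes),
        consensus=consensus,
        iterations=iterations,
        converged=converged,
        tangent_projected=tangent,
        specimen_ids=list(ds.specimen_ids),
        landmark_labels=list(ds.landmark_labels),
        factors=ds.factors.copy() if ds.factors is not None else None,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean norm of the coordinate-wise difference of two aligned shapes.

    The tangent-space (small-variation) approximation to the shape-space
    geodesic; a metric on any aligned dataset.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


@dataclass
class OutlierReport:
    """Per-specimen Procrustes distances to the consensus plus flag sets.

    ``above_q3`` is the literal screening rule (distance above the upper
    quartile); ``extreme`` the conservative Q3 + 1.5*IQR rule.  The extreme
    set is always nested inside the above-Q3 set.  Flagging never removes
    specimens.
    """

    distances: pd.Series  # index: specimen id
    q3: float
    iqr: float
    above_q3: list[str]
    extreme: list[str]


def flag_specimen_outliers(al: AlignedDataset) -> OutlierReport:
    """Screen specimens by Procrustes distance from the mean shape.

    Quartiles use the linear-interpolation convention (numpy default), on
    which the above-Q3 membership depends.
    """
    if al.n_specimens < 4:
        raise ValueError("outlier screening needs n >= 4")
    d = np.linalg.norm(al.flat() - al.consensus.reshape(-1), axis=1)
    dist = pd.Series(d, index=al.specimen_ids, name="procrustes_distance")
    q1, q3 = np.quantile(d, [0.25, 0.75])
    iqr = q3 - q1
    eps = 1e-9  # numerical-noise floor: exactly-equal distances never flag
    above = dist.index[d > q3 + eps].tolist()
    extreme = dist.index[d > q3 + 1.5 * iqr + eps].tolist()
    return OutlierReport(
        distances=dist, q3=float(q3), iqr=float(iqr), above_q3=above, extreme=extreme
    )


@dataclass
class LandmarkVariabilityReport:
    """Per-landmark variance totals across aligned specimens.

    ``variances`` sums the three coordinate variances per landmark; the sum
    over landmarks equals the total shape variance.  ``rank_order`` lists
    landmark labels from most to least variable — the screening signal that
    motivates removals like the pelvic-spine points.
    """

    variances: pd.Series  # index: landmark label
    rank_order: list[str]
    total_variance: float


def landmark_variability(al: AlignedDataset) -> LandmarkVariabilityReport:
    """Rank landmarks by positional variance in the aligned dataset."""
    if al.n_specimens < 3:
        raise ValueError("landmark variability needs n >= 3")
    per_coord = al.shapes.var(axis=0, ddof=1)  # (p, 3)
    per_lm = per_coord.sum(axis=1)
    s = pd.Series(per_lm, index=al.landmark_labels, name="variance")
    order = s.sort_values(ascending=False, kind="stable").index.tolist()
    return LandmarkVariabilityReport(
        variances=s, rank_order=order, total_variance=float(per_lm.sum())
    )
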