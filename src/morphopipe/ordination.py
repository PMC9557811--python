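"""PCA of aligned shapes and broken-stick component retention.

Shape PCA eigen-decomposes the covariance of the vectorized aligned
coordinates; the scores on the retained axes are the shape response used by
the permutation models.  Retention follows the broken-stick rule: a
component is kept while its eigenvalue exceeds the expected share of total
variance obtained by breaking a stick of length T at random into m pieces,

    b_k = (T / m) * sum_{i=k..m} 1 / i .

Components are retained as a contiguous prefix: retention stops at the
first component whose eigenvalue falls at or below its broken-stick
expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .superimposition import AlignedDataset

__all__ = ["PCAResult", "shape_pca", "broken_stick", "retain_components"]

# relative eigenvalue cutoff below which a component is treated as null space
_RANK_TOL = 1e-12


@dataclass
class PCAResult:
    """Eigen-structure of the aligned shape data.

    ``axes`` rows are orthonormal loading vectors of length 3p; ``scores``
    are projections of the centered data onto them.  ``percent_variance``
    sums to 100 over positive components.  ``retained`` is the broken-stick
    count k*.
    """

    eigenvalues: np.ndarray  # non-increasing, length n_components
    axes: np.ndarray  # (n_components, 3p)
    scores: np.ndarray  # (n, n_components)
    percent_variance: np.ndarray
    retained: int
    center: np.ndarray  # (3p,) mean of the vectorized shapes

    @property
    def total_variance(self) -> float:
        return float(self.eigenvalues.sum())

    @property
    def n_positive(self) -> int:
        total = self.eigenvalues.sum()
        return int(np.sum(self.eigenvalues > _RANK_TOL * max(total, 1.0)))

    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.retained]


def shape_pca(al: AlignedDataset, retention: str = "prefix") -> PCAResult:
    """Principal components analysis of an aligned dataset.

    Uses an SVD of the centered n x 3p coordinate matrix; eigenvalues are
    squared singular values over n−1, so their sum equals the total variance
    of the centered coordinates.  Axis signs follow a deterministic
    convention: the largest-magnitude loading of each axis is positive.
    Broken-stick retention is evaluated on the realized positive spectrum
    (GPA consumes 7 degrees of freedom in 3D, so the rank is at most
    min(n−1, 3p−7)).
    """
    n = al.n_specimens
    if n < 3:
        raise ValueError("shape PCA needs n >= 3")
    V = al.flat()
    center = V.mean(axis=0)
    C = V - center
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    eig = s**2 / (n - 1)
    # deterministic sign convention
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    axes = Vt * flip[:, None]
    scores = C @ axes.T
    total = float(eig.sum())
    pos = eig > _RANK_TOL * max(total, 1.0)
    pct = np.zeros_like(eig)
    if total > 0:
        pct[pos] = 100.0 * eig[pos] / eig[pos].sum()
    result = PCAResult(
        eigenvalues=eig,
        axes=axes,
        scores=scores,
        percent_variance=pct,
        retained=1,
        center=center,
    )
    result.retained = retain_components(result, rule=retention)
    return result


def broken_stick(eigenvalues: np.ndarray, m: int | None = None) -> np.ndarray:
    """Broken-stick expected eigenvalues, scaled to the total variance.

    ``m`` defaults to the count of positive (non-null) eigenvalues; the
    expectations are returned for components 1..m and satisfy
    ``sum(b) == sum(eigenvalues[:m considered total])`` and strict decrease.
    """
    eig = np.asarray(eigenvalues, dtype=float)
    total = float(eig.sum())
    if m is None:
        m = int(np.sum(eig > _RANK_TOL * max(total, 1.0)))
        m = max(m, 1)
    if m < 1:
        raise ValueError("m must be >= 1")
    inv = 1.0 / np.arange(1, m + 1)
    # b_k = (T/m) * sum_{i=k..m} 1/i  — cumulative tail of the harmonic series
    return (total / m) * np.cumsum(inv[::-1])[::-1]


def retain_components(pca: PCAResult, rule: str = "prefix") -> int:
    """Number of components to keep under the broken-stick criterion.

    ``prefix`` (default): largest k such that eigenvalue_j > b_j for every
    j <= k; stops at the first failure.  ``pointwise``: counts every
    component anywhere in the spectrum that exceeds its expectation.
    At least one component is always retained; if PC1 itself fails the
    criterion a warning is emitted.
    """
    eig = pca.eigenvalues
    m = pca.n_positive
    if m == 0:
        warnings.warn("degenerate spectrum: no positive eigenvalues", RuntimeWarning)
        return 1
    b = broken_stick(eig, m)
    exceeds = eig[:m] > b
    if rule == "pointwise":
        k = int(exceeds.sum())
    elif rule == "prefix":
        k = int(np.argmin(exceeds)) if not exceeds.all() else m
    else:
        raise ValueError(f"unknown retention rule {rule!r}")
    if k < 1:
        warnings.warn(
            "PC1 does not exceed its broken-stick expectation; retaining it anyway",
            RuntimeWarning,
        )
        k = 1
    return k
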