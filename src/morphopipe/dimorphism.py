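"""Index of sexual shape dimorphism.

The index scales the squared Procrustes distance between the two sex mean
shapes by the summed within-sex Procrustes variances,

    index = D^2 / (V_f + V_m),

where V_g is the mean squared Procrustes distance of group g's specimens
from their own mean shape (sample divisor n_g − 1).  Zero means no
differentiation; increasingly positive values mean stronger between-sex
shape differentiation relative to within-sex variation, so high within-sex
variance deflates the index even when the mean shapes are well separated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .superimposition import AlignedDataset, procrustes_distance

__all__ = [
    "DimorphismIndexResult",
    "group_procrustes_variance",
    "dimorphism_index",
    "index_from_summaries",
]


@dataclass
class DimorphismIndexResult:
    """One dimorphism-index computation (one table row).

    ``undefined_reason`` is set (and ``index`` is NaN) when both group
    variances are zero — the index has no value there, and infinity is
    never returned.
    """

    D: float  # Procrustes distance between group mean shapes
    V_f: float
    V_m: float
    n_f: int
    n_m: int
    index: float
    group_labels: tuple[str, str]
    undefined_reason: str | None = None

    def to_row(self) -> dict:
        return {
            "Index": self.index,
            "Female variance": self.V_f,
            "Male variance": self.V_m,
            "Procrustes distance": self.D,
            "n_female": self.n_f,
            "n_male": self.n_m,
        }


def group_procrustes_variance(
    al: AlignedDataset, labels, group, ddof: int = 1
) -> float:
    """Within-group Procrustes variance: mean squared distance to the group mean.

    ``labels`` is a per-specimen array of group assignments; ``group``
    selects the level.  ``ddof=1`` (default) gives the sample estimator
    sum d_i^2 / (n_g − 1); ``ddof=0`` the divisor-n variant.
    """
    labels = np.asarray([str(x) for x in labels])
    mask = labels == str(group)
    n_g = int(mask.sum())
    if n_g < 2:
        raise ValueError(f"group {group!r} has n={n_g} < 2")
    V = al.flat()[mask]
    mean_g = V.mean(axis=0)
    d2 = np.sum((V - mean_g) ** 2, axis=1)
    return float(d2.sum() / (n_g - ddof))


def dimorphism_index(
    al: AlignedDataset,
    labels=None,
    factor: str = "sex",
    ddof: int = 1,
) -> DimorphismIndexResult:
    """Sexual-dimorphism index for an aligned dataset.

    ``labels`` is a two-level per-specimen grouping; if omitted, the
    ``factor`` column of the attached factor table is used.  Levels are
    ordered alphabetically, so with F/M coding the first group is female.
    Both levels need n >= 2 and a positive summed variance.
    """
    if labels is None:
        if al.factors is None or factor not in al.factors.columns:
            raise KeyError(f"factor {factor!r} not present in aligned dataset")
        labels = al.factors[factor]
    labels = np.asarray([str(x) for x in labels])
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError(f"dimorphism index needs exactly 2 levels, got {levels}")
    g_f, g_m = levels
    V = al.flat()
    mask_f = labels == g_f
    mask_m = labels == g_m
    n_f, n_m = int(mask_f.sum()), int(mask_m.sum())
    if n_f < 2 or n_m < 2:
        raise ValueError(f"both groups need n >= 2; got {g_f}:{n_f}, {g_m}:{n_m}")
    mean_f = V[mask_f].mean(axis=0)
    mean_m = V[mask_m].mean(axis=0)
    D = procrustes_distance(mean_f, mean_m)
    V_f = group_procrustes_variance(al, labels, g_f, ddof=ddof)
    V_m = group_procrustes_variance(al, labels, g_m, ddof=ddof)
    if V_f + V_m <= 0:
        return DimorphismIndexResult(
            D=D, V_f=V_f, V_m=V_m, n_f=n_f, n_m=n_m, index=float("nan"),
            group_labels=(g_f, g_m),
            undefined_reason="zero within-group variance in both groups",
        )
    return DimorphismIndexResult(
        D=D, V_f=V_f, V_m=V_m, n_f=n_f, n_m=n_m,
        index=D**2 / (V_f + V_m), group_labels=(g_f, g_m),
    )


def index_from_summaries(D: float, v_f: float, v_m: float) -> float:
    """Dimorphism index from published summaries: D^2 / (v_f + v_m).

    Summary-level entry point for checking printed tables of distances and
    variances without the underlying coordinates.
    """
    if D < 0:
        raise ValueError("Procrustes distance must be >= 0")
    if v_f + v_m <= 0:
        raise ValueError("summed group variances must be positive")
    return float(D**2 / (v_f + v_m))


def dimorphism_table(results: dict[str, DimorphismIndexResult]) -> pd.DataFrame:
    """Assemble index rows (keyed by dataset/subset name) into one table."""
    return pd.DataFrame({k: r.to_row() for k, r in results.items()}).T
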