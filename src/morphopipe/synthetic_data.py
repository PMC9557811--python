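"""Synthetic 3D landmark data with known ground truth.

Generates raw landmark datasets with the statistical structure the pipeline
assumes: a deterministic template shape; additive group mean-shape offsets
for habitat, site-within-habitat, sex and a sex-by-habitat interaction along
fixed unit directions in shape space; an allometric shape direction tied to
log centroid size; per-coordinate Gaussian digitizing noise; and arbitrary
similarity transforms (uniform over proper rotations, translation in a box,
scale = exp of the drawn log size) applied to each raw configuration.

The default design reproduces the study's sampling: two habitats
(fresh, marine) with two sites each and the observed unbalanced
female/male counts per site (n = 179 in total), with landmark-count
presets of 70 (skull), 14 (pectoral girdle) and 16/18 (pelvic girdle).

Specimen generation order and the random draw order within each specimen
are fixed, so a (spec, seed) pair reproduces a dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .landmark_io import LandmarkDataset
from .superimposition import centroid_size

__all__ = [
    "SimulationSpec",
    "GroundTruth",
    "TABLE1_DESIGN",
    "make_template",
    "simulate_dataset",
    "recovery_report",
]

# (habitat, site, sex) -> n, the study's observed per-cell sample sizes
TABLE1_DESIGN: dict[tuple[str, str, str], int] = {
    ("fresh", "Hotel Lake", "F"): 9,
    ("fresh", "Hotel Lake", "M"): 37,
    ("fresh", "Klein Lake", "F"): 28,
    ("fresh", "Klein Lake", "M"): 16,
    ("marine", "Bargain Bay Lagoon", "F"): 14,
    ("marine", "Bargain Bay Lagoon", "M"): 26,
    ("marine", "Hospital Bay Lagoon", "F"): 23,
    ("marine", "Hospital Bay Lagoon", "M"): 26,
}

LANDMARK_PRESETS = {"skull": 70, "pectoral": 14, "pelvic": 16, "pelvic_raw": 18}


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    Effect magnitudes are Procrustes distances (shape units on a
    unit-centroid-size template) between the two levels of each contrast;
    ``noise_sd`` is the per-coordinate digitizing error, also in shape
    units.  ``allometry_slope`` is shape displacement per unit log centroid
    size.  Log centroid sizes are Gaussian per cell: ``logsize_base`` plus
    habitat/sex shifts, sd ``logsize_sd`` (sizes in mm via exp).  Nuisance
    similarity transforms are drawn per specimen: a uniform proper rotation,
    a translation uniform in ``[-translation_range, +translation_range]^3``
    and scale ``exp(logsize)``.
    """

    p: int = 16
    design: dict[tuple[str, str, str], int] = field(
        default_factory=lambda: dict(TABLE1_DESIGN)
    )
    template_kind: str = "helix"
    habitat_magnitude: float = 0.08
    site_magnitude: float = 0.03
    sex_magnitude: float = 0.035
    sex_habitat_magnitude: float = 0.0
    allometry_slope: float = 0.10
    logsize_base: float = 3.0  # ~20 mm centroid size
    logsize_habitat_shift: float = 0.15  # marine larger
    logsize_sex_shift: float = 0.05  # males larger
    logsize_sd: float = 0.12
    noise_sd: float = 0.01
    translation_range: float = 100.0
    orthogonalize_effects: bool = True
    seed: int = 0
    nuisance_seed: int | None = None  # separate stream for rotation/translation

    def __post_init__(self) -> None:
        if not self.design:
            raise ValueError("empty design: no cells to simulate")
        for key, n in self.design.items():
            if n < 0:
                raise ValueError(f"negative cell size for {key}")
        if sum(self.design.values()) < 1:
            raise ValueError("empty design: all cell sizes are zero")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for m in (
            self.habitat_magnitude,
            self.site_magnitude,
            self.sex_magnitude,
            self.sex_habitat_magnitude,
        ):
            if m < 0:
                raise ValueError("effect magnitudes must be >= 0")


@dataclass
class GroundTruth:
    """Everything needed to score pipeline recovery on a simulated dataset."""

    spec: SimulationSpec
    template: np.ndarray  # (p, 3) unit centroid size
    effect_vectors: dict[str, np.ndarray]  # unit vectors, (p, 3)
    true_shapes: np.ndarray  # (n, p, 3) pre-nuisance, pre... noise included
    true_logsizes: np.ndarray
    cells: pd.DataFrame  # specimen_id, habitat, site, sex

    def manifest(self) -> dict:
        spec_d = asdict(self.spec)
        spec_d["design"] = {"|".join(k): v for k, v in self.spec.design.items()}
        return {
            "spec": spec_d,
            "n": int(len(self.cells)),
            "cells": self.cells.to_dict(orient="list"),
            "true_logsizes": self.true_logsizes.tolist(),
        }


def make_template(p: int, kind: str = "helix") -> np.ndarray:
    """Deterministic non-degenerate template shape with unit centroid size.

    ``helix`` places points on two turns of a 3D helix (good landmark
    spread, affine rank 3); ``grid`` fills a near-cubic lattice; and
    ``jittered_sphere`` spreads points on a sphere via a Fibonacci lattice
    with a small deterministic radial jitter.
    """
    if p < 4:
        raise ValueError(f"template needs p >= 4, got {p}")
    if kind == "helix":
        t = np.linspace(0.0, 4.0 * np.pi, p)
        # tapered radius: distinct principal-axis spreads, so orientation
        # conventions downstream are well conditioned
        r = 1.0 + 0.35 * t / (4.0 * np.pi)
        pts = np.column_stack([r * np.cos(t), r * np.sin(t), t / (2.0 * np.pi)])
    elif kind == "grid":
        side = int(np.ceil(p ** (1.0 / 3.0)))
        axes_ = np.arange(side, dtype=float)
        grid = np.array(np.meshgrid(axes_, axes_, axes_)).reshape(3, -1).T
        # sample evenly through the lattice, with a small deterministic
        # symmetry-breaking offset so the selection always spans 3 axes
        idx = np.linspace(0, len(grid) - 1, p).round().astype(int)
        k = np.arange(p, dtype=float)[:, None] * np.array([1.0, 2.0, 3.0])
        pts = grid[idx] + 0.1 * np.sin(k + np.array([0.0, 1.0, 2.0]))
    elif kind == "jittered_sphere":
        k = np.arange(p, dtype=float)
        phi = np.arccos(1.0 - 2.0 * (k + 0.5) / p)
        theta = np.pi * (1.0 + 5.0**0.5) * k
        r = 1.0 + 0.05 * np.sin(7.0 * k)  # deterministic jitter
        pts = np.column_stack(
            [r * np.sin(phi) * np.cos(theta), r * np.sin(phi) * np.sin(theta),
             r * np.cos(phi)]
        )
    else:
        raise ValueError(f"unknown template kind {kind!r}")
    pts = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(pts, tol=1e-9) < 3:
        raise ValueError(f"template ({p}, {kind}) is degenerate")
    return pts / centroid_size(pts)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation: QR of a Gaussian matrix with sign fixes."""
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q @ np.diag(np.sign(np.diag(R)))
    if np.linalg.det(Q) < 0:
        Q[:, -1] = -Q[:, -1]
    return Q


def _effect_directions(spec: SimulationSpec, rng: np.random.Generator,
                       template: np.ndarray) -> dict[str, np.ndarray]:
    """Unit shape-space directions for each contrast, centered per landmark set.

    Directions are drawn Gaussian, centered (no net translation), and — by
    default — orthogonalized against the template (pure shape, not scale)
    and against each other, so injected effects decompose additively.
    """
    names = ["habitat", "site_fresh", "site_marine", "sex", "sex_habitat",
             "allometry"]
    basis: list[np.ndarray] = [template.reshape(-1) / np.linalg.norm(template)]
    out: dict[str, np.ndarray] = {}
    p = spec.p
    for name in names:
        v = rng.standard_normal((p, 3))
        v = v - v.mean(axis=0)
        vec = v.reshape(-1)
        if spec.orthogonalize_effects:
            for b in basis:
                vec = vec - (vec @ b) * b
        vec = vec / np.linalg.norm(vec)
        basis.append(vec)
        out[name] = vec.reshape(p, 3)
    return out


def simulate_dataset(spec: SimulationSpec) -> tuple[LandmarkDataset, GroundTruth]:
    """Simulate a raw landmark dataset plus its ground truth.

    Per specimen i in cell (habitat, site, sex):

    * ``logCS_i ~ N(cell mean, logsize_sd)``;
    * true shape = template + habitat/site/sex/interaction offsets +
      ``allometry_slope * (logCS_i − design mean logCS) *`` allometric
      direction + iid ``N(0, noise_sd^2)`` per coordinate;
    * raw configuration = ``exp(logCS_i) * shape_i @ R_i + t_i`` with
      ``R_i`` uniform proper rotation, ``t_i`` uniform in the translation
      box.

    The per-cell generation order is the sorted design; draw order within
    each specimen is logsize, noise, rotation, translation.  When
    ``nuisance_seed`` is set, rotations and translations come from their own
    stream, so nuisance transforms can be re-drawn while holding shapes and
    sizes fixed (the pipeline must be immune to that re-draw).
    """
    rng = np.random.default_rng(spec.seed)
    nuis_rng = (
        rng if spec.nuisance_seed is None
        else np.random.default_rng(spec.nuisance_seed)
    )
    template = make_template(spec.p, spec.template_kind)
    eff = _effect_directions(spec, rng, template)

    cells = sorted(spec.design.items())
    # design-mean log size for centering the allometric term
    cell_means = {}
    for (hab, site, sex), n in cells:
        mu = spec.logsize_base
        if hab == "marine":
            mu += spec.logsize_habitat_shift
        if sex == "M":
            mu += spec.logsize_sex_shift
        cell_means[(hab, site, sex)] = mu
    total_n = sum(n for _, n in cells)
    grand_mu = sum(cell_means[k] * n for k, n in cells) / total_n

    sites_by_hab: dict[str, list[str]] = {}
    for (hab, site, _), _n in cells:
        sites_by_hab.setdefault(hab, [])
        if site not in sites_by_hab[hab]:
            sites_by_hab[hab].append(site)

    ids, raw, shapes, logsizes, rows = [], [], [], [], []
    i = 0
    for (hab, site, sex), n in cells:
        for _ in range(n):
            i += 1
            sid = f"spec{i:03d}"
            logcs = cell_means[(hab, site, sex)] + spec.logsize_sd * rng.standard_normal()
            shape = template.copy()
            if hab == "marine":
                shape = shape + spec.habitat_magnitude * eff["habitat"]
            site_vec = eff["site_fresh"] if hab == "fresh" else eff["site_marine"]
            if site == sites_by_hab[hab][-1] and len(sites_by_hab[hab]) > 1:
                shape = shape + spec.site_magnitude * site_vec
            if sex == "M":
                shape = shape + spec.sex_magnitude * eff["sex"]
                if hab == "marine":
                    shape = shape + spec.sex_habitat_magnitude * eff["sex_habitat"]
            shape = shape + spec.allometry_slope * (logcs - grand_mu) * eff["allometry"]
            shape = shape + spec.noise_sd * rng.standard_normal((spec.p, 3))
            R = _random_rotation(nuis_rng)
            t = nuis_rng.uniform(
                -spec.translation_range, spec.translation_range, size=3
            )
            cfg = np.exp(logcs) * (shape @ R.T) + t
            ids.append(sid)
            raw.append(cfg)
            shapes.append(shape)
            logsizes.append(logcs)
            rows.append({"specimen_id": sid, "sex": sex, "habitat": hab,
                         "site": site})

    factors = pd.DataFrame(rows).set_index("specimen_id")
    ds = LandmarkDataset(
        specimen_ids=ids,
        coords=np.stack(raw),
        factors=factors,
        provenance=[f"simulated (seed={spec.seed}, p={spec.p})"],
    )
    truth = GroundTruth(
        spec=spec,
        template=template,
        effect_vectors=eff,
        true_shapes=np.stack(shapes),
        true_logsizes=np.array(logsizes),
        cells=factors.reset_index(),
    )
    return ds, truth


def recovery_report(truth: GroundTruth, anova_table=None, index_result=None,
                    pca_result=None, alpha: float = 0.05) -> dict:
    """Score pipeline outputs against the simulation's ground truth.

    Reports, for whichever outputs are supplied: which injected terms were
    detected at ``alpha`` (and whether the detection matches a nonzero
    injected magnitude), the dimorphism index next to the injected sex
    magnitude, and the retained-PC count next to the number of injected
    structural directions.
    """
    spec = truth.spec
    injected = {
        "logsize": spec.allometry_slope,
        "habitat": spec.habitat_magnitude,
        "site": spec.site_magnitude,
        "sex": spec.sex_magnitude,
        "sex:habitat": spec.sex_habitat_magnitude,
    }
    report: dict = {"injected_magnitudes": injected}
    if anova_table is not None:
        detected = {}
        for term in anova_table.table.index:
            if term in ("Residuals", "Total"):
                continue
            p = anova_table.term_p(term)
            key = term if term in injected else term.replace("site", "site")
            detected[term] = {
                "p": p,
                "significant": bool(p < alpha),
                "injected": injected.get(key),
                "Rsq": anova_table.term_rsq(term),
            }
        report["terms"] = detected
    if index_result is not None:
        report["dimorphism"] = {
            "index": index_result.index,
            "injected_sex_magnitude": spec.sex_magnitude,
        }
    if pca_result is not None:
        n_structural = sum(
            1 for k, v in injected.items() if v > 0
        )
        report["ordination"] = {
            "retained": int(pca_result.retained),
            "injected_structural_directions": n_structural,
        }
    return report
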