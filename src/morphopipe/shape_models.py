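"""Permutation linear models for shape: RRPP with Type III sums of squares.

Shape (retained PC scores, or full Procrustes coordinates behind a flag) is
modeled against a size covariate (log centroid size) and categorical factors
(sex, habitat, site) with interactions.  Inference is by randomization of
residuals in a permutation procedure (RRPP): for each term, the residual
rows of the reduced model lacking that term are shuffled and added back to
the reduced-model fitted values, the statistic is recomputed, and the
p-value is the fraction of the permutation distribution at or above the
observed value.

Sums of squares are Type III: each term is assessed by the increase in the
residual cross-product trace when that term alone is deleted from the full
model,

    SS_term = tr(E_reduced) − tr(E_full),
    F       = (SS_term / df_term) / (SS_resid / df_resid),

which accommodates responses with more variables than observations.  The
effect size Z locates ln F_obs within the permutation distribution of ln F.

The formula mini-language is ``shape ~ logsize + sex + habitat +
sex:habitat`` — terms separated by ``+``, interactions by ``:``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd

from .landmark_io import LandmarkDataset
from .ordination import shape_pca
from .superimposition import gpa

__all__ = [
    "ModelFormula",
    "PermutationSpec",
    "ShapeAnovaTable",
    "parse_formula",
    "build_design",
    "fit_shape_model",
    "compare_models",
    "subset_reanalysis",
]

ANOVA_COLUMNS = ["df", "SS", "MS", "Rsq", "F", "Z", "p"]


@dataclass(frozen=True)
class ModelFormula:
    """Ordered model terms for a shape response.

    ``terms`` holds main effects and interactions in model order; an
    interaction is written ``a:b`` (or ``a:b:c``) and sorted tuples of its
    constituents are kept for nesting checks.
    """

    terms: tuple[str, ...]
    response: str = "shape"

    def term_components(self, term: str) -> tuple[str, ...]:
        return tuple(term.split(":"))

    def is_nested_in(self, other: "ModelFormula") -> bool:
        mine = {tuple(sorted(t.split(":"))) for t in self.terms}
        theirs = {tuple(sorted(t.split(":"))) for t in other.terms}
        return mine <= theirs

    def __str__(self) -> str:
        return f"{self.response} ~ " + " + ".join(self.terms)


def parse_formula(formula: str) -> ModelFormula:
    """Parse ``shape ~ logsize + sex + habitat + sex:habitat``."""
    if "~" not in formula:
        raise ValueError(f"formula needs '~': {formula!r}")
    lhs, rhs = formula.split("~", 1)
    terms = tuple(t.strip() for t in rhs.split("+") if t.strip())
    if len(set(terms)) != len(terms):
        raise ValueError(f"duplicate terms in formula: {formula!r}")
    return ModelFormula(terms=terms, response=lhs.strip() or "shape")


@dataclass(frozen=True)
class PermutationSpec:
    """Permutation schedule: count (study default 10,000), seed, statistic."""

    n_perm: int = 10_000
    seed: int = 0
    statistic: str = "F"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.statistic != "F":
            raise ValueError("only the F statistic is supported")


@dataclass
class DesignInfo:
    """Full design matrix plus the per-term reduced designs (Type III)."""

    full: pd.DataFrame  # n x k, includes intercept
    term_columns: dict[str, list[str]]  # term -> its columns in `full`
    formula: ModelFormula

    def reduced(self, term: str) -> pd.DataFrame:
        drop = self.term_columns[term]
        return self.full.drop(columns=drop)


def _encode_factor(series: pd.Series, name: str) -> pd.DataFrame:
    levels = sorted(pd.unique(series.astype(str)))
    if len(levels) < 2:
        raise ValueError(
            f"factor {name!r} has a single level ({levels}) in the modeled "
            "subset; term is confounded with the intercept"
        )
    cols = {}
    s = series.astype(str)
    # sum-to-zero (effect) coding: +1 own level, -1 last level.  Keeps main
    # effects marginal to interactions, so Type III term deletion is
    # well-defined and SS decompose additively in balanced designs.
    for lev in levels[:-1]:
        col = np.where(s == lev, 1.0, 0.0) - np.where(s == levels[-1], 1.0, 0.0)
        cols[f"{name}[{lev}]"] = col
    return pd.DataFrame(cols, index=series.index)


def build_design(formula: ModelFormula, data: pd.DataFrame) -> DesignInfo:
    """Effect-coded design matrices for a formula over a factor table.

    Numeric columns of ``data`` enter as covariates; non-numeric columns get
    sum-to-zero effect coding over their sorted levels.  Interaction
    columns are element-wise products of their constituents' columns.  For
    every term the matching reduced design simply deletes that term's
    columns — the Type III convention.
    """
    n = len(data)
    pieces: dict[str, pd.DataFrame] = {}
    for term in formula.terms:
        comps = formula.term_components(term)
        comp_frames = []
        for c in comps:
            if c not in data.columns:
                raise KeyError(f"term component {c!r} not in factor table columns "
                               f"{list(data.columns)}")
            col = data[c]
            if pd.api.types.is_numeric_dtype(col):
                comp_frames.append(pd.DataFrame({c: col.to_numpy(float)},
                                                index=data.index))
            else:
                comp_frames.append(_encode_factor(col, c))
        block = comp_frames[0]
        for nxt in comp_frames[1:]:
            prod = {}
            for a in block.columns:
                for b in nxt.columns:
                    prod[f"{a}:{b}"] = block[a].to_numpy() * nxt[b].to_numpy()
            block = pd.DataFrame(prod, index=data.index)
        pieces[term] = block

    full = pd.concat(
        [pd.DataFrame({"(Intercept)": np.ones(n)}, index=data.index)]
        + [pieces[t] for t in formula.terms],
        axis=1,
    )
    rank = np.linalg.matrix_rank(full.to_numpy())
    if rank < full.shape[1]:
        raise ValueError(
            f"design is rank-deficient (rank {rank} < {full.shape[1]} columns); "
            "some terms are confounded in this subset"
        )
    term_columns = {t: list(pieces[t].columns) for t in formula.terms}
    return DesignInfo(full=full, term_columns=term_columns, formula=formula)


@dataclass
class ShapeAnovaTable:
    """Per-term df/SS/MS/Rsq/F/Z/p plus Residuals and Total rows.

    ``table`` mirrors the conventional permutation-ANOVA layout with columns
    ``df SS MS Rsq F Z p``.  ``n_perm`` and ``seed`` record the permutation
    schedule; ``exhaustive`` is set when every distinct residual ordering was
    enumerated instead of sampled.
    """

    table: pd.DataFrame
    n_perm: int
    seed: int
    exhaustive: bool = False
    notes: list[str] = field(default_factory=list)

    def term_p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])

    def term_rsq(self, term: str) -> float:
        return float(self.table.loc[term, "Rsq"])

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "term", out.index)
        out.to_csv(path, sep="\t", index=False)


def _orthobasis(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis for the column space of X (economy SVD, rank-trimmed)."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int(np.sum(s > 1e-10 * s[0]))
    return U[:, :r]


def fit_shape_model(
    Y: np.ndarray,
    design: DesignInfo,
    perm: PermutationSpec,
) -> ShapeAnovaTable:
    """Fit a multivariate shape model and test each term by RRPP.

    For each term the reduced model deletes that term's columns from the
    full design (Type III).  The observed F is computed from residual
    cross-product traces; each of ``perm.n_perm`` random permutations
    shuffles the reduced-model residual rows (whole specimens, preserving
    within-specimen covariance), adds them back to the reduced fitted
    values, and recomputes F.  One shared permutation schedule is used for
    all terms.  p uses the add-one rule, ``(#{F* >= F_obs} + 1) /
    (n_perm + 1)``, counting the observed arrangement; when ``n_perm``
    meets or exceeds the number of distinct row orderings (n!), every
    ordering is enumerated instead and p is the exact fraction.

    Z is the standardized position of ln F_obs in the permutation
    distribution of ln F (permutations with non-positive F are excluded
    from the moments).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, q = Y.shape
    if q == 0:
        raise ValueError("response has zero columns")
    X_full = design.full.to_numpy(dtype=float)
    if n != X_full.shape[0]:
        raise ValueError(f"response rows {n} != design rows {X_full.shape[0]}")
    k_full = np.linalg.matrix_rank(X_full)
    df_resid = n - k_full
    if df_resid <= 0:
        raise ValueError(f"no residual degrees of freedom (n={n}, model df={k_full})")

    U_full = _orthobasis(X_full)
    total_center = Y - Y.mean(axis=0)
    ss_total = float(np.sum(total_center**2))
    ss_resid_full = float(np.sum(Y**2) - np.sum((U_full.T @ Y) ** 2))
    if ss_resid_full <= 1e-14 * max(ss_total, 1.0):
        raise ValueError("zero residual variance: model saturates the response")

    # permutation schedule shared across terms
    n_distinct = math.factorial(n) if n <= 13 else None
    exhaustive = n_distinct is not None and perm.n_perm >= n_distinct
    notes: list[str] = []
    if exhaustive:
        perm_idx = np.array(list(_iter_permutations(range(n))))
        notes.append(
            f"requested {perm.n_perm} permutations >= {n_distinct} distinct "
            "orderings; enumerated exhaustively"
        )
    else:
        rng = np.random.default_rng(perm.seed)
        perm_idx = np.array([rng.permutation(n) for _ in range(perm.n_perm)])

    rows = []
    for term in design.formula.terms:
        X_red = design.reduced(term).to_numpy(dtype=float)
        k_red = np.linalg.matrix_rank(X_red)
        df_term = k_full - k_red
        if df_term == 0:
            raise ValueError(f"term {term!r} adds no rank to the design")
        U_red = _orthobasis(X_red)
        ss_resid_red = float(np.sum(Y**2) - np.sum((U_red.T @ Y) ** 2))
        ss_term = ss_resid_red - ss_resid_full
        F_obs = (ss_term / df_term) / (ss_resid_full / df_resid)

        # RRPP: Y* = fitted_red + P @ resid_red.  Both projections annihilate
        # fitted_red (nested designs), so only the permuted residuals matter.
        R_red = Y - U_red @ (U_red.T @ Y)
        tot0 = float(np.sum(R_red**2))  # invariant under row permutation
        F_parts = []
        for start in range(0, len(perm_idx), 2048):
            A = R_red[perm_idx[start : start + 2048]]  # (b, n, q)
            hf = np.sum(np.einsum("nk,bnq->bkq", U_full, A) ** 2, axis=(1, 2))
            hr = np.sum(np.einsum("nk,bnq->bkq", U_red, A) ** 2, axis=(1, 2))
            with np.errstate(divide="ignore", invalid="ignore"):
                F_parts.append(((hf - hr) / df_term) / ((tot0 - hf) / df_resid))
        F_star = np.concatenate(F_parts)

        if exhaustive:
            p_val = float(np.mean(F_star >= F_obs - 1e-12))
            F_dist = F_star
        else:
            p_val = (np.sum(F_star >= F_obs - 1e-12) + 1) / (perm.n_perm + 1)
            F_dist = np.concatenate([[F_obs], F_star])
        pos = F_dist > 0
        lnF = np.log(F_dist[pos])
        sd = float(lnF.std(ddof=0))
        z = float((np.log(F_obs) - lnF.mean()) / sd) if F_obs > 0 and sd > 0 else np.nan

        rows.append(
            {
                "term": term,
                "df": df_term,
                "SS": ss_term,
                "MS": ss_term / df_term,
                "Rsq": ss_term / ss_total,
                "F": F_obs,
                "Z": z,
                "p": float(p_val),
            }
        )

    tbl = pd.DataFrame(rows).set_index("term")
    tbl.loc["Residuals"] = {
        "df": df_resid,
        "SS": ss_resid_full,
        "MS": ss_resid_full / df_resid,
        "Rsq": ss_resid_full / ss_total,
        "F": np.nan,
        "Z": np.nan,
        "p": np.nan,
    }
    tbl.loc["Total"] = {
        "df": n - 1,
        "SS": ss_total,
        "MS": np.nan,
        "Rsq": np.nan,
        "F": np.nan,
        "Z": np.nan,
        "p": np.nan,
    }
    tbl = tbl[ANOVA_COLUMNS]
    tbl["df"] = tbl["df"].astype(int)
    return ShapeAnovaTable(
        table=tbl,
        n_perm=perm.n_perm if not exhaustive else len(perm_idx),
        seed=perm.seed,
        exhaustive=exhaustive,
        notes=notes,
    )


@dataclass
class ModelComparison:
    """Sequential fits of nested formulas with the best-fit decision."""

    formulas: list[ModelFormula]
    tables: list[ShapeAnovaTable]
    best_index: int
    common_allometry_rejected: bool
    alpha: float

    @property
    def best_formula(self) -> ModelFormula:
        return self.formulas[self.best_index]

    @property
    def best_table(self) -> ShapeAnovaTable:
        return self.tables[self.best_index]


def compare_models(
    Y: np.ndarray,
    data: pd.DataFrame,
    formulas: list[ModelFormula | str],
    perm: PermutationSpec,
    alpha: float = 0.05,
    size_term: str = "logsize",
    habitat_term: str = "habitat",
) -> ModelComparison:
    """Fit a nested sequence of shape models and flag the best fit.

    Models must be nested in order (each formula's terms a subset of the
    next).  A more complex model supersedes the current best when at least
    one of its added terms is significant at ``alpha`` in its own fit.  The
    null hypothesis of common allometry is rejected when a size-by-habitat
    interaction term is significant in the most complex model containing it.
    """
    fl = [parse_formula(f) if isinstance(f, str) else f for f in formulas]
    for a, b in zip(fl, fl[1:]):
        if not a.is_nested_in(b):
            raise ValueError(f"formulas not nested in order: {a} !< {b}")
    tables = [fit_shape_model(Y, build_design(f, data), perm) for f in fl]

    best = 0
    for i in range(1, len(fl)):
        added = set(fl[i].terms) - set(fl[i - 1].terms)
        if any(tables[i].term_p(t) < alpha for t in added):
            best = i

    allom_rejected = False
    for f, t in zip(reversed(fl), reversed(tables)):
        inter = [
            term
            for term in f.terms
            if ":" in term
            and size_term in term.split(":")
            and habitat_term in term.split(":")
        ]
        if inter:
            allom_rejected = any(t.term_p(term) < alpha for term in inter)
            break
    return ModelComparison(
        formulas=fl,
        tables=tables,
        best_index=best,
        common_allometry_rejected=allom_rejected,
        alpha=alpha,
    )


@dataclass
class SubsetResult:
    """One split level's fresh superimposition, ordination and model fit."""

    level: str
    n: int
    aligned: object
    pca: object
    table: ShapeAnovaTable | None
    skipped_reason: str | None = None


def subset_reanalysis(
    ds: LandmarkDataset,
    split_by: str,
    formula: ModelFormula | str,
    perm: PermutationSpec,
    min_n: int = 8,
    tangent: bool = True,
) -> dict[str, SubsetResult]:
    """Re-run GPA → PCA → retention → model within each level of a factor.

    Each subset is re-superimposed from the raw coordinates — the pooled
    alignment is never reused — so subset consensus shapes and PC counts can
    legitimately differ from the pooled analysis.  Subsets below ``min_n``
    (or below the model's degrees of freedom) are skipped with a logged
    reason rather than raising.
    """
    if ds.factors is None or split_by not in ds.factors.columns:
        raise KeyError(f"split factor {split_by!r} not in dataset factors")
    formula = parse_formula(formula) if isinstance(formula, str) else formula
    out: dict[str, SubsetResult] = {}
    for level in sorted(ds.factors[split_by].astype(str).unique()):
        mask = (ds.factors[split_by].astype(str) == level).to_numpy()
        n_sub = int(mask.sum())
        if n_sub < min_n:
            out[level] = SubsetResult(
                level, n_sub, None, None, None,
                skipped_reason=f"subset n={n_sub} < minimum {min_n}",
            )
            continue
        sub = LandmarkDataset(
            specimen_ids=[s for s, m in zip(ds.specimen_ids, mask) if m],
            coords=ds.coords[mask],
            landmark_labels=list(ds.landmark_labels),
            factors=ds.factors.loc[mask].copy(),
        )
        al = gpa(sub, tangent=tangent)
        pca = shape_pca(al)
        data = _model_frame(al)
        try:
            design = build_design(formula, data)
            tbl = fit_shape_model(pca.retained_scores(), design, perm)
        except ValueError as exc:
            out[level] = SubsetResult(level, n_sub, al, pca, None,
                                      skipped_reason=str(exc))
            continue
        out[level] = SubsetResult(level, n_sub, al, pca, tbl)
    return out


def _model_frame(al) -> pd.DataFrame:
    """Factor table augmented with the log centroid size covariate."""
    data = al.factors.copy() if al.factors is not None else pd.DataFrame(
        index=pd.Index(al.specimen_ids)
    )
    data["logsize"] = al.log_centroid_sizes
    return data
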