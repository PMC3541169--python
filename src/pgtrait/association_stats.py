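"""Association statistics for the gene-content screen.

Four tools: chi-squared association on 2x2 tables (per-family domain
associations), the phi coefficient (Pearson correlation of two binary
indicators, in closed form), principal-component analysis of the absence
indicators (eight families plus PG), and binary logistic regression of PG
absence on binarized genome covariates (GC < 50%, genome size < 1.5 Mb,
obligate intracellular lifestyle) with a Hosmer-Lemeshow goodness-of-fit
test.

Genomes of unknown PG status are excluded wherever PG enters; no multiple-
testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

from .annotation_io import (
    FAMILIES,
    GC_CUTOFF_PERCENT,
    GENOME_SIZE_CUTOFF_MB,
    Cohort,
    ValidationError,
)

__all__ = [
    "TwoByTwo",
    "ChiSquareResult",
    "PCAResult",
    "RegressionResult",
    "RegressionReport",
    "chisq_association",
    "phi_correlation",
    "absence_pca",
    "pg_absence_regression",
    "hosmer_lemeshow",
]


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table; rows = indicator 1/0, columns = outcome 1/0."""

    a: int  # indicator 1, outcome 1
    b: int  # indicator 1, outcome 0
    c: int  # indicator 0, outcome 1
    d: int  # indicator 0, outcome 0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("cell counts must be non-negative")
        if self.total == 0:
            raise ValidationError("table must have at least one observation")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)

    @classmethod
    def from_indicators(cls, x, y) -> "TwoByTwo":
        x = np.asarray(x, dtype=bool)
        y = np.asarray(y, dtype=bool)
        if x.shape != y.shape:
            raise ValidationError("indicator vectors must have equal length")
        return cls(
            a=int(np.sum(x & y)),
            b=int(np.sum(x & ~y)),
            c=int(np.sum(~x & y)),
            d=int(np.sum(~x & ~y)),
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float | None
    p_value: float | None
    yates: bool


def chisq_association(t: TwoByTwo, yates: bool = False) -> ChiSquareResult:
    """Pearson chi-squared test of independence on a 2x2 table (1 df).

    Continuity (Yates) correction is off by default; a zero margin makes the
    test undefined and yields ``None`` markers rather than an exception.
    """
    if 0 in t.margins():
        return ChiSquareResult(statistic=None, p_value=None, yates=yates)
    stat, p, _, _ = stats.chi2_contingency(t.as_array(), correction=yates)
    return ChiSquareResult(statistic=float(stat), p_value=float(p), yates=yates)


def phi_correlation(t: TwoByTwo) -> float | None:
    """Phi coefficient: Pearson correlation of the two expanded 0/1 vectors.

    Computed in closed form ``(ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d))``; equal
    to brute-force Pearson on the expanded indicators.  ``None`` when a margin
    is zero.
    """
    r1, r0, c1, c0 = t.margins()
    if 0 in (r1, r0, c1, c0):
        return None
    num = t.a * t.d - t.b * t.c
    den = np.sqrt(float(r1) * r0 * c1 * c0)
    return float(num / den)


@dataclass
class PCAResult:
    """Orthonormal loadings of the absence indicators on principal components."""

    loadings: pd.DataFrame  # rows: variables, columns: PC1, PC2, ...
    explained_variance_ratio: np.ndarray
    dropped: list[str]


def absence_pca(cohort: Cohort, n_components: int = 2, scale: bool = False) -> PCAResult:
    """PCA of the absence indicators (eight families + PG) over known-status genomes.

    The indicator matrix is centered (optionally scaled to unit variance);
    constant columns are dropped with a warning.  Returned loadings are the
    principal axes, hence orthonormal (``L.T @ L = I``).
    """
    rows = []
    for rec in cohort:
        if rec.pg_status == "unknown":
            continue
        row = {f: int(rec.family_counts[f] == 0) for f in FAMILIES}
        row["PG"] = int(rec.pg_status == "absent")
        rows.append(row)
    if len(rows) < 3:
        raise ValidationError("need at least 3 known-status records for PCA")
    frame = pd.DataFrame(rows)
    dropped = [c for c in frame.columns if frame[c].nunique() <= 1]
    if dropped:
        warnings.warn(f"dropping constant column(s): {dropped}", stacklevel=2)
        frame = frame.drop(columns=dropped)
    if frame.shape[1] < 2:
        raise ValidationError("fewer than 2 varying columns; PCA not meaningful")
    X = frame.to_numpy(dtype=float)
    if scale:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    k = min(n_components, frame.shape[1])
    pca = PCA(n_components=k)
    pca.fit(X)
    loadings = pd.DataFrame(
        pca.components_.T,
        index=frame.columns,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return PCAResult(
        loadings=loadings,
        explained_variance_ratio=pca.explained_variance_ratio_,
        dropped=dropped,
    )


@dataclass(frozen=True)
class RegressionResult:
    """Per-predictor odds ratio with Wald 95% CI and p-value.

    ``separated`` flags complete/quasi-complete separation; the odds ratio is
    then ``inf`` (or 0) rather than a finite estimate.
    """

    predictor: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float | None
    separated: bool = False


def hosmer_lemeshow(y: np.ndarray, p: np.ndarray, n_groups: int = 10) -> float | None:
    """Hosmer-Lemeshow goodness-of-fit p-value on deciles of fitted risk."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    order = np.argsort(p, kind="stable")
    groups = np.array_split(order, n_groups)
    groups = [g for g in groups if len(g)]
    if len(groups) <= 2:
        return None
    chi2 = 0.0
    for g in groups:
        obs1 = y[g].sum()
        exp1 = p[g].sum()
        exp0 = len(g) - exp1
        if exp1 <= 0 or exp0 <= 0:
            continue
        chi2 += (obs1 - exp1) ** 2 / exp1 + ((len(g) - obs1) - exp0) ** 2 / exp0
    df = len(groups) - 2
    return float(stats.chi2.sf(chi2, df))


_PREDICTORS = ("gc_below_cutoff", "size_below_cutoff", "obligate_intracellular")


@dataclass
class RegressionReport:
    """Per-predictor odds ratios plus the model goodness-of-fit p-value."""

    per_predictor: dict[str, RegressionResult]
    hosmer_lemeshow_p: float | None
    n_used: int
    joint: bool

    def __getitem__(self, predictor: str) -> RegressionResult:
        return self.per_predictor[predictor]


def pg_absence_regression(
    cohort: Cohort,
    joint: bool = True,
    gc_cutoff: float = GC_CUTOFF_PERCENT,
    size_cutoff: float = GENOME_SIZE_CUTOFF_MB,
) -> RegressionReport:
    """Logistic regression of PG absence on binarized genome covariates.

    Uses known-status records with all three covariates available.  With
    ``joint=True`` (multivariable, the default) all predictors enter one
    model; otherwise each is fitted alone.
    """
    ys, xs = [], []
    for rec in cohort:
        if rec.pg_status == "unknown":
            continue
        if rec.gc_percent is None or rec.genome_size_mb is None or rec.lifestyle is None:
            continue
        ys.append(int(rec.pg_status == "absent"))
        xs.append(
            [
                int(rec.gc_percent < gc_cutoff),
                int(rec.genome_size_mb < size_cutoff),
                int(rec.lifestyle == "obligate_intracellular"),
            ]
        )
    if len(ys) < 10:
        raise ValidationError("too few complete records for regression")
    y = np.asarray(ys, dtype=float)
    X = np.asarray(xs, dtype=float)
    if y.min() == y.max():
        raise ValidationError("outcome does not vary; regression undefined")

    results: dict[str, RegressionResult] = {}

    def fit_one(cols: list[int]) -> tuple[sm.Logit, object]:
        design = sm.add_constant(X[:, cols], has_constant="add")
        model = sm.Logit(y, design)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(disp=0, maxiter=200)
            except Exception:
                # Newton fails on a singular Hessian under (quasi-)separation;
                # BFGS still yields estimates, with non-finite standard errors
                res = model.fit(disp=0, maxiter=500, method="bfgs")
        return model, res

    def extract(res, position: int, name: str) -> RegressionResult:
        beta = res.params[position]
        se = res.bse[position]
        separated = bool(abs(beta) > 15 or not np.isfinite(se) or se > 100)
        if separated:
            return RegressionResult(
                predictor=name,
                odds_ratio=float("inf") if beta > 0 else 0.0,
                ci_low=0.0,
                ci_high=float("inf"),
                p_value=None,
                separated=True,
            )
        return RegressionResult(
            predictor=name,
            odds_ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - 1.959964 * se)),
            ci_high=float(np.exp(beta + 1.959964 * se)),
            p_value=float(res.pvalues[position]),
        )

    if joint:
        _, res = fit_one([0, 1, 2])
        for i, name in enumerate(_PREDICTORS):
            results[name] = extract(res, i + 1, name)
        hl = hosmer_lemeshow(y, res.predict())
    else:
        hl = None
        for i, name in enumerate(_PREDICTORS):
            _, res = fit_one([i])
            results[name] = extract(res, 1, name)
            if hl is None:
                hl = hosmer_lemeshow(y, res.predict())
    return RegressionReport(
        per_predictor=results, hosmer_lemeshow_p=hl, n_used=len(y), joint=joint
    )
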