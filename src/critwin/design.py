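"""Fixed-covariate design matrix and exposure blocks for the probit model.

Covariates follow the usual term-birth adjustment set: gestational age
(linear, weeks), season of birth, infant sex, parity, maternal age group,
race/ethnicity, education, birth year, and 4-df cubic B-spline bases for the
region-wide temperature and dewpoint on the birth date. Reference levels:
winter, male, no previous live births, age 30-34, NH-white, <HS, and the
first birth year. With all factors present the design has p = 29 columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .exposure import ExposureMatrix, trimester_matrix
from .synthetic import (AGE_LEVELS, EDU_LEVELS, PARITY_LEVELS, RACE_LEVELS,
                        SEASON_LEVELS, SEX_LEVELS)


class DesignError(ValueError):
    """Raised for unusable covariate inputs (unseen levels, constants)."""


MODEL_ALIASES = {
    1: "weekly_structured", 2: "trimester", 3: "weekly_naive",
    "weekly_structured": "weekly_structured", "trimester": "trimester",
    "weekly_naive": "weekly_naive",
    "1": "weekly_structured", "2": "trimester", "3": "weekly_naive",
}

# factor -> (reference level, full level list)
FACTORS = {
    "season_of_birth": ("winter", SEASON_LEVELS),
    "sex": ("male", SEX_LEVELS),
    "parity": ("0", PARITY_LEVELS),
    "maternal_age_group": ("30-34", AGE_LEVELS),
    "race_ethnicity": ("NH-white", RACE_LEVELS),
    "education": ("<HS", EDU_LEVELS),
}


@dataclass
class DesignMatrix:
    matrix: np.ndarray
    column_names: list[str]
    reference_levels: dict[str, str]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.column_names)


@dataclass
class ExposureBlock:
    """Exposure columns entering the linear predictor for one model variant."""
    matrix: np.ndarray
    labels: list[str]
    weeks: np.ndarray | None  # pregnancy-week ids for weekly models
    model: str


def bspline_basis(values: np.ndarray, df: int = 4) -> np.ndarray:
    """Cubic B-spline basis, ``df`` columns, no intercept column.

    Boundary knots at the data min/max; ``df - 3`` interior knots at
    quantiles (one knot at the median for the default df=4). Matches the
    drop-first-column convention of R's ``bs(x, df=4)``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise DesignError("spline input must be a vector")
    if np.unique(x).size < 5:
        raise DesignError("spline input needs at least 5 distinct values")
    degree = 3
    n_interior = df - degree
    if n_interior < 0:
        raise DesignError("df must be at least 3 for a cubic spline")
    lo, hi = float(x.min()), float(x.max())
    interior = np.quantile(x, [(i + 1) / (n_interior + 1) for i in range(n_interior)])
    t = np.r_[[lo] * (degree + 1), interior, [hi] * (degree + 1)]
    # clip guards exact-boundary evaluation against round-off
    xc = np.clip(x, lo, hi)
    full = BSpline.design_matrix(xc, t, degree, extrapolate=False).toarray()
    return full[:, 1:]


def _dummies(series: pd.Series, name: str, reference: str,
             levels: list[str]) -> tuple[np.ndarray, list[str]]:
    vals = series.astype(str)
    unseen = set(vals.unique()) - set(levels)
    if unseen:
        raise DesignError(f"unseen {name} level(s): {sorted(unseen)}")
    cols, labels = [], []
    for lev in levels:
        if lev == reference:
            continue
        cols.append((vals == lev).to_numpy(dtype=float))
        labels.append(f"{name}[{lev} vs {reference}]")
    return np.column_stack(cols) if cols else np.empty((len(series), 0)), labels


def build_design(cohort: pd.DataFrame, spline_df: int = 4,
                 include_splines: bool = True,
                 drop_collinear: bool = True) -> DesignMatrix:
    """Assemble the n x p covariate matrix (p = 29 with all factors present).

    Constant columns (for example a factor level absent from the cohort, or
    a single birth year) and any remaining linearly dependent columns are
    dropped with a warning so the matrix has full column rank.
    """
    n = len(cohort)
    cols = [np.ones(n)]
    names = ["intercept"]
    refs: dict[str, str] = {}

    cols.append(cohort["gestational_age"].to_numpy(dtype=float))
    names.append("gestational_age")

    for factor, (ref, levels) in FACTORS.items():
        block, labels = _dummies(cohort[factor], factor, ref, levels)
        refs[factor] = ref
        if block.shape[1]:
            cols.append(block)
            names.extend(labels)

    years = np.sort(cohort["birth_year"].unique())
    ref_year = int(years[0])
    refs["birth_year"] = str(ref_year)
    for yr in years[1:]:
        cols.append((cohort["birth_year"] == yr).to_numpy(dtype=float))
        names.append(f"birth_year[{yr} vs {ref_year}]")

    if include_splines:
        for var in ("temperature", "dewpoint"):
            basis = bspline_basis(cohort[var].to_numpy(dtype=float), df=spline_df)
            cols.append(basis)
            names.extend(f"{var}_bs{k + 1}" for k in range(basis.shape[1]))

    X = np.column_stack([c if c.ndim == 2 else c[:, None] for c in cols])

    # constant columns (other than the intercept) carry no information
    keep = np.ones(X.shape[1], dtype=bool)
    for j in range(1, X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            keep[j] = False
            warnings.warn(f"dropping constant design column {names[j]!r}")
    X = X[:, keep]
    names = [nm for nm, k in zip(names, keep) if k]

    if drop_collinear and X.shape[1] > 1:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            from scipy.linalg import qr
            _, _, piv = qr(X, mode="economic", pivoting=True)
            drop = sorted(piv[rank:])
            for j in drop:
                warnings.warn(f"dropping collinear design column {names[j]!r}")
            keep2 = np.ones(X.shape[1], dtype=bool)
            keep2[drop] = False
            X = X[:, keep2]
            names = [nm for nm, k in zip(names, keep2) if k]

    return DesignMatrix(X, names, refs)


def build_exposure_block(exposure: ExposureMatrix, model,
                         max_week: int = 44) -> ExposureBlock:
    """Exposure columns for a model variant.

    * ``weekly_structured`` / ``weekly_naive`` (models 1/3): one column per
      pregnancy week up to ``max_week``; weeks with zero valid observations
      are dropped (their effect is not estimable).
    * ``trimester`` (model 2): three columns of standardized trimester
      averages.
    """
    variant = MODEL_ALIASES.get(model)
    if variant is None:
        raise DesignError(f"unknown model variant {model!r}")
    if variant == "trimester":
        T = trimester_matrix(exposure)
        c = T.mean(axis=0)
        s = T.std(axis=0, ddof=1)
        if np.any(s <= 0):
            raise DesignError("zero-variance trimester average")
        block = (T - c) / s
        return ExposureBlock(block, [f"trimester_{k}" for k in (1, 2, 3)],
                             None, variant)
    if not 1 <= max_week <= 44:
        raise DesignError("max_week must lie in 1..44")
    counts = exposure.valid[:, :max_week].sum(axis=0)
    weeks = np.flatnonzero(counts > 0) + 1
    block = exposure.values[:, weeks - 1]
    labels = [f"week_{j}" for j in weeks]
    return ExposureBlock(block, labels, weeks, variant)


def write_design(design: DesignMatrix, path) -> None:
    design.to_frame().to_csv(path, index=False)
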