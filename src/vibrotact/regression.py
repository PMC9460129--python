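"""Exhaustive regression families with leave-one-sample-out selection.

Perceived tactile scores are related to physical features (subarea
features D_i and the dynamic friction coefficient mu') through four
candidate model families:

    linear        y = b0 + sum_i b_i x_i
    logarithmic   y = b0 + sum_i b_i log10(x_i)
    interaction   y = b0 + b1 x_i + b2 x_j + b3 x_i x_j
    polynomial    y = b0 + sum_k b_k x^k      (one variable, degree a)

Every variable subset (brute force) of every family is fitted by
ordinary least squares; the selection metric is the mean squared
prediction error under leave-one-sample-out cross-validation (fit on all
samples but one, predict the held-out sample, cycle).  The published
best-fit equations per cluster/component are frozen here verbatim for
reference evaluation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "FAMILIES",
    "InfeasibleModelError",
    "ModelSpec",
    "FittedModel",
    "CVResult",
    "enumerate_specs",
    "design_matrix",
    "fit_spec",
    "loso_error",
    "select_models",
    "SelectionResult",
    "evaluate_frozen",
    "FROZEN_MODELS",
    "ExhaustiveTactileRegressor",
]

FAMILIES = ("linear", "logarithmic", "interaction", "polynomial")


class InfeasibleModelError(ValueError):
    """A spec cannot be fitted on the given data (log of <=0, rank deficiency,
    or more parameters than observations); callers skip such specs."""


@dataclass(frozen=True)
class ModelSpec:
    """One regression structure: family, variables and (polynomial) degree."""

    family: str
    variables: tuple[str, ...]
    degree: int = 1
    method: str = ""  # feature-extraction tag, e.g. "A" or "B"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.variables:
            raise ValueError("spec needs at least one variable")
        if self.family == "interaction" and len(self.variables) != 2:
            raise ValueError("interaction model uses exactly 2 variables")
        if self.family == "polynomial":
            if len(self.variables) != 1:
                raise ValueError("polynomial model uses exactly 1 variable")
            if self.degree < 1:
                raise ValueError("polynomial degree must be >= 1")

    @property
    def n_parameters(self) -> int:
        """Number of fitted coefficients including the intercept."""
        if self.family == "interaction":
            return 4
        if self.family == "polynomial":
            return self.degree + 1
        return len(self.variables) + 1


@dataclass
class FittedModel:
    """OLS fit of one spec: coefficients and the usual diagnostics."""

    spec: ModelSpec
    params: pd.Series  # const + design columns
    std_params: pd.Series  # standardized coefficients (slopes only)
    pvalues: pd.Series
    r_squared: float
    r_squared_adj: float
    f_pvalue: float

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        M, cols = design_matrix(self.spec, X)
        return M @ self.params.loc[["const", *cols]].to_numpy()


@dataclass
class CVResult:
    """Leave-one-sample-out record for one spec."""

    spec: ModelSpec
    fold_errors: pd.Series  # squared prediction error per held-out sample
    error: float  # aggregated metric
    metric: str = "mse"


def enumerate_specs(
    family: str,
    candidates: list[str],
    p_max: int = 5,
    a_max: int = 3,
    method: str = "",
) -> list[ModelSpec]:
    """All model structures of one family over the candidate variables.

    linear/logarithmic: every subset of size 1..p_max; interaction: every
    unordered pair; polynomial: one spec per variable at degree ``a_max``.
    """
    if not candidates:
        raise ValueError("no candidate variables")
    candidates = list(candidates)
    if family in ("linear", "logarithmic"):
        if p_max > len(candidates):
            import warnings

            warnings.warn(
                f"p_max={p_max} exceeds {len(candidates)} candidates; clamped"
            )
            p_max = len(candidates)
        return [
            ModelSpec(family, combo, method=method)
            for p in range(1, p_max + 1)
            for combo in itertools.combinations(candidates, p)
        ]
    if family == "interaction":
        return [
            ModelSpec(family, pair, method=method)
            for pair in itertools.combinations(candidates, 2)
        ]
    if family == "polynomial":
        return [ModelSpec(family, (v,), degree=a_max, method=method) for v in candidates]
    raise ValueError(f"unknown family {family!r}")


def design_matrix(spec: ModelSpec, X: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Build the design matrix (intercept column first) for one spec."""
    missing = [v for v in spec.variables if v not in X.columns]
    if missing:
        raise KeyError(f"missing feature column(s): {missing}")
    cols: list[str] = []
    arrays: list[np.ndarray] = []
    if spec.family == "linear":
        for v in spec.variables:
            arrays.append(X[v].to_numpy(float))
            cols.append(v)
    elif spec.family == "logarithmic":
        for v in spec.variables:
            x = X[v].to_numpy(float)
            if np.any(x <= 0):
                raise InfeasibleModelError(
                    f"logarithmic model needs positive {v}; found min {x.min():g}"
                )
            arrays.append(np.log10(x))
            cols.append(f"log10({v})")
    elif spec.family == "interaction":
        xi = X[spec.variables[0]].to_numpy(float)
        xj = X[spec.variables[1]].to_numpy(float)
        arrays += [xi, xj, xi * xj]
        cols += [
            spec.variables[0],
            spec.variables[1],
            f"{spec.variables[0]}*{spec.variables[1]}",
        ]
    elif spec.family == "polynomial":
        x = X[spec.variables[0]].to_numpy(float)
        for k in range(1, spec.degree + 1):
            arrays.append(x**k)
            cols.append(spec.variables[0] if k == 1 else f"{spec.variables[0]}^{k}")
    M = np.column_stack([np.ones(len(X)), *arrays])
    return M, cols


def fit_spec(spec: ModelSpec, X: pd.DataFrame, y: pd.Series | np.ndarray) -> FittedModel:
    """Ordinary least squares fit with diagnostics.

    Raises :class:`InfeasibleModelError` when the problem is rank
    deficient or has no residual degrees of freedom.
    """
    y = np.asarray(y, float)
    M, cols = design_matrix(spec, X)
    if M.shape[0] <= M.shape[1]:
        raise InfeasibleModelError(
            f"{M.shape[0]} observations cannot identify {M.shape[1]} parameters"
        )
    if np.linalg.matrix_rank(M) < M.shape[1]:
        raise InfeasibleModelError("rank-deficient design matrix")
    names = ["const", *cols]
    res = sm.OLS(y, pd.DataFrame(M, columns=names)).fit()
    sy = np.std(y, ddof=1)
    std = {}
    for name in cols:
        sx = np.std(M[:, names.index(name)], ddof=1)
        std[name] = res.params[name] * sx / sy if sy > 0 else np.nan
    return FittedModel(
        spec=spec,
        params=res.params,
        std_params=pd.Series(std),
        pvalues=res.pvalues,
        r_squared=float(res.rsquared),
        r_squared_adj=float(res.rsquared_adj),
        f_pvalue=float(res.f_pvalue) if res.df_model > 0 else np.nan,
    )


def loso_error(
    spec: ModelSpec,
    X: pd.DataFrame,
    y: pd.Series,
    metric: str = "mse",
) -> CVResult:
    """Leave-one-sample-out cross-validated prediction error.

    X rows are per-sample (repetition-averaged) feature values; every
    sample serves once as the held-out validation point.  ``metric`` is
    "mse" (mean squared error) or "rmse".
    """
    if len(X) < 3:
        raise ValueError("leave-one-sample-out needs at least 3 samples")
    y = pd.Series(np.asarray(y, float), index=X.index)
    sq_errors = {}
    for holdout in X.index:
        train = X.index != holdout
        model = fit_spec(spec, X.loc[train], y.loc[train])
        pred = float(model.predict(X.loc[[holdout]])[0])
        sq_errors[holdout] = (pred - y.loc[holdout]) ** 2
    folds = pd.Series(sq_errors)
    mse = float(folds.mean())
    if metric == "mse":
        err = mse
    elif metric == "rmse":
        err = math.sqrt(mse)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return CVResult(spec=spec, fold_errors=folds, error=err, metric=metric)


def _spec_sort_key(cv: CVResult) -> tuple:
    # lowest error, then fewer parameters, then lexicographic variables
    return (cv.error, cv.spec.n_parameters, cv.spec.variables)


@dataclass
class SelectionResult:
    """Per-target grid of minimum errors over (method, family) cells."""

    grid: pd.DataFrame  # index: target, columns: (method, family), values: min error
    best: dict[str, CVResult]  # per-target winning spec
    cell_best: dict[tuple[str, str, str], CVResult] = field(default_factory=dict)
    metric: str = "mse"


def select_models(
    feature_tables: dict[str, pd.DataFrame],
    targets: pd.DataFrame,
    p_max: int = 5,
    a_max: int = 3,
    metric: str = "mse",
    families: tuple[str, ...] = FAMILIES,
) -> SelectionResult:
    """Exhaustive search over feature methods x families for each target.

    ``feature_tables`` maps a method tag (e.g. "A", "B") to a per-sample
    candidate table; ``targets`` holds one column per objective variable
    (per-cluster component scores) on the same sample index.  Each
    (method, family) cell reports the minimum cross-validated error over
    that cell's specs; the per-target best cell is recorded with ties
    broken by fewer parameters, then variable names.  Cells where every
    spec is infeasible report NaN.
    """
    if targets.shape[1] == 0:
        raise ValueError("no targets")
    cols = pd.MultiIndex.from_product([feature_tables.keys(), families])
    grid = pd.DataFrame(np.nan, index=targets.columns, columns=cols)
    best: dict[str, CVResult] = {}
    cell_best: dict[tuple[str, str, str], CVResult] = {}
    for target in targets.columns:
        y = targets[target]
        winners: list[CVResult] = []
        for method, table in feature_tables.items():
            X = table.loc[targets.index]
            for family in families:
                results = []
                for spec in enumerate_specs(
                    family, list(X.columns), p_max=p_max, a_max=a_max, method=method
                ):
                    # polynomial cell searched at every degree up to a_max
                    degrees = range(1, a_max + 1) if family == "polynomial" else (spec.degree,)
                    for d in degrees:
                        s = ModelSpec(family, spec.variables, degree=d, method=method)
                        try:
                            results.append(loso_error(s, X, y, metric=metric))
                        except InfeasibleModelError:
                            continue
                if results:
                    cell_winner = min(results, key=_spec_sort_key)
                    grid.loc[target, (method, family)] = cell_winner.error
                    cell_best[(target, method, family)] = cell_winner
                    winners.append(cell_winner)
        if winners:
            best[target] = min(winners, key=_spec_sort_key)
    return SelectionResult(grid=grid, best=best, cell_best=cell_best, metric=metric)


class ExhaustiveTactileRegressor(RegressorMixin, BaseEstimator):
    """Brute-force family/subset regression selected by leave-one-out error.

    Fit on a per-sample feature table (DataFrame, one row per material
    sample) and a target vector; the estimator enumerates every spec of
    the requested families, scores each by leave-one-sample-out
    cross-validation, keeps the lowest-error spec and refits it on all
    samples.

    Attributes (after fit): ``best_spec_``, ``best_error_``, ``model_``
    (the refitted :class:`FittedModel`), ``cv_results_`` (one row per
    feasible spec).
    """

    def __init__(
        self,
        families: tuple[str, ...] | str = FAMILIES,
        p_max: int = 5,
        a_max: int = 3,
        metric: str = "mse",
    ):
        self.families = families
        self.p_max = p_max
        self.a_max = a_max
        self.metric = metric

    def fit(self, X: pd.DataFrame, y) -> "ExhaustiveTactileRegressor":
        X = pd.DataFrame(X)
        families = (self.families,) if isinstance(self.families, str) else tuple(self.families)
        results: list[CVResult] = []
        for family in families:
            for spec in enumerate_specs(
                family, list(X.columns), p_max=self.p_max, a_max=self.a_max
            ):
                degrees = (
                    range(1, self.a_max + 1) if family == "polynomial" else (spec.degree,)
                )
                for d in degrees:
                    s = ModelSpec(family, spec.variables, degree=d)
                    try:
                        results.append(loso_error(s, X, pd.Series(np.asarray(y, float), index=X.index), metric=self.metric))
                    except InfeasibleModelError:
                        continue
        if not results:
            raise InfeasibleModelError("every candidate spec was infeasible")
        results.sort(key=_spec_sort_key)
        self.cv_results_ = pd.DataFrame(
            {
                "family": [r.spec.family for r in results],
                "variables": [",".join(r.spec.variables) for r in results],
                "degree": [r.spec.degree for r in results],
                "error": [r.error for r in results],
            }
        )
        winner = results[0]
        self.best_spec_ = winner.spec
        self.best_error_ = winner.error
        self.model_ = fit_spec(winner.spec, X, np.asarray(y, float))
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        return self.model_.predict(pd.DataFrame(X))


# ---------------------------------------------------------------------------
# Published best-fit equations, frozen verbatim (cluster i, component j).
# Term kinds: "lin" -> c*x, "log" -> c*log10(x), "pow" -> c*x**k,
# "prod" -> c*x1*x2.

FROZEN_MODELS: dict[str, dict] = {
    "C1PC1": {
        "intercept": -4136.0,
        "terms": [
            (5.544, "log", ("D_SAISAIIFAI",)),
            (-98.20, "log", ("D_SAIIFAII",)),
            (466.3, "log", ("D_FAII",)),
            (0.9490, "log", ("mu_prime",)),
        ],
    },
    "C1PC2": {
        "intercept": 0.0,
        "terms": [
            (1.828, "pow", ("D_SAIIFAII", 1)),
            (-3.5e-4, "pow", ("D_SAIIFAII", 2)),
            (1.69e-8, "pow", ("D_SAIIFAII", 3)),
        ],
    },
    "C2PC1": {
        "intercept": -16.88,
        "terms": [
            (2.856, "log", ("D_SAISAIIFAI",)),
            (1.114, "log", ("mu_prime",)),
        ],
    },
    "C2PC2": {
        "intercept": -94.98,
        "terms": [
            (4.824e-3, "lin", ("D_SAISAIIFAII",)),
            (-4.270e-3, "lin", ("D_ALL",)),
            (8.772e-3, "lin", ("D_SAIIFAII",)),
        ],
    },
    "C2PC3": {
        "intercept": 4911.0,
        "terms": [
            (-2.237, "lin", ("D_SAISAIIFAII",)),
            (-0.4273, "lin", ("D_SAIIFAII",)),
            (2.151e-4, "prod", ("D_SAISAIIFAI", "D_SAIIFAII")),
        ],
    },
}


def evaluate_frozen(model_id: str, features: dict[str, float]) -> float:
    """Evaluate one published best-fit equation with its printed coefficients.

    ``features`` maps feature names (``D_<label>`` and ``mu_prime``) to
    values; logarithms are base 10 and require positive arguments.
    """
    if model_id not in FROZEN_MODELS:
        raise KeyError(
            f"unknown model {model_id!r}; choose from {sorted(FROZEN_MODELS)}"
        )
    eq = FROZEN_MODELS[model_id]

    def get(name: str) -> float:
        if name not in features:
            raise KeyError(f"model {model_id} requires feature {name!r}")
        return float(features[name])

    y = eq["intercept"]
    for coef, kind, args in eq["terms"]:
        if kind == "lin":
            y += coef * get(args[0])
        elif kind == "log":
            x = get(args[0])
            if x <= 0:
                raise ValueError(f"log term needs positive {args[0]}, got {x}")
            y += coef * math.log10(x)
        elif kind == "pow":
            y += coef * get(args[0]) ** args[1]
        elif kind == "prod":
            y += coef * get(args[0]) * get(args[1])
        else:  # pragma: no cover
            raise AssertionError(kind)
    return y
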