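"""OLS binding-score models, QSAR metrics, and the six-model registry.

Metric conventions
------------------
``R²`` (training) and ``Q²`` (external/test) are the squared Pearson
correlation between observed and fitted/predicted values. Because a squared
correlation is blind to scale shifts and to sign, the PRESS-style external
metric ``q2_press = 1 − Σ(y−ŷ)²/Σ(y−ȳ_train)²`` is always computed
alongside, and anti-correlated predictions trigger a sign warning. RMSE is
the root mean squared residual.

The registry mirrors the study's modeling plan: two exploratory models on
all 28 descriptors (regression and CPANN), and four predictive models —
regression/CPANN on (QPpolrz, TD) and regression/CPANN on the optimal
descriptor DCW — each evaluated per response on the recorded split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cpann import CPANN
from .dcw import DCWModel, optimize_weights
from .errors import (
    DimensionError,
    MetricError,
    RegistryError,
    SingularityError,
)
from .synthetic import RESPONSES, SyntheticDataset


def pearson_r(x, y) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.std() == 0 or y.std() == 0:
        raise MetricError("Pearson r undefined for a constant vector")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class RegressionModel:
    """A fitted least-squares model with its stored predictions and metrics."""

    predictor_names: list[str]
    coefficients: np.ndarray
    intercept: float
    r2_train: float
    rmse_train: float
    fitted_ids: list[str] = field(default_factory=list)
    fitted_values: np.ndarray | None = None

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.coefficients):
            raise DimensionError(
                f"model has {len(self.coefficients)} predictors, got {X.shape[1]}"
            )
        return self.intercept + X @ self.coefficients

    def equation(self) -> str:
        terms = " + ".join(
            f"{c:+.6g}*{n}" for c, n in zip(self.coefficients, self.predictor_names)
        )
        return f"y = {self.intercept:.6g} {terms}"


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Name columns implicated in rank deficiency (constant or duplicated)."""
    bad = [n for j, n in enumerate(names) if X[:, j].std() == 0]
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if np.isfinite(corr[i, j]) and abs(corr[i, j]) > 1 - 1e-10:
                bad += [names[i], names[j]]
    return sorted(set(bad)) or list(names)


def fit_ols(X, y, predictor_names=None, ids=None) -> RegressionModel:
    """Ordinary least squares with intercept.

    R² is the squared Pearson correlation of observed vs fitted; RMSE the
    root mean squared residual. Rank-deficient designs raise
    :class:`SingularityError` naming the collinear columns; a constant
    response raises :class:`MetricError`.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = list(predictor_names) if predictor_names is not None else [
        f"x{j}" for j in range(p)
    ]
    if n <= p + 1:
        raise SingularityError(f"need n > p+1 observations, got n={n}, p={p}")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise SingularityError("non-finite values in the design or response")
    if y.std() == 0:
        raise MetricError("constant response: regression metrics undefined")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < p + 1:
        raise SingularityError(
            f"rank-deficient design; collinear columns: {_collinear_columns(X, names)}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ beta
    resid = y - fitted
    model = RegressionModel(
        predictor_names=names,
        coefficients=beta[1:],
        intercept=float(beta[0]),
        r2_train=pearson_r(y, fitted) ** 2,
        rmse_train=float(np.sqrt(np.mean(resid ** 2))),
        fitted_ids=list(ids) if ids is not None else [],
        fitted_values=fitted,
    )
    return model


def evaluate(observed, predicted, y_train_mean: float | None = None) -> dict:
    """External-set metrics for any model's predictions.

    Returns ``q2`` (squared Pearson r), ``q2_press`` (1 − PRESS/SS about the
    training mean; the observed mean is used when no training mean is given)
    and ``rmse``. Anti-correlated predictions emit a sign warning — the
    squared-correlation metric alone cannot see the flipped sign.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise DimensionError(
            f"length mismatch: observed {observed.shape} vs predicted {predicted.shape}"
        )
    r = pearson_r(observed, predicted)
    if r < 0:
        warnings.warn(
            "predictions are anti-correlated with observations; "
            "Q² (squared correlation) hides the sign flip",
            stacklevel=2,
        )
    center = float(observed.mean()) if y_train_mean is None else y_train_mean
    ss_tot = float(((observed - center) ** 2).sum())
    press = float(((observed - predicted) ** 2).sum())
    return {
        "q2": float(r ** 2),
        "q2_press": 1.0 - press / ss_tot if ss_tot > 0 else np.nan,
        "rmse": float(np.sqrt(np.mean((observed - predicted) ** 2))),
    }


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of a response/descriptor table."""
    if table.shape[1] < 2:
        raise MetricError("need at least 2 columns for a correlation matrix")
    const = [c for c in table.columns if np.asarray(table[c], float).std() == 0]
    if const:
        raise MetricError(f"constant column(s): {const}")
    return table.astype(float).corr(method="pearson")


# ---------------------------------------------------------------------------
# six-model registry
# ---------------------------------------------------------------------------

MODEL_NAMES = [
    "ALL_regression", "ALL_CPANN",
    "regression_1", "regression_2",
    "cpann_1", "cpann_2",
]


@dataclass
class ModelRegistry:
    """All six study models fitted on train, evaluated on test, per response."""

    summary: pd.DataFrame                     # model × response metrics, long form
    regressions: dict[tuple[str, str], RegressionModel]
    cpanns: dict[str, object]                 # entry name → CPANN or per-response dict
    dcw_models: dict[str, DCWModel]           # per-response DCW (model-2 family)
    dcw_shared: DCWModel                      # the 28th descriptor column's model

    def summary_csv(self, path) -> None:
        self.summary.to_csv(path, index=False)


def _informative_columns(train_block: pd.DataFrame) -> list[str]:
    """Columns usable in an OLS design: non-constant, not duplicating a kept one.

    Synthetic single-core datasets share cage-derived counts (ring closures,
    aromatic atoms, ...) across all compounds; those columns carry no signal
    and would make the 28-descriptor design singular.
    """
    from scipy import linalg

    cols = [c for c in train_block.columns
            if train_block[c].to_numpy(dtype=float).std() > 0]
    Z = train_block[cols].to_numpy(dtype=float)
    Z = (Z - Z.mean(axis=0)) / Z.std(axis=0)
    _, R, piv = linalg.qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag[0] * 1e-7 if diag.size else 0.0
    keep_idx = sorted(piv[k] for k in range(len(diag)) if diag[k] > tol)
    return [cols[j] for j in keep_idx]


def _registry_row(model, response, train_metrics, test_metrics):
    return {
        "model": model, "response": response,
        "r2_train": train_metrics["q2"], "rmse_train": train_metrics["rmse"],
        "q2_test": test_metrics["q2"], "q2_press_test": test_metrics["q2_press"],
        "rmse_test": test_metrics["rmse"],
    }


def build_registry(
    dataset: SyntheticDataset,
    *,
    dcw_params: dict | None = None,
    cpann_params: dict | None = None,
    seed: int = 0,
) -> ModelRegistry:
    """Fit the six-model registry on a dataset with a recorded split.

    ``cpann_params`` may override per-entry net sizes; defaults follow the
    study architectures (ALL: 20×20/600 epochs; models 1–2: 14×14 with
    400/300 epochs). The shared DCW descriptor column is optimized against
    the average binding score; the model-2 entries refit DCW per response.
    """
    dcw_params = dict(dcw_params or {})
    dcw_params.setdefault("seed", seed)
    cp = {
        "ALL_CPANN": {"grid_n": 20, "n_epochs": 600},
        "cpann_1": {"grid_n": 14, "n_epochs": 400},
        "cpann_2": {"grid_n": 14, "n_epochs": 300},
    }
    for key, override in (cpann_params or {}).items():
        cp[key].update(override)

    train, test = dataset.train_ids(), dataset.test_ids()
    desc, resp = dataset.descriptor_table, dataset.response_table
    missing = [c for c in ("QPpolrz", "TD") if c not in desc.columns]
    if missing:
        raise RegistryError(f"descriptor table lacks predictor columns: {missing}")
    smiles = dataset.smiles

    # shared DCW column (optimized against the average binding score)
    dcw_shared = optimize_weights(
        smiles.loc[train], resp.loc[train, "AverageBScore"],
        train_ids=list(train), **dcw_params,
    )
    dcw_col = pd.Series(
        [dcw_shared.dcw_from_smiles(s) for s in smiles], index=smiles.index, name="DCW"
    )
    desc28 = desc.join(dcw_col)

    rows = []
    regressions: dict[tuple[str, str], RegressionModel] = {}
    cpanns: dict[str, object] = {}
    dcw_models: dict[str, DCWModel] = {}

    def eval_reg(name: str, predictors: pd.DataFrame):
        for response in RESPONSES:
            y_tr = resp.loc[train, response]
            model = fit_ols(predictors.loc[train], y_tr,
                            predictor_names=list(predictors.columns), ids=list(train))
            tr = evaluate(y_tr, model.predict(predictors.loc[train]),
                          y_train_mean=float(y_tr.mean()))
            te = evaluate(resp.loc[test, response], model.predict(predictors.loc[test]),
                          y_train_mean=float(y_tr.mean()))
            regressions[(name, response)] = model
            rows.append(_registry_row(name, response, tr, te))

    def eval_cpann(name: str, predictors: pd.DataFrame):
        net = CPANN(seed=seed, **cp[name])
        net.fit(predictors.loc[train].to_numpy(), resp.loc[train].to_numpy())
        pred_tr = net.predict(predictors.loc[train].to_numpy())
        pred_te = net.predict(predictors.loc[test].to_numpy())
        cpanns[name] = net
        for j, response in enumerate(RESPONSES):
            y_tr = resp.loc[train, response]
            tr = evaluate(y_tr, pred_tr[:, j], y_train_mean=float(y_tr.mean()))
            te = evaluate(resp.loc[test, response], pred_te[:, j],
                          y_train_mean=float(y_tr.mean()))
            rows.append(_registry_row(name, response, tr, te))

    eval_reg("ALL_regression", desc28[_informative_columns(desc28.loc[train])])
    eval_cpann("ALL_CPANN", desc28)
    eval_reg("regression_1", desc28[["QPpolrz", "TD"]])
    eval_cpann("cpann_1", desc28[["QPpolrz", "TD"]])

    # model-2 family: per-response DCW, frozen before touching the test set
    cpann2: dict[str, CPANN] = {}
    for response in RESPONSES:
        y_tr = resp.loc[train, response]
        dm = optimize_weights(smiles.loc[train], y_tr,
                              train_ids=list(train), **dcw_params)
        dcw_models[response] = dm
        col = pd.DataFrame(
            {"DCW": [dm.dcw_from_smiles(s) for s in smiles]}, index=smiles.index
        )
        model = fit_ols(col.loc[train], y_tr, predictor_names=["DCW"], ids=list(train))
        tr = evaluate(y_tr, model.predict(col.loc[train]), y_train_mean=float(y_tr.mean()))
        te = evaluate(resp.loc[test, response], model.predict(col.loc[test]),
                      y_train_mean=float(y_tr.mean()))
        regressions[("regression_2", response)] = model
        rows.append(_registry_row("regression_2", response, tr, te))

        net = CPANN(seed=seed, **cp["cpann_2"])
        net.fit(col.loc[train].to_numpy(), y_tr.to_numpy())
        tr = evaluate(y_tr, net.predict(col.loc[train].to_numpy()).ravel(),
                      y_train_mean=float(y_tr.mean()))
        te = evaluate(resp.loc[test, response],
                      net.predict(col.loc[test].to_numpy()).ravel(),
                      y_train_mean=float(y_tr.mean()))
        cpann2[response] = net
        rows.append(_registry_row("cpann_2", response, tr, te))
    cpanns["cpann_2"] = cpann2

    summary = pd.DataFrame(rows)
    return ModelRegistry(
        summary=summary, regressions=regressions, cpanns=cpanns,
        dcw_models=dcw_models, dcw_shared=dcw_shared,
    )
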