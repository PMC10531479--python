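"""Leverage-based applicability domain (Williams plot).

The leverage of a compound against the training design matrix,
``h = x'(X'X)⁻¹x`` with an intercept column, measures how far its
descriptors sit from the training chemical space; the conventional warning
threshold is ``h* = 3(p+1)/n``. Compounds with ``h > h*`` are structural
outliers; compounds whose standardized residual exceeds ±3σ are response
outliers. Standardized residuals divide by the training residual SD with a
p+1 degrees-of-freedom correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SingularityError
from .regression import RegressionModel
from .synthetic import SyntheticDataset


def leverages(X_train, X_query=None) -> np.ndarray:
    """Diagonal of the hat projection for training (or query) rows.

    Query leverages are quadratic forms against the *training* design
    matrix; training leverages sum to p+1 (trace of the projection).
    """
    X_train = np.asarray(X_train, dtype=float)
    if X_train.ndim == 1:
        X_train = X_train[:, None]
    n, p = X_train.shape
    design = np.column_stack([np.ones(n), X_train])
    xtx = design.T @ design
    if np.linalg.matrix_rank(design) < p + 1:
        raise SingularityError("rank-deficient training design matrix")
    xtx_inv = np.linalg.inv(xtx)
    if X_query is None:
        Q = design
    else:
        X_query = np.asarray(X_query, dtype=float)
        if X_query.ndim == 1:
            X_query = X_query[:, None]
        Q = np.column_stack([np.ones(len(X_query)), X_query])
    return np.einsum("ij,jk,ik->i", Q, xtx_inv, Q)


def warning_leverage(n: int, p: int) -> float:
    """Conventional Williams-plot threshold h* = 3(p+1)/n."""
    if n <= p + 1:
        raise ParameterError(f"need n > p+1, got n={n}, p={p}")
    return 3.0 * (p + 1) / n


@dataclass
class WilliamsData:
    """Per-compound leverages, standardized residuals, and outlier flags."""

    table: pd.DataFrame     # h, std_residual, set, structural/response flags
    h_star: float

    def flagged(self) -> pd.DataFrame:
        return self.table[self.table.structural_outlier | self.table.response_outlier]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=True, index_label="id")

    def plot(self, path=None):
        """Standardized residual vs leverage, with h* and ±3σ bounds."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4.5))
        for label, marker in (("train", "o"), ("test", "^")):
            sub = self.table[self.table["set"] == label]
            ax.scatter(sub["leverage"], sub["std_residual"], s=18,
                       marker=marker, label=label, alpha=0.75)
        ax.axvline(self.h_star, ls="--", c="k", lw=1)
        for y in (-3, 3):
            ax.axhline(y, ls=":", c="r", lw=1)
        ax.set_xlabel("leverage h")
        ax.set_ylabel("standardized residual")
        ax.legend()
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def williams(model: RegressionModel, dataset: SyntheticDataset,
             response: str, dcw_column: pd.Series | None = None) -> WilliamsData:
    """Williams-plot table for a fitted regression model over a dataset.

    ``dcw_column`` supplies the DCW descriptor when the model uses it (the
    descriptor table holds only structure-derived columns).
    """
    desc = dataset.descriptor_table
    if dcw_column is not None:
        desc = desc.join(pd.Series(dcw_column, name="DCW"))
    X = desc[model.predictor_names]
    y = dataset.response_table[response]
    train, test = dataset.train_ids(), dataset.test_ids()

    h_train = leverages(X.loc[train])
    h_test = leverages(X.loc[train], X.loc[test])
    h = pd.Series(np.concatenate([h_train, h_test]),
                  index=train.append(test)).loc[dataset.ids]

    resid = y - model.predict(X.to_numpy())
    n, p = len(train), len(model.predictor_names)
    s = float(np.sqrt((resid.loc[train] ** 2).sum() / (n - p - 1)))
    std_resid = resid / s if s > 0 else resid * 0.0

    h_star = warning_leverage(n, p)
    table = pd.DataFrame({
        "leverage": h,
        "std_residual": std_resid,
        "set": dataset.split.loc[dataset.ids],
        "structural_outlier": h > h_star,
        "response_outlier": std_resid.abs() > 3.0,
    })
    return WilliamsData(table=table, h_star=h_star)
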