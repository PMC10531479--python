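"""Counter-propagation artificial neural network (CPANN).

A Kohonen self-organizing map whose square input-weight layer clusters
objects by their descriptors while a congruent output-weight layer —
same lattice, same neurons — stores the response values. Training moves
both layers of every neuron inside a shrinking neighborhood of the
best-matching unit (BMU) toward the presented object's descriptor and
target vectors; prediction is a pure lookup of the BMU's output weights.

Numerical choices (all exposed as parameters):

* planar (non-toroidal) rectangular lattice, Euclidean lattice distance;
* triangular neighborhood kernel, linear falloff to 0 at the current radius;
* radius decays linearly from ``grid_n / 2`` to 0 over the epochs;
* learning rate decays linearly from ``lr_max`` to ``lr_min``;
* per-column min-max normalization of X and Y from the training data;
  query objects are clipped into [0, 1] with a warning;
* object presentation order reshuffled every epoch from the run seed;
* BMU ties broken by the lowest row-major neuron index.

Because every update is a convex combination of a weight in [0, 1] and a
normalized value in [0, 1], trained weights stay in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DataError,
    DimensionError,
    MetricError,
    ParameterError,
    StateError,
)


@dataclass
class MapSet:
    """Exported views of a trained map."""

    top_map: pd.DataFrame            # per object: BMU row/col
    weight_maps: dict[str, np.ndarray]   # per descriptor: n×n plane
    output_maps: dict[str, np.ndarray]   # per response: n×n plane


class CPANN:
    """Counter-propagation network on an ``grid_n × grid_n`` neuron lattice."""

    def __init__(self, grid_n: int = 14, n_epochs: int = 400,
                 lr_max: float = 0.5, lr_min: float = 0.01, seed: int = 0):
        if grid_n < 1:
            raise ParameterError(f"grid_n must be >= 1, got {grid_n}")
        if n_epochs < 1:
            raise ParameterError(f"n_epochs must be >= 1, got {n_epochs}")
        if not 0 <= lr_min <= lr_max:
            raise ParameterError("need 0 <= lr_min <= lr_max")
        self.grid_n = grid_n
        self.n_epochs = n_epochs
        self.lr_max = lr_max
        self.lr_min = lr_min
        self.seed = seed
        self.input_weights: np.ndarray | None = None   # (n*n, p)
        self.output_weights: np.ndarray | None = None  # (n*n, r)
        self.x_min = self.x_range = None
        self.y_min = self.y_range = None
        self.x_names: list[str] = []
        self.y_names: list[str] = []
        self.qe_history: list[float] = []
        rows, cols = np.divmod(np.arange(grid_n * grid_n), grid_n)
        self._coords = np.column_stack([rows, cols]).astype(float)

    # -- normalization -----------------------------------------------------
    @staticmethod
    def _ranges(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        lo = M.min(axis=0)
        rng = M.max(axis=0) - lo
        rng[rng == 0] = 1.0          # constant column: map to 0
        return lo, rng

    def _norm_x(self, X: np.ndarray, clip: bool = False) -> np.ndarray:
        Z = (X - self.x_min) / self.x_range
        if clip and ((Z < 0).any() or (Z > 1).any()):
            warnings.warn(
                "query descriptors outside the training range were clipped to [0, 1]",
                stacklevel=2,
            )
            Z = np.clip(Z, 0.0, 1.0)
        return Z

    # -- training ----------------------------------------------------------
    def fit(self, X, Y) -> "CPANN":
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if Y.ndim == 1:
            Y = Y[:, None]
        if np.isnan(X).any() or np.isnan(Y).any():
            bad = sorted(
                set(np.nonzero(np.isnan(X))[0]) | set(np.nonzero(np.isnan(Y))[0])
            )
            raise DataError(f"NaN values in rows {bad}")
        if Y.shape[1] < 1:
            raise DataError("need at least one response column")
        if isinstance(X, pd.DataFrame):
            self.x_names = list(X.columns)
        self.x_min, self.x_range = self._ranges(X)
        self.y_min, self.y_range = self._ranges(Y)
        Xn = self._norm_x(X)
        Yn = (Y - self.y_min) / self.y_range

        n_neurons = self.grid_n * self.grid_n
        rng = np.random.default_rng(self.seed)
        W = rng.uniform(0.0, 1.0, size=(n_neurons, X.shape[1]))
        O = rng.uniform(0.0, 1.0, size=(n_neurons, Y.shape[1]))
        coords = self._coords
        r_max = self.grid_n / 2.0
        denom = max(self.n_epochs - 1, 1)
        self.qe_history = []
        for epoch in range(self.n_epochs):
            frac = epoch / denom
            lr = self.lr_max + (self.lr_min - self.lr_max) * frac
            radius = r_max * (1.0 - frac)
            order = rng.permutation(len(Xn))
            for i in order:
                x = Xn[i]
                d2 = ((W - x) ** 2).sum(axis=1)
                bmu = int(d2.argmin())
                ld = np.sqrt(((coords - coords[bmu]) ** 2).sum(axis=1))
                kernel = 1.0 - ld / (radius + 1.0)
                mask = kernel > 0.0
                k = (lr * kernel[mask])[:, None]
                W[mask] += k * (x - W[mask])
                O[mask] += k * (Yn[i] - O[mask])
            # quantization error after this epoch
            d = np.sqrt(
                (((Xn[:, None, :] - W[None, :, :]) ** 2).sum(-1)).min(axis=1)
            )
            self.qe_history.append(float(d.mean()))
        self.input_weights, self.output_weights = W, O
        return self

    # -- inference ---------------------------------------------------------
    def _check_fitted(self) -> None:
        if self.input_weights is None:
            raise StateError("CPANN model is not trained")

    def best_matching_unit(self, x) -> tuple[int, int]:
        """Lattice (row, col) of the neuron nearest to a *normalized* vector."""
        self._check_fitted()
        x = np.asarray(x, dtype=float)
        if x.shape != (self.input_weights.shape[1],):
            raise DimensionError(
                f"expected {self.input_weights.shape[1]} components, got {x.shape}"
            )
        d2 = ((self.input_weights - x) ** 2).sum(axis=1)
        bmu = int(d2.argmin())          # argmin → lowest row-major index on ties
        return bmu // self.grid_n, bmu % self.grid_n

    def predict(self, X) -> np.ndarray:
        """De-normalized output weights of each object's BMU (pure lookup)."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        Xn = self._norm_x(X, clip=True)
        out = np.empty((len(Xn), self.output_weights.shape[1]))
        for i, x in enumerate(Xn):
            r, c = self.best_matching_unit(x)
            out[i] = self.output_weights[r * self.grid_n + c]
        out = self.y_min + out * self.y_range
        return out[0] if single else out

    def export_maps(self, X, ids=None, x_names=None, y_names=None) -> MapSet:
        """Top map for the given objects plus all weight/output planes."""
        self._check_fitted()
        X = np.asarray(X, dtype=float)
        Xn = self._norm_x(X, clip=True)
        bmus = [self.best_matching_unit(x) for x in Xn]
        top = pd.DataFrame(bmus, columns=["row", "col"],
                           index=ids if ids is not None else range(len(Xn)))
        n = self.grid_n
        x_names = list(x_names) if x_names is not None else [
            f"x{j}" for j in range(self.input_weights.shape[1])
        ]
        y_names = list(y_names) if y_names is not None else [
            f"y{j}" for j in range(self.output_weights.shape[1])
        ]
        weight_maps = {
            name: self.input_weights[:, j].reshape(n, n)
            for j, name in enumerate(x_names)
        }
        output_maps = {
            name: self.output_weights[:, j].reshape(n, n)
            for j, name in enumerate(y_names)
        }
        return MapSet(top_map=top, weight_maps=weight_maps, output_maps=output_maps)


def loo_cv(X, Y, *, grid_n: int = 14, n_epochs: int = 400,
           lr_max: float = 0.5, lr_min: float = 0.01, seed: int = 0) -> dict:
    """Leave-one-out cross-validation of a CPANN configuration.

    Retrains n times, each run omitting one object and predicting it with
    the refitted net. Returns per-response Q²cv (squared Pearson r between
    observed and LOO-predicted) and RMSEcv, plus the LOO prediction matrix.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n = len(X)
    if n < 3:
        raise ParameterError(f"LOO-CV needs at least 3 objects, got {n}")
    if (Y.std(axis=0) == 0).any():
        const = [j for j in range(Y.shape[1]) if Y[:, j].std() == 0]
        raise MetricError(f"constant response column(s) {const}: Q2cv undefined")
    preds = np.empty_like(Y)
    for i in range(n):
        keep = np.arange(n) != i
        net = CPANN(grid_n=grid_n, n_epochs=n_epochs,
                    lr_max=lr_max, lr_min=lr_min, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # left-out object may clip
            net.fit(X[keep], Y[keep])
            preds[i] = net.predict(X[i])
    q2, rmse = [], []
    for j in range(Y.shape[1]):
        r = np.corrcoef(Y[:, j], preds[:, j])[0, 1] if preds[:, j].std() > 0 else 0.0
        q2.append(float(r ** 2))
        rmse.append(float(np.sqrt(np.mean((Y[:, j] - preds[:, j]) ** 2))))
    return {"q2cv": np.array(q2), "rmsecv": np.array(rmse), "predictions": preds}
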