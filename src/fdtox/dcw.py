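"""SMILES-attribute optimal descriptor (DCW) with Monte-Carlo weight tuning.

The optimal descriptor of a molecule is

    DCW(m) = sum_k  count_k(m) * CW(A_k)

where A_k are local SMILES attributes (single tokens, or adjacent token
pairs) and CW are correlation weights tuned by a seeded hill-climbing
Monte-Carlo search to maximize |Pearson r| between DCW and the training
endpoint. Rare attributes — present in fewer than ``threshold`` training
compounds — are frozen at weight 0 so the model cannot memorize
singletons. A final OLS line (endpoint ~ DCW) calibrates the raw
descriptor onto endpoint units.

Attributes are extracted from RDKit-canonicalized SMILES so training is
reproducible across input atom orderings.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from scipy import stats

from .errors import OptimizationError, ParseError

# one SMILES token: bracket atom, two-letter organic-subset element,
# %nn ring closure, or any single symbol
_TOKEN = re.compile(r"\[[^\]]*\]|Cl|Br|%\d{2}|.")


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into attribute tokens.

    Multi-character atoms (Cl, Br, bracket atoms) and two-digit ring-bond
    labels are single tokens; everything else is one character.
    """
    if not smiles:
        raise ParseError("cannot tokenize an empty SMILES string")
    return _TOKEN.findall(smiles)


def extract_attributes(smiles: str, order: int = 2) -> Counter:
    """Multiset of SMILES attributes of a molecule.

    Order 1: single tokens of the canonical SMILES. Order 2: order-1 tokens
    plus adjacent token pairs, each pair written in lexicographic order so
    the attribute is direction-independent.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ParseError(f"unparseable SMILES: {smiles!r}")
    tokens = tokenize(Chem.MolToSmiles(mol))
    attrs = Counter(tokens)
    if order == 2:
        for a, b in zip(tokens, tokens[1:]):
            lo, hi = sorted((a, b))
            attrs[f"{lo}|{hi}"] += 1
    return attrs


@dataclass
class DCWModel:
    """Fitted attribute→correlation-weight map plus calibration line."""

    weights: dict[str, float]
    order: int
    threshold: int
    n_epochs: int
    step: float
    seed: int
    slope: float = 1.0
    intercept: float = 0.0
    train_ids: list[str] = field(default_factory=list)
    train_r_history: list[float] = field(default_factory=list)
    unknown_attribute_count: int = 0

    def dcw_value(self, attributes: Counter) -> float:
        """Sum of count × weight; unknown/sub-threshold attributes add 0."""
        total = 0.0
        for attr, count in attributes.items():
            w = self.weights.get(attr)
            if w is None:
                self.unknown_attribute_count += 1
            else:
                total += count * w
        return total

    def dcw_from_smiles(self, smiles: str) -> float:
        return self.dcw_value(extract_attributes(smiles, self.order))

    def predict(self, smiles_list) -> np.ndarray:
        """Calibrated endpoint predictions (frozen weights, no refitting)."""
        raw = np.array([self.dcw_from_smiles(s) for s in smiles_list])
        return self.intercept + self.slope * raw

    def to_json(self, path) -> None:
        payload = {
            "weights": self.weights, "order": self.order,
            "threshold": self.threshold, "n_epochs": self.n_epochs,
            "step": self.step, "seed": self.seed,
            "slope": self.slope, "intercept": self.intercept,
            "train_ids": self.train_ids,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "DCWModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def _pearson_abs(x: np.ndarray, y: np.ndarray) -> float:
    sx = x.std()
    if sx == 0:
        return 0.0
    return abs(float(np.corrcoef(x, y)[0, 1]))


def optimize_weights(
    smiles_list,
    endpoint,
    *,
    order: int = 2,
    threshold: int = 3,
    n_epochs: int = 30,
    step: float = 0.1,
    seed: int = 0,
    train_ids: list[str] | None = None,
) -> DCWModel:
    """Fit correlation weights by greedy Monte-Carlo hill climbing.

    All active weights start at 1.0. Each move perturbs one randomly chosen
    active weight by ±step and is kept iff |Pearson r(DCW, endpoint)| on the
    training set does not decrease; one epoch makes as many moves as there
    are active attributes. Deterministic for a fixed seed.
    """
    smiles_list = list(smiles_list)
    endpoint = np.asarray(endpoint, dtype=float)
    if len(smiles_list) < 10:
        raise OptimizationError(
            f"need at least 10 training compounds, got {len(smiles_list)}"
        )
    if endpoint.std() == 0:
        raise OptimizationError("endpoint has zero variance on the training set")

    attr_sets = [extract_attributes(s, order) for s in smiles_list]
    presence = Counter()
    for attrs in attr_sets:
        presence.update(attrs.keys())
    active = sorted(a for a, n in presence.items() if n >= threshold)
    if not active:
        raise OptimizationError(
            f"no active attributes: none occur in >= {threshold} training compounds"
        )
    col = {a: j for j, a in enumerate(active)}
    counts = np.zeros((len(smiles_list), len(active)))
    for i, attrs in enumerate(attr_sets):
        for a, n in attrs.items():
            if a in col:
                counts[i, col[a]] = n

    rng = np.random.default_rng(seed)
    w = np.ones(len(active))
    dcw = counts @ w
    best = _pearson_abs(dcw, endpoint)
    history = [best]
    for _ in range(n_epochs):
        for _ in range(len(active)):
            j = int(rng.integers(len(active)))
            delta = step if rng.random() < 0.5 else -step
            cand = dcw + delta * counts[:, j]
            r = _pearson_abs(cand, endpoint)
            if r >= best:
                w[j] += delta
                dcw = cand
                best = r
                history.append(best)

    # calibration line on the training set only
    if dcw.std() == 0:
        slope, intercept = 0.0, float(endpoint.mean())
    else:
        res = stats.linregress(dcw, endpoint)
        slope, intercept = float(res.slope), float(res.intercept)
    weights = {a: float(w[col[a]]) for a in active}
    # sub-threshold attributes are recorded with weight fixed at 0
    for a in presence:
        if a not in weights:
            weights[a] = 0.0
    return DCWModel(
        weights=weights, order=order, threshold=threshold, n_epochs=n_epochs,
        step=step, seed=seed, slope=slope, intercept=intercept,
        train_ids=list(train_ids) if train_ids is not None else [],
        train_r_history=history,
    )
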