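"""Structural-alert (toxicophore) screening for aquatic toxicity.

The 14 aquatic-toxicity alerts named in the study (TA identifiers from the
ToxAlerts catalogue) are shipped as a local SMARTS library, so screening
needs no web service. The authoritative ToxAlerts patterns sit behind a
login; the SMARTS here are independent approximations written from each
alert's printed chemical name, and the contract of each pattern is its
positive/negative control pair (both shipped with the library and enforced
by the test suite), not parity with OCHEM.

Match counting is symmetry-deduplicated (unique atom sets) and
non-overlapping (greedy disjoint selection), so e.g. a tetra-ammonium
compound counts 4 distinct ``NH3+`` hits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from rdkit import Chem

from .descriptors import parse_smiles
from .errors import JoinError, LoadError
from .synthetic import SyntheticDataset

#: score below which a compound is considered of low aquatic-toxicity concern
DEFAULT_CONCERN_THRESHOLD = 5000.0


@dataclass(frozen=True)
class AlertDefinition:
    alert_id: str
    name: str
    smarts: tuple[str, ...]
    positive_control: str = ""
    negative_control: str = ""
    note: str = ""
    _compiled: tuple = field(default=(), compare=False, repr=False)

    def compiled(self):
        if not self._compiled:
            patterns = []
            for s in self.smarts:
                patt = Chem.MolFromSmarts(s)
                if patt is None:
                    raise LoadError(f"alert {self.alert_id}: invalid SMARTS {s!r}")
                patterns.append(patt)
            object.__setattr__(self, "_compiled", tuple(patterns))
        return self._compiled


@dataclass
class AlertHit:
    compound_id: str
    alert_id: str
    match_count: int


class AlertLibrary:
    """An ordered, id-unique collection of alert definitions."""

    def __init__(self, alerts: list[AlertDefinition]):
        ids = [a.alert_id for a in alerts]
        dup = sorted({i for i in ids if ids.count(i) > 1})
        if dup:
            raise LoadError(f"duplicate alert_id(s): {dup}")
        for a in alerts:
            a.compiled()          # fail fast on bad SMARTS
        self.alerts = list(alerts)
        self.by_id = {a.alert_id: a for a in alerts}

    def __len__(self) -> int:
        return len(self.alerts)

    def __iter__(self):
        return iter(self.alerts)

    def save(self, path) -> None:
        payload = {"alerts": [
            {"alert_id": a.alert_id, "name": a.name, "smarts": list(a.smarts),
             "positive_control": a.positive_control,
             "negative_control": a.negative_control, "note": a.note}
            for a in self.alerts
        ]}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _parse_payload(payload: dict) -> list[AlertDefinition]:
    alerts = []
    for raw in payload.get("alerts", []):
        alerts.append(AlertDefinition(
            alert_id=raw["alert_id"], name=raw.get("name", ""),
            smarts=tuple(raw["smarts"]),
            positive_control=raw.get("positive_control", ""),
            negative_control=raw.get("negative_control", ""),
            note=raw.get("note", ""),
        ))
    return alerts


def load_alert_library(path=None, include_defaults: bool = True) -> AlertLibrary:
    """Load the default library, a user file, or both (user entries override).

    With ``include_defaults=False`` and no path, the library is empty and
    screening returns no hits.
    """
    alerts: dict[str, AlertDefinition] = {}
    if include_defaults:
        text = resources.files("fdtox").joinpath("data/aquatic_alerts.json").read_text()
        for a in _parse_payload(json.loads(text)):
            alerts[a.alert_id] = a
    if path is not None:
        try:
            with open(path) as fh:
                payload = json.load(fh)
        except (OSError, json.JSONDecodeError) as exc:
            raise LoadError(f"cannot load alert library {path}: {exc}") from exc
        user = _parse_payload(payload)
        ids = [a.alert_id for a in user]
        dup = sorted({i for i in ids if ids.count(i) > 1})
        if dup:
            raise LoadError(f"duplicate alert_id(s) in user file: {dup}")
        for a in user:
            alerts[a.alert_id] = a
    return AlertLibrary(list(alerts.values()))


def _disjoint_match_count(mol: Chem.Mol, alert: AlertDefinition) -> int:
    """Distinct non-overlapping matches over all of an alert's patterns."""
    atom_sets: list[frozenset] = []
    for patt in alert.compiled():
        for match in mol.GetSubstructMatches(patt, uniquify=True):
            s = frozenset(match)
            if s not in atom_sets:
                atom_sets.append(s)
    taken: set[int] = set()
    count = 0
    for s in sorted(atom_sets, key=lambda s: (len(s), sorted(s))):
        if not (s & taken):
            taken |= s
            count += 1
    return count


def screen(molecule, library: AlertLibrary, compound_id: str = "") -> list[AlertHit]:
    """Screen one molecule (SMILES or Mol) against a library.

    Returns one hit per matched alert, carrying the disjoint match count;
    alerts that do not match are omitted. Deterministic, and invariant to
    SMILES canonicalization of the input.
    """
    mol = parse_smiles(molecule) if isinstance(molecule, str) else molecule
    hits = []
    for alert in library:
        n = _disjoint_match_count(mol, alert)
        if n >= 1:
            hits.append(AlertHit(compound_id=compound_id, alert_id=alert.alert_id,
                                 match_count=n))
    return hits


def screening_report(
    dataset: SyntheticDataset,
    library: AlertLibrary,
    predicted_scores: pd.Series,
    concern_threshold: float = DEFAULT_CONCERN_THRESHOLD,
) -> pd.DataFrame:
    """Per-compound alert annotation joined with predicted average scores.

    Columns: predicted score, semicolon-joined ``alert:count`` pairs, total
    alert count, the alert-set signature used for grouping (the study's
    "groups of FDs sharing alerts" analogue), and a ``review`` flag for
    compounds predicted above the concern threshold with **no** alert —
    potentially toxic structures the alert catalogue cannot explain.
    """
    ids = list(dataset.ids)
    pred = pd.Series(predicted_scores)
    if pred.index.duplicated().any():
        raise JoinError("duplicate compound ids in predicted scores")
    missing = [i for i in ids if i not in pred.index]
    if missing:
        raise JoinError(f"predicted scores missing for compounds: {missing[:5]}")
    rows = []
    for rec in dataset.compounds:
        hits = screen(rec.smiles, library, compound_id=rec.cid)
        signature = ",".join(sorted(h.alert_id for h in hits))
        score = float(pred.loc[rec.cid])
        rows.append({
            "id": rec.cid,
            "predicted_avg_bscore": score,
            "alerts": ";".join(f"{h.alert_id}:{h.match_count}" for h in hits),
            "n_alerts": sum(h.match_count for h in hits),
            "alert_signature": signature,
            "review": bool(score >= concern_threshold and not hits),
        })
    return pd.DataFrame(rows).set_index("id")


def group_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Groups of compounds sharing an alert-set signature, by mean score."""
    grouped = (
        report[report.alert_signature != ""]
        .groupby("alert_signature")
        .agg(n_compounds=("predicted_avg_bscore", "size"),
             mean_score=("predicted_avg_bscore", "mean"))
        .sort_values("mean_score", ascending=False)
        .reset_index()
    )
    grouped.insert(0, "group", range(1, len(grouped) + 1))
    return grouped
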