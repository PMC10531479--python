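"""End-to-end orchestration: data → descriptors → DCW → models → AD → alerts.

A single YAML-able config dict drives the run; every random stage draws from
explicit seeds so two runs with equal manifests produce byte-equal CSVs.
The output bundle mirrors the study's artifact set: the descriptor table,
the fitted optimal-descriptor model, the six-model registry summary,
Williams applicability-domain tables for the predictive regression models,
Kohonen map exports, the structural-alert report, and a ranked
prioritization table (descending predicted average binding score, annotated
with alert and applicability-domain flags).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alerts import (
    DEFAULT_CONCERN_THRESHOLD,
    group_summary,
    load_alert_library,
    screening_report,
)
from .domain import williams
from .errors import ConfigurationError, DataError, JoinError
from .regression import build_registry
from .synthetic import (
    RESPONSES,
    GeneratorConfig,
    SyntheticDataset,
    generate_dataset,
    load_compound_table,
)

log = logging.getLogger("fdtox")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "data": {"mode": "synthetic", "path": None},
    "generator": {},                 # GeneratorConfig field overrides
    "dcw": {"order": 2, "threshold": 3, "n_epochs": 30, "step": 0.1},
    "cpann": {},                     # per-entry {grid_n, n_epochs} overrides
    "ranking_model": "regression_1",  # or "cpann_1"
    "concern_threshold": DEFAULT_CONCERN_THRESHOLD,
    "alert_library": None,           # optional user JSON path
    "render_plots": True,
    "out_dir": "fdtox_out",
}


def merge_config(overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))   # deep copy
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def resolve_dataset(cfg: dict) -> SyntheticDataset:
    mode = cfg["data"]["mode"]
    if mode == "synthetic":
        gen = GeneratorConfig(seed=cfg["seed"], **cfg["generator"])
        return generate_dataset(gen)
    if mode == "csv":
        path = cfg["data"]["path"]
        if not path or not Path(path).exists():
            raise DataError(f"data.mode=csv but no table at {path!r}")
        # recorded split honored verbatim; generation skipped entirely
        return load_compound_table(path)
    raise ConfigurationError(f"unknown data mode {mode!r}")


def rank_compounds(predictions: pd.Series, alert_report: pd.DataFrame,
                   ad_flags: pd.Series) -> pd.DataFrame:
    """Prioritization table: descending predicted score, stable id tie-break.

    Out-of-domain compounds are retained and flagged, never dropped.
    """
    pred = pd.Series(predictions, name="predicted_avg_bscore")
    if pred.index.duplicated().any():
        raise JoinError("duplicate compound ids in predictions")
    if set(pred.index) != set(alert_report.index) or set(pred.index) != set(ad_flags.index):
        raise JoinError("compound ids do not align across predictions/alerts/AD")
    table = pd.DataFrame({
        "predicted_avg_bscore": pred,
        "alerts": alert_report["alerts"],
        "n_alerts": alert_report["n_alerts"],
        "review": alert_report["review"],
        "out_of_ad": ad_flags.astype(bool),
    })
    table = (
        table.reset_index(names="id")
        .sort_values(["predicted_avg_bscore", "id"], ascending=[False, True],
                     kind="mergesort")
        .set_index("id")
    )
    table.insert(0, "rank", range(1, len(table) + 1))
    return table


def run_all(cfg: dict | None = None, out_dir=None) -> dict:
    """Run the full analysis; returns the output bundle and writes artifacts.

    Any stage failure aborts with the stage name attached to the exception.
    """
    cfg = merge_config(cfg)
    out = Path(out_dir if out_dir is not None else cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[str] = []
    stage = "configure"

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        outputs.append(name)

    try:
        stage = "data"
        dataset = resolve_dataset(cfg)
        emit("dataset.csv", dataset.to_csv)

        stage = "descriptors"
        emit("descriptors.csv",
             lambda p: dataset.descriptor_table.to_csv(p, index_label="id"))
        with open(out / "descriptor_provenance.json", "w") as fh:
            json.dump(dataset.provenance, fh, indent=2, sort_keys=True)
        outputs.append("descriptor_provenance.json")

        stage = "models"
        registry = build_registry(
            dataset, dcw_params=cfg["dcw"], cpann_params=cfg["cpann"], seed=cfg["seed"]
        )
        emit("registry_summary.csv", registry.summary_csv)
        emit("dcw_model.json", registry.dcw_shared.to_json)
        equations = {
            f"{m}:{r}": registry.regressions[(m, r)].equation()
            for (m, r) in registry.regressions
        }
        with open(out / "regression_equations.json", "w") as fh:
            json.dump(equations, fh, indent=2, sort_keys=True)
        outputs.append("regression_equations.json")

        stage = "applicability_domain"
        dcw_col = pd.Series(
            [registry.dcw_models["AverageBScore"].dcw_from_smiles(s)
             for s in dataset.smiles],
            index=dataset.ids, name="DCW",
        )
        wil1 = williams(registry.regressions[("regression_1", "AverageBScore")],
                        dataset, "AverageBScore")
        wil2 = williams(registry.regressions[("regression_2", "AverageBScore")],
                        dataset, "AverageBScore", dcw_column=dcw_col)
        emit("williams_regression_1.csv", wil1.to_csv)
        emit("williams_regression_2.csv", wil2.to_csv)
        if cfg["render_plots"]:
            emit("williams_regression_1.svg", wil1.plot)
            emit("williams_regression_2.svg", wil2.plot)

        stage = "maps"
        net = registry.cpanns["ALL_CPANN"]
        desc28 = dataset.descriptor_table.join(
            pd.Series([registry.dcw_shared.dcw_from_smiles(s) for s in dataset.smiles],
                      index=dataset.ids, name="DCW")
        )
        maps = net.export_maps(desc28.to_numpy(), ids=dataset.ids,
                               x_names=desc28.columns, y_names=RESPONSES)
        emit("top_map.csv", lambda p: maps.top_map.to_csv(p, index_label="id"))
        for response in ("AverageBScore",):
            plane = maps.output_maps[response]
            emit(f"output_map_{response}.csv",
                 lambda p, pl=plane: pd.DataFrame(pl).to_csv(p, index=False))

        stage = "predictions"
        model_name = cfg["ranking_model"]
        if model_name == "cpann_1":
            net1 = registry.cpanns["cpann_1"]
            pred = pd.Series(
                net1.predict(dataset.descriptor_table[["QPpolrz", "TD"]].to_numpy())[:, 0],
                index=dataset.ids,
            )
        else:
            model = registry.regressions[("regression_1", "AverageBScore")]
            pred = pd.Series(
                model.predict(dataset.descriptor_table[["QPpolrz", "TD"]].to_numpy()),
                index=dataset.ids,
            )

        stage = "alerts"
        library = load_alert_library(cfg["alert_library"])
        report = screening_report(dataset, library, pred,
                                  concern_threshold=cfg["concern_threshold"])
        emit("alert_report.csv", lambda p: report.to_csv(p, index_label="id"))
        emit("alert_groups.csv", lambda p: group_summary(report).to_csv(p, index=False))

        stage = "prioritization"
        ranking = rank_compounds(pred, report, wil1.table["structural_outlier"])
        emit("prioritization.csv", lambda p: ranking.to_csv(p, index_label="id"))

        stage = "manifest"
        manifest = {
            "config": cfg,
            "config_hash": config_hash(cfg),
            "seed": cfg["seed"],
            "version": __version__,
            "n_compounds": len(dataset.ids),
            "outputs": outputs,
        }
        if cfg["data"]["mode"] == "csv":
            digest = hashlib.sha256(Path(cfg["data"]["path"]).read_bytes()).hexdigest()
            manifest["input_digest"] = digest
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        outputs.append("manifest.json")
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    return {
        "dataset": dataset, "registry": registry, "williams": (wil1, wil2),
        "maps": maps, "alert_report": report, "prioritization": ranking,
        "manifest": manifest, "out_dir": out,
    }
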