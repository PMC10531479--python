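"""Structural-alert screening and compound prioritization.

Screens every compound against the 14 aquatic-toxicity alerts, groups
compounds sharing alert signatures, flags high-scoring alert-free
structures for manual review, and emits the final ranking: predicted
average binding score, descending, annotated with alerts and
applicability-domain flags.
"""

import argparse
from pathlib import Path

import pandas as pd

from fdtox import fit_ols, load_alert_library, rank_compounds, screening_report
from fdtox.alerts import group_summary
from fdtox.synthetic import load_compound_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    ds = load_compound_table(ROOT / "results" / "dataset.csv")
    tr = ds.train_ids()
    res = ROOT / "results"
    y = ds.response_table["AverageBScore"]
    X = ds.descriptor_table[["QPpolrz", "TD"]]

    model = fit_ols(X.loc[tr], y.loc[tr], predictor_names=["QPpolrz", "TD"])
    pred = pd.Series(model.predict(X.to_numpy()), index=ds.ids)

    library = load_alert_library()
    report = screening_report(ds, library, pred)
    report.to_csv(res / "alert_report.csv", index_label="id")
    groups = group_summary(report)
    groups.to_csv(res / "alert_groups.csv", index=False)

    ad = pd.read_csv(res / "williams_regression_1.csv", index_col="id")
    ranking = rank_compounds(pred, report, ad["structural_outlier"])
    ranking.to_csv(res / "prioritization.csv", index_label="id")

    n_hit = int((report.n_alerts > 0).sum())
    print(f"{n_hit}/{len(report)} compounds carry >= 1 aquatic-toxicity alert; "
          f"{int(report.review.sum())} high-scoring alert-free compounds "
          f"flagged for review")
    print(f"{len(groups)} alert-signature groups; "
          f"highest-scoring: {groups.iloc[0].alert_signature} "
          f"(mean score {groups.iloc[0].mean_score:.0f})")
    print("top 5 prioritized compounds:")
    print(ranking.head(5)[["rank", "predicted_avg_bscore", "alerts", "out_of_ad"]]
          .to_string(float_format="%.0f"))


if __name__ == "__main__":
    main()
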