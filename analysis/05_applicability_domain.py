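"""Applicability domain of the predictive regressions (Williams plots).

Computes leverages against the training design, standardized residuals,
and the h* = 3(p+1)/n warning threshold for regression model 1
(QPpolrz + TD) and regression model 2 (DCW), flagging structural and
response outliers. Writes tables and SVG Williams plots.
"""

import argparse
from pathlib import Path

import pandas as pd

from fdtox import fit_ols, williams
from fdtox.dcw import DCWModel
from fdtox.synthetic import load_compound_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    ds = load_compound_table(ROOT / "results" / "dataset.csv")
    tr = ds.train_ids()
    y = ds.response_table["AverageBScore"]
    res = ROOT / "results"

    model1 = fit_ols(ds.descriptor_table.loc[tr, ["QPpolrz", "TD"]], y.loc[tr],
                     predictor_names=["QPpolrz", "TD"], ids=list(tr))
    wil1 = williams(model1, ds, "AverageBScore")
    wil1.to_csv(res / "williams_regression_1.csv")
    wil1.plot(res / "williams_regression_1.svg")

    dcw = DCWModel.from_json(res / "dcw_model.json")
    col = pd.Series({i: dcw.dcw_from_smiles(s) for i, s in ds.smiles.items()},
                    name="DCW")
    model2 = fit_ols(col.loc[tr].to_frame(), y.loc[tr],
                     predictor_names=["DCW"], ids=list(tr))
    wil2 = williams(model2, ds, "AverageBScore", dcw_column=col)
    wil2.to_csv(res / "williams_regression_2.csv")
    wil2.plot(res / "williams_regression_2.svg")

    for name, wd in (("regression 1", wil1), ("regression 2", wil2)):
        t = wd.table
        print(f"{name}: h* = {wd.h_star:.4f}; "
              f"{int(t.structural_outlier.sum())} structural outliers "
              f"(h > h*), {int(t.response_outlier.sum())} response outliers "
              f"(|std residual| > 3)")
        flagged = wd.flagged()
        if len(flagged):
            print("  flagged: " + ", ".join(flagged.index))


if __name__ == "__main__":
    main()
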