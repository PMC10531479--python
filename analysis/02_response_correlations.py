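"""Correlation structure of the 12 binding-score responses.

Quantifies how strongly the ten protein scores track the average binding
score and each other — the empirical basis for treating the average score
as the unifying reference response in the later models. Writes the full
Pearson matrix and the descriptor-vs-response correlations.
"""

import argparse
from pathlib import Path

from fdtox import correlation_matrix
from fdtox.synthetic import RESPONSES, load_compound_table

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    argparse.ArgumentParser(description=__doc__).parse_args()
    ds = load_compound_table(ROOT / "results" / "dataset.csv")
    C = correlation_matrix(ds.response_table)
    C.round(4).to_csv(ROOT / "results" / "response_correlations.csv")

    proteins = [c for c in RESPONSES if c not in ("AverageBScore", "BindingAffinity")]
    r_avg = C.loc[proteins, "AverageBScore"]
    off = C.loc[proteins, proteins].to_numpy()
    off = off[off < 1 - 1e-12]
    print(f"protein scores vs average score: r = {r_avg.min():.3f} .. {r_avg.max():.3f}")
    print(f"among protein scores:            r = {off.min():.3f} .. {off.max():.3f}")

    joint = ds.descriptor_table[["QPpolrz", "TD", "mw", "tsa",
                                 "rotatable_bonds", "non_h_atoms"]].join(
        ds.response_table)
    D = correlation_matrix(joint)
    block = D.loc[["QPpolrz", "TD", "mw", "tsa", "rotatable_bonds", "non_h_atoms"],
                  RESPONSES]
    block.round(4).to_csv(ROOT / "results" / "descriptor_response_correlations.csv")
    print("strongest descriptor correlates of the average score:")
    print(block["AverageBScore"].sort_values(ascending=False).round(3).to_string())


if __name__ == "__main__":
    main()
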