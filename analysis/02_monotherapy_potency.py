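"""Monotherapy potency: Hill fits and IC50s from the simulated assays.

Fits four-parameter log-logistic curves to the monotherapy edges of each
replicate checkerboard (at the terminal timepoint for the kinetic assay) and
tabulates absolute IC50, relative EC50, Hill slope and the resistant
plateau, mean +/- SD across replicates.  Writes results/monotherapy_ic50.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from synercomb import absolute_ic50, fit_hill, read_checkerboard

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"


def main() -> None:
    argparse.ArgumentParser().parse_args()
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for assay, csv in (("mts", "mts_checkerboard.csv"),
                       ("rtglo", "rtglo_checkerboard.csv")):
        matrices = read_checkerboard(DATA / csv, {"assay_label": assay})
        terminal = max(m.timepoint_h for m in matrices)
        matrices = [m for m in matrices if m.timepoint_h == terminal]
        for drug, axis in (("siremadlin", "row"), ("trametinib", "col")):
            fits = []
            for m in matrices:
                doses = m.doses_row if axis == "row" else m.doses_col
                resp = m.response[:, 0] if axis == "row" else m.response[0, :]
                fits.append(fit_hill(doses, resp))
            ic50 = [absolute_ic50(f) for f in fits]
            ic50 = [v for v in ic50 if v is not None]
            rows.append({
                "assay": assay, "drug": drug, "time_h": terminal,
                "n_replicates": len(fits),
                "ic50_nM": np.mean(ic50), "ic50_sd": np.std(ic50, ddof=1),
                "ec50_nM": np.mean([f.C for f in fits]),
                "hill_slope": np.mean([f.h for f in fits]),
                "resistant_fraction_pct": np.mean(
                    [f.resistant_fraction for f in fits]),
                "r_squared_min": min(f.r_squared for f in fits),
            })
    table = pd.DataFrame(rows)
    out = RESULTS / "monotherapy_ic50.csv"
    table.to_csv(out, index=False, float_format="%.4g")
    print(table.to_string(index=False))
    print(f"\nwritten to {out}")


if __name__ == "__main__":
    main()
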