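"""Simulate the raw study datasets: combination checkerboards, PK, tumours.

Generates, with one seed, everything the downstream analyses consume:

* an MTS-style 5x5 checkerboard (12.5-200 nM x 0.25-4 nM + controls),
  4 replicates at 72 h;
* a RealTime-Glo-style 7x7 checkerboard (62.5-4000 nM x 0.625-40 nM +
  controls), 3 replicates at 13 timepoints from 0 to 80 h;
* oral PK profiles for both drugs in plasma and tumour, alone and in
  combination, destructively sampled at 1.5/4/8/24 h (n = 3);
* a four-arm xenograft efficacy study with qdx3/qdx6 schedules.

Raw CSVs land in scratch/data/ (regenerated on demand, not versioned).
"""

import argparse
from pathlib import Path

from synercomb import write_checkerboard
from synercomb.synthgen import (
    generate_matrix,
    generate_pk,
    generate_tumour_study,
    pk_to_csv,
    preset,
    tumour_to_csv,
)

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"

PK_PRESETS = ("pk-hdm201-plasma", "pk-hdm201-tumour",
              "pk-trametinib-plasma", "pk-trametinib-tumour")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    DATA.mkdir(parents=True, exist_ok=True)

    for name in ("mts-default", "rtglo-default"):
        mats = generate_matrix(preset(name, seed=args.seed))
        out = DATA / f"{name.split('-')[0]}_checkerboard.csv"
        write_checkerboard(mats, out)
        print(f"{name}: {len(mats)} matrices "
              f"({mats[0].response.shape[0]}x{mats[0].response.shape[1]} incl. controls) -> {out}")

    profiles = []
    for name in PK_PRESETS:
        profiles += generate_pk(preset(name, seed=args.seed))
    pk_to_csv(profiles, DATA / "pk_profiles.csv")
    print(f"PK: {len(profiles)} condition profiles -> {DATA / 'pk_profiles.csv'}")

    study = generate_tumour_study(preset("efficacy-combo-100-1", seed=args.seed))
    tumour_to_csv(study, DATA / "tumour_study.csv")
    print(f"tumour study: {len(study.measurements)} measurements, "
          f"groups {study.groups} -> {DATA / 'tumour_study.csv'}")


if __name__ == "__main__":
    main()
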