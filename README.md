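# synercomb

Quantitative analysis of two-drug combination experiments, built around the
preclinical evaluation of an MDM2 inhibitor (Siremadlin/HDM201) combined with
a MEK inhibitor (Trametinib) in A375 melanoma: synergy scoring of
dose-response checkerboards, MuSyC surface fitting, non-compartmental
pharmacokinetics, and xenograft tumour-growth inhibition.

It is written for the translational-pharmacology workflow where the same
question — *do these two drugs interact, and how strongly?* — has to be
answered at three levels: in vitro response surfaces, in vivo exposure, and
in vivo efficacy.

## What it computes

**δ synergy scores.** A checkerboard crosses increasing concentrations of two
drugs so every dose pair is measured. For each reference model of
non-interaction the cell-wise excess of observed over expected inhibition is
the δ score (percentage points), averaged over combination cells:

- Bliss independence: `y = y1 + y2 − y1·y2`
- HSA (highest single agent): `y = max(y1, y2)`
- Loewe additivity: the `y` solving `d1/D1(y) + d2/D2(y) = 1`, with `Di` the
  inverse Hill function of drug i
- ZIP (zero interaction potency): potency-shifted conditional Hill fits
  compared against the Bliss expectation of the fitted monotherapy curves

δ ≥ 5 is called synergism, δ ≤ −5 antagonism, in between additivity.

**MuSyC surface.** The combination response is modelled as the steady state
of a four-state population (unaffected U, affected by drug 1/2, affected by
both) with Hill-type mass-action rates. The fitted surface decouples synergy
into potency (α: fold change of one drug's effective dose induced by the
other; >1 synergistic), efficacy (β: fractional increase of the maximal
combination effect beyond the best single agent; >0 synergistic) and
cooperativity (γ: fold change of the Hill slope; >1 synergistic).

**Monotherapy fits.** Four-parameter log-logistic (Hill) curves,
`E(d) = E0 + (Emax − E0)·d^h/(C^h + d^h)`, with absolute IC50, relative
EC50, and the resistant plateau (100 − Emax) that survives at high dose.

**NCA pharmacokinetics.** AUC(0–t) by the linear trapezoidal rule, Cmax and
Tmax from destructive-sampling designs via index-paired pseudo-profiles,
and combination/monotherapy exposure ratios.

**Tumour growth inhibition.** Prolate-ellipsoid volumes `V = d²·D/2` from
calliper pairs and `TGI(%) = 100 − 100·T/C` against the control-group mean,
summarized as the maximum per-day mean ± SEM.

A seed-deterministic synthetic-data generator (`synercomb.synthgen`)
reproduces the statistical structure of all three study designs — the 5×5
(MTS-style, 72 h, n = 4) and 7×7 (RealTime-Glo-style, 0–80 h, n = 3)
checkerboards with plate noise and delayed effect onset, sparse oral PK
sampling, and qdx3/qdx6 efficacy arms — so the whole pipeline runs and is
tested without any raw assay files.

## Worked example

```python
from synercomb import delta_matrix, musyc_fit
from synercomb.synthgen import generate_matrix, preset

# one synthetic MTS-style checkerboard (6x6 with control edges, % inhibition)
matrix = generate_matrix(preset("mts-default", seed=5))[0]

for model in ("zip", "loewe", "hsa", "bliss"):
    print(model, round(delta_matrix(matrix, model).mean_delta, 2))

surface = musyc_fit(matrix)
print("musyc alpha12", round(surface.alpha12, 2), "beta", round(surface.beta, 3))
```

prints

```
zip 12.43
loewe 19.55
hsa 22.95
bliss 13.04
musyc alpha12 3.25 beta 0.406
```

— every reference model scores this surface well above the δ = 5 synergy
threshold (the generating truth has 3-fold potency synergy and a combination
plateau deeper than either single agent), and the fitted MuSyC metrics agree:
α > 1 (potency synergy) and β > 0 (efficacy synergy).

The same computations run from the shell:

```bash
synercomb simulate matrix --preset mts-default --seed 5 --out board.csv
synercomb synergy board.csv --time-window 0:100 --out report.json
```

## Analysis scripts

`analysis/` holds the numbered drivers for the full study workflow, each a
thin script over the library that prints what it finds and writes its table
under `results/`:

1. `01_simulate_assays.py` — synthesize checkerboards, PK and tumour data
   (into `scratch/data/`)
2. `02_monotherapy_potency.py` — Hill fits and IC50 table
3. `03_synergy_scoring.py` — per-assay δ scores for all four reference
   models, 28–80 h window, with cross-model consensus
4. `04_musyc_surface.py` — MuSyC α/β/γ per assay, R² ≥ 0.8 gate,
   unstable-parameter exclusion
5. `05_pk_nca.py` — NCA exposure table and combination exposure ratios
6. `06_tumour_tgi.py` — per-arm maximum TGI ± SEM

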