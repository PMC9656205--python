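"""Non-compartmental PK analysis for sparse destructive-sampling designs.

In a destructive (terminal) sampling design each animal contributes a single
concentration at a single timepoint, so no within-animal profile exists.
Exposure metrics are computed on *pseudo-profiles* formed by pairing the
k-th animal at each timepoint — a documented convention that yields SDs
comparable across metrics.  AUC uses the linear trapezoidal rule from dose
time to the last sample, with C(0) = 0 assumed for extravascular (oral)
dosing; no extrapolation to infinity is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ConcProfile:
    """Animal × timepoint concentration grid from destructive sampling."""

    analyte: str
    matrix_tissue: str                 # plasma | tumour | other
    condition: str                     # alone | combination
    timepoints: np.ndarray             # h, strictly increasing
    concentrations: np.ndarray         # nM, shape (n_animals, n_timepoints)
    dose_mg_kg: float = float("nan")

    def __post_init__(self) -> None:
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.concentrations = np.atleast_2d(np.asarray(self.concentrations, dtype=float))
        if np.any(np.diff(self.timepoints) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if self.concentrations.shape[1] != len(self.timepoints):
            raise ValueError("concentration grid does not match timepoints")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")

    @property
    def n_animals(self) -> int:
        return self.concentrations.shape[0]


@dataclass
class NCAResult:
    """Exposure metrics (mean ± sample SD over pseudo-profiles)."""

    analyte: str
    matrix_tissue: str
    condition: str
    auc_0_t: float
    auc_sd: float
    cmax: float
    cmax_sd: float
    tmax: float
    tmax_sd: float
    n: int
    t_last: float

    def as_row(self) -> dict:
        return {
            "analyte": self.analyte,
            "tissue": self.matrix_tissue,
            "condition": self.condition,
            "AUC_0_t (nM*h)": self.auc_0_t,
            "AUC SD": self.auc_sd,
            "Cmax (nM)": self.cmax,
            "Cmax SD": self.cmax_sd,
            "Tmax (h)": self.tmax,
            "Tmax SD": self.tmax_sd,
            "n": self.n,
        }


def auc_linear_trapezoid(times, concs, prepend_zero: bool = True) -> float:
    """AUC by the linear trapezoidal rule: Σ (C_i + C_{i+1})/2 · Δt.

    When the first sample time is > 0 and *prepend_zero* is set, a (0, 0)
    point is prepended (oral dosing: nothing is in circulation at t = 0).
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concs, dtype=float)
    if t.shape != c.shape:
        raise ValueError("times and concentrations must have the same length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if t.size < 2 and not (prepend_zero and t.size == 1 and t[0] > 0):
        raise ValueError("need at least two points for a trapezoid")
    if prepend_zero and t[0] > 0:
        t = np.concatenate([[0.0], t])
        c = np.concatenate([[0.0], c])
    return float(np.trapezoid(c, t))


def nca_from_pseudoprofiles(profile: ConcProfile, lloq: float = 0.0) -> NCAResult:
    """NCA metrics from index-paired pseudo-profiles.

    The k-th pseudo-profile pairs the k-th animal at each timepoint.  Per
    profile: AUC(0→t_last) by linear trapezoid with a prepended (0, 0) point,
    Cmax the maximum observed concentration, Tmax the earliest time attaining
    it.  Means ± sample SDs are reported across the n pseudo-profiles.
    Concentrations below *lloq* are set to 0 before integration.
    """
    if len(profile.timepoints) < 2:
        raise ValueError("need >= 2 timepoints")
    conc = profile.concentrations.copy()
    if np.isnan(conc).any():
        bad = np.where(np.isnan(conc).any(axis=0))[0]
        raise ValueError(
            f"unequal animal count across timepoints (missing at t = "
            f"{profile.timepoints[bad].tolist()} h)"
        )
    conc[conc < lloq] = 0.0

    aucs, cmaxs, tmaxs = [], [], []
    for k in range(profile.n_animals):
        c = conc[k]
        aucs.append(auc_linear_trapezoid(profile.timepoints, c))
        cmaxs.append(float(c.max()))
        tmaxs.append(float(profile.timepoints[int(np.argmax(c))]))  # earliest max

    def ms(v):
        v = np.asarray(v)
        return float(v.mean()), (float(np.std(v, ddof=1)) if v.size > 1 else 0.0)

    auc_m, auc_s = ms(aucs)
    cmax_m, cmax_s = ms(cmaxs)
    tmax_m, tmax_s = ms(tmaxs)
    return NCAResult(
        analyte=profile.analyte,
        matrix_tissue=profile.matrix_tissue,
        condition=profile.condition,
        auc_0_t=auc_m, auc_sd=auc_s,
        cmax=cmax_m, cmax_sd=cmax_s,
        tmax=tmax_m, tmax_sd=tmax_s,
        n=profile.n_animals,
        t_last=float(profile.timepoints[-1]),
    )


def exposure_ratio(combo: NCAResult, mono: NCAResult) -> dict:
    """Combination / monotherapy exposure ratios with direction flags."""
    if combo.analyte != mono.analyte or combo.matrix_tissue != mono.matrix_tissue:
        raise ValueError("exposure ratio requires matching analyte and tissue")
    out = {}
    for metric, c, m in (("auc", combo.auc_0_t, mono.auc_0_t),
                         ("cmax", combo.cmax, mono.cmax)):
        if m == 0:
            raise ZeroDivisionError(f"monotherapy {metric} is zero")
        ratio = c / m
        out[metric] = {
            "ratio": float(ratio),
            "direction": "increased" if ratio > 1 else ("decreased" if ratio < 1 else "unchanged"),
        }
    return out


def read_pk_csv(path) -> list[ConcProfile]:
    """Read a long PK CSV (analyte, tissue, condition, animal_id, time_h,
    conc_nM, dose_mg_kg) into one profile per (analyte, tissue, condition)."""
    df = pd.read_csv(path)
    required = {"analyte", "tissue", "condition", "animal_id", "time_h", "conc_nM"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing column(s): {sorted(missing)}")
    profiles = []
    for (analyte, tissue, condition), grp in df.groupby(["analyte", "tissue", "condition"]):
        times = np.sort(grp["time_h"].unique())
        counts = grp.groupby("time_h")["conc_nM"].size()
        if counts.nunique() != 1:
            bad = counts[counts != counts.mode().iloc[0]].index.tolist()
            raise ValueError(f"unequal animal count at timepoint(s) {bad} h")
        n = int(counts.iloc[0])
        grid = np.full((n, len(times)), np.nan)
        for j, t in enumerate(times):
            vals = grp[grp["time_h"] == t].sort_values("animal_id")["conc_nM"].to_numpy()
            grid[:, j] = vals
        dose = float(grp["dose_mg_kg"].iloc[0]) if "dose_mg_kg" in grp else float("nan")
        profiles.append(ConcProfile(
            analyte=str(analyte), matrix_tissue=str(tissue), condition=str(condition),
            timepoints=times, concentrations=grid, dose_mg_kg=dose,
        ))
    return profiles
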