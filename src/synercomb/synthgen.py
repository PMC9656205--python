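"""Synthetic study-data generator.

Emulates the three kinds of raw data the analysis consumes, with the
statistical structure the pipeline assumes, so every stage is testable
without access to raw assay files:

* **Checkerboards** — MuSyC-structured (or reference-null) combination
  surfaces on the study dose grids, with Hill-shaped monotherapy kill curves,
  resistant plateaus, Gaussian plate noise and a time-dependent effect onset.
  Default grids: MTS-style 5×5 (MDM2 inhibitor 12.5–200 nM × MEK inhibitor
  0.25–4 nM, 2-fold steps, 72 h, 4 replicates) and RealTime-Glo-style 7×7
  (62.5–4000 nM × 0.625–40 nM, timepoints 0–80 h, 3 replicates), each with
  zero-dose control edges.
* **PK profiles** — one-compartment oral absorption
  C(t) = A·(exp(−ke·t) − exp(−ka·t)) scaled to a target Cmax, destructively
  sampled at 1.5, 4, 8 and 24 h with n = 3 animals per timepoint and
  log-normal between-animal variability.
* **Tumour studies** — exponential control growth from ~160–180 mm³ with
  log-normal noise; treated arms multiply the daily growth factor by
  (1 − kill) on dosing days under qdx3/qdx6 schedules; calliper (width,
  length) pairs are back-computed from volume at a fixed aspect ratio.

Every output is fully determined by the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .hillfit import HillCurve, hill_predict
from .matrixio import INHIBITION, ResponseMatrix
from .musyc import MuSyCSurface, musyc_grid
from .pknca import ConcProfile
from .tgi import TumourStudy

# study dose grids (nM), 2-fold dilution series
MTS_DOSES_ROW = (12.5, 25.0, 50.0, 100.0, 200.0)
MTS_DOSES_COL = (0.25, 0.5, 1.0, 2.0, 4.0)
RTGLO_DOSES_ROW = (62.5, 125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0)
RTGLO_DOSES_COL = (0.625, 1.25, 2.5, 5.0, 10.0, 20.0, 40.0)
RTGLO_TIMEPOINTS = (0.0, 12.0, 24.0, 28.0, 32.0, 36.0, 48.0, 52.0, 56.0, 60.0, 72.0, 76.0, 80.0)
PK_TIMEPOINTS = (1.5, 4.0, 8.0, 24.0)

NULLS = ("bliss", "loewe-sham", "hsa")


@dataclass
class SynthConfig:
    """Complete recipe for one synthetic dataset (seed-deterministic)."""

    seed: int = 0
    # checkerboard
    doses_row: Sequence[float] = MTS_DOSES_ROW
    doses_col: Sequence[float] = MTS_DOSES_COL
    include_control_edges: bool = True
    surface: MuSyCSurface | None = None
    null_model: str | None = None          # bliss | loewe-sham | hsa
    null_curve_row: HillCurve | None = None
    null_curve_col: HillCurve | None = None
    noise_sd: float = 0.0                  # % response
    timepoints: Sequence[float] = (72.0,)
    n_replicates: int = 4
    onset_delay_h: float = 24.0
    reference_time_h: float = 80.0
    drug_row_name: str = "siremadlin"
    drug_col_name: str = "trametinib"
    assay_label: str = "mts"
    # PK
    ka: float = 2.0                        # /h; fast oral absorption (observed Tmax 1.5 h)
    ke: float = 0.1                        # /h
    target_cmax: float = 9778.0            # nM
    pk_timepoints: Sequence[float] = PK_TIMEPOINTS
    n_animals: int = 3
    pk_cv: float = 0.0                     # log-normal sigma on concentrations
    combo_multiplier: float = 1.0          # scales A under the combination condition
    analyte: str = "siremadlin"
    tissue: str = "plasma"
    # tumour study
    v0_mm3: float = 165.0
    growth_rate: float = 0.12              # /day, exponential control growth
    kill_factors: dict = field(default_factory=dict)   # group -> daily kill on dosing days
    schedules: dict = field(default_factory=dict)      # group -> dosing-day tuple
    study_days: Sequence[float] = (0, 3, 5, 7, 10, 12, 14)
    n_per_group: int = 6
    n_control: int = 11
    tumour_cv: float = 0.0
    aspect_ratio: float = 0.8              # width / length

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.pk_cv < 0 or self.tumour_cv < 0:
            raise ValueError("noise levels must be >= 0")
        if self.null_model is not None and self.null_model not in NULLS:
            raise ValueError(f"unknown null name {self.null_model!r}; expected one of {NULLS}")
        if self.null_model == "loewe-sham":
            # a drug combined with itself shares one dose axis
            self.doses_col = tuple(self.doses_row)


# default ground truth: synergy in potency and efficacy, neutral cooperativity;
# EC50s follow the observed monotherapy potencies per assay style
DEFAULT_MTS_SURFACE = MuSyCSurface(
    E0=1.0, E1=0.40, E2=0.30, E3=0.05, h1=1.5, h2=1.2,
    C1=65.7, C2=0.58, alpha12=3.0, alpha21=3.0, gamma12=1.0, gamma21=1.0,
)
DEFAULT_RTGLO_SURFACE = MuSyCSurface(
    E0=1.0, E1=0.40, E2=0.30, E3=0.05, h1=1.0, h2=1.0,
    C1=260.1, C2=0.8, alpha12=3.0, alpha21=3.0, gamma12=1.0, gamma21=1.0,
)


def preset(name: str, seed: int = 0) -> SynthConfig:
    """Named configurations mirroring the study arms."""
    presets = {
        "mts-default": SynthConfig(
            seed=seed, surface=DEFAULT_MTS_SURFACE, noise_sd=3.0,
            timepoints=(72.0,), n_replicates=4, assay_label="mts",
        ),
        "rtglo-default": SynthConfig(
            seed=seed, surface=DEFAULT_RTGLO_SURFACE, noise_sd=3.0,
            doses_row=RTGLO_DOSES_ROW, doses_col=RTGLO_DOSES_COL,
            timepoints=RTGLO_TIMEPOINTS, n_replicates=3, assay_label="rtglo",
        ),
        # combination multipliers follow the observed exposure interaction:
        # MDM2-inhibitor exposure rises when co-administered (x1.14 plasma,
        # x1.22 tumour); MEK-inhibitor plasma exposure falls (x0.80) while
        # its tumour exposure rises slightly (x1.06)
        "pk-hdm201-plasma": SynthConfig(
            seed=seed, target_cmax=9778.0, pk_cv=0.3,
            analyte="siremadlin", tissue="plasma", combo_multiplier=1.14,
        ),
        "pk-hdm201-tumour": SynthConfig(
            seed=seed, target_cmax=16214.0, pk_cv=0.3,
            analyte="siremadlin", tissue="tumour", combo_multiplier=1.22,
        ),
        "pk-trametinib-plasma": SynthConfig(
            seed=seed, target_cmax=567.0, pk_cv=0.1, ka=0.35, ke=0.08,
            analyte="trametinib", tissue="plasma", combo_multiplier=0.8,
        ),
        "pk-trametinib-tumour": SynthConfig(
            seed=seed, target_cmax=587.0, pk_cv=0.1, ka=0.35, ke=0.08,
            analyte="trametinib", tissue="tumour", combo_multiplier=1.06,
        ),
        # daily kill factors back-computed from the observed max TGI of each
        # arm: TGI = 1 - (1-kill)^n_doses at the day of maximal separation
        "efficacy-combo-100-1": SynthConfig(
            seed=seed, tumour_cv=0.15,
            kill_factors={
                "siremadlin_100_qdx3": 0.387,   # ~77% TGI after 3 doses
                "trametinib_1_qdx6": 0.319,     # ~90% TGI after 6 doses
                "combo_100_1": 0.415,           # ~96% TGI after 6 doses
            },
            schedules={
                "siremadlin_100_qdx3": (0, 1, 2),
                "trametinib_1_qdx6": (0, 1, 2, 3, 4, 5),
                "combo_100_1": (0, 1, 2, 3, 4, 5),
            },
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(presets)}")
    return presets[name]


# ---------------------------------------------------------------------------
# checkerboards


def _grid_axes(config: SynthConfig):
    row = np.asarray(config.doses_row, dtype=float)
    col = np.asarray(config.doses_col, dtype=float)
    if config.include_control_edges:
        row = np.concatenate([[0.0], row])
        col = np.concatenate([[0.0], col])
    return row, col


def _truth_inhibition(config: SynthConfig, row: np.ndarray, col: np.ndarray) -> np.ndarray:
    """Noise-free % inhibition surface on the (row, col) grid."""
    if config.null_model is None:
        if config.surface is None:
            raise ValueError("config needs either a MuSyC surface or a null name")
        viability = musyc_grid(config.surface, row, col)
        return 100.0 * (1.0 - viability)

    c1 = config.null_curve_row or HillCurve(E0=0.0, Emax=95.0, C=float(np.median(row[row > 0])), h=1.3)
    if config.null_model == "loewe-sham":
        # a drug combined with itself: dose-additive by construction
        d1, d2 = np.meshgrid(row, col, indexing="ij")
        return np.asarray(hill_predict(c1, d1 + d2))
    c2 = config.null_curve_col or HillCurve(E0=0.0, Emax=90.0, C=float(np.median(col[col > 0])), h=1.1)
    y1 = np.asarray(hill_predict(c1, row)) / 100.0
    y2 = np.asarray(hill_predict(c2, col)) / 100.0
    g1, g2 = np.meshgrid(y1, y2, indexing="ij")
    if config.null_model == "bliss":
        return 100.0 * (g1 + g2 - g1 * g2)
    return 100.0 * np.maximum(g1, g2)       # hsa


def _time_scaling(config: SynthConfig, t: float) -> float:
    """Effect-onset multiplier: 0 before the delay, ramping to 1 at the
    reference time (concentration- and time-dependent kill)."""
    if config.reference_time_h <= config.onset_delay_h:
        return 1.0
    return float(np.clip(
        (t - config.onset_delay_h) / (config.reference_time_h - config.onset_delay_h),
        0.0, 1.0,
    ))


def generate_matrix(config: SynthConfig) -> list[ResponseMatrix]:
    """One checkerboard per replicate × timepoint: truth surface + noise."""
    rng = np.random.default_rng(config.seed)
    row, col = _grid_axes(config)
    base = _truth_inhibition(config, row, col)
    matrices = []
    single_time = len(config.timepoints) == 1
    for t in config.timepoints:
        scale = 1.0 if single_time else _time_scaling(config, t)
        truth = base * scale
        for rep in range(1, config.n_replicates + 1):
            noise = rng.normal(0.0, config.noise_sd, size=truth.shape) if config.noise_sd else 0.0
            matrices.append(ResponseMatrix(
                drug_row_name=config.drug_row_name,
                drug_col_name=config.drug_col_name,
                doses_row=row, doses_col=col,
                response=truth + noise,
                response_scale=INHIBITION,
                timepoint_h=float(t),
                replicate_id=rep,
                assay_label=config.assay_label,
            ))
    return matrices


# ---------------------------------------------------------------------------
# PK


def oral_concentration(t, ka: float, ke: float, A: float):
    """One-compartment oral profile C(t) = A·(exp(−ke·t) − exp(−ka·t))."""
    t = np.asarray(t, dtype=float)
    return A * (np.exp(-ke * t) - np.exp(-ka * t))


def _amplitude_for_cmax(ka: float, ke: float, target: float) -> float:
    tmax = math.log(ka / ke) / (ka - ke)
    peak = math.exp(-ke * tmax) - math.exp(-ka * tmax)
    return target / peak


def generate_pk(config: SynthConfig, conditions=("alone", "combination")) -> list[ConcProfile]:
    """Destructively sampled oral PK profiles, one per condition.

    The amplitude is scaled so the continuous profile's Cmax hits the target;
    the combination condition multiplies the amplitude by
    ``combo_multiplier`` to emulate exposure interaction.  Per-animal
    log-normal factors (sigma = ``pk_cv``) are applied per sample.
    """
    if config.ka == config.ke:
        raise ValueError("ka must differ from ke (degenerate profile)")
    rng = np.random.default_rng(config.seed)
    A0 = _amplitude_for_cmax(config.ka, config.ke, config.target_cmax)
    times = np.asarray(config.pk_timepoints, dtype=float)
    profiles = []
    for condition in conditions:
        A = A0 * (config.combo_multiplier if condition == "combination" else 1.0)
        clean = oral_concentration(times, config.ka, config.ke, A)
        grid = np.empty((config.n_animals, len(times)))
        for k in range(config.n_animals):
            factors = (
                rng.lognormal(mean=0.0, sigma=config.pk_cv, size=len(times))
                if config.pk_cv else np.ones(len(times))
            )
            grid[k] = clean * factors
        profiles.append(ConcProfile(
            analyte=config.analyte, matrix_tissue=config.tissue,
            condition=condition, timepoints=times, concentrations=grid,
        ))
    return profiles


# ---------------------------------------------------------------------------
# tumour studies


def _volume_to_calipers(v: float, aspect: float) -> tuple[float, float]:
    # V = d^2 D / 2 with d = aspect * D  =>  D = (2V / aspect^2)^(1/3)
    D = (2.0 * v / aspect ** 2) ** (1.0 / 3.0)
    return aspect * D, D


def generate_tumour_study(config: SynthConfig) -> TumourStudy:
    """Exponential control growth plus treated arms under dosing schedules.

    Volumes evolve daily as V_{t+1} = V_t · exp(growth_rate) · (1 − kill)
    on dosing days (kill = 0 otherwise); measurements are taken on
    ``study_days`` with per-animal log-normal noise.  kill must be in [0, 1).
    """
    for group, kill in config.kill_factors.items():
        if not (0.0 <= kill < 1.0):
            raise ValueError(f"kill factor for {group!r} outside [0, 1)")
    rng = np.random.default_rng(config.seed)
    last_day = int(max(config.study_days))
    rows = []

    def simulate_arm(group: str, n: int, kill: float, dosing_days: tuple):
        for animal in range(1, n + 1):
            v = config.v0_mm3 * (rng.lognormal(0.0, config.tumour_cv) if config.tumour_cv else 1.0)
            traj = {0: v}
            for day in range(1, last_day + 1):
                v *= math.exp(config.growth_rate)
                if (day - 1) in dosing_days:
                    v *= (1.0 - kill)
                traj[day] = v
            for day in config.study_days:
                vol = traj[int(day)]
                if config.tumour_cv:
                    vol *= rng.lognormal(0.0, config.tumour_cv / 4.0)
                d, D = _volume_to_calipers(vol, config.aspect_ratio)
                rows.append({
                    "group": group, "animal_id": animal, "day": float(day),
                    "width_mm": d, "length_mm": D,
                })

    simulate_arm("vehicle", config.n_control, 0.0, ())
    for group, kill in config.kill_factors.items():
        schedule = tuple(config.schedules.get(group, (0, 1, 2)))
        simulate_arm(group, config.n_per_group, kill, schedule)

    meta = {"schedules": dict(config.schedules), "kill_factors": dict(config.kill_factors)}
    return TumourStudy(measurements=pd.DataFrame(rows), control_label="vehicle", metadata=meta)


# ---------------------------------------------------------------------------
# CSV export (same schemas the readers consume)


def pk_to_csv(profiles: list[ConcProfile], path) -> None:
    rows = []
    for p in profiles:
        for k in range(p.n_animals):
            for j, t in enumerate(p.timepoints):
                rows.append({
                    "analyte": p.analyte, "tissue": p.matrix_tissue,
                    "condition": p.condition, "animal_id": k + 1,
                    "time_h": t, "conc_nM": p.concentrations[k, j],
                    "dose_mg_kg": p.dose_mg_kg,
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def tumour_to_csv(study: TumourStudy, path) -> None:
    study.measurements.to_csv(path, index=False)
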