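"""Xenograft tumour volume and tumour-growth-inhibition (TGI) analysis.

Tumour volume from calliper width d and length D uses the prolate ellipsoid
formula V = d²·D/2 (mm³, d the shorter axis).  TGI compares treated against
control volumes: TGI(%) = 100 − 100·T/C; per-day group TGI is computed per
treated animal against the control-group mean and summarized as mean ± SEM,
and the reported maximum TGI is the largest per-day mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TumourStudy:
    """Calliper measurements per group/animal/day plus schedule metadata."""

    measurements: pd.DataFrame         # group, animal_id, day, width_mm, length_mm
    control_label: str = "vehicle"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"group", "animal_id", "day", "width_mm", "length_mm"}
        missing = required - set(self.measurements.columns)
        if missing:
            raise ValueError(f"missing column(s): {sorted(missing)}")
        if self.control_label not in set(self.measurements["group"]):
            raise ValueError(f"control group {self.control_label!r} absent")

    @property
    def groups(self) -> list[str]:
        return sorted(self.measurements["group"].unique())

    def volumes(self) -> pd.DataFrame:
        df = self.measurements.copy()
        df["volume_mm3"] = [
            tumour_volume(w, l) for w, l in zip(df["width_mm"], df["length_mm"])
        ]
        return df


def tumour_volume(d: float, D: float) -> float:
    """Prolate ellipsoid volume V = d²·D/2 (d = width, D = length, mm)."""
    if d <= 0 or D <= 0:
        raise ValueError("calliper measurements must be > 0")
    if d > D:
        warnings.warn("width > length; swapping axes (calliper transcription)")
        d, D = D, d
    return float(d * d * D / 2.0)


def tgi_percent(T: float, C: float) -> float:
    """TGI(%) = 100 − 100·T/C; negative when treated exceeds control."""
    if C <= 0:
        raise ValueError("control mean volume must be > 0")
    if T < 0:
        raise ValueError("treated volume must be >= 0")
    return float(100.0 - 100.0 * T / C)


def _nearest_day_match(treated_days, control_days, tol: int = 1):
    """Map each treated day to the nearest control day within ±tol."""
    control_days = np.asarray(sorted(control_days))
    mapping = {}
    for day in sorted(treated_days):
        i = int(np.argmin(np.abs(control_days - day)))
        if abs(control_days[i] - day) <= tol:
            mapping[day] = float(control_days[i])
    return mapping


def tgi_series(study: TumourStudy, group: str, day_tolerance: int = 1) -> dict:
    """Per-day TGI mean ± SEM for one treated group, plus the max TGI.

    Per animal i on each matched day, TGI_i = 100·(1 − T_i / mean C); the
    group summary is mean ± SEM (SD/√n) per day.  Control uncertainty is not
    propagated.  Animals removed mid-study contribute until their last
    measurement.  The max TGI is the maximum per-day mean, reported with
    that day's SEM.
    """
    if group not in study.groups:
        raise ValueError(f"unknown group {group!r}")
    vols = study.volumes()
    control = vols[vols["group"] == study.control_label]
    treated = vols[vols["group"] == group]
    mapping = _nearest_day_match(
        treated["day"].unique(), control["day"].unique(), day_tolerance
    )
    if not mapping:
        raise ValueError("no overlapping measurement days between groups")

    days, means, sems, ns = [], [], [], []
    for day, cday in mapping.items():
        c_mean = control[control["day"] == cday]["volume_mm3"].mean()
        t_vols = treated[treated["day"] == day]["volume_mm3"].to_numpy()
        if t_vols.size == 0 or not np.isfinite(c_mean) or c_mean <= 0:
            continue
        per_animal = 100.0 * (1.0 - t_vols / c_mean)
        days.append(float(day))
        means.append(float(per_animal.mean()))
        sems.append(float(per_animal.std(ddof=1) / np.sqrt(per_animal.size))
                    if per_animal.size > 1 else 0.0)
        ns.append(int(per_animal.size))
    if not days:
        raise ValueError("no computable TGI days")
    imax = int(np.argmax(means))
    return {
        "group": group,
        "days": days,
        "tgi_mean": means,
        "tgi_sem": sems,
        "n": ns,
        "max_tgi": means[imax],
        "max_tgi_sem": sems[imax],
        "max_tgi_day": days[imax],
    }


def tgi_table(study: TumourStudy) -> pd.DataFrame:
    """Max TGI ± SEM for every treated group (control excluded)."""
    rows = []
    for group in study.groups:
        if group == study.control_label:
            continue
        s = tgi_series(study, group)
        rows.append({
            "group": group,
            "max_tgi_percent": s["max_tgi"],
            "sem": s["max_tgi_sem"],
            "day": s["max_tgi_day"],
        })
    return pd.DataFrame(rows)


def read_tumour_csv(path, control_label: str = "vehicle") -> TumourStudy:
    """Read a calliper CSV (group, animal_id, day, width_mm, length_mm)."""
    return TumourStudy(measurements=pd.read_csv(path), control_label=control_label)
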