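"""End-to-end checkerboard analysis: score, gate, aggregate, classify.

Thin orchestration over the scoring modules: each replicate/timepoint matrix
is scored independently under every requested reference model plus MuSyC;
fits failing the R² gate are excluded; retained δ and MuSyC metrics are
aggregated (mean ± sample SD) per model within the time window; the
aggregated values are classified and a cross-model consensus is attached.
"""

from __future__ import annotations

import hashlib
import json
from typing import Sequence

from .consensus import (
    DEFAULT_R2_THRESHOLD,
    DEFAULT_TIME_WINDOW,
    classify_delta,
    consensus_strength,
    mean_sd,
)
from .hillfit import DegenerateFitError
from .matrixio import AnalysisReport, ResponseMatrix
from .musyc import musyc_fit
from .refmodels import MODELS, delta_matrix


def analyze_checkerboards(
    matrices: Sequence[ResponseMatrix],
    models: Sequence[str] = MODELS,
    fit_musyc: bool = True,
    time_window: tuple[float, float] = DEFAULT_TIME_WINDOW,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Score every matrix, aggregate per model, classify, and report."""
    per_matrix = []
    for m in matrices:
        entry: dict = {
            "assay": m.assay_label,
            "timepoint_h": m.timepoint_h,
            "replicate": m.replicate_id,
            "deltas": {},
        }
        for model in models:
            try:
                scores = delta_matrix(m, model)
                entry["deltas"][model] = scores.summary()
            except (DegenerateFitError, ValueError) as exc:
                entry["deltas"][model] = {"error": str(exc)}
        if fit_musyc:
            try:
                surf = musyc_fit(m)
                entry["musyc"] = {
                    "alpha12": surf.alpha12, "alpha21": surf.alpha21,
                    "beta": surf.beta,
                    "gamma12": surf.gamma12, "gamma21": surf.gamma21,
                    "r_squared": surf.r_squared,
                    "unstable": surf.unstable or {},
                }
            except (DegenerateFitError, ValueError) as exc:
                entry["musyc"] = {"error": str(exc), "r_squared": float("-inf"),
                                  "unstable": {}}
        per_matrix.append(entry)

    lo, hi = time_window
    in_window = [
        e for e in per_matrix if lo <= e["timepoint_h"] <= hi
    ]
    aggregates: dict = {"models": {}, "time_window_h": list(time_window)}
    model_means = []
    for model in models:
        vals = [
            e["deltas"][model]["mean_delta"]
            for e in in_window
            if "mean_delta" in e["deltas"].get(model, {})
        ]
        if vals:
            mean, sd = mean_sd(vals)
            aggregates["models"][model] = {"mean_delta": mean, "sd": sd, "n": len(vals)}
            model_means.append(mean)
    if model_means:
        grand, grand_sd = mean_sd(model_means)
        aggregates["mean_across_models"] = {"mean_delta": grand, "sd": grand_sd}

    classifications = []
    if model_means:
        per_model_calls = [
            classify_delta(aggregates["models"][m]["mean_delta"]) for m in models
            if m in aggregates["models"]
        ]
        for call in per_model_calls:
            classifications.append({"basis": "delta", "model": call.basis,
                                    "value": call.value, "label": call.label})
        if len(per_model_calls) >= 2:
            aggregates["consensus_strength"] = consensus_strength(per_model_calls)
        call = classify_delta(grand)
        classifications.append({"basis": "delta", "model": "mean_across_models",
                                "value": call.value, "label": call.label})

    if fit_musyc:
        musyc_entries = [
            e["musyc"] for e in in_window
            if "musyc" in e and e["musyc"]["r_squared"] >= r2_threshold
        ]
        agg_musyc = {}
        for key in ("alpha12", "alpha21", "beta", "gamma12", "gamma21"):
            vals = [
                e[key] for e in musyc_entries if not e["unstable"].get(key, False)
            ]
            if vals:
                mean, sd = mean_sd(vals)
                agg_musyc[key] = {"mean": mean, "sd": sd, "n": len(vals)}
        aggregates["musyc"] = agg_musyc

    prov = dict(provenance or {})
    prov.setdefault("n_matrices", len(matrices))
    blob = json.dumps({"models": list(models), "window": list(time_window),
                       "r2": r2_threshold}, sort_keys=True)
    prov.setdefault("config_hash", hashlib.sha256(blob.encode()).hexdigest()[:12])
    return AnalysisReport(
        per_matrix=per_matrix,
        aggregates=aggregates,
        classifications=classifications,
        provenance=prov,
    )
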