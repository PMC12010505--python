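"""Transition, Use, and Speed Delta Indices versus a control baseline.

Each index is the mean absolute deviation of a per-subject summary from the
control-group elementwise average of that summary:

    TDI = sum_ij |T_i - T_cbar| / m^2     (transition probability matrices,
                                           switch-only by default)
    UDI = sum_m  |U_i - U_cbar| / m       (usage vectors, percent)
    SDI = sum_m  |S_i - S_cbar| / m       (per-motif mean speed vectors)

Controls are included in their own baseline means, and for cross-index
comparison each subject's raw index is further normalized by the control
group's mean raw index, so the control group mean of every normalized index
is exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CohortTable, ValidationError

__all__ = ["tdi", "udi", "sdi", "delta_report", "DeltaIndexReport"]


def tdi(subject_matrix: np.ndarray, baseline_matrix: np.ndarray) -> float:
    """Grand sum of absolute transition-probability differences over m^2."""
    a = np.asarray(subject_matrix, float)
    b = np.asarray(baseline_matrix, float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError(f"matrix shape mismatch: {a.shape} vs {b.shape}")
    m = a.shape[0]
    return float(np.abs(a - b).sum() / (m * m))


def udi(subject_usage: np.ndarray, baseline_usage: np.ndarray) -> float:
    """Mean absolute usage-percent difference across motifs."""
    a = np.asarray(subject_usage, float)
    b = np.asarray(baseline_usage, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"usage length mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(a - b).sum() / a.size)


def sdi(subject_speeds: np.ndarray, baseline_speeds: np.ndarray) -> float:
    """Mean absolute per-motif speed difference across motifs.

    Motifs the subject never displayed (NaN speed) contribute the baseline
    value, i.e. a zero difference, keeping the denominator at m.
    """
    a = np.asarray(subject_speeds, float)
    b = np.asarray(baseline_speeds, float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(f"speed length mismatch: {a.shape} vs {b.shape}")
    diff = np.abs(a - b)
    diff[np.isnan(a) & ~np.isnan(b)] = 0.0
    if np.isnan(diff).any():
        raise ValidationError("baseline speeds contain NaN")
    return float(diff.sum() / a.size)


@dataclass
class DeltaIndexReport:
    """Per-subject raw and control-normalized delta indices + baselines."""

    table: pd.DataFrame
    baseline_matrix: np.ndarray
    baseline_usage: np.ndarray
    baseline_speeds: np.ndarray
    control: str
    flags: dict[str, list[str]] = field(default_factory=dict)


def delta_report(cohort: CohortTable,
                 matrices: dict[str, np.ndarray],
                 usages: dict[str, np.ndarray],
                 speeds: dict[str, np.ndarray],
                 control: str, factor: str = "genotype",
                 usage_baseline: str = "vector") -> DeltaIndexReport:
    """Compute TDI/UDI/SDI for every subject against control-group baselines.

    Baselines are elementwise means over control subjects (NaN speeds
    excluded per motif); ``usage_baseline="scalar"`` collapses the usage and
    speed baselines to their grand means, a sensitivity variant of the
    per-motif vector reading. Normalized values divide each raw index by
    the control group's mean raw index; if that mean is zero (all controls
    identical to the baseline) normalization is skipped with a flag.
    """
    control_ids = cohort.subjects_where(**{factor: control})
    if not control_ids:
        raise ValidationError(f"no control subjects with {factor}={control!r}")
    T_bar = np.mean([matrices[s] for s in control_ids], axis=0)
    U_bar = np.mean([usages[s] for s in control_ids], axis=0)
    with np.errstate(invalid="ignore"):
        S_bar = np.nanmean([speeds[s] for s in control_ids], axis=0)
    if np.isnan(S_bar).any():
        raise ValidationError(
            "some motifs have no control speed observation at all")
    if usage_baseline == "scalar":
        U_bar = np.full_like(U_bar, U_bar.mean())
        S_bar = np.full_like(S_bar, S_bar.mean())
    elif usage_baseline != "vector":
        raise ValidationError(f"unknown usage_baseline {usage_baseline!r}")

    meta = cohort.table.set_index("subject_id")[factor]
    rows = []
    flags: dict[str, list[str]] = {"imputed_speed": [], "skipped_norm": []}
    for sid in cohort.subject_ids:
        s_speeds = np.asarray(speeds[sid], float)
        if np.isnan(s_speeds).any():
            flags["imputed_speed"].append(sid)
        rows.append((sid, meta[sid],
                     tdi(matrices[sid], T_bar),
                     udi(usages[sid], U_bar),
                     sdi(s_speeds, S_bar)))
    df = pd.DataFrame(rows, columns=["subject_id", "group", "tdi", "udi",
                                     "sdi"])
    ctl = df[df["subject_id"].isin(control_ids)]
    for col in ("tdi", "udi", "sdi"):
        mean_ctl = ctl[col].mean()
        if mean_ctl == 0:
            flags["skipped_norm"].append(col)
            df[f"{col}_norm"] = np.nan
        else:
            df[f"{col}_norm"] = df[col] / mean_ctl
    return DeltaIndexReport(df, T_bar, U_bar, S_bar, control, flags)
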