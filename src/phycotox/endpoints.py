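"""Bioassay endpoints and assay-validity rules.

Two endpoints are computed per replicate well:

* specific growth rate (SGR, d⁻¹) — the log-scale increase in cell density,
  ``SGR = (ln X_j - ln X_i) / (t_j - t_i)``;
* effective quantum yield (ΔF/Fm′, dimensionless) — the light-adapted PAM
  measure of PSII efficiency, ``(Fm' - F) / Fm'``.

Percent inhibition of each treatment replicate is taken relative to the mean
of the control group, ``100 * (X̄_control - X) / X̄_control``, and the
proportional response is ``1 - inhibition/100``. Negative inhibition
(stimulation) is retained, not truncated, so fits see the full error
structure.

Validity rules enforced: the growth assay requires mean control SGR
≥ 0.92 d⁻¹; fluorescence wells require a pre-exposure yield strictly above
0.45.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "specific_growth_rate",
    "effective_quantum_yield",
    "percent_inhibition",
    "build_endpoint_table",
    "validate_growth_controls",
    "validate_yield_screen",
    "QCVerdict",
    "CONTROL_SGR_MIN",
    "YIELD_SCREEN_MIN",
]

CONTROL_SGR_MIN = 0.92   # d-1, growth-assay validity threshold
YIELD_SCREEN_MIN = 0.45  # pre-exposure yield must be strictly above this


def specific_growth_rate(x_i, x_j, t_i, t_j):
    """Specific growth rate in d⁻¹ from densities at two times.

    Parameters
    ----------
    x_i, x_j : float or array
        Cell densities (cells mL⁻¹) at times ``t_i`` and ``t_j``; must be
        strictly positive.
    t_i, t_j : float
        Times in days with ``t_j > t_i``.

    Returns
    -------
    float or ndarray
        ``(ln x_j - ln x_i) / (t_j - t_i)``. Scale-invariant: multiplying
        both densities by the same factor leaves the rate unchanged.
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    if np.any(x_i <= 0) or np.any(x_j <= 0):
        raise ValueError("cell densities must be strictly positive")
    if not np.all(np.asarray(t_j) > np.asarray(t_i)):
        raise ValueError("t_j must be greater than t_i")
    out = (np.log(x_j) - np.log(x_i)) / (np.asarray(t_j) - np.asarray(t_i))
    return out if out.ndim else float(out)


def effective_quantum_yield(F, Fm_prime):
    """Effective quantum yield ΔF/Fm′ = (Fm′ − F)/Fm′ ∈ [0, 1].

    ``Fm_prime`` must be positive and ``0 <= F <= Fm_prime``.
    """
    F = np.asarray(F, dtype=float)
    Fm = np.asarray(Fm_prime, dtype=float)
    if np.any(Fm <= 0):
        raise ValueError("Fm_prime must be strictly positive")
    if np.any(F < 0) or np.any(F > Fm):
        raise ValueError("F must satisfy 0 <= F <= Fm_prime")
    out = (Fm - F) / Fm
    return out if out.ndim else float(out)


def percent_inhibition(control_values, treatment_values, per_replicate=False):
    """Percent inhibition of a treatment relative to the control mean.

    With ``per_replicate=False`` returns the treatment-level value
    ``100 * (mean(control) - mean(treatment)) / mean(control)``; with
    ``per_replicate=True`` returns one value per treatment replicate against
    the control mean (their average equals the treatment-level value).
    """
    control = np.asarray(control_values, dtype=float)
    treat = np.asarray(treatment_values, dtype=float)
    if control.size == 0 or treat.size == 0:
        raise ValueError("control and treatment sequences must be non-empty")
    cbar = control.mean()
    if cbar <= 0:
        raise ValueError("degenerate control: mean must be > 0")
    inh = 100.0 * (cbar - treat) / cbar
    if per_replicate:
        return inh
    return float(inh.mean())


@dataclass
class QCVerdict:
    """Outcome of an assay-validity check."""

    valid: bool
    rule: str
    detail: str
    flags: set = field(default_factory=set)

    def __bool__(self):
        return self.valid


def _control_roles(wells: pd.DataFrame, alpha: float = 0.05):
    """Decide whether solvent controls pool with seawater controls.

    Solvent controls are pooled only after a non-significant one-way ANOVA
    against the seawater controls (no solvent effect); otherwise they stay
    separate and a ``solvent_effect`` flag is raised.
    """
    roles = set(wells["role"])
    if "solvent_control" not in roles:
        return ["control"], False
    swc = wells.loc[wells["role"] == "control", "_endpoint"].to_numpy()
    sc = wells.loc[wells["role"] == "solvent_control", "_endpoint"].to_numpy()
    if len(swc) < 2 or len(sc) < 2 or (np.ptp(swc) == 0 and np.ptp(sc) == 0):
        return ["control", "solvent_control"], False
    _, p = stats.f_oneway(swc, sc)
    if p >= alpha:
        return ["control", "solvent_control"], False
    return ["control"], True


def build_endpoint_table(wells: pd.DataFrame, endpoint: str = "sgr",
                         duration_days: float | None = None) -> pd.DataFrame:
    """Per-replicate endpoint table from a wells table.

    Parameters
    ----------
    wells : DataFrame
        Wells in the standard dialect (herbicide, role, nominal_ugL,
        replicate, t0_cells_per_mL, t72_cells_per_mL, F, Fm_prime).
    endpoint : {"sgr", "yield"}
        Which endpoint to compute; "sgr" needs the density columns
        (duration defaults to 3 d), "yield" the fluorescence pair.
    duration_days : float, optional
        Exposure duration for the SGR endpoint; default 3.

    Returns
    -------
    DataFrame
        One row per replicate with columns ``endpoint_value``,
        ``inhibition_pct``, ``proportional_response`` and ``qc_flags``.
        Controls are included; their mean inhibition is 0 by construction.
    """
    if endpoint not in ("sgr", "yield"):
        raise ValueError("endpoint must be 'sgr' or 'yield'")
    required = {"herbicide", "role", "nominal_ugL", "replicate"}
    missing = required - set(wells.columns)
    if missing:
        raise ValueError(f"wells table missing columns: {sorted(missing)}")

    df = wells.copy()
    if endpoint == "sgr":
        dur = 3.0 if duration_days is None else float(duration_days)
        df["_endpoint"] = specific_growth_rate(
            df["t0_cells_per_mL"].to_numpy(),
            df["t72_cells_per_mL"].to_numpy(),
            0.0, dur,
        )
    else:
        df["_endpoint"] = effective_quantum_yield(
            df["F"].to_numpy(), df["Fm_prime"].to_numpy()
        )

    control_roles, solvent_effect = _control_roles(df)
    control_mask = df["role"].isin(control_roles)
    control_mean = df.loc[control_mask, "_endpoint"].mean()
    if control_mean <= 0:
        raise ValueError("degenerate control: mean endpoint must be > 0")

    df["inhibition_pct"] = 100.0 * (control_mean - df["_endpoint"]) / control_mean
    df["proportional_response"] = 1.0 - df["inhibition_pct"] / 100.0
    flags = []
    for _, row in df.iterrows():
        f = set()
        if solvent_effect and row["role"] == "solvent_control":
            f.add("solvent_effect")
        flags.append(f)
    df["qc_flags"] = flags
    out = df.rename(columns={"_endpoint": "endpoint_value"})
    out["endpoint"] = endpoint
    cols = ["herbicide", "role", "nominal_ugL", "replicate", "endpoint",
            "endpoint_value", "inhibition_pct", "proportional_response",
            "qc_flags"]
    return out[cols].reset_index(drop=True)


def validate_growth_controls(endpoints: pd.DataFrame,
                             threshold: float = CONTROL_SGR_MIN) -> QCVerdict:
    """Growth-assay validity: mean control SGR must be ≥ 0.92 d⁻¹ (boundary valid)."""
    controls = endpoints.loc[
        endpoints["role"].isin(["control", "solvent_control"]), "endpoint_value"
    ]
    if controls.empty:
        return QCVerdict(False, "control_sgr", "no control wells present",
                         {"control_sgr_low"})
    mean_sgr = float(controls.mean())
    ok = mean_sgr >= threshold
    detail = f"mean control SGR {mean_sgr:.3f} d-1 (threshold {threshold} d-1)"
    return QCVerdict(ok, "control_sgr", detail,
                     set() if ok else {"control_sgr_low"})


def validate_yield_screen(pre_exposure_yields,
                          threshold: float = YIELD_SCREEN_MIN) -> QCVerdict:
    """Pre-exposure screen: every well's yield must be strictly > 0.45."""
    y = np.asarray(pre_exposure_yields, dtype=float)
    failing = int(np.sum(y <= threshold))
    ok = failing == 0
    detail = f"{failing}/{y.size} wells at or below {threshold}"
    return QCVerdict(ok, "yield_screen", detail,
                     set() if ok else {"yield_screen_fail"})
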