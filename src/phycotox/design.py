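"""Assay designs and simulation ground truths.

The study design emulated here is a 72 h static growth-inhibition bioassay
and a 24 h PAM-fluorometry well-plate assay on a marine cryptophyte:
five replicate vessels per treatment, a seawater control (optionally a
solvent control), a diuron reference treatment, and an ascending ladder of
nominal herbicide concentrations in µg L⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence, Union

import numpy as np

__all__ = [
    "AssayDesign",
    "FourPLTruth",
    "NECExpTruth",
    "GroundTruth",
]


@dataclass(frozen=True)
class AssayDesign:
    """Layout of one herbicide bioassay.

    Parameters
    ----------
    herbicide_name : str
        Test compound label used in all output tables.
    nominal_concentrations : sequence of float
        Treatment ladder in µg L⁻¹; strictly positive and strictly ascending.
    n_replicates : int
        Replicate vessels per treatment (study design: 5).
    include_solvent_control : bool
        Add a solvent-control group alongside the seawater control.
    reference_concentration : float
        Diuron reference concentration in µg L⁻¹ (4 in all assays except the
        simazine assay, which used 2).
    start_density : float
        Inoculation density, cells mL⁻¹: 3e3 for the 72 h growth assay,
        3.5e5 for the 24 h fluorescence assay.
    duration_days : float
        Growth-assay exposure duration in days (3).
    control_sgr_mean : float
        Expected control specific growth rate, d⁻¹.
    control_yield_mean : float
        Expected control effective quantum yield ΔF/Fm′, in (0, 1);
        controls in the study sat at 0.45-0.53.
    """

    herbicide_name: str
    nominal_concentrations: tuple
    n_replicates: int = 5
    include_solvent_control: bool = False
    reference_concentration: float = 4.0
    start_density: float = 3e3
    duration_days: float = 3.0
    control_sgr_mean: float = 1.2
    control_yield_mean: float = 0.5

    def __post_init__(self):
        conc = tuple(float(c) for c in self.nominal_concentrations)
        object.__setattr__(self, "nominal_concentrations", conc)
        if len(conc) == 0:
            raise ValueError("at least one treatment concentration required")
        arr = np.asarray(conc)
        if np.any(arr <= 0):
            raise ValueError("nominal concentrations must be strictly positive")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("nominal concentrations must be strictly ascending")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if not (0 < self.control_yield_mean < 1):
            raise ValueError("control_yield_mean must be in (0, 1)")
        if self.start_density <= 0 or self.duration_days <= 0:
            raise ValueError("start_density and duration_days must be positive")


@dataclass(frozen=True)
class FourPLTruth:
    """Four-parameter logistic inhibition curve used as generating truth.

    Inhibition (percent of the control endpoint) follows

        I(c) = bottom + (top - bottom) / (1 + 10**((log10 EC50 - log10 c) * hill))
    """

    ec50: float
    hill: float = 1.0
    bottom: float = 0.0
    top: float = 100.0

    def inhibition_pct(self, conc):
        conc = np.asarray(conc, dtype=float)
        z = (np.log10(self.ec50) - np.log10(conc)) * self.hill
        return self.bottom + (self.top - self.bottom) / (1.0 + 10.0 ** z)

    def response_fraction(self, conc):
        """Fraction of the control endpoint remaining at ``conc``."""
        return 1.0 - self.inhibition_pct(conc) / 100.0


@dataclass(frozen=True)
class NECExpTruth:
    """Threshold-exponential (segmented) generating truth.

    The expected proportional response is flat at ``alpha - delta`` up to the
    no-effect concentration exp(gamma) and decays exponentially (rate beta in
    log-concentration units) beyond it.
    """

    gamma: float  # NEC on the natural-log concentration axis
    beta: float = 1.0
    alpha: float = 1.0
    delta: float = 0.0

    def response_fraction(self, conc):
        x = np.log(np.asarray(conc, dtype=float))
        step = np.maximum(x - self.gamma, 0.0)
        return self.alpha * np.exp(-self.beta * step) - self.delta

    def inhibition_pct(self, conc):
        return 100.0 * (1.0 - self.response_fraction(conc))


@dataclass(frozen=True)
class GroundTruth:
    """Generating model plus noise/chemistry settings for a synthetic assay.

    Noise is placed directly on the endpoint scale (SGR in d⁻¹, yield as a
    dimensionless fraction), matching the replicate variability the study
    reports for its endpoints rather than raw-count noise. The diuron
    reference wells are generated from fixed reference inhibition levels
    (study-wide means ~31% for SGR, ~80% for yield) because the reference is
    a different compound than the simulated test herbicide.
    """

    model: Union[FourPLTruth, NECExpTruth]
    noise_sd_sgr: float = 0.04
    noise_sd_yield: float = 0.01
    loss_fraction: float = 0.3
    dosing_cv: float = 0.02
    reference_inhibition_sgr_pct: float = 31.4
    reference_inhibition_yield_pct: float = 80.2
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd_sgr < 0 or self.noise_sd_yield < 0:
            raise ValueError("noise SDs must be >= 0")
        if not (0 <= self.loss_fraction < 1):
            raise ValueError("loss_fraction must be in [0, 1)")
        if self.dosing_cv < 0:
            raise ValueError("dosing_cv must be >= 0")

    @property
    def model_kind(self) -> str:
        return "four_pl" if isinstance(self.model, FourPLTruth) else "nec_exponential"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["model_kind"] = self.model_kind
        return d
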