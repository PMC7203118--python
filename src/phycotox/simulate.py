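"""Synthetic bioassay generator.

Produces ground-truth-annotated well tables and chemistry tables with the
study's design (5 replicates per treatment, seawater/solvent controls, a
diuron reference, exponential growth from the inoculation density) so that
every downstream stage — endpoints, exposure chemistry, concentration-response
fits, NEC estimation — can be exercised and scored without any external data.

Wells CSV schema: herbicide, role, nominal_ugL, replicate, t0_cells_per_mL,
t72_cells_per_mL, F, Fm_prime. Growth wells carry densities and leave the
fluorescence pair empty; fluorescence wells the reverse.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .design import AssayDesign, FourPLTruth, GroundTruth, NECExpTruth

__all__ = [
    "simulate_growth_wells",
    "simulate_yield_wells",
    "simulate_chemistry",
    "simulate_assay",
    "write_fixture",
]

logger = logging.getLogger(__name__)

WELL_COLUMNS = [
    "herbicide",
    "role",
    "nominal_ugL",
    "replicate",
    "t0_cells_per_mL",
    "t72_cells_per_mL",
    "F",
    "Fm_prime",
]

# Fm' instrument scale is arbitrary; a fixed value keeps fixtures readable.
_FM_PRIME = 500.0
_YIELD_MAX = 0.75
_MAX_REDRAWS = 100

# Distinct deterministic streams per generator so growth/yield/chemistry
# tables are individually reproducible from the one master seed.
_STREAM_GROWTH, _STREAM_YIELD, _STREAM_CHEM = 11, 13, 17


def _rng(truth: GroundTruth, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(truth.seed), stream]))


def _treatment_rows(design: AssayDesign):
    """(role, nominal) pairs in output order: controls, reference, ladder."""
    rows = [("control", 0.0)]
    if design.include_solvent_control:
        rows.append(("solvent_control", 0.0))
    rows.append(("reference", float(design.reference_concentration)))
    rows.extend(("treatment", float(c)) for c in design.nominal_concentrations)
    return rows


def _mean_fraction(design, truth, role, nominal, endpoint):
    if role in ("control", "solvent_control"):
        return 1.0
    if role == "reference":
        ref = (
            truth.reference_inhibition_sgr_pct
            if endpoint == "sgr"
            else truth.reference_inhibition_yield_pct
        )
        return 1.0 - ref / 100.0
    return float(truth.model.response_fraction(nominal))


def simulate_growth_wells(design: AssayDesign, truth: GroundTruth) -> pd.DataFrame:
    """Simulate the 72 h growth assay: one row per replicate per treatment.

    Each well's specific growth rate is drawn as
    ``control_sgr_mean * response_fraction(c) + N(0, noise_sd_sgr)`` and the
    72 h density is ``start_density * exp(SGR * duration)``. The 0 h density
    is the inoculation density exactly. Regeneration with the same seed is
    bit-identical.
    """
    rng = _rng(truth, _STREAM_GROWTH)
    records = []
    for role, nominal in _treatment_rows(design):
        frac = _mean_fraction(design, truth, role, nominal, "sgr")
        sgr_mean = design.control_sgr_mean * frac
        for rep in range(1, design.n_replicates + 1):
            sgr = sgr_mean + rng.normal(0.0, truth.noise_sd_sgr)
            t72 = design.start_density * np.exp(sgr * design.duration_days)
            for _ in range(_MAX_REDRAWS):
                if np.isfinite(t72) and t72 > 0:
                    break
                sgr = sgr_mean + rng.normal(0.0, truth.noise_sd_sgr)
                t72 = design.start_density * np.exp(sgr * design.duration_days)
            else:
                raise RuntimeError(
                    f"could not draw a positive 72 h density for {role} "
                    f"at {nominal} ugL after {_MAX_REDRAWS} redraws"
                )
            records.append(
                (design.herbicide_name, role, nominal, rep,
                 design.start_density, t72, np.nan, np.nan)
            )
    return pd.DataFrame.from_records(records, columns=WELL_COLUMNS)


def simulate_yield_wells(design: AssayDesign, truth: GroundTruth) -> pd.DataFrame:
    """Simulate the 24 h PAM assay: light-adapted (F, Fm′) pairs per well.

    The effective quantum yield (Fm′−F)/Fm′ equals
    ``control_yield_mean * response_fraction(c)`` plus gaussian noise and is
    clipped to the physically meaningful PAM range [0, 0.75]; clipping is
    logged. Fm′ is fixed at an arbitrary instrument scale.
    """
    rng = _rng(truth, _STREAM_YIELD)
    records = []
    n_clipped = 0
    for role, nominal in _treatment_rows(design):
        frac = _mean_fraction(design, truth, role, nominal, "yield")
        y_mean = design.control_yield_mean * frac
        for rep in range(1, design.n_replicates + 1):
            y = y_mean + rng.normal(0.0, truth.noise_sd_yield)
            if y < 0.0 or y > _YIELD_MAX:
                n_clipped += 1
                y = float(np.clip(y, 0.0, _YIELD_MAX))
            f = _FM_PRIME * (1.0 - y)
            records.append(
                (design.herbicide_name, role, nominal, rep,
                 np.nan, np.nan, f, _FM_PRIME)
            )
    if n_clipped:
        logger.info("clipped %d yield values to [0, %.2f]", n_clipped, _YIELD_MAX)
    return pd.DataFrame.from_records(records, columns=WELL_COLUMNS)


def simulate_chemistry(design: AssayDesign, truth: GroundTruth) -> pd.DataFrame:
    """Simulate measured exposure concentrations for the treatment ladder.

    0 h measurements scatter around nominal with a multiplicative gaussian
    dosing error (CV ``dosing_cv``); 72 h measurements equal the 0 h value
    times ``1 - loss_fraction``, emulating degradation/adsorption losses of
    0-50 % of nominal over the test.
    """
    rng = _rng(truth, _STREAM_CHEM)
    nominal = np.asarray(design.nominal_concentrations)
    m0 = nominal * (1.0 + rng.normal(0.0, truth.dosing_cv, size=nominal.size))
    m0 = np.abs(m0)  # dosing error is small; reflect any pathological draw
    m72 = m0 * (1.0 - truth.loss_fraction)
    return pd.DataFrame(
        {
            "herbicide": design.herbicide_name,
            "nominal_ugL": nominal,
            "measured_0h_ugL": m0,
            "measured_72h_ugL": m72,
        }
    )


def simulate_assay(design: AssayDesign, truth: GroundTruth):
    """Convenience: (growth wells, yield wells, chemistry) for one assay."""
    growth = simulate_growth_wells(design, truth)
    fluo_design = AssayDesign(
        herbicide_name=design.herbicide_name,
        nominal_concentrations=design.nominal_concentrations,
        n_replicates=design.n_replicates,
        include_solvent_control=design.include_solvent_control,
        reference_concentration=design.reference_concentration,
        start_density=3.5e5,
        duration_days=1.0,
        control_sgr_mean=design.control_sgr_mean,
        control_yield_mean=design.control_yield_mean,
    )
    fluo = simulate_yield_wells(fluo_design, truth)
    chem = simulate_chemistry(design, truth)
    return growth, fluo, chem


def write_fixture(wells: pd.DataFrame, chemistry: pd.DataFrame,
                  truth: GroundTruth, path) -> dict:
    """Write a wells CSV, chemistry CSV and a JSON truth sidecar.

    The sidecar records the generating model and noise settings so every
    downstream stage can be re-scored against the truth that produced the
    fixture. Returns the three paths.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    wells_path = path / "wells.csv"
    chem_path = path / "chemistry.csv"
    truth_path = path / "truth.json"
    wells.to_csv(wells_path, index=False)
    chemistry.to_csv(chem_path, index=False)
    truth_path.write_text(json.dumps(truth.to_dict(), indent=2, sort_keys=True))
    return {"wells": wells_path, "chemistry": chem_path, "truth": truth_path}


def read_truth(path) -> GroundTruth:
    """Rebuild a :class:`GroundTruth` from a fixture sidecar."""
    d = json.loads(Path(path).read_text())
    kind = d.pop("model_kind")
    model_d = d.pop("model")
    model = FourPLTruth(**model_d) if kind == "four_pl" else NECExpTruth(**model_d)
    return GroundTruth(model=model, **d)
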