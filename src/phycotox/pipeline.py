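"""End-to-end orchestration: wells + chemistry in, threshold tables out.

Runs the full analysis for one herbicide assay — endpoints and QC, exposure
chemistry, 4PL ECx fits with bootstrap CIs, the Bayesian NEC on the growth
endpoint — and assembles the reporting surfaces: a threshold table
(EC10/EC50/NEC with 95 % intervals, ReP and the endpoint EC50 ratio), an
assay-performance table (control/reference means ± SD and reference
inhibition), and a QC report. Every output embeds the config hash, seed and
package version as ``#``-prefixed comment lines (pandas round-trips them
with ``comment='#'``); re-running with an identical config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .doseresponse import (FourPLModel, bootstrap_ecx, ec50_ratio_summary,
                           ols_endpoint_regression, relative_potency)
from .endpoints import (build_endpoint_table, validate_growth_controls,
                        validate_yield_screen)
from .exposure import build_exposure_series
from .nec import NECModel

__all__ = [
    "RunConfig",
    "InvalidAssayError",
    "NonConvergenceError",
    "run_pipeline",
    "build_threshold_table",
    "compare_endpoints",
    "render_value",
]

logger = logging.getLogger(__name__)


class InvalidAssayError(RuntimeError):
    """The assay failed a validity rule (e.g. control SGR below 0.92 d⁻¹)."""


class NonConvergenceError(RuntimeError):
    """A model fit failed to converge."""


@dataclass
class RunConfig:
    """Configuration for one pipeline run (YAML or JSON on disk)."""

    wells_growth: str
    chemistry: str
    out_dir: str
    wells_yield: str | None = None
    endpoint: str = "both"          # sgr | yield | both
    n_boot: int = 1000
    bootstrap_seed: int = 0
    mcmc_chains: int = 5
    mcmc_burn_in: int = 20000
    mcmc_draws: int = 10000
    mcmc_seed: int = 0
    loss_adjustment: bool = True
    lod_ugL: float = 0.01
    log_concentration_base: str = "e"
    reference_ec50_sgr: float | None = None
    reference_ec50_yield: float | None = None
    log_level: str = "INFO"
    strict_convergence: bool = False

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML superset: JSON accepted too
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def render_value(v: float, censored: bool = False) -> str:
    """Render a concentration at 3 significant figures, thousands-separated;
    censored values as '>x'."""
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return ""
    r = float(f"{v:.3g}")
    s = f"{r:,.0f}" if abs(r) >= 1000 else f"{r:g}"
    return f">{s}" if censored else s


def _meta_header(config: RunConfig, seed) -> str:
    return (f"# phycotox v{__version__}\n"
            f"# config_hash={config.config_hash}\n"
            f"# seed={seed}\n")


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig, seed) -> None:
    with open(path, "w") as fh:
        fh.write(_meta_header(config, seed))
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    """Read a pipeline CSV, skipping embedded metadata comment lines."""
    return pd.read_csv(path, comment="#")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = sorted(set(cols) - set(df.columns))
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


def _endpoint_block(endpoints, exposure, config, endpoint_name):
    """4PL fit + bootstrapped EC10/EC50 for one endpoint."""
    fit = FourPLModel.from_endpoints(endpoints, exposure).fit()
    if not fit.converged:
        raise NonConvergenceError(
            f"4PL fit for endpoint '{endpoint_name}' did not converge: {fit.message}")
    block = {"fit": fit}
    for x, key in ((50, "ec50"), (10, "ec10")):
        block[key] = bootstrap_ecx(endpoints, exposure, x,
                                   n_boot=config.n_boot,
                                   seed=config.bootstrap_seed)
    return block


def build_threshold_table(herbicide: str, blocks: dict, nec: dict | None,
                          reps: dict, ratio: float | None) -> pd.DataFrame:
    """Assemble one herbicide's block of the threshold table.

    ``blocks`` maps endpoint name -> {"ec50": ECxEstimate, "ec10": ...};
    ``nec`` is the NEC summary dict for the growth endpoint (or None);
    ``reps`` maps endpoint -> ReP (or NaN); ``ratio`` is EC50_SGR/EC50_yield.
    Full precision is retained; rendering happens only in ``render_threshold_table``.
    """
    rows = []
    for metric in ("ec50", "ec10"):
        row = {"herbicide": herbicide, "metric": metric.upper()}
        for ep in ("sgr", "yield"):
            est = blocks.get(ep, {}).get(metric)
            if est is None:
                row.update({f"{ep}": np.nan})
                continue
            row[f"{ep}"] = est.point
            row[f"{ep}_ci_low"] = est.ci_low
            row[f"{ep}_ci_high"] = est.ci_high
            row[f"{ep}_censored"] = est.censored
        row["ec50_ratio"] = ratio if metric == "ec50" else np.nan
        rows.append(row)
    nec_row = {"herbicide": herbicide, "metric": "NEC", "yield": np.nan}
    if nec is not None:
        nec_row.update({"sgr": nec["nec"], "sgr_ci_low": nec["ci_low"],
                        "sgr_ci_high": nec["ci_high"],
                        "sgr_censored": False})
    rows.append(nec_row)
    rows.append({"herbicide": herbicide, "metric": "ReP",
                 "sgr": reps.get("sgr", np.nan),
                 "yield": reps.get("yield", np.nan)})
    return pd.DataFrame(rows)


def render_threshold_table(table: pd.DataFrame) -> str:
    """Human-readable threshold table, 3 significant figures, '>x' censoring."""
    lines = [f"{'herbicide':<14}{'metric':<7}{'SGR':>22}{'dF/Fm':>22}{'ratio':>8}"]
    for _, r in table.iterrows():
        cells = []
        for ep in ("sgr", "yield"):
            v = r.get(ep, np.nan)
            if pd.isna(v):
                cells.append("")
                continue
            if r["metric"] == "ReP":
                cells.append(f"{v:.2g}")
                continue
            cen = bool(r.get(f"{ep}_censored", False))
            s = render_value(v, censored=cen)
            lo, hi = r.get(f"{ep}_ci_low", np.nan), r.get(f"{ep}_ci_high", np.nan)
            if not cen and not (pd.isna(lo) or pd.isna(hi)):
                s += f" ({render_value(lo)}-{render_value(hi)})"
            cells.append(s)
        ratio = r.get("ec50_ratio", np.nan)
        ratio_s = f"{ratio:.1f}" if not pd.isna(ratio) else ""
        lines.append(f"{r['herbicide']:<14}{r['metric']:<7}"
                     f"{cells[0]:>22}{cells[1]:>22}{ratio_s:>8}")
    return "\n".join(lines)


def assay_performance(endpoint_tables: dict) -> pd.DataFrame:
    """Control/reference mean ± SD and reference percent inhibition per endpoint."""
    rows = []
    for ep, tab in endpoint_tables.items():
        ctrl = tab[tab["role"].isin(["control", "solvent_control"])]
        ref = tab[tab["role"] == "reference"]
        rows.append({
            "endpoint": ep,
            "control_mean": ctrl["endpoint_value"].mean(),
            "control_sd": ctrl["endpoint_value"].std(ddof=1),
            "reference_mean": ref["endpoint_value"].mean(),
            "reference_sd": ref["endpoint_value"].std(ddof=1),
            "reference_inhibition_pct": ref["inhibition_pct"].mean(),
            "reference_inhibition_sd": ref["inhibition_pct"].std(ddof=1),
        })
    return pd.DataFrame(rows)


def compare_endpoints(ec50_table: pd.DataFrame) -> dict:
    """Endpoint-sensitivity comparison across herbicides.

    From a table with columns herbicide, ec50_sgr, ec50_yield: per-herbicide
    EC50 ratios with their mean, relative potencies against the reference
    herbicide (diuron row required for ReP), and the OLS regression of the
    growth EC50s on the quantum-yield EC50s.
    """
    ratios, mean_ratio = ec50_ratio_summary(ec50_table)
    reg = ols_endpoint_regression(ec50_table["ec50_sgr"], ec50_table["ec50_yield"])
    out = {"ratios": ratios, "mean_ratio": mean_ratio,
           "regression": {"slope": reg.slope, "intercept": reg.intercept,
                          "r_squared": reg.r_squared, "n": reg.n}}
    ref = ec50_table[ec50_table["herbicide"].str.lower() == "diuron"]
    if not ref.empty:
        rep = ec50_table.copy()
        rep["rep_sgr"] = [relative_potency(float(ref["ec50_sgr"].iloc[0]), v)
                          for v in rep["ec50_sgr"]]
        rep["rep_yield"] = [relative_potency(float(ref["ec50_yield"].iloc[0]), v)
                            for v in rep["ec50_yield"]]
        out["rep"] = rep[["herbicide", "rep_sgr", "rep_yield"]]
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis for one assay and write all outputs.

    Raises :class:`InvalidAssayError` when a validity rule fails and, with
    ``strict_convergence``, :class:`NonConvergenceError` when the NEC fit
    does not pass its diagnostics.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {"bootstrap": config.bootstrap_seed, "mcmc": config.mcmc_seed}

    wells_growth = read_table(config.wells_growth)
    _require_columns(wells_growth,
                     ["herbicide", "role", "nominal_ugL", "replicate",
                      "t0_cells_per_mL", "t72_cells_per_mL"], config.wells_growth)
    chem = read_table(config.chemistry)
    _require_columns(chem, ["herbicide", "nominal_ugL", "measured_0h_ugL",
                            "measured_72h_ugL"], config.chemistry)
    herbicide = str(wells_growth["herbicide"].iloc[0])

    endpoint_tables = {}
    qc = {}
    if config.endpoint in ("sgr", "both"):
        tab = build_endpoint_table(wells_growth, "sgr")
        endpoint_tables["sgr"] = tab
        verdict = validate_growth_controls(tab)
        qc["control_sgr"] = {"valid": verdict.valid, "detail": verdict.detail}
        if not verdict.valid:
            (out / "qc_report.json").write_text(json.dumps(qc, indent=2))
            raise InvalidAssayError(verdict.detail)
    if config.endpoint in ("yield", "both") and config.wells_yield:
        wells_yield = read_table(config.wells_yield)
        _require_columns(wells_yield, ["herbicide", "role", "nominal_ugL",
                                       "replicate", "F", "Fm_prime"],
                         config.wells_yield)
        tab = build_endpoint_table(wells_yield, "yield")
        endpoint_tables["yield"] = tab
        # unexposed (control) wells stand in for the pre-exposure screen
        screen = validate_yield_screen(
            tab.loc[tab["role"].isin(["control", "solvent_control"]),
                    "endpoint_value"])
        qc["yield_screen"] = {"valid": screen.valid, "detail": screen.detail}
        if not screen.valid:
            (out / "qc_report.json").write_text(json.dumps(qc, indent=2))
            raise InvalidAssayError(screen.detail)

    exposure = build_exposure_series(chem, lod_ugL=config.lod_ugL,
                                     apply_loss_adjustment=config.loss_adjustment)

    blocks = {}
    for ep, tab in endpoint_tables.items():
        blocks[ep] = _endpoint_block(tab, exposure, config, ep)

    nec_summary = None
    nec_res = None
    if "sgr" in endpoint_tables:
        nec_model = NECModel.from_endpoints(endpoint_tables["sgr"], exposure,
                                            log_base=config.log_concentration_base)
        nec_res = nec_model.fit(chains=config.mcmc_chains,
                                burn_in=config.mcmc_burn_in,
                                draws=config.mcmc_draws, seed=config.mcmc_seed)
        nec_summary = nec_res.nec_summary()
        if not nec_res.converged:
            logger.warning("NEC fit flagged non-converged (max R-hat %.3f)",
                           float(nec_res.rhat.max()))
            if config.strict_convergence:
                raise NonConvergenceError("NEC MCMC failed convergence diagnostics")

    reps, ratio = {}, None
    refs = {"sgr": config.reference_ec50_sgr, "yield": config.reference_ec50_yield}
    for ep, block in blocks.items():
        est = block["ec50"]
        if refs[ep] is not None and not est.censored:
            reps[ep] = relative_potency(refs[ep], est.point)
    if ("sgr" in blocks and "yield" in blocks
            and not blocks["sgr"]["ec50"].censored
            and not blocks["yield"]["ec50"].censored):
        ratio = blocks["sgr"]["ec50"].point / blocks["yield"]["ec50"].point

    threshold = build_threshold_table(
        herbicide,
        {ep: {"ec50": b["ec50"], "ec10": b["ec10"]} for ep, b in blocks.items()},
        nec_summary, reps, ratio)
    performance = assay_performance(endpoint_tables)

    for ep, tab in endpoint_tables.items():
        dumpable = tab.copy()
        dumpable["qc_flags"] = dumpable["qc_flags"].apply(
            lambda s: ";".join(sorted(s)))
        _write_csv(dumpable, out / f"endpoints_{ep}.csv", config, seeds)
    _write_csv(exposure, out / "exposure.csv", config, seeds)
    _write_csv(threshold, out / "threshold_table.csv", config, seeds)
    (out / "threshold_table.txt").write_text(
        _meta_header(config, seeds) + render_threshold_table(threshold) + "\n")
    _write_csv(performance, out / "assay_performance.csv", config, seeds)
    if nec_res is not None:
        _write_csv(nec_res.posterior, out / "nec_posterior.csv", config, seeds)
        nec_json = dict(nec_summary)
        nec_json.update({"rhat": nec_res.rhat.to_dict(),
                         "ess": nec_res.ess.to_dict(),
                         "log_base": config.log_concentration_base})
        (out / "nec_summary.json").write_text(json.dumps(nec_json, indent=2))
    (out / "qc_report.json").write_text(json.dumps(qc, indent=2))
    (out / "run_metadata.json").write_text(json.dumps(
        {"package_version": __version__, "config_hash": config.config_hash,
         "seeds": seeds, "config": config.to_dict()}, indent=2, sort_keys=True))

    return {"herbicide": herbicide, "endpoints": endpoint_tables,
            "exposure": exposure, "blocks": blocks, "nec": nec_summary,
            "nec_results": nec_res, "threshold_table": threshold,
            "performance": performance, "qc": qc, "out_dir": out}
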