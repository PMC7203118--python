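"""Four-parameter logistic concentration-response modelling and ECx.

The mean inhibition (percent of the control endpoint) is modelled as

    y(c) = bottom + (top - bottom) / (1 + 10**((log10 EC50 - log10 c) * hill))

fit by least squares to per-replicate inhibition on log10 analysis
concentration. ECx is defined as absolute x % inhibition relative to the
control (not relative to the curve asymptotes): the smallest positive
concentration with y(c) = x. When the fitted curve never reaches x % below
the maximum tested concentration the estimate is censored and reported as
"> max tested".

Controls do not appear on the log-concentration axis; they anchor the fit
through the inhibition normalisation, and the bottom parameter is estimated
near 0 (bounded to [-20, 20]) while the top is bounded to [50, 110], which
tolerates mild stimulation while keeping the curve a genuine 0→~100 %
sigmoid.

Also provided: percentile-bootstrap confidence intervals for ECx by case
resampling of replicates within treatments, relative potencies against the
diuron reference, the per-herbicide EC50 ratio between the growth and
quantum-yield endpoints, the OLS regression between the two endpoints'
EC50s, and classical one-way ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

__all__ = [
    "FourPLModel",
    "FourPLResults",
    "ECxEstimate",
    "bootstrap_ecx",
    "relative_potency",
    "ec50_ratio_summary",
    "ols_endpoint_regression",
    "one_way_anova",
    "AnovaResult",
    "RegressionResult",
]

_BOUNDS_LO = np.array([-20.0, 50.0, -np.inf, 1e-3])   # bottom, top, log10_ec50, hill
_BOUNDS_HI = np.array([20.0, 110.0, np.inf, 20.0])
PARAM_NAMES = ("bottom", "top", "log10_ec50", "hill")


def four_pl(conc, bottom, top, log10_ec50, hill):
    """Evaluate the 4PL inhibition curve at concentration ``conc`` (µg L⁻¹)."""
    logc = np.log10(np.asarray(conc, dtype=float))
    z = (log10_ec50 - logc) * hill
    return bottom + (top - bottom) / (1.0 + 10.0 ** z)


@dataclass
class ECxEstimate:
    """Point estimate (and optional bootstrap CI) of an effective concentration."""

    x_pct: float
    point: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    censored: bool = False
    max_tested: float = np.nan

    def render(self) -> str:
        if self.censored:
            return f">{self.max_tested:,.0f}"
        return f"{self.point:.3g}"


class FourPLModel:
    """Sigmoidal (4-parameter) concentration-response model.

    Parameters
    ----------
    concentration : array
        Analysis concentrations, µg L⁻¹, strictly positive, one per
        replicate observation.
    inhibition_pct : array
        Percent inhibition relative to the control mean.
    max_tested : float, optional
        Highest tested analysis concentration (defaults to
        ``max(concentration)``); used for ECx censoring.
    """

    def __init__(self, concentration, inhibition_pct, max_tested=None):
        conc = np.asarray(concentration, dtype=float)
        y = np.asarray(inhibition_pct, dtype=float)
        if conc.shape != y.shape:
            raise ValueError("concentration and inhibition must align")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if np.unique(conc).size < 4:
            raise ValueError("at least 4 distinct concentrations required")
        self.conc = conc
        self.logc = np.log10(conc)
        self.y = y
        self.max_tested = float(max_tested) if max_tested is not None else float(conc.max())

    @classmethod
    def from_endpoints(cls, endpoints: pd.DataFrame, exposure: pd.DataFrame):
        """Build from an endpoint table and an exposure series.

        Treatment replicates are matched to their analysis concentration via
        the nominal concentration; controls and references are excluded from
        the regression (controls enter through the inhibition normalisation).
        """
        treat = endpoints[endpoints["role"] == "treatment"]
        conc_map = exposure.set_index("nominal_ugL")["analysis_ugL"]
        conc = treat["nominal_ugL"].map(conc_map)
        if conc.isna().any():
            missing = sorted(treat.loc[conc.isna(), "nominal_ugL"].unique())
            raise ValueError(f"no analysis concentration for nominals {missing}")
        return cls(conc.to_numpy(), treat["inhibition_pct"].to_numpy())

    def _residuals(self, theta):
        return four_pl(self.conc, *theta) - self.y

    def _jacobian(self, theta):
        b, t, L, h = theta
        z = (L - self.logc) * h
        w = 1.0 / (1.0 + 10.0 ** z)
        ww = np.log(10.0) * w * (1.0 - w) * (t - b)
        return np.column_stack([1.0 - w, w, -ww * h, -ww * (L - self.logc)])

    def fit(self, start=None, xtol=1e-15, ftol=1e-15, gtol=1e-15) -> "FourPLResults":
        """Least-squares fit; non-convergence is flagged, never silent."""
        if start is None:
            top0 = float(np.clip(np.max(self.y), 50.0, 110.0))
            mid = np.argmin(np.abs(self.y - 0.5 * top0))
            start = np.array([0.0, top0, self.logc[mid], 1.0])
        start = np.clip(start, _BOUNDS_LO + 1e-9, _BOUNDS_HI - 1e-9)
        sol = optimize.least_squares(
            self._residuals, start, jac=self._jacobian,
            bounds=(_BOUNDS_LO, _BOUNDS_HI),
            xtol=xtol, ftol=ftol, gtol=gtol, max_nfev=20000,
        )
        converged = bool(sol.success and np.all(np.isfinite(sol.x)))
        return FourPLResults(self, sol.x, converged, message=sol.message)


class FourPLResults:
    """Results of a :class:`FourPLModel` fit.

    Attributes
    ----------
    params : pandas.Series
        bottom, top (percent inhibition), log10_ec50 (log10 µg L⁻¹),
        hill (dimensionless, > 0).
    converged : bool
    r_squared, residual_sd, sse : float
    """

    def __init__(self, model: FourPLModel, theta, converged: bool, message: str = ""):
        self.model = model
        self.params = pd.Series(np.asarray(theta, dtype=float), index=PARAM_NAMES)
        self.converged = converged
        self.message = message
        resid = model._residuals(self.params.to_numpy())
        self.sse = float(resid @ resid)
        sst = float(np.sum((model.y - model.y.mean()) ** 2))
        self.r_squared = 1.0 - self.sse / sst if sst > 0 else np.nan
        dof = max(model.y.size - 4, 1)
        self.residual_sd = float(np.sqrt(self.sse / dof))

    @property
    def ec50(self) -> float:
        return float(10.0 ** self.params["log10_ec50"])

    def predict(self, conc):
        return four_pl(conc, *self.params.to_numpy())

    def ecx(self, x_pct: float) -> ECxEstimate:
        """Interpolate the concentration producing ``x_pct`` absolute inhibition.

        Closed-form inversion of the fitted logistic; censored at the maximum
        tested concentration when the curve never reaches ``x_pct`` there.
        """
        if not self.converged:
            raise RuntimeError("cannot interpolate from a non-converged fit")
        b, t, L, h = self.params
        mx = self.model.max_tested
        if x_pct >= t or x_pct <= b or self.predict(mx) < x_pct:
            return ECxEstimate(x_pct, point=mx, censored=True, max_tested=mx)
        logc = L - np.log10((t - x_pct) / (x_pct - b)) / h
        return ECxEstimate(x_pct, point=float(10.0 ** logc), max_tested=mx)

    def summary(self) -> str:
        lines = ["Four-parameter logistic concentration-response fit",
                 "-" * 50,
                 f"n obs:        {self.model.y.size}",
                 f"converged:    {self.converged}"]
        for name, val in self.params.items():
            lines.append(f"{name:<13} {val: .6g}")
        lines.append(f"{'EC50 (ugL)':<13} {self.ec50: .6g}")
        lines.append(f"{'R-squared':<13} {self.r_squared: .4f}")
        lines.append(f"{'residual SD':<13} {self.residual_sd: .4g}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Fitted curve over the replicate data on a log-concentration axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogx(self.model.conc, self.model.y, "o", mfc="none", label="replicates")
        grid = np.geomspace(self.model.conc.min(), self.model.conc.max(), 200)
        ax.semilogx(grid, self.predict(grid), "-", label="4PL fit")
        ax.set_xlabel("concentration (µg L$^{-1}$)")
        ax.set_ylabel("inhibition (%)")
        ax.legend()
        return ax


def bootstrap_ecx(endpoints: pd.DataFrame, exposure: pd.DataFrame,
                  x_pct: float, n_boot: int = 1000, seed: int = 0) -> ECxEstimate:
    """Percentile-bootstrap 95 % CI for ECx by within-treatment case resampling.

    Each resample redraws m = n-1 replicates (with replacement) independently
    within the control group and within every treatment — the
    Davison-Hinkley small-sample correction, which makes the resampled
    group-mean variance an unbiased s²/n rather than the (n-1)/n-deflated
    value of the plain n-out-of-n case bootstrap — recomputes inhibition
    against the resampled control mean, refits the 4PL and re-interpolates
    ECx. Deterministic for a given ``seed``. Censored resamples are dropped
    from the percentile computation; if more than half are censored the
    returned estimate is censored.
    """
    rng = np.random.default_rng(seed)
    ctrl = endpoints.loc[
        endpoints["role"].isin(["control", "solvent_control"]), "endpoint_value"
    ].to_numpy()
    treat = endpoints[endpoints["role"] == "treatment"]
    conc_map = exposure.set_index("nominal_ugL")["analysis_ugL"]
    groups = [
        (float(conc_map[nom]), g["endpoint_value"].to_numpy())
        for nom, g in treat.groupby("nominal_ugL")
    ]
    base = FourPLModel.from_endpoints(endpoints, exposure).fit()
    est = base.ecx(x_pct)
    if est.censored:
        return est

    points = np.empty(n_boot)
    n_censored = 0
    for b in range(n_boot):
        m_ctrl = max(ctrl.size - 1, 2)
        cbar = rng.choice(ctrl, size=m_ctrl, replace=True).mean()
        conc_list, inh_list = [], []
        for conc, vals in groups:
            m = max(vals.size - 1, 2)
            draw = rng.choice(vals, size=m, replace=True)
            conc_list.append(np.full(m, conc))
            inh_list.append(100.0 * (cbar - draw) / cbar)
        model = FourPLModel(np.concatenate(conc_list), np.concatenate(inh_list),
                            max_tested=base.model.max_tested)
        res = model.fit(start=base.params.to_numpy(), xtol=1e-10, ftol=1e-10, gtol=1e-10)
        e = res.ecx(x_pct)
        if e.censored or not res.converged:
            n_censored += 1
            points[b] = np.nan
        else:
            points[b] = e.point
    ok = points[np.isfinite(points)]
    if n_censored > n_boot // 2 or ok.size < 10:
        return ECxEstimate(x_pct, point=base.model.max_tested, censored=True,
                           max_tested=base.model.max_tested)
    lo, hi = np.percentile(ok, [2.5, 97.5])
    return ECxEstimate(x_pct, point=est.point, ci_low=float(lo), ci_high=float(hi),
                       max_tested=base.model.max_tested)


def relative_potency(ec50_reference: float, ec50_herbicide: float) -> float:
    """ReP = EC50(reference) / EC50(test); > 1 means more potent than diuron."""
    if ec50_reference <= 0 or ec50_herbicide <= 0:
        raise ValueError("EC50 values must be strictly positive")
    return ec50_reference / ec50_herbicide


def ec50_ratio_summary(table: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Per-herbicide EC50 ratio SGR : ΔF/Fm′ and its arithmetic mean.

    ``table`` needs columns ``herbicide``, ``ec50_sgr``, ``ec50_yield``;
    rows with a missing (censored) EC50 get a NaN ratio and are excluded
    from the mean.
    """
    out = table.copy()
    out["ec50_ratio"] = out["ec50_sgr"] / out["ec50_yield"]
    mean_ratio = float(out["ec50_ratio"].dropna().mean())
    return out, mean_ratio


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def ols_endpoint_regression(ec50_sgr: Sequence[float],
                            ec50_yield: Sequence[float]) -> RegressionResult:
    """OLS of the growth-endpoint EC50s on the quantum-yield EC50s.

    Fits ``EC50_SGR = intercept + slope · EC50_yield`` by ordinary least
    squares (with intercept) and reports slope and R².
    """
    y = np.asarray(ec50_sgr, dtype=float)
    x = np.asarray(ec50_yield, dtype=float)
    if y.size != x.size or y.size < 2:
        raise ValueError("need >= 2 paired EC50 values")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(slope=float(fit.params[1]),
                            intercept=float(fit.params[0]),
                            r_squared=float(fit.rsquared), n=int(y.size))


@dataclass
class AnovaResult:
    statistic: float
    pvalue: float
    df_between: int
    df_within: int

    def __str__(self):
        return (f"F({self.df_between},{self.df_within}) = {self.statistic:.3g}, "
                f"p = {self.pvalue:.3g}")


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA (with replicates) across treatment groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance: ANOVA is degenerate")
    f, p = stats.f_oneway(*arrays)
    n = sum(a.size for a in arrays)
    return AnovaResult(float(f), float(p), len(arrays) - 1, n - len(arrays))
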