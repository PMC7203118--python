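"""Bayesian no-effect-concentration (NEC) threshold-exponential model.

The proportional decline in specific growth rate, Y, is modelled as a
function of log concentration x by the segmented (Fox-type) gaussian model

    E[Y | x] = mu(x) = alpha * exp(-beta * (x - gamma) * 1[x > gamma]) - delta
    Y | x ~ Normal(mu(x), sigma**2)

with parameters

* ``alpha`` — the response at zero or low concentration ("top");
* ``beta``  — the decay rate of the response beyond the threshold (>= 0);
* ``gamma`` — the NEC on the log-concentration axis: below it the expected
  response is exactly flat at ``alpha - delta``;
* ``delta`` — an offset (intercept);
* ``sigma`` — the residual SD of Y.

Priors (un-informative, with the normals parameterised by mean and
PRECISION): alpha ~ N(0, prec 0.1), beta ~ Gamma(1e-4, 1e-4),
gamma ~ N(0, prec 0.01), delta ~ N(0, prec 0.1), sigma ~ Uniform(0, 29).

Posterior sampling uses a component-wise adaptive random-walk Metropolis
sampler: proposal scales are tuned toward a 0.2-0.4 acceptance rate during
burn-in only and frozen afterwards (preserving detailed balance for the
kept draws). Five chains of 10,000 kept iterations after a 20,000-iteration
burn-in are the defaults. Convergence is diagnosed by split R-hat and
effective sample size; a fit with any R-hat > 1.05 or ESS < 400 is flagged,
never silently accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import lgamma, log, pi

import numpy as np
import pandas as pd

__all__ = ["NECModel", "NECResults", "PARAM_NAMES"]

PARAM_NAMES = ("alpha", "beta", "gamma", "delta", "sigma")

# Prior hyperparameters, exactly as stated (normals: mean, precision).
_PREC_ALPHA = 0.1
_GAMMA_SHAPE = 1e-4
_GAMMA_RATE = 1e-4
_PREC_GAMMA = 0.01
_PREC_DELTA = 0.1
_SIGMA_UPPER = 29.0

_RHAT_MAX = 1.05
_ESS_MIN = 400.0


def _model_mean(alpha, beta, gamma, delta, x):
    step = np.where(x > gamma, x - gamma, 0.0)
    return alpha * np.exp(-beta * step) - delta


class NECModel:
    """Threshold-exponential concentration-response model for gaussian data.

    Parameters
    ----------
    log_conc : array
        Log concentrations (one per replicate observation).
    response : array
        Proportional response, e.g. 1 - inhibition/100 of the growth rate.
    log_base : {"e", "10"}
        Base of ``log_conc``; used only to back-transform the NEC to the
        concentration scale.
    """

    def __init__(self, log_conc, response, log_base: str = "e"):
        x = np.asarray(log_conc, dtype=float)
        y = np.asarray(response, dtype=float)
        if x.shape != y.shape or x.size < 3:
            raise ValueError("log_conc and response must align, n >= 3")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("inputs must be finite")
        if log_base not in ("e", "10"):
            raise ValueError("log_base must be 'e' or '10'")
        self.x = x
        self.y = y
        self.log_base = log_base

    @classmethod
    def from_endpoints(cls, endpoints: pd.DataFrame, exposure: pd.DataFrame,
                       log_base: str = "e", control_divisor: float = 10.0):
        """Build from an endpoint table and exposure series.

        Treatment replicates enter at the log of their analysis
        concentration. Control (and pooled solvent-control) replicates
        anchor ``alpha`` at a pseudo-log-concentration
        ``log(lowest treatment / control_divisor)`` since zero has no
        logarithm.
        """
        logf = np.log if log_base == "e" else np.log10
        conc_map = exposure.set_index("nominal_ugL")["analysis_ugL"]
        treat = endpoints[endpoints["role"] == "treatment"]
        conc = treat["nominal_ugL"].map(conc_map).to_numpy(dtype=float)
        if np.any(~np.isfinite(conc)):
            raise ValueError("missing analysis concentration for a treatment")
        ctrl = endpoints[endpoints["role"].isin(["control", "solvent_control"])]
        x0 = logf(conc.min() / control_divisor)
        x = np.concatenate([np.full(len(ctrl), x0), logf(conc)])
        y = np.concatenate([ctrl["proportional_response"].to_numpy(),
                            treat["proportional_response"].to_numpy()])
        return cls(x, y, log_base=log_base)

    # -- densities -------------------------------------------------------

    @staticmethod
    def model_mean(params, x):
        """Expected response at log-concentration ``x``.

        ``params`` is (alpha, beta, gamma, delta, sigma) or the first four.
        Constant at ``alpha - delta`` at and below the threshold ``gamma``.
        """
        a, b, g, d = (float(p) for p in params[:4])
        x = np.asarray(x, dtype=float)
        out = _model_mean(a, b, g, d, x)
        return out if out.ndim else float(out)

    @staticmethod
    def log_prior(params) -> float:
        """Joint log prior density; -inf outside the support."""
        a, b, g, d, s = (float(p) for p in params)
        if b <= 0 or not (0 < s <= _SIGMA_UPPER):
            return -np.inf
        lp = 0.5 * log(_PREC_ALPHA / (2 * pi)) - 0.5 * _PREC_ALPHA * a * a
        lp += (_GAMMA_SHAPE * log(_GAMMA_RATE) - lgamma(_GAMMA_SHAPE)
               + (_GAMMA_SHAPE - 1.0) * log(b) - _GAMMA_RATE * b)
        lp += 0.5 * log(_PREC_GAMMA / (2 * pi)) - 0.5 * _PREC_GAMMA * g * g
        lp += 0.5 * log(_PREC_DELTA / (2 * pi)) - 0.5 * _PREC_DELTA * d * d
        lp += -log(_SIGMA_UPPER)
        return lp

    def log_likelihood(self, params) -> float:
        a, b, g, d, s = (float(p) for p in params)
        if s <= 0:
            return -np.inf
        resid = self.y - _model_mean(a, b, g, d, self.x)
        n = self.y.size
        return -0.5 * n * log(2 * pi * s * s) - 0.5 * float(resid @ resid) / (s * s)

    def log_posterior(self, params) -> float:
        """Log posterior kernel: log prior + gaussian log likelihood."""
        lp = self.log_prior(params)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.log_likelihood(params)

    # -- sampling --------------------------------------------------------

    def sample_prior(self, n: int, seed: int = 0) -> pd.DataFrame:
        """Direct draws from the joint prior (validates its parameterisation)."""
        rng = np.random.default_rng(seed)
        return pd.DataFrame({
            "alpha": rng.normal(0.0, 1.0 / np.sqrt(_PREC_ALPHA), n),
            "beta": rng.gamma(_GAMMA_SHAPE, 1.0 / _GAMMA_RATE, n),
            "gamma": rng.normal(0.0, 1.0 / np.sqrt(_PREC_GAMMA), n),
            "delta": rng.normal(0.0, 1.0 / np.sqrt(_PREC_DELTA), n),
            "sigma": rng.uniform(0.0, _SIGMA_UPPER, n),
        })

    def _init_point(self, rng, use_likelihood):
        if not use_likelihood:
            return np.array([rng.normal(0, 1), rng.gamma(1.0, 1.0) + 0.1,
                             rng.normal(0, 1), rng.normal(0, 1),
                             rng.uniform(1.0, 20.0)])
        order = np.argsort(self.x)
        lowk = order[: max(3, self.x.size // 8)]
        a0 = float(np.mean(self.y[lowk]))
        g0 = float(np.median(self.x))
        s0 = float(np.clip(np.std(self.y) / 2 + 1e-3, 1e-3, _SIGMA_UPPER / 2))
        start = np.array([a0, 1.0, g0, 0.0, s0])
        jitter = np.array([0.05 * max(abs(a0), 0.1), 0.3,
                           0.3 * max(np.ptp(self.x), 0.5) / 2, 0.02, 0.0])
        pt = start + rng.normal(size=5) * jitter
        pt[1] = abs(pt[1]) + 1e-3
        pt[4] = float(np.clip(s0 * rng.uniform(0.5, 2.0), 1e-3, _SIGMA_UPPER - 1e-3))
        return pt

    def _start(self, rng, use_likelihood, logpost):
        theta = self._init_point(rng, use_likelihood)
        lp = logpost(theta)
        tries = 0
        while not np.isfinite(lp) and tries < 100:
            theta = self._init_point(rng, use_likelihood)
            lp = logpost(theta)
            tries += 1
        if not np.isfinite(lp):
            raise RuntimeError("could not find a finite starting point")
        return theta, lp

    def _run_chain_joint(self, rng, burn_in, draws, target_accept):
        """Adaptive full-covariance random-walk Metropolis (Haario-style).

        During burn-in the proposal covariance tracks the empirical chain
        covariance (scaled by 2.38²/d) and a global step-size multiplier is
        tuned toward the target acceptance rate; both are frozen at the end
        of burn-in so the kept draws come from a fixed Markov kernel.
        """
        logpost = self.log_posterior
        theta, lp = self._start(rng, True, logpost)
        d = 5
        s_d = 2.38 ** 2 / d
        history = np.empty((burn_in, d))

        # stage 1: component-wise scale adaptation moves the chain to the
        # mode region and calibrates marginal step sizes
        stage1 = max(burn_in // 2, 1)
        log_scales = np.log(np.array([0.05, 0.2, 0.2, 0.05, 0.05]))
        batch, batch_acc = 50, np.zeros(d)
        for it in range(stage1):
            for j in range(d):
                prop = theta.copy()
                prop[j] += np.exp(log_scales[j]) * rng.normal()
                lpp = logpost(prop)
                if np.log(rng.uniform()) < lpp - lp:
                    theta, lp = prop, lpp
                    batch_acc[j] += 1
            if (it + 1) % batch == 0:
                delta_n = min(0.1, ((it + 1) / batch) ** -0.5)
                log_scales += np.where(batch_acc / batch > target_accept,
                                       delta_n, -delta_n)
                batch_acc[:] = 0.0
            history[it] = theta

        # stage 2: joint proposals; covariance estimated from post-transient
        # history, refreshed periodically; global scale tuned to the target
        def _chol_from(h):
            emp = np.cov(h, rowvar=False)
            return np.linalg.cholesky(s_d * emp + 1e-12 * np.eye(d))

        chol = _chol_from(history[stage1 // 2:stage1])
        log_lam = 0.0
        for it in range(stage1, burn_in):
            prop = theta + np.exp(0.5 * log_lam) * (chol @ rng.standard_normal(d))
            lpp = logpost(prop)
            acc = np.log(rng.uniform()) < lpp - lp
            if acc:
                theta, lp = prop, lpp
            log_lam += (float(acc) - target_accept) / (1 + it - stage1) ** 0.6
            history[it] = theta
            if (it + 1 - stage1) % 200 == 0:
                lo = stage1 + (it + 1 - stage1) // 2
                chol = _chol_from(history[lo:it + 1])

        # sampling phase: frozen kernel (detailed balance preserved)
        chol = chol * np.exp(0.5 * log_lam)
        kept = np.empty((draws, d))
        accepts = 0
        for it in range(draws):
            prop = theta + chol @ rng.standard_normal(d)
            lpp = logpost(prop)
            if np.log(rng.uniform()) < lpp - lp:
                theta, lp = prop, lpp
                accepts += 1
            kept[it] = theta
        return kept, np.full(d, accepts / max(draws, 1))

    def _run_chain_componentwise(self, rng, burn_in, draws, target_accept):
        """Component-wise adaptive random-walk Metropolis on the prior only.

        The prior factorises over parameters, so single-site updates mix
        well; scales adapt in diminishing batches during burn-in and are
        frozen afterwards.
        """
        logpost = self.log_prior
        theta, lp = self._start(rng, False, logpost)
        log_scales = np.zeros(5)
        kept = np.empty((draws, 5))
        accepts = np.zeros(5)
        batch = 50
        batch_acc = np.zeros(5)
        total = burn_in + draws
        for it in range(total):
            for j in range(5):
                prop = theta.copy()
                prop[j] += np.exp(log_scales[j]) * rng.normal()
                lpp = logpost(prop)
                if np.log(rng.uniform()) < lpp - lp:
                    theta, lp = prop, lpp
                    batch_acc[j] += 1
                    if it >= burn_in:
                        accepts[j] += 1
            if it < burn_in and (it + 1) % batch == 0:
                delta_n = min(0.1, ((it + 1) / batch) ** -0.5)
                rate = batch_acc / batch
                log_scales += np.where(rate > target_accept, delta_n, -delta_n)
                batch_acc[:] = 0.0
            if it >= burn_in:
                kept[it - burn_in] = theta
        return kept, accepts / max(draws, 1)

    def _run_chain(self, rng, burn_in, draws, use_likelihood, target_accept):
        if use_likelihood:
            return self._run_chain_joint(rng, burn_in, draws, target_accept)
        return self._run_chain_componentwise(rng, burn_in, draws, target_accept)

    def fit(self, chains: int = 5, burn_in: int = 20000, draws: int = 10000,
            seed: int = 0, target_accept: float = 0.3,
            use_likelihood: bool = True) -> "NECResults":
        """Sample the posterior and return a :class:`NECResults`.

        ``use_likelihood=False`` samples the prior only (same machinery),
        which is useful for validating the prior parameterisation.
        Per-chain RNG streams are spawned deterministically from ``seed``.
        """
        ss = np.random.SeedSequence(int(seed))
        child = ss.spawn(chains)
        kept = np.empty((chains, draws, 5))
        acc = np.empty((chains, 5))
        for c in range(chains):
            rng = np.random.default_rng(child[c])
            kept[c], acc[c] = self._run_chain(rng, burn_in, draws,
                                              use_likelihood, target_accept)
        return NECResults(self, kept, acc,
                          settings={"chains": chains, "burn_in": burn_in,
                                    "draws": draws, "seed": int(seed),
                                    "use_likelihood": use_likelihood,
                                    "log_base": self.log_base})


class NECResults:
    """Posterior draws, convergence diagnostics and NEC summaries."""

    def __init__(self, model: NECModel, kept: np.ndarray, acceptance: np.ndarray,
                 settings: dict):
        self.model = model
        self.draws = kept            # (chains, draws, 5)
        self.acceptance = acceptance
        self.settings = settings
        self.rhat, self.ess = self._diagnostics()
        self.converged = bool((self.rhat <= _RHAT_MAX).all()
                              and (self.ess >= _ESS_MIN).all())

    def _diagnostics(self):
        import arviz as az
        data = {name: self.draws[:, :, i] for i, name in enumerate(PARAM_NAMES)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = az.from_dict(posterior=data)
            rhat = az.rhat(idata).to_pandas()
            ess = az.ess(idata).to_pandas()
        return rhat.reindex(list(PARAM_NAMES)), ess.reindex(list(PARAM_NAMES))

    @property
    def posterior(self) -> pd.DataFrame:
        """Tidy draws: one row per kept iteration, with a chain column."""
        chains, n, _ = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(chains * n, 5), columns=PARAM_NAMES)
        df.insert(0, "chain", np.repeat(np.arange(chains), n))
        return df

    def _to_conc(self, g):
        return np.exp(g) if self.settings["log_base"] == "e" else 10.0 ** g

    def nec_summary(self) -> dict:
        """NEC on the concentration scale: posterior median, mean, 95 % CI.

        The credible-interval bounds are the back-transform of the
        gamma-draw quantiles (monotone transform).
        """
        g = self.draws[:, :, 2].ravel()
        lo, med, hi = np.quantile(g, [0.025, 0.5, 0.975])
        return {
            "nec": float(self._to_conc(med)),
            "nec_mean": float(np.mean(self._to_conc(g))),
            "ci_low": float(self._to_conc(lo)),
            "ci_high": float(self._to_conc(hi)),
            "converged": self.converged,
        }

    def ecx(self, x_pct: float) -> dict:
        """Posterior ECx: concentration where the mean response has declined
        by ``x_pct`` % of the no-effect level ``alpha - delta``. Off the main
        reporting path (threshold tables use the 4PL ECx)."""
        a = self.draws[:, :, 0].ravel()
        b = self.draws[:, :, 1].ravel()
        g = self.draws[:, :, 2].ravel()
        d = self.draws[:, :, 3].ravel()
        frac = (1.0 - x_pct / 100.0)
        arg = (frac * (a - d) + d) / a
        with np.errstate(divide="ignore", invalid="ignore"):
            xc = g - np.log(arg) / b
        xc = xc[np.isfinite(xc)]
        lo, med, hi = np.quantile(xc, [0.025, 0.5, 0.975])
        return {"ecx": float(self._to_conc(med)),
                "ci_low": float(self._to_conc(lo)),
                "ci_high": float(self._to_conc(hi))}

    def summary(self) -> str:
        stats = self.posterior[list(PARAM_NAMES)].describe().T
        nec = self.nec_summary()
        lines = ["Bayesian NEC threshold-exponential model",
                 "-" * 58,
                 f"chains x kept draws: "
                 f"{self.settings['chains']} x {self.settings['draws']} "
                 f"(burn-in {self.settings['burn_in']})",
                 f"converged: {self.converged} "
                 f"(max R-hat {self.rhat.max():.3f}, min ESS {self.ess.min():.0f})",
                 "",
                 f"{'param':<7}{'mean':>10}{'sd':>10}{'2.5%':>10}{'97.5%':>10}"
                 f"{'R-hat':>8}{'ESS':>8}"]
        q = self.posterior[list(PARAM_NAMES)].quantile([0.025, 0.975])
        for p in PARAM_NAMES:
            lines.append(
                f"{p:<7}{stats.loc[p,'mean']:>10.4g}{stats.loc[p,'std']:>10.4g}"
                f"{q.loc[0.025,p]:>10.4g}{q.loc[0.975,p]:>10.4g}"
                f"{self.rhat[p]:>8.3f}{self.ess[p]:>8.0f}")
        lines.append("")
        lines.append(f"NEC (concentration scale): {nec['nec']:.4g} "
                     f"({nec['ci_low']:.4g}-{nec['ci_high']:.4g}) 95% CrI")
        return "\n".join(lines)

    def plot_trace(self, axes=None):
        import matplotlib.pyplot as plt

        if axes is None:
            _, axes = plt.subplots(len(PARAM_NAMES), 1, sharex=True, figsize=(7, 9))
        for i, (ax, p) in enumerate(zip(axes, PARAM_NAMES)):
            for c in range(self.draws.shape[0]):
                ax.plot(self.draws[c, :, i], lw=0.4)
            ax.set_ylabel(p)
        return axes

    def to_csv(self, path):
        self.posterior.to_csv(path, index=False)
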