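"""Univariate random-effects meta-analysis by restricted maximum likelihood.

Model: for study i with effect estimate y_i and known within-study variance
s_i^2,

    y_i ~ Normal(mu, s_i^2 + tau^2),

with tau^2 the between-study variance.  tau^2 is estimated by maximising the
restricted log-likelihood

    l_R(tau^2) = -1/2 [ sum log(s_i^2 + tau^2) + log sum w_i
                        + sum w_i (y_i - mu_hat)^2 ],    w_i = 1/(s_i^2+tau^2),

and mu by the inverse-variance weighted mean at the fitted tau^2.  The
standard error of mu is taken from the observed information of the joint
restricted objective in (mu, tau^2), so that it reflects the uncertainty in
the between-study variance estimate; the plain generalised-least-squares
standard error 1/sqrt(sum w_i) is also exposed.  95% confidence intervals
are Wald intervals on the log odds ratio scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess2

__all__ = ["UnivariateMeta", "UnivariateResults", "fit_uvma", "InsufficientDataError"]

_LOG_TAU2_LO, _LOG_TAU2_HI = np.log(1e-10), np.log(400.0)
_Z = 1.959963984540054  # Phi^{-1}(0.975)


class InsufficientDataError(ValueError):
    """Fewer than two usable effect estimates."""


@dataclass
class UnivariateResults:
    """Fitted univariate random-effects meta-analysis."""

    outcome_id: str | None
    mu: float
    se_mu: float
    se_mu_gls: float
    tau: float
    tau2: float
    ci_low: float
    ci_high: float
    n_studies: int
    status: str
    loglik: float

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.mu))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))

    @property
    def significant_5pct(self) -> bool:
        return bool(self.ci_low > 0 or self.ci_high < 0)

    def to_dict(self) -> dict:
        return {
            "outcome_id": self.outcome_id, "model": "univariate",
            "mu": self.mu, "se_mu": self.se_mu, "tau": self.tau,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "or": self.odds_ratio, "or_ci_low": self.or_ci[0],
            "or_ci_high": self.or_ci[1], "n_studies": self.n_studies,
            "status": self.status,
        }

    def summary(self) -> str:
        lo, hi = self.or_ci
        return (
            f"Univariate random-effects meta-analysis (REML)\n"
            f"  outcome:   {self.outcome_id}\n"
            f"  studies:   {self.n_studies}\n"
            f"  log OR:    {self.mu:.4f} (SE {self.se_mu:.4f})\n"
            f"  OR:        {self.odds_ratio:.2f} (95% CI {lo:.2f}-{hi:.2f})\n"
            f"  tau:       {self.tau:.4f}\n"
            f"  status:    {self.status}\n"
        )


class UnivariateMeta:
    """Random-effects meta-analysis model for one outcome.

    Parameters
    ----------
    y, v : array-like
        Effect estimates (log odds ratios) and their within-study variances.
    outcome_id : str, optional
        Label carried through to the results.
    """

    def __init__(self, y, v, outcome_id: str | None = None,
                 study_ids=None) -> None:
        self.y = np.asarray(y, dtype=float)
        self.v = np.asarray(v, dtype=float)
        if self.y.shape != self.v.shape or self.y.ndim != 1:
            raise ValueError("y and v must be 1-d arrays of equal length")
        if np.any(self.v <= 0):
            raise ValueError("within-study variances must be positive")
        if len(self.y) < 2:
            raise InsufficientDataError(
                f"need >= 2 non-missing effects, got {len(self.y)}")
        self.outcome_id = outcome_id
        self.study_ids = list(study_ids) if study_ids is not None else None

    @classmethod
    def from_effects(cls, effects: pd.DataFrame, outcome_id: str) -> "UnivariateMeta":
        """Build from a derived-effects frame (see ``derive_effects``)."""
        sub = effects[(effects["outcome_id"] == outcome_id) & (~effects["missing"])]
        return cls(sub["log_or"].to_numpy(), sub["var"].to_numpy(),
                   outcome_id=outcome_id, study_ids=list(sub["study_id"]))

    # -- likelihood ------------------------------------------------------
    def _mu_gls(self, tau2: float) -> tuple[float, float]:
        w = 1.0 / (self.v + tau2)
        sw = w.sum()
        return float((w * self.y).sum() / sw), float(sw)

    def restricted_nll(self, tau2: float, mu: float | None = None) -> float:
        """Negative restricted log-likelihood; mu profiled out when None."""
        if tau2 < 0:
            return np.inf
        w = 1.0 / (self.v + tau2)
        sw = w.sum()
        mu_hat = (w * self.y).sum() / sw if mu is None else mu
        quad = (w * (self.y - mu_hat) ** 2).sum()
        k = len(self.y)
        return 0.5 * (np.log(self.v + tau2).sum() + np.log(sw) + quad
                      + (k - 1) * np.log(2 * np.pi))

    def nll(self, tau2: float, mu: float | None = None) -> float:
        """Negative (unrestricted) log-likelihood, for ML comparison."""
        w = 1.0 / (self.v + tau2)
        mu_hat = (w * self.y).sum() / w.sum() if mu is None else mu
        quad = (w * (self.y - mu_hat) ** 2).sum()
        return 0.5 * (np.log(self.v + tau2).sum() + quad
                      + len(self.y) * np.log(2 * np.pi))

    # -- fitting ---------------------------------------------------------
    def fit(self, fix_tau2: float | None = None,
            restricted: bool = True) -> UnivariateResults:
        """Fit by REML (default) or ML; optionally with tau^2 held fixed.

        tau^2 is optimised on the log scale with an explicit comparison
        against the tau^2 = 0 boundary.
        """
        obj = self.restricted_nll if restricted else self.nll
        status = "converged"
        if fix_tau2 is not None:
            tau2 = float(fix_tau2)
        else:
            res = optimize.minimize_scalar(
                lambda lt: obj(np.exp(lt)),
                bounds=(_LOG_TAU2_LO, _LOG_TAU2_HI), method="bounded",
                options={"xatol": 1e-12})
            if not res.success:  # pragma: no cover - bounded Brent rarely fails
                status = "failed"
            tau2 = float(np.exp(res.x))
            if obj(0.0) <= res.fun or tau2 < 1e-9:
                tau2 = 0.0
        mu, sw = self._mu_gls(tau2)
        se_gls = 1.0 / np.sqrt(sw)
        se = self._se_information(mu, tau2, obj) if fix_tau2 is None else se_gls
        return UnivariateResults(
            outcome_id=self.outcome_id, mu=mu, se_mu=se, se_mu_gls=se_gls,
            tau=float(np.sqrt(tau2)), tau2=tau2,
            ci_low=mu - _Z * se, ci_high=mu + _Z * se,
            n_studies=len(self.y), status=status, loglik=-obj(tau2))

    def _se_information(self, mu: float, tau2: float, obj) -> float:
        """SE of mu from the observed information of the joint objective.

        At the tau^2 = 0 boundary the joint information is one-sided, so the
        GLS standard error is used there.
        """
        _, sw = self._mu_gls(tau2)
        if tau2 <= 0:
            return 1.0 / np.sqrt(sw)
        hess = approx_hess2(np.array([mu, tau2]),
                            lambda p: obj(p[1], mu=p[0]))
        try:
            cov = np.linalg.inv(hess)
            var = cov[0, 0]
            if var <= 0 or not np.isfinite(var):
                raise np.linalg.LinAlgError
            return float(np.sqrt(var))
        except np.linalg.LinAlgError:
            return 1.0 / np.sqrt(sw)


def fit_uvma(effects: pd.DataFrame, outcome_id: str,
             **fit_kwargs) -> UnivariateResults:
    """One-call univariate fit for one outcome of a derived-effects frame."""
    return UnivariateMeta.from_effects(effects, outcome_id).fit(**fit_kwargs)
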