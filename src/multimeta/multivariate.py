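"""Multivariate random-effects meta-analysis by restricted maximum likelihood.

Two models are provided, both estimated by (restricted) maximum likelihood
with explicit convergence diagnostics.

Fully hierarchical model
    For study i with observed effect vector y_i over its reported outcomes,

        y_i ~ Normal(mu_i, S_i + Sigma_i),

    where S_i is the *known* within-study covariance matrix (diagonal =
    within-study variances, off-diagonals from the analytic structural
    correlations or externally fixed values) and Sigma is the between-study
    covariance matrix, restricted to the study's observed outcomes.  Sigma
    is parameterised through its Cholesky factor with log-transformed
    diagonal, or through between-study SDs against a fixed correlation
    matrix when correlations are held fixed.

Overall-correlation (Riley) model
    When within-study correlations are unknown, outcome j of study i has
    marginal variance s_ij^2 + psi_j^2 and each within-study outcome pair
    (j, k) has covariance rho_jk sqrt((s_ij^2+psi_j^2)(s_ik^2+psi_k^2)): a
    single "overall" correlation per pair amalgamating the within- and
    between-study correlation.  rho is parameterised by a Fisher
    z-transform; with ``fix_correlations`` supplied only (mu, psi) are
    estimated.

Studies with missing outcomes contribute the observed sub-vector and the
matching sub-matrix, which is what produces borrowing of strength across
outcomes.  Summary effects mu are profiled out by generalised least squares;
their covariance comes from the observed information of the joint objective
in (mu, variance parameters), so standard errors account for uncertainty in
the variance estimates (a GLS-only covariance is available behind a flag).

Failure to converge is a reportable state (`status = "failed_convergence"`),
not an exception: multivariate models of sparse meta-analytic data often
cannot be estimated, and the comparison layer renders such fits as "FC".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize
from statsmodels.tools.numdiff import approx_fprime, approx_hess2

from .data import MetaDataset, RelationKind, ValidationError, eligibility_filter
from .effects import WithinStudyCov, assemble_within_cov, derive_effects
from .univariate import InsufficientDataError, _Z

__all__ = [
    "FitOptions",
    "MultivariateResults",
    "HierarchicalMeta",
    "RileyMeta",
    "OptimizerTrace",
    "convergence_policy",
    "fit_hierarchical",
    "fit_riley",
    "fit_all_pairs",
]

_BIG = 1e10
_BOUNDARY_RHO = 1e-4      # |rho| within this of 1 is reported at the boundary
_LOG_VAR_BOUNDS = (-24.0, 7.0)
_Z_BOUNDS = (-7.0, 7.0)   # Fisher z, |rho| <= tanh(7) ~ 0.999998
_CHOL_OFF_BOUNDS = (-50.0, 50.0)
_LOG_DIAG_BOUNDS = (-12.0, 3.5)


# ---------------------------------------------------------------------------
# options / results
# ---------------------------------------------------------------------------

@dataclass
class FitOptions:
    """Estimation controls shared by the multivariate models."""

    restricted: bool = True
    max_iterations: int = 500
    objective_tolerance: float = 1e-8
    n_random_starts: int = 10
    seed: int = 0
    fix_correlations: np.ndarray | dict | None = None
    gls_cov: bool = False

    def __post_init__(self) -> None:
        if self.n_random_starts < 1:
            raise ValueError("n_random_starts must be >= 1")


@dataclass
class MultivariateResults:
    """Fitted multivariate meta-analysis (hierarchical or Riley)."""

    model: str                      # "hierarchical" | "riley" | "riley_fixed"
    outcome_ids: list[str]
    mu: np.ndarray
    cov_mu: np.ndarray
    tau: np.ndarray                 # between-study SDs (psi_j for Riley)
    rho_between: np.ndarray         # between-study / overall correlations
    ci_low: np.ndarray
    ci_high: np.ndarray
    status: str                     # "converged" | "failed_convergence"
    boundary_flags: np.ndarray      # bool, per outcome pair (d x d)
    n_starts_used: int
    loglik: float
    n_studies: np.ndarray           # reporting studies per outcome
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.status == "converged"

    @property
    def se_mu(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_mu))

    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.mu)

    def significant_5pct(self) -> np.ndarray:
        return (self.ci_low > 0) | (self.ci_high < 0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for j, oid in enumerate(self.outcome_ids):
            rows.append({
                "outcome_id": oid, "model": self.model,
                "mu": self.mu[j], "se_mu": self.se_mu[j],
                "or": np.exp(self.mu[j]),
                "or_ci_low": np.exp(self.ci_low[j]),
                "or_ci_high": np.exp(self.ci_high[j]),
                "tau": self.tau[j], "n_studies": int(self.n_studies[j]),
                "status": self.status,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        head = (f"Multivariate random-effects meta-analysis "
                f"({self.model}, REML)\n"
                f"  status: {self.status} "
                f"(starts used: {self.n_starts_used})\n"
                f"  log-restricted-likelihood: {self.loglik:.4f}\n")
        lines = [head,
                 f"  {'outcome':<22}{'OR':>8}{'95% CI':>18}{'tau':>8}{'k':>4}"]
        for j, oid in enumerate(self.outcome_ids):
            lo, hi = np.exp(self.ci_low[j]), np.exp(self.ci_high[j])
            lines.append(
                f"  {oid:<22}{np.exp(self.mu[j]):>8.2f}"
                f"{f'({lo:.2f}-{hi:.2f})':>18}{self.tau[j]:>8.2f}"
                f"{int(self.n_studies[j]):>4}")
        d = len(self.outcome_ids)
        if d > 1:
            lines.append("  correlations:")
            for j, k in itertools.combinations(range(d), 2):
                flag = " (boundary)" if self.boundary_flags[j, k] else ""
                lines.append(
                    f"    rho({self.outcome_ids[j]}, {self.outcome_ids[k]}) "
                    f"= {self.rho_between[j, k]:+.3f}{flag}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# convergence policy
# ---------------------------------------------------------------------------

@dataclass
class OptimizerTrace:
    """What the convergence policy inspects after an optimisation run."""

    fun: float                 # objective (negative log-likelihood) at optimum
    improvement: float         # objective decrease over the final polish step
    grad: np.ndarray           # numeric gradient at the optimum
    hess_eig_min: float        # min eigenvalue of the nll Hessian, free coords
    at_bound: np.ndarray       # bool mask of parameters at a box boundary
    n_free: int


def convergence_policy(trace: OptimizerTrace,
                       options: FitOptions) -> tuple[bool, dict]:
    """Decide whether an optimisation run counts as converged.

    Criteria (all required):

    1. the final polish step improved the objective by less than
       ``options.objective_tolerance``;
    2. the gradient is numerically zero (max |g| < 1e-5 relative to the
       objective scale) on every parameter not sitting at a boundary;
    3. the objective's Hessian restricted to non-boundary parameters is
       positive definite (the log-likelihood is locally concave) with
       minimum eigenvalue above 1e-4 — a ~zero eigenvalue means a flat,
       non-identified direction and is classed as failure.

    Parameters pinned at a box boundary (e.g. a correlation at +/-1 or a
    between-study variance at zero) are exempt from 2 and 3.
    """
    scale = max(1.0, abs(trace.fun))
    free = ~trace.at_bound
    diag = {
        "objective": trace.fun,
        "final_improvement": trace.improvement,
        "grad_max_free": float(np.max(np.abs(trace.grad[free])))
        if free.any() else 0.0,
        "hess_eig_min_free": trace.hess_eig_min,
        "n_at_boundary": int(trace.at_bound.sum()),
    }
    if trace.n_free == 0:
        return True, diag
    ok = trace.improvement < max(options.objective_tolerance, 1e-12) * scale
    if free.any():
        ok = ok and diag["grad_max_free"] < 1e-5 * scale
        ok = ok and trace.hess_eig_min > 1e-4
    diag["converged"] = bool(ok)
    return bool(ok), diag


# ---------------------------------------------------------------------------
# parameter maps (theta -> between-study structure)
# ---------------------------------------------------------------------------

class _ThetaMap:
    """Maps the unconstrained parameter vector to model covariance pieces."""

    labels: list[str]
    bounds: list[tuple[float, float]]

    @property
    def n_free(self) -> int:
        return len(self.labels)


class _CholMap(_ThetaMap):
    """Sigma = L L' with log-transformed diagonal of L (hierarchical)."""

    def __init__(self, d: int, tau0: np.ndarray):
        self.d = d
        self.labels, self.bounds, self._x0 = [], [], []
        for j in range(d):
            for k in range(j):
                self.labels.append(f"L[{j},{k}]")
                self.bounds.append(_CHOL_OFF_BOUNDS)
                self._x0.append(0.0)
            self.labels.append(f"log L[{j},{j}]")
            self.bounds.append(_LOG_DIAG_BOUNDS)
            self._x0.append(float(np.log(max(tau0[j], 1e-3))))

    def x0(self) -> np.ndarray:
        return np.array(self._x0)

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        L = np.zeros((self.d, self.d))
        pos = 0
        for j in range(self.d):
            for k in range(j):
                L[j, k] = theta[pos]
                pos += 1
            L[j, j] = np.exp(theta[pos])
            pos += 1
        return L @ L.T


class _FixedCorrMap(_ThetaMap):
    """Sigma = D R D with R fixed; free log between-study SDs."""

    def __init__(self, R: np.ndarray, tau0: np.ndarray):
        self.R = np.asarray(R, dtype=float)
        d = self.R.shape[0]
        self.labels = [f"log tau[{j}]" for j in range(d)]
        self.bounds = [_LOG_DIAG_BOUNDS] * d
        self._x0 = np.log(np.maximum(tau0, 1e-3))

    def x0(self) -> np.ndarray:
        return np.array(self._x0)

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        tau = np.exp(theta)
        return self.R * np.outer(tau, tau)


class _FixedTauMap(_ThetaMap):
    """Fixed between-study SDs; free Fisher-z correlations per pair."""

    def __init__(self, tau: np.ndarray):
        self.tau = np.asarray(tau, dtype=float)
        d = len(self.tau)
        self.pairs = list(itertools.combinations(range(d), 2))
        self.labels = [f"z[{j},{k}]" for j, k in self.pairs]
        self.bounds = [_Z_BOUNDS] * len(self.pairs)

    def x0(self) -> np.ndarray:
        return np.zeros(len(self.pairs))

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        d = len(self.tau)
        R = np.eye(d)
        for (j, k), z in zip(self.pairs, theta):
            R[j, k] = R[k, j] = np.tanh(z)
        return R * np.outer(self.tau, self.tau)


class _FixedSigmaMap(_ThetaMap):
    """Everything fixed: pure GLS."""

    def __init__(self, sigma: np.ndarray):
        self._sigma = np.asarray(sigma, dtype=float)
        self.labels, self.bounds = [], []

    def x0(self) -> np.ndarray:
        return np.zeros(0)

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        return self._sigma


# ---------------------------------------------------------------------------
# base machinery
# ---------------------------------------------------------------------------

def _dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    """DerSimonian-Laird moment estimate, used only to initialise REML."""
    w = 1.0 / v
    mu = (w * y).sum() / w.sum()
    q = (w * (y - mu) ** 2).sum()
    denom = w.sum() - (w ** 2).sum() / w.sum()
    if denom <= 0:
        return 0.0
    return max(0.0, float((q - (len(y) - 1)) / denom))


class _MultivariateBase:
    """Shared REML machinery over studies with arbitrary missingness."""

    model_name = "multivariate"

    def __init__(self, y: np.ndarray, outcome_ids: list[str],
                 study_ids=None) -> None:
        self.y = np.asarray(y, dtype=float)
        if self.y.ndim != 2:
            raise ValidationError("y must be a (studies x outcomes) array")
        self.k, self.d = self.y.shape
        if self.d < 2:
            raise ValidationError("multivariate models need >= 2 outcomes")
        if len(outcome_ids) != self.d:
            raise ValidationError("outcome_ids length must match y columns")
        self.outcome_ids = list(outcome_ids)
        self.study_ids = (list(study_ids) if study_ids is not None
                          else [f"study_{i+1}" for i in range(self.k)])
        self.n_per_outcome = (~np.isnan(self.y)).sum(axis=0)
        if (self.n_per_outcome < 2).any():
            bad = [o for o, n in zip(self.outcome_ids, self.n_per_outcome)
                   if n < 2]
            raise InsufficientDataError(
                f"outcomes {bad} have < 2 reporting studies")
        self._build_patterns()

    # -- patterns --------------------------------------------------------
    def _build_patterns(self) -> None:
        """Group studies by which outcomes they observe, for batched algebra."""
        pats: dict[tuple[int, ...], list[int]] = {}
        for i in range(self.k):
            idx = tuple(np.flatnonzero(~np.isnan(self.y[i])))
            if idx:
                pats.setdefault(idx, []).append(i)
        self.patterns = []
        for idx, rows in pats.items():
            self.patterns.append({
                "idx": np.array(idx),
                "rows": np.array(rows),
                "y": self.y[np.ix_(rows, idx)],
            })
        self.n_obs_total = int((~np.isnan(self.y)).sum())

    # hooks -------------------------------------------------------------
    def _pattern_V(self, pat: dict, theta: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # likelihood ---------------------------------------------------------
    def _gls_pieces(self, theta: np.ndarray):
        """Return (A, b, yVy, sum_logdet) or None when some V is not PD."""
        A = np.zeros((self.d, self.d))
        b = np.zeros(self.d)
        yVy = 0.0
        sld = 0.0
        for pat in self.patterns:
            V = self._pattern_V(pat, theta)
            sign, logdet = np.linalg.slogdet(V)
            if np.any(sign <= 0):
                return None
            sld += logdet.sum()
            Vinv = np.linalg.inv(V)
            idx = pat["idx"]
            A[np.ix_(idx, idx)] += Vinv.sum(axis=0)
            b[idx] += np.einsum("mij,mj->i", Vinv, pat["y"])
            yVy += float(np.einsum("mi,mij,mj->", pat["y"], Vinv, pat["y"]))
        return A, b, yVy, sld

    def nll(self, theta: np.ndarray, mu: np.ndarray | None = None,
            restricted: bool = True) -> float:
        pieces = self._gls_pieces(theta)
        if pieces is None:
            return _BIG
        A, b, yVy, sld = pieces
        signA, logdetA = np.linalg.slogdet(A)
        if signA <= 0:
            return _BIG
        try:
            mu_hat = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return _BIG
        if mu is None:
            quad = yVy - b @ mu_hat
        else:
            quad = yVy - 2 * b @ mu + mu @ A @ mu
        val = 0.5 * (sld + quad + self.n_obs_total * np.log(2 * np.pi))
        if restricted:
            val += 0.5 * (logdetA - self.d * np.log(2 * np.pi))
        return float(val) if np.isfinite(val) else _BIG

    def _gls(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        pieces = self._gls_pieces(theta)
        if pieces is None:
            raise ValidationError("covariance not positive definite at optimum")
        A, b, _, _ = pieces
        return np.linalg.solve(A, b), np.linalg.inv(A)

    # fitting ------------------------------------------------------------
    def _optimize_once(self, x0: np.ndarray, options: FitOptions):
        f = lambda th: self.nll(th, restricted=options.restricted)
        bounds = self._map.bounds
        res = optimize.minimize(
            f, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": options.max_iterations,
                     "ftol": 1e-14, "gtol": 1e-9})
        x, fun = res.x, res.fun
        improvement = np.inf
        for _ in range(4):
            res2 = optimize.minimize(
                f, x, method="Nelder-Mead", bounds=bounds,
                options={"xatol": 1e-10, "fatol": 1e-13,
                         "maxiter": 400 * max(1, len(x))})
            improvement = fun - res2.fun
            if res2.fun <= fun:
                x, fun = res2.x, res2.fun
            if improvement < max(options.objective_tolerance, 1e-12):
                break
        lo = np.array([bb[0] for bb in bounds])
        hi = np.array([bb[1] for bb in bounds])
        at_bound = (x - lo < 1e-3) | (hi - x < 1e-3)
        grad = (approx_fprime(x, f, centered=True) if len(x)
                else np.zeros(0))
        if (~at_bound).any():
            hess = approx_hess2(x, f)
            sub = hess[np.ix_(~at_bound, ~at_bound)]
            eig_min = float(np.linalg.eigvalsh(0.5 * (sub + sub.T)).min())
        else:
            eig_min = np.inf
        trace = OptimizerTrace(
            fun=float(fun), improvement=float(max(improvement, 0.0)),
            grad=grad, hess_eig_min=eig_min, at_bound=at_bound,
            n_free=len(x))
        return x, trace

    def fit(self, options: FitOptions | None = None) -> MultivariateResults:
        """Estimate the model; never raises on lack of convergence."""
        options = options or FitOptions()
        rng = np.random.default_rng(options.seed)
        x0 = self._map.x0()
        if self._map.n_free == 0:
            mu, cov = self._gls(x0)
            return self._make_results(x0, mu, cov, "converged", 1,
                                      {"note": "no free variance parameters"},
                                      options)
        best = None
        n_starts = 0
        for start in range(options.n_random_starts):
            n_starts += 1
            xs = x0 if start == 0 else self._perturb(x0, rng)
            x, trace = self._optimize_once(xs, options)
            ok, diag = convergence_policy(trace, options)
            if best is None or trace.fun < best[1].fun - 1e-12:
                best = (x, trace, diag, ok)
            elif ok and abs(trace.fun - best[1].fun) < 1e-6 and not best[3]:
                best = (x, trace, diag, ok)
            if ok:
                best = (x, trace, diag, ok)
                break
        x, trace, diag, ok = best
        status = "converged" if ok else "failed_convergence"
        try:
            mu, gls_cov = self._gls(x)
        except ValidationError:
            mu = np.full(self.d, np.nan)
            gls_cov = np.full((self.d, self.d), np.nan)
            status = "failed_convergence"
        cov = gls_cov
        if (status == "converged" and not options.gls_cov
                and np.isfinite(mu).all()):
            cov = self._information_cov(x, mu, trace.at_bound, options,
                                        fallback=gls_cov)
        return self._make_results(x, mu, cov, status, n_starts, diag, options)

    def _perturb(self, x0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        lo = np.array([b[0] for b in self._map.bounds])
        hi = np.array([b[1] for b in self._map.bounds])
        return np.clip(x0 + rng.normal(scale=1.0, size=len(x0)), lo + 1e-6,
                       hi - 1e-6)

    def _information_cov(self, x, mu, at_bound, options, fallback):
        """mu-block of the inverse observed information of the joint nll."""
        free = np.flatnonzero(~at_bound)

        def joint(p):
            th = x.copy()
            th[free] = p[self.d:]
            return self.nll(th, mu=p[:self.d], restricted=options.restricted)

        p0 = np.concatenate([mu, x[free]])
        try:
            H = approx_hess2(p0, joint)
            H = 0.5 * (H + H.T)
            cov = np.linalg.inv(H)[:self.d, :self.d]
            cov = 0.5 * (cov + cov.T)
            if not np.all(np.isfinite(cov)):
                return fallback
            eigs = np.linalg.eigvalsh(cov)
            if eigs.min() <= 0:
                return fallback
            return cov
        except np.linalg.LinAlgError:
            return fallback

    # results ------------------------------------------------------------
    def _tau_rho(self, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def _make_results(self, theta, mu, cov, status, n_starts, diag,
                      options) -> MultivariateResults:
        tau, rho = self._tau_rho(theta)
        tau = np.where(tau < 1e-5, 0.0, tau)
        boundary = np.zeros((self.d, self.d), dtype=bool)
        rho_out = rho.copy()
        for j, k in itertools.combinations(range(self.d), 2):
            if abs(rho[j, k]) > 1 - _BOUNDARY_RHO:
                boundary[j, k] = boundary[k, j] = True
                rho_out[j, k] = rho_out[k, j] = float(np.sign(rho[j, k]))
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        ll = -self.nll(theta, restricted=options.restricted)
        return MultivariateResults(
            model=self.model_name, outcome_ids=self.outcome_ids,
            mu=mu, cov_mu=cov, tau=tau, rho_between=rho_out,
            ci_low=mu - _Z * se, ci_high=mu + _Z * se,
            status=status, boundary_flags=boundary, n_starts_used=n_starts,
            loglik=float(ll), n_studies=self.n_per_outcome.copy(),
            diagnostics=diag)


# ---------------------------------------------------------------------------
# hierarchical model
# ---------------------------------------------------------------------------

class HierarchicalMeta(_MultivariateBase):
    """Fully hierarchical multivariate model with known within-study S_i.

    Parameters
    ----------
    y : (k, d) array
        Log odds ratios, NaN where an outcome is missing in a study.
    within : list of (p_i, p_i) arrays
        Within-study covariance over each study's observed outcomes, in the
        same outcome order as the columns of ``y``.
    fix_rho_between : (d, d) array, optional
        Hold the between-study correlation matrix fixed (free SDs).
    fix_tau : length-d array, optional
        Hold the between-study SDs fixed (free correlations, Fisher z).
    """

    model_name = "hierarchical"

    def __init__(self, y, within, outcome_ids, study_ids=None,
                 fix_rho_between=None, fix_tau=None) -> None:
        super().__init__(y, outcome_ids, study_ids)
        if len(within) != self.k:
            raise ValidationError("need one within-study matrix per study")
        self.within = [np.asarray(S, dtype=float) for S in within]
        for i, pat_idx in enumerate(
                tuple(np.flatnonzero(~np.isnan(self.y[i]))) for i in range(self.k)):
            if self.within[i].shape != (len(pat_idx), len(pat_idx)):
                raise ValidationError(
                    f"study {self.study_ids[i]!r}: within-study matrix has "
                    f"shape {self.within[i].shape}, expected "
                    f"({len(pat_idx)}, {len(pat_idx)})")
        for pat in self.patterns:
            pat["S"] = np.stack([self.within[i] for i in pat["rows"]])
        tau0 = self._tau0()
        if fix_rho_between is not None and fix_tau is not None:
            R = np.asarray(fix_rho_between, dtype=float)
            t = np.asarray(fix_tau, dtype=float)
            self._map: _ThetaMap = _FixedSigmaMap(R * np.outer(t, t))
        elif fix_rho_between is not None:
            self._map = _FixedCorrMap(fix_rho_between, tau0)
        elif fix_tau is not None:
            self._map = _FixedTauMap(fix_tau)
        else:
            self._map = _CholMap(self.d, tau0)

    @classmethod
    def from_dataset(cls, dataset: MetaDataset, outcomes=None,
                     fixed_corr=None, **kwargs) -> "HierarchicalMeta":
        """Derive effects and within-study matrices from a raw dataset."""
        outcomes = list(outcomes) if outcomes is not None else dataset.outcome_ids
        effects = derive_effects(dataset)
        effects = effects[effects["outcome_id"].isin(outcomes)]
        covs, complete = assemble_within_cov(
            effects, dataset.relations, outcomes, fixed_corr=fixed_corr)
        if not complete:
            raise ValidationError(
                "within-study correlations unavailable for some outcome pair; "
                "use RileyMeta (overall-correlation model) instead")
        return cls.from_effects(effects, covs, outcomes, **kwargs)

    @classmethod
    def from_effects(cls, effects: pd.DataFrame, within: list[WithinStudyCov],
                     outcomes, **kwargs) -> "HierarchicalMeta":
        outcomes = list(outcomes)
        by_study = {w.study_id: w for w in within}
        study_ids = [w.study_id for w in within]
        y = np.full((len(study_ids), len(outcomes)), np.nan)
        mats = []
        obs = effects[~effects["missing"]]
        for i, sid in enumerate(study_ids):
            w = by_study[sid]
            for oid in w.outcome_ids:
                row = obs[(obs["study_id"] == sid) & (obs["outcome_id"] == oid)]
                y[i, outcomes.index(oid)] = float(row["log_or"].iloc[0])
            mats.append(w.matrix)
        return cls(y, mats, outcomes, study_ids=study_ids, **kwargs)

    def _tau0(self) -> np.ndarray:
        tau0 = np.zeros(self.d)
        for j in range(self.d):
            rows = ~np.isnan(self.y[:, j])
            v = np.array([
                self.within[i][list(np.flatnonzero(~np.isnan(self.y[i]))).index(j),
                               list(np.flatnonzero(~np.isnan(self.y[i]))).index(j)]
                for i in np.flatnonzero(rows)])
            tau0[j] = np.sqrt(_dl_tau2(self.y[rows, j], v))
        return tau0

    def _pattern_V(self, pat, theta) -> np.ndarray:
        sigma = self._map.sigma(theta)
        idx = pat["idx"]
        return pat["S"] + sigma[np.ix_(idx, idx)]

    def _tau_rho(self, theta):
        sigma = self._map.sigma(theta)
        tau = np.sqrt(np.clip(np.diag(sigma), 0, None))
        denom = np.outer(tau, tau)
        with np.errstate(divide="ignore", invalid="ignore"):
            rho = np.where(denom > 0, sigma / denom, 0.0)
        np.fill_diagonal(rho, 1.0)
        return tau, np.clip(rho, -1.0, 1.0)


# ---------------------------------------------------------------------------
# Riley overall-correlation model
# ---------------------------------------------------------------------------

class RileyMeta(_MultivariateBase):
    """Overall-correlation multivariate model (no within-study correlations).

    Parameters
    ----------
    y, v : (k, d) arrays
        Log odds ratios and within-study variances, NaN where missing.
    fix_correlations : (d, d) array or {(id_a, id_b): rho} dict, optional
        Hold overall correlations fixed (``model = "riley_fixed"``); NaN
        entries in a matrix remain free.
    share_rho : bool
        Share a single overall correlation across all pairs (d > 2).
    """

    def __init__(self, y, v, outcome_ids, study_ids=None,
                 fix_correlations=None, fix_psi=None,
                 share_rho: bool = False) -> None:
        super().__init__(y, outcome_ids, study_ids)
        self.v = np.asarray(v, dtype=float)
        if self.v.shape != self.y.shape:
            raise ValidationError("v must match the shape of y")
        if np.logical_xor(np.isnan(self.y), np.isnan(self.v)).any():
            raise ValidationError("y and v must share their missingness pattern")
        for pat in self.patterns:
            pat["s2"] = self.v[np.ix_(pat["rows"], pat["idx"])]
        self.pairs = list(itertools.combinations(range(self.d), 2))
        self.share_rho = bool(share_rho)
        self._fixed_rho = self._resolve_fixed(fix_correlations)
        self._fix_psi = (np.asarray(fix_psi, dtype=float)
                         if fix_psi is not None else None)
        self._build_map()

    @property
    def model_name(self) -> str:  # type: ignore[override]
        if any(r is not None for r in self._fixed_rho.values()):
            return "riley_fixed"
        return "riley"

    @classmethod
    def from_effects(cls, effects: pd.DataFrame, outcomes,
                     **kwargs) -> "RileyMeta":
        outcomes = list(outcomes)
        obs = effects[~effects["missing"]]
        obs = obs[obs["outcome_id"].isin(outcomes)]
        study_ids = list(dict.fromkeys(obs["study_id"]))
        y = np.full((len(study_ids), len(outcomes)), np.nan)
        v = np.full_like(y, np.nan)
        for _, r in obs.iterrows():
            i = study_ids.index(r["study_id"])
            j = outcomes.index(r["outcome_id"])
            y[i, j] = r["log_or"]
            v[i, j] = r["var"]
        return cls(y, v, outcomes, study_ids=study_ids, **kwargs)

    @classmethod
    def from_dataset(cls, dataset: MetaDataset, outcomes=None,
                     **kwargs) -> "RileyMeta":
        outcomes = list(outcomes) if outcomes is not None else dataset.outcome_ids
        return cls.from_effects(derive_effects(dataset), outcomes, **kwargs)

    def _resolve_fixed(self, fix) -> dict[tuple[int, int], float | None]:
        fixed: dict[tuple[int, int], float | None] = {p: None for p in self.pairs}
        if fix is None:
            return fixed
        if isinstance(fix, dict):
            for (a, b), val in fix.items():
                ja, jb = self.outcome_ids.index(a), self.outcome_ids.index(b)
                fixed[(min(ja, jb), max(ja, jb))] = float(val)
            return fixed
        mat = np.asarray(fix, dtype=float)
        for j, k in self.pairs:
            if not np.isnan(mat[j, k]):
                fixed[(j, k)] = float(mat[j, k])
        return fixed

    def _build_map(self) -> None:
        m = _ThetaMap()
        m.labels, m.bounds = [], []
        x0 = []
        self._psi_slice = None
        if self._fix_psi is None:
            tau0 = np.zeros(self.d)
            for j in range(self.d):
                rows = ~np.isnan(self.y[:, j])
                tau0[j] = _dl_tau2(self.y[rows, j], self.v[rows, j])
            m.labels += [f"log psi2[{j}]" for j in range(self.d)]
            m.bounds += [_LOG_VAR_BOUNDS] * self.d
            x0 += list(np.log(np.maximum(tau0, 1e-4)))
            self._psi_slice = slice(0, self.d)
        self._free_pairs = [p for p in self.pairs if self._fixed_rho[p] is None]
        n_z = (1 if (self.share_rho and self._free_pairs) else
               len(self._free_pairs))
        start = self.d if self._fix_psi is None else 0
        self._z_slice = slice(start, start + n_z)
        if n_z:
            if self.share_rho:
                m.labels += ["z[shared]"]
            else:
                m.labels += [f"z[{j},{k}]" for j, k in self._free_pairs]
            m.bounds += [_Z_BOUNDS] * n_z
            x0 += [0.0] * n_z
        m.x0 = lambda: np.array(x0)  # type: ignore[attr-defined]
        self._map = m

    def _psi2(self, theta: np.ndarray) -> np.ndarray:
        if self._fix_psi is not None:
            return self._fix_psi ** 2
        return np.exp(theta[self._psi_slice])

    def _rho_matrix(self, theta: np.ndarray) -> np.ndarray:
        R = np.eye(self.d)
        z = theta[self._z_slice]
        for j, k in self.pairs:
            fixed = self._fixed_rho[(j, k)]
            if fixed is not None:
                R[j, k] = R[k, j] = fixed
        if self._free_pairs:
            if self.share_rho:
                vals = [np.tanh(z[0])] * len(self._free_pairs)
            else:
                vals = np.tanh(z)
            for (j, k), val in zip(self._free_pairs, vals):
                R[j, k] = R[k, j] = val
        return R

    def _pattern_V(self, pat, theta) -> np.ndarray:
        psi2 = self._psi2(theta)
        idx = pat["idx"]
        tot = pat["s2"] + psi2[idx]          # (m, p) marginal variances
        sd = np.sqrt(tot)
        R = self._rho_matrix(theta)[np.ix_(idx, idx)]
        return R[None, :, :] * sd[:, :, None] * sd[:, None, :]

    def _tau_rho(self, theta):
        return np.sqrt(self._psi2(theta)), self._rho_matrix(theta)


# ---------------------------------------------------------------------------
# functional wrappers & the all-pairs driver
# ---------------------------------------------------------------------------

def fit_hierarchical(y, within, outcome_ids,
                     options: FitOptions | None = None,
                     **kwargs) -> MultivariateResults:
    """Fit the fully hierarchical model (see :class:`HierarchicalMeta`)."""
    return HierarchicalMeta(y, within, outcome_ids, **kwargs).fit(options)


def fit_riley(y, v, outcome_ids, options: FitOptions | None = None,
              **kwargs) -> MultivariateResults:
    """Fit the overall-correlation model (see :class:`RileyMeta`)."""
    options = options or FitOptions()
    if options.fix_correlations is not None and "fix_correlations" not in kwargs:
        kwargs["fix_correlations"] = options.fix_correlations
    return RileyMeta(y, v, outcome_ids, **kwargs).fit(options)


def _failed_fit(model: str, outcomes: list[str], reason: str,
                n_studies) -> MultivariateResults:
    d = len(outcomes)
    nanv = np.full(d, np.nan)
    return MultivariateResults(
        model=model, outcome_ids=outcomes, mu=nanv.copy(),
        cov_mu=np.full((d, d), np.nan), tau=nanv.copy(),
        rho_between=np.full((d, d), np.nan), ci_low=nanv.copy(),
        ci_high=nanv.copy(), status="failed_convergence",
        boundary_flags=np.zeros((d, d), dtype=bool), n_starts_used=0,
        loglik=np.nan, n_studies=np.asarray(n_studies),
        diagnostics={"reason": reason})


def fit_all_pairs(dataset: MetaDataset, options: FitOptions | None = None,
                  min_studies: int = 3,
                  fixed_corr=None) -> dict[str, MultivariateResults]:
    """Fit every eligible outcome pair, plus the full joint model.

    Each pair is fitted with the hierarchical model when its within-study
    correlations are analytically available (structural relation between the
    outcomes), and with the Riley model otherwise; likewise the full d-variate
    model.  Per-fit failures are recorded as ``failed_convergence`` statuses,
    never raised, so one failing pair does not affect the others.

    Returns a mapping from labels such as ``"bivariate(1,2)"`` (1-based
    positions within the eligible outcomes) to results.
    """
    options = options or FitOptions()
    elig = eligibility_filter(dataset, min_studies=min_studies)
    outcomes = elig.eligible_outcomes
    if len(outcomes) < 2:
        raise ValidationError(
            "need >= 2 eligible outcomes for a multivariate analysis")
    effects = derive_effects(dataset)
    results: dict[str, MultivariateResults] = {}

    def one_fit(subset: list[str], label: str) -> None:
        covs, complete = assemble_within_cov(
            effects[effects["outcome_id"].isin(subset)],
            dataset.relations, subset, fixed_corr=fixed_corr)
        n_rep = [len(dataset.studies_reporting(o)) for o in subset]
        try:
            if complete:
                model: _MultivariateBase = HierarchicalMeta.from_effects(
                    effects, covs, subset)
            else:
                model = RileyMeta.from_effects(
                    effects, subset, fix_correlations=_subset_fixed(
                        fixed_corr, subset, outcomes=dataset.outcome_ids))
            results[label] = model.fit(options)
        except (InsufficientDataError, ValidationError) as exc:
            results[label] = _failed_fit(
                "hierarchical" if complete else "riley", subset, str(exc), n_rep)

    pos = {o: i + 1 for i, o in enumerate(outcomes)}
    for oa, ob in itertools.combinations(outcomes, 2):
        one_fit([oa, ob], f"bivariate({pos[oa]},{pos[ob]})")
    if len(outcomes) > 2:
        name = {3: "trivariate", 4: "quadvariate"}.get(
            len(outcomes), f"{len(outcomes)}-variate")
        one_fit(list(outcomes),
                f"{name}({','.join(str(pos[o]) for o in outcomes)})")
    return results


def _subset_fixed(fixed_corr, subset: list[str], outcomes: list[str]):
    """Restrict a fixed-correlation input to a subset of outcomes."""
    if fixed_corr is None:
        return None
    if isinstance(fixed_corr, dict):
        out = {pair: val for pair, val in fixed_corr.items()
               if pair[0] in subset and pair[1] in subset}
        return out or None
    mat = np.asarray(fixed_corr, dtype=float)
    idx = [outcomes.index(o) for o in subset]
    return mat[np.ix_(idx, idx)]
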