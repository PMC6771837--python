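"""Independent oracles used by the test-suite.

Everything here is implemented directly from first principles (Monte-Carlo
simulation at the count level, brute-force grid evaluation of restricted
log-likelihoods) without calling the code paths under test.
"""

from __future__ import annotations

import numpy as np


def _log_odds(events: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-table log-odds with the 0.5 zero-cell rule.

    Returns (log-odds treatment-control difference pieces are assembled by
    the caller); here: per-arm log odds for one outcome given event counts
    in that arm, with a 0.5 added to both cells when the count is 0 or n.
    """
    corr = (events == 0) | (events == n)
    a = events + 0.5 * corr
    b = (n - events) + 0.5 * corr
    return np.log(a / b), corr


def mc_log_or_pair(counts_t: np.ndarray, n_t: int,
                   counts_c: np.ndarray, n_c: int):
    """Log OR replicates for one outcome from arm-level event-count draws.

    Applies the same policy as the estimator: outcome missing when no
    events in either arm (replicate flagged), else 0.5 to every cell of the
    2x2 table when any cell is zero.
    """
    missing = (counts_t == 0) & (counts_c == 0)
    corr = ((counts_t == 0) | (counts_t == n_t)
            | (counts_c == 0) | (counts_c == n_c))
    at = counts_t + 0.5 * corr
    bt = (n_t - counts_t) + 0.5 * corr
    ac = counts_c + 0.5 * corr
    bc = (n_c - counts_c) + 0.5 * corr
    return np.log((at / bt) / (ac / bc)), missing


def mc_corr_exclusive(n_t: int, at: int, bt: int, n_c: int, ac: int, bc: int,
                      reps: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo within-study correlation for mutually exclusive outcomes.

    Draws per-arm multinomial replicates at the observed proportions and
    correlates the two resulting log odds ratios.
    """
    rng = np.random.default_rng(seed)
    dt = rng.multinomial(n_t, [at / n_t, bt / n_t, 1 - (at + bt) / n_t],
                         size=reps)
    dc = rng.multinomial(n_c, [ac / n_c, bc / n_c, 1 - (ac + bc) / n_c],
                         size=reps)
    ya, ma = mc_log_or_pair(dt[:, 0], n_t, dc[:, 0], n_c)
    yb, mb = mc_log_or_pair(dt[:, 1], n_t, dc[:, 1], n_c)
    ok = ~(ma | mb)
    return float(np.corrcoef(ya[ok], yb[ok])[0, 1])


def mc_corr_subset(n_t: int, sub_t: int, sup_t: int,
                   n_c: int, sub_c: int, sup_c: int,
                   reps: int = 100_000, seed: int = 0) -> float:
    """Monte-Carlo within-study correlation for subset/superset outcomes.

    Nested events: each arm draws multinomial cells (subset, superset-only,
    neither) at the observed proportions.
    """
    rng = np.random.default_rng(seed)
    dt = rng.multinomial(
        n_t, [sub_t / n_t, (sup_t - sub_t) / n_t, 1 - sup_t / n_t], size=reps)
    dc = rng.multinomial(
        n_c, [sub_c / n_c, (sup_c - sub_c) / n_c, 1 - sup_c / n_c], size=reps)
    ysub, ms = mc_log_or_pair(dt[:, 0], n_t, dc[:, 0], n_c)
    ysup, mp = mc_log_or_pair(dt[:, 0] + dt[:, 1], n_t,
                              dc[:, 0] + dc[:, 1], n_c)
    ok = ~(ms | mp)
    return float(np.corrcoef(ysub[ok], ysup[ok])[0, 1])


def uv_reml_nll(y: np.ndarray, v: np.ndarray, tau2: np.ndarray) -> np.ndarray:
    """Vectorised negative restricted log-likelihood over a tau^2 grid."""
    y = np.asarray(y)[None, :]
    v = np.asarray(v)[None, :]
    t2 = np.asarray(tau2)[:, None]
    w = 1.0 / (v + t2)
    sw = w.sum(axis=1)
    mu = (w * y).sum(axis=1) / sw
    quad = (w * (y - mu[:, None]) ** 2).sum(axis=1)
    return 0.5 * (np.log(v + t2).sum(axis=1) + np.log(sw) + quad)


def bivariate_rho_profile_nll(y: np.ndarray, S: np.ndarray,
                              tau: tuple[float, float],
                              rho_grid: np.ndarray) -> np.ndarray:
    """REML nll over a rho grid for complete bivariate data, taus fixed.

    Direct dense evaluation: V_i(rho) = S_i + D R D with D = diag(tau);
    mu profiled by GLS; restricted term log |sum V_i^{-1}|.
    """
    G = len(rho_grid)
    k = y.shape[0]
    t1, t2 = tau
    Sig = np.zeros((G, 2, 2))
    Sig[:, 0, 0] = t1 * t1
    Sig[:, 1, 1] = t2 * t2
    Sig[:, 0, 1] = Sig[:, 1, 0] = rho_grid * t1 * t2
    V = S[None, :, :, :] + Sig[:, None, :, :]          # (G, k, 2, 2)
    det = V[..., 0, 0] * V[..., 1, 1] - V[..., 0, 1] ** 2
    inv = np.empty_like(V)
    inv[..., 0, 0] = V[..., 1, 1] / det
    inv[..., 1, 1] = V[..., 0, 0] / det
    inv[..., 0, 1] = inv[..., 1, 0] = -V[..., 0, 1] / det
    A = inv.sum(axis=1)                                 # (G, 2, 2)
    b = np.einsum("gkij,kj->gi", inv, y)
    detA = A[:, 0, 0] * A[:, 1, 1] - A[:, 0, 1] ** 2
    Ainv = np.empty_like(A)
    Ainv[:, 0, 0] = A[:, 1, 1] / detA
    Ainv[:, 1, 1] = A[:, 0, 0] / detA
    Ainv[:, 0, 1] = Ainv[:, 1, 0] = -A[:, 0, 1] / detA
    mu = np.einsum("gij,gj->gi", Ainv, b)
    yVy = np.einsum("ki,gkij,kj->g", y, inv, y)
    quad = yVy - np.einsum("gi,gi->g", b, mu)
    nll = 0.5 * (np.log(det).sum(axis=1) + np.log(detA) + quad)
    nll[~np.isfinite(nll)] = np.inf
    return nll
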