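import numpy as np
import pandas as pd
import pytest

import multimeta as mm
from multimeta.multivariate import FitOptions, MultivariateResults, fit_all_pairs
from multimeta.reporting import (
    band_counts_by_tercile,
    build_comparison,
    classify_band,
    comparison_frame,
    funnel_data,
    render_reports,
)
from multimeta.univariate import UnivariateResults


def _uv(outcome, mu, se, tau=0.1):
    z = 1.959963984540054
    return UnivariateResults(
        outcome_id=outcome, mu=mu, se_mu=se, se_mu_gls=se, tau=tau,
        tau2=tau ** 2, ci_low=mu - z * se, ci_high=mu + z * se,
        n_studies=5, status="converged", loglik=0.0)


def _mv(outcomes, mus, ses, status="converged", label_model="riley"):
    z = 1.959963984540054
    d = len(outcomes)
    mus = np.asarray(mus, dtype=float)
    ses = np.asarray(ses, dtype=float)
    return MultivariateResults(
        model=label_model, outcome_ids=list(outcomes), mu=mus,
        cov_mu=np.diag(ses ** 2), tau=np.full(d, 0.1),
        rho_between=np.eye(d), ci_low=mus - z * ses, ci_high=mus + z * ses,
        status=status, boundary_flags=np.zeros((d, d), bool),
        n_starts_used=1, loglik=0.0, n_studies=np.full(d, 5))


def test_significance_flip_listed_in_change_summary():
    """A CI moving from (1.00, 1.46) to (0.99, 1.52) on the OR scale flips
    the 5% significance flag and surfaces in the change summary."""
    # log-scale fits that exponentiate to the target CIs
    uv = _uv("caesarean", np.log(1.208), 0.0962)     # OR CI ~ (1.000, 1.459)
    mv = _mv(["caesarean"], [np.log(1.227)], [0.1095])  # OR CI ~ (0.99, 1.52)
    assert uv.significant_5pct
    rows, summary = build_comparison([uv], {"bivariate(1,2)": mv})
    assert summary["outcomes_with_significance_change"] == ["caesarean"]
    detail = summary["details"]["caesarean"][0]
    assert detail["univariate_significant"] is True
    assert detail["multivariate_significant"] is False


def test_identical_fits_empty_change_summary():
    uv = _uv("o1", -0.4, 0.1)
    mv = _mv(["o1"], [-0.4], [0.1])
    _, summary = build_comparison([uv], {"bivariate(1,2)": mv})
    assert summary["outcomes_with_significance_change"] == []


def test_failed_fit_rendered_as_fc():
    uv = _uv("o1", -0.4, 0.1)
    mv = _mv(["o1", "o2"], [np.nan, np.nan], [np.nan, np.nan],
             status="failed_convergence")
    rows, summary = build_comparison([uv], {"bivariate(1,2)": mv})
    frame = comparison_frame(rows)
    fc = frame[frame["model"] == "bivariate(1,2)"]
    assert (fc["display"] == "FC").all()
    assert "o2" in summary["outcomes_without_univariate_fit"]


def test_significance_flag_identical_on_both_scales():
    rng = np.random.default_rng(0)
    for _ in range(50):
        mu = rng.normal(0, 0.5)
        se = rng.uniform(0.05, 0.5)
        row_sig = _uv("o", mu, se).significant_5pct
        lo, hi = np.exp(mu - 1.959963984540054 * se), np.exp(mu + 1.959963984540054 * se)
        assert row_sig == (lo > 1 or hi < 1)


def test_contour_membership():
    assert classify_band(1.959963984540054 * 0.2 + 1e-9, 0.2) == "0.01<p<=0.05"
    assert classify_band(0.1, 0.2) == "p>0.10"
    assert classify_band(3 * 0.2, 0.2) == "p<=0.01"


def test_contour_membership_sign_invariant():
    rng = np.random.default_rng(1)
    effects = rng.normal(0, 0.5, 40)
    ses = rng.uniform(0.05, 0.4, 40)
    for e, s in zip(effects, ses):
        assert classify_band(e, s) == classify_band(-e, s)


def _effects_frame(y, v):
    return pd.DataFrame({
        "study_id": [f"s{i}" for i in range(len(y))],
        "outcome_id": "o1", "log_or": y, "var": v,
        "correction_applied": False, "missing": False,
        "cells": [None] * len(y),
    })


def test_funnel_requires_three_studies():
    eff = _effects_frame([0.1, 0.2], [0.02, 0.03])
    with pytest.raises(ValueError, match=">= 3"):
        funnel_data(eff, "o1")


def test_funnel_contours_at_wald_boundaries():
    eff = _effects_frame([0.1, -0.2, 0.3, 0.0], [0.02, 0.03, 0.04, 0.05])
    fd = funnel_data(eff, "o1")
    sub = fd.contours[fd.contours["level"] == 0.05]
    np.testing.assert_allclose(sub["upper"], 1.959963984540054 * sub["se"])
    point = [p for p in fd.points if p.study_id == "s0"][0]
    assert point.se == pytest.approx(np.sqrt(0.02))


def test_symmetric_null_effects_balanced_bands():
    """Without selection, band counts are roughly symmetric about zero."""
    rng = np.random.default_rng(5)
    pos = neg = 0
    for _ in range(100):
        v = rng.uniform(0.02, 0.3, 12)
        y = rng.normal(0, np.sqrt(v))
        fd = funnel_data(_effects_frame(y, v), "o1")
        for p in fd.points:
            if p.contour_band != "p>0.10":
                pos += p.effect > 0
                neg += p.effect < 0
    assert abs(pos - neg) / max(pos + neg, 1) < 0.2


def test_selective_reporting_induces_small_study_asymmetry():
    """Under significance-driven selective reporting, reported small studies
    carry systematically larger effects, visible in the band counts."""
    small_sig = small_tot = large_sig = large_tot = 0
    for rep in range(120):
        truth = mm.preset("bivariate_k20_tau0.3_rho0.5_selective",
                          seed=8000 + rep)
        sim = mm.generate_dataset(truth)
        eff = mm.derive_effects(sim.dataset)
        sub = eff[(eff["outcome_id"] == "outcome_1") & (~eff["missing"])]
        if len(sub) < 3:
            continue
        fd = funnel_data(eff, "outcome_1")
        counts = band_counts_by_tercile(fd)
        sig_bands = ["0.01<p<=0.05", "p<=0.01"]
        small_sig += counts.loc["small", sig_bands].sum()
        small_tot += counts.loc["small"].sum()
        large_sig += counts.loc["large", sig_bands].sum()
        large_tot += counts.loc["large"].sum()
    assert small_sig / small_tot > large_sig / large_tot


def test_render_reports_deterministic_csv(tmp_path, exclusive_dataset):
    eff = mm.derive_effects(exclusive_dataset)
    uv = [mm.UnivariateMeta.from_effects(eff, o).fit()
          for o in exclusive_dataset.outcome_ids]
    mv = fit_all_pairs(exclusive_dataset, FitOptions(seed=0, n_random_starts=2))
    rows, summary = build_comparison(uv, mv)
    out1 = render_reports(rows, summary, tmp_path / "a", effects=eff,
                          funnel_outcomes=["caesarean"])
    out2 = render_reports(rows, summary, tmp_path / "b", effects=eff,
                          funnel_outcomes=["caesarean"])
    assert (tmp_path / "a" / "comparison.csv").read_bytes() == \
        (tmp_path / "b" / "comparison.csv").read_bytes()
    # one comparison table, one forest figure per outcome, one funnel
    names = {p.name for p in (tmp_path / "a").iterdir()}
    assert {"comparison.csv", "comparison.json", "forest_caesarean.png",
            "forest_instrumental.png", "funnel_caesarean.png"} <= names
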