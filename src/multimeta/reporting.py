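"""Comparison of univariate vs multivariate fits and small-study diagnostics.

The comparison surface mirrors how applied meta-analysts read these models:
a side-by-side table of summary odds ratios, 95% CIs and between-study SDs
per outcome per model (with failed fits rendered as "FC"), a list of
outcomes whose 5%-level statistical significance differs between the
univariate fit and any multivariate fit, per-outcome forest plots, and
contour-enhanced funnel plots for visual assessment of small-study effects.
Funnel asymmetry is summarised descriptively (contour-band counts by
study-size tercile); an Egger-type regression test is available behind a
flag but is off by default because the intended assessment is visual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .univariate import UnivariateResults, _Z
from .multivariate import MultivariateResults

__all__ = [
    "ComparisonRow",
    "FunnelPoint",
    "FunnelData",
    "build_comparison",
    "funnel_data",
    "band_counts_by_tercile",
    "egger_test",
    "render_reports",
]

#: contour bands of the funnel plot, outermost first
_BANDS = ["p>0.10", "0.05<p<=0.10", "0.01<p<=0.05", "p<=0.01"]
_ZQ = {0.10: stats.norm.ppf(0.95), 0.05: stats.norm.ppf(0.975),
       0.01: stats.norm.ppf(0.995)}


@dataclass(frozen=True)
class ComparisonRow:
    outcome_id: str
    model_label: str
    or_estimate: float | None
    ci_low_or: float | None
    ci_high_or: float | None
    tau: float | None
    status: str
    significant_5pct: bool | None


@dataclass(frozen=True)
class FunnelPoint:
    study_id: str
    effect: float
    se: float
    contour_band: str


@dataclass
class FunnelData:
    outcome_id: str
    points: list[FunnelPoint]
    contours: pd.DataFrame  # columns: se, level, lower, upper

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "study_id": p.study_id, "effect": p.effect, "se": p.se,
            "contour_band": p.contour_band} for p in self.points])


# ---------------------------------------------------------------------------
# comparison table
# ---------------------------------------------------------------------------

def _row_from_uv(res: UnivariateResults) -> ComparisonRow:
    lo, hi = res.or_ci
    return ComparisonRow(res.outcome_id, "univariate", res.odds_ratio,
                         lo, hi, res.tau, res.status, res.significant_5pct)


def _rows_from_mv(label: str, res: MultivariateResults) -> list[ComparisonRow]:
    rows = []
    for j, oid in enumerate(res.outcome_ids):
        if res.status != "converged" or not np.isfinite(res.mu[j]):
            rows.append(ComparisonRow(oid, label, None, None, None, None,
                                      res.status, None))
            continue
        rows.append(ComparisonRow(
            oid, label, float(np.exp(res.mu[j])),
            float(np.exp(res.ci_low[j])), float(np.exp(res.ci_high[j])),
            float(res.tau[j]), res.status,
            bool(res.ci_low[j] > 0 or res.ci_high[j] < 0)))
    return rows


def build_comparison(
    uv: Sequence[UnivariateResults],
    mv: Mapping[str, MultivariateResults],
) -> tuple[list[ComparisonRow], dict]:
    """One row per (outcome, model), plus a significance-change summary.

    The change summary lists each outcome whose 5%-level significance flag
    differs between the univariate fit and any converged multivariate fit —
    the headline of a UVMA-vs-MVMA comparison.  Outcomes present
    only in a multivariate fit are kept and labelled, not dropped.
    """
    rows: list[ComparisonRow] = [_row_from_uv(r) for r in uv]
    uv_sig = {r.outcome_id: r.significant_5pct for r in uv}
    changes: dict[str, list] = {}
    for label, res in mv.items():
        for row in _rows_from_mv(label, res):
            rows.append(row)
            if row.significant_5pct is None:
                continue
            if row.outcome_id not in uv_sig:
                continue
            if row.significant_5pct != uv_sig[row.outcome_id]:
                changes.setdefault(row.outcome_id, []).append({
                    "model": label,
                    "univariate_significant": uv_sig[row.outcome_id],
                    "multivariate_significant": row.significant_5pct,
                })
    uv_outcomes = set(uv_sig)
    extra = sorted({r.outcome_id for r in rows} - uv_outcomes)
    summary = {
        "outcomes_with_significance_change": sorted(changes),
        "details": changes,
        "outcomes_without_univariate_fit": extra,
    }
    return rows, summary


def comparison_frame(rows: Iterable[ComparisonRow],
                     round_digits: int = 2) -> pd.DataFrame:
    """Render comparison rows as a table, failed fits marked "FC"."""
    out = []
    for r in rows:
        if r.or_estimate is None:
            rendered = "FC"
            out.append({"outcome_id": r.outcome_id, "model": r.model_label,
                        "or": None, "ci_low": None, "ci_high": None,
                        "tau": None, "status": r.status,
                        "significant_5pct": None, "display": rendered})
        else:
            rd = round_digits
            rendered = (f"{r.or_estimate:.{rd}f} "
                        f"({r.ci_low_or:.{rd}f}-{r.ci_high_or:.{rd}f}) "
                        f"{r.tau:.{rd}f}")
            out.append({"outcome_id": r.outcome_id, "model": r.model_label,
                        "or": r.or_estimate, "ci_low": r.ci_low_or,
                        "ci_high": r.ci_high_or, "tau": r.tau,
                        "status": r.status,
                        "significant_5pct": r.significant_5pct,
                        "display": rendered})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# funnel diagnostics
# ---------------------------------------------------------------------------

def classify_band(effect: float, se: float) -> str:
    """Contour band from the two-sided Wald p-value of effect/se."""
    z = abs(effect) / se
    if z > _ZQ[0.01]:
        return "p<=0.01"
    if z > _ZQ[0.05]:
        return "0.01<p<=0.05"
    if z > _ZQ[0.10]:
        return "0.05<p<=0.10"
    return "p>0.10"


def funnel_data(effects: pd.DataFrame, outcome_id: str,
                n_se_grid: int = 50) -> FunnelData:
    """Per-study funnel coordinates plus significance-contour polylines.

    Requires at least three non-missing effects.  For a grid of standard
    errors the contour at level q is the pair of lines effect = +/- z_q * se;
    no asymmetry test statistic is computed here — the assessment this
    supports is visual, with :func:`band_counts_by_tercile` as a descriptive
    summary and :func:`egger_test` as an optional add-on.
    """
    sub = effects[(effects["outcome_id"] == outcome_id) & (~effects["missing"])]
    if len(sub) < 3:
        raise ValueError(
            f"funnel plot needs >= 3 studies, outcome {outcome_id!r} has "
            f"{len(sub)}")
    points = []
    for _, r in sub.iterrows():
        se = float(np.sqrt(r["var"]))
        points.append(FunnelPoint(str(r["study_id"]), float(r["log_or"]), se,
                                  classify_band(r["log_or"], se)))
    se_max = max(p.se for p in points) * 1.05
    grid = np.linspace(1e-9, se_max, n_se_grid)
    rows = []
    for q, zq in _ZQ.items():
        for se in grid:
            rows.append({"se": se, "level": q, "lower": -zq * se,
                         "upper": zq * se})
    return FunnelData(outcome_id, points, pd.DataFrame(rows))


def band_counts_by_tercile(funnel: FunnelData) -> pd.DataFrame:
    """Contour-band counts within study-size terciles (size ~ 1/se).

    Selective reporting of significant results in small studies shows up as
    an excess of small-tercile studies inside the significant bands.
    """
    df = funnel.to_frame()
    order = df["se"].rank(method="first")
    tercile = pd.cut(order, bins=3, labels=["large", "medium", "small"])
    df = df.assign(size_tercile=tercile)
    counts = (df.groupby(["size_tercile", "contour_band"], observed=False)
              .size().unstack(fill_value=0))
    for band in _BANDS:
        if band not in counts.columns:
            counts[band] = 0
    return counts[_BANDS]


def egger_test(funnel: FunnelData) -> dict:
    """Egger-type regression of effect/se on 1/se (off by default upstream)."""
    df = funnel.to_frame()
    z = df["effect"] / df["se"]
    x = 1.0 / df["se"]
    res = stats.linregress(x, z)
    if res.intercept_stderr and res.intercept_stderr > 0:
        p = float(2 * stats.t.sf(abs(res.intercept / res.intercept_stderr),
                                 len(df) - 2))
    else:
        p = float("nan")
    return {"intercept": float(res.intercept), "slope": float(res.slope),
            "intercept_p": p}


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_reports(rows: Sequence[ComparisonRow],
                   summary: dict,
                   out_dir: str | Path,
                   effects: pd.DataFrame | None = None,
                   funnel_outcomes: Sequence[str] = (),
                   figures: bool = True) -> dict[str, Path]:
    """Write the comparison table (CSV + JSON) and figures to ``out_dir``.

    Produces one forest figure per outcome (study effects plus each model's
    summary diamond; failed fits annotated as FC) and one contour-enhanced
    funnel figure per requested outcome.  The CSV is byte-identical across
    re-runs on identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    frame = comparison_frame(rows)
    csv_path = out_dir / "comparison.csv"
    frame.to_csv(csv_path, index=False, float_format="%.10g")
    written["comparison_csv"] = csv_path

    json_path = out_dir / "comparison.json"
    payload = {
        "rows": [
            {k: (None if v is None or (isinstance(v, float) and np.isnan(v))
                 else v)
             for k, v in frame.iloc[i].items()}
            for i in range(len(frame))
        ],
        "change_summary": summary,
    }
    json_path.write_text(json.dumps(payload, indent=2, default=str))
    written["comparison_json"] = json_path

    if not figures:
        return written
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for outcome in sorted({r.outcome_id for r in rows}):
        fig, ax = plt.subplots(figsize=(7, 5))
        ypos = 0
        labels = []
        if effects is not None:
            sub = effects[(effects["outcome_id"] == outcome)
                          & (~effects["missing"])]
            for _, r in sub.iterrows():
                se = np.sqrt(r["var"])
                ax.errorbar(r["log_or"], ypos, xerr=_Z * se, fmt="s",
                            color="0.4", capsize=2)
                labels.append(str(r["study_id"]))
                ypos += 1
        for r in [r for r in rows if r.outcome_id == outcome]:
            if r.or_estimate is None:
                ax.text(0, ypos, f"{r.model_label}: FC", color="crimson",
                        va="center")
            else:
                mid = np.log(r.or_estimate)
                lo, hi = np.log(r.ci_low_or), np.log(r.ci_high_or)
                ax.plot([lo, mid, hi, mid, lo],
                        [ypos, ypos - 0.25, ypos, ypos + 0.25, ypos],
                        color="navy")
            labels.append(r.model_label)
            ypos += 1
        ax.axvline(0, color="k", lw=0.8)
        ax.set_yticks(range(len(labels)))
        ax.set_yticklabels(labels, fontsize=7)
        ax.set_xlabel("log odds ratio")
        ax.set_title(f"Forest plot: {outcome}")
        fig.tight_layout()
        path = out_dir / f"forest_{_safe(outcome)}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written[f"forest_{outcome}"] = path

    for outcome in funnel_outcomes:
        if effects is None:
            break
        fd = funnel_data(effects, outcome)
        fig, ax = plt.subplots(figsize=(6, 5))
        se_max = fd.contours["se"].max()
        shades = {0.10: "0.92", 0.05: "0.82", 0.01: "0.70"}
        for q in [0.10, 0.05, 0.01]:
            sub = fd.contours[fd.contours["level"] == q]
            ax.fill_betweenx(sub["se"], sub["lower"], sub["upper"],
                             color=shades[q], zorder=1)
        pts = fd.to_frame()
        ax.scatter(pts["effect"], pts["se"], zorder=3, color="navy", s=18)
        ax.set_ylim(se_max, 0)
        ax.set_xlabel("log odds ratio")
        ax.set_ylabel("standard error")
        ax.set_title(f"Contour-enhanced funnel plot: {outcome}")
        fig.tight_layout()
        path = out_dir / f"funnel_{_safe(outcome)}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written[f"funnel_{outcome}"] = path
    return written


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in name)
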