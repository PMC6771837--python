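"""Synthetic multi-outcome binary meta-analysis datasets.

The generator emulates the statistical structure the analysis models assume:
study-level true log odds ratios drawn from a multivariate normal
random-effects distribution (heterogeneity tau, between-study correlation
matrix), binomially generated arm-level events at a fixed control-arm
baseline risk (the random effect acts on the treatment contrast, not on arm
risks), structural outcome relations realised at the patient level
(multinomial cells for mutually exclusive outcomes, nested draws for subset
outcomes, independent draws for unrelated outcomes), and two missingness
mechanisms: missing completely at random, and significance-driven selective
reporting of small studies — the mechanism that produces funnel-plot
asymmetry and the univariate bias that multivariate borrowing of strength
partially corrects.

All randomness flows from one integer seed through a single
`numpy.random.Generator`.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data import MetaDataset, OutcomeRelation, RelationKind, ValidationError
from .effects import derive_effects

__all__ = [
    "Missingness",
    "SimTruth",
    "SimResult",
    "generate_dataset",
    "apply_selective_reporting",
    "review7_scenario",
    "preset",
    "PRESETS",
]


@dataclass(frozen=True)
class Missingness:
    """Missing-outcome mechanism applied after data generation.

    kind "none"     : complete reporting;
    kind "mcar"     : each (study, outcome) cell dropped with probability p;
    kind "selective": a designated outcome's result is deleted with
                      probability ``drop_prob`` when its two-sided Wald
                      p-value exceeds ``threshold`` *and* the study is
                      smaller than the dataset median — small null results
                      go unreported.
    """

    kind: str = "none"                    # none | mcar | selective
    p: float = 0.3
    threshold: float = 0.05
    drop_prob: float = 0.8
    outcomes: tuple[str, ...] = ()        # selective targets; empty = all

    def __post_init__(self) -> None:
        if self.kind not in {"none", "mcar", "selective"}:
            raise ValidationError(f"unknown missingness kind {self.kind!r}")


@dataclass
class SimTruth:
    """Generating parameters of one synthetic meta-analysis."""

    mu_true: np.ndarray                   # true summary log ORs
    tau_true: np.ndarray                  # between-study SDs
    rho_between_true: np.ndarray          # between-study correlation matrix
    baseline_risk: np.ndarray             # control-arm event probabilities
    relations: list[OutcomeRelation] = field(default_factory=list)
    k_studies: int = 10
    n_range: tuple[int, int] = (50, 500)  # per-arm sizes, uniform
    missingness: Missingness = field(default_factory=Missingness)
    outcome_ids: list[str] = field(default_factory=list)
    reporting_pattern: np.ndarray | None = None   # (k, d) bool base mask
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu_true = np.atleast_1d(np.asarray(self.mu_true, dtype=float))
        self.tau_true = np.atleast_1d(np.asarray(self.tau_true, dtype=float))
        self.rho_between_true = np.asarray(self.rho_between_true, dtype=float)
        self.baseline_risk = np.atleast_1d(
            np.asarray(self.baseline_risk, dtype=float))
        d = len(self.mu_true)
        if not self.outcome_ids:
            self.outcome_ids = [f"outcome_{j+1}" for j in range(d)]
        if not (len(self.tau_true) == len(self.baseline_risk)
                == len(self.outcome_ids) == d):
            raise ValidationError("parameter vectors must share length d")
        if self.rho_between_true.shape != (d, d):
            raise ValidationError("rho_between_true must be d x d")
        if np.linalg.eigvalsh(self.rho_between_true).min() < -1e-10:
            raise ValidationError("rho_between_true must be PSD")
        if np.any((self.baseline_risk <= 0) | (self.baseline_risk >= 1)):
            raise ValidationError("baseline risks must lie in (0, 1)")
        if np.any(self.tau_true < 0):
            raise ValidationError("tau_true must be non-negative")
        if self.n_range[0] < 2 or self.n_range[1] < self.n_range[0]:
            raise ValidationError("invalid n_range")
        idx = {o: j for j, o in enumerate(self.outcome_ids)}
        seen: set[str] = set()
        for rel in self.relations:
            if rel.relation == RelationKind.UNRELATED:
                continue
            a, b = rel.outcome_a, rel.outcome_b
            if a in seen or b in seen:
                raise ValidationError(
                    "each outcome may take part in at most one structural "
                    "relation in the generator")
            seen.update((a, b))
            pa, pb = self.baseline_risk[idx[a]], self.baseline_risk[idx[b]]
            if rel.relation == RelationKind.MUTUALLY_EXCLUSIVE and pa + pb >= 1:
                raise ValidationError(
                    f"exclusive outcomes {a!r}+{b!r}: baseline risks sum >= 1")
            if rel.relation == RelationKind.SUBSET_A_OF_B and pa > pb:
                raise ValidationError(
                    f"subset {a!r} must have baseline risk <= superset {b!r}")
            if rel.relation == RelationKind.SUBSET_B_OF_A and pb > pa:
                raise ValidationError(
                    f"subset {b!r} must have baseline risk <= superset {a!r}")

    @property
    def d(self) -> int:
        return len(self.mu_true)

    def sigma_between(self) -> np.ndarray:
        t = self.tau_true
        return self.rho_between_true * np.outer(t, t)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "mu_true": self.mu_true.tolist(),
            "tau_true": self.tau_true.tolist(),
            "rho_between_true": self.rho_between_true.tolist(),
            "baseline_risk": self.baseline_risk.tolist(),
            "relations": [{"outcomes": [r.outcome_a, r.outcome_b],
                           "relation": r.relation.value}
                          for r in self.relations],
            "k_studies": self.k_studies,
            "n_range": list(self.n_range),
            "missingness": {"kind": self.missingness.kind,
                            "p": self.missingness.p,
                            "threshold": self.missingness.threshold,
                            "drop_prob": self.missingness.drop_prob,
                            "outcomes": list(self.missingness.outcomes)},
            "outcome_ids": self.outcome_ids,
            "seed": self.seed,
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class SimResult:
    dataset: MetaDataset
    truth: SimTruth
    per_study_true_effects: np.ndarray    # (k, d) theta_i draws
    deletions: list[tuple[str, str]] = field(default_factory=list)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


def _structural_groups(truth: SimTruth):
    """Partition outcomes into exclusive pairs, subset pairs and singletons."""
    idx = {o: j for j, o in enumerate(truth.outcome_ids)}
    used: set[int] = set()
    groups = []
    for rel in truth.relations:
        if rel.relation == RelationKind.UNRELATED:
            continue
        ja, jb = idx[rel.outcome_a], idx[rel.outcome_b]
        if rel.relation == RelationKind.MUTUALLY_EXCLUSIVE:
            groups.append(("exclusive", ja, jb))
        elif rel.relation == RelationKind.SUBSET_A_OF_B:
            groups.append(("subset", ja, jb))      # (sub, sup)
        else:
            groups.append(("subset", jb, ja))
        used.update((ja, jb))
    for j in range(truth.d):
        if j not in used:
            groups.append(("single", j))
    return groups


def _draw_arm(rng: np.random.Generator, n: int, probs: np.ndarray,
              groups) -> np.ndarray:
    """Event counts for one arm respecting the structural relations."""
    events = np.zeros(len(probs), dtype=int)
    for g in groups:
        if g[0] == "single":
            j = g[1]
            events[j] = rng.binomial(n, probs[j])
        elif g[0] == "exclusive":
            _, ja, jb = g
            pa, pb = probs[ja], probs[jb]
            tot = pa + pb
            if tot >= 1:  # treatment-shifted risks may collide; rescale
                pa, pb = pa / tot * 0.999, pb / tot * 0.999
            draw = rng.multinomial(n, [pa, pb, 1.0 - pa - pb])
            events[ja], events[jb] = draw[0], draw[1]
        else:  # subset: every subset event is also a superset event
            _, jsub, jsup = g
            psub, psup = probs[jsub], probs[jsup]
            sup = rng.binomial(n, psup)
            cond = 1.0 if psup <= 0 else min(1.0, psub / psup)
            events[jsup] = sup
            events[jsub] = rng.binomial(sup, cond) if sup > 0 else 0
    return events


def generate_dataset(truth: SimTruth,
                     rng: np.random.Generator | None = None) -> SimResult:
    """Generate one synthetic meta-analysis dataset from its true parameters.

    Per study: draw per-arm sizes uniformly from ``n_range``; draw the
    study's true log OR vector from Normal(mu_true, Sigma_between); map the
    control-arm baseline risks to treatment-arm risks on the logit scale;
    draw the correlated event counts in each arm; then apply the missingness
    mechanism.  Same seed, same result.
    """
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    d, k = truth.d, truth.k_studies
    groups = _structural_groups(truth)
    theta = rng.multivariate_normal(truth.mu_true, truth.sigma_between(),
                                    size=k, method="svd")
    p_c = truth.baseline_risk
    rows = []
    for i in range(k):
        n_t = int(rng.integers(truth.n_range[0], truth.n_range[1] + 1))
        n_c = int(rng.integers(truth.n_range[0], truth.n_range[1] + 1))
        p_t = _expit(_logit(p_c) + theta[i])
        ev_t = _draw_arm(rng, n_t, p_t, groups)
        ev_c = _draw_arm(rng, n_c, p_c, groups)
        for j, oid in enumerate(truth.outcome_ids):
            if (truth.reporting_pattern is not None
                    and not truth.reporting_pattern[i, j]):
                continue
            rows.append({"study_id": f"study_{i+1:02d}", "outcome_id": oid,
                         "events_t": int(ev_t[j]), "n_t": n_t,
                         "events_c": int(ev_c[j]), "n_c": n_c})
    dataset = MetaDataset(tables=pd.DataFrame(rows),
                          relations=list(truth.relations),
                          outcome_ids=list(truth.outcome_ids))
    deletions: list[tuple[str, str]] = []
    if truth.missingness.kind == "mcar":
        keep = rng.random(len(dataset.tables)) >= truth.missingness.p
        dropped = dataset.tables[~keep]
        deletions = list(zip(dropped["study_id"], dropped["outcome_id"]))
        tables = dataset.tables[keep].reset_index(drop=True)
        if tables.empty:
            raise ValidationError("MCAR removed every observation; lower p")
        dataset = MetaDataset(tables=tables, relations=list(truth.relations),
                              outcome_ids=list(truth.outcome_ids))
    elif truth.missingness.kind == "selective":
        dataset, deletions = apply_selective_reporting(
            dataset, truth.missingness, rng=rng)
    return SimResult(dataset, truth, theta, deletions)


def apply_selective_reporting(
    dataset: MetaDataset,
    rule: Missingness,
    rng: np.random.Generator | None = None,
) -> tuple[MetaDataset, list[tuple[str, str]]]:
    """Delete non-significant small-study results for designated outcomes.

    A (study, outcome) result is deleted with probability ``rule.drop_prob``
    when its two-sided Wald p-value exceeds ``rule.threshold`` and the
    study's mean per-arm size is below the dataset median.  Deletions are
    returned alongside the reduced dataset.
    """
    if rule.kind == "none":
        return dataset, []
    if rule.kind != "selective":
        raise ValidationError("apply_selective_reporting needs a selective rule")
    rng = rng if rng is not None else np.random.default_rng(0)
    effects = derive_effects(dataset, drop_all_missing_studies=False)
    targets = set(rule.outcomes) or set(dataset.outcome_ids)
    sizes = (dataset.tables.groupby("study_id")[["n_t", "n_c"]].mean()
             .mean(axis=1))
    median_n = sizes.median()
    drop: list[tuple[str, str]] = []
    for _, r in effects.iterrows():
        if r["outcome_id"] not in targets:
            continue
        if r["missing"]:
            continue
        z = abs(r["log_or"]) / np.sqrt(r["var"])
        from scipy.stats import norm
        pval = 2 * norm.sf(z)
        small = sizes[r["study_id"]] < median_n
        if pval > rule.threshold and small and rng.random() < rule.drop_prob:
            drop.append((r["study_id"], r["outcome_id"]))
    if not drop:
        return dataset, []
    mask = ~dataset.tables.apply(
        lambda t: (t["study_id"], t["outcome_id"]) in set(drop), axis=1)
    tables = dataset.tables[mask].reset_index(drop=True)
    return MetaDataset(tables=tables, relations=list(dataset.relations),
                       outcome_ids=list(dataset.outcome_ids)), drop


# ---------------------------------------------------------------------------
# packaged scenarios
# ---------------------------------------------------------------------------

def review7_scenario(seed: int = 0) -> SimTruth:
    """Four correlated outcomes with selective reporting on outcome 2.

    The reporting pattern mirrors the published nausea-and-vomiting review
    whose multivariate re-analysis flagged small-study effects: 11 studies
    of which 8 report outcome 1, 7 report outcome 2, 4 report outcome 3 and
    5 report outcome 4, with outcome 2 additionally subject to
    significance-driven selective reporting in small studies.  No study
    reports outcomes 1, 2 and 3 jointly, so a trivariate overall-correlation
    model with externally fixed pairwise correlations has a well-defined
    likelihood even when those fixed values do not form a positive
    semi-definite 3x3 matrix (only the observed 2x2 principal minors enter).

    Between-study correlation is strong and shared (0.95).  The univariate
    estimate for outcome 2 is biased away from the null by the selection;
    a multivariate model borrowing strength from the unselected outcomes
    attenuates the bias (see :func:`amalgamated_correlation` for the
    consistent overall-correlation values to fix in a Riley-model fit).
    """
    k = 11
    pattern = np.zeros((k, 4), dtype=bool)
    pattern[0:8, 0] = True                 # outcome 1: eight studies
    pattern[[1, 2, 3, 4, 5, 8, 9], 1] = True   # outcome 2: seven, selection follows
    pattern[[7, 8, 9, 10], 2] = True       # outcome 3: four studies
    pattern[[6, 7, 8, 9, 10], 3] = True    # outcome 4: five studies
    rho = np.full((4, 4), 0.95)
    np.fill_diagonal(rho, 1.0)
    return SimTruth(
        mu_true=np.array([-0.7, -0.4, -0.9, -0.8]),
        tau_true=np.array([0.45, 0.45, 0.45, 0.45]),
        rho_between_true=rho,
        baseline_risk=np.array([0.35, 0.30, 0.25, 0.30]),
        relations=[],
        k_studies=k,
        n_range=(30, 150),
        missingness=Missingness(kind="selective", threshold=0.05,
                                drop_prob=0.8, outcomes=("outcome_2",)),
        outcome_ids=["outcome_1", "outcome_2", "outcome_3", "outcome_4"],
        reporting_pattern=pattern,
        seed=seed,
    )


def amalgamated_correlation(truth: SimTruth) -> dict[tuple[str, str], float]:
    """Overall (within + between) correlations implied by a SimTruth.

    The overall-correlation model amalgamates the between-study correlation
    with independent sampling error:

        rho_jk^overall = rho_jk tau_j tau_k /
                         sqrt((tau_j^2 + s_j^2)(tau_k^2 + s_k^2)),

    where s_j^2 is the typical within-study variance of outcome j's log
    odds ratio, approximated here at the mid-range arm size and the
    generating event probabilities.  These are the consistent values to fix
    in a Riley-model fit of data generated from ``truth``.
    """
    n_bar = 0.5 * (truth.n_range[0] + truth.n_range[1])
    p_c = truth.baseline_risk
    p_t = _expit(_logit(p_c) + truth.mu_true)
    s2 = (1.0 / (n_bar * p_t * (1 - p_t)) + 1.0 / (n_bar * p_c * (1 - p_c)))
    tot = truth.tau_true ** 2 + s2
    out = {}
    for j in range(truth.d):
        for k in range(j + 1, truth.d):
            val = (truth.rho_between_true[j, k] * truth.tau_true[j]
                   * truth.tau_true[k] / np.sqrt(tot[j] * tot[k]))
            out[(truth.outcome_ids[j], truth.outcome_ids[k])] = float(val)
    return out


def _bivariate_subset(k=20, tau=0.3, rho=0.7, seed=0) -> SimTruth:
    return SimTruth(
        mu_true=np.array([-0.7, -0.4]),
        tau_true=np.array([tau, tau]),
        rho_between_true=np.array([[1.0, rho], [rho, 1.0]]),
        baseline_risk=np.array([0.10, 0.25]),
        relations=[OutcomeRelation("outcome_1", "outcome_2",
                                   RelationKind.SUBSET_A_OF_B)],
        k_studies=k, n_range=(100, 1000), seed=seed,
    )


def _bivariate_exclusive(k=10, tau=0.3, rho=0.5, seed=0) -> SimTruth:
    return SimTruth(
        mu_true=np.array([0.2, -0.3]),
        tau_true=np.array([tau, tau]),
        rho_between_true=np.array([[1.0, rho], [rho, 1.0]]),
        baseline_risk=np.array([0.25, 0.30]),
        relations=[OutcomeRelation("outcome_1", "outcome_2",
                                   RelationKind.MUTUALLY_EXCLUSIVE)],
        k_studies=k, n_range=(50, 500), seed=seed,
    )


def _bivariate_unrelated(k=20, tau=0.3, rho=0.7, missing="none",
                         seed=0) -> SimTruth:
    miss = {"none": Missingness(),
            "mcar": Missingness(kind="mcar", p=0.3),
            "selective": Missingness(kind="selective",
                                     outcomes=("outcome_1",))}[missing]
    return SimTruth(
        mu_true=np.array([-0.5, -0.4]),
        tau_true=np.array([tau, tau]),
        rho_between_true=np.array([[1.0, rho], [rho, 1.0]]),
        baseline_risk=np.array([0.2, 0.3]),
        relations=[], k_studies=k, n_range=(50, 500),
        missingness=miss, seed=seed,
    )


#: named scenario presets; the k/tau/rho grid of the default study conditions
PRESETS: dict[str, callable] = {"review7": review7_scenario}
for _k in (5, 10, 20, 50):
    for _tau in (0.0, 0.3, 0.6):
        for _rho in (0.0, 0.5, 0.9):
            for _miss in ("none", "mcar", "selective"):
                PRESETS[f"bivariate_k{_k}_tau{_tau}_rho{_rho}_{_miss}"] = (
                    lambda k=_k, tau=_tau, rho=_rho, miss=_miss, seed=0:
                    _bivariate_unrelated(k, tau, rho, miss, seed))
PRESETS["bivariate_subset"] = _bivariate_subset
PRESETS["bivariate_exclusive"] = _bivariate_exclusive


def _recovery_subset(seed: int = 0) -> SimTruth:
    """Parameter-recovery conditions: large trials so that within-study
    estimates sit in their asymptotic regime and the simulation isolates the
    behaviour of the REML estimator itself."""
    return SimTruth(
        mu_true=np.array([-0.7, -0.4]),
        tau_true=np.array([0.3, 0.3]),
        rho_between_true=np.array([[1.0, 0.7], [0.7, 1.0]]),
        baseline_risk=np.array([0.20, 0.40]),
        relations=[OutcomeRelation("outcome_1", "outcome_2",
                                   RelationKind.SUBSET_A_OF_B)],
        k_studies=20, n_range=(1000, 5000), seed=seed,
    )


def _riley_recovery(seed: int = 0) -> SimTruth:
    """Conditions under which the overall (amalgamated) correlation of the
    two outcomes is ~0.7: tau = 0.5, between-study correlation 0.9, and
    within-study variances ~0.06."""
    return SimTruth(
        mu_true=np.array([-0.4, -0.3]),
        tau_true=np.array([0.5, 0.5]),
        rho_between_true=np.array([[1.0, 0.9], [0.9, 1.0]]),
        baseline_risk=np.array([0.30, 0.35]),
        relations=[], k_studies=50, n_range=(100, 200), seed=seed,
    )


PRESETS["recovery_subset"] = _recovery_subset
PRESETS["riley_recovery"] = _riley_recovery


def preset(name: str, seed: int = 0, **overrides) -> SimTruth:
    """Look up a named scenario preset, optionally overriding fields."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
    truth = PRESETS[name](seed=seed)
    return replace(truth, **overrides) if overrides else truth
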