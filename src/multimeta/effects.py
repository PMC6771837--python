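"""Log odds ratios and analytic within-study correlations from 2x2 tables.

Effect derivation follows the standard rules for sparse binary data: a study
in which *neither* arm has any events carries no information about the odds
ratio and the outcome is treated as missing in that study; if only one arm
has 0% or 100% events, 0.5 is added to every cell of the table (continuity
correction) before computing

    log OR = log[(a / b) / (c / d)],    var = 1/a + 1/b + 1/c + 1/d,

with (a, b) the treatment events / non-events and (c, d) the control ones.

When two binary outcomes are structurally related, the correlation between
their log odds ratios *within* a study is available in closed form by the
delta method, because the joint distribution of the event counts in an arm
is multinomial:

* mutually exclusive outcomes (no patient has both): the per-arm covariance
  of the two log odds is ``-n / ((n - a)(n - b))`` — always negative;
* subset outcomes (every event of the subset is also an event of the
  superset): the per-arm covariance is ``n / (a_sup (n - a_sub))`` — always
  positive, and exactly 1 after normalisation when the two outcomes have the
  same event counts in both arms.

Study-level covariance is the sum over the two (independent) arms, and the
correlation normalises by the two variances.  These closed forms are checked
against Monte-Carlo simulation in the test-suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data import (
    MetaDataset,
    OutcomeRelation,
    OutcomeTable,
    RelationKind,
    ValidationError,
)

__all__ = [
    "EffectEstimate",
    "CorrelationValue",
    "WithinStudyCov",
    "log_odds_ratio",
    "derive_effects",
    "corr_mutually_exclusive",
    "corr_subset",
    "assemble_within_cov",
    "effects_to_csv",
]

logger = logging.getLogger(__name__)

#: correlations are clamped to +/- this value before matrix assembly so that
#: assembled within-study covariance matrices are never exactly singular; the
#: raw value is preserved on the CorrelationValue.
CORR_CLAMP = 0.999999


@dataclass(frozen=True)
class EffectEstimate:
    """Log odds ratio and variance for one (study, outcome).

    ``cells`` holds the 2x2 cells *after* any continuity correction, as
    (events_t, nonevents_t, events_c, nonevents_c); the correlation formulas
    reuse them so that the diagonal and off-diagonal entries of the
    within-study covariance matrix are mutually consistent.
    """

    study_id: str
    outcome_id: str
    log_or: float | None
    var: float | None
    correction_applied: bool
    missing: bool
    cells: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.missing:
            if self.log_or is not None or self.var is not None:
                raise ValidationError("missing effect must not carry estimates")
        else:
            if self.var is None or self.var <= 0:
                raise ValidationError("non-missing effect must have var > 0")


@dataclass(frozen=True)
class CorrelationValue:
    """Within-study correlation between two outcomes' log odds ratios."""

    study_id: str
    pair: tuple[str, str]
    rho_w: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_w <= 1.0:
            raise ValidationError(f"rho_w={self.rho_w} outside [-1, 1]")


@dataclass
class WithinStudyCov:
    """Assembled within-study covariance matrix S_i over observed outcomes.

    ``source`` mirrors the matrix and labels each off-diagonal entry with how
    it was obtained: ``analytic_exclusive``, ``analytic_subset``,
    ``fixed_external``, ``zero_unrelated`` (declared unrelated) or
    ``unavailable`` (entry set to 0 because no method applied).
    """

    study_id: str
    outcome_ids: list[str]
    matrix: np.ndarray
    source: np.ndarray

    @property
    def complete(self) -> bool:
        return not (self.source == "unavailable").any()


# ---------------------------------------------------------------------------
# effect derivation
# ---------------------------------------------------------------------------

def log_odds_ratio(table: OutcomeTable) -> EffectEstimate:
    """Derive the log odds ratio and its variance from one 2x2 table.

    Zero-cell policy: no events in either arm -> the outcome is missing in
    this study (zero weight); otherwise any zero cell triggers a 0.5
    continuity correction to all four cells.
    """
    a, b = float(table.events_t), float(table.n_t - table.events_t)
    c, d = float(table.events_c), float(table.n_c - table.events_c)
    if table.events_t == 0 and table.events_c == 0:
        return EffectEstimate(table.study_id, table.outcome_id,
                              None, None, False, True)
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = float(np.log((a / b) / (c / d)))
    var = 1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d
    return EffectEstimate(table.study_id, table.outcome_id, log_or, float(var),
                          corrected, False, (a, b, c, d))


def derive_effects(dataset: MetaDataset,
                   drop_all_missing_studies: bool = True) -> pd.DataFrame:
    """Derive effects for every table; one row per (study, outcome).

    Studies in which *all* analysed outcomes are missing (no events anywhere)
    are dropped entirely when ``drop_all_missing_studies`` (they would get
    zero weight in every model).
    """
    rows = []
    for _, r in dataset.tables.iterrows():
        est = log_odds_ratio(OutcomeTable(
            str(r["study_id"]), str(r["outcome_id"]),
            int(r["events_t"]), int(r["n_t"]), int(r["events_c"]), int(r["n_c"])))
        rows.append({
            "study_id": est.study_id, "outcome_id": est.outcome_id,
            "log_or": est.log_or, "var": est.var,
            "correction_applied": est.correction_applied, "missing": est.missing,
            "cells": est.cells,
        })
    df = pd.DataFrame(rows)
    if drop_all_missing_studies:
        all_missing = df.groupby("study_id")["missing"].transform("all")
        df = df[~all_missing].reset_index(drop=True)
    return df


def effects_to_csv(effects: pd.DataFrame, path: str | Path) -> None:
    effects.drop(columns=["cells"]).to_csv(path, index=False)


def derive_correlations(dataset: MetaDataset) -> pd.DataFrame:
    """All analytically available within-study correlations of a dataset.

    One row per (study, structurally related outcome pair) where both
    effects are non-missing; columns ``study_id, outcome_a, outcome_b,
    rho_w``.
    """
    effects = derive_effects(dataset)
    rows = []
    pairs = [(r.outcome_a, r.outcome_b, r.relation) for r in dataset.relations
             if r.relation != RelationKind.UNRELATED]
    obs = effects[~effects["missing"]]
    for study, grp in obs.groupby("study_id", sort=False):
        ests = {
            r["outcome_id"]: EffectEstimate(
                str(r["study_id"]), str(r["outcome_id"]), r["log_or"],
                r["var"], bool(r["correction_applied"]), False, r["cells"])
            for _, r in grp.iterrows()
        }
        for oa, ob, relation in pairs:
            if oa in ests and ob in ests:
                corr = within_correlation(ests[oa], ests[ob], relation)
                rows.append({"study_id": study, "outcome_a": oa,
                             "outcome_b": ob, "rho_w": corr.rho_w})
    return pd.DataFrame(rows, columns=["study_id", "outcome_a", "outcome_b",
                                       "rho_w"])


def correlations_to_csv(dataset: MetaDataset, path: str | Path) -> None:
    derive_correlations(dataset).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# within-study correlations
# ---------------------------------------------------------------------------

def _as_estimate(x) -> EffectEstimate:
    if isinstance(x, EffectEstimate):
        return x
    if isinstance(x, OutcomeTable):
        return log_odds_ratio(x)
    raise TypeError(f"expected OutcomeTable or EffectEstimate, got {type(x)}")


def _check_pair(ea: EffectEstimate, eb: EffectEstimate) -> None:
    if ea.study_id != eb.study_id:
        raise ValidationError(
            f"correlation requested across studies {ea.study_id!r} / {eb.study_id!r}")
    if ea.missing or eb.missing:
        raise ValidationError("correlation undefined when an effect is missing")
    # corrected tables have totals n+1; compare raw totals
    raw = lambda cells: (cells[0] + cells[1] - (1 if cells[0] % 1 else 0),
                         cells[2] + cells[3] - (1 if cells[2] % 1 else 0))
    if raw(ea.cells) != raw(eb.cells):
        raise ValidationError(
            f"study {ea.study_id!r}: arm totals differ between outcomes "
            f"{ea.outcome_id!r} and {eb.outcome_id!r}")


def _arm_cells(est: EffectEstimate):
    a, b, c, d = est.cells
    return (a, b), (c, d)


def corr_mutually_exclusive(table_a, table_b) -> CorrelationValue:
    """Within-study correlation for two mutually exclusive outcomes.

    Delta-method result under per-arm multinomial sampling; accepts raw
    tables or already-derived :class:`EffectEstimate` objects (in which case
    continuity-corrected cells are used, keeping S_i internally consistent).
    The correlation is always <= 0.
    """
    ea, eb = _as_estimate(table_a), _as_estimate(table_b)
    _check_pair(ea, eb)
    cov = 0.0
    for (aa, ab), (ba, bb) in zip(_arm_cells(ea), _arm_cells(eb)):
        if aa + ba > aa + ab + 1e-9:  # events_a + events_b <= n (raw scale)
            raise ValidationError(
                f"study {ea.study_id!r}: combined events exceed arm total for "
                f"mutually exclusive pair")
        n_eff = 0.5 * ((aa + ab) + (ba + bb))
        cov += -n_eff / (ab * bb)
    rho = cov / np.sqrt(ea.var * eb.var)
    return CorrelationValue(ea.study_id, (ea.outcome_id, eb.outcome_id),
                            float(np.clip(rho, -1.0, 0.0)))


def corr_subset(table_subset, table_superset) -> CorrelationValue:
    """Within-study correlation for a subset outcome and its superset.

    Delta-method result for nested binary events; always >= 0, and exactly 1
    when the subset and superset event counts coincide in both arms.
    """
    es, ep = _as_estimate(table_subset), _as_estimate(table_superset)
    _check_pair(es, ep)
    cov = 0.0
    for (sa, sb), (pa, pb) in zip(_arm_cells(es), _arm_cells(ep)):
        if sa > pa + 1e-9:
            raise ValidationError(
                f"study {es.study_id!r}: subset outcome {es.outcome_id!r} has "
                f"more events than superset {ep.outcome_id!r}")
        n_eff = 0.5 * ((sa + sb) + (pa + pb))
        cov += n_eff / (pa * sb)
    rho = cov / np.sqrt(es.var * ep.var)
    # exact-by-construction when the cells coincide; clip guards rounding
    return CorrelationValue(es.study_id, (es.outcome_id, ep.outcome_id),
                            float(np.clip(rho, 0.0, 1.0)))


def within_correlation(ea: EffectEstimate, eb: EffectEstimate,
                       relation: RelationKind) -> CorrelationValue | None:
    """Dispatch on the declared relation; None when no analytic form exists."""
    if relation == RelationKind.MUTUALLY_EXCLUSIVE:
        return corr_mutually_exclusive(ea, eb)
    if relation == RelationKind.SUBSET_A_OF_B:
        return corr_subset(ea, eb)
    if relation == RelationKind.SUBSET_B_OF_A:
        c = corr_subset(eb, ea)
        return CorrelationValue(c.study_id, (ea.outcome_id, eb.outcome_id), c.rho_w)
    return None


# ---------------------------------------------------------------------------
# covariance assembly
# ---------------------------------------------------------------------------

def _shrink_to_psd(mat: np.ndarray, floor: float = 1e-8) -> tuple[np.ndarray, float]:
    """Uniformly shrink off-diagonals by the minimal factor restoring PSD."""
    diag = np.diag(np.diag(mat))
    off = mat - diag
    lo, hi = 0.0, 1.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if np.linalg.eigvalsh(diag + mid * off).min() >= floor:
            lo = mid
        else:
            hi = mid
    return diag + lo * off, lo


def assemble_within_cov(
    effects: pd.DataFrame,
    relations: Sequence[OutcomeRelation],
    outcome_ids: Sequence[str],
    fixed_corr: np.ndarray | dict | None = None,
) -> tuple[list[WithinStudyCov], bool]:
    """Build per-study within-study covariance matrices S_i.

    For each study the matrix runs over its non-missing outcomes: diagonal =
    within-study variances; off-diagonals from the analytic correlations for
    structurally related pairs, from ``fixed_corr`` (a full matrix over
    ``outcome_ids`` or a ``{(a, b): rho}`` dict) when supplied, otherwise 0
    and flagged ``unavailable``.

    Returns the matrices plus a dataset-level flag: True when every study's
    matrix is complete, i.e. the fully hierarchical multivariate model is
    applicable; False routes the dataset to the overall-correlation (Riley)
    model.
    """
    rel_lookup: dict[tuple[str, str], RelationKind] = {}
    for rel in relations:
        rel_lookup[(rel.outcome_a, rel.outcome_b)] = rel.relation
        sw = rel.swapped()
        rel_lookup[(sw.outcome_a, sw.outcome_b)] = sw.relation

    def fixed_entry(a: str, b: str) -> float | None:
        if fixed_corr is None:
            return None
        if isinstance(fixed_corr, dict):
            if (a, b) in fixed_corr:
                return float(fixed_corr[(a, b)])
            if (b, a) in fixed_corr:
                return float(fixed_corr[(b, a)])
            return None
        ia, ib = list(outcome_ids).index(a), list(outcome_ids).index(b)
        return float(np.asarray(fixed_corr)[ia, ib])

    out: list[WithinStudyCov] = []
    all_complete = True
    for study, grp in effects.groupby("study_id", sort=False):
        obs = grp[~grp["missing"]]
        ids = [o for o in outcome_ids if o in set(obs["outcome_id"])]
        if not ids:
            continue
        ests = {
            r["outcome_id"]: EffectEstimate(
                str(r["study_id"]), str(r["outcome_id"]), r["log_or"], r["var"],
                bool(r["correction_applied"]), False, r["cells"])
            for _, r in obs.iterrows()
        }
        p = len(ids)
        mat = np.zeros((p, p))
        source = np.full((p, p), "diagonal", dtype=object)
        for j, oj in enumerate(ids):
            mat[j, j] = ests[oj].var
        for j in range(p):
            for k in range(j + 1, p):
                oj, ok = ids[j], ids[k]
                relation = rel_lookup.get((oj, ok), RelationKind.UNRELATED)
                corr = within_correlation(ests[oj], ests[ok], relation)
                if corr is not None:
                    rho = float(np.clip(corr.rho_w, -CORR_CLAMP, CORR_CLAMP))
                    src = ("analytic_exclusive"
                           if relation == RelationKind.MUTUALLY_EXCLUSIVE
                           else "analytic_subset")
                else:
                    fx = fixed_entry(oj, ok)
                    if fx is not None:
                        rho = float(np.clip(fx, -CORR_CLAMP, CORR_CLAMP))
                        src = "fixed_external"
                    elif (oj, ok) in rel_lookup:  # declared unrelated
                        rho, src = 0.0, "zero_unrelated"
                    else:
                        rho, src = 0.0, "unavailable"
                        all_complete = False
                mat[j, k] = mat[k, j] = rho * np.sqrt(mat[j, j] * mat[k, k])
                source[j, k] = source[k, j] = src
        if p >= 2 and np.linalg.eigvalsh(mat).min() < 1e-8 * mat.diagonal().max():
            mat, factor = _shrink_to_psd(mat, floor=1e-8 * mat.diagonal().max())
            msg = (f"study {study!r}: assembled within-study covariance not "
                   f"positive semi-definite; off-diagonals shrunk by factor "
                   f"{factor:.4f}")
            logger.warning(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        out.append(WithinStudyCov(str(study), ids, mat, source))
    return out, all_complete
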