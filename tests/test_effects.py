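import logging

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from multimeta.data import OutcomeTable, OutcomeRelation, RelationKind, ValidationError
from multimeta.effects import (
    assemble_within_cov,
    corr_mutually_exclusive,
    corr_subset,
    derive_effects,
    log_odds_ratio,
)

import _oracles


# ---------------------------------------------------------------------------
# log odds ratio derivation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("tbl,log_or,var,corrected", [
    # balanced table: exact zero effect and symmetric variance
    ((10, 100, 10, 100), 0.0, 2 * (1 / 10 + 1 / 90), False),
    # plain evaluation of the standard formulas
    ((10, 100, 5, 100), np.log((10 / 90) / (5 / 95)),
     1 / 10 + 1 / 90 + 1 / 5 + 1 / 95, False),
    # single-arm zero: 0.5 to every cell
    ((0, 50, 5, 50), np.log((0.5 / 50.5) / (5.5 / 45.5)),
     1 / 0.5 + 1 / 50.5 + 1 / 5.5 + 1 / 45.5, True),
    # all events in one arm: also corrected
    ((50, 50, 5, 50), np.log((50.5 / 0.5) / (5.5 / 45.5)),
     1 / 50.5 + 1 / 0.5 + 1 / 5.5 + 1 / 45.5, True),
])
def test_log_odds_ratio_values(tbl, log_or, var, corrected):
    et, nt, ec, nc = tbl
    est = log_odds_ratio(OutcomeTable("s", "o", et, nt, ec, nc))
    assert est.log_or == pytest.approx(log_or, abs=1e-12)
    assert est.var == pytest.approx(var, abs=1e-12)
    assert est.correction_applied is corrected
    assert not est.missing


def test_double_zero_is_missing():
    est = log_odds_ratio(OutcomeTable("s", "o", 0, 50, 0, 50))
    assert est.missing and est.log_or is None and est.var is None


def test_all_missing_study_dropped(exclusive_dataset):
    import pandas as pd
    extra = pd.DataFrame([
        {"study_id": "s9", "outcome_id": "caesarean", "events_t": 0,
         "n_t": 30, "events_c": 0, "n_c": 30},
        {"study_id": "s9", "outcome_id": "instrumental", "events_t": 0,
         "n_t": 30, "events_c": 0, "n_c": 30},
    ])
    from multimeta.data import MetaDataset
    ds = MetaDataset(tables=pd.concat([exclusive_dataset.tables, extra]),
                     relations=exclusive_dataset.relations)
    eff = derive_effects(ds)
    assert "s9" not in set(eff["study_id"])


@given(et=st.integers(0, 40), ec=st.integers(0, 40))
@settings(max_examples=60, deadline=None)
def test_log_or_antisymmetric_under_arm_swap(et, ec):
    a = log_odds_ratio(OutcomeTable("s", "o", et, 40, ec, 40))
    b = log_odds_ratio(OutcomeTable("s", "o", ec, 40, et, 40))
    assert a.missing == b.missing
    if not a.missing:
        assert a.log_or == pytest.approx(-b.log_or)
        assert a.var == pytest.approx(b.var)


# ---------------------------------------------------------------------------
# within-study correlations
# ---------------------------------------------------------------------------

def _tables_excl(at, bt, nt, ac, bc, nc):
    return (OutcomeTable("s", "A", at, nt, ac, nc),
            OutcomeTable("s", "B", bt, nt, bc, nc))


def test_exclusive_correlation_derived_value():
    ta, tb = _tables_excl(30, 20, 100, 25, 25, 100)
    assert corr_mutually_exclusive(ta, tb).rho_w == pytest.approx(-0.3295, abs=2e-4)


def test_exclusive_correlation_symmetric():
    ta, tb = _tables_excl(30, 20, 100, 25, 25, 100)
    assert corr_mutually_exclusive(ta, tb).rho_w == pytest.approx(
        corr_mutually_exclusive(tb, ta).rho_w)


@given(at=st.integers(1, 30), bt=st.integers(1, 30),
       ac=st.integers(1, 30), bc=st.integers(1, 30))
@settings(max_examples=60, deadline=None)
def test_exclusive_correlation_never_positive(at, bt, ac, bc):
    ta, tb = _tables_excl(at, bt, 80, ac, bc, 80)
    assert corr_mutually_exclusive(ta, tb).rho_w <= 0


def test_subset_correlation_derived_value():
    sub = OutcomeTable("s", "sub", 10, 100, 8, 100)
    sup = OutcomeTable("s", "sup", 30, 100, 25, 100)
    assert corr_subset(sub, sup).rho_w == pytest.approx(0.5099, abs=2e-4)


def test_subset_equal_counts_gives_exactly_one():
    sub = OutcomeTable("s", "sub", 7, 120, 9, 118)
    sup = OutcomeTable("s", "sup", 7, 120, 9, 118)
    assert corr_subset(sub, sup).rho_w == 1.0


@given(sub_t=st.integers(1, 20), extra_t=st.integers(0, 20),
       sub_c=st.integers(1, 20), extra_c=st.integers(0, 20))
@settings(max_examples=60, deadline=None)
def test_subset_correlation_never_negative(sub_t, extra_t, sub_c, extra_c):
    sub = OutcomeTable("s", "sub", sub_t, 60, sub_c, 60)
    sup = OutcomeTable("s", "sup", sub_t + extra_t, 60, sub_c + extra_c, 60)
    assert 0 <= corr_subset(sub, sup).rho_w <= 1


def test_correlation_pair_consistency_checks():
    ta = OutcomeTable("s", "A", 30, 100, 25, 100)
    tb = OutcomeTable("s", "B", 20, 90, 25, 100)   # different arm total
    with pytest.raises(ValidationError, match="arm totals"):
        corr_mutually_exclusive(ta, tb)
    sub = OutcomeTable("s", "sub", 40, 100, 8, 100)
    sup = OutcomeTable("s", "sup", 30, 100, 25, 100)
    with pytest.raises(ValidationError, match="more events"):
        corr_subset(sub, sup)


def test_corrected_counts_used_for_correlations():
    """A zero cell in one outcome feeds corrected cells into the formula."""
    sub = OutcomeTable("s", "sub", 0, 50, 2, 50)    # corrected
    sup = OutcomeTable("s", "sup", 10, 50, 12, 50)
    est_sub = log_odds_ratio(sub)
    assert est_sub.correction_applied
    rho = corr_subset(sub, sup).rho_w
    # recompute by hand from the corrected cells
    a_sub = (0.5, 50.5, 2.5, 48.5)
    a_sup = (10, 40, 12, 38)
    cov = 0.0
    for (sa, sb, n_sub), (pa, pb, n_sup) in [
        ((a_sub[0], a_sub[1], 51), (a_sup[0], a_sup[1], 50)),
        ((a_sub[2], a_sub[3], 51), (a_sup[2], a_sup[3], 50)),
    ]:
        cov += 0.5 * (n_sub + n_sup) / (pa * sb)
    var_sub = sum(1 / c for c in a_sub)
    var_sup = sum(1 / c for c in a_sup)
    assert rho == pytest.approx(cov / np.sqrt(var_sub * var_sup))


@pytest.mark.parametrize("kind,counts", [
    ("exclusive", (25, 15, 90, 18, 22, 90)),
    ("subset", (6, 20, 90, 9, 24, 90)),
])
def test_delta_method_matches_monte_carlo(kind, counts):
    """Closed-form correlations agree with 1e5-replicate simulation."""
    if kind == "exclusive":
        at, bt, nt, ac, bc, nc = counts
        ta, tb = _tables_excl(at, bt, nt, ac, bc, nc)
        analytic = corr_mutually_exclusive(ta, tb).rho_w
        mc = _oracles.mc_corr_exclusive(nt, at, bt, nc, ac, bc, seed=7)
    else:
        sub_t, sup_t, nt, sub_c, sup_c, nc = counts
        sub = OutcomeTable("s", "sub", sub_t, nt, sub_c, nc)
        sup = OutcomeTable("s", "sup", sup_t, nt, sup_c, nc)
        analytic = corr_subset(sub, sup).rho_w
        mc = _oracles.mc_corr_subset(nt, sub_t, sup_t, nc, sub_c, sup_c, seed=7)
    assert analytic == pytest.approx(mc, abs=0.02)


# ---------------------------------------------------------------------------
# covariance assembly
# ---------------------------------------------------------------------------

def test_assemble_exclusive_dataset(exclusive_dataset):
    eff = derive_effects(exclusive_dataset)
    covs, complete = assemble_within_cov(
        eff, exclusive_dataset.relations, exclusive_dataset.outcome_ids)
    assert complete and len(covs) == 4
    for w in covs:
        assert w.matrix.shape == (2, 2)
        assert w.matrix[0, 1] < 0
        assert w.source[0, 1] == "analytic_exclusive"
        assert np.linalg.eigvalsh(w.matrix).min() > 0


def test_assemble_unrelated_flags_unavailable(subset_dataset):
    import pandas as pd
    rows = subset_dataset.tables.copy()
    ds_unrel = type(subset_dataset)(tables=rows, relations=[])
    eff = derive_effects(ds_unrel)
    covs, complete = assemble_within_cov(eff, [], ds_unrel.outcome_ids)
    assert not complete
    assert all((w.source[0, 1] == "unavailable") for w in covs
               if len(w.outcome_ids) == 2)


def test_assemble_fixed_external_trivariate():
    import pandas as pd
    rows = []
    for i in range(3):
        for j, o in enumerate(["o1", "o2", "o3"]):
            rows.append({"study_id": f"s{i}", "outcome_id": o,
                         "events_t": 5 + i + j, "n_t": 50,
                         "events_c": 7 + i, "n_c": 50})
    from multimeta.data import MetaDataset
    ds = MetaDataset(tables=pd.DataFrame(rows))
    eff = derive_effects(ds)
    # PSD-compatible fixed values are applied exactly
    fixed_psd = {("o1", "o2"): 0.60, ("o2", "o3"): 0.60, ("o1", "o3"): 0.30}
    covs, complete = assemble_within_cov(eff, [], ["o1", "o2", "o3"], fixed_psd)
    assert complete
    w = covs[0]
    rho01 = w.matrix[0, 1] / np.sqrt(w.matrix[0, 0] * w.matrix[1, 1])
    rho12 = w.matrix[1, 2] / np.sqrt(w.matrix[1, 1] * w.matrix[2, 2])
    assert rho01 == pytest.approx(0.60)
    assert rho12 == pytest.approx(0.60)
    assert (w.source[0, 1], w.source[1, 2]) == ("fixed_external",) * 2

    # the published sensitivity values (0.60, 0.93, 0) do not form a PSD
    # matrix: on a study observing all three outcomes the documented
    # proportional shrink applies, preserving the ratios and the zero
    fixed = {("o1", "o2"): 0.60, ("o2", "o3"): 0.93, ("o1", "o3"): 0.0}
    with pytest.warns(RuntimeWarning, match="shrunk"):
        covs, complete = assemble_within_cov(eff, [], ["o1", "o2", "o3"], fixed)
    assert complete
    w = covs[0]
    rho01 = w.matrix[0, 1] / np.sqrt(w.matrix[0, 0] * w.matrix[1, 1])
    rho12 = w.matrix[1, 2] / np.sqrt(w.matrix[1, 1] * w.matrix[2, 2])
    factor = rho01 / 0.60
    assert 0.85 < factor <= 1.0
    assert rho12 == pytest.approx(0.93 * factor, rel=1e-6)
    assert w.matrix[0, 2] == pytest.approx(0.0)


def test_non_psd_fixed_matrix_shrunk_with_warning():
    import pandas as pd
    rows = []
    for j, o in enumerate(["o1", "o2", "o3"]):
        rows.append({"study_id": "s0", "outcome_id": o,
                     "events_t": 10 + j, "n_t": 60, "events_c": 12, "n_c": 60})
    from multimeta.data import MetaDataset
    ds = MetaDataset(tables=pd.DataFrame(rows))
    eff = derive_effects(ds)
    fixed = {("o1", "o2"): 0.95, ("o2", "o3"): 0.95, ("o1", "o3"): -0.95}
    with pytest.warns(RuntimeWarning, match="shrunk"):
        covs, _ = assemble_within_cov(eff, [], ["o1", "o2", "o3"], fixed)
    assert np.linalg.eigvalsh(covs[0].matrix).min() >= 0


def test_generator_replicates_match_subset_formula():
    """Empirical correlation across generated replicates of one study
    configuration agrees with the closed form (generator as oracle)."""
    import multimeta as mm
    rng = np.random.default_rng(3)
    n = 400
    reps = 40_000
    draws = rng.multinomial(n, [0.06, 0.14, 0.80], size=reps)
    drawsc = rng.multinomial(n, [0.08, 0.15, 0.77], size=reps)
    ysub, ms = _oracles.mc_log_or_pair(draws[:, 0], n, drawsc[:, 0], n)
    ysup, mp = _oracles.mc_log_or_pair(draws[:, 0] + draws[:, 1], n,
                                       drawsc[:, 0] + drawsc[:, 1], n)
    ok = ~(ms | mp)
    emp = np.corrcoef(ysub[ok], ysup[ok])[0, 1]
    sub = OutcomeTable("s", "sub", int(0.06 * n), n, int(0.08 * n), n)
    sup = OutcomeTable("s", "sup", int(0.20 * n), n, int(0.23 * n), n)
    assert corr_subset(sub, sup).rho_w == pytest.approx(emp, abs=0.02)


def test_correlation_csv_export(tmp_path, exclusive_dataset, subset_dataset):
    from multimeta.effects import correlations_to_csv, derive_correlations
    df = derive_correlations(exclusive_dataset)
    assert len(df) == 4 and (df["rho_w"] <= 0).all()
    correlations_to_csv(subset_dataset, tmp_path / "c.csv")
    import pandas as pd
    back = pd.read_csv(tmp_path / "c.csv")
    assert list(back.columns) == ["study_id", "outcome_a", "outcome_b", "rho_w"]
    assert (back["rho_w"] >= 0).all() and back["rho_w"].max() == 1.0
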