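"""Data containers, I/O and eligibility screening for multi-outcome binary
meta-analysis datasets.

A dataset is a collection of per-study 2x2 tables (events / totals in the
treatment and control arm) for one or more binary outcomes, together with a
declaration of the structural relation between each pair of outcomes:
*mutually exclusive* (no patient can experience both, e.g. vaginal birth and
caesarean section), *subset* (every event of one outcome is also an event of
the other, e.g. neonatal death within perinatal mortality), or *unrelated*.
The structural relation determines whether within-study correlations between
the outcomes' log odds ratios can be derived analytically from the tables
alone (see :mod:`multimeta.effects`).

Tables are stored as a plain :class:`pandas.DataFrame` with one row per
(study, outcome); relations live in a small YAML config.  Both formats are
deliberately flat so that data extracted from published review tables can be
typed in by hand.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

__all__ = [
    "RelationKind",
    "OutcomeTable",
    "OutcomeRelation",
    "MetaDataset",
    "EligibilityReport",
    "DatasetEligibility",
    "ValidationError",
    "read_dataset",
    "write_dataset",
    "eligibility_filter",
]

TABLE_COLUMNS = ["study_id", "outcome_id", "events_t", "n_t", "events_c", "n_c"]


class ValidationError(ValueError):
    """Raised when a dataset violates a structural invariant."""


class RelationKind(str, enum.Enum):
    MUTUALLY_EXCLUSIVE = "mutually_exclusive"
    SUBSET_A_OF_B = "subset_a_of_b"
    SUBSET_B_OF_A = "subset_b_of_a"
    UNRELATED = "unrelated"


@dataclass(frozen=True)
class OutcomeTable:
    """One study's 2x2 table for one binary outcome."""

    study_id: str
    outcome_id: str
    events_t: int
    n_t: int
    events_c: int
    n_c: int

    def __post_init__(self) -> None:
        for arm, (e, n) in {
            "treatment": (self.events_t, self.n_t),
            "control": (self.events_c, self.n_c),
        }.items():
            if n < 1:
                raise ValidationError(
                    f"study {self.study_id!r} outcome {self.outcome_id!r}: "
                    f"{arm} arm total must be >= 1, got {n}"
                )
            if not 0 <= e <= n:
                raise ValidationError(
                    f"study {self.study_id!r} outcome {self.outcome_id!r}: "
                    f"{arm} arm has events={e} outside [0, n={n}]"
                )


@dataclass(frozen=True)
class OutcomeRelation:
    """Structural relation between a pair of outcomes.

    The relation is symmetric under swapping the outcomes provided the subset
    direction is flipped, which :meth:`swapped` implements.
    """

    outcome_a: str
    outcome_b: str
    relation: RelationKind

    def __post_init__(self) -> None:
        if self.outcome_a == self.outcome_b:
            raise ValidationError(
                f"relation declared between {self.outcome_a!r} and itself"
            )

    def swapped(self) -> "OutcomeRelation":
        flip = {
            RelationKind.SUBSET_A_OF_B: RelationKind.SUBSET_B_OF_A,
            RelationKind.SUBSET_B_OF_A: RelationKind.SUBSET_A_OF_B,
        }
        return OutcomeRelation(
            self.outcome_b, self.outcome_a, flip.get(self.relation, self.relation)
        )


@dataclass
class MetaDataset:
    """Validated multi-outcome meta-analysis dataset.

    Parameters
    ----------
    tables : pandas.DataFrame
        One row per (study, outcome) with the six columns in
        ``TABLE_COLUMNS``.
    relations : list of OutcomeRelation
        Declared pairwise relations; pairs not declared default to unrelated.
    outcome_ids : list of str
        Analysis order of the outcomes.  Defaults to order of first
        appearance in ``tables``.
    """

    tables: pd.DataFrame
    relations: list[OutcomeRelation] = field(default_factory=list)
    outcome_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tables = self.tables.reset_index(drop=True)
        if not self.outcome_ids:
            self.outcome_ids = list(dict.fromkeys(self.tables["outcome_id"]))
        self.validate()

    # -- queries ---------------------------------------------------------
    def relation_between(self, a: str, b: str) -> RelationKind:
        """Relation of outcome ``a`` to outcome ``b`` (undeclared = unrelated)."""
        for rel in self.relations:
            if (rel.outcome_a, rel.outcome_b) == (a, b):
                return rel.relation
            if (rel.outcome_a, rel.outcome_b) == (b, a):
                return rel.swapped().relation
        return RelationKind.UNRELATED

    def studies_reporting(self, outcome_id: str) -> list[str]:
        sub = self.tables[self.tables["outcome_id"] == outcome_id]
        return list(sub["study_id"])

    def table_for(self, study_id: str, outcome_id: str) -> OutcomeTable | None:
        sub = self.tables[
            (self.tables["study_id"] == study_id)
            & (self.tables["outcome_id"] == outcome_id)
        ]
        if sub.empty:
            return None
        row = sub.iloc[0]
        return OutcomeTable(
            str(row["study_id"]), str(row["outcome_id"]),
            int(row["events_t"]), int(row["n_t"]),
            int(row["events_c"]), int(row["n_c"]),
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        df = self.tables
        missing_cols = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing_cols:
            raise ValidationError(f"tables missing columns {missing_cols}")
        if df.empty or not self.outcome_ids:
            raise ValidationError("dataset must contain at least one outcome")

        for col in ["events_t", "n_t", "events_c", "n_c"]:
            vals = pd.to_numeric(df[col], errors="coerce")
            if vals.isna().any():
                row = int(vals[vals.isna()].index[0])
                raise ValidationError(f"row {row}: column {col} is missing/non-numeric")
            frac = vals % 1 != 0
            if frac.any():
                row = int(vals[frac].index[0])
                raise ValidationError(
                    f"row {row}: column {col} has non-integer value {vals[row]}"
                )
            df[col] = vals.astype("int64")

        # per-row invariants (reuse OutcomeTable's checks, naming the row)
        for i, row in df.iterrows():
            try:
                OutcomeTable(
                    str(row["study_id"]), str(row["outcome_id"]),
                    int(row["events_t"]), int(row["n_t"]),
                    int(row["events_c"]), int(row["n_c"]),
                )
            except ValidationError as exc:
                raise ValidationError(f"row {i}: {exc}") from None

        dups = df.duplicated(subset=["study_id", "outcome_id"])
        if dups.any():
            row = df[dups].iloc[0]
            raise ValidationError(
                f"duplicate (study, outcome) pair "
                f"({row['study_id']!r}, {row['outcome_id']!r})"
            )

        declared = set(self.outcome_ids)
        undeclared = set(df["outcome_id"]) - declared
        if undeclared:
            raise ValidationError(f"tables reference undeclared outcomes {undeclared}")
        for rel in self.relations:
            for o in (rel.outcome_a, rel.outcome_b):
                if o not in declared:
                    raise ValidationError(
                        f"relation references undeclared outcome {o!r}"
                    )
        self._validate_structural()

    def _validate_structural(self) -> None:
        # Subset/exclusivity count constraints are checked eagerly: the
        # analytic correlation formulas are undefined when they fail.
        for rel in self.relations:
            if rel.relation == RelationKind.UNRELATED:
                continue
            a, b = rel.outcome_a, rel.outcome_b
            for study in set(self.tables["study_id"]):
                ta, tb = self.table_for(study, a), self.table_for(study, b)
                if ta is None or tb is None:
                    continue
                if (ta.n_t, ta.n_c) != (tb.n_t, tb.n_c):
                    raise ValidationError(
                        f"study {study!r}: arm totals differ between related "
                        f"outcomes {a!r} and {b!r}"
                    )
                if rel.relation == RelationKind.MUTUALLY_EXCLUSIVE:
                    if (ta.events_t + tb.events_t > ta.n_t
                            or ta.events_c + tb.events_c > ta.n_c):
                        raise ValidationError(
                            f"study {study!r}: mutually exclusive outcomes "
                            f"{a!r}+{b!r} have combined events exceeding n"
                        )
                else:
                    sub, sup = (ta, tb) if rel.relation == RelationKind.SUBSET_A_OF_B \
                        else (tb, ta)
                    if (sub.events_t > sup.events_t
                            or sub.events_c > sup.events_c):
                        raise ValidationError(
                            f"study {study!r}: subset outcome has more events "
                            f"than its superset ({a!r} vs {b!r})"
                        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_dataset(tables_path: str | Path,
                 relations_path: str | Path | None = None) -> MetaDataset:
    """Read a dataset from a tables CSV and an optional relations YAML.

    The CSV must carry a header row with the six columns
    ``study_id, outcome_id, events_t, n_t, events_c, n_c``.  The relations
    file is a YAML document of the form::

        relations:
          - outcomes: [caesarean, instrumental]
            relation: mutually_exclusive

    Pairs not declared default to unrelated.  Malformed counts or duplicate
    (study, outcome) pairs raise :class:`ValidationError` naming the row.
    """
    df = pd.read_csv(tables_path)
    relations: list[OutcomeRelation] = []
    if relations_path is not None:
        raw = yaml.safe_load(Path(relations_path).read_text()) or {}
        for entry in raw.get("relations", []):
            try:
                a, b = entry["outcomes"]
                kind = RelationKind(entry["relation"])
            except (KeyError, TypeError) as exc:
                raise ValidationError(f"malformed relation entry {entry!r}") from exc
            except ValueError:
                raise ValidationError(
                    f"unknown relation keyword {entry.get('relation')!r}; expected "
                    f"one of {[k.value for k in RelationKind]}"
                ) from None
            relations.append(OutcomeRelation(str(a), str(b), kind))
    return MetaDataset(tables=df, relations=relations)


def write_dataset(dataset: MetaDataset, tables_path: str | Path,
                  relations_path: str | Path | None = None) -> None:
    """Write a dataset back to CSV (+ YAML); inverse of :func:`read_dataset`."""
    dataset.tables[TABLE_COLUMNS].to_csv(tables_path, index=False)
    if relations_path is not None:
        doc = {
            "relations": [
                {"outcomes": [r.outcome_a, r.outcome_b],
                 "relation": r.relation.value}
                for r in dataset.relations
            ]
        }
        Path(relations_path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EligibilityReport:
    outcome_id: str
    n_studies_reporting: int
    eligible: bool
    reason: str


@dataclass(frozen=True)
class DatasetEligibility:
    """Per-outcome eligibility plus the dataset-level multivariate flag.

    An outcome is eligible when at least ``min_studies`` studies report it;
    a joint (multivariate) analysis additionally needs at least two eligible
    outcomes.
    """

    reports: tuple[EligibilityReport, ...]
    min_studies: int
    mvma_feasible: bool

    @property
    def eligible_outcomes(self) -> list[str]:
        return [r.outcome_id for r in self.reports if r.eligible]

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "min_studies": self.min_studies,
            "mvma_feasible": self.mvma_feasible,
            "outcomes": [
                {"outcome_id": r.outcome_id,
                 "n_studies_reporting": r.n_studies_reporting,
                 "eligible": r.eligible, "reason": r.reason}
                for r in self.reports
            ],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


def eligibility_filter(dataset: MetaDataset, min_studies: int = 3) -> DatasetEligibility:
    """Screen each outcome against the minimum-studies criterion.

    Defaults to three reporting studies per outcome, and flags the dataset
    as suitable for multivariate analysis only when two or more outcomes
    pass.
    """
    reports = []
    for outcome in dataset.outcome_ids:
        n = len(dataset.studies_reporting(outcome))
        eligible = n >= min_studies
        reason = (f"reported by {n} studies (>= {min_studies})" if eligible
                  else f"reported by only {n} studies (< {min_studies})")
        reports.append(EligibilityReport(outcome, n, eligible, reason))
    n_eligible = sum(r.eligible for r in reports)
    return DatasetEligibility(tuple(reports), min_studies, n_eligible >= 2)
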