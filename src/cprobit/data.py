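"""Ingestion and pairing of two-time-point repeated-measures data.

The estimators in this package all operate on within-subject differences.
A *paired dataset* holds, for each subject i with outcomes (y_i1, y_i2) and
covariate rows (x_i1, x_i2):

    delta_y[i]  = y_i2 - y_i1
    delta_x[i]  = x_i2 - x_i1           (row vector, one entry per covariate)
    I[i]        = 1{y_i2 > y_i1}        (the increase indicator)

Differencing eliminates any subject-specific intercept, so time-invariant
covariates difference to exactly zero; such columns are rejected at
construction to make explicit that they are implicitly controlled for rather
than estimable.  Subjects with delta_y = 0 carry no information about the
direction of change; by default they are dropped with a logged count
(``tie_count``), since the conditional likelihood is undefined for ties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataValidationError, DesignError, SchemaError, TieError

logger = logging.getLogger(__name__)

__all__ = ["ObservationRecord", "PairedDataset", "read_long_csv", "build_paired_dataset"]


class ObservationRecord(NamedTuple):
    """One subject-time observation in long format."""

    subject_id: object
    time_index: int
    outcome: float
    covariates: tuple


@dataclass(frozen=True)
class PairedDataset:
    """Within-subject difference design for n subjects with two time points each.

    Attributes
    ----------
    n_subjects : int
        Number of retained (non-tied) subjects.
    delta_y : (n,) ndarray
        Outcome differences, time 2 minus time 1.
    delta_x : (n, p) ndarray
        Covariate differences.  A baseline-by-time interaction differences to
        the baseline value; a period indicator differences to 1.
    increase_indicator : (n,) ndarray of {0, 1}
        1 where delta_y > 0.
    raw_outcomes : (n, 2) ndarray
        (y_i1, y_i2), retained so a transformation can be applied later.
    tie_count : int
        Number of subjects excluded because delta_y = 0.
    subject_ids : tuple
        Identifiers of retained subjects, in output order.
    covariate_names : tuple of str
        Column labels for delta_x.
    """

    n_subjects: int
    delta_y: np.ndarray
    delta_x: np.ndarray
    increase_indicator: np.ndarray
    raw_outcomes: np.ndarray
    tie_count: int
    subject_ids: tuple = ()
    covariate_names: tuple = field(default=())

    @property
    def n_covariates(self) -> int:
        return self.delta_x.shape[1]


def read_long_csv(path, column_map: Mapping[str, object]) -> list[ObservationRecord]:
    """Read long-format paired data from a CSV file.

    Parameters
    ----------
    path : str or path-like
        CSV file with a header row; UTF-8; no missing values.
    column_map : mapping
        Keys ``"subject"``, ``"time"``, ``"outcome"`` (column names) and
        ``"covariates"`` (sequence of column names, possibly empty).

    Returns
    -------
    list of ObservationRecord, ordered by (subject_id, time_index).

    Raises
    ------
    SchemaError
        If a mapped column is absent or a value cannot be parsed.
    DataValidationError
        If any subject does not have exactly the time points {1, 2}.
    """
    df = pd.read_csv(path)
    subject_col = column_map["subject"]
    time_col = column_map["time"]
    outcome_col = column_map["outcome"]
    covariate_cols = list(column_map.get("covariates", []))

    missing = [c for c in [subject_col, time_col, outcome_col, *covariate_cols] if c not in df.columns]
    if missing:
        raise SchemaError(f"column(s) {missing} not found in {path}; available: {list(df.columns)}")

    def _numeric(col, what):
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            raise SchemaError(f"non-numeric {what} in column '{col}' at row(s) {list(bad[:5])}")
        return parsed.to_numpy(dtype=float)

    outcome = _numeric(outcome_col, "outcome")
    time_raw = _numeric(time_col, "time index")
    covs = np.column_stack([_numeric(c, "covariate") for c in covariate_cols]) if covariate_cols else np.empty((len(df), 0))

    time_idx = time_raw.astype(int)
    if not np.array_equal(time_idx, time_raw) or not np.isin(time_idx, (1, 2)).all():
        bad_rows = np.nonzero(~np.isin(time_raw, (1.0, 2.0)))[0][:5]
        raise DataValidationError(f"time index must be 1 or 2; offending row(s): {list(bad_rows)}")

    subjects = df[subject_col].to_numpy()
    records = [
        ObservationRecord(subjects[i], int(time_idx[i]), float(outcome[i]), tuple(covs[i]))
        for i in range(len(df))
    ]
    _validate_pairing(records)
    records.sort(key=lambda r: (str(r.subject_id), r.time_index))
    return records


def _validate_pairing(records: Sequence[ObservationRecord]) -> dict:
    """Group records by subject, checking the exactly-{1,2} contract.

    Returns {subject_id: (record_t1, record_t2)}.
    """
    by_subject: dict = {}
    for rec in records:
        by_subject.setdefault(rec.subject_id, []).append(rec)
    bad = []
    pairs = {}
    for sid, recs in by_subject.items():
        times = sorted(r.time_index for r in recs)
        if times != [1, 2]:
            bad.append(sid)
            continue
        r1, r2 = sorted(recs, key=lambda r: r.time_index)
        pairs[sid] = (r1, r2)
    if bad:
        raise DataValidationError(
            f"{len(bad)} subject(s) without exactly one observation at each of times 1 and 2: "
            f"{bad[:10]}"
        )
    return pairs


def build_paired_dataset(
    records: Sequence[ObservationRecord],
    drop_ties: bool = True,
    covariate_names: Sequence[str] | None = None,
) -> PairedDataset:
    """Difference long-format records into a :class:`PairedDataset`.

    Differences are computed as time 2 minus time 1.  Subjects with
    delta_y = 0 are dropped (and counted) when ``drop_ties`` is set,
    otherwise a :class:`TieError` is raised.  Covariate columns whose
    difference is identically zero are rejected: after differencing they are
    implicitly controlled for and cannot be estimated.
    """
    if not records:
        raise DataValidationError("no records supplied")
    pairs = _validate_pairing(records)

    sids, dy, dx, inds, raw = [], [], [], [], []
    tie_count = 0
    tied_subjects = []
    for sid in sorted(pairs, key=str):
        r1, r2 = pairs[sid]
        d = r2.outcome - r1.outcome
        if d == 0.0:
            if not drop_ties:
                raise TieError(
                    f"subject {sid!r} has identical outcomes at both times (delta_y = 0); "
                    "the increase indicator is undefined for ties (pass drop_ties=True to exclude)"
                )
            tie_count += 1
            tied_subjects.append(sid)
            continue
        if len(r1.covariates) != len(r2.covariates):
            raise DataValidationError(f"subject {sid!r} has covariate vectors of unequal length")
        sids.append(sid)
        dy.append(d)
        dx.append(np.subtract(r2.covariates, r1.covariates, dtype=float))
        inds.append(1 if d > 0 else 0)
        raw.append((r1.outcome, r2.outcome))

    if tie_count:
        logger.warning("dropped %d tied subject(s) with delta_y = 0: %s", tie_count, tied_subjects[:10])
    if not sids:
        raise DesignError("all subjects tied (delta_y = 0 for every subject); empty design")

    delta_x = np.asarray(dx, dtype=float)
    if delta_x.size:
        zero_cols = np.nonzero(np.all(delta_x == 0.0, axis=0))[0]
        if len(zero_cols):
            names = covariate_names or [f"x{j}" for j in range(delta_x.shape[1])]
            offenders = [names[j] for j in zero_cols]
            raise DesignError(
                f"covariate column(s) {offenders} are time-invariant (difference identically zero); "
                "after within-subject differencing they are implicitly controlled for and must be "
                "removed from the covariate list"
            )

    p = delta_x.shape[1]
    names = tuple(covariate_names) if covariate_names is not None else tuple(f"x{j}" for j in range(p))
    if len(names) != p:
        raise DataValidationError(f"{len(names)} covariate names supplied for {p} columns")

    return PairedDataset(
        n_subjects=len(sids),
        delta_y=np.asarray(dy, dtype=float),
        delta_x=delta_x,
        increase_indicator=np.asarray(inds, dtype=int),
        raw_outcomes=np.asarray(raw, dtype=float),
        tie_count=tie_count,
        subject_ids=tuple(sids),
        covariate_names=names,
    )
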