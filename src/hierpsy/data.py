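"""Reading, validating and aggregating forced-choice trial tables.

The canonical in-memory container is :class:`TrialTable`, a thin wrapper
around a tidy :class:`pandas.DataFrame` with one row per observation cell:

    subject, stimulus, condition, group (optional), successes, trials

Two CSV dialects are accepted, distinguished by the column schema:

* per-trial — one row per trial with a binary ``response`` column; rows are
  kept as ``trials=1``, ``successes`` in {0, 1};
* aggregated — one row per (subject, stimulus, condition[, group]) cell with
  explicit ``successes`` and ``trials`` counts.

``aggregate_binomial`` collapses a per-trial (Bernoulli) table into binomial
cells; the two forms are likelihood-equivalent up to the binomial
coefficient, which the model layer includes explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "TrialTable",
    "SchemaError",
    "ValidationError",
    "read_trials",
    "write_trials",
    "aggregate_binomial",
    "validate_trials",
]

CANONICAL_COLUMNS = ["subject", "stimulus", "condition", "group", "successes", "trials"]

#: Default column-name map for aggregated CSV files.
DEFAULT_SCHEMA: dict[str, str] = {
    "subject": "subject",
    "stimulus": "stimulus",
    "condition": "condition",
    "group": "group",
    "successes": "successes",
    "trials": "trials",
}


class SchemaError(ValueError):
    """A required column could not be resolved in the input file."""


class ValidationError(ValueError):
    """The table violates a structural invariant (e.g. successes > trials)."""


@dataclass
class TrialTable:
    """Tidy forced-choice observations plus study-level metadata.

    ``frame`` holds the canonical columns; ``group`` is pandas ``NA`` when
    the study has no group structure.  ``reference`` is the reference
    stimulus of the two-interval task (optional; used for interpreting the
    PSE as bias), ``units`` the stimulus units (cm/s in the shipped
    presets).
    """

    frame: pd.DataFrame
    study: str = ""
    reference: float | None = None
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.frame.copy()
        missing = [c for c in CANONICAL_COLUMNS if c not in df.columns and c != "group"]
        if missing:
            raise SchemaError(f"missing canonical column(s): {', '.join(missing)}")
        if "group" not in df.columns:
            df["group"] = pd.NA
        df = df[CANONICAL_COLUMNS].reset_index(drop=True)
        df["subject"] = df["subject"].astype(str)
        df["condition"] = df["condition"].astype(str)
        df["stimulus"] = pd.to_numeric(df["stimulus"], errors="raise").astype(float)
        df["successes"] = df["successes"].astype(int)
        df["trials"] = df["trials"].astype(int)
        self.frame = df
        _check_hard_invariants(df)

    # -- convenience accessors -------------------------------------------
    @property
    def subjects(self) -> list[str]:
        """Subject labels in order of first appearance."""
        return list(dict.fromkeys(self.frame["subject"]))

    @property
    def conditions(self) -> list[str]:
        """Condition labels in order of first appearance."""
        return list(dict.fromkeys(self.frame["condition"]))

    @property
    def groups(self) -> list[str]:
        """Group labels in order of first appearance (empty if ungrouped)."""
        col = self.frame["group"].dropna()
        return list(dict.fromkeys(col.astype(str)))

    @property
    def has_groups(self) -> bool:
        return len(self.groups) > 0

    def subject_group(self) -> dict[str, str | None]:
        """Map each subject to its (unique) group label, or None."""
        out: dict[str, str | None] = {}
        for subj, sub in self.frame.groupby("subject", sort=False):
            gs = sub["group"].dropna().astype(str).unique()
            if len(gs) > 1:
                raise ValidationError(f"subject {subj!r} appears in multiple groups: {sorted(gs)}")
            out[str(subj)] = str(gs[0]) if len(gs) else None
        return out

    def n_trials(self) -> int:
        return int(self.frame["trials"].sum())

    def select(self, *, group: str | None = None, condition: str | None = None) -> "TrialTable":
        """Return a sub-table restricted to one group and/or condition."""
        df = self.frame
        if group is not None:
            df = df[df["group"].astype("string") == group]
        if condition is not None:
            df = df[df["condition"] == condition]
        return replace(self, frame=df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)


def _check_hard_invariants(df: pd.DataFrame) -> None:
    if not np.all(np.isfinite(df["stimulus"].to_numpy())):
        raise ValidationError("non-finite stimulus value")
    bad = df.index[(df["successes"] < 0) | (df["trials"] < 1) | (df["successes"] > df["trials"])]
    if len(bad):
        i = int(bad[0])
        raise ValidationError(
            f"row {i}: successes={int(df.loc[i, 'successes'])} "
            f"trials={int(df.loc[i, 'trials'])} violates 0 <= successes <= trials, trials >= 1"
        )
    # a subject must not straddle groups
    sub = df.dropna(subset=["group"])
    if len(sub):
        per = sub.groupby("subject")["group"].nunique()
        multi = per[per > 1]
        if len(multi):
            raise ValidationError(f"subject {multi.index[0]!r} appears in more than one group")


def read_trials(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    *,
    study: str = "",
    reference: float | None = None,
    units: str = "",
) -> TrialTable:
    """Read a long-format CSV of forced-choice trials.

    Parameters
    ----------
    path
        CSV file with a header row (RFC-4180, UTF-8).
    schema
        Map from canonical names (``subject``, ``stimulus``, ``condition``,
        ``group``, and either ``response`` or ``successes``/``trials``) to
        the column names used in the file.  Keys left out fall back to the
        canonical name itself.  Presence of a resolvable ``response`` column
        selects the per-trial dialect; otherwise ``successes``/``trials``
        are required.

    Returns
    -------
    TrialTable
        Per-trial input is kept row-per-trial with ``trials=1``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    schema = dict(schema or {})
    raw = pd.read_csv(path, float_precision="round_trip")

    def col(name: str, required: bool = True) -> str | None:
        c = schema.get(name, name)
        if c in raw.columns:
            return c
        if required:
            raise SchemaError(f"{name} column not found (looked for {c!r} in {list(raw.columns)})")
        return None

    out = pd.DataFrame()
    out["subject"] = raw[col("subject")]
    stim_col = col("stimulus")
    stim = pd.to_numeric(raw[stim_col], errors="coerce")
    if stim.isna().any():
        i = int(stim.index[stim.isna()][0])
        raise ValidationError(f"non-numeric stimulus value in column {stim_col!r} at row {i}")
    out["stimulus"] = stim
    out["condition"] = raw[col("condition")]
    gcol = col("group", required=False)
    out["group"] = raw[gcol] if gcol is not None else pd.NA

    rcol = schema.get("response", "response")
    if rcol in raw.columns:
        resp = pd.to_numeric(raw[rcol], errors="coerce")
        if resp.isna().any() or not resp.isin([0, 1]).all():
            raise ValidationError(f"per-trial response column {rcol!r} must be binary 0/1")
        out["successes"] = resp.astype(int)
        out["trials"] = 1
    else:
        out["successes"] = pd.to_numeric(raw[col("successes")], errors="raise")
        out["trials"] = pd.to_numeric(raw[col("trials")], errors="raise")

    return TrialTable(out, study=study, reference=reference, units=units)


def write_trials(table: TrialTable, path: str | Path) -> None:
    """Write the canonical aggregated CSV (round-trips with read_trials)."""
    df = table.frame.copy()
    # full-precision stimulus so read->write->read is exact
    df.to_csv(path, index=False, float_format="%.17g")


def aggregate_binomial(table: TrialTable) -> TrialTable:
    """Collapse rows sharing (subject, stimulus, condition, group) cells.

    Sums successes and trials within each cell.  Idempotent; conserves the
    totals of both counts exactly.
    """
    df = table.frame
    keys = ["subject", "stimulus", "condition", "group"]
    agg = (
        df.groupby(keys, sort=False, dropna=False)[["successes", "trials"]]
        .sum()
        .reset_index()
    )
    return replace(table, frame=agg)


def validate_trials(table: TrialTable) -> list[dict]:
    """Report-only validation; returns a list of violation/warning records.

    Each record has keys ``kind``, ``message`` and, where applicable,
    ``row`` or ``subject``.  Hard invariants (successes > trials and the
    like) are already rejected at construction; this surfaces softer
    issues: duplicate cells that would be merged by aggregation, and
    subjects observed at a single stimulus level, for whom intercept and
    slope are not separately identifiable.
    """
    report: list[dict] = []
    df = table.frame
    if len(df) == 0:
        report.append({"kind": "empty", "message": "table has no rows"})
        return report

    keys = ["subject", "stimulus", "condition", "group"]
    dup = df.duplicated(subset=keys, keep=False)
    if dup.any():
        ncell = int(df[dup].groupby(keys, dropna=False).ngroups)
        report.append(
            {
                "kind": "aggregatable",
                "message": f"{ncell} cell(s) appear on multiple rows; aggregate_binomial will merge them",
            }
        )
    for subj, sub in df.groupby("subject", sort=False):
        for cond, subc in sub.groupby("condition", sort=False):
            if subc["stimulus"].nunique() < 2:
                report.append(
                    {
                        "kind": "slope_unidentifiable",
                        "subject": str(subj),
                        "message": (
                            f"slope unidentifiable for subject {subj!r} in condition {cond!r}: "
                            "only one stimulus level observed"
                        ),
                    }
                )
    return report
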