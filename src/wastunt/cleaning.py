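"""Exclusion rules for longitudinal anthropometric records.

Two visit-level rules are applied in order:

1. *Implausible z-scores*: LAZ > 6 or < -6, or WLZ > 5 or < -5 (strict
   inequalities; these mirror the WHO flagging limits).
2. *Extreme change*: a jump of more than 3 SD in LAZ or WLZ between
   consecutive visits of the same child.  Of the offending pair, the visit
   whose z-score lies farther from that child's median is treated as the
   outlier and excluded; the sweep repeats until no violating pair remains.
   Ties go against the later visit.

A participant whose visits are all excluded is counted as an excluded
participant; otherwise only individual visits are dropped.  The report
keeps the exact conservation identity

    input visits == output visits + sum of per-rule exclusions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd

from .visits import sort_visits

__all__ = [
    "CleaningReport",
    "filter_implausible",
    "filter_extreme_change",
    "build_cleaning_report",
    "clean_cohort",
    "LAZ_LIMIT",
    "WLZ_LIMITS",
    "EXTREME_CHANGE_SD",
]

LAZ_LIMIT = 6.0
WLZ_LIMITS = 5.0
EXTREME_CHANGE_SD = 3.0

REASON_IMPLAUSIBLE = "implausible_z"
REASON_EXTREME = "extreme_change"


@dataclass
class CleaningReport:
    """Figure-1-style accounting of excluded participants vs excluded visits."""

    input_subjects: int
    input_visits: int
    visits_excluded: dict = field(default_factory=dict)  # rule -> count
    subjects_excluded_no_visits: int = 0
    output_subjects: int = 0
    output_visits: int = 0

    def validate(self) -> None:
        total_excluded = sum(self.visits_excluded.values())
        if self.input_visits != self.output_visits + total_excluded:
            raise ValueError(
                "cleaning report inconsistent: "
                f"{self.input_visits} != {self.output_visits} + {total_excluded}"
            )
        if self.input_subjects != self.output_subjects + self.subjects_excluded_no_visits:
            raise ValueError("subject counts inconsistent in cleaning report")

    def to_json(self, path=None) -> str:
        s = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    def log_block(self) -> str:
        lines = [
            f"input: {self.input_subjects} subjects, {self.input_visits} visits",
        ]
        for rule, n in self.visits_excluded.items():
            lines.append(f"  excluded visits ({rule}): {n}")
        lines.append(
            f"  excluded participants (no visits left): {self.subjects_excluded_no_visits}"
        )
        lines.append(
            f"output: {self.output_subjects} subjects, {self.output_visits} visits"
        )
        return "\n".join(lines)


def filter_implausible(visits: pd.DataFrame):
    """Drop visits with LAZ outside (-6, 6) or WLZ outside (-5, 5), strictly.

    Returns ``(kept, excluded, n_excluded)``; excluded rows carry
    ``exclusion_reason`` and per-axis flags.
    """
    laz = visits["laz"].to_numpy(float)
    wlz = visits["wlz"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        bad_laz = np.abs(laz) > LAZ_LIMIT  # NaN compares False: missing passes
        bad_wlz = np.abs(wlz) > WLZ_LIMITS
    bad = bad_laz | bad_wlz
    excluded = visits.loc[bad].copy()
    excluded["exclusion_reason"] = REASON_IMPLAUSIBLE
    excluded["flag_laz"] = bad_laz[bad]
    excluded["flag_wlz"] = bad_wlz[bad]
    kept = visits.loc[~bad].copy()
    return kept, excluded, int(bad.sum())


def _extreme_change_one_subject(z: np.ndarray) -> set[int]:
    """Positions (into the subject's visit sequence) excluded by the >3 SD rule.

    The subject median is fixed at entry; the pair sweep repeats on the
    surviving sequence until stable.
    """
    n = len(z)
    valid = np.isfinite(z)
    if valid.sum() < 2:
        return set()
    med = np.median(z[valid])
    alive = [i for i in range(n) if valid[i]]
    dropped: set[int] = set()
    while True:
        pairs = [
            (alive[k], alive[k + 1])
            for k in range(len(alive) - 1)
            if abs(z[alive[k + 1]] - z[alive[k]]) > EXTREME_CHANGE_SD
        ]
        if not pairs:
            return dropped
        i, j = pairs[0]
        di, dj = abs(z[i] - med), abs(z[j] - med)
        out = j if dj >= di else i  # tie -> later visit
        dropped.add(out)
        alive.remove(out)


def filter_extreme_change(visits: pd.DataFrame):
    """Drop outlying visits creating >3 SD jumps between consecutive visits.

    Applied independently to LAZ and WLZ on the per-subject, date-sorted
    sequence; a visit flagged on either axis is excluded entirely.
    Returns ``(kept, excluded, n_excluded)``.
    """
    df = sort_visits(visits)
    drop_mask = np.zeros(len(df), dtype=bool)
    flag_laz = np.zeros(len(df), dtype=bool)
    flag_wlz = np.zeros(len(df), dtype=bool)
    for _, idx in df.groupby("subject_id", sort=False).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            continue
        for col, flags in (("laz", flag_laz), ("wlz", flag_wlz)):
            z = df.loc[idx, col].to_numpy(float)
            for pos in _extreme_change_one_subject(z):
                flags[idx[pos]] = True
    drop_mask = flag_laz | flag_wlz
    excluded = df.loc[drop_mask].copy()
    excluded["exclusion_reason"] = REASON_EXTREME
    excluded["flag_laz"] = flag_laz[drop_mask]
    excluded["flag_wlz"] = flag_wlz[drop_mask]
    kept = df.loc[~drop_mask].copy()
    return kept, excluded, int(drop_mask.sum())


def build_cleaning_report(
    input_visits: pd.DataFrame,
    output_visits: pd.DataFrame,
    per_rule_exclusions: dict,
) -> CleaningReport:
    """Assemble and validate the participant/visit exclusion accounting."""
    report = CleaningReport(
        input_subjects=input_visits["subject_id"].nunique(),
        input_visits=len(input_visits),
        visits_excluded=dict(per_rule_exclusions),
        output_subjects=output_visits["subject_id"].nunique(),
        output_visits=len(output_visits),
    )
    report.subjects_excluded_no_visits = (
        report.input_subjects - report.output_subjects
    )
    report.validate()
    return report


def clean_cohort(visits: pd.DataFrame):
    """Run both exclusion rules in order and report.

    Returns ``(kept, excluded, report)`` where ``excluded`` concatenates the
    per-rule exclusion tables (each visit appears at most once, with exactly
    one reason code).
    """
    df = sort_visits(visits)
    kept1, excl1, n1 = filter_implausible(df)
    kept2, excl2, n2 = filter_extreme_change(kept1)
    excluded = pd.concat([excl1, excl2], ignore_index=True)
    report = build_cleaning_report(
        df, kept2, {REASON_IMPLAUSIBLE: n1, REASON_EXTREME: n2}
    )
    return kept2.reset_index(drop=True), excluded, report
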