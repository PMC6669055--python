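#!/usr/bin/env python
"""Score raw anthropometry to LAZ/WLZ and apply the exclusion rules.

Reads results/cohort/visits_raw.csv, writes the scored-and-cleaned visit
table, the excluded-visit listing and the participant/visit accounting.
Reports how many of the planted corruptions the rules caught.
"""

import pandas as pd
from pathlib import Path

from wastunt import cleaning, lms
from wastunt.visits import read_visits_csv

BASE = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main():
    visits = read_visits_csv(BASE / "visits_raw.csv")
    refs = lms.read_lms_csv(BASE / "lms_reference.csv")
    visits = lms.add_zscores(visits, refs["age_days"], refs["length_cm"])

    kept, excluded, report = cleaning.clean_cohort(visits)
    kept.to_csv(BASE / "visits_clean.csv", index=False)
    excluded.to_csv(BASE / "visits_excluded.csv", index=False)
    report.to_json(BASE / "cleaning_report.json")
    print(report.log_block())

    planted = pd.read_csv(BASE / "truth_planted.csv")
    for kind in ("implausible", "spike"):
        sub = planted[planted["kind"] == kind]
        caught = sub["visit_id"].isin(excluded["visit_id"]).mean()
        print(f"planted {kind} records caught: {100 * caught:.1f}% of {len(sub)}")


if __name__ == "__main__":
    main()
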