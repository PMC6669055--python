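#!/usr/bin/env python
"""Cross-sectional prevalence of wasting/stunting/concurrence by month of age.

Writes the sex-by-month prevalence table and the same table grouped by the
20-24-month stunting outcome and by current wasting, and prints where each
condition peaks.
"""

import numpy as np
from pathlib import Path

from wastunt import prevalence
from wastunt.visits import read_visits_csv

BASE = Path(__file__).resolve().parent.parent / "results" / "cohort"
OUT = BASE.parent / "prevalence"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    visits = read_visits_csv(BASE / "visits_clean.csv")
    monthly = prevalence.monthly_classification(visits)
    table = prevalence.prevalence_table(monthly)
    table.to_csv(OUT / "prevalence_by_age.csv", index=False)

    outcome = prevalence.outcome_stunted_20_24(visits)
    prevalence.grouped_prevalence(monthly, outcome).to_csv(
        OUT / "prevalence_by_20_24mo_outcome.csv", index=False
    )
    prevalence.grouped_prevalence(
        monthly.dropna(subset=["wasted"]), monthly.dropna(subset=["wasted"])["wasted"]
    ).to_csv(OUT / "prevalence_by_current_wasting.csv", index=False)

    pooled = table.query("n > 0").groupby("month").apply(
        lambda g: np.average(g[["pct_stunted", "pct_wasted", "pct_concurrent"]],
                             weights=g["n"], axis=0),
        include_groups=False,
    )
    arr = np.vstack(pooled.to_numpy())
    months = pooled.index.to_numpy()
    print(f"stunting rises from {arr[0, 0]:.1f}% (month 0) to {arr[-1, 0]:.1f}% (month 23)")
    print(f"wasting peaks at {arr[:, 1].max():.1f}% in month {months[arr[:, 1].argmax()]}")
    print(f"concurrence peaks at {arr[:, 2].max():.1f}% in month {months[arr[:, 2].argmax()]}")


if __name__ == "__main__":
    main()
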