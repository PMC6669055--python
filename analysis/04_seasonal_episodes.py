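#!/usr/bin/env python
"""Repeated wasting across the first two wet seasons of life.

Builds each child's first-wet / intervening-dry / second-wet windows,
classifies per-window wasting by median WLZ, and fits the logistic model
of second-wet-season wasting on first-wet and dry-season wasting.
"""

from pathlib import Path

from wastunt import risk, seasons
from wastunt.visits import read_visits_csv

BASE = Path(__file__).resolve().parent.parent / "results" / "cohort"
OUT = BASE.parent / "seasonal"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    visits = read_visits_csv(BASE / "visits_clean.csv")
    episodes = seasons.summarize_episodes(visits)
    episodes.to_csv(OUT / "season_episodes.csv", index=False)
    n_elig = int(episodes["eligible"].sum())
    print(f"{n_elig}/{len(episodes)} children observed in all three windows")

    fit = risk.season_repeat_model(episodes)
    fit.table().to_csv(OUT / "season_repeat_model.csv", index=False)
    tab = fit.table().set_index("term")
    for term, label in (
        ("wasted_wet1", "wasted in first wet season"),
        ("wasted_dry", "wasted in intervening dry season"),
    ):
        o, lo, hi = tab.loc[term, ["odds_ratio", "ci_low", "ci_high"]]
        print(f"{label}: OR {o:.1f} (95% CI {lo:.1f}, {hi:.1f})")


if __name__ == "__main__":
    main()
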