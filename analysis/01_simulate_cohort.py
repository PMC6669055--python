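#!/usr/bin/env python
"""Generate the default-condition synthetic cohort used by the later steps.

Emits the raw visit table (with a 2% planted-corruption rate so the
cleaning step has real work to do), the ground-truth manifest and the LMS
reference tables under results/cohort/.
"""

from pathlib import Path

from wastunt import lms
from wastunt.simulate import SyntheticConfig, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 20260901


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    refs = lms.toy_reference()
    cfg = SyntheticConfig(n_subjects=800, seed=SEED, outlier_rate=0.02)
    visits, manifest = generate_cohort(cfg, refs=refs)

    visits.to_csv(OUT / "visits_raw.csv", index=False)
    lms.write_lms_csv(refs, OUT / "lms_reference.csv")
    manifest.subjects.to_csv(OUT / "truth_subjects.csv")
    manifest.planted.to_csv(OUT / "truth_planted.csv", index=False)

    per = visits.groupby("subject_id").size()
    print(f"cohort: {visits['subject_id'].nunique()} children, {len(visits)} visits")
    print(f"visits per child: median {per.median():.0f}, IQR {per.quantile(.25):.0f}-{per.quantile(.75):.0f}")
    print(f"planted corruptions: {len(manifest.planted)} "
          f"({(manifest.planted['kind'] == 'implausible').sum()} implausible, "
          f"{(manifest.planted['kind'] == 'spike').sum()} spikes)")


if __name__ == "__main__":
    main()
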