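#!/usr/bin/env python
"""Extract all 55 pairwise group contrasts with the AND-rule.

Refits the rotation ensemble (deterministic given the cohort), extracts every
pairwise intercept and edge difference from the two relevant rotations,
applies the AND-rule, and scores detection against the planted ground truth.
"""

from pathlib import Path

from modnet import (
    GroundTruthNetwork,
    all_contrasts,
    comparison_universe,
    detection_scores,
    load_cohort_csv,
    rotate_references,
)
from modnet.contrasts import contrasts_frame

OUT = Path("results/analysis")


def main() -> None:
    cohort = load_cohort_csv(OUT / "cohort.csv")
    truth = GroundTruthNetwork.from_json(OUT / "truth.json")
    u = comparison_universe(len(cohort.groups), cohort.panel.n_items)
    print(f"{u['group_pairs']} group pairs x ({u['symptoms_per_comparison']} symptoms "
          f"+ {u['unordered_cooccurrence_slots']} symptom pairs)")

    contrasts = all_contrasts(rotate_references(cohort))
    frame = contrasts_frame(contrasts)
    frame.to_csv(OUT / "contrasts.csv", index=False)

    detected = frame.groupby("kind")["detected"].sum()
    print(f"AND-rule detected differences: {detected.to_dict()}")
    scores = detection_scores(contrasts, truth)
    for kind, s in scores.items():
        print(f"  {kind}: sensitivity={s['sensitivity']:.2f} "
              f"specificity={s['specificity']:.3f} (tp={s['tp']}, fp={s['fp']})")
    print(
        "note: at this desk-scale n the AND-rule is typically fully\n"
        "conservative for the smaller groups - a difference is confirmed only\n"
        "if it also survives the rotation where the affected (possibly tiny)\n"
        "group is the reference, where expressing it needs G-1 penalized\n"
        "coefficients. Adequately powered per-group recovery is demonstrated\n"
        "in 06_recovery_study.py."
    )
    print(f"wrote contrasts.csv to {OUT}/")


if __name__ == "__main__":
    main()
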