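#!/usr/bin/env python
"""Behavioral ANOVA: emotion main effects, PsyCap moderation, simple effects.

Reads results/trials.csv (written by 04_simulate_behavior.py; regenerated
if absent) and runs, per dependent variable: one-way ANOVA across emotions
with Bonferroni post hoc, the 3x2 factorial ANOVA with eta-squared effect
sizes, and — where the interaction is significant — simple effects of
emotion within each PsyCap group.
"""

import json
from pathlib import Path

from emosafe import (
    generate_trials,
    one_way_anova,
    preset_reported_means,
    read_trials_csv,
    simple_effects,
    two_way_anova,
)
from emosafe.synth_behavior import DVS

SEED = 3
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    trials_path = ROOT / "results" / "trials.csv"
    if trials_path.exists():
        trials = read_trials_csv(trials_path)
    else:
        trials = generate_trials(preset_reported_means(), seed=SEED)

    report = {}
    for dv in DVS:
        y = trials[dv].to_numpy()
        emotion = trials["emotion"].to_numpy()
        group = trials["psycap_group"].to_numpy()

        one = one_way_anova(y, emotion, posthoc=True)
        two = two_way_anova(y, emotion, group, unbalanced="type2")
        entry = {
            "one_way": one.to_frame().round(4).to_dict(orient="records"),
            "one_way_posthoc": [
                {"pair": f"{c.level_a} vs {c.level_b}", "direction": c.direction,
                 "p_adjusted": round(c.p_adjusted, 4)}
                for c in one.posthoc
            ],
            "two_way": two.to_frame().round(4).to_dict(orient="records"),
        }
        inter = two.effect("emotion:psycap")
        print(f"{dv}: emotion F={two.effect('emotion').F:.2f} "
              f"(p={two.effect('emotion').p:.4f}), "
              f"interaction F={inter.F:.2f} (p={inter.p:.4f})")
        if inter.p < 0.05:
            simples = simple_effects(y, emotion, group, focal_name="emotion")
            entry["simple_effects"] = {
                lev: res.to_frame().round(4).to_dict(orient="records")
                for lev, res in simples.items()
            }
            print(f"  interaction significant -> simple effects within "
                  f"{sorted(simples)} groups")

        report[dv] = entry

    out = ROOT / "results" / "behavior_anova.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(report, indent=2))
    print("wrote results/behavior_anova.json")


if __name__ == "__main__":
    main()
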