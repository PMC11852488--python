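#!/usr/bin/env python
"""Monte-Carlo calibration of the behavioral statistics.

Two checks on the synthetic-data + ANOVA machinery: (1) type-I error —
on zero-effect tables the emotion F-test should reject at ~5%; (2)
parameter recovery — an injected +0.10 RA fear-vs-neutral shift should be
recovered without bias at the study's sample size (n = 22).
"""

import json
from pathlib import Path

from scipy import stats

from emosafe.experiments import null_rejection_rate, ra_shift_recovery

SEED = 4
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    rate, pvals = null_rejection_rate(n_replicates=500, seed=SEED)
    _, ks_p = stats.kstest(pvals, "uniform")
    print(f"null rejection rate at alpha=0.05: {rate:.3f} over 500 tables "
          f"(nominal 0.05); KS uniformity p = {ks_p:.3f}")

    recovered, half_width = ra_shift_recovery(shift=0.10, n_replicates=200, seed=SEED)
    print(f"injected RA shift 0.10 recovered as {recovered:.4f} "
          f"+/- {half_width:.4f} (95% MC interval, 200 replicates, n=22)")

    out = ROOT / "results" / "calibration.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps({
        "null_rejection_rate": round(rate, 4),
        "ks_uniformity_p": round(float(ks_p), 4),
        "ra_shift_recovered": round(recovered, 4),
        "ra_shift_mc_halfwidth": round(half_width, 4),
    }, indent=2))
    print("wrote results/calibration.json")


if __name__ == "__main__":
    main()
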