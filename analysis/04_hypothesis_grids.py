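#!/usr/bin/env python
"""Score the cooperative-mechanism hypotheses on the fitted Model 3.

For each hypothesis (H1 general inclination, H2 reciprocity, H3 kin,
H4 friends, H5a/H5b closure, H6 status gap, H7 gender homophily) this
sweeps the attractiveness of one hypothetical tie over the 33 x 65 grid
of ego out-degree by alter in-degree, for an otherwise-typical woman and
man. Full long-format grids (~0.4 MB each) go to scratch/grids/; the
compact per-hypothesis summary goes to results/.
"""

from pathlib import Path

import pandas as pd

from coopnet.estimator import EstimationResult
from coopnet.hypotheses import default_scenarios, sweep_grid
from studyconf import RESULTS

SCRATCH = Path(__file__).resolve().parent.parent / "scratch" / "grids"


def main() -> None:
    est = EstimationResult.from_json((RESULTS / "estimate_model3.json").read_text())
    SCRATCH.mkdir(parents=True, exist_ok=True)
    summaries = []
    for scenario in default_scenarios():
        df = sweep_grid(est, scenario)
        df.to_csv(SCRATCH / f"grid_{scenario.hypothesis}.csv", index=False)
        means = df.groupby("gender")["value"].mean()
        diff = float(means["woman"] - means["man"])
        sig = float(df["significant"].mean())
        summaries.append(
            {
                "hypothesis": scenario.hypothesis,
                "label": scenario.label,
                "cells_per_gender": int(len(df) / 2),
                "mean_attractiveness_woman": float(means["woman"]),
                "mean_attractiveness_man": float(means["man"]),
                "mean_gender_gap": diff,
                "share_p_below_001": sig,
            }
        )
        print(
            f"{scenario.hypothesis:3s} ({scenario.label}): mean woman-man gap "
            f"{diff:+.3f} over {len(df)} combinations"
        )
    pd.DataFrame(summaries).to_csv(RESULTS / "hypothesis_summary.csv", index=False)
    print(
        "\nFinding: the gender gap per panel equals the sum of the gender-term "
        "contributions by construction; panels differ only through the focal "
        "mechanism's main effect and its woman interaction."
    )


if __name__ == "__main__":
    main()
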