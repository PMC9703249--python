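#!/usr/bin/env python
"""Generate the synthetic two-village study and describe it.

Writes the study CSVs (roster, covariates, dyads, two network waves,
composition schedule) plus a one-row summary table to results/.
"""

import json

import pandas as pd

from coopnet import io as cio
from studyconf import RESULTS, load_study


def main() -> None:
    roster, table, dyads, attrs, w1, w2, schedule, spec, beta = load_study()
    outdir = RESULTS / "study_data"
    outdir.mkdir(parents=True, exist_ok=True)
    cio.write_roster(outdir / "roster.csv", roster)
    cio.write_monadic(outdir / "monadic.csv", table, roster)
    cio.write_edge_list(outdir / "wave1.csv", w1, roster)
    cio.write_edge_list(outdir / "wave2.csv", w2, roster)
    cio.write_schedule(outdir / "schedule.csv", schedule, roster)
    (outdir / "true_beta.json").write_text(json.dumps(dict(zip(spec.names, beta.tolist())), indent=2))

    hamming = int((w1.adjacency != w2.adjacency).sum())
    jaccard = (w1.adjacency & w2.adjacency).sum() / max((w1.adjacency | w2.adjacency).sum(), 1)
    summary = pd.DataFrame(
        [
            {
                "n_actors": attrs.n,
                "ties_wave1": w1.tie_count,
                "ties_wave2": w2.tie_count,
                "density_wave1": round(float(w1.adjacency.mean()), 4),
                "hamming": hamming,
                "jaccard": round(float(jaccard), 3),
                "mean_age": round(float(table.frame["age"].mean()), 2),
                "share_women": round(float(table.frame["woman"].mean()), 3),
            }
        ]
    )
    summary.to_csv(RESULTS / "study_summary.csv", index=False)
    print("Synthetic study written to", outdir)
    print(summary.to_string(index=False))
    print(
        f"\nFinding: the generator produced a sparse directed support network "
        f"({w1.tie_count} -> {w2.tie_count} ties over {attrs.n} actors, "
        f"Jaccard {jaccard:.2f} between waves), in the regime the estimator expects."
    )


if __name__ == "__main__":
    main()
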