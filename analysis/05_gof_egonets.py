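#!/usr/bin/env python
"""Goodness of fit and gender-split ego-network comparison.

Simulates an ensemble of end-of-period networks under each fitted model,
computes the joint Mahalanobis-distance GOF tests on five auxiliary
statistics, and compares observed vs simulated gender differences in
ego-network structure under Model 3. Writes results/gof.csv and
results/egonet_comparison.csv.
"""

import numpy as np
import pandas as pd

from coopnet.estimator import EstimationResult
from coopnet.gof import GofConfig, auxiliary_suite, compare_egonets_by_gender, mahalanobis_gof
from coopnet.pipeline import _model_from_names
from coopnet.simulator import simulate_ensemble
from studyconf import MODELS, RESULTS, STUDY_SEED, load_study

ENSEMBLE = 500


def main() -> None:
    roster, table, dyads, attrs, w1, w2, schedule, _, _ = load_study()
    cfg = GofConfig()
    rows = []
    ego_df = None
    rng = np.random.default_rng(STUDY_SEED + 2)
    for key in ("model1", "model2", "model3"):
        est = EstimationResult.from_json((RESULTS / f"estimate_{key}.json").read_text())
        compiled = _model_from_names(MODELS[key]).compile(attrs)
        sims = list(
            simulate_ensemble(
                compiled, est.params, w1, schedule=schedule,
                n_sims=ENSEMBLE, seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
        obs_aux = auxiliary_suite(w2, attrs, cfg)
        sim_aux = [auxiliary_suite(w, attrs, cfg) for w in sims]
        for k, aux in enumerate(obs_aux):
            res = mahalanobis_gof(aux, [sa[k] for sa in sim_aux])
            rows.append({"model": key, "statistic": aux.name, "mhd": res.mhd, "gof_p": res.p_value})
            print(f"{key} {aux.name:24s} MHD={res.mhd:7.2f}  GOFp={res.p_value:.3f}")
        if key == "model3":
            ego_df = compare_egonets_by_gender(w2, sims, attrs)
    pd.DataFrame(rows).to_csv(RESULTS / "gof.csv", index=False)
    ego_df.to_csv(RESULTS / "egonet_comparison.csv", index=False)
    print("\nObserved vs simulated gender differences (Model 3):")
    print(ego_df.to_string(index=False))
    print(
        "\nNote: the fitted specifications are larger than the true "
        "data-generating model, so GOF reflects estimation quality at this "
        "sample size; low GOFp rows flag auxiliary features (typically triad "
        "composition) that the fitted parameters fail to reproduce."
    )


if __name__ == "__main__":
    main()
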