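#!/usr/bin/env python
"""Nested-model Wald tests.

Tests whether the effects added at each rung of the model ladder are
jointly zero: Model 2 vs Model 1 (all gender terms) and Model 3 vs
Model 2 (all constraint covariates). Writes results/wald_tests.csv.
"""

import pandas as pd

from coopnet.estimator import EstimationResult, wald_test
from studyconf import MODELS, RESULTS


def main() -> None:
    res = {
        k: EstimationResult.from_json((RESULTS / f"estimate_{k}.json").read_text())
        for k in ("model2", "model3")
    }
    rows = []
    for full, reduced, key in (("model2", "model1", "model2_vs_model1"), ("model3", "model2", "model3_vs_model2")):
        added = [n for n in MODELS[full] if n not in MODELS[reduced]]
        w = wald_test(res[full], added)
        rows.append({"comparison": key, "chi2": w.chi2, "df": w.df, "p": w.p_value})
        print(f"{key}: chi2 = {w.chi2:.2f}, df = {w.df}, one-tailed p = {w.p_value:.4f}")
    pd.DataFrame(rows).to_csv(RESULTS / "wald_tests.csv", index=False)
    print(
        "\nNote: the synthetic data-generating process contains only a small "
        "gender asymmetry (woman ego 0.1, woman x reciprocity 0.2), so at this "
        "sample size the Model 2 vs Model 1 test has limited power; Model 3's "
        "additions are pure noise and its test should not reject."
    )


if __name__ == "__main__":
    main()
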