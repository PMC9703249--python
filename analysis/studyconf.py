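"""Shared settings for the numbered analysis drivers.

One moderate-size synthetic study (two villages of 100 actors each) runs
through all stages; every driver regenerates the data deterministically
from STUDY_SEED so the stages can run independently.
"""

from pathlib import Path

from coopnet.estimator import EstimationConfig
from coopnet.synthetic import GeneratorConfig, generate_study

STUDY_SEED = 20170901
RESULTS = Path(__file__).resolve().parent.parent / "results"

GENERATOR = GeneratorConfig(n_per_village=100, seed=STUDY_SEED)

ESTIMATION = EstimationConfig(
    phase2_subphases=4,
    phase2_iterations=60,
    n_phase3=300,
    gain=0.3,
    strict=False,
    max_retries=1,
)

#: nested model ladder (full study specification)
from coopnet.pipeline import nested_ladder  # noqa: E402

MODELS = nested_ladder()


def load_study():
    return generate_study(GENERATOR)
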