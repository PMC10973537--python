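"""Shared configuration for the numbered analysis scripts.

The flagship cohort reproduces the study design this pipeline targets:
two matched groups of 43, 200 parcels, 175 retained timepoints, a
DMN-weighted contraction (kappa = 0.6) planted in the case group, and
clinical scores negatively coupled to the planted DMN gradient level.
"""

from pathlib import Path

from gradhier.gradients import GradientParams
from gradhier.pipeline import run_cohort_pipeline
from gradhier.simulate import SimulationConfig, simulate_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"

FLAGSHIP_SEED = 11

FLAGSHIP_CONFIG = SimulationConfig(
    n_parcels=200,
    n_per_group=43,
    n_timepoints=175,
    network_kappa={"Default": 0.6},
    seed=FLAGSHIP_SEED,
)

GRADIENT_PARAMS = GradientParams()  # sparsity 0.9, 10 components


def flagship_cohort():
    return simulate_cohort(FLAGSHIP_CONFIG)


def flagship_pipeline(sim=None):
    if sim is None:
        sim = flagship_cohort()
    return sim, run_cohort_pipeline(sim, GRADIENT_PARAMS)
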