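"""Shared constants for the numbered analysis drivers.

The study design mirrors a 4-cohort skin gene-expression meta-analysis:
three two-channel cohorts and one single-channel cohort over a shared
regulator universe, with planted intrinsic regulators and a severe driver
pair as ground truth.
"""

import dataclasses
from pathlib import Path

from regact.io_formats import SINGLE_CHANNEL
from regact.synthetic_data import default_config

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM_DIR = RESULTS / "sim"

MASTER_SEED = 20200903
N_COHORTS = 4
N_PERM_BASE = 60
N_PERM_WB = 200


def cohort_configs():
    base = default_config(
        seed=MASTER_SEED,
        n_genes=600,
        n_regulators=60,
        targets_per_regulator=30,
        samples_per_subset=15,
    )
    cfgs = [
        dataclasses.replace(base, seed=MASTER_SEED + i) for i in range(N_COHORTS)
    ]
    # the last cohort is a single-channel intensity array, like a study
    # mixing two-channel ratio platforms with one intensity platform
    cfgs[-1] = dataclasses.replace(cfgs[-1], dialect=SINGLE_CHANNEL)
    return cfgs


def cohort_names():
    return [f"cohort{i}" for i in range(N_COHORTS)]
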