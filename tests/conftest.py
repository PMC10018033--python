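"""Shared fixtures: small synthetic datasets and reusable short fits.

Everything is generated programmatically with fixed seeds; the session-scoped
fits are shared across test modules to keep the suite fast.
"""

from __future__ import annotations

from dataclasses import replace

import pandas as pd
import pytest

from hierpsy import (
    ChainConfig,
    TrialTable,
    TruePopulation,
    build_model,
    preset_design,
    run_chains,
    simulate_study,
)


@pytest.fixture(scope="session")
def tiny_table() -> TrialTable:
    """Two subjects, two conditions, three speeds; hand-written counts."""
    rows = []
    for subj in ("S1", "S2"):
        for cond in ("vib0", "vib1"):
            for x, y in zip((1.0, 3.0, 5.0), (2, 10, 18)):
                rows.append(
                    {
                        "subject": subj,
                        "stimulus": x,
                        "condition": cond,
                        "successes": y,
                        "trials": 20,
                    }
                )
    return TrialTable(pd.DataFrame(rows), study="tiny", units="cm/s")


@pytest.fixture(scope="session")
def small_design():
    """One-condition, 4-subject design for fast fitting tests."""
    return replace(
        preset_design("touch_diabetes"),
        groups=("",),
        n_subjects_per_group=4,
        conditions=("vib0",),
        repetitions=10,
        study="small",
    )


@pytest.fixture(scope="session")
def small_truth():
    return TruePopulation(pse=3.4, slope=0.46, tau_pse=25.0, tau_beta=100.0)


@pytest.fixture(scope="session")
def small_table(small_design, small_truth):
    table, _ = simulate_study(small_design, small_truth, 11)
    return table


@pytest.fixture(scope="session")
def small_fit(small_table):
    """Short but converged fit of the pse-slope model to the small dataset."""
    spec = build_model("pse_slope")
    cc = ChainConfig(n_chains=2, n_iterations=600, n_warmup=600, seed=5)
    draws = run_chains(spec, small_table, cc)
    return spec, draws, small_table


@pytest.fixture(scope="session")
def diab_ctrl_truth():
    """Unbiased control-group truth: population PSE at the 3.4 cm/s reference."""
    return TruePopulation(
        pse=3.4,
        slope={("", "vib0"): 0.46, ("", "vib1"): 0.32},
        tau_pse=25.0,
        tau_beta=100.0,
    )


@pytest.fixture(scope="session")
def diab_ctrl_table(diab_ctrl_truth):
    design = replace(preset_design("touch_diabetes"), groups=("",), study="touch_diabetes_controls")
    table, _ = simulate_study(design, diab_ctrl_truth, 42)
    return table


@pytest.fixture(scope="session")
def diab_ctrl_fit(diab_ctrl_table):
    """Preset-scale control-group fit shared by convergence/recovery tests."""
    spec = build_model("pse_slope")
    cc = ChainConfig(n_chains=4, n_iterations=2000, n_warmup=2000, seed=1)
    draws = run_chains(spec, diab_ctrl_table, cc)
    return spec, draws, diab_ctrl_table
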