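"""Synthetic forced-choice data from the hierarchical generative model.

Data are generated exactly as the fitted models assume: subject-level curve
parameters are normal draws around population locations with stated
precisions, and cell counts are binomial with probit success probabilities,

    pse_i^h ~ Normal(PSE_k^h, tau_pse),   beta_i^h ~ Normal(b_k^h, tau_beta),
    Y_ijh   ~ Binomial(n, Phi(beta_i^h * (x_j - pse_i^h))).

Two design presets emulate the studies the package's examples are built
around: a tactile speed-discrimination study with masking vibrations
(9 observers, 7 speeds spanning 1.0-16.0 cm/s, 40 repetitions per cell =
560 trials each) and a three-group clinical study of tactile dysfunction
(3 x 20 observers, 5 speeds spanning 0.6-6.4 cm/s, reference 3.4 cm/s,
120 trials each).  Exact stimulus grids are not published for either study;
the presets use evenly spaced grids between the stated endpoints, an
emulation rather than a reproduction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .data import TrialTable
from .models import ParamSet

__all__ = [
    "DesignSpec",
    "TruePopulation",
    "preset_design",
    "preset_truth",
    "draw_subject_params",
    "simulate_dataset",
    "simulate_study",
]

#: Precisions above this are treated as infinite: subjects share the
#: population value exactly (documented large-precision cap).
PRECISION_CAP = 1e12


@dataclass(frozen=True)
class DesignSpec:
    """Factorial design of a two-interval forced-choice experiment."""

    n_subjects_per_group: int
    groups: tuple[str, ...]
    conditions: tuple[str, ...]
    stimulus_levels: tuple[float, ...]
    repetitions: int
    reference: float | None = None
    units: str = "cm/s"
    study: str = "simulated"

    def __post_init__(self) -> None:
        if self.n_subjects_per_group < 1 or self.repetitions < 1:
            raise ValueError("need >= 1 subject per group and >= 1 repetition")
        if len(self.groups) < 1 or len(self.conditions) < 1:
            raise ValueError("need >= 1 group and >= 1 condition")
        if len(self.stimulus_levels) < 2:
            raise ValueError("need >= 2 stimulus levels (slope unidentifiable otherwise)")

    @property
    def grouped(self) -> bool:
        return not (len(self.groups) == 1 and self.groups[0] == "")

    @property
    def n_subjects(self) -> int:
        return self.n_subjects_per_group * len(self.groups)

    @property
    def trials_per_subject(self) -> int:
        return len(self.stimulus_levels) * len(self.conditions) * self.repetitions

    def subject_labels(self) -> list[tuple[str, str]]:
        """(subject, group) pairs, S01... numbering across groups."""
        out = []
        i = 0
        for g in self.groups:
            for _ in range(self.n_subjects_per_group):
                i += 1
                out.append((f"S{i:02d}", g))
        return out


@dataclass(frozen=True)
class TruePopulation:
    """Generative truth: population PSE/slope locations and precisions.

    ``pse`` and ``slope`` are either scalars (shared by every group and
    condition) or mappings keyed ``(group, condition)`` — use ``""`` for the
    group of an ungrouped design.  ``tau_pse`` and ``tau_beta`` are
    between-subject precisions (1 / variance).
    """

    pse: float | Mapping[tuple[str, str], float]
    slope: float | Mapping[tuple[str, str], float]
    tau_pse: float = 25.0
    tau_beta: float = 100.0

    def __post_init__(self) -> None:
        if not (self.tau_pse > 0 and self.tau_beta > 0):
            raise ValueError("precisions must be positive")

    def pse_at(self, group: str, cond: str) -> float:
        return self.pse if np.isscalar(self.pse) else self.pse[(group, cond)]

    def slope_at(self, group: str, cond: str) -> float:
        return self.slope if np.isscalar(self.slope) else self.slope[(group, cond)]

    def digest(self) -> str:
        pse = self.pse if np.isscalar(self.pse) else sorted(self.pse.items())
        slope = self.slope if np.isscalar(self.slope) else sorted(self.slope.items())
        payload = repr((pse, slope, self.tau_pse, self.tau_beta))
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_json(self) -> dict:
        def conv(v):
            return v if np.isscalar(v) else {f"{g}|{h}": x for (g, h), x in v.items()}

        return {
            "pse": conv(self.pse),
            "slope": conv(self.slope),
            "tau_pse": self.tau_pse,
            "tau_beta": self.tau_beta,
        }


def preset_design(name: str) -> DesignSpec:
    """Named design presets for the two example study layouts.

    ``touch_vibrations``: 9 subjects, one group, two masking conditions,
    7 speeds evenly spaced 1.0-16.0 cm/s, 40 repetitions per cell — 560
    trials per participant.

    ``touch_diabetes``: 3 groups (controls / mild / moderate) of 20
    subjects, two masking conditions, 5 speeds evenly spaced 0.6-6.4 cm/s,
    reference 3.4 cm/s, 12 repetitions per cell — 120 trials per
    participant (the published total; the per-cell split is our even
    allocation).
    """
    if name == "touch_vibrations":
        return DesignSpec(
            n_subjects_per_group=9,
            groups=("",),
            conditions=("vib0", "vib1"),
            stimulus_levels=tuple(np.round(np.linspace(1.0, 16.0, 7), 6)),
            repetitions=40,
            reference=None,
            study="touch_vibrations",
        )
    if name == "touch_diabetes":
        return DesignSpec(
            n_subjects_per_group=20,
            groups=("controls", "mild", "moderate"),
            conditions=("vib0", "vib1"),
            stimulus_levels=tuple(np.round(np.linspace(0.6, 6.4, 5), 6)),
            repetitions=12,
            reference=3.4,
            study="touch_diabetes",
        )
    raise ValueError(f"unknown design preset {name!r}")


def preset_truth(name: str) -> TruePopulation:
    """Plausible generative truths matched to the presets.

    Slopes are chosen so the no-masking curves span roughly (0.1, 0.9) over
    the design's stimulus grid; masking vibration (and, in the clinical
    design, tactile dysfunction) reduces the slope, giving shallower
    curves.  PSEs are unbiased (at the reference for ``touch_diabetes``).
    These are named fixtures for recovery tests, not estimates of the real
    studies.
    """
    if name == "touch_vibrations":
        return TruePopulation(
            pse={("", "vib0"): 6.0, ("", "vib1"): 6.0},
            slope={("", "vib0"): 0.26, ("", "vib1"): 0.17},
            tau_pse=4.0,
            tau_beta=400.0,
        )
    if name == "touch_diabetes":
        pse = {(g, h): 3.4 for g in ("controls", "mild", "moderate") for h in ("vib0", "vib1")}
        slope = {
            ("controls", "vib0"): 0.46, ("controls", "vib1"): 0.32,
            ("mild", "vib0"): 0.35, ("mild", "vib1"): 0.26,
            ("moderate", "vib0"): 0.25, ("moderate", "vib1"): 0.20,
        }
        return TruePopulation(pse=pse, slope=slope, tau_pse=25.0, tau_beta=100.0)
    raise ValueError(f"unknown truth preset {name!r}")


def draw_subject_params(
    pop: TruePopulation, design: DesignSpec, seed: int
) -> ParamSet:
    """Draw per-subject (pse, beta) values from the population normals.

    Returns a ParamSet with subject-level names
    (``pse[subject=S01,cond=...]``, ``beta[...]``); precisions above
    ``PRECISION_CAP`` collapse subjects onto the population values.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    sd_pse = 0.0 if pop.tau_pse >= PRECISION_CAP else pop.tau_pse ** -0.5
    sd_beta = 0.0 if pop.tau_beta >= PRECISION_CAP else pop.tau_beta ** -0.5
    out = ParamSet()
    for subj, g in design.subject_labels():
        for h in design.conditions:
            out[f"pse[subject={subj},cond={h}]"] = (
                pop.pse_at(g, h) + sd_pse * rng.standard_normal()
            )
            out[f"beta[subject={subj},cond={h}]"] = (
                pop.slope_at(g, h) + sd_beta * rng.standard_normal()
            )
    return out


def simulate_dataset(design: DesignSpec, params: Mapping[str, float], seed: int) -> TrialTable:
    """Binomial responses for every design cell given subject parameters.

    successes ~ Binomial(repetitions, Phi(beta * (x - pse))) per
    (subject, condition, stimulus) cell; returns an aggregated TrialTable
    whose metadata records the seed and a digest of the parameters used.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for subj, g in design.subject_labels():
        for h in design.conditions:
            try:
                pse = params[f"pse[subject={subj},cond={h}]"]
                beta = params[f"beta[subject={subj},cond={h}]"]
            except KeyError as e:
                raise KeyError(f"params missing subject-level entry {e.args[0]!r}") from None
            for x in design.stimulus_levels:
                p = float(ndtr(beta * (x - pse)))
                y = int(rng.binomial(design.repetitions, p))
                rows.append(
                    {
                        "subject": subj,
                        "stimulus": x,
                        "condition": h,
                        "group": g if design.grouped else pd.NA,
                        "successes": y,
                        "trials": design.repetitions,
                    }
                )
    digest = hashlib.sha256(
        json.dumps({k: params[k] for k in sorted(params)}).encode()
    ).hexdigest()[:16]
    return TrialTable(
        pd.DataFrame(rows),
        study=design.study,
        reference=design.reference,
        units=design.units,
        meta={"seed": seed, "params_digest": digest, "design": asdict(design)},
    )


def simulate_study(
    design: DesignSpec, pop: TruePopulation, seed: int
) -> tuple[TrialTable, ParamSet]:
    """Draw subject parameters and responses in one deterministic call.

    Derives separate sub-seeds for the two stages from ``seed``; returns
    the table and the subject-level truth.
    """
    ss = np.random.SeedSequence(seed).generate_state(2)
    params = draw_subject_params(pop, design, int(ss[0] % (2**31)))
    table = simulate_dataset(design, params, int(ss[1] % (2**31)))
    table.meta["truth"] = pop.to_json()
    table.meta["truth_digest"] = pop.digest()
    return table, params
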