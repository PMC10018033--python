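"""Declarative hierarchical probit model variants and their log-densities.

Every model in the package shares the same two-stage skeleton.  At the first
stage each subject ``i`` in condition ``h`` has a probit psychometric curve,
either in intercept--slope form,

    Phi^{-1}(pi_ijh) = alpha_i^h + beta_i^h * x_j,

or reparameterized so the point of subjective equality is explicit,

    Phi^{-1}(pi_ijh) = -pse_i^h * beta_i^h + beta_i^h * x_j,

with ``Y_ijh ~ Binomial(n_ijh, pi_ijh)``.  At the second stage the subject
parameters are exchangeable draws from population normals, e.g.
``pse_i^h ~ Normal(PSE^h, tau_pse^h)`` (second argument a PRECISION, the
JAGS convention), whose locations get ``Normal(0, sigma)`` priors and whose
precisions get Gamma(shape, rate) hyperpriors — Gamma(1, 0.001) at the first
stage and Gamma(1, 0.01) at the second by default.

Variants differ only in bookkeeping: whether population locations are
per-condition or per-(group, condition), whether first-stage precisions are
shared per condition, per subject, or per (group, condition), and whether a
second (historical) study is attached — either through a joint hierarchy in
which current population locations are centred on historical ones, or
through a power prior in which the historical likelihood enters raised to a
weight ``a0`` in [0, 1].

The module compiles a :class:`ModelSpec` plus data into flat arrays
(:class:`CompiledModel`) used both by the public log-density operations and
by the MCMC sampler.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import gammaln, ndtr

from .data import TrialTable

__all__ = [
    "ModelSpec",
    "ParamSet",
    "PowerPriorSpec",
    "build_model",
    "build_joint_model",
    "default_conversion",
    "compile_model",
    "log_likelihood",
    "log_prior",
    "log_posterior_power",
    "PROB_CLAMP",
]

#: Success probabilities are clamped to [PROB_CLAMP, 1 - PROB_CLAMP] inside
#: the likelihood so extreme linear predictors keep log terms finite.
PROB_CLAMP = 1e-12

_LOG_2PI = math.log(2.0 * math.pi)

PARAMETERIZATIONS = ("intercept_slope", "pse_slope")
GROUPINGS = ("none", "by_group")
PRECISION_STRUCTURES = ("by_condition", "by_subject", "by_group_and_condition")

# default hyperpriors, shape-rate on the precision scale
_DEFAULT_HYPER = {
    "tau1": (1.0, 0.001),
    "tau2": (1.0, 0.001),
    "sigma1": (1.0, 0.01),
    "sigma2": (1.0, 0.01),
    "tau1_hist": (1.0, 0.001),
    "tau2_hist": (1.0, 0.001),
    "sigma1_hist": (1.0, 0.01),
    "sigma2_hist": (1.0, 0.01),
}

# public hyperparameter names -> internal slots
_HYPER_ALIASES = {
    "tau_alpha": "tau1", "tau_pse": "tau1",
    "tau_beta": "tau2", "tau_b": "tau2",
    "sigma_a": "sigma1", "sigma_pse": "sigma1",
    "sigma_b": "sigma2",
    "tau_alpha0": "tau1_hist", "tau_pse0": "tau1_hist",
    "tau_beta0": "tau2_hist",
    "sigma_a0": "sigma1_hist", "sigma_pse0": "sigma1_hist",
    "sigma_b0": "sigma2_hist",
}


class ParamSet(dict):
    """One point in parameter space, addressable by canonical names.

    A plain mapping from parameter name (e.g. ``"beta[subject=S1,cond=vib0]"``,
    ``"PSE[cond=vib0]"``, ``"tau_pse[cond=vib0]"``, ``"sigma_b"``) to float.
    """


@dataclass(frozen=True)
class JointInfo:
    """Historical-study attachment for the joint two-study hierarchy."""

    conversion: float = 1.0


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one hierarchical model variant."""

    parameterization: str = "pse_slope"
    grouping: str = "none"
    precision_structure: str = "by_condition"
    hyperpriors: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    link: str = "probit"
    variant: str = ""
    joint: JointInfo | None = None

    def __post_init__(self) -> None:
        if self.parameterization not in PARAMETERIZATIONS:
            raise ValueError(f"unknown parameterization {self.parameterization!r}")
        if self.grouping not in GROUPINGS:
            raise ValueError(f"unknown grouping {self.grouping!r}")
        if self.precision_structure not in PRECISION_STRUCTURES:
            raise ValueError(f"unknown precision structure {self.precision_structure!r}")
        if self.link != "probit":
            raise ValueError("only the probit link is supported")
        if self.precision_structure == "by_group_and_condition" and self.grouping != "by_group":
            raise ValueError("by_group_and_condition precisions require grouping='by_group'")
        hp = dict(_DEFAULT_HYPER)
        for key, val in dict(self.hyperpriors).items():
            slot = _HYPER_ALIASES.get(key, key)
            if slot not in hp:
                raise ValueError(f"unknown hyperprior {key!r}")
            shape, rate = float(val[0]), float(val[1])
            if shape <= 0 or rate <= 0:
                raise ValueError(f"hyperprior {key!r} parameters must be positive")
            hp[slot] = (shape, rate)
        object.__setattr__(self, "hyperpriors", hp)

    # names used in the public parameter grammar
    @property
    def loc1_name(self) -> str:
        return "alpha" if self.parameterization == "intercept_slope" else "pse"

    @property
    def pop1_name(self) -> str:
        return "a" if self.parameterization == "intercept_slope" else "PSE"

    @property
    def tau1_name(self) -> str:
        return "tau_alpha" if self.parameterization == "intercept_slope" else "tau_pse"

    @property
    def sigma1_name(self) -> str:
        return "sigma_a" if self.parameterization == "intercept_slope" else "sigma_pse"

    def digest(self) -> str:
        payload = repr(
            (
                self.parameterization,
                self.grouping,
                self.precision_structure,
                sorted(self.hyperpriors.items()),
                self.link,
                self.variant,
                self.joint,
            )
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass(frozen=True)
class PowerPriorSpec:
    """Power-prior configuration: historical data raised to weight ``a0``.

    The prior for the current study is proportional to
    ``L(theta | D0)^a0 * pi0(theta)``: the historical likelihood enters
    down-weighted by ``a0`` in [0, 1] (0 ignores the historical study, 1
    pools it fully) on top of the initial prior ``pi0``.  Population
    locations are shared between the studies; subject-level parameters are
    study-specific, and the historical slope location is the shared slope
    divided by ``conversion`` (the factor that maps historical slopes onto
    the current stimulus scale; see :func:`default_conversion`).
    """

    a0: float
    historical: TrialTable
    conversion: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.a0 <= 1.0):
            raise ValueError(f"a0 must lie in [0, 1], got {self.a0}")
        if self.conversion is not None and not self.conversion > 0:
            raise ValueError("conversion factor must be positive")

    def resolve_conversion(self, current: TrialTable) -> float:
        if self.conversion is not None:
            return float(self.conversion)
        return default_conversion(current, self.historical)


def default_conversion(current: TrialTable, historical: TrialTable) -> float:
    """Slope conversion factor between studies on different stimulus ranges.

    Weber-type scaling makes the psychometric slope depend on the stimulus
    magnitudes probed, so slope locations cannot be shared verbatim between
    studies with different speed ranges.  The default factor is

        mean(current stimuli) / mean(historical stimuli),

    applied so that (current slope location) = factor x (historical slope
    location).  The orientation is a modelling choice and can be overridden
    with any positive value (pass ``conversion=`` explicitly; the reciprocal
    is the natural choice if slopes are taken inversely proportional to
    stimulus magnitude).
    """
    xc = float(np.mean(np.unique(current.frame["stimulus"])))
    xh = float(np.mean(np.unique(historical.frame["stimulus"])))
    if xh == 0:
        raise ValueError("historical design has zero mean stimulus")
    return xc / xh


def build_model(variant: str, **options) -> ModelSpec:
    """Construct a :class:`ModelSpec` for one of the named variants.

    Variants
    --------
    ``intercept_slope``
        Subject curves ``(alpha_i^h, beta_i^h)`` around population
        ``(a^h, b^h)``; per-condition precisions.
    ``pse_slope``
        Reparameterized ``(pse_i^h, beta_i^h)`` around ``(PSE^h, b^h)``;
        per-condition precisions.
    ``per_subject_precision``
        As ``pse_slope`` but each subject carries its own first-stage
        precisions ``tau_pse_i``, ``tau_beta_i``.
    ``grouped``
        As ``pse_slope`` with population locations and first-stage
        precisions indexed by (group, condition).

    ``options`` may override ``hyperpriors`` (a mapping such as
    ``{"tau_pse": (1, 0.001)}``) or any ModelSpec field.
    """
    table = {
        "intercept_slope": dict(parameterization="intercept_slope"),
        "pse_slope": dict(parameterization="pse_slope"),
        "per_subject_precision": dict(
            parameterization="pse_slope", precision_structure="by_subject"
        ),
        "grouped": dict(
            parameterization="pse_slope",
            grouping="by_group",
            precision_structure="by_group_and_condition",
        ),
    }
    if variant not in table:
        raise ValueError(
            f"unknown variant {variant!r}; expected one of {sorted(table)} "
            "(use build_joint_model for the two-study hierarchy)"
        )
    kwargs = dict(table[variant])
    kwargs["variant"] = variant
    kwargs.update(options)
    return ModelSpec(**kwargs)


def build_joint_model(
    current_spec: ModelSpec, historical_spec: ModelSpec, conversion: float
) -> ModelSpec:
    """Joint two-study hierarchy with current locations centred on historical.

    Both studies get their own subject and population parameters; the
    current population locations are given normal priors centred at the
    historical ones, with the slope centre multiplied by ``conversion``.
    The posterior second-stage precisions (``sigma_a[cond=...]``,
    ``sigma_b[cond=...]``) then quantify between-study agreement: the larger
    they are, the closer the two studies' population parameters sit.

    All precision hyperpriors default to Gamma(1, 0.01) in this variant.
    """
    if current_spec.parameterization != historical_spec.parameterization:
        raise ValueError("joint model requires both studies to share a parameterization")
    if not conversion > 0:
        raise ValueError("conversion factor must be positive")
    if current_spec.grouping != "none" or historical_spec.grouping != "none":
        raise ValueError("joint model supports ungrouped studies only")
    hyper = {
        "tau1": (1.0, 0.01),
        "tau2": (1.0, 0.01),
        "tau1_hist": (1.0, 0.01),
        "tau2_hist": (1.0, 0.01),
        "sigma1": (1.0, 0.01),
        "sigma2": (1.0, 0.01),
        "sigma1_hist": (1.0, 0.01),
        "sigma2_hist": (1.0, 0.01),
    }
    hyper.update(dict(current_spec.hyperpriors) if current_spec.hyperpriors != _DEFAULT_HYPER else {})
    return ModelSpec(
        parameterization=current_spec.parameterization,
        grouping="none",
        precision_structure="by_condition",
        hyperpriors=hyper,
        variant="joint",
        joint=JointInfo(conversion=float(conversion)),
    )


# ---------------------------------------------------------------------------
# compilation
# ---------------------------------------------------------------------------


class CompiledModel:
    """A ModelSpec bound to data: flat parameter vector + node arrays.

    Parameters are laid out in a single float vector.  Likelihood cells are
    arrays referencing the two subject-level parameters of each cell; prior
    structure is stored as vectorized normal nodes (child, mean reference,
    mean scale, precision reference) plus gamma nodes for the precisions.
    The sampler additionally uses the classification of parameters into
    likelihood-bearing subject locations (Metropolis blocks), population
    locations (conjugate normal Gibbs) and precisions (conjugate gamma
    Gibbs).
    """

    def __init__(
        self,
        spec: ModelSpec,
        data: TrialTable,
        historical: TrialTable | None = None,
        power: PowerPriorSpec | None = None,
    ):
        if power is not None and spec.joint is not None:
            raise ValueError("power prior and joint hierarchy are mutually exclusive")
        if power is not None:
            if spec.grouping != "none":
                raise ValueError("power-prior borrowing supports ungrouped current models only")
            historical = power.historical
        if spec.joint is not None and historical is None:
            raise ValueError("joint model requires a historical TrialTable")

        self.spec = spec
        self.data = data
        self.historical = historical
        self.power = power

        self.names: list[str] = []
        self._index: dict[str, int] = {}
        # normal prior nodes
        self._nn_child: list[int] = []
        self._nn_midx: list[int] = []
        self._nn_mscale: list[float] = []
        self._nn_mconst: list[float] = []
        self._nn_pidx: list[int] = []
        self._nn_pconst: list[float] = []
        # gamma prior nodes
        self._gn_idx: list[int] = []
        self._gn_shape: list[float] = []
        self._gn_rate: list[float] = []

        self._subject_loc1: list[int] = []
        self._subject_loc2: list[int] = []
        self._pop_locs: list[int] = []

        self._build()
        self._finalize()

    # -- construction helpers --------------------------------------------
    def _add(self, name: str) -> int:
        if name in self._index:
            raise ValueError(f"duplicate parameter {name!r}")
        self._index[name] = len(self.names)
        self.names.append(name)
        return self._index[name]

    def _normal(self, child, midx, mscale, mconst, pidx, pconst=1.0) -> None:
        self._nn_child.append(child)
        self._nn_midx.append(midx)
        self._nn_mscale.append(float(mscale))
        self._nn_mconst.append(float(mconst))
        self._nn_pidx.append(pidx)
        self._nn_pconst.append(float(pconst))

    def _gamma(self, idx, shape, rate) -> None:
        self._gn_idx.append(idx)
        self._gn_shape.append(float(shape))
        self._gn_rate.append(float(rate))

    def _build(self) -> None:
        spec = self.spec
        data = self.data
        hyper = spec.hyperpriors

        self.conditions = data.conditions
        if not self.conditions and self.historical is not None:
            # degenerate joint/power call with no current observations: the
            # posterior reduces to the historical model's
            self.conditions = self.historical.conditions
        if not self.conditions:
            raise ValueError("current data has no rows")
        self.subjects = data.subjects
        if spec.grouping == "by_group":
            if not data.has_groups:
                raise ValueError("grouped model requested but data has no group labels")
            self.groups = data.groups
            sg = data.subject_group()
            missing = [s for s, g in sg.items() if g is None]
            if missing:
                raise ValueError(f"grouped model: subject {missing[0]!r} has no group label")
            self.subject_group = sg
        else:
            self.groups = []
            self.subject_group = {s: None for s in self.subjects}

        p1, P1 = spec.loc1_name, spec.pop1_name
        tau1, sigma1 = spec.tau1_name, spec.sigma1_name
        conds = self.conditions

        pop_keys = (
            [(g, h) for g in self.groups for h in conds]
            if spec.grouping == "by_group"
            else [(None, h) for h in conds]
        )

        def popname(base: str, key) -> str:
            g, h = key
            return f"{base}[cond={h}]" if g is None else f"{base}[group={g},cond={h}]"

        def tauname(base: str, key) -> str:
            if spec.precision_structure == "by_condition":
                return f"{base}[cond={key}]"
            if spec.precision_structure == "by_subject":
                return f"{base}[subject={key}]"
            g, h = key
            return f"{base}[group={g},cond={h}]"

        joint = spec.joint is not None

        # ---- historical population block (parents first) ----
        if joint:
            hist = self.historical
            if set(hist.conditions) != set(conds):
                raise ValueError(
                    "joint model requires matching condition labels across studies"
                )
            pop1_hist, pop2_hist, s1h, s2h = {}, {}, None, None
            s1h = self._add("sigma_a0" if P1 == "a" else "sigma_pse0")
            s2h = self._add("sigma_b0")
            self._gamma(s1h, *hyper["sigma1_hist"])
            self._gamma(s2h, *hyper["sigma2_hist"])
            for h in conds:
                pop1_hist[h] = self._add(f"{P1}0[cond={h}]")
                pop2_hist[h] = self._add(f"b0[cond={h}]")
                self._normal(pop1_hist[h], -1, 0.0, 0.0, s1h)
                self._normal(pop2_hist[h], -1, 0.0, 0.0, s2h)
                self._pop_locs += [pop1_hist[h], pop2_hist[h]]

        # ---- current population block ----
        if joint:
            # per-condition second-stage precisions quantifying study agreement
            sig1 = {h: self._add(popname(sigma1, (None, h))) for h in conds}
            sig2 = {h: self._add(popname("sigma_b", (None, h))) for h in conds}
            for h in conds:
                self._gamma(sig1[h], *hyper["sigma1"])
                self._gamma(sig2[h], *hyper["sigma2"])
        else:
            s1 = self._add(sigma1)
            s2 = self._add("sigma_b")
            self._gamma(s1, *hyper["sigma1"])
            self._gamma(s2, *hyper["sigma2"])

        self._pop1 = {}
        self._pop2 = {}
        for key in pop_keys:
            i1 = self._add(popname(P1, key))
            i2 = self._add(popname("b", key))
            self._pop1[key], self._pop2[key] = i1, i2
            if joint:
                h = key[1]
                self._normal(i1, pop1_hist[h], 1.0, 0.0, sig1[h])
                self._normal(i2, pop2_hist[h], spec.joint.conversion, 0.0, sig2[h])
            else:
                self._normal(i1, -1, 0.0, 0.0, s1)
                self._normal(i2, -1, 0.0, 0.0, s2)
            self._pop_locs += [i1, i2]

        # ---- first-stage precisions ----
        if spec.precision_structure == "by_condition":
            tkeys = list(conds)
        elif spec.precision_structure == "by_subject":
            tkeys = list(self.subjects)
        else:
            tkeys = [(g, h) for g in self.groups for h in conds]
        self._tau1 = {k: self._add(tauname(tau1, k)) for k in tkeys}
        self._tau2 = {k: self._add(tauname("tau_beta", k)) for k in tkeys}
        for k in tkeys:
            self._gamma(self._tau1[k], *hyper["tau1"])
            self._gamma(self._tau2[k], *hyper["tau2"])

        def taukey(subj: str, cond: str):
            if spec.precision_structure == "by_condition":
                return cond
            if spec.precision_structure == "by_subject":
                return subj
            return (self.subject_group[subj], cond)

        # ---- current subject parameters ----
        self._loc1 = {}
        self._loc2 = {}
        for s in self.subjects:
            gk = self.subject_group[s] if spec.grouping == "by_group" else None
            for h in conds:
                i1 = self._add(f"{p1}[subject={s},cond={h}]")
                i2 = self._add(f"beta[subject={s},cond={h}]")
                self._loc1[(s, h)], self._loc2[(s, h)] = i1, i2
                tk = taukey(s, h)
                self._normal(i1, self._pop1[(gk, h)], 1.0, 0.0, self._tau1[tk])
                self._normal(i2, self._pop2[(gk, h)], 1.0, 0.0, self._tau2[tk])
                self._subject_loc1.append(i1)
                self._subject_loc2.append(i2)

        # ---- historical study block ----
        self._hloc1 = {}
        self._hloc2 = {}
        if self.historical is not None:
            hist = self.historical
            hconds = hist.conditions
            if set(hconds) != set(conds):
                raise ValueError(
                    "historical study must use the same condition labels as the current one"
                )
            if joint:
                htau1 = {h: self._add(f"{tau1}0[cond={h}]") for h in conds}
                htau2 = {h: self._add(f"tau_beta0[cond={h}]") for h in conds}
            else:
                # power prior: study-specific first-stage precisions, shared pop
                htau1 = {h: self._add(f"{tau1}0[cond={h}]") for h in conds}
                htau2 = {h: self._add(f"tau_beta0[cond={h}]") for h in conds}
            for h in conds:
                self._gamma(htau1[h], *hyper["tau1_hist"])
                self._gamma(htau2[h], *hyper["tau2_hist"])
            if joint:
                conv = None
            else:
                conv = self.power.resolve_conversion(data)
                self.conversion = conv
            for s in hist.subjects:
                for h in conds:
                    i1 = self._add(f"{p1}0[subject={s},cond={h}]")
                    i2 = self._add(f"beta0[subject={s},cond={h}]")
                    self._hloc1[(s, h)], self._hloc2[(s, h)] = i1, i2
                    if joint:
                        self._normal(i1, pop1_hist[h], 1.0, 0.0, htau1[h])
                        self._normal(i2, pop2_hist[h], 1.0, 0.0, htau2[h])
                    else:
                        self._normal(i1, self._pop1[(None, h)], 1.0, 0.0, htau1[h])
                        self._normal(i2, self._pop2[(None, h)], 1.0 / conv, 0.0, htau2[h])
                    self._subject_loc1.append(i1)
                    self._subject_loc2.append(i2)

        # ---- likelihood cells ----
        cx, cy, cn, cw, ci1, ci2 = [], [], [], [], [], []
        for row in data.frame.itertuples(index=False):
            key = (row.subject, row.condition)
            cx.append(row.stimulus)
            cy.append(row.successes)
            cn.append(row.trials)
            cw.append(1.0)
            ci1.append(self._loc1[key])
            ci2.append(self._loc2[key])
        if self.historical is not None:
            w = self.power.a0 if self.power is not None else 1.0
            for row in self.historical.frame.itertuples(index=False):
                key = (row.subject, row.condition)
                cx.append(row.stimulus)
                cy.append(row.successes)
                cn.append(row.trials)
                cw.append(w)
                ci1.append(self._hloc1[key])
                ci2.append(self._hloc2[key])
        self.cell_x = np.asarray(cx, dtype=float)
        self.cell_y = np.asarray(cy, dtype=float)
        self.cell_n = np.asarray(cn, dtype=float)
        self.cell_w = np.asarray(cw, dtype=float)
        self.cell_i1 = np.asarray(ci1, dtype=np.intp)
        self.cell_i2 = np.asarray(ci2, dtype=np.intp)
        self.cell_lgamma = (
            gammaln(self.cell_n + 1.0)
            - gammaln(self.cell_y + 1.0)
            - gammaln(self.cell_n - self.cell_y + 1.0)
        )
        self.n_current_cells = len(data.frame)

    def _finalize(self) -> None:
        n = len(self.names)
        self.n_params = n
        self.ZERO = n  # extended-vector slot holding 0.0
        self.ONE = n + 1  # extended-vector slot holding 1.0

        def ref(idx_list, const_slot):
            return np.asarray(
                [i if i >= 0 else const_slot for i in idx_list], dtype=np.intp
            )

        self.nn_child = np.asarray(self._nn_child, dtype=np.intp)
        self.nn_midx = ref(self._nn_midx, self.ZERO)
        self.nn_mscale = np.asarray(self._nn_mscale)
        self.nn_mconst = np.asarray(self._nn_mconst)
        self.nn_pidx = ref(self._nn_pidx, self.ONE)
        self.nn_pconst = np.asarray(self._nn_pconst)
        self.gn_idx = np.asarray(self._gn_idx, dtype=np.intp)
        self.gn_shape = np.asarray(self._gn_shape)
        self.gn_rate = np.asarray(self._gn_rate)
        self.gn_lognorm = self.gn_shape * np.log(self.gn_rate) - gammaln(self.gn_shape)

        self.positive_mask = np.zeros(n, dtype=bool)
        self.positive_mask[self.gn_idx] = True

        self.subject_loc1 = np.asarray(self._subject_loc1, dtype=np.intp)
        self.subject_loc2 = np.asarray(self._subject_loc2, dtype=np.intp)
        self.pop_locs = np.asarray(self._pop_locs, dtype=np.intp)

        # map each parameter to its (unique) normal prior node, if any
        node_of = {int(c): k for k, c in enumerate(self.nn_child)}
        self.prior_node_of = node_of

        # cells touching each subject-location parameter (positions in the
        # loc1/loc2 lists), for blockwise Metropolis updates
        pos1 = {int(p): k for k, p in enumerate(self.subject_loc1)}
        pos2 = {int(p): k for k, p in enumerate(self.subject_loc2)}
        self.cell_block1 = np.asarray([pos1[int(i)] for i in self.cell_i1], dtype=np.intp)
        self.cell_block2 = np.asarray([pos2[int(i)] for i in self.cell_i2], dtype=np.intp)

        # children of each parameter in the normal-node graph (for Gibbs)
        children: dict[int, list[int]] = {}
        for k, m in enumerate(self._nn_midx):
            if m >= 0:
                children.setdefault(int(m), []).append(k)
        self.mean_children = {j: np.asarray(v, dtype=np.intp) for j, v in children.items()}
        prec_children: dict[int, list[int]] = {}
        for k, p in enumerate(self._nn_pidx):
            if p >= 0:
                prec_children.setdefault(int(p), []).append(k)
        self.prec_children = {j: np.asarray(v, dtype=np.intp) for j, v in prec_children.items()}

        self.is_pse = self.spec.parameterization == "pse_slope"

    # -- vector interface -------------------------------------------------
    def index_of(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown parameter {name!r} for this model/data") from None

    def pack(self, params: Mapping[str, float]) -> np.ndarray:
        """Mapping -> flat vector; errors name missing/orphan parameters."""
        missing = [nm for nm in self.names if nm not in params]
        if missing:
            raise KeyError(f"missing parameter {missing[0]!r} (and {len(missing) - 1} more)")
        extra = [nm for nm in params if nm not in self._index]
        if extra:
            raise KeyError(f"parameter {extra[0]!r} does not belong to this model/data")
        return np.asarray([float(params[nm]) for nm in self.names])

    def unpack(self, v: np.ndarray) -> ParamSet:
        return ParamSet(zip(self.names, map(float, v)))

    # -- densities ---------------------------------------------------------
    def cell_logpmf(self, v: np.ndarray, cells: slice | np.ndarray = slice(None)) -> np.ndarray:
        """Unweighted binomial log-pmf per cell (includes the coefficient)."""
        i1, i2 = self.cell_i1[cells], self.cell_i2[cells]
        x = self.cell_x[cells]
        if self.is_pse:
            eta = v[i2] * (x - v[i1])
        else:
            eta = v[i1] + v[i2] * x
        p = np.clip(ndtr(eta), PROB_CLAMP, 1.0 - PROB_CLAMP)
        y, n = self.cell_y[cells], self.cell_n[cells]
        return self.cell_lgamma[cells] + y * np.log(p) + (n - y) * np.log1p(-p)

    def loglik(self, v: np.ndarray) -> float:
        """a0-weighted total log-likelihood (current + weighted historical)."""
        return float(np.dot(self.cell_w, self.cell_logpmf(v)))

    def loglik_current(self, v: np.ndarray) -> float:
        sl = slice(0, self.n_current_cells)
        return float(np.sum(self.cell_logpmf(v, sl)))

    def loglik_historical(self, v: np.ndarray) -> float:
        if self.historical is None:
            return 0.0
        sl = slice(self.n_current_cells, None)
        return float(np.sum(self.cell_logpmf(v, sl)))

    def logprior(self, v: np.ndarray) -> float:
        if np.any(v[self.positive_mask] <= 0.0):
            return -math.inf
        ve = np.concatenate([v, [0.0, 1.0]])
        m = ve[self.nn_midx] * self.nn_mscale + self.nn_mconst
        prec = ve[self.nn_pidx] * self.nn_pconst
        c = v[self.nn_child]
        lp = 0.5 * np.sum(np.log(prec) - _LOG_2PI - prec * (c - m) ** 2)
        t = v[self.gn_idx]
        lp += np.sum(self.gn_lognorm + (self.gn_shape - 1.0) * np.log(t) - self.gn_rate * t)
        return float(lp)

    def logpost(self, v: np.ndarray) -> float:
        lp = self.logprior(v)
        if not np.isfinite(lp):
            return -math.inf
        return lp + self.loglik(v)

    # -- labelled lookups used by evaluate/summarize ----------------------
    def pop_param_names(self) -> dict[str, dict]:
        """Population location names keyed by role for downstream summaries."""
        out = {"loc1": {}, "loc2": {}}
        for key, idx in self._pop1.items():
            out["loc1"][key] = self.names[idx]
        for key, idx in self._pop2.items():
            out["loc2"][key] = self.names[idx]
        return out

    def subject_param_names(self) -> dict[str, dict]:
        out = {"loc1": {}, "loc2": {}}
        for key, idx in self._loc1.items():
            out["loc1"][key] = self.names[idx]
        for key, idx in self._loc2.items():
            out["loc2"][key] = self.names[idx]
        return out

    def data_digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.data.frame.to_csv(index=False).encode())
        if self.historical is not None:
            h.update(self.historical.frame.to_csv(index=False).encode())
        return h.hexdigest()[:16]


def compile_model(
    spec: ModelSpec,
    data: TrialTable,
    historical: TrialTable | None = None,
    power: PowerPriorSpec | None = None,
) -> CompiledModel:
    """Bind a ModelSpec to data, returning the flat-vector representation."""
    return CompiledModel(spec, data, historical=historical, power=power)


# ---------------------------------------------------------------------------
# public log-density operations
# ---------------------------------------------------------------------------


def log_likelihood(
    spec: ModelSpec,
    params: Mapping[str, float],
    data: TrialTable,
    historical: TrialTable | None = None,
) -> float:
    """Binomial log-likelihood of ``data`` at ``params`` under ``spec``.

    Sums, over observation cells, the binomial log-pmf (including the
    binomial coefficient) with success probability ``Phi(linear predictor)``
    clamped away from {0, 1}.  ``params`` must structurally match the spec
    and the data's subjects/conditions/groups; a missing parameter raises a
    ``KeyError`` naming it.  For a joint two-study spec pass the historical
    table as well; both studies then contribute at weight 1.
    """
    cm = CompiledModel(spec, data, historical=historical)
    v = cm.pack(params)
    return cm.loglik(v)


def log_prior(
    spec: ModelSpec,
    params: Mapping[str, float],
    data: TrialTable,
    historical: TrialTable | None = None,
    power: PowerPriorSpec | None = None,
) -> float:
    """Sum of log-densities of every stochastic node given its parents.

    Normal densities (precision parameterization) for subject- and
    population-level locations plus gamma densities for all precisions.
    Returns ``-inf`` (rather than raising) for non-positive precisions, so
    samplers simply reject such states.  ``data`` (and, for two-study specs,
    ``historical``/``power``) is needed to determine the prior's node
    structure — how many subject-level parameters exist and which group each
    subject belongs to.
    """
    cm = CompiledModel(spec, data, historical=historical, power=power)
    missing = [nm for nm in cm.names if nm not in params]
    if missing:
        raise KeyError(f"missing parameter {missing[0]!r} (and {len(missing) - 1} more)")
    v = np.asarray([float(params[nm]) for nm in cm.names])
    return cm.logprior(v)


def log_posterior_power(
    spec: ModelSpec,
    params: Mapping[str, float],
    current: TrialTable,
    pp: PowerPriorSpec,
) -> float:
    """Log posterior kernel under the power prior.

    ``log L(theta | D) + a0 * log L(theta | D0) + log pi0(theta)``: the
    current-study likelihood, the historical likelihood down-weighted by
    ``a0``, and the initial prior over the full shared parameter structure.
    At ``a0 = 0`` this is the current-only log posterior (plus the
    historical block's data-free prior terms); at ``a0 = 1`` the pooled one.
    """
    cm = CompiledModel(spec, current, power=pp)
    v = cm.pack(params)
    lp = cm.logprior(v)
    if not np.isfinite(lp):
        return -math.inf
    return lp + cm.loglik_current(v) + pp.a0 * cm.loglik_historical(v)
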