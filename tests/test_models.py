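"""Model variants: likelihood/prior oracles, power prior, joint hierarchy."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hierpsy import (
    ModelSpec,
    PowerPriorSpec,
    TrialTable,
    build_joint_model,
    build_model,
    compile_model,
    default_conversion,
    log_likelihood,
    log_posterior_power,
    log_prior,
)


def random_params(cm, rng, scale=0.8):
    v = rng.normal(0.5, scale, cm.n_params)
    v[cm.positive_mask] = np.abs(v[cm.positive_mask]) + 0.1
    return cm.unpack(v), v


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(123)


@pytest.fixture(scope="module")
def pair(small_table):
    """(current, historical) tables with identical design."""
    hist = TrialTable(small_table.frame.copy(), study="hist")
    return small_table, hist


class TestLogLikelihood:
    def test_single_bernoulli_cell_at_chance(self):
        df = pd.DataFrame(
            {"subject": ["S1", "S1"], "stimulus": [0.0, 1.0], "condition": ["a", "a"],
             "successes": [1, 1], "trials": [1, 1]}
        )
        spec = build_model("intercept_slope")
        cm = compile_model(spec, TrialTable(df))
        params = cm.unpack(np.ones(cm.n_params))
        # alpha = 0, beta = 0 -> both cells at mu = 0.5
        params.update({k: 0.0 for k in params if k.startswith(("alpha[", "beta["))})
        assert log_likelihood(spec, params, TrialTable(df)) == pytest.approx(2 * math.log(0.5))

    def test_binomial_cell_closed_form(self):
        df = pd.DataFrame(
            {"subject": ["S1", "S1"], "stimulus": [0.0, 2.0], "condition": ["a", "a"],
             "successes": [3, 10], "trials": [10, 10]}
        )
        spec = build_model("intercept_slope")
        table = TrialTable(df)
        cm = compile_model(spec, table)
        params = cm.unpack(np.ones(cm.n_params))
        params["alpha[subject=S1,cond=a]"] = 0.0
        params["beta[subject=S1,cond=a]"] = 0.0
        expected = (math.log(math.comb(10, 3)) + 10 * math.log(0.5)) + 10 * math.log(0.5)
        assert log_likelihood(spec, params, table) == pytest.approx(expected)

    def test_matches_bruteforce_binomial_sum(self, tiny_table, rng):
        """Independent oracle: scipy binom.logpmf looped over cells."""
        spec = build_model("pse_slope")
        cm = compile_model(spec, tiny_table)
        params, _ = random_params(cm, rng)
        expected = 0.0
        for row in tiny_table.frame.itertuples():
            pse = params[f"pse[subject={row.subject},cond={row.condition}]"]
            beta = params[f"beta[subject={row.subject},cond={row.condition}]"]
            p = stats.norm.cdf(beta * (row.stimulus - pse))
            expected += stats.binom.logpmf(row.successes, row.trials, p)
        assert log_likelihood(spec, params, tiny_table) == pytest.approx(expected, rel=1e-10)

    def test_missing_parameter_named(self, tiny_table):
        spec = build_model("pse_slope")
        cm = compile_model(spec, tiny_table)
        params, _ = random_params(cm, np.random.default_rng(0))
        del params["beta[subject=S2,cond=vib1]"]
        with pytest.raises(KeyError, match=r"beta\[subject=S2,cond=vib1\]"):
            log_likelihood(spec, params, tiny_table)

    def test_parameterization_equivalence(self, tiny_table, rng):
        """intercept-slope and pse-slope likelihoods agree when alpha = -pse*beta."""
        spec_is = build_model("intercept_slope")
        spec_ps = build_model("pse_slope")
        cm = compile_model(spec_is, tiny_table)
        params, _ = random_params(cm, rng)
        mapped = {}
        for k, val in params.items():
            if k.startswith("alpha["):
                beta = params["beta[" + k[6:]]
                mapped["pse[" + k[6:]] = -val / beta
            elif k.startswith("a["):
                mapped["PSE[" + k[2:]] = val
            elif k == "sigma_a":
                mapped["sigma_pse"] = val
            elif k.startswith("tau_alpha"):
                mapped["tau_pse" + k[9:]] = val
            else:
                mapped[k] = val
        assert log_likelihood(spec_is, params, tiny_table) == pytest.approx(
            log_likelihood(spec_ps, mapped, tiny_table), rel=1e-12
        )

    def test_relabeling_invariance(self, tiny_table, rng):
        spec = build_model("pse_slope")
        cm = compile_model(spec, tiny_table)
        params, _ = random_params(cm, rng)
        sub = {"S1": "ZZ", "S2": "AA"}
        cond = {"vib0": "x1", "vib1": "x0"}
        df = tiny_table.frame.copy()
        df["subject"] = df["subject"].map(sub)
        df["condition"] = df["condition"].map(cond)
        relabeled = TrialTable(df)
        renamed = {}
        for k, val in params.items():
            nk = k
            for old, new in {**sub, **cond}.items():
                nk = nk.replace(f"={old}", f"={new}").replace(f"cond={old}", f"cond={new}")
            renamed[nk] = val
        total = log_likelihood(spec, params, tiny_table) + log_prior(spec, params, tiny_table)
        total_rel = log_likelihood(spec, renamed, relabeled) + log_prior(spec, renamed, relabeled)
        assert total == pytest.approx(total_rel, rel=1e-12)


class TestLogPrior:
    def test_matches_per_node_density_oracle(self, tiny_table, rng):
        """Independent enumeration of every stochastic node's log density."""
        spec = build_model("pse_slope")
        cm = compile_model(spec, tiny_table)
        params, _ = random_params(cm, rng)

        def norm_lp(x, mean, prec):
            return stats.norm.logpdf(x, mean, 1.0 / math.sqrt(prec))

        def gamma_lp(x, shape, rate):
            return stats.gamma.logpdf(x, shape, scale=1.0 / rate)

        expected = gamma_lp(params["sigma_pse"], 1, 0.01) + gamma_lp(params["sigma_b"], 1, 0.01)
        for h in ("vib0", "vib1"):
            expected += gamma_lp(params[f"tau_pse[cond={h}]"], 1, 0.001)
            expected += gamma_lp(params[f"tau_beta[cond={h}]"], 1, 0.001)
            expected += norm_lp(params[f"PSE[cond={h}]"], 0.0, params["sigma_pse"])
            expected += norm_lp(params[f"b[cond={h}]"], 0.0, params["sigma_b"])
            for s in ("S1", "S2"):
                expected += norm_lp(
                    params[f"pse[subject={s},cond={h}]"],
                    params[f"PSE[cond={h}]"],
                    params[f"tau_pse[cond={h}]"],
                )
                expected += norm_lp(
                    params[f"beta[subject={s},cond={h}]"],
                    params[f"b[cond={h}]"],
                    params[f"tau_beta[cond={h}]"],
                )
        assert log_prior(spec, params, tiny_table) == pytest.approx(expected, rel=1e-10)

    def test_normal_kernel_shift(self, tiny_table, rng):
        """Doubling a subject's deviation changes the prior by -tau/2*(d2^2-d1^2)."""
        spec = build_model("pse_slope")
        cm = compile_model(spec, tiny_table)
        params, _ = random_params(cm, rng)
        tau = params["tau_pse[cond=vib0]"]
        mu = params["PSE[cond=vib0]"]
        d1 = 0.3
        base = dict(params)
        base["pse[subject=S1,cond=vib0]"] = mu + d1
        shifted = dict(base)
        shifted["pse[subject=S1,cond=vib0]"] = mu + 2 * d1
        delta = log_prior(spec, shifted, tiny_table) - log_prior(spec, base, tiny_table)
        assert delta == pytest.approx(-tau / 2 * ((2 * d1) ** 2 - d1**2), rel=1e-9)

    def test_negative_precision_gives_neg_inf(self, tiny_table, rng):
        spec = build_model("pse_slope")
        cm = compile_model(spec, tiny_table)
        params, _ = random_params(cm, rng)
        params["tau_pse[cond=vib0]"] = -1.0
        assert log_prior(spec, params, tiny_table) == -math.inf


class TestBuildModel:
    def test_pse_slope_defaults(self):
        spec = build_model("pse_slope")
        assert spec.parameterization == "pse_slope"
        assert spec.hyperpriors["tau1"] == (1.0, 0.001)
        assert spec.hyperpriors["sigma1"] == (1.0, 0.01)

    def test_per_subject_precision_names(self, tiny_table):
        cm = compile_model(build_model("per_subject_precision"), tiny_table)
        assert "tau_pse[subject=S1]" in cm.names
        assert "tau_beta[subject=S2]" in cm.names
        assert not any(n.startswith("tau_pse[cond=") for n in cm.names)

    def test_grouped_names_three_groups(self):
        rows = []
        for i, g in enumerate(["controls", "mild", "moderate"]):
            for x in (1.0, 2.0):
                rows.append(
                    {"subject": f"S{i}", "stimulus": x, "condition": "vib0",
                     "group": g, "successes": 1, "trials": 5}
                )
        table = TrialTable(pd.DataFrame(rows))
        cm = compile_model(build_model("grouped"), table)
        for g in ("controls", "mild", "moderate"):
            assert f"PSE[group={g},cond=vib0]" in cm.names
            assert f"b[group={g},cond=vib0]" in cm.names
            assert f"tau_pse[group={g},cond=vib0]" in cm.names

    def test_unknown_variant(self):
        with pytest.raises(ValueError, match="unknown variant"):
            build_model("weibull")

    def test_grouped_requires_group_labels(self, tiny_table):
        with pytest.raises(ValueError, match="no group"):
            compile_model(build_model("grouped"), tiny_table)

    def test_hyperprior_override(self):
        spec = build_model("pse_slope", hyperpriors={"tau_pse": (2.0, 0.5)})
        assert spec.hyperpriors["tau1"] == (2.0, 0.5)
        with pytest.raises(ValueError, match="positive"):
            build_model("pse_slope", hyperpriors={"tau_pse": (0.0, 1.0)})


class TestPowerPrior:
    def test_a0_domain(self, pair):
        cur, hist = pair
        with pytest.raises(ValueError, match=r"a0 must lie in \[0, 1\]"):
            PowerPriorSpec(a0=1.5, historical=hist)

    def test_limit_identities_and_affinity(self, pair, rng):
        """a0=0 drops the historical likelihood; a0=1 pools; affine in between."""
        cur, hist = pair
        spec = build_model("pse_slope")
        pp1 = PowerPriorSpec(a0=1.0, historical=hist)
        cm = compile_model(spec, cur, power=pp1)
        for _ in range(10):
            params, v = random_params(cm, rng)
            llc = cm.loglik_current(v)
            llh = cm.loglik_historical(v)
            lp = cm.logprior(v)
            l0 = log_posterior_power(spec, params, cur, PowerPriorSpec(0.0, hist))
            l1 = log_posterior_power(spec, params, cur, pp1)
            lmid = log_posterior_power(spec, params, cur, PowerPriorSpec(0.5, hist))
            assert l0 == pytest.approx(llc + lp, rel=1e-12)
            assert l1 == pytest.approx(llc + llh + lp, rel=1e-12)
            # affine in a0 with slope = historical log-likelihood
            assert lmid == pytest.approx(l0 + 0.5 * (l1 - l0), rel=1e-12)

    def test_historical_block_present_and_shared_population(self, pair):
        cur, hist = pair
        spec = build_model("pse_slope")
        cm = compile_model(spec, cur, power=PowerPriorSpec(0.5, hist))
        assert any(n.startswith("pse0[") for n in cm.names)
        assert any(n.startswith("tau_pse0[") for n in cm.names)
        # shared population: no separate historical PSE/b locations
        assert not any(n.startswith("PSE0[") for n in cm.names)

    def test_default_conversion_is_stimulus_mean_ratio(self):
        from hierpsy import preset_design, preset_truth, simulate_study

        cur, _ = simulate_study(preset_design("touch_diabetes"), preset_truth("touch_diabetes"), 0)
        hist, _ = simulate_study(preset_design("touch_vibrations"), preset_truth("touch_vibrations"), 0)
        expected = np.mean(np.linspace(0.6, 6.4, 5)) / np.mean(np.linspace(1.0, 16.0, 7))
        assert default_conversion(cur, hist) == pytest.approx(expected, rel=1e-9)


class TestJointModel:
    def test_requires_matching_parameterization(self):
        with pytest.raises(ValueError, match="parameterization"):
            build_joint_model(build_model("pse_slope"), build_model("intercept_slope"), 1.0)

    def test_current_population_centred_on_historical(self, pair, rng):
        """Shifting b off c*b0 costs exactly the sigma_b normal kernel.

        Uses an empty current table so b has no subject-level children and
        the shift touches only its own prior term.
        """
        cur, hist = pair
        empty = TrialTable(cur.frame.iloc[0:0])
        conv = 1.7
        spec = build_joint_model(build_model("intercept_slope"), build_model("intercept_slope"), conv)
        cm = compile_model(spec, empty, historical=hist)
        params, _ = random_params(cm, rng)
        centred = dict(params)
        centred["b[cond=vib0]"] = conv * centred["b0[cond=vib0]"]
        shifted = dict(centred)
        d = 0.37
        shifted["b[cond=vib0]"] += d
        delta = log_prior(spec, shifted, empty, historical=hist) - log_prior(
            spec, centred, empty, historical=hist
        )
        assert delta == pytest.approx(-0.5 * params["sigma_b[cond=vib0]"] * d**2, rel=1e-9)

    def test_joint_hyperprior_rates(self):
        spec = build_joint_model(build_model("intercept_slope"), build_model("intercept_slope"), 1.0)
        assert spec.hyperpriors["tau1"] == (1.0, 0.01)
        assert spec.hyperpriors["tau1_hist"] == (1.0, 0.01)

    def test_empty_current_reduces_to_historical(self, pair, rng):
        cur, hist = pair
        empty = TrialTable(cur.frame.iloc[0:0])
        spec = build_joint_model(build_model("intercept_slope"), build_model("intercept_slope"), 1.0)
        cm = compile_model(spec, empty, historical=hist)
        params, v = random_params(cm, rng)
        assert cm.loglik_current(v) == 0.0
        assert cm.loglik(v) == pytest.approx(cm.loglik_historical(v))

    def test_likelihood_sums_both_studies(self, pair, rng):
        cur, hist = pair
        spec = build_joint_model(build_model("pse_slope"), build_model("pse_slope"), 1.0)
        cm = compile_model(spec, cur, historical=hist)
        params, v = random_params(cm, rng)
        assert log_likelihood(spec, params, cur, historical=hist) == pytest.approx(
            cm.loglik_current(v) + cm.loglik_historical(v), rel=1e-12
        )


class TestProbabilityClamping:
    def test_extreme_linear_predictor_stays_finite(self, tiny_table):
        spec = build_model("pse_slope")
        cm = compile_model(spec, tiny_table)
        params = cm.unpack(np.ones(cm.n_params))
        params["beta[subject=S1,cond=vib0]"] = 1e4  # saturates several cells
        ll = log_likelihood(spec, params, tiny_table)
        assert np.isfinite(ll)
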