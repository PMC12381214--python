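"""Kinetic Monte Carlo simulator: analytic oracles and state-machine rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from catchbond import (
    BEParams,
    ConstantSpeedConfig,
    ForceClampConfig,
    StateModel,
    TransitionSearchConfig,
    analytic_pathway_lifetime,
    example_catch_bond_model,
    fit_transition_parameters,
    simulate_constant_speed,
    simulate_force_clamp,
    single_state_model,
)
from catchbond.montecarlo import force_schedule

BELL = BEParams(k0=0.1, delta_x=0.5)


def bell_ramp_cdf(params, cfg):
    """Analytic rupture-force CDF for a single barrier under the pulling
    schedule: S(F(t)) = exp(-integral k(F) dt), integrated by trapezoid.
    Independent of the event-sampling code path."""
    sched = force_schedule(cfg)
    k = params.k0 * np.exp(cfg.thermal.beta * sched["F"] * params.delta_x)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (k[1:] + k[:-1]) * np.diff(sched["t"]))])
    forces = sched["F"]
    cdf_vals = 1.0 - np.exp(-cum)

    def cdf(f):
        return np.interp(f, forces, cdf_vals)

    return cdf


def test_constant_speed_matches_analytic_bell_ramp_distribution():
    cfg = ConstantSpeedConfig(pulling_speed=1600.0, replicates=500, seed=11)
    sim = simulate_constant_speed(single_state_model(BELL), cfg)
    assert not sim["censored"].any()
    stat = sps.kstest(sim["rupture_force_pN"], bell_ramp_cdf(BELL, cfg)).statistic
    critical = 1.6276 / np.sqrt(len(sim))  # alpha = 0.01
    assert stat < critical


def test_median_rupture_force_increases_with_speed_and_tracks_bell():
    """Loading-rate dependence: medians rise across an 8x speed range and sit
    within 10% of the Bell–Evans dynamic force spectrum at the median
    loading rate."""
    from catchbond import be_force

    params = BEParams(k0=0.01, delta_x=0.5)
    medians = []
    for j, v in enumerate([800.0, 1600.0, 3200.0, 6400.0]):
        cfg = ConstantSpeedConfig(pulling_speed=v, replicates=500, seed=100 + j)
        sim = simulate_constant_speed(single_state_model(params), cfg)
        med_F = sim["rupture_force_pN"].median()
        med_r = sim["loading_rate_pN_s"].median()
        medians.append(med_F)
        assert med_F == pytest.approx(be_force(params, med_r), rel=0.10)
    assert np.all(np.diff(medians) > 0)


def test_all_rates_zero_yields_only_censored_replicates():
    dead = StateModel(
        p0=BEParams(0.0, 0.0), p1=BEParams(0.0, 0.0), p2=BEParams(0.0, 0.0),
        n_to_i1=BEParams(0.0, 0.0), i1_to_i2=BEParams(0.0, 0.0),
    )
    cfg = ConstantSpeedConfig(pulling_speed=1600.0, replicates=20, seed=0, grid_step=0.5)
    sim = simulate_constant_speed(dead, cfg)
    assert sim["censored"].all()
    assert sim["rupture_force_pN"].isna().all()


def test_pathway_legality_and_strong_i2_ordering():
    """P1 only from I1, P2 only from I2; no transitions => all P0; a
    mechanically strong I2 gives median P2 > P1 > P0 rupture forces."""
    no_trans = single_state_model(BELL)
    cfg = ConstantSpeedConfig(pulling_speed=1600.0, replicates=200, seed=3)
    sim = simulate_constant_speed(no_trans, cfg)
    assert (sim.loc[~sim["censored"], "pathway"] == "P0").all()

    tiered = StateModel(
        p0=BEParams(1.0, 0.6),
        p1=BEParams(0.1, 0.3),
        p2=BEParams(0.01, 0.1),
        n_to_i1=BEParams(0.5, 0.8),
        i1_to_i2=BEParams(0.5, 0.5),
    )
    frames = [
        simulate_constant_speed(
            tiered, ConstantSpeedConfig(pulling_speed=1600.0, replicates=300, seed=s)
        )
        for s in range(10)
    ]
    sim = pd.concat(frames)
    sim = sim[~sim["censored"]]
    med = sim.groupby("pathway")["rupture_force_pN"].median()
    assert med["P2"] > med["P1"] > med["P0"]
    for _, row in sim.iterrows():
        final = row["state_path"].split("->")[-1]
        assert {"P0": "N", "P1": "I1", "P2": "I2"}[row["pathway"]] == final


def test_clamp_lifetime_mean_and_exponentiality():
    """Single-state clamp: lifetimes ~ Exp(k(F)); mean within 3 SE of 1/k."""
    cfg = ForceClampConfig(setpoints=(20.0,), replicates=1000, seed=7)
    rec, freq = simulate_force_clamp(single_state_model(BELL), cfg)
    assert not rec["censored"].any()
    lifetimes = rec["lifetime_s"].to_numpy()
    tau = analytic_pathway_lifetime(BELL, 20.0)
    assert tau == pytest.approx(0.88, abs=0.01)
    se = tau / np.sqrt(len(lifetimes))
    assert abs(lifetimes.mean() - tau) < 3 * se
    stat = sps.kstest(lifetimes, sps.expon(scale=tau).cdf).statistic
    assert stat < 1.6276 / np.sqrt(len(lifetimes))
    assert freq.loc[freq["pathway"] == "P0", "frequency"].iloc[0] == 1.0


def test_analytic_lifetime_properties():
    assert analytic_pathway_lifetime(BELL, 0.0) == pytest.approx(1.0 / BELL.k0)
    forces = np.linspace(0, 100, 20)
    taus = [analytic_pathway_lifetime(BELL, f) for f in forces]
    assert np.all(np.diff(taus) < 0)


def test_catch_bond_model_lifetime_non_monotonic():
    """Reversible three-state model with delta_x decreasing and stability
    increasing P0 -> P2: mean clamp lifetime has an interior maximum."""
    model = example_catch_bond_model()
    setpoints = (5.0, 10.0, 20.0, 30.0, 40.0, 50.0, 80.0, 120.0)
    cfg = ForceClampConfig(setpoints=setpoints, replicates=200, seed=21)
    with pytest.warns(UserWarning):
        rec, _ = simulate_force_clamp(model, cfg)
    mean_lt = rec.groupby("setpoint_pN")["lifetime_s"].mean()
    peak = mean_lt.idxmax()
    assert setpoints[0] < peak < setpoints[-1]
    assert mean_lt[peak] > 2 * mean_lt[setpoints[0]]
    assert mean_lt[peak] > 2 * mean_lt[setpoints[-1]]


def test_bitwise_reproducibility_under_fixed_seed():
    cfg = ConstantSpeedConfig(pulling_speed=3200.0, replicates=50, seed=42, grid_step=0.2)
    a = simulate_constant_speed(example_catch_bond_model(), cfg)
    b = simulate_constant_speed(example_catch_bond_model(), cfg)
    pd.testing.assert_frame_equal(a, b)
    ccfg = ForceClampConfig(setpoints=(30.0,), replicates=50, seed=42)
    ra, _ = simulate_force_clamp(example_catch_bond_model(), ccfg)
    rb, _ = simulate_force_clamp(example_catch_bond_model(), ccfg)
    pd.testing.assert_frame_equal(ra, rb)


def test_reverse_edges_must_come_in_pairs():
    with pytest.raises(ValueError):
        StateModel(
            p0=BELL, p1=BELL, p2=BELL,
            n_to_i1=BELL, i1_to_i2=BELL, i1_to_n=BELL,
        )


def test_transition_search_point_bounds_and_trace():
    """Collapsed bounds return exactly that point; the best-SSR trace is
    monotone non-increasing under a reduced budget."""
    truth = example_catch_bond_model()
    cfg = ConstantSpeedConfig(pulling_speed=1600.0, replicates=150, seed=5, grid_step=0.25)
    target = simulate_constant_speed(truth, cfg)
    targets = {1600.0: target.loc[~target["censored"], "rupture_force_pN"].to_numpy()}

    search = TransitionSearchConfig(
        k0_bounds=(0.5, 0.5), dx_bounds=(0.3, 0.3),
        n_starts=3, replicates=50, seed=1, refine_iterations=0,
    )
    res = fit_transition_parameters(truth, targets, cfg, search)
    assert res.model.n_to_i1.k0 == pytest.approx(0.5)
    assert res.model.i1_to_i2.delta_x == pytest.approx(0.3)

    search2 = TransitionSearchConfig(n_starts=8, replicates=50, seed=2, refine_iterations=1)
    res2 = fit_transition_parameters(truth, targets, cfg, search2)
    assert np.all(np.diff(res2.best_ssr_trace) <= 1e-15)
    assert np.isfinite(res2.ssr)
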