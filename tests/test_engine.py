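"""Population engine: environment balance, washout, heat shocks,
super-individual rebalancing and whole-run determinism."""

import numpy as np
import pytest

from yeastabm import (AgentManagerConfig, ChemostatState, ConfigurationError,
                      HeatShockSchedule, PhysiologyParams, StrainParams,
                      StrainTable, apply_heat_shock, apply_washout,
                      manage_agents, run_simulation, step_environment)
from yeastabm.config import (EngineSettings, EnvSettings, InitSettings,
                             ScenarioConfig)
from yeastabm.exceptions import StepSizeError
from yeastabm.population import Population


def toy_population(nu, strain_idx=None, fT=None, n=None):
    nu = np.asarray(nu, dtype=np.int64)
    n = nu.size
    m = np.full(n, 20e-12)
    fT = np.zeros(n) if fT is None else np.asarray(fT, dtype=float)
    return Population(
        m_X=m * (1 - fT), m_D=np.zeros(n), m_T=m * fT,
        m_b=np.full(n, 15e-12), m_b0_i=np.full(n, 15e-12),
        m_at_bud=np.zeros(n), mu_mg_i=np.full(n, 0.45),
        n_d_i=np.full(n, 2.0), fr_Tsl1_i=np.ones(n), fr_Tps3_i=np.ones(n),
        n_B=np.zeros(n, np.int64),
        strain_idx=np.zeros(n, np.int64) if strain_idx is None
        else np.asarray(strain_idx, np.int64),
        nu=nu, budding=np.zeros(n, bool))


# ------------------------------------------------------------- environment

def test_environment_relaxes_to_inflow_without_cells():
    env = ChemostatState(G=0.2, G_in=1.0, D=0.15, V=1e-5)
    for _ in range(5000):
        step_environment(env, uptake_g_per_h=0.0, dt=0.05)
    assert env.G == pytest.approx(env.G_in, rel=1e-6)


def test_environment_clips_overshoot_with_warning():
    env = ChemostatState(G=0.01, G_in=1.0, D=0.0, V=1e-5, mode="batch")
    clipped = step_environment(env, uptake_g_per_h=1.0, dt=1.0)
    assert clipped == 1 and env.G == 0.0


def test_batch_mode_requires_zero_dilution():
    with pytest.raises(ConfigurationError):
        ChemostatState(D=0.15, mode="batch")


# ----------------------------------------------------------------- washout

def test_washout_noop_at_zero_dilution(rng):
    pop = toy_population([5, 7, 9])
    assert apply_washout(pop, 0.0, 0.05, rng) == 0
    assert pop.total_cells == 21


def test_washout_matches_exponential_survival(rng):
    """Binomial thinning at p = 1-exp(-D dt): over many steps the removed
    fraction of 1e4 cells stays within 3 SE of 1 - exp(-D t)."""
    pop = toy_population([10_000])
    D, dt, steps = 0.15, 0.05, 200
    for _ in range(steps):
        if pop.n_agents:
            apply_washout(pop, D, dt, rng)
    p_survive = np.exp(-D * dt * steps)
    expected = 10_000 * p_survive
    se = np.sqrt(10_000 * p_survive * (1 - p_survive))
    assert abs(pop.total_cells - expected) < 3 * se


def test_washout_removes_emptied_agents(rng):
    pop = toy_population([1, 50])
    # p ~ 1: the nu=1 agent disappears almost surely
    apply_washout(pop, 100.0, 0.009, rng)
    assert pop.n_agents <= 2
    with pytest.raises(StepSizeError):
        apply_washout(pop, 10.0, 0.2, rng)


# -------------------------------------------------------------- heat shock

def test_heat_shock_enumerated_tolerances(phys):
    """Cells at m_T/m = 0, K_h, 3K_h have H_t = 0, 0.5, 0.75: a shock at
    H_a = 0.6 kills exactly the first two."""
    pop = toy_population([4, 5, 6], fT=[0.0, phys.K_h, 3 * phys.K_h])
    killed = apply_heat_shock(pop, 0.6, phys)
    assert killed == 9
    assert pop.n_agents == 1 and pop.total_cells == 6


def test_heat_shock_boundaries(phys):
    pop = toy_population([3, 3], fT=[0.0, 0.2])
    assert apply_heat_shock(pop, 0.0, phys) == 0      # H_t >= 0 always
    assert apply_heat_shock(pop, 1.0, phys) == 6      # H_t < 1 strictly
    assert pop.n_agents == 0


# -------------------------------------------------------------- rebalancing

def test_split_preserves_state_and_total(rng):
    pop = toy_population([5])
    manage_agents(pop, AgentManagerConfig(N_min=2, N_max=10), rng)
    assert pop.n_agents == 2
    assert sorted(pop.nu.tolist()) == [2, 3]
    assert np.allclose(pop.m_X, pop.m_X[0])


def test_rebalance_conserves_real_cells_both_directions(rng):
    pop = toy_population(np.arange(1, 41), strain_idx=np.arange(40) % 2)
    total = pop.total_cells
    manage_agents(pop, AgentManagerConfig(N_min=60, N_max=200), rng)
    assert pop.total_cells == total and pop.n_agents >= 60
    manage_agents(pop, AgentManagerConfig(N_min=5, N_max=12), rng)
    assert pop.total_cells == total and pop.n_agents <= 12
    # both strains keep at least one representative
    assert set(pop.strain_idx.tolist()) == {0, 1}


def test_split_stops_at_singletons(rng):
    pop = toy_population([1, 1, 1])
    manage_agents(pop, AgentManagerConfig(N_min=10, N_max=20), rng)
    assert pop.n_agents == 3


# ---------------------------------------------------------------- schedule

def test_periodic_schedule_times():
    sched = HeatShockSchedule(H_a=0.5, F_h=0.25)          # every 4 h
    assert sched.shocks_in(0.0, 4.0) == [4.0]
    assert sched.shocks_in(4.0, 8.05) == [8.0]
    assert sched.shocks_in(0.0, 12.0) == [4.0, 8.0, 12.0]
    offset = HeatShockSchedule(H_a=0.5, F_h=0.25, phase_offset=1.0)
    assert offset.shocks_in(0.0, 6.0) == [5.0]


def test_zero_frequency_never_fires():
    sched = HeatShockSchedule(H_a=0.9, F_h=0.0)
    assert sched.shocks_in(0.0, 1e5) == []


def test_explicit_times_mode():
    sched = HeatShockSchedule(H_a=0.5, mode="explicit-times",
                              times=(3.0, 7.5))
    assert sched.shocks_in(0.0, 5.0) == [3.0]
    assert sched.shocks_in(5.0, 10.0) == [7.5]


# ------------------------------------------------------------- full engine

def tiny_scenario(seed=0, H_a=0.0, F_h=0.0, duration=24.0):
    return ScenarioConfig(
        phys=PhysiologyParams(),
        strains=[StrainParams(strain_id="wt")],
        env=EnvSettings(mode="chemostat", D=0.15, G_in=1.0, V=5e-7),
        schedule=HeatShockSchedule(H_a=H_a, F_h=F_h),
        engine=EngineSettings(dt=0.05, duration=duration, N_min=50,
                              N_max=200, record_every=1.0, seed=seed),
        init=InitSettings(cells_per_strain=500, agents_per_strain=25),
    )


def test_identical_seed_gives_bit_identical_timeseries(tmp_path):
    files = []
    for run in range(2):
        res = run_simulation(tiny_scenario(seed=99))
        path = tmp_path / f"run{run}.csv"
        res.timeseries.to_csv(path, index=False)
        files.append(path.read_bytes())
    assert files[0] == files[1]


def test_different_seeds_diverge():
    a = run_simulation(tiny_scenario(seed=1))
    b = run_simulation(tiny_scenario(seed=2))
    assert a.population.total_cells != b.population.total_cells


def test_shock_free_run_has_no_kill_events():
    res = run_simulation(tiny_scenario(H_a=0.9, F_h=0.0))
    assert res.log["shock_events"] == []


def test_shocks_fire_and_cut_density():
    res = run_simulation(tiny_scenario(H_a=0.99, F_h=0.1, duration=30.0))
    events = res.log["shock_events"]
    assert [e["time"] for e in events] == [10.0, 20.0, 30.0]
    assert sum(e["killed"] for e in events) > 0


def test_oversized_dt_rejected():
    scen = tiny_scenario()
    scen.engine.dt = 0.2
    with pytest.raises(ConfigurationError):
        run_simulation(scen)


def test_strain_table_rejects_duplicate_ids():
    with pytest.raises(ConfigurationError):
        StrainTable([StrainParams(strain_id="a"),
                     StrainParams(strain_id="a")])
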