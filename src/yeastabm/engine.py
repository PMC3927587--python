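"""Chemostat/batch population engine.

Each step executes, in fixed order: (1) expression + kinetics for all agents,
(2) budding/division events, (3) extracellular glucose update, (4) stochastic
washout, (5) scheduled heat shocks whose time falls inside the step,
(6) super-individual rebalancing, (7) recording.  With a fixed seed the whole
trajectory is bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinetics
from .cells import draw_individual_params
from .exceptions import ConfigurationError, InvariantViolation, StepSizeError
from .params import HeterogeneityToggles, PhysiologyParams
from .population import Population, StrainTable, weighted_mean, weighted_var

BATCH = "batch"
CHEMOSTAT = "chemostat"


@dataclass
class ChemostatState:
    """Extracellular environment of a well-mixed culture."""

    G: float = 1.0          # glucose, g L^-1
    G_in: float = 1.0       # inflow glucose, g L^-1
    D: float = 0.15         # dilution rate, h^-1
    V: float = 1e-5         # culture volume, L
    mode: str = CHEMOSTAT

    def __post_init__(self):
        problems = []
        if self.G < 0 or self.G_in < 0:
            problems.append("glucose concentrations must be >= 0")
        if self.D < 0 or self.V <= 0:
            problems.append("need D >= 0 and V > 0")
        if self.mode not in (BATCH, CHEMOSTAT):
            problems.append(f"mode must be '{BATCH}' or '{CHEMOSTAT}'")
        if self.mode == BATCH and self.D != 0:
            problems.append("batch mode requires D = 0")
        if problems:
            raise ConfigurationError(problems)


@dataclass
class HeatShockSchedule:
    """Heat shocks of severity H_a, periodic at frequency F_h (h^-1) starting
    at ``phase_offset + 1/F_h``, or at explicit times."""

    H_a: float = 0.0
    F_h: float = 0.0        # h^-1
    phase_offset: float = 0.0
    mode: str = "periodic"
    times: tuple = ()       # used when mode == "explicit-times"

    def __post_init__(self):
        if not 0.0 <= self.H_a <= 1.0:
            raise ConfigurationError(f"H_a={self.H_a} outside [0, 1]")
        if self.F_h < 0:
            raise ConfigurationError("F_h must be >= 0")
        if self.mode not in ("periodic", "explicit-times"):
            raise ConfigurationError(f"unknown schedule mode {self.mode!r}")

    def shocks_in(self, t0: float, t1: float) -> list[float]:
        """Shock times falling in the half-open step interval (t0, t1]."""
        if self.mode == "explicit-times":
            return [t for t in self.times if t0 < t <= t1]
        if self.F_h <= 0:
            return []
        period = 1.0 / self.F_h
        k0 = math.floor((t0 - self.phase_offset) / period)
        out = []
        k = max(k0, 0) + 1
        t = self.phase_offset + k * period
        while t <= t1:
            if t > t0:
                out.append(t)
            k += 1
            t = self.phase_offset + k * period
        return out


@dataclass
class AgentManagerConfig:
    """Super-individual count bounds: split below N_min, combine above N_max."""

    N_min: int = 300
    N_max: int = 800

    def __post_init__(self):
        if not 0 < self.N_min < self.N_max:
            raise ConfigurationError(
                f"need 0 < N_min < N_max, got {self.N_min}, {self.N_max}")


# ----------------------------------------------------------------------
# population-level operations
# ----------------------------------------------------------------------

def step_environment(env: ChemostatState, uptake_g_per_h: float,
                     dt: float) -> int:
    """Euler step of dG/dt = D (G_in - G) - U/V, clipping at zero.

    ``uptake_g_per_h`` is the total glucose consumption of the population
    (g h^-1).  Returns 1 if the step overshot below zero (warning counter).
    """
    if dt <= 0:
        raise StepSizeError("dt must be positive")
    dG = env.D * (env.G_in - env.G) - uptake_g_per_h / env.V
    G_new = env.G + dG * dt
    clipped = int(G_new < 0)
    env.G = max(G_new, 0.0)
    return clipped


def apply_washout(pop: Population, D: float, dt: float, rng) -> int:
    """Binomial thinning of every agent's multiplicity with per-cell removal
    probability 1 - exp(-D dt); agents reaching nu = 0 disappear.  Returns
    the number of real cells washed out."""
    if D * dt >= 1.0:
        raise StepSizeError(f"D*dt = {D * dt:.3g} >= 1; reduce dt")
    if D <= 0 or pop.n_agents == 0:
        return 0
    p = -np.expm1(-D * dt)
    removed = rng.binomial(pop.nu, p)
    pop.nu = pop.nu - removed
    if np.any(pop.nu == 0):
        pop.keep(pop.nu > 0)
    return int(removed.sum())


def apply_heat_shock(pop: Population, H_a: float, phys: PhysiologyParams
                     ) -> int:
    """Deterministic kill: every agent with H_t < H_a dies whole (all nu real
    cells share the phenotype).  Returns the number of real cells killed."""
    if not 0.0 <= H_a <= 1.0:
        raise ConfigurationError(f"H_a={H_a} outside [0, 1]")
    if pop.n_agents == 0 or H_a == 0.0:
        return 0
    m = pop.m
    f_T = np.divide(pop.m_T, m, out=np.zeros_like(m), where=m > 0)
    H_t = kinetics.heat_tolerance_kernel(f_T, phys.K_h)
    die = H_t < H_a
    killed = int(pop.nu[die].sum())
    if killed:
        pop.keep(~die)
    return killed


def manage_agents(pop: Population, cfg: AgentManagerConfig, rng) -> dict:
    """Rebalance the super-individual count into [N_min, N_max].

    Splitting clones the highest-multiplicity agents (nu divided as evenly
    as possible); combining removes a nu-proportionally chosen agent and
    credits its multiplicity to a random surviving agent of the same strain.
    The real-cell count sum(nu) is conserved exactly in both directions.
    """
    log = {"splits": 0, "combines": 0}
    if pop.n_agents == 0:
        return log
    # -- split until count >= N_min (or every agent has nu = 1)
    while pop.n_agents < cfg.N_min and np.any(pop.nu >= 2):
        deficit = cfg.N_min - pop.n_agents
        order = np.argsort(pop.nu)[::-1]
        split_idx = order[: min(deficit, int((pop.nu >= 2).sum()))]
        split_idx = split_idx[pop.nu[split_idx] >= 2]
        if split_idx.size == 0:
            break
        nu_half = pop.nu[split_idx] // 2
        clones = {f: getattr(pop, f)[split_idx] for f in
                  ("m_X", "m_D", "m_T", "m_b", "m_b0_i", "m_at_bud",
                   "mu_mg_i", "n_d_i", "fr_Tsl1_i", "fr_Tps3_i",
                   "n_B", "strain_idx", "budding")}
        clones["nu"] = nu_half
        pop.nu[split_idx] -= nu_half
        pop.append(**clones)
        log["splits"] += int(split_idx.size)
    # -- combine until count <= N_max: victims drawn nu-proportionally
    # without replacement, each one's multiplicity credited to a random
    # surviving agent of the same strain
    while pop.n_agents > cfg.N_max:
        excess = pop.n_agents - cfg.N_max
        w = pop.nu.astype(float)
        victims = rng.choice(pop.n_agents, size=excess, replace=False,
                             p=w / w.sum())
        is_victim = np.zeros(pop.n_agents, bool)
        is_victim[victims] = True
        progress = False
        for s_idx in np.unique(pop.strain_idx[victims]):
            strain_mask = pop.strain_idx == s_idx
            heirs = np.nonzero(strain_mask & ~is_victim)[0]
            sv = victims[pop.strain_idx[victims] == s_idx]
            if heirs.size == 0:
                # keep one victim alive as the strain's sole representative
                is_victim[sv[0]] = False
                sv = sv[1:]
                heirs = np.nonzero(strain_mask & ~is_victim)[0]
            if sv.size == 0:
                continue
            chosen = rng.choice(heirs, size=sv.size, replace=True)
            np.add.at(pop.nu, chosen, pop.nu[sv])
            progress = True
        removed = int(is_victim.sum())
        if removed:
            pop.keep(~is_victim)
            log["combines"] += removed
        if not progress and removed == 0:
            break  # every strain down to a sole representative
    return log


def divide_agents(pop: Population, strain_table: StrainTable,
                  phys: PhysiologyParams, rng,
                  toggles: HeterogeneityToggles | None = None) -> int:
    """Budding onset and division for all agents; returns division count.

    Division is only evaluated for agents that were already budding at the
    step start, so a cell can never bud and divide within the same step.
    """
    if pop.n_agents == 0:
        return 0
    t = toggles or HeterogeneityToggles()
    m = pop.m
    was_budding = pop.budding.copy()
    onset = (~was_budding) & (m >= pop.m_b)
    pop.budding[onset] = True
    pop.m_at_bud[onset] = m[onset]

    # replication size is proportional to the size at which budding actually
    # started (== m_b up to one Euler step; larger only for daughters born
    # above their own threshold), so the daughter always gets ~(f_mr-1)*m_b
    div = was_budding & (m >= phys.f_mr * np.maximum(pop.m_b, pop.m_at_bud))
    idx = np.nonzero(div)[0]
    if idx.size == 0:
        return 0

    s_d = 0.5 if t.damage_split_equal else phys.s_d
    (mX_m, mD_m, mT_m), (mX_d, mD_d, mT_d) = kinetics.split_masses(
        pop.m_at_bud[idx], pop.m_X[idx], pop.m_D[idx], pop.m_T[idx], s_d)
    if (np.minimum(mX_m, mX_d) < 0).any() or (np.minimum(mT_m, mT_d) < 0).any():
        bad = int(idx[np.argmin(np.minimum(mX_m, mX_d))])
        raise InvariantViolation(
            "division produced a negative compartment; offending agent: "
            f"index={bad}, m_X={pop.m_X[bad]:.3e}, m_D={pop.m_D[bad]:.3e}, "
            f"m_T={pop.m_T[bad]:.3e}, m_at_bud={pop.m_at_bud[bad]:.3e}, "
            f"n_B={pop.n_B[bad]}")

    # mothers in place
    n_B_new = pop.n_B[idx] + 1
    if t.scarring_off:
        age_for_mb = np.full(idx.size,
                             np.average(pop.n_B, weights=pop.nu.astype(float)))
    else:
        age_for_mb = n_B_new.astype(float)
    exponent = np.maximum(age_for_mb + phys.mb_exponent_offset, 0.0)
    pop.m_X[idx], pop.m_D[idx], pop.m_T[idx] = mX_m, mD_m, mT_m
    pop.n_B[idx] = n_B_new
    pop.budding[idx] = False
    pop.m_at_bud[idx] = 0.0
    pop.m_b[idx] = pop.m_b0_i[idx] * phys.a_mb ** exponent

    # daughters appended, grouped by strain so vectorized draws stay
    # deterministic in array order
    k = idx.size
    mu_d = np.empty(k)
    nd_d = np.empty(k)
    fr1_d = np.empty(k)
    fr3_d = np.empty(k)
    mb0_d = np.empty(k)
    strain_of = pop.strain_idx[idx]
    for s_idx in np.unique(strain_of):
        sel = strain_of == s_idx
        d = draw_individual_params(phys, strain_table.strains[s_idx], rng,
                                   size=int(sel.sum()), toggles=t)
        mu_d[sel], nd_d[sel] = d.mu_mg_i, d.n_d_i
        fr1_d[sel], fr3_d[sel], mb0_d[sel] = (d.fr_Tsl1_i, d.fr_Tps3_i,
                                              d.m_b0_i)
    pop.append(m_X=mX_d, m_D=mD_d, m_T=mT_d, m_b=mb0_d, m_b0_i=mb0_d,
               m_at_bud=np.zeros(k), mu_mg_i=mu_d, n_d_i=nd_d,
               fr_Tsl1_i=fr1_d, fr_Tps3_i=fr3_d,
               n_B=np.zeros(k, dtype=np.int64), strain_idx=strain_of,
               nu=pop.nu[idx], budding=np.zeros(k, bool))
    return int(k)


# ----------------------------------------------------------------------
# orchestration
# ----------------------------------------------------------------------

@dataclass
class SimulationResult:
    timeseries: pd.DataFrame
    population: Population
    env: ChemostatState
    strain_table: StrainTable
    phys: PhysiologyParams
    log: dict
    seed: int
    snapshots: list = None   # [(time, per-agent DataFrame)] when opted in

    def final_snapshot(self, toggles=None) -> pd.DataFrame:
        return self.population.to_frame(self.strain_table, self.phys,
                                        self.env.G, toggles)


def run_simulation(scenario, seed: int | None = None) -> SimulationResult:
    """Run a :class:`~yeastabm.config.ScenarioConfig` to completion.

    ``seed`` overrides the scenario's engine seed.  Identical scenario +
    seed gives bit-identical output.
    """
    phys = scenario.phys
    strain_table = StrainTable(scenario.strains)
    eng = scenario.engine
    toggles = scenario.toggles or HeterogeneityToggles()
    if seed is None:
        seed = eng.seed
    rng = np.random.default_rng(seed)

    dt = eng.dt
    if dt <= 0:
        raise ConfigurationError("engine.dt must be > 0")
    mu_worst = phys.mu_mg_mean * (1.0 + 3.0 * phys.mu_mg_cv)
    if mu_worst * dt >= 0.05:
        raise ConfigurationError(
            f"dt too large: max mu * dt = {mu_worst * dt:.3g} >= 0.05")

    env = ChemostatState(G=scenario.init.G0 if scenario.init.G0 is not None
                         else scenario.env.G_in,
                         G_in=scenario.env.G_in, D=scenario.env.D,
                         V=scenario.env.V, mode=scenario.env.mode)
    pop = Population.inoculate(phys, strain_table,
                               scenario.init.cells_per_strain,
                               scenario.init.agents_per_strain, rng, toggles)
    mgr = AgentManagerConfig(eng.N_min, eng.N_max)
    schedule = scenario.schedule or HeatShockSchedule()

    n_steps = int(round(eng.duration / dt))
    record_stride = max(int(round(eng.record_every / dt)), 1)
    snap_stride = None
    if getattr(eng, "snapshot_every", None):
        snap_stride = max(int(round(eng.snapshot_every / dt)), 1)
    snapshots = []
    rows = []
    log = {"shock_events": [], "washed_out": 0, "divisions": 0,
           "splits": 0, "combines": 0, "G_clipped_steps": 0}

    def record(t):
        w = pop.nu.astype(float)
        row = {"time": t, "G": env.G, "n_agents": pop.n_agents,
               "total_cells": pop.total_cells,
               "density": pop.total_cells / env.V}
        if pop.n_agents:
            r = pop.rates(strain_table, phys, env.G, toggles)
            row.update(
                mean_mu=weighted_mean(r["mu"], w),
                mean_mu_spec=weighted_mean(r["mu_spec"], w),
                mean_trehalose_frac=weighted_mean(r["f_T"], w),
                cv_trehalose_frac=_weighted_cv(r["f_T"], w),
                mean_damage_frac=weighted_mean(r["f_D"], w),
                mean_Ht=weighted_mean(r["H_t"], w),
                cv_Ht=_weighted_cv(r["H_t"], w),
                mean_nB=weighted_mean(pop.n_B, w),
                mean_eTsl1=weighted_mean(r["e_Tsl1"], w))
        else:
            row.update(mean_mu=np.nan, mean_mu_spec=np.nan,
                       mean_trehalose_frac=np.nan, cv_trehalose_frac=np.nan,
                       mean_damage_frac=np.nan, mean_Ht=np.nan, cv_Ht=np.nan,
                       mean_nB=np.nan, mean_eTsl1=np.nan)
        for s_idx, sid in enumerate(strain_table.ids):
            cells = int(pop.nu[pop.strain_idx == s_idx].sum()) \
                if pop.n_agents else 0
            row[f"cells_{sid}"] = cells
            row[f"density_{sid}"] = cells / env.V
        rows.append(row)

    record(0.0)
    for k in range(n_steps):
        t0, t1 = k * dt, (k + 1) * dt
        # (1) kinetics
        if pop.n_agents:
            r = pop.rates(strain_table, phys, env.G, toggles)
            uptake = float(np.sum(pop.nu * r["mu"] * pop.m_X)) / phys.Y_gx
            pop.m_X, pop.m_D, pop.m_T = kinetics.euler_masses(
                pop.m_X, pop.m_D, pop.m_T, r["mu"], r["f_s"], r["k_d"], dt)
            # (2) division
            log["divisions"] += divide_agents(pop, strain_table, phys, rng,
                                              toggles)
        else:
            uptake = 0.0
        # (3) environment
        log["G_clipped_steps"] += step_environment(env, uptake, dt)
        # (4) washout
        if env.mode == CHEMOSTAT and pop.n_agents:
            log["washed_out"] += apply_washout(pop, env.D, dt, rng)
        # (5) heat shocks scheduled inside this step
        for t_shock in schedule.shocks_in(t0, t1):
            killed = apply_heat_shock(pop, schedule.H_a, phys)
            log["shock_events"].append({"time": t_shock, "killed": killed})
        # (6) rebalance
        if pop.n_agents:
            m = manage_agents(pop, mgr, rng)
            log["splits"] += m["splits"]
            log["combines"] += m["combines"]
        # (7) record
        if (k + 1) % record_stride == 0:
            record(t1)
        if snap_stride and (k + 1) % snap_stride == 0 and pop.n_agents:
            snapshots.append((t1, pop.to_frame(strain_table, phys, env.G,
                                               toggles)))

    return SimulationResult(timeseries=pd.DataFrame(rows), population=pop,
                            env=env, strain_table=strain_table, phys=phys,
                            log=log, seed=seed, snapshots=snapshots)


def _weighted_cv(values, w) -> float:
    mean = weighted_mean(values, w)
    if not np.isfinite(mean) or mean == 0:
        return float("nan")
    return float(np.sqrt(weighted_var(values, w)) / mean)
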