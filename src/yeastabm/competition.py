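"""Strain grids and tournament-style competition experiments.

Strains differing only in their Tsl1/Tps3 expression strategy (constant
magnitude ec_Tsl1, age-dependent magnitude ea_Tsl1, stochastic CV
fr_Tsl1_cv; Tps3 tied through a fixed ratio) are co-cultured in one
glucose-limited chemostat under a periodic heat-shock schedule.  The winner
of a match is the strain with the highest final real-cell count; tournament
rounds of up to 10 strains repeat until a single champion remains.  The
implicit trade-off: trehalose synthesis diverts growth from structural
biomass (slower proliferation) but raises heat-shock tolerance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (EngineSettings, EnvSettings, InitSettings,
                     ScenarioConfig)
from .engine import HeatShockSchedule, run_simulation
from .exceptions import ConfigurationError
from .params import PhysiologyParams, StrainParams


@dataclass
class StrainGrid:
    """Full-factorial grid over the three Tsl1 strategy parameters.

    Level lists must be strictly increasing; ec and ea lists start at 0 so
    the null (no-expression) strategy is always on the grid.
    """

    ec_levels: tuple          # mol L^-1
    ea_levels: tuple          # mol L^-1
    frcv_levels: tuple        # dimensionless
    tps3_ratio: float = 1.0
    K_Tsl1: float = 0.20

    def __post_init__(self):
        problems = []
        for name in ("ec_levels", "ea_levels", "frcv_levels"):
            levels = tuple(getattr(self, name))
            setattr(self, name, levels)
            if len(set(levels)) != len(levels):
                problems.append(f"{name}: duplicate levels")
            if list(levels) != sorted(levels):
                problems.append(f"{name}: levels must be increasing")
        if self.ec_levels and self.ec_levels[0] != 0:
            problems.append("ec_levels must start at 0")
        if self.ea_levels and self.ea_levels[0] != 0:
            problems.append("ea_levels must start at 0")
        if problems:
            raise ConfigurationError(problems)

    @property
    def size(self) -> int:
        return (len(self.ec_levels) * len(self.ea_levels)
                * len(self.frcv_levels))


def generate_strains(grid: StrainGrid) -> list[StrainParams]:
    """Cartesian product of the level lists; strain ids encode the level
    indices as ``s<ec><ea><cv>`` so a champion is traceable to its levels."""
    strains = []
    for (i, ec), (j, ea), (k, cv) in itertools.product(
            enumerate(grid.ec_levels), enumerate(grid.ea_levels),
            enumerate(grid.frcv_levels)):
        strains.append(StrainParams(
            strain_id=f"s{i:02d}{j:02d}{k:02d}",
            ec_Tsl1=ec, ea_Tsl1=ea, fr_Tsl1_cv=cv,
            K_Tsl1=grid.K_Tsl1, tps3_ratio=grid.tps3_ratio))
    return strains


# ----------------------------------------------------------------------
# presets
# ----------------------------------------------------------------------

def desk_scale_grid() -> StrainGrid:
    """5 x 5 x 5 grid for desk-scale 5-day matches.

    Level spacing respects the selection resolution of a 5-day match at desk
    agent counts: demographic noise (whole-agent division/washout granularity)
    is a few tenths of a log unit per match, so the smallest nonzero ec and
    ea levels are placed where their trehalose cost is >= ~5-10% of growth
    (>= ~1.5 e-folds over the match) and the upper levels bracket the
    K_s-saturating concentration needed to survive severe shocks.
    """
    uM = 1e-6
    return StrainGrid(ec_levels=(0.0, 0.6 * uM, 1.2 * uM, 2.0 * uM, 3.5 * uM),
                      ea_levels=(0.0, 6.0 * uM, 10.0 * uM, 16.0 * uM,
                                 26.0 * uM),
                      frcv_levels=(0.0, 0.25, 0.5, 0.75, 1.0),
                      K_Tsl1=0.20)


def full_scale_grid() -> StrainGrid:
    """10 x 10 x 10 grid (1,000 strains), log-spaced above zero."""
    uM = 1e-6
    ec = (0.0,) + tuple(np.geomspace(0.3, 3.5, 9) * uM)
    ea = (0.0,) + tuple(np.geomspace(2.0, 26.0, 9) * uM)
    cv = tuple(np.linspace(0.0, 1.0, 10))
    return StrainGrid(ec_levels=ec, ea_levels=ea, frcv_levels=cv,
                      K_Tsl1=0.20)


def desk_match_settings() -> dict:
    """Engine/environment settings for a desk-scale 5-day match.

    ``shock_offset`` delays the first scheduled shock until the culture has
    passed its inoculation transient (cells start trehalose-free, so a shock
    inside the first generation would kill even a fully protected strain).
    """
    return dict(duration=120.0, dt=0.05, N_min=300, N_max=800, V=2e-6,
                cells_per_strain=2000, agents_per_strain=40,
                shock_offset=24.0)


def full_match_settings() -> dict:
    """Full-design 20-day match at higher computational resolution."""
    return dict(duration=480.0, dt=0.01, N_min=2000, N_max=6000, V=1e-4,
                cells_per_strain=50000, agents_per_strain=400,
                shock_offset=24.0)


#: desk-scale heat-shock conditions (H_a, F_h in h^-1); frequencies are
#: scaled so the shock count inside a 5-day match matches the regime
#: (>= 1 shock even in the low-frequency condition; see docs/methods.md)
DESK_CONDITIONS: dict[str, tuple[float, float]] = {
    "no_shock": (0.0, 0.0),
    "low_severity": (0.65, 0.06),
    "high_severity_low_freq": (0.85, 0.012),
    "high_severity_high_freq": (0.85, 0.25),
}


# ----------------------------------------------------------------------
# matches and tournaments
# ----------------------------------------------------------------------

@dataclass
class MatchResult:
    condition: tuple          # (H_a, F_h in h^-1)
    strain_ids: list
    final_cells: dict         # strain_id -> final real-cell count
    winner: str | None        # None if the match was void (all extinct)
    seed: int
    duration: float
    tie_broken: bool = False


def run_match(strains, condition, phys: PhysiologyParams | None = None,
              seed: int = 0, settings: dict | None = None) -> MatchResult:
    """Co-culture up to 10 strains in one chemostat under the condition
    ``(H_a, F_h)`` and rank them by final real-cell count.

    Extinct strains stay in the result with count 0; if every strain is
    extinct the match is void (winner ``None``).  Exact ties are broken
    uniformly at random with the match seed (logged via ``tie_broken``).
    """
    if not strains:
        raise ConfigurationError("run_match needs at least one strain")
    ids = [s.strain_id for s in strains]
    H_a, F_h = condition
    s = dict(desk_match_settings(), **(settings or {}))
    scenario = ScenarioConfig(
        phys=phys or PhysiologyParams(),
        strains=list(strains),
        env=EnvSettings(mode="chemostat", D=0.15, G_in=1.0, V=s["V"]),
        schedule=HeatShockSchedule(H_a=H_a, F_h=F_h,
                                   phase_offset=s.get("shock_offset", 0.0)),
        engine=EngineSettings(dt=s["dt"], duration=s["duration"],
                              N_min=s["N_min"], N_max=s["N_max"],
                              record_every=max(s["duration"] / 60, s["dt"]),
                              seed=seed),
        init=InitSettings(cells_per_strain=s["cells_per_strain"],
                          agents_per_strain=s["agents_per_strain"]),
    )
    res = run_simulation(scenario, seed=seed)
    pop = res.population
    counts = {}
    for idx, sid in enumerate(res.strain_table.ids):
        counts[sid] = int(pop.nu[pop.strain_idx == idx].sum()) \
            if pop.n_agents else 0
    best = max(counts.values())
    if best == 0:
        return MatchResult(condition=condition, strain_ids=ids,
                           final_cells=counts, winner=None, seed=seed,
                           duration=s["duration"])
    leaders = [sid for sid, c in counts.items() if c == best]
    tie = len(leaders) > 1
    rng = np.random.default_rng(seed)
    winner = leaders[0] if not tie else leaders[rng.integers(len(leaders))]
    return MatchResult(condition=condition, strain_ids=ids,
                       final_cells=counts, winner=winner, seed=seed,
                       duration=s["duration"], tie_broken=tie)


def partition_into_matches(n: int, match_size: int = 10) -> list[range]:
    """Index ranges of one tournament round (last match may be smaller)."""
    return [range(i, min(i + match_size, n))
            for i in range(0, n, match_size)]


@dataclass
class TournamentLog:
    champion: StrainParams
    rounds: list = field(default_factory=list)   # list of lists of MatchResult
    void_matches: int = 0


def run_tournament(strains, condition, phys=None, seed: int = 0,
                   settings: dict | None = None,
                   match_size: int = 10) -> TournamentLog:
    """Single-elimination tournament: random partition into matches of up to
    ``match_size``, winners advance, repeat until one strain remains.

    A void match (all competitors extinct) is retried once with a fresh
    spawned seed; if still void, a uniformly random participant advances
    (logged).  A leftover single strain gets a bye.
    """
    if len(strains) < 2:
        raise ConfigurationError("tournament needs at least 2 strains")
    by_id = {s.strain_id: s for s in strains}
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    alive = list(strains)
    log = TournamentLog(champion=None)
    while len(alive) > 1:
        order = rng.permutation(len(alive))
        shuffled = [alive[i] for i in order]
        round_results = []
        winners = []
        for rng_block in partition_into_matches(len(shuffled), match_size):
            group = [shuffled[i] for i in rng_block]
            if len(group) == 1:
                winners.append(group[0])     # bye
                continue
            match_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            result = run_match(group, condition, phys=phys, seed=match_seed,
                               settings=settings)
            if result.winner is None:
                retry_seed = int(ss.spawn(1)[0].generate_state(1)[0]
                                 % (2**31))
                result = run_match(group, condition, phys=phys,
                                   seed=retry_seed, settings=settings)
                if result.winner is None:
                    log.void_matches += 1
                    forced = group[rng.integers(len(group))].strain_id
                    result.winner = forced
            round_results.append(result)
            winners.append(by_id[result.winner])
        log.rounds.append(round_results)
        alive = winners
    log.champion = alive[0]
    return log


@dataclass
class TournamentSummary:
    champions: pd.DataFrame    # one row per (condition, replicate)
    summary: pd.DataFrame      # per condition: mean/sd of winning parameters


def sweep_conditions(strains, conditions, n_replicates: int = 10,
                     phys=None, seed: int = 0, settings: dict | None = None,
                     ea_zero: bool = False) -> TournamentSummary:
    """Replicate tournaments over a list of ``(H_a, F_h)`` conditions.

    ``ea_zero=True`` restricts the field to strains with no age-dependent
    term (the constrained comparison).  Champions are summarized as mean and
    SD of the winning (ec_Tsl1, ea_Tsl1, fr_Tsl1_cv) per condition.
    """
    field_strains = [s for s in strains if s.ea_Tsl1 == 0.0] if ea_zero \
        else list(strains)
    if len(field_strains) < 2:
        raise ConfigurationError("fewer than 2 strains in the field")
    rows = []
    ss = np.random.SeedSequence(seed)
    for cond in conditions:
        for rep in range(n_replicates):
            t_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
            log = run_tournament(field_strains, cond, phys=phys, seed=t_seed,
                                 settings=settings)
            champ = log.champion
            rows.append({"H_a": cond[0], "F_h": cond[1],
                         "F_h_per_day": cond[1] * 24.0, "replicate": rep,
                         "strain_id": champ.strain_id,
                         "ec_Tsl1": champ.ec_Tsl1, "ea_Tsl1": champ.ea_Tsl1,
                         "fr_Tsl1_cv": champ.fr_Tsl1_cv,
                         "void_matches": log.void_matches})
    champions = pd.DataFrame(rows)
    summary = (champions.groupby(["H_a", "F_h"], sort=False)
               .agg(ec_mean=("ec_Tsl1", "mean"), ec_sd=("ec_Tsl1", "std"),
                    ea_mean=("ea_Tsl1", "mean"), ea_sd=("ea_Tsl1", "std"),
                    frcv_mean=("fr_Tsl1_cv", "mean"),
                    frcv_sd=("fr_Tsl1_cv", "std"))
               .reset_index())
    summary["F_h_per_day"] = summary["F_h"] * 24.0
    return TournamentSummary(champions=champions, summary=summary)
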