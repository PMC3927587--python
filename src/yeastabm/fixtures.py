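"""Seeded fixture populations for tests and examples.

Fixtures are small, deterministic populations emitted as snapshot CSV tables
(the same column dictionary as engine snapshots); regenerating with the same
seed reproduces the file byte for byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cells import draw_individual_params
from .config import (EngineSettings, EnvSettings, InitSettings,
                     ScenarioConfig)
from .engine import HeatShockSchedule, run_simulation
from .exceptions import ConfigurationError
from .params import PhysiologyParams, null_strain
from .population import FIELDS, Population, StrainTable
from .scenarios import default_strain

KINDS = ("uniform", "aged-cohort", "two-strain")


def make_fixture(kind: str, seed: int = 0, n: int = 100,
                 phys: PhysiologyParams | None = None):
    """Build a reference population of the given kind.

    * ``uniform``: ``n`` identical newborn cells (zero variance everywhere).
    * ``aged-cohort``: a founder lineage grown forward under default
      parameters in replete glucose until ages 0..10 are all represented,
      then subsampled to about ``n`` agents spanning every age class.
    * ``two-strain``: equal-multiplicity newborns of the null strain and the
      default hedging strain.

    Returns ``(population, strain_table, phys)``.
    """
    phys = phys or PhysiologyParams()
    rng = np.random.default_rng(seed)
    if kind == "uniform":
        strain = default_strain()
        table = StrainTable([strain])
        d = draw_individual_params(phys, strain, rng)  # one shared draw
        ones = np.ones(n)
        pop = Population(
            m_X=d.m_b0_i * 0.8 * ones, m_D=np.zeros(n), m_T=np.zeros(n),
            m_b=d.m_b0_i * ones, m_b0_i=d.m_b0_i * ones,
            m_at_bud=np.zeros(n), mu_mg_i=d.mu_mg_i * ones,
            n_d_i=d.n_d_i * ones, fr_Tsl1_i=d.fr_Tsl1_i * ones,
            fr_Tps3_i=d.fr_Tps3_i * ones,
            n_B=np.zeros(n, np.int64), strain_idx=np.zeros(n, np.int64),
            nu=np.ones(n, np.int64), budding=np.zeros(n, bool))
        return pop, table, phys
    if kind == "aged-cohort":
        return _aged_cohort(seed, n, phys)
    if kind == "two-strain":
        strains = [null_strain(), default_strain().replace(strain_id="hedge")]
        table = StrainTable(strains)
        pop = Population.inoculate(phys, table, cells_per_strain=n // 2,
                                   agents_per_strain=n // 2, rng=rng)
        return pop, table, phys
    raise ConfigurationError(
        f"unknown fixture kind {kind!r}; choose from {KINDS}")


def _aged_cohort(seed: int, n: int, phys: PhysiologyParams):
    """Grow a small batch culture from a single founder until the oldest
    mother carries 10 bud scars, then keep ~n agents covering all ages."""
    strain = default_strain()
    scenario = ScenarioConfig(
        phys=phys, strains=[strain],
        env=EnvSettings(mode="batch", D=0.0, G_in=5.0, V=1e-3),
        schedule=HeatShockSchedule(),
        engine=EngineSettings(dt=0.02, duration=28.0, N_min=2,
                              N_max=200000, record_every=28.0, seed=seed),
        init=InitSettings(cells_per_strain=1, agents_per_strain=1, G0=5.0),
    )
    res = run_simulation(scenario, seed=seed)
    pop = res.population
    if pop.n_agents == 0 or pop.n_B.max() < 10:
        raise ConfigurationError(
            "aged-cohort fixture did not reach age 10; founder run too short")
    keep = np.zeros(pop.n_agents, bool)
    rng = np.random.default_rng(seed + 1)
    per_class = max(n // 11, 1)
    for age in range(11):
        members = np.nonzero(pop.n_B == age)[0]
        if members.size:
            chosen = rng.choice(members, size=min(per_class, members.size),
                                replace=False)
            keep[chosen] = True
    pop.keep(keep)
    return pop, res.strain_table, phys


def fixture_to_csv(kind: str, path, seed: int = 0, n: int = 100) -> Path:
    """Write the fixture snapshot table; same seed gives identical bytes."""
    pop, table, phys = make_fixture(kind, seed=seed, n=n)
    frame = pop.to_frame(table, phys, G=0.0)
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.12e")
    return path


def population_from_frame(frame: pd.DataFrame,
                          strain_table: StrainTable) -> Population:
    """Rebuild a Population from a snapshot table (inverse of ``to_frame``)."""
    arrays = {f: frame[f].to_numpy() for f in FIELDS}
    return Population(**arrays)
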