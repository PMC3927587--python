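"""Vectorized population container.

The engine keeps the whole population as a struct of numpy arrays (one entry
per agent = super-individual); :class:`StrainTable` holds the per-strain
expression parameters as arrays indexed by ``strain_idx`` so that a mixed
community evaluates in a single vectorized pass.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import kinetics
from .cells import BUDDING, UNBUDDED, CellState, draw_individual_params
from .exceptions import ConfigurationError
from .params import HeterogeneityToggles, PhysiologyParams, StrainParams

_FLOAT_FIELDS = ("m_X", "m_D", "m_T", "m_b", "m_b0_i", "m_at_bud",
                 "mu_mg_i", "n_d_i", "fr_Tsl1_i", "fr_Tps3_i")
_INT_FIELDS = ("n_B", "strain_idx", "nu")
_BOOL_FIELDS = ("budding",)
FIELDS = _FLOAT_FIELDS + _INT_FIELDS + _BOOL_FIELDS


class StrainTable:
    """Per-strain expression parameters, array-indexed for the engine."""

    def __init__(self, strains: Sequence[StrainParams]):
        ids = [s.strain_id for s in strains]
        if len(set(ids)) != len(ids):
            raise ConfigurationError("duplicate strain_id in strain list")
        self.strains = list(strains)
        self.ids = ids
        self.ec = np.array([s.ec_Tsl1 for s in strains])
        self.ea = np.array([s.ea_Tsl1 for s in strains])
        self.K = np.array([s.K_Tsl1 for s in strains])
        self.fr_cv = np.array([s.fr_Tsl1_cv for s in strains])
        self.ratio = np.array([s.tps3_ratio for s in strains])

    def __len__(self):
        return len(self.strains)

    def index(self, strain_id: str) -> int:
        return self.ids.index(strain_id)


class Population:
    """All agents of a simulation as parallel arrays.

    ``nu`` is each agent's multiplicity (number of real cells represented);
    population-level statistics are always nu-weighted.
    """

    def __init__(self, **arrays):
        n = len(arrays.get("m_X", ()))
        for f in _FLOAT_FIELDS:
            setattr(self, f, np.asarray(arrays.get(f, np.zeros(n)),
                                        dtype=float).copy())
        for f in _INT_FIELDS:
            default = np.ones(n) if f == "nu" else np.zeros(n)
            setattr(self, f, np.asarray(arrays.get(f, default),
                                        dtype=np.int64).copy())
        for f in _BOOL_FIELDS:
            setattr(self, f, np.asarray(arrays.get(f, np.zeros(n, bool)),
                                        dtype=bool).copy())

    # -- basic bookkeeping -------------------------------------------------
    @property
    def n_agents(self) -> int:
        return self.m_X.size

    @property
    def total_cells(self) -> int:
        """Real-cell count sum(nu)."""
        return int(self.nu.sum())

    @property
    def m(self) -> np.ndarray:
        return self.m_X + self.m_D + self.m_T

    def keep(self, mask: np.ndarray) -> None:
        for f in FIELDS:
            setattr(self, f, getattr(self, f)[mask])

    def append(self, **arrays) -> None:
        for f in FIELDS:
            cur = getattr(self, f)
            setattr(self, f, np.concatenate([cur, np.asarray(arrays[f],
                                                             dtype=cur.dtype)]))

    def copy(self) -> "Population":
        return Population(**{f: getattr(self, f) for f in FIELDS})

    # -- construction ------------------------------------------------------
    @classmethod
    def inoculate(cls, phys: PhysiologyParams, strain_table: StrainTable,
                  cells_per_strain: int, agents_per_strain: int, rng,
                  toggles: HeterogeneityToggles | None = None) -> "Population":
        """Seed the culture with newborn-like cells of every strain.

        Each strain contributes ``agents_per_strain`` agents whose
        multiplicities sum exactly to ``cells_per_strain``.  Initial sizes
        are the drawn budding thresholds scaled by U(0.6, 1.0) so the cohort
        does not bud in lockstep.
        """
        if agents_per_strain < 1 or cells_per_strain < agents_per_strain:
            raise ConfigurationError(
                "need agents_per_strain >= 1 and cells_per_strain >= "
                "agents_per_strain")
        chunks = []
        for s_idx, strain in enumerate(strain_table.strains):
            d = draw_individual_params(phys, strain, rng,
                                       size=agents_per_strain,
                                       toggles=toggles)
            m_X = d.m_b0_i * rng.uniform(0.6, 1.0, size=agents_per_strain)
            nu = np.full(agents_per_strain,
                         cells_per_strain // agents_per_strain, dtype=np.int64)
            nu[: cells_per_strain % agents_per_strain] += 1
            chunks.append(dict(
                m_X=m_X, m_D=np.zeros_like(m_X), m_T=np.zeros_like(m_X),
                m_b=d.m_b0_i, m_b0_i=d.m_b0_i, m_at_bud=np.zeros_like(m_X),
                mu_mg_i=d.mu_mg_i, n_d_i=d.n_d_i,
                fr_Tsl1_i=d.fr_Tsl1_i, fr_Tps3_i=d.fr_Tps3_i,
                n_B=np.zeros_like(nu), strain_idx=np.full_like(nu, s_idx),
                nu=nu, budding=np.zeros(agents_per_strain, bool)))
        merged = {f: np.concatenate([c[f] for c in chunks]) for f in FIELDS}
        return cls(**merged)

    @classmethod
    def from_cells(cls, cells: Sequence[CellState],
                   strain_table: StrainTable) -> "Population":
        arrays = {f: [] for f in FIELDS}
        for c in cells:
            arrays["m_X"].append(c.m_X)
            arrays["m_D"].append(c.m_D)
            arrays["m_T"].append(c.m_T)
            arrays["m_b"].append(c.m_b)
            arrays["m_b0_i"].append(c.m_b0_i)
            arrays["m_at_bud"].append(c.m_at_bud)
            arrays["mu_mg_i"].append(c.mu_mg_i)
            arrays["n_d_i"].append(c.n_d_i)
            arrays["fr_Tsl1_i"].append(c.fr_Tsl1_i)
            arrays["fr_Tps3_i"].append(c.fr_Tps3_i)
            arrays["n_B"].append(c.n_B)
            arrays["strain_idx"].append(strain_table.index(c.strain_id))
            arrays["nu"].append(c.multiplicity)
            arrays["budding"].append(c.phase == BUDDING)
        return cls(**{k: np.asarray(v) for k, v in arrays.items()})

    def to_cells(self, strain_table: StrainTable) -> list[CellState]:
        out = []
        for i in range(self.n_agents):
            out.append(CellState(
                m_X=float(self.m_X[i]), m_D=float(self.m_D[i]),
                m_T=float(self.m_T[i]), n_B=int(self.n_B[i]),
                phase=BUDDING if self.budding[i] else UNBUDDED,
                m_b=float(self.m_b[i]), m_at_bud=float(self.m_at_bud[i]),
                mu_mg_i=float(self.mu_mg_i[i]), n_d_i=float(self.n_d_i[i]),
                fr_Tsl1_i=float(self.fr_Tsl1_i[i]),
                fr_Tps3_i=float(self.fr_Tps3_i[i]),
                m_b0_i=float(self.m_b0_i[i]),
                strain_id=strain_table.ids[int(self.strain_idx[i])],
                multiplicity=int(self.nu[i])))
        return out

    # -- derived per-agent quantities --------------------------------------
    def rates(self, strain_table: StrainTable, phys: PhysiologyParams,
              G: float, toggles: HeterogeneityToggles | None = None) -> dict:
        """Evaluate every kinetic law for all agents at glucose G.

        Returns a dict of arrays: f_D, f_T, e_Tsl1, e_Tps3, e_s, f_s, k_d,
        mu, mu_spec (specific total-biomass growth rate mu*m_X/m) and H_t.
        Mean-field ablation toggles substitute nu-weighted population
        averages into the expression (m_D/m) and synthesis (e_s) laws.
        """
        t = toggles or _NO_TOGGLES
        m = self.m
        w = self.nu.astype(float)
        W = w.sum()
        f_D = np.divide(self.m_D, m, out=np.zeros_like(m), where=m > 0)
        f_T = np.divide(self.m_T, m, out=np.zeros_like(m), where=m > 0)
        si = self.strain_idx
        f_D_expr = (np.full_like(f_D, np.average(f_D, weights=w))
                    if (t.mean_field_mD and W > 0) else f_D)
        e1, e3 = kinetics.expression_kernel(
            f_D_expr, self.fr_Tsl1_i, self.fr_Tps3_i,
            strain_table.ec[si], strain_table.ea[si],
            strain_table.K[si], strain_table.ratio[si])
        e_s = e1 + e3
        e_s_syn = (np.full_like(e_s, np.average(e_s, weights=w))
                   if (t.mean_field_es and W > 0) else e_s)
        f_s = kinetics.synthesis_fraction(e_s_syn, phys)
        if t.scarring_off and W > 0:
            n_eff = np.full(self.n_agents, np.average(self.n_B, weights=w))
        else:
            n_eff = self.n_B
        k_d = kinetics.damage_rate(n_eff, phys)
        mu = kinetics.growth_rate_kernel(self.mu_mg_i, self.n_d_i, f_D, G,
                                         phys)
        mu_spec = mu * np.divide(self.m_X, m, out=np.zeros_like(m),
                                 where=m > 0)
        H_t = kinetics.heat_tolerance_kernel(f_T, phys.K_h)
        return dict(f_D=f_D, f_T=f_T, e_Tsl1=e1, e_Tps3=e3, e_s=e_s,
                    f_s=f_s, k_d=k_d, mu=mu, mu_spec=mu_spec, H_t=H_t)

    def to_frame(self, strain_table: StrainTable, phys: PhysiologyParams,
                 G: float = 0.0,
                 toggles: HeterogeneityToggles | None = None) -> pd.DataFrame:
        """Snapshot table: one row per agent, state plus derived quantities."""
        r = self.rates(strain_table, phys, G, toggles)
        data = {f: getattr(self, f) for f in FIELDS}
        data["strain_id"] = [strain_table.ids[i] for i in self.strain_idx]
        data["m"] = self.m
        for k in ("mu", "f_s", "H_t", "e_Tsl1", "e_Tps3", "f_D", "f_T",
                  "mu_spec"):
            data[k] = r[k]
        return pd.DataFrame(data)


_NO_TOGGLES = HeterogeneityToggles()


def weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        return float("nan")
    return float(np.average(np.asarray(values, dtype=float), weights=w))


def weighted_var(values: np.ndarray, weights: np.ndarray) -> float:
    """nu-weighted population variance (real cells, not agents)."""
    w = np.asarray(weights, dtype=float)
    if w.sum() == 0:
        return float("nan")
    mean = np.average(values, weights=w)
    return float(np.average((np.asarray(values, dtype=float) - mean) ** 2,
                            weights=w))
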