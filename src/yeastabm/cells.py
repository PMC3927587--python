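"""Single-cell state and operations.

:class:`CellState` is the scalar, one-agent view of the model; the population
engine runs the identical kernels from :mod:`yeastabm.kinetics` over arrays.
A ``CellState`` with ``multiplicity`` nu > 1 is a super-individual standing
for nu phenotypically identical real cells.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from . import kinetics
from .exceptions import InvariantViolation
from .params import HeterogeneityToggles, PhysiologyParams, StrainParams
from .sampling import truncated_normal, truncated_normal_mean

UNBUDDED = "unbudded"
BUDDING = "budding"


@dataclass
class CellState:
    """One yeast cell (or super-individual of ``multiplicity`` real cells)."""

    m_X: float                  # structural biomass, g
    m_D: float = 0.0            # damaged biomass, g
    m_T: float = 0.0            # trehalose biomass, g
    n_B: int = 0                # bud scars (replicative age)
    phase: str = UNBUDDED
    m_b: float = 0.0            # current budding-size threshold, g
    m_at_bud: float = 0.0       # total mass when budding started, g
    mu_mg_i: float = 0.45       # this cell's drawn max growth rate, h^-1
    n_d_i: float = 2.0          # this cell's drawn damage exponent
    fr_Tsl1_i: float = 1.0
    fr_Tps3_i: float = 1.0
    m_b0_i: float = 0.0         # this cell's drawn birth threshold, g
    strain_id: str = "wt"
    multiplicity: int = 1

    def __post_init__(self):
        if min(self.m_X, self.m_D, self.m_T) < 0 or self.m <= 0:
            raise InvariantViolation(f"non-positive biomass state: {self}")
        if self.n_B < 0 or self.multiplicity < 1:
            raise InvariantViolation(f"bad n_B/multiplicity: {self}")
        if self.phase not in (UNBUDDED, BUDDING):
            raise InvariantViolation(f"unknown phase {self.phase!r}")

    @property
    def m(self) -> float:
        """Total biomass m = m_X + m_D + m_T."""
        return self.m_X + self.m_D + self.m_T

    @property
    def damage_fraction(self) -> float:
        return self.m_D / self.m

    @property
    def trehalose_fraction(self) -> float:
        return self.m_T / self.m


class IndividualDraws(NamedTuple):
    mu_mg_i: float
    n_d_i: float
    fr_Tsl1_i: float
    fr_Tps3_i: float
    m_b0_i: float


def draw_individual_params(phys: PhysiologyParams, strain: StrainParams,
                           rng, size=None,
                           toggles: HeterogeneityToggles | None = None
                           ) -> IndividualDraws:
    """Draw a newborn's individual parameters from the global truncated
    normals (the mother's values never shift the distribution).

    With ``size`` set, each entry is an array of independent draws.  Ablation
    toggles replace the corresponding draw by the analytic mean of the same
    truncated normal (mean-preserving) without consuming random numbers.
    """
    t = toggles or _NO_TOGGLES

    def one(mean, cv, off):
        if off or cv == 0.0:
            val = truncated_normal_mean(mean, cv) if mean > 0 else float(mean)
            return val if size is None else np.full(int(size), val)
        return truncated_normal(mean, cv, size=size, rng=rng)

    mu = one(phys.mu_mg_mean, phys.mu_mg_cv, t.randomize_mu_off)
    nd = one(phys.n_d_mean, phys.n_d_cv, t.randomize_nd_off)
    fr1 = one(1.0, strain.fr_Tsl1_cv, t.randomize_frTsl1_off)
    fr3 = one(1.0, strain.fr_Tsl1_cv, t.randomize_frTps3_off)
    mb0 = one(phys.m_b0_mean, phys.m_b0_cv, t.randomize_mb0_off)
    return IndividualDraws(mu, nd, fr1, fr3, mb0)


_NO_TOGGLES = HeterogeneityToggles()


def newborn(phys: PhysiologyParams, strain: StrainParams, rng,
            m_X: float | None = None,
            toggles: HeterogeneityToggles | None = None) -> CellState:
    """A freshly drawn virgin daughter (n_B = 0, no damage, no trehalose)."""
    d = draw_individual_params(phys, strain, rng, toggles=toggles)
    return CellState(m_X=d.m_b0_i if m_X is None else m_X,
                     m_b=d.m_b0_i, m_b0_i=d.m_b0_i,
                     mu_mg_i=d.mu_mg_i, n_d_i=d.n_d_i,
                     fr_Tsl1_i=d.fr_Tsl1_i, fr_Tps3_i=d.fr_Tps3_i,
                     strain_id=strain.strain_id)


def damage_rate(n_B: int, phys: PhysiologyParams) -> float:
    """k_d = a_d * n_B**b_d (h^-1)."""
    return float(kinetics.damage_rate(n_B, phys))


def growth_rate(cell: CellState, G: float, phys: PhysiologyParams) -> float:
    """Kinetic growth rate mu of this cell at glucose concentration G."""
    return float(kinetics.growth_rate_kernel(
        cell.mu_mg_i, cell.n_d_i, cell.damage_fraction, G, phys))


def expression_levels(cell: CellState, strain: StrainParams
                      ) -> tuple[float, float, float]:
    """(e_Tsl1, e_Tps3, e_s) in mol L^-1, from the current damage fraction."""
    e1, e3 = kinetics.expression_kernel(
        cell.damage_fraction, cell.fr_Tsl1_i, cell.fr_Tps3_i,
        strain.ec_Tsl1, strain.ea_Tsl1, strain.K_Tsl1, strain.tps3_ratio)
    return float(e1), float(e3), float(e1 + e3)


def synthesis_fraction(e_s: float, phys: PhysiologyParams) -> float:
    """f_s = f_ms * e_s^n_s / (K_s^n_s + e_s^n_s)."""
    return float(kinetics.synthesis_fraction(e_s, phys))


def heat_tolerance(cell: CellState, phys: PhysiologyParams) -> float:
    """H_t = fT / (K_h + fT) with fT = m_T/m; in [0, 1)."""
    return float(kinetics.heat_tolerance_kernel(cell.trehalose_fraction,
                                                phys.K_h))


def step_cell(cell: CellState, G: float, dt: float, phys: PhysiologyParams,
              strain: StrainParams) -> CellState:
    """One explicit-Euler step of the mass balances, rates evaluated at the
    step start.  Does not handle budding/division (see
    :func:`update_cycle_and_divide`)."""
    _, _, e_s = expression_levels(cell, strain)
    f_s = synthesis_fraction(e_s, phys)
    k_d = damage_rate(cell.n_B, phys)
    mu = growth_rate(cell, G, phys)
    m_X, m_D, m_T = kinetics.euler_masses(cell.m_X, cell.m_D, cell.m_T,
                                          mu, f_s, k_d, dt)
    return replace(cell, m_X=float(m_X), m_D=float(m_D), m_T=float(m_T))


def update_cycle_and_divide(cell: CellState, phys: PhysiologyParams,
                            strain: StrainParams, rng,
                            toggles: HeterogeneityToggles | None = None,
                            mean_n_B: float | None = None):
    """Advance the budding cycle; return the cell, or ``(mother, daughter)``.

    * unbudded and m >= m_b: budding starts, current mass recorded.
    * budding and m >= f_mr * m_b: division.  The daughter gets the mass
      synthesized since budding, a fresh set of individual draws and n_B = 0;
      the mother keeps m_at_bud, gains a bud scar, retains fraction s_d of
      the damage, and her next threshold is m_b0_i * a_mb**(n_B + offset).

    ``mean_n_B`` substitutes the population-mean age in the threshold
    generation factor when the scarring ablation is active.
    """
    t = toggles or _NO_TOGGLES
    m = cell.m
    if cell.phase == UNBUDDED:
        if m >= cell.m_b:
            return replace(cell, phase=BUDDING, m_at_bud=m)
        return cell
    # replication size is proportional to the size at which budding actually
    # started (== m_b up to one Euler step for normal cells)
    if m < phys.f_mr * max(cell.m_b, cell.m_at_bud):
        return cell

    s_d = 0.5 if t.damage_split_equal else phys.s_d
    (mX_m, mD_m, mT_m), (mX_d, mD_d, mT_d) = kinetics.split_masses(
        cell.m_at_bud, cell.m_X, cell.m_D, cell.m_T, s_d)
    if min(mX_m, mT_m, mX_d, mT_d) < 0:
        raise InvariantViolation(
            f"division produced a negative compartment for cell {cell}")

    n_B_new = cell.n_B + 1
    age_for_mb = mean_n_B if (t.scarring_off and mean_n_B is not None) \
        else n_B_new
    exponent = max(age_for_mb + phys.mb_exponent_offset, 0)
    mother = replace(cell, m_X=float(mX_m), m_D=float(mD_m), m_T=float(mT_m),
                     n_B=n_B_new, phase=UNBUDDED, m_at_bud=0.0,
                     m_b=cell.m_b0_i * phys.a_mb ** exponent)

    d = draw_individual_params(phys, strain, rng, toggles=t)
    daughter = CellState(m_X=float(mX_d), m_D=float(mD_d), m_T=float(mT_d),
                         n_B=0, phase=UNBUDDED, m_b=d.m_b0_i,
                         m_b0_i=d.m_b0_i, m_at_bud=0.0,
                         mu_mg_i=d.mu_mg_i, n_d_i=d.n_d_i,
                         fr_Tsl1_i=d.fr_Tsl1_i, fr_Tps3_i=d.fr_Tps3_i,
                         strain_id=cell.strain_id,
                         multiplicity=cell.multiplicity)
    return mother, daughter
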