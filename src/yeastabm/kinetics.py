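"""Single-cell kinetic laws as vectorized kernels.

Every function accepts scalars or equal-length numpy arrays and is the single
implementation used both by the scalar :class:`~yeastabm.cells.CellState` API
and by the vectorized population engine.

Model summary (per cell, internal units h / g / L / mol L^-1):

* growth        mu = mu_mg_i * G/(K_g+G) * K_d^n / (K_d^n + fD^n),  fD = m_D/m
* damage        k_d = a_d * n_B^b_d   (structural -> damaged, first order)
* expression    e_Tsl1 = (ec + ea * fD/(K_Tsl1+fD)) * fr_Tsl1_i  (memoryless)
* synthesis     f_s = f_ms * e_s^n_s / (K_s^n_s + e_s^n_s),  e_s = e_Tsl1+e_Tps3
* tolerance     H_t = fT / (K_h + fT),  fT = m_T/m
* mass balance  dm_X/dt = (1-f_s) mu m_X - k_d m_X
                dm_D/dt = k_d m_X
                dm_T/dt = f_s mu m_X          (explicit Euler)
"""

from __future__ import annotations

import numpy as np

from .exceptions import StepSizeError


def damage_rate(n_B, phys):
    """First-order damage rate k_d = a_d * n_eff**b_d (h^-1).

    ``n_eff = n_B + phys.kd_age_offset``; with the default offset 0 a
    never-divided daughter (n_B = 0, b_d > 0) accrues no damage.
    """
    n_eff = np.asarray(n_B, dtype=float) + phys.kd_age_offset
    return phys.a_d * n_eff ** phys.b_d


def monod(G, K):
    """Saturating substrate term G/(K+G); 0 when both G and K are 0."""
    G = np.asarray(G, dtype=float)
    denom = K + G
    return np.divide(G, denom, out=np.zeros_like(G), where=denom > 0)


def growth_rate_kernel(mu_mg_i, n_d_i, f_D, G, phys):
    """Kinetic growth rate mu (h^-1): Monod in glucose, Hill-inhibited by
    the damage mass fraction, using the cell's individual mu_mg_i and n_d_i."""
    f_D = np.asarray(f_D, dtype=float)
    n_d_i = np.asarray(n_d_i, dtype=float)
    Kn = phys.K_d ** n_d_i
    inhib = Kn / (Kn + f_D ** n_d_i)
    return np.asarray(mu_mg_i) * monod(G, phys.K_g) * inhib


def expression_kernel(f_D, fr_Tsl1_i, fr_Tps3_i, strain_ec, strain_ea,
                      strain_K, strain_ratio):
    """Instantaneous Tsl1/Tps3 concentrations (mol L^-1).

    Expression adjusts rapidly to the current damage fraction, so no protein
    dynamics are carried: constant term + damage-saturating age term, times
    the cell's lifelong randomization factor.  Tps3 mirrors Tsl1 with every
    magnitude scaled by ``strain_ratio``.
    """
    f_D = np.asarray(f_D, dtype=float)
    denom = strain_K + f_D
    age_term = np.divide(f_D, denom, out=np.zeros_like(f_D), where=denom > 0)
    base = strain_ec + strain_ea * age_term
    e_Tsl1 = base * np.asarray(fr_Tsl1_i)
    e_Tps3 = strain_ratio * base * np.asarray(fr_Tps3_i)
    return e_Tsl1, e_Tps3


def synthesis_fraction(e_s, phys):
    """Trehalose synthesis fraction f_s in [0, f_ms): Hill function of the
    total synthesis-enzyme concentration e_s = e_Tsl1 + e_Tps3."""
    e_s = np.asarray(e_s, dtype=float)
    en = e_s ** phys.n_s
    denom = phys.K_s ** phys.n_s + en
    return phys.f_ms * np.divide(en, denom, out=np.zeros_like(en),
                                 where=denom > 0)


def heat_tolerance_kernel(f_T, K_h):
    """Heat-shock tolerance H_t in [0, 1): saturating in the trehalose mass
    fraction; H_t = 0.5 exactly at f_T = K_h."""
    f_T = np.asarray(f_T, dtype=float)
    return f_T / (K_h + f_T)


def euler_masses(m_X, m_D, m_T, mu, f_s, k_d, dt):
    """One explicit-Euler step of the three-compartment mass balance.

    All rates are evaluated at the step start; the total-mass increment is
    exactly mu * m_X * dt (growth adds mass, damage only converts it).
    Raises :class:`StepSizeError` if the structural compartment would go
    negative, i.e. ``((1-f_s) mu - k_d) dt < -1``.
    """
    if dt <= 0:
        raise StepSizeError(f"dt must be positive, got {dt}")
    m_X = np.asarray(m_X, dtype=float)
    growth = np.asarray(mu) * m_X * dt
    damage = np.asarray(k_d) * m_X * dt
    new_X = m_X + (1.0 - np.asarray(f_s)) * growth - damage
    if np.any(new_X < 0):
        raise StepSizeError(
            "structural biomass driven negative; reduce dt "
            f"(max k_d*dt = {float(np.max(np.asarray(k_d) * dt)):.3g})")
    new_D = np.asarray(m_D, dtype=float) + damage
    new_T = np.asarray(m_T, dtype=float) + np.asarray(f_s) * growth
    return new_X, new_D, new_T


def split_masses(m_at_bud, m_X, m_D, m_T, s_d):
    """Partition a dividing cell into (mother, daughter) compartment triples.

    The mother keeps the biomass she had when budding started (``m_at_bud``),
    the daughter receives everything synthesized since.  Damage splits by the
    retention fraction s_d (mother share); the remaining non-damage mass of
    each cell is filled with structural and trehalose mass in the cell's
    pre-division X:T ratio, so m_X, m_D and m_T are each conserved exactly.

    Returns ``((mX_m, mD_m, mT_m), (mX_d, mD_d, mT_d))``; inputs may be
    arrays.  Raises :class:`~yeastabm.exceptions.InvariantViolation` upstream
    if a compartment would go negative (checked by the caller, which can
    report the offending agent).
    """
    m_at_bud = np.asarray(m_at_bud, dtype=float)
    m_X = np.asarray(m_X, dtype=float)
    m_D = np.asarray(m_D, dtype=float)
    m_T = np.asarray(m_T, dtype=float)
    m_tot = m_X + m_D + m_T
    mD_m = s_d * m_D
    mD_d = m_D - mD_m
    nondam_m = m_at_bud - mD_m
    nondam_d = (m_tot - m_at_bud) - mD_d
    pool = m_X + m_T
    x_frac = np.divide(m_X, pool, out=np.ones_like(pool), where=pool > 0)
    mother = (nondam_m * x_frac, mD_m, nondam_m * (1.0 - x_frac))
    daughter = (nondam_d * x_frac, mD_d, nondam_d * (1.0 - x_frac))
    return mother, daughter
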