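"""Parameter containers: shared physiology, per-strain expression strategy,
and the heterogeneity-ablation switches.

All values are stored in internal units (hours, grams, liters, mol L^-1).
The shipped defaults are repository choices within literature-plausible
ranges for *S. cerevisiae* in glucose-limited culture; every value can be
overridden from a config file (see :mod:`yeastabm.config`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .exceptions import ConfigurationError


@dataclass
class PhysiologyParams:
    """Kinetic constants shared by every strain in a simulation.

    Attributes
    ----------
    mu_mg_mean, mu_mg_cv
        Population mean and CV of the maximum growth rate mu_m,g (h^-1);
        each cell draws its own value at birth from a truncated normal.
    K_g
        Glucose half-saturation of the Monod term (g L^-1).
    K_d, n_d_mean, n_d_cv
        Half-saturation (damage mass fraction, dimensionless) and Hill
        exponent of the damage inhibition of growth; the exponent is
        individually randomized like mu_m,g.
    a_d, b_d
        Damage-rate law k_d = a_d * n_B**b_d (h^-1): structural biomass is
        converted to damaged biomass first-order at a rate that grows with
        replicative age (bud scars n_B).
    s_d
        Fraction of damaged mass retained by the mother at division
        (asymmetric damage segregation), in [0.5, 1].
    f_ms, K_s, n_s
        Trehalose synthesis saturation: f_s = f_ms * e_s^n_s / (K_s^n_s +
        e_s^n_s) with e_s the summed Tsl1+Tps3 concentration (mol L^-1).
    K_h
        Trehalose mass fraction m_T/m giving heat tolerance H_t = 0.5.
    m_b0_mean, m_b0_cv
        Daughter budding-size threshold distribution (g dry mass).
    a_mb
        Per-generation growth factor of the mother's budding threshold.
    f_mr
        Replication-size multiplier: division at m >= f_mr * m_b.
    Y_gx
        Biomass yield on glucose (g dry mass per g glucose); closes the
        extracellular glucose balance.
    kd_age_offset
        0 (default): k_d = a_d * n_B**b_d so virgin daughters accrue no
        damage; 1: k_d = a_d * (n_B + 1)**b_d.
    mb_exponent_offset
        Exponent convention for the budding-threshold generation factor:
        m_b = m_b0_i * a_mb**max(n_B + offset, 0).  0 (default) or -1.
    """

    mu_mg_mean: float = 0.45      # h^-1
    mu_mg_cv: float = 0.10
    K_g: float = 0.10             # g L^-1
    K_d: float = 0.30
    n_d_mean: float = 2.0
    n_d_cv: float = 0.10
    a_d: float = 0.004            # h^-1
    b_d: float = 1.0
    s_d: float = 0.70
    f_ms: float = 0.40
    K_s: float = 2.0e-6           # mol L^-1
    n_s: float = 2.0
    K_h: float = 0.05
    m_b0_mean: float = 15e-12     # g
    m_b0_cv: float = 0.15
    a_mb: float = 1.10
    f_mr: float = 1.65
    Y_gx: float = 0.50            # g biomass per g glucose
    kd_age_offset: int = 0
    mb_exponent_offset: int = 0

    def __post_init__(self):
        problems = []
        for name in ("mu_mg_mean", "K_g", "K_d", "n_d_mean", "a_d", "b_d",
                     "K_s", "n_s", "K_h", "m_b0_mean", "Y_gx"):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        for name in ("mu_mg_cv", "n_d_cv", "m_b0_cv"):
            if getattr(self, name) < 0:
                problems.append(f"{name} (a CV) must be >= 0")
        if not 0.5 <= self.s_d <= 1.0:
            problems.append(f"s_d={self.s_d} outside [0.5, 1]")
        if not 0.0 <= self.f_ms <= 1.0:
            problems.append(f"f_ms={self.f_ms} outside [0, 1]")
        if self.f_mr <= 1.0:
            problems.append(f"f_mr={self.f_mr} must be > 1")
        if self.a_mb < 1.0:
            problems.append(f"a_mb={self.a_mb} must be >= 1")
        if self.kd_age_offset not in (0, 1):
            problems.append("kd_age_offset must be 0 or 1")
        if self.mb_exponent_offset not in (0, -1):
            problems.append("mb_exponent_offset must be 0 or -1")
        if problems:
            raise ConfigurationError(problems)

    def replace(self, **kwargs) -> "PhysiologyParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class StrainParams:
    """One strain's Tsl1/Tps3 expression strategy.

    Expression follows e_Tsl1 = (ec_Tsl1 + ea_Tsl1 * fD/(K_Tsl1 + fD)) *
    fr_Tsl1_i with fD = m_D/m the cell's damage fraction and fr_Tsl1_i a
    per-cell randomization factor (truncated normal, mean 1, CV
    ``fr_Tsl1_cv``).  Tps3 uses the same form with every magnitude scaled by
    ``tps3_ratio`` and its own randomization factor (same CV).
    """

    strain_id: str = "wt"
    ec_Tsl1: float = 0.1e-6       # mol L^-1, constant expression
    ea_Tsl1: float = 3.0e-6       # mol L^-1, age(damage)-dependent magnitude
    K_Tsl1: float = 0.20          # damage-fraction half-saturation
    fr_Tsl1_cv: float = 0.30      # CV of the stochastic factor (mean 1.0)
    tps3_ratio: float = 1.0

    def __post_init__(self):
        problems = []
        if self.ec_Tsl1 < 0 or self.ea_Tsl1 < 0:
            problems.append("expression magnitudes must be >= 0")
        if self.K_Tsl1 < 0:
            problems.append("K_Tsl1 must be >= 0")
        if self.fr_Tsl1_cv < 0:
            problems.append("fr_Tsl1_cv must be >= 0")
        if self.tps3_ratio < 0:
            problems.append("tps3_ratio must be >= 0")
        if problems:
            raise ConfigurationError(problems)

    def replace(self, **kwargs) -> "StrainParams":
        return dataclasses.replace(self, **kwargs)


def null_strain(strain_id: str = "null") -> StrainParams:
    """Strain with no trehalose expression at all (zero cost, zero tolerance)."""
    return StrainParams(strain_id=strain_id, ec_Tsl1=0.0, ea_Tsl1=0.0,
                        fr_Tsl1_cv=0.0)


@dataclass
class HeterogeneityToggles:
    """Switches that remove individual sources/links of cell-to-cell
    variability for the heterogeneity-network diagnostic.

    The base case is all flags False.  ``*_off`` flags replace a stochastic
    draw with the mean of its truncated-normal distribution (mean-preserving);
    ``damage_split_equal`` forces s_d = 0.5; ``scarring_off`` makes every cell
    use the population-mean bud-scar count in the damage rate and in the
    budding-threshold generation factor; the two ``mean_field_*`` flags cut
    network links by feeding population-average quantities into the synthesis
    (e_s in the Hill term) and expression (m_D/m in the damage term) laws.
    """

    scarring_off: bool = False
    damage_split_equal: bool = False
    randomize_mb0_off: bool = False
    randomize_frTsl1_off: bool = False
    randomize_frTps3_off: bool = False
    randomize_mu_off: bool = False
    randomize_nd_off: bool = False
    mean_field_es: bool = False
    mean_field_mD: bool = False

    def any_active(self) -> bool:
        return any(dataclasses.asdict(self).values())

    @classmethod
    def all_on(cls) -> "HeterogeneityToggles":
        return cls(**{f.name: True for f in dataclasses.fields(cls)})

    def replace(self, **kwargs) -> "HeterogeneityToggles":
        return dataclasses.replace(self, **kwargs)


#: config-file dimension of every PhysiologyParams field
PHYSIOLOGY_DIMENSIONS = {
    "mu_mg_mean": "rate", "mu_mg_cv": "dimensionless", "K_g": "mass_conc",
    "K_d": "dimensionless", "n_d_mean": "dimensionless",
    "n_d_cv": "dimensionless", "a_d": "rate", "b_d": "dimensionless",
    "s_d": "dimensionless", "f_ms": "dimensionless", "K_s": "molar",
    "n_s": "dimensionless", "K_h": "dimensionless", "m_b0_mean": "mass",
    "m_b0_cv": "dimensionless", "a_mb": "dimensionless",
    "f_mr": "dimensionless", "Y_gx": "dimensionless",
    "kd_age_offset": "int", "mb_exponent_offset": "int",
}

#: config-file dimension of every StrainParams field
STRAIN_DIMENSIONS = {
    "strain_id": "str", "ec_Tsl1": "molar", "ea_Tsl1": "molar",
    "K_Tsl1": "dimensionless", "fr_Tsl1_cv": "dimensionless",
    "tps3_ratio": "dimensionless",
}
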