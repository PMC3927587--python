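"""Heterogeneity-network diagnostic and expression-sorted survival.

All heterogeneity in the model originates at replication (stochastic draws,
scarring, unequal damage split) and propagates through damage, expression and
trehalose to the terminal phenotype, heat-shock tolerance.  The diagnostic
turns off one source or link at a time
(:class:`~yeastabm.params.HeterogeneityToggles`), reruns the culture to a
statistically steady state, and attributes to each node/link the fractional
reduction of the variance of normalized tolerance:

    attribution = (var_base - var_ablated) / var_base

computed on nu-weighted real cells with H_t normalized by its population
mean (switchable to min-max).  Attributions can be negative: removing one
source can raise the variance through interactions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinetics
from .engine import run_simulation
from .exceptions import ConfigurationError, YeastABMError
from .params import HeterogeneityToggles
from .population import Population, StrainTable, weighted_var

#: named single-source/link ablations, in the order they appear in outputs
STANDARD_TOGGLES: dict[str, HeterogeneityToggles] = {
    "scar": HeterogeneityToggles(scarring_off=True),
    "dam": HeterogeneityToggles(damage_split_equal=True),
    "mb0": HeterogeneityToggles(randomize_mb0_off=True),
    "fr_tsl1": HeterogeneityToggles(randomize_frTsl1_off=True),
    "fr_tps3": HeterogeneityToggles(randomize_frTps3_off=True),
    "mu": HeterogeneityToggles(randomize_mu_off=True),
    "nd": HeterogeneityToggles(randomize_nd_off=True),
    "mf_es": HeterogeneityToggles(mean_field_es=True),
    "mf_mD": HeterogeneityToggles(mean_field_mD=True),
    "all": HeterogeneityToggles.all_on(),
}


@dataclass
class VarianceAttribution:
    """Per-ablation variance of normalized H_t and attribution vs base."""

    table: pd.DataFrame        # columns: toggle, replicate, variance, attribution
    summary: pd.DataFrame      # per toggle: mean/sd of variance & attribution
    base_variance: float       # mean base-case variance over replicates
    steady: bool               # False if any run looked non-steady (warned)


def normalized_tolerance_variance(pop: Population, strain_table: StrainTable,
                                  phys, G: float = 0.0,
                                  normalization: str = "mean") -> float:
    """nu-weighted variance of normalized heat tolerance.

    ``normalization='mean'`` divides H_t by its population mean (default);
    ``'minmax'`` rescales to [0, 1] over the population range.
    """
    if pop.n_agents == 0:
        return float("nan")
    m = pop.m
    f_T = np.divide(pop.m_T, m, out=np.zeros_like(m), where=m > 0)
    H_t = kinetics.heat_tolerance_kernel(f_T, phys.K_h)
    w = pop.nu.astype(float)
    if normalization == "mean":
        mean = np.average(H_t, weights=w)
        if mean == 0:
            return 0.0
        return weighted_var(H_t / mean, w)
    if normalization == "minmax":
        lo, hi = H_t.min(), H_t.max()
        if hi == lo:
            return 0.0
        return weighted_var((H_t - lo) / (hi - lo), w)
    raise ConfigurationError(f"unknown normalization {normalization!r}")


def run_ablation_suite(base_scenario, toggle_sets=None, n_replicates: int = 5,
                       seed: int = 0, normalization: str = "mean",
                       steady_window: int = 40,
                       measure_window: float = 20.0) -> VarianceAttribution:
    """Run base case + each ablation to steady state and attribute variance.

    Each replicate reruns every configuration with a common replicate seed so
    attributions are paired.  The scenario's duration acts as the burn-in and
    should cover at least ~10 mean generation times.  To damp sampling noise
    the reported variance is the average of the per-snapshot variances of
    normalized H_t over snapshots taken every 4 h during the final
    ``measure_window`` hours.  A drift of the recorded mean trehalose
    fraction over the last ``steady_window`` records larger than 10% flags
    the result as non-steady (warning, not an error).
    """
    if toggle_sets is None:
        toggle_sets = STANDARD_TOGGLES
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    rows = []
    steady = True
    snap_dt = 4.0
    eng = dataclasses.replace(base_scenario.engine, snapshot_every=snap_dt)
    base_scenario = base_scenario.replace(engine=eng)
    t_measure = base_scenario.engine.duration - measure_window
    for rep, rep_seed in enumerate(seeds):
        variances = {}
        for name, tog in [("base", base_scenario.toggles)] + \
                list(toggle_sets.items()):
            scen = base_scenario.replace(toggles=tog)
            res = run_simulation(scen, seed=int(rep_seed))
            if res.population.n_agents == 0:
                raise YeastABMError(
                    f"ablation run {name!r} (replicate {rep}) went extinct")
            steady &= _looks_steady(res.timeseries, steady_window)
            per_snap = [_frame_variance(frame, normalization)
                        for t, frame in res.snapshots if t >= t_measure]
            variances[name] = float(np.mean(per_snap)) if per_snap else \
                normalized_tolerance_variance(
                    res.population, res.strain_table, res.phys, res.env.G,
                    normalization)
        base_var = variances.pop("base")
        rows.append({"toggle": "base", "replicate": rep,
                     "variance": base_var, "attribution": 0.0})
        for name, var in variances.items():
            attribution = (base_var - var) / base_var if base_var > 0 \
                else float("nan")
            rows.append({"toggle": name, "replicate": rep, "variance": var,
                         "attribution": attribution})
    table = pd.DataFrame(rows)
    summary = (table.groupby("toggle", sort=False)
               .agg(variance_mean=("variance", "mean"),
                    variance_sd=("variance", "std"),
                    attribution_mean=("attribution", "mean"),
                    attribution_sd=("attribution", "std"))
               .reset_index())
    base_mean = float(table.loc[table.toggle == "base", "variance"].mean())
    return VarianceAttribution(table=table, summary=summary,
                               base_variance=base_mean, steady=steady)


def _frame_variance(frame: pd.DataFrame, normalization: str) -> float:
    """Variance of normalized H_t from one per-agent snapshot table."""
    H_t = frame["H_t"].to_numpy()
    w = frame["nu"].to_numpy(dtype=float)
    if normalization == "mean":
        mean = np.average(H_t, weights=w)
        return 0.0 if mean == 0 else weighted_var(H_t / mean, w)
    if normalization == "minmax":
        lo, hi = H_t.min(), H_t.max()
        return 0.0 if hi == lo else weighted_var((H_t - lo) / (hi - lo), w)
    raise ConfigurationError(f"unknown normalization {normalization!r}")


def _looks_steady(ts: pd.DataFrame, window: int) -> bool:
    tail = ts["mean_trehalose_frac"].dropna().tail(window)
    if len(tail) < 8 or tail.mean() == 0:
        return True
    half = len(tail) // 2
    drift = abs(tail.iloc[half:].mean() - tail.iloc[:half].mean()) \
        / abs(tail.mean())
    return bool(drift < 0.10)


# ----------------------------------------------------------------------
# expression-sorted survival (scaled-down flow-sorting protocol)
# ----------------------------------------------------------------------

def sorted_survival(pop: Population, strain_table: StrainTable, phys,
                    bins=((0.0, 0.001), (0.0, 0.01), (0.0, 0.1), (0.0, 1.0)),
                    H_a: float = 0.6) -> pd.DataFrame:
    """Heat-shock survival of Tsl1-expression-sorted fractions.

    Cells are ranked by e_Tsl1 from the highest expressor down; each bin
    ``(lo, hi)`` selects the real cells between cumulative population
    fractions lo and hi of that ranking (so ``(0, 0.001)`` is the top 0.1%).
    Survival of a bin is the nu-weighted fraction of its cells with
    H_t >= H_a, with agents straddling a bin edge counted fractionally.
    """
    if pop.n_agents == 0:
        raise YeastABMError("cannot sort an empty population")
    r = pop.rates(strain_table, phys, G=0.0)
    order = np.argsort(r["e_Tsl1"])[::-1]          # highest expression first
    w = pop.nu.astype(float)[order]
    survive = (r["H_t"][order] >= H_a).astype(float)
    W = w.sum()
    upper = np.cumsum(w)
    lower = upper - w
    out = []
    for lo, hi in bins:
        if not 0.0 <= lo < hi <= 1.0:
            raise ConfigurationError(f"bad bin ({lo}, {hi})")
        a, b = lo * W, hi * W
        overlap = np.clip(np.minimum(upper, b) - np.maximum(lower, a),
                          0.0, None)
        total = overlap.sum()
        if total < 1.0:       # narrower than one real cell
            raise YeastABMError(f"bin ({lo}, {hi}) contains no cells")
        out.append({"bin_lo": lo, "bin_hi": hi,
                    "cells": total,
                    "survival": float(np.sum(overlap * survive) / total)})
    return pd.DataFrame(out)


# ----------------------------------------------------------------------
# heterogeneity network export
# ----------------------------------------------------------------------

#: (toggle name, tail node, head node) for the DOT export; source toggles
#: attach to the node where their variability enters the network
_NETWORK_EDGES = [
    ("scar", "SCAR", "n_B"),
    ("dam", "DAM", "m_D"),
    ("mb0", "MB0", "m_b0"),
    ("fr_tsl1", "FR_TSL1", "e_Tsl1"),
    ("fr_tps3", "FR_TPS3", "e_Tps3"),
    ("mu", "MU", "mu"),
    ("nd", "ND", "mu"),
    ("mf_mD", "m_D", "expression"),
    ("mf_es", "e_s", "f_s"),
]

_STRUCTURAL_EDGES = [
    ("n_B", "m_D"), ("m_D", "m"), ("m_D", "mu"), ("expression", "e_Tsl1"),
    ("expression", "e_Tps3"), ("e_Tsl1", "e_s"), ("e_Tps3", "e_s"),
    ("f_s", "m_T"), ("mu", "m_T"), ("m_T", "H_t"), ("m", "H_t"),
    ("m_b0", "m"),
]


def heterogeneity_network_dot(attr: VarianceAttribution) -> str:
    """DOT digraph of the heterogeneity network; edge penwidth scales with
    the attributed contribution to tolerance heterogeneity."""
    weights = dict(zip(attr.summary["toggle"], attr.summary["attribution_mean"]))
    lines = ["digraph heterogeneity {", "  rankdir=LR;",
             '  node [shape=ellipse];']
    for name, tail, head in _NETWORK_EDGES:
        wgt = weights.get(name, float("nan"))
        pen = 0.5 + 6.0 * max(wgt, 0.0) if np.isfinite(wgt) else 0.5
        label = f"{name}={wgt:.3f}" if np.isfinite(wgt) else name
        lines.append(f'  "{tail}" -> "{head}" '
                     f'[penwidth={pen:.2f}, label="{label}"];')
    for tail, head in _STRUCTURAL_EDGES:
        lines.append(f'  "{tail}" -> "{head}" [penwidth=0.5, style=dashed];')
    lines.append("}")
    return "\n".join(lines)
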