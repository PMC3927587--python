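# Methods

`yeastabm` simulates populations of individual budding-yeast cells whose
heat-shock resistance is continuously graded and correlated with replicative
age, and asks when an age-correlated stress-protection strategy beats a
uniform or a randomly heterogeneous one.

## Single-cell model

Each cell carries three biomass compartments — structural `m_X`, damaged
`m_D` and trehalose `m_T` (all g dry mass; total `m = m_X + m_D + m_T`) —
plus a bud-scar count `n_B` and a cycle phase (unbudded/budding).  The mass
balances are

    dm_X/dt = (1 - f_s) mu m_X - k_d m_X
    dm_D/dt = k_d m_X
    dm_T/dt = f_s mu m_X

so growth adds mass at rate `mu*m_X` while damage only converts structural
to damaged mass.  The kinetic laws:

* growth: `mu = mu_mg_i * G/(K_g+G) * K_d^n / (K_d^n + (m_D/m)^n)` —
  Monod in extracellular glucose `G`, Hill-inhibited by the damage mass
  fraction, using the cell's individually drawn `mu_mg_i` and exponent
  `n_d_i`;
* damage: `k_d = a_d * n_B^b_d` — first order in `m_X`, accelerating with
  replicative age.  Under the default literal reading a virgin daughter
  (`n_B = 0`, `b_d > 0`) accrues no damage; set
  `kd_age_offset = 1` for the `a_d (n_B+1)^b_d` variant;
* expression: `e_Tsl1 = (ec + ea * fD/(K_Tsl1 + fD)) * fr_Tsl1_i` with
  `fD = m_D/m`, and analogously for Tps3 with every magnitude multiplied by
  `tps3_ratio`.  Expression is memoryless: the enzyme level adjusts fast
  relative to the damage dynamics, so no protein ODE is carried;
* synthesis: `f_s = f_ms * e_s^n_s/(K_s^n_s + e_s^n_s)` with
  `e_s = e_Tsl1 + e_Tps3`;
* tolerance: `H_t = fT/(K_h + fT)` with `fT = m_T/m`; a heat shock of
  severity `H_a` deterministically kills every cell with `H_t < H_a`.

A useful closed-form consequence: because `dm/dt = mu*m_X` and
`dm_T/dt = f_s*mu*m_X`, a cell with constant `f_s` relaxes to
`m_T/m -> f_s` exactly.  A constant-expression strain therefore survives a
shock of severity `H_a` iff its `f_s` exceeds `K_h*H_a/(1-H_a)`, which is
what makes protection against severe shocks expensive.

## Replication, aging, inheritance

Budding starts when `m` reaches the threshold `m_b`; division occurs at the
replication size proportional to the size at which budding actually started
(`f_mr` times it; for normal cells that size equals `m_b` up to one Euler
step — the distinction matters only for daughters of old mothers that are
born above their own threshold).  The daughter receives the mass
synthesized during budding; the mother keeps her budding-onset mass, gains
a bud scar, and retains fraction `s_d` of the damaged mass.  The remaining
non-damage mass of each cell is filled with `m_X` and `m_T` in the
pre-division X:T ratio, so all three compartments are conserved exactly and
a trehalose-rich mother bears a trehalose-rich daughter (protection decays
in the daughter line by growth dilution).  The mother's next threshold is
`m_b0_i * a_mb^(n_B)`; the generation-factor exponent convention is
switchable (`mb_exponent_offset = -1`).

At birth a daughter draws `m_b0_i`, `mu_mg_i`, `n_d_i` and the two
expression randomization factors from *global* truncated normal
distributions (mean-parameterized, sd = mean*CV, truncated to
(0, mean+3sd], rejection-sampled), so phenotype randomization is
non-heritable.  A CV of 0 returns the mean exactly and consumes no random
numbers; ablations that replace draws by their distribution mean use the
analytic truncated-normal mean (scipy) and are therefore mean-preserving.

## Population engine

Agents are super-individuals: one simulated cell standing for `nu`
identical real cells.  Each step runs, in fixed order: kinetics (explicit
Euler, rates at step start), budding/division, the glucose balance
`dG/dt = D(G_in - G) - sum(nu*mu*m_X)/(Y_gx*V)`, stochastic washout
(binomial thinning of `nu` with `p = 1-exp(-D dt)`, exact for any step),
scheduled heat shocks (agents die whole — within-agent phenotype is
uniform), agent-count rebalancing into `[N_min, N_max]` (splitting clones
high-`nu` agents; combining reassigns a `nu`-proportionally chosen victim's
multiplicity to a same-strain survivor, so per-strain real-cell counts are
conserved exactly), and recording.  Fixed seed implies bit-identical
output.

Default step `dt = 0.01-0.05 h` with a startup guard `max(mu)*dt < 0.05`;
a compartment driven negative raises a step-size error, and a division that
cannot accommodate its damage split aborts with the offending agent dumped.

## Default parameters

SI-grade calibration data are not available to this package, so the
defaults are repository choices inside literature-plausible ranges, all
overridable from the config file (units are tagged; internally h, g, L,
mol/L):

| parameter | default | reasoning |
|---|---|---|
| `mu_mg_mean` | 0.45 h^-1 | glucose-replete budding-yeast doubling ~1.7 h; comfortably above D = 0.15 h^-1 |
| `mu_mg_cv`, `n_d_cv` | 0.10 | catch-all for unresolved expression noise |
| `K_g` | 0.1 g/L | Monod half-saturation for glucose-limited growth |
| `K_d`, `n_d_mean` | 0.3, 2 | growth halves when damage reaches 30% of biomass, sigmoidal onset |
| `a_d`, `b_d` | 0.004 h^-1, 1 | damage-growth inhibition reaches half-effect near age 10-12, consistent with a replicative lifespan of ~20+ divisions and a roughly linear damage-vs-age curve |
| `s_d` | 0.7 | asymmetric damage retention by the mother |
| `f_ms`, `K_s`, `n_s` | 0.4, 2 uM, 2 | trehalose can reach ~40% of dry mass at saturating enzyme; half-max at ~1 uM per subunit |
| `K_h` | 0.05 | 5% trehalose gives tolerance 0.5; severe shocks (H_a = 0.85) then demand m_T/m > 0.28 |
| `m_b0_mean`, `m_b0_cv` | 15 pg, 0.15 | daughter budding threshold |
| `a_mb`, `f_mr` | 1.1, 1.65 | mothers grow per generation; daughter/mother size ratio ~0.65 |
| `Y_gx` | 0.5 g/g | biomass yield closing the glucose balance |
| `K_Tsl1` | 0.2 | age-dependent expression activates between newborns (fD ~ 0.015) and ~2-division-old cells (fD ~ 0.03) — the boundary that lets a hedging strain leave its youngest cells unprotected |

The default "wild-type" strategy (`ec = 0.1 uM`, `ea = 3 uM`,
`fr_Tsl1_cv = 0.3`) expresses all three routes: weak constant, dominant
age-dependent, moderate stochastic.

## Virtual experiments

**Heterogeneity network.**  All heterogeneity originates at replication.
Each toggle removes one source (scarring, unequal damage split, one of the
stochastic draws) or cuts one link (population-average `e_s` into the
synthesis law; population-average `m_D/m` into the expression law).  Runs
burn in for >= 10 mean generation times (~46 h at D = 0.15 h^-1; the suite
uses 72 h), then the variance of `H_t`, normalized by its population mean
(min-max normalization is available), is averaged over per-snapshot
estimates from the final 20 h to damp sampling noise.  Attribution is the
paired fractional variance reduction versus the base case; negative values
are reported as such (removing one source can raise variance through
interactions).  Replicates pair base and ablated runs by seed.

**Expression-sorted survival.**  Cells ranked by `e_Tsl1` from the top;
quantile bins (top 0.1%, 1%, 10%, all) are filled `nu`-exactly with
fractional edge agents; survival is the weighted fraction with
`H_t >= H_a`.  This is a scaled-down analogue of flow-sorting experiments:
it reproduces orderings, not absolute axis values.

## Competition experiments

Strains share one chemostat (D = 0.15 h^-1, shared glucose pool) under a
periodic shock schedule; the match winner has the highest final real-cell
count (exact ties broken uniformly with the match seed).  Tournaments
randomly partition the field into matches of up to 10, advance winners, and
repeat; the full design is a 10x10x10 grid (1,000 strains), the desk-scale
preset a 5x5x5 grid with 5-day matches used by the test suite and the
acceptance script.

Desk-scale choices, made from the model's own arithmetic:

* **Grid levels.**  Demographic noise in a 5-day match at desk agent counts
  (whole-agent division and washout granularity; effective population size
  is the per-strain agent count) is a few tenths of a log unit of final
  density.  Grid levels are therefore spaced so every nonzero expression
  level costs at least ~5-10% of growth (>= ~1.5 e-folds of selection per
  match): ec in {0, 0.6, 1.2, 2, 3.5} uM, ea in {0, 6, 10, 16, 26} uM,
  CV in {0, 0.25, 0.5, 0.75, 1}.
* **Shock phase offset 24 h.**  Inocula start trehalose-free
  (`m_T/m -> f_s` only after ~1-2 generations), so a shock in the first
  generation would kill even a fully protected constant strain.
* **Conditions.**  Severities/frequencies are placed around the model's own
  protection thresholds: low severity (H_a = 0.65, F_h = 0.06 h^-1, ~5
  shocks/match) sits between the young-cell trehalose of an age-dependent
  strain and the uniform level of the cheapest constant strain, so constant
  expression protects everyone at the lower cost; high severity
  (H_a = 0.85) demands m_T/m > 0.28, which a constant strain can only buy
  with ~30% of its growth, while an age-dependent strain provisions only
  its older (slower-growing, less valuable) cells — at low frequency
  (F_h = 0.012 h^-1, one shock/match) the per-shock loss is paid rarely and
  hedging wins, at high frequency (F_h = 0.25 h^-1, shocks every 4 h) the
  repeated losses overwhelm it and constant expression wins again.  A
  5-day match cannot hold a shock of the full design's 7-day period, hence
  the rescaled frequencies.

## What the synthetic conditions do and do not show

The generator emulates clonal, glucose-limited, well-mixed liquid culture
with deterministic shock mortality and exactly three stochastic expression
routes.  It does not emulate measurement noise (flow-cytometry spread,
negative fluorescence readings), induced heat-shock response, stationary
phase, spatial structure, or mutation between tournament rounds.  Passing
tests therefore demonstrate the internal logic of age-correlated bet
hedging under the stated assumptions — not quantitative prediction for any
particular strain background.  Desk-scale tournament outcomes are
statistical: criteria are majority-over-replicates statements, and the
sparsely populated oldest age classes carry visible sampling noise.

## Numerical notes

* Explicit Euler is first-order; at the chemostat operating point the 24-h
  single-cell trajectory error at dt = 0.01 h is ~0.3% and halves with the
  step.
* The chemostat-balance check uses the specific total-biomass growth rate
  `mu*m_X/m` (recorded as `mean_mu_spec`): only structural mass
  synthesizes, so the kinetic `mu` exceeds the dilution rate by the factor
  `m/m_X` at steady state, while standard chemostat balance pins the
  biomass-weighted specific rate at D.  The nu-weighted mean sits 2-4%
  above D (small cells grow relatively faster and count per capita).
* Glucose is clipped at zero with a warning counter if uptake overshoots
  within a step.
* The steadiness flag compares half-window means of the recorded trehalose
  fraction; heavily ablated (near-homogeneous) populations divide in
  partial synchrony and can trip it while being statistically stationary —
  it is a warning, not an error.
* Seeds: every stochastic component draws from one `numpy` Generator per
  run; replicate and match seeds are spawned from `SeedSequence` and kept
  below 2^31.
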