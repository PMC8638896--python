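# Methods

This note documents the mathematical model implemented in `assemblysim`, the
numerical methods, and every modelling convention the package had to choose
where the source description leaves a gap. Conventions marked **(package
choice)** are defaults that can be overridden through the public API.

## 1. Model

The community is a MacArthur-type consumer–resource system with S microbial
species (guilds) and M explicit resource pools:

```
dN_i/dt = Σ_α F_i · G_iα · C_iα · R_α · N_i  −  m_i · N_i            (1)
dR_α/dt = H_α − Σ_i F_i · G_iα · C_iα · R_α · N_i
          + l · Σ_{β,i} F_i · G_iβ · D^i_αβ · C_iβ · R_β · N_i       (2)
```

- `N_i` — biomass of species *i*; `R_α` — amount of resource α.
- `C` — per-species uptake-rate matrix; every row lies on the M-simplex.
- `F_i = s_i / (K_i + s_i)` — essential-symbiont gating, with `s_i` the
  summed biomass of the species essential for *i* (an S×S boolean network
  `E`). A species with an empty essential set has `F_i = 1`, so the
  no-symbiont control reduces to ungated consumer-resource dynamics.
- `G_iα = 4·I·L_i/(L_i+I)²` — specialisation for a supplied-resource
  concentration, applied only to species specialised for the supplied
  resource at the supplied-resource column; 1 everywhere else, and
  identically 1 when concentration specialisation is disabled. `G` is a
  function of the constant supply concentration `I`, not of the dynamic
  `R_α`, and is computed once per run.
- `D^i` — per-species stoichiometric matrix; `D^i[α, β]` is the fraction of
  species *i*'s uptake flux of resource β secreted as resource α. Columns
  lie on the M-simplex (or are all-zero for a resource nobody converts).
- `H_α = (I_α − R_α)/τ_α` — chemostat supply/washout, applied to **all**
  resources with `I_α = 0` off the single supplied resource **(package
  choice)**: without washout of byproducts no steady composition exists.
- `l` — secretion fraction (see §3).

Baseline parameter scales: `m = 0.05`, `K = 0.01`, `τ = 1`, `L ∈ {1, 100}`,
`I ∈ {1, 100}`, `μ = 0.4`, `σ = 0.01`.

### Byproduct-term index convention

The secretion term converts **consumed** resource β into secreted resource α
(`D^i_αβ C_iβ R_β`), the convention of the Goldford-style cross-feeding
lineage. An alternative index placement (secretion proportional to uptake at
the secreted resource itself) is available behind
`ModelParameters.byproduct_literal_reading` for sensitivity checks; it has no
analytic Jacobian and is numerically fragile at high supply.

## 2. Ensemble sampling

One *parameter set* is a draw of `(C, D, E)`:

- `C_{i,f_i} ~ Normal(μ, σ²)` truncated to [0, 1] by resampling; off-target
  entries are Uniform(0,1) draws rescaled so each row sums to 1.
- `D^i` columns are independent flat-Dirichlet points on the M-simplex
  **(package choice; concentration exposed as a knob)**. A species may
  secrete its own specialised resource.
- `E`: each species draws `n_essential` partners uniformly without
  replacement from the pool of species specialised for **other** resources
  (never itself); `"all"` marks the entire pool.

Each parameter set is integrated from `n_replicates` initial biomass vectors
with i.i.d. Uniform(0.01, 1) entries; replicates share `(C, D, E)` exactly.
Initial resources are `R_α(0) = I_α` **(package choice, configurable)**.

Seeding uses a `SeedSequence` hierarchy (master → per-set → {parameter
stream, per-replicate streams}), so changing `n_replicates` never changes
which parameter sets are drawn, and every run is bit-reproducible from
`(config, seed)`.

### Community layouts

- **Uniform** — M = 10 resources × k specialists each (k = 10 → S = 100);
  concentration specialisation disabled.
- **Concentration-adapted** — the supplied resource has 45 specialists
  adapted to one concentration and 5 to the other (`L ∈ {100, 1}`), plus 10
  specialists for each of the 9 other resources (S = 140).

## 3. Secretion fraction (deviation from the printed equations)

With column-stochastic `D` and `l = 1`, total secretion equals total
consumption, so `d(ΣR)/dt = (I_tot − ΣR)/τ`: the total resource pool is
pinned at the supply total no matter how much biomass exists. Because every
row of `C` sums to 1, the resource vector then relaxes to a uniform level at
which every species' per-unit uptake is equal — no competitive exclusion, no
extinction, and near-constant replicate similarity (~0.67) in **every**
condition, contradicting all of the contrasts this model is meant to produce.
Verified empirically before any tuning: the full-strength equations give mean
similarity 0.675 with zero extinctions for both the no-symbiont and
10-symbiont conditions.

The experiments therefore use a secretion fraction `l = 0.8` — the standard
leakage value in the cross-feeding literature this model family descends
from — which makes biomass a net resource drain and restores selection.
`ModelParameters` defaults to `l = 1` (the printed form); the experiment
drivers set 0.8.

## 4. Supply concentration for the uniform layouts

The uniform-community experiments (essential sweep, richness sweep) do not
define a supply concentration. The package uses `I = 1` **(package
choice)**: the washout design pins attainable resource levels at order `I`,
and only at order-1 supply can per-unit uptake (≤ ΣC·R ≈ I) balance the
death rate in a bounded steady state. At `I = 100` the uniform community
enters a high-biomass regime with no exclusion (see §7).

## 5. Numerical integration

- Stiff solver (`scipy.solve_ivp`, BDF) with an **analytic Jacobian** of the
  stacked (N, R) system; RK45 and LSODA available as config fallbacks.
- Positivity guard: the right-hand side is evaluated on the state clipped at
  zero.
- Integration proceeds in growing windows (100 → doubled up to 4000 time
  units) up to `t_max = 40 000`.
- **Convergence rule (package choice):** at each window boundary the run is
  converged when both the composition derivative
  `max_i |d(N_i/ΣN)/dt| < 10⁻⁶` and the relative total-biomass drift
  `|Σ dN|/ΣN < 10⁻⁶` hold. The composition criterion (rather than a raw
  `|dN_i|` test) also covers the balanced-exponential-growth regime, where
  the composition freezes while total biomass still grows.
- **Biomass rescaling:** when total biomass exceeds 10⁸ (detected by a
  terminal solver event) the biomass vector is rescaled to total 10⁶. At
  those biomasses the symbiont factors are saturated (`s_i ≫ K`), so the
  composition dynamics are exactly invariant under this rescaling; it only
  prevents floating-point overflow in the balanced-growth regime.
- **Extinction threshold:** species with final `N_i < 10⁻⁶ × ΣN` are set to
  0 before normalising the surviving biomass into the final composition.
  All-extinct replicates yield an invalid composition that is dropped (and
  logged) from similarity pairs, never imputed.

## 6. Stochasticity quantification

Renkonen similarity of two relative-abundance vectors is
`1 − ½ Σ|x_i − y_i|` (the complement of Bray–Curtis dissimilarity on
proportions). Each parameter set contributes all C(n_replicates, 2)
unordered pairs; the ensemble statistic is the mean over pooled pairs. A
**pattern** occurred in a parameter set when at least one replicate pair has
similarity ≥ 0.9; the pattern probability is the fraction of parameter sets
with a pattern (the per-replicate counts are also reported so the
alternative denominator is available).

Experiment scale: the study protocol is 100 parameter sets × 10 replicates
per condition; the CI scale (`--fast`) is 20 × 10 and the acceptance script
defaults to 20 × 10 **(package choice: problem sizes are the package's own
runtime/precision trade-off)**.

The same machinery applies to empirical sample-by-taxon tables after
collapsing taxonomy to genus level and converting to per-sample relative
abundances (`assemblysim.abundance`).

## 7. Known limitations

**High-supply neutral regime.** At supply `I = 100` the inflow of 100
mass/time forces an equilibrium total biomass of order 10³–10⁴ for any
`l < 1`. At that biomass, aggregate cross-feeding replenishes every resource
pool and the resource vector relaxes toward the uniform level `R ≈ m`, at
which — because all rows of `C` sum to 1 and death rates are identical —
every surviving species' growth exactly balances death regardless of its
uptake profile, and the essential-symbiont factors are saturated
(`s_i ≫ K = 0.01`). The community freezes into a neutral state whose
composition mostly reflects the transient: species whose supplied-resource
uptake is suppressed by `G` die, everything else persists. Consequently the
high-supply conditions of the concentration experiment are substantially
*less* stochastic/extinction-prone in this implementation than the published
values for them (agreement-high similarity ≈ 0.67 here vs 0.37 reported;
high-supply disagreement patterns are correspondingly rare). Sparser
stoichiometric tensors, the alternative byproduct index reading, and a
dynamic-concentration reading of `G` were all evaluated and none breaks this
regime; reproducing the published high-supply behaviour appears to require a
mechanism (e.g. a biomass scale small enough for `K` to bite at high supply)
that is not recoverable from the printed equations and parameters. The
low-supply conditions and all uniform-layout results reproduce the published
contrasts.

**Not simulated:** serial-batch passaging (the ex situ dilution protocol),
spatial structure, demographic noise, evolution; empirical similarity values
that depend on external sequence data and taxonomy-database versions.
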