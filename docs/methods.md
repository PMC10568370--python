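# Methods

## Model and adjustment problems

The package operates on constraint-based metabolic models: a
stoichiometric matrix `N` (m metabolites × n reactions), steady state
`N r = 0`, flux bounds `lb <= r <= ub` in mmol/(gDW·h), and optional
general linear constraints `A r <= b` (accepted as opaque input, e.g.
enzyme-allocation constraints produced elsewhere). Measurements fix rates
`r_i = f_i` for a set `F`; a reaction whose model bounds already satisfy
`lb = ub` is rejected as a measurement target, since its rate is not free
to begin with.

Feasibility is restored by correction variables, enabled per class:

* **Fluxes.** `r_i = f_i − δ_i` with `δ_i` free (quadratic mode) or split
  into `δ_i⁺, δ_i⁻ ≥ 0` (linear mode). A measurement with `sd = 0` is
  *exactly known*: it gets no correction variable and is hard-fixed.
* **Biomass components.** For each component `k` of the biomass reaction
  with coefficient `c_k` (signed, consumed < 0) the steady-state row gains
  `β_k μ`, equivalent to replacing `c_k` by `c_k + β_k`. Two side
  constraints: mass conservation `Σ_k β_k MW_k = 0` keeps the biomass at
  its nominal 1 g/gDW, and `|β_k| ≤ ρ |c_k|` (default ρ = 0.3,
  configurable up to 1) prevents components from being eliminated or
  produced. The growth rate `μ` must be measured and is always hard-fixed
  when this class is active — the constraint is otherwise bilinear in
  `β_k μ`.
* **GAM.** The five GAM species (ATP, ADP, H2O, Pi, H+) have
  `c_k = c_k,B + c_k,GAM` with `|c_k,GAM| = g`; signs are taken from the
  hydrolysis direction (ATP, H2O consumed; ADP, Pi, H+ produced). One
  shared variable `β_GAM ∈ [−1, 1]` shifts all five coherently by
  `γ·sign(c_k,GAM)·β_GAM`, with `γ = min(g, user maximum)` the maximal
  allowed change; the adjusted GAM is `g' = g + γ β_GAM`. The GAM value
  is read off as the ADP coefficient of the biomass reaction (ADP is
  produced there only by the embedded hydrolysis); species are matched by
  id stem (`atp`, `adp`, `h2o`, `pi`, `h`) with optional compartment
  suffix, overridable per scenario. If none of the five species appears
  in the biomass reaction, GAM is taken as 0 (e.g. after extraction into
  a separate reaction); ADP absent while other GAM species are present is
  ambiguous and raises.

Pure GAM carriers — species whose biomass part `c_k,B` is zero — are not
adjustable components: their coefficients move only through `β_GAM`, and a
relative weight `1/c_k,B` would be undefined. Mass conservation is
unaffected because the hydrolysis stoichiometry is mass balanced.

Objectives: quadratic `Σ w_i δ_i² + Σ z_k β_k² + w_GAM β_GAM²`, linear
the weighted sum of the split halves. Enabled classes share one merged
objective.

## Weights

* Flux schemes: `sd_reciprocal` (default) sets `w_i = (1/sd_i)/s`, with
  the same `w_i` multiplying `δ_i²` in the QP and `|δ_i|` in the LP;
  `sd_reciprocal_squared` (`1/sd_i²`) is available as an option.
  `relative` sets `w_i = (1/|f_i|)/s`, minimizing relative changes; a
  measured 0 under this scheme is hard-fixed. The scale factor `s`
  (default 1) divides all flux weights, so lowering it makes flux
  corrections more expensive relative to biomass/GAM changes. A
  measurement without an sd under an sd-based scheme falls back to the
  relative weight for that entry, with a warning.
* Biomass schemes: `relative_molar` (default) minimizes relative molar
  changes, `z_k = 1/c_k²` (QP) or `1/|c_k|` (LP); `relative_mass`
  minimizes gram changes against the 1-g total, `z_k = MW_k²` (QP) or
  `MW_k` (LP). Custom per-component mappings are accepted.
* The normalized `β_GAM` enters the objective directly with a
  configurable weight (default 1).

## Solvers and numerics

LPs run through `scipy.optimize.linprog` (HiGHS) with deterministic
default settings; feasibility tolerance is the solver's (~1e-9 absolute).
QPs have diagonal positive-semidefinite Hessians (reaction rates carry no
cost); they are solved by `trust-constr` from an LP-found feasible point,
after replacing the equality block by an SVD-derived full-row-rank
equivalent (steady-state matrices routinely contain redundant rows, and
fixing every flux makes the system overdetermined). The iterate is then
polished: the active bounds/inequalities are guessed at increasing
tolerances (1e-7, 1e-5, 1e-3), each guess is re-solved exactly through the
equality-constrained KKT system (least-squares, handling the
rank-deficient zero-cost directions), and a polish is accepted only when
it is feasible (1e-6 absolute) and not worse — over-guessing the active
set is therefore safe. This yields optima that agree with independent
solvers (GLPK for LPs, multi-start SLSQP for QPs) to ~1e-12 relative on
the random-network suite.

LP optima can be non-unique. The objective value is canonical; an
optional post-pass fixes the objective at `OV·(1 + 1e-6)` and
minimizes/maximizes a named quantity (the adjusted GAM, or any linear
function of the fluxes) to report its range over the optimal face. QP
optima of strictly weighted corrections are unique and the post-pass
refuses them.

A note on monotonicity: adding adjustment classes under the shared merged
objective never increases the optimum *when the treatment of the growth
rate is the same on both sides*. Enabling biomass/GAM adjustment
hard-fixes the growth rate, so comparing against a flux-only run in which
growth was soft is not an embedding and the objective can go either way;
the comparison suites therefore carry the growth rate with `sd = 0`.

## Biomass introspection

`check_biomass_mass` evaluates `−Σ c_k,B MW_k` and warns when it misses
1 g by more than 5e-3 g (published biomass reactions rarely sum exactly;
the tolerance is configurable). Molecular weights come from metabolite
formulas (flat Hill notation; `R`-group and polymer formulas are rejected
at parse time and tolerated as formula-less on SBML import) and a fixed
IUPAC-2021 standard-atomic-weights table bundled with the package, so
elemental results are bit-reproducible.

`gam_to_separate_reaction` removes the `c_k,GAM` terms from the biomass
reaction and adds a reaction `g ATP + g H2O → g ADP + g Pi + g H+`; the
caller measures its rate equal to the growth rate. `lump_biomass`
collects organic components into macromolecule pseudo-metabolites
(protein, RNA, ...) entering the biomass reaction with coefficient −1 and
produced by one synthesis reaction each carrying the original
stoichiometry — the pseudo-metabolite's molecular weight then equals the
grams of that class per gDW; per-class maintenance ATP is added to the
synthesis reaction and subtracted from the biomass GAM, leaving the
growth optimum unchanged.

## Diagnostics

The elemental balance sums, per element, the net production of the
measured exchange species (`coefficient × f_i`) minus the biomass drain
`μ × content_e`, where `content_e = −Σ c_k,B count_e(k)`; GAM terms net
to zero. Only elements are balanced, not charge, and measured internal
reactions are excluded with a warning — they move matter inside the
system, not across its boundary. Exchanges are recognized as reactions
with exactly one participating species. The FVA pre-check
minimizes/maximizes each measured reaction under the model constraints
alone and flags measurements outside their closed ranges; unbounded
directions report ±inf.

## Synthetic models

The toy generator emulates the standard core-model anatomy: glucose
uptake, respiration-style catabolism producing a configurable ATP yield,
one synthesis route per biomass component (carbohydrate-like `(CH2O)_n`
formulas with seed-drawn sizes 1–6), and a biomass reaction with embedded
GAM. Mass fractions are drawn from a Dirichlet(2) and the coefficients
solved as `c_k = −p_k/MW_k`, so the biomass weighs exactly 1 g by
construction; the GAM value, ATP yield (default 20 mmol/mmol glucose),
synthesis cost (2 mmol ATP/mmol component) and substrate uptake limit
(10 mmol/(gDW·h)) are parameters with defaults in the physiological range
of heterotrophic bacteria. Measurement noise is independent Gaussian per
reaction with stated sds, seeded through `numpy.random.default_rng`.

What the generator does *not* emulate: realistic network redundancy
(dozens of alternative pathways and exchange outlets), cofactor diversity
beyond the adenylate pool, nitrogen/phosphate assimilation, measured-sd
correlation structure, or thermodynamic constraints. Passing the property
suite therefore demonstrates the correctness of the optimization
machinery and its bookkeeping — not that adjustments inferred on a
genome-scale model are biologically unique; on real models the
degrees of freedom are larger and alternate optima more common, which is
why the LP post-pass and the guideline's side-by-side comparison exist.

The random ≤5-reaction networks used for solver cross-checks draw sparse
integer stoichiometries and measurements as a perturbed FBA vertex, so
the fixed systems are generically infeasible with a nonzero correction
optimum.

## Known limitations

* The QP path is dense; it is sized for core models and measurement sets,
  not for genome-scale Hessians with tens of thousands of variables.
* GAM species detection relies on id stems plus overrides; models with
  fully opaque ids require explicit role mappings.
* Biomass adjustment requires molecular weights for all adjustable
  components; formula-less components must be given weights explicitly.
* Charge balancing and full network consistency checking (leaks, orphan
  metabolites) are out of scope — the diagnostics assume the model is
  internally sound and interrogate only the measured boundary.
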