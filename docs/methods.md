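# Methods

## Constraint-based core

The package works on box-constrained steady-state flux models: maximize
(or minimize) `c·v` subject to `S·v = 0` and `lb <= v <= ub`, with `S`
the stoichiometric matrix (rows = compartmented metabolites, columns =
reactions) and fluxes in mmol/gDW/h. The LP is solved with the dual
simplex of HiGHS through `scipy.optimize.linprog` with feasibility and
optimality tolerances of 1e-9; fluxes below 1e-6 are reported as zero.
Reversibility is encoded purely through bound signs; exchange reactions
are boundary reactions touching exactly one metabolite; bounds missing
from an input file default to 0/±1000 by reversibility, the usual COBRA
convention.

**Shadow prices.** The dual of each mass-balance row is reported with
the convention `sp_i = dZ*/db_i` for `S·v = b`, where `b_i > 0` forces
net accumulation of metabolite `i`. Under maximization a *negative*
shadow price therefore marks an objective-limiting metabolite (external
supply would raise the optimum). A metabolite "affects the objective"
when `|sp| > 1e-9`. Two caveats are inherent to LP duality and are
surfaced rather than hidden: duals of degenerate optima are not unique,
so affecting-metabolite *counts* can depend on the solver's returned
vertex; and the package also ships a finite-difference probe
(`shadow_price_finite_difference`) as a solver-independent check for
non-degenerate cases. Species-level counts collapse compartmented
copies: a species counts as affecting when any compartment form does.

**FVA and the 40 % rule.** Flux variability analysis solves, for every
reaction, a minimization and a maximization under the original
constraints plus `c·v >= f·Z*`. The default `f = 1.0` pins the
objective at its optimum; this is deliberate, since a secondary
substrate only *has* to carry flux on the optimal face (otherwise its
minimum is trivially zero). The flux range is `|v_max − v_min|`.
Comparing two conditions, a reaction is *activated* when its range
rises from below 1e-6 to above, *deactivated* in the converse case,
and *changed* when the range moves by at least 40 % of its
before-range (inclusive, with a 1e-9 relative epsilon so that exact
40 % cases do not fall to float roundoff). Both full-set tallies and
tallies over a user-supplied curated reaction subset are reported,
because published subsets of "properly defined" reactions are not
always enumerated in model annotations.

## The gluconate study pipeline

The question the pipeline asks: what does feeding D-gluconate into the
hexose monophosphate shunt (HMS) via gluconokinase do to a red-cell
metabolic network whose objective is the ATP-dependent Na+/K+ pump?

`add_gluconate` extends a model with exactly three reactions —
exchange `EX_glcn_e`, passive transport `GLCNt`, and gluconokinase
`GNTK: atp_c + glcn_c -> adp_c + 6pgc_c + h_c` (the proton follows
BiGG convention and is dropped when the host model tracks no cytosolic
proton). The added species carry chemical formulas so the kinase step
can be checked for carbon/phosphorus balance. The exchange is created
closed: the extended-but-closed model is the baseline condition, so
both FVA runs share one reaction set.

Study constraints: glucose uptake fixed (both exchange bounds) at
1.12 mmol/gDW/h; glucose-6-phosphate dehydrogenase floated at 5–10 %
of that uptake; the pump located by its stoichiometry (ATP hydrolysis
coupled to Na+ export and K+ import) rather than by a hard-coded id,
with `NaKt` as a fallback.

Analyses around the extension:

* **Robustness** — gluconate uptake forced (both bounds) over a grid,
  FBA re-solved per point; the uptake where the objective first
  reaches its maximum and the last uptake before decline are bisected
  to 1e-3. Infeasible grid points are recorded per point, not fatal.
* **Shadow comparison** — per-metabolite duals with the exchange
  closed vs open, with affect flags and species-level counts.
* **Relaxation scan** — each exchange/transport bound widened one at a
  time, FBA re-solved, and reactions whose relaxation moves the
  objective by more than 1e-6 flagged. Exchanges are opened fully to
  ±1000 (medium availability is a modelling choice); internal
  transports keep their directionality and only have magnitudes
  widened — reversing an irreversible active transporter would
  manufacture thermodynamically impossible energy-generating loops
  (observed concretely on the toy network when a reversed ATP-driven
  exporter pairs with the passive outlet).

## The synthetic toy network

`make_toy_network` builds a 15–25 reaction glycolysis+HMS model that
reproduces the study's qualitative mechanics at desk scale, with
defaults chosen once as the study conditions: glucose fixed at 1.12,
HMS entry floated at 5–10 % of it, a glutathione-like NADPH demand of
0.2, non-oxidative pentose-phosphate recycling (`6 p5p -> 5 g6p`)
capacity-limited at 0.03, a passive CO2 outlet capped at 0.5 backed by
an ATP-consuming export, an ATP-neutral ribose-phosphate salvage
(`p5p + adp -> atp`, the lumped nucleotide-pool route), and an
ATP-driven pump objective.

These pieces were chosen so the network exhibits, provably, the three
regimes of the full model: while recycling has spare capacity each
gluconate nets +2/3 ATP (objective rises); once recycling saturates the
salvage route makes marginal gluconate exactly ATP-neutral (plateau,
i.e. a degenerate optimal face whose gluconokinase FVA span equals the
two breakpoints); past the CO2 cap every further unit pays one ATP for
active export (sharp drop to infeasibility). The breakpoints have
closed forms used as test oracles: the plateau starts at
`6·recycle_cap − 0.05·glucose` = 0.124 and ends at
`co2_cap − 0.05·glucose` = 0.444 mmol/gDW/h.

What the toy does *not* emulate: the electroneutral chloride/
bicarbonate antiport coupling that makes the real pump's decline a
bicarbonate story, osmotic/ionic balance, and the ~470-reaction
redundancy of a genome-scale network (which is what makes real
affecting-metabolite counts large and solver-sensitive). Passing toy
tests therefore demonstrates the correctness of the machinery and the
qualitative mechanism, not the deposited model's exact counts; those
are recomputed only when the deposited SBML file is supplied (see the
README's reproduction section).

## Enzyme kinetics

The coupled assay is modelled as Michaelis–Menten consumption of
gluconate by gluconokinase at saturating co-substrate, followed by a
first-order (6PGDH) coupling step producing NADPH 1:1:

    dS/dt  = −Vmax·S/(Km+S)
    dP/dt  =  Vmax·S/(Km+S) − k_c·P
    dNADPH/dt = k_c·P

integrated with LSODA (rtol 1e-8), converted to absorbance at 340 nm
by Beer–Lambert (ε = 6220 M⁻¹cm⁻¹, path 0.5 cm — configuration, not
constants, since plate path lengths vary), on top of a 0.04 AU blank.
Defaults: enzyme 0.25 µM, substrate series 0.1–10 mM, reads every 1 s
for 240 s, coupling rate 5 s⁻¹ (a coupled assay requires the indicator
step to be non-limiting; a lag above 5 % of the assay duration
triggers a warning). The closed-form Lambert-W solution of the
depletion ODE serves as an independent oracle in the tests.

**Initial rates.** Absorbance is converted to NADPH through a standard
curve and the rate taken as the least-squares slope of a contiguous
early window restricted to the first 10 % of substrate conversion.
Windows of at least `min_points` reads (default 10 at the 1 s
interval) are scored by R²; because a depleting curve gets locally
*straighter* with time, a pure R² argmax drifts away from t = 0 and
biases rates low, so among windows within 1e-4 of the best R² the
earliest is taken. Residual bias of the estimator is a few percent at
S ≈ Km and negligible at saturation; it is the dominant contribution
to the ~+7 % Km bias of the full pipeline, which sits comfortably
inside the ±18.5 µM uncertainty band used as the recovery criterion.

**Fitting.** `v = Vmax·S/(Km+S)` is fit by nonlinear least squares
(lmfit), initialized at Vmax₀ = max rate and Km₀ = substrate of the
half-maximal rate, with kcat = Vmax/[E] and kcat/Km derived at full
precision (printed-table roundings are not matched digit-for-digit).
A fitted Km outside the sampled substrate range warns. The
double-reciprocal (Lineweaver–Burk) transform is provided for plotting
only, never for estimation.

**Replicates.** The generator emulates six biological replicates each
stored as the mean of three technical reads, with per-read Gaussian
noise of 2 % CV of the instantaneous absorbance (photometric noise
grows with the signal it rides on). Rates are extracted per replicate
and averaged per concentration before fitting.

## Plate screening

Each compound's background-corrected signal is
`delta = sample − control` (matched no-enzyme control per compound);
phosphorylation activity depletes ATP and hence luminescence, so hits
are strongly *negative*. z-scores standardize deltas over the whole
plate — hits included, matching the plate-mean convention — using the
sample (n−1) standard deviation by default, with population and
median/MAD variants exposed. p-values are one-tailed lower-tail
normal probabilities; printed p-values in the literature often imply
unrounded z-scores, so p is always recomputed from the full-precision
z rather than compared digit-wise. The synthetic 122-compound plate
spikes two hits whose ATP-depletion fractions (0.86, 0.70) were chosen
once so that, at 2 % lognormal noise, they score near z = −8.2 and
−6.7; hit calling at z ≤ −3 returns exactly these.

## Numerical and scale choices

Problem sizes were picked so the whole suite and the acceptance script
each run in well under a few minutes: the toy network has 21 reactions
(two FVA sweeps ≈ 90 LPs), robustness grids use steps of 0.02 with
bisection refinement, and the kinetics recovery experiment uses 200
seeded trials of 7 substrate concentrations × 6 replicates. All
generators are seed-deterministic; every analysis consumes the same
formats the generators emit, so the full pipeline runs without any
external input. The deposited red-cell model reproduction is the one
computation that needs a download, and it is optional everywhere.

## Known limitations

* Shadow-price counts on degenerate genome-scale models depend on the
  solver vertex; the package documents and flags this instead of
  post-processing duals into a canonical choice.
* The objective-pinning constraint `c·v >= f·Z*` assumes the usual
  positive-optimum case when `f < 1`.
* The initial-rate estimator is a chord estimator: it inherits a small
  systematic underestimate at substrate concentrations near Km, which
  propagates into a small positive Km bias in the recovery study.
* The SBML reader targets constraint-based models (FBC v2 or legacy
  kinetic-law bounds); kinetic SBML in general is out of scope, as is
  writing SBML.
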