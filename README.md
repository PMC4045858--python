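# gluconet

Constraint-based analysis of gluconate metabolism in the human red
blood cell, together with the enzymology that motivates it.

D-gluconate is phosphorylated by gluconokinase (GntK) to
6-phospho-D-gluconate, which enters the hexose monophosphate shunt
(HMS) at the 6-phosphogluconate dehydrogenase step — a carbon route
into the NADPH-producing arm of metabolism that bypasses
glucose-6-phosphate dehydrogenase. `gluconet` is for systems
biologists and enzymologists who want to ask, quantitatively, what
such a feed does to a steady-state metabolic network, and to analyse
the wet-lab side of the same question (coupled kinetic assays and
substrate-specificity plates).

The package covers:

* **Model core** — stoichiometric models with box flux bounds read
  from SBML (FBC v2 or the legacy kinetic-law bound dialect of
  2011-era deposited models), a lossless JSON round trip, TSV export
  and structural validation.
* **FBA** — `max c·v` s.t. `S·v = 0`, `lb ≤ v ≤ ub` (HiGHS via scipy),
  with per-metabolite shadow prices (mass-balance duals) and reduced
  costs.
* **FVA** — per-reaction flux extrema with the objective optionally
  pinned at its optimum, flux ranges `|v_max − v_min|`, and a
  two-condition classifier: a reaction is *changed* when its range
  moves by ≥ 40 % of its baseline range, *activated* when it starts
  carrying flux only in the second condition.
* **The gluconate study pipeline** — extend a red-cell model with
  exchange, transport and gluconokinase reactions; fix glucose uptake
  at 1.12 mmol/gDW/h with the HMS entry floated at 5–10 % of it; then
  run FVA before/after, a robustness sweep of forced gluconate uptake
  against the Na⁺/K⁺-pump objective, a shadow-price comparison, and an
  exchange/transport bound-relaxation scan.
* **Kinetics** — simulation of the 6PGDH-coupled GntK assay (NADPH
  absorbance at 340 nm), initial-rate extraction, and nonlinear
  Michaelis–Menten fitting: `v = Vmax·S/(Km+S)`, `kcat = Vmax/[E]`.
* **Screening** — plate z-scores of background-corrected luminescence
  (ATP depletion ⇒ negative z) with one-tailed normal p-values and hit
  calling.
* **Synthetic generators** — a seed-deterministic toy glycolysis+HMS
  network with the study's qualitative structure, replicated noisy
  assay curves, and a 122-compound plate with spiked hits, so every
  analysis runs end-to-end with no downloads.

## Worked example

```python
import numpy as np
from gluconet import (make_toy_network, StudyConfig, run_study,
                      KineticParams, AssayConfig, make_assay_dataset,
                      initial_rate, fit_mm)

# -- network side: what does opening a gluconate feed do? -----------
model = make_toy_network()          # 21-reaction glycolysis+HMS toy
config = StudyConfig(sweep_grid=tuple(np.round(np.arange(0, 1.001, 0.02), 3)))
report = run_study(model, config)
s = report["summary"]
print(f"pump objective without/with gluconate: "
      f"{s['objective_closed']:.3f} / {s['objective_open']:.3f}")
print(f"gluconokinase span at the optimum:      "
      f"{s['gntk_flux_min']:.3f}-{s['gntk_flux_max']:.3f} mmol/gDW/h")
print(f"robustness: max from {s['robustness_first_max_uptake']:.3f}, "
      f"decline past {s['robustness_decline_uptake']:.3f} mmol/gDW/h")

# -- bench side: recover kinetic constants from noisy curves --------
truth = KineticParams.from_km_vmax(km=106.4, vmax=2.3, enzyme_conc=0.25)
assay = AssayConfig()
curves, _ = make_assay_dataset(truth, assay, n_replicates=6, seed=1)
rates = {}
for c in curves:
    r = initial_rate(c, assay.absorbance_per_uM, assay.blank_absorbance)
    rates.setdefault(c.substrate_label, []).append(r)
fit = fit_mm([(s_, float(np.mean(v))) for s_, v in rates.items()],
             enzyme_conc=0.25)
print(f"fitted Km {fit.km:.1f} uM, Vmax {fit.vmax:.2f} uM/s, "
      f"kcat {fit.kcat:.1f} 1/s")
```

prints

```
pump objective without/with gluconate: 2.190 / 2.398
gluconokinase span at the optimum:      0.124-0.444 mmol/gDW/h
robustness: max from 0.124, decline past 0.444 mmol/gDW/h
fitted Km 114.6 uM, Vmax 2.30 uM/s, kcat 9.2 1/s
```

Reading this: opening the gluconate exchange raises the ATP-driven
pump optimum by 0.208 mmol/gDW/h; with the objective pinned there, the
gluconokinase flux is free to roam a plateau between 0.124 (where
pentose recycling saturates) and 0.444 mmol/gDW/h (where the capped
CO₂ outlet starts charging ATP for export) — the same two numbers the
robustness sweep finds as the first-maximum and decline breakpoints.
The fitted constants recover the ground truth (Km 106.4 µM, Vmax
2.3 µM/s) to within the assay's expected bias and noise.

The same pipeline is available from a shell:

```sh
gluconet make-toy --out toy.json
gluconet study run --model toy.json --outdir results/
gluconet make-plate --out plate.tsv
gluconet screen score plate.tsv --out scored.tsv
```

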