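"""Seed-deterministic generators for desk-scale study inputs.

Three generators close the loop so every analysis in the package can
run without downloads:

* :func:`make_toy_network` -- a 15-25 reaction glycolysis + hexose
  monophosphate shunt (HMS) network with the qualitative structure of
  the red-cell study: fixed glucose uptake, an oxidative-HMS entry
  floated at 5-10 % of it, an NADPH (glutathione) demand, limited
  non-oxidative recycling of pentose phosphate back into glycolysis, a
  capped passive CO2 outlet backed by an ATP-consuming export, and an
  ATP-driven pump as objective. Opening the optional gluconate branch
  raises the optimum, and forcing uptake past the CO2 cap collapses it
  -- the rise / plateau / sharp-drop robustness shape.
* :func:`make_assay_dataset` -- replicated noisy coupled-assay progress
  curves with a paired ground-truth rate table.
* :func:`make_plate` -- a 122-compound luminescence plate with spiked
  ATP-depleting hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import MetabolicModel, Metabolite, Reaction, validate
from .lp import fba
from .kinetics import AssayConfig, KineticParams, simulate_assay
from . import study as _study

#: taxonomy classes cycled over synthetic plate compounds
_PLATE_CLASSES = ("carbohydrate", "organic acid", "amino acid", "nucleotide",
                  "polyol", "lipid", "cofactor")


@dataclass
class ToyNetworkSpec:
    """Shape and constraints of the toy glycolysis + HMS network.

    Fluxes are mmol/gDW/h at toy scale. The defaults are the study
    conditions scaled down: glucose fixed at 1.12, HMS entry floated at
    5-10 % of it, and a CO2 outlet whose cap is what eventually limits
    gluconate catabolism.
    """

    n_glycolysis_steps: int = 3
    include_hms: bool = True
    include_gluconate_branch: bool = True
    pump_atp_stoich: int = 1
    glucose_uptake: float = 1.12
    hms_split_fraction_bounds: tuple[float, float] = (0.05, 0.10)
    #: passive CO2 outlet capacity; beyond it export costs ATP
    capped_exchange_bound: float = 0.5
    #: required NADPH (glutathione regeneration) drain
    nadph_demand: float = 0.2
    #: cap on non-oxidative recycling (6 p5p -> 5 g6p) flux
    recycle_cap: float = 0.03
    #: glucose transporter capacity, binds only when uptake is relaxed
    transporter_capacity: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.n_glycolysis_steps <= 7:
            raise ValueError("n_glycolysis_steps must be in 1..7")
        lo, hi = self.hms_split_fraction_bounds
        if not 0 < lo <= hi < 1:
            raise ValueError("hms_split_fraction_bounds must lie in (0,1), ordered")
        if self.capped_exchange_bound <= 0:
            raise ValueError("capped_exchange_bound must be positive")
        if self.pump_atp_stoich < 1:
            raise ValueError("pump_atp_stoich must be >= 1")


def make_toy_network(spec: ToyNetworkSpec | None = None) -> MetabolicModel:
    """Build the toy network; deterministic for a given spec.

    The model is validated and solved on construction; an infeasible
    parameter combination (e.g. an NADPH demand the floated HMS entry
    cannot cover) raises naming the failing balance.
    """
    spec = spec or ToyNetworkSpec()
    B = 1000.0
    g = spec.glucose_uptake
    lo, hi = spec.hms_split_fraction_bounds

    mets = [
        Metabolite("glc_D_e", "D-glucose", "e", "C6H12O6"),
        Metabolite("glc_D_c", "D-glucose", "c", "C6H12O6"),
        Metabolite("g6p_c", "D-glucose 6-phosphate", "c", "C6H11O9P"),
        Metabolite("pyr_c", "pyruvate", "c", "C3H3O3"),
        Metabolite("pyr_e", "pyruvate", "e", "C3H3O3"),
        Metabolite("atp_c", "ATP", "c", "C10H12N5O13P3"),
        Metabolite("adp_c", "ADP", "c", "C10H12N5O10P2"),
        Metabolite("h_c", "proton", "c", "H"),
        Metabolite("co2_c", "CO2", "c", "CO2"),
        Metabolite("co2_e", "CO2", "e", "CO2"),
    ]
    rxns = [
        Reaction("EX_glc_D_e", {"glc_D_e": -1}, -g, -g, "D-glucose exchange"),
        Reaction("GLCt1", {"glc_D_e": -1, "glc_D_c": 1}, 0,
                 spec.transporter_capacity, "glucose transport"),
        Reaction("HEX1", {"glc_D_c": -1, "atp_c": -1, "g6p_c": 1,
                          "adp_c": 1, "h_c": 1}, 0, B, "hexokinase"),
        Reaction("PYRt", {"pyr_c": -1, "pyr_e": 1}, 0, B, "pyruvate export"),
        Reaction("EX_pyr_e", {"pyr_e": -1}, 0, B, "pyruvate exchange"),
        Reaction("NaKt", {"atp_c": -spec.pump_atp_stoich,
                          "adp_c": spec.pump_atp_stoich,
                          "h_c": spec.pump_atp_stoich},
                 0, B, "Na+/K+ pump (ATP-driven, lumped)"),
        Reaction("CO2t", {"co2_c": -1, "co2_e": 1}, 0,
                 spec.capped_exchange_bound, "passive CO2 outlet (capped)"),
        Reaction("HCO3EXP", {"co2_c": -1, "atp_c": -1, "co2_e": 1,
                             "adp_c": 1, "h_c": 1}, 0, B,
                 "ATP-dependent bicarbonate-like export"),
        Reaction("EX_co2_e", {"co2_e": -1}, 0, B, "CO2 exchange"),
        Reaction("EX_h_c", {"h_c": -1}, -B, B, "proton sink/source"),
    ]

    # lumped glycolysis chain: g6p -> ... -> 2 pyr, net 3 ATP at the
    # final step (so one glucose nets +2 ATP after hexokinase)
    chain = ["g6p_c"]
    for i in range(1, spec.n_glycolysis_steps):
        mid = f"glyc{i}_c"
        mets.append(Metabolite(mid, f"glycolytic intermediate {i}", "c"))
        chain.append(mid)
    chain.append("pyr_c")
    for i in range(spec.n_glycolysis_steps):
        sub, prod = chain[i], chain[i + 1]
        stoich: dict[str, float] = {sub: -1, prod: 1}
        if i == spec.n_glycolysis_steps - 1:
            stoich[prod] = 2
            stoich.update({"adp_c": -3, "atp_c": 3, "h_c": -3})
        rxns.append(Reaction(f"GLY{i + 1}", stoich, 0, B,
                             f"glycolysis lump step {i + 1}"))

    if spec.include_hms:
        mets += [
            Metabolite("6pgc_c", "6-phospho-D-gluconate", "c", "C6H10O10P"),
            Metabolite("p5p_c", "pentose 5-phosphate pool", "c", "C5H9O8P"),
            Metabolite("nadp_c", "NADP+", "c"),
            Metabolite("nadph_c", "NADPH", "c"),
        ]
        rxns += [
            Reaction("G6PDH", {"g6p_c": -1, "nadp_c": -1, "6pgc_c": 1,
                               "nadph_c": 1, "h_c": 1},
                     lo * g, hi * g,
                     "oxidative HMS entry (G6PD+lactonase lump), floated"),
            Reaction("GND", {"6pgc_c": -1, "nadp_c": -1, "p5p_c": 1,
                             "nadph_c": 1, "co2_c": 1}, 0, B,
                     "6-phosphogluconate dehydrogenase"),
            Reaction("TKTL", {"p5p_c": -6, "g6p_c": 5}, 0, spec.recycle_cap,
                     "non-oxidative HMS recycling (lumped), capacity-limited"),
            Reaction("R5PSALV", {"p5p_c": -1, "adp_c": -1, "h_c": -1,
                                 "atp_c": 1}, 0, B,
                     "ribose-phosphate salvage into the nucleotide pool (lumped)"),
            Reaction("NADPHOX", {"nadph_c": -1, "nadp_c": 1, "h_c": 1},
                     spec.nadph_demand, B,
                     "glutathione-cycle NADPH demand (lumped)"),
        ]

    model = MetabolicModel(metabolites=mets, reactions=rxns,
                           objective={"NaKt": 1.0},
                           id=f"toy_glycolysis_hms_seed{spec.seed}")
    if spec.include_gluconate_branch:
        if not spec.include_hms:
            raise ValueError("gluconate branch requires the HMS "
                             "(6-phospho-D-gluconate is its entry point)")
        model = _study.add_gluconate(model)

    issues = validate(model)
    if issues:
        raise ValueError("toy network inconsistent: "
                         + "; ".join(i.message for i in issues))
    sol = fba(model)
    if not sol.optimal or sol.objective_value <= 0:
        raise ValueError(
            "toy network has no positive optimum (status "
            f"{sol.status}); likely the NADPH demand {spec.nadph_demand} "
            f"exceeds what the HMS split {spec.hms_split_fraction_bounds} "
            "of glucose uptake can supply")
    return model


# ---------------------------------------------------------------------------
# kinetics dataset


def make_assay_dataset(true_params: KineticParams,
                       config: AssayConfig | None = None,
                       noise_sd: float | None = None,
                       n_replicates: int = 6,
                       n_technical: int = 3,
                       seed: int = 0):
    """Replicated noisy progress curves plus the ground-truth rate table.

    Emulates the replicate structure of a plate-based kinetic study:
    ``n_replicates`` biological replicates per substrate concentration,
    each stored as the mean of ``n_technical`` technically replicated
    reads. ``noise_sd`` is the per-read Gaussian absorbance noise in
    AU; the default (None) makes each read 2 % CV of its own
    noise-free absorbance -- read noise proportional to the signal it
    rides on, the usual photometric behaviour. Returns
    ``(curves, truth)`` where ``truth`` is a DataFrame of the
    closed-form Michaelis-Menten rate at each substrate concentration.
    """
    config = config or AssayConfig()
    rng = np.random.default_rng(seed)
    clean = simulate_assay(true_params, config, noise_sd=0.0)
    curves = []
    for c in clean:
        sd = noise_sd if noise_sd is not None else 0.02 * c.absorbance_340
        for rep in range(n_replicates):
            noise = rng.normal(0.0, 1.0, size=(n_technical,)
                               + c.absorbance_340.shape).mean(axis=0) * sd
            curves.append(type(c)(time=c.time,
                                  absorbance_340=c.absorbance_340 + noise,
                                  substrate_label=c.substrate_label,
                                  replicate=rep))
    truth = pd.DataFrame({
        "substrate_uM": list(config.substrate_series),
        "rate_uM_per_s": [float(true_params.rate(s))
                          for s in config.substrate_series],
    })
    return curves, truth


# ---------------------------------------------------------------------------
# screening plate


def make_plate(n_compounds: int = 122,
               hit_effect_sizes: tuple[float, ...] = (0.86, 0.70),
               noise_cv: float = 0.02,
               baseline_rlu: float = 1.0e6,
               seed: int = 0) -> pd.DataFrame:
    """Synthetic luminescence plate with spiked ATP-depleting hits.

    The first ``len(hit_effect_sizes)`` compounds (named ``hit_1``,
    ``hit_2``, ...) lose that fraction of the ATP signal; the rest are
    inactive. Luminescence noise is multiplicative lognormal with
    coefficient of variation ``noise_cv`` (plate-reader behaviour).
    The default effect sizes were chosen so that, at the default plate
    size and noise, the two hits score near z = -8 and z = -7.
    """
    n_hits = len(hit_effect_sizes)
    if n_compounds < n_hits + 2:
        raise ValueError("need at least two inactive compounds beyond the hits")
    if any(not 0 < e <= 1 for e in hit_effect_sizes):
        raise ValueError("hit effect sizes must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv ** 2)) if noise_cv > 0 else 0.0

    def lognoise(size):
        if sigma == 0:
            return np.ones(size)
        return rng.lognormal(-0.5 * sigma ** 2, sigma, size)

    compounds = [f"hit_{i + 1}" for i in range(n_hits)] + \
                [f"compound_{i + 1:03d}" for i in range(n_compounds - n_hits)]
    depletion = np.concatenate([np.asarray(hit_effect_sizes, dtype=float),
                                np.zeros(n_compounds - n_hits)])
    control = baseline_rlu * lognoise(n_compounds)
    sample = baseline_rlu * (1.0 - depletion) * lognoise(n_compounds)
    return pd.DataFrame({
        "compound": compounds,
        "taxonomy_class": [_PLATE_CLASSES[i % len(_PLATE_CLASSES)]
                           for i in range(n_compounds)],
        "luminescence": sample,
        "control_luminescence": control,
    })
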