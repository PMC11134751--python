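"""Synthetic fixtures: a compartmentalised toy metabolic network, a
phenotype-microarray table and noisy fermentation trajectories.

The toy network mirrors the structure of a fungal citric-acid producer at
1/50 scale: four compartments (extracellular, cytosol, mitochondria,
peroxisome), glucose and xylose uptake, lumped glycolysis/pentose
catabolism, a mitochondrial TCA lump with a citrate shuttle and citrate
secretion, oxidative phosphorylation, ATP maintenance, a measured-
composition biomass reaction drawing phosphate, plus optional decoy
dead-end appendages. Every non-boundary, non-biomass reaction is
elementally balanced, and stoichiometric coefficients are small integers
so LP optima are hand-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .biomass import PELLETED_COMPOSITION, MonomerTable, build_biomass_reaction
from .core import MetabolicModel, Metabolite, Reaction
from .dfba import (FermentationState, KineticParameters, Trajectory, run_dfba)
from .fba import PhenotypeComparison, phenotype_array
from .gpr import parse_gpr

__all__ = [
    "ToySpec", "make_toy_model", "toy_monomer_table",
    "make_phenotype_fixture", "make_fermentation_dataset",
    "make_random_network",
]


@dataclass
class ToySpec:
    seed: int = 0
    include_xylose_path: bool = True
    n_decoy_deadends: int = 0
    citrate_overflow: bool = True


_TOY_METABOLITES: list[tuple[str, str, str | None]] = [
    # (id, compartment, formula)
    ("glc__D_e", "e", "C6H12O6"), ("xyl__D_e", "e", "C5H10O5"),
    ("fru_e", "e", "C6H12O6"), ("man_e", "e", "C6H12O6"),
    ("gal_e", "e", "C6H12O6"), ("rib__D_e", "e", "C5H10O5"),
    ("arab__L_e", "e", "C5H10O5"), ("srb_e", "e", "C6H12O6"),
    ("cit_e", "e", "C6H8O7"),
    ("pi_e", "e", "H3O4P"), ("nh4_e", "e", "H4N"), ("o2_e", "e", "O2"),
    ("co2_e", "e", "CO2"), ("h2o_e", "e", "H2O"), ("h_e", "e", "H"),
    ("glc__D_c", "c", "C6H12O6"), ("xyl__D_c", "c", "C5H10O5"),
    ("fru_c", "c", "C6H12O6"), ("man_c", "c", "C6H12O6"),
    ("gal_c", "c", "C6H12O6"), ("rib__D_c", "c", "C5H10O5"),
    ("arab__L_c", "c", "C5H10O5"), ("srb_c", "c", "C6H12O6"),
    ("cit_c", "c", "C6H8O7"),
    ("pi_c", "c", "H3O4P"), ("nh4_c", "c", "H4N"), ("o2_c", "c", "O2"),
    ("co2_c", "c", "CO2"), ("h2o_c", "c", "H2O"), ("h_c", "c", "H"),
    ("pyr_c", "c", "C3H4O3"),
    ("atp_c", "c", "C10H16N5O13P3"), ("adp_c", "c", "C10H15N5O10P2"),
    ("nad_c", "c", "C21H27N7O14P2"), ("nadh_c", "c", "C21H28N7O14P2"),
    ("aa_c", "c", "C3H7NO2"), ("nt_c", "c", "C10H14N5O7P"),
    ("lip_c", "c", "C16H32O2"), ("cw_c", "c", "C6H10O5"),
    ("ac_c", "c", "C2H4O2"), ("biomass_c", "c", None),
    ("pyr_m", "m", "C3H4O3"), ("cit_m", "m", "C6H8O7"),
    ("o2_m", "m", "O2"), ("co2_m", "m", "CO2"), ("h2o_m", "m", "H2O"),
    ("h_m", "m", "H"),
    ("atp_m", "m", "C10H16N5O13P3"), ("adp_m", "m", "C10H15N5O10P2"),
    ("pi_m", "m", "H3O4P"),
    ("nad_m", "m", "C21H27N7O14P2"), ("nadh_m", "m", "C21H28N7O14P2"),
    ("lip_x", "x", "C16H32O2"), ("ac_x", "x", "C2H4O2"), ("o2_x", "x", "O2"),
]

# (id, stoichiometry, lb, ub, gpr, subsystem)
_TOY_REACTIONS: list[tuple] = [
    # exchanges: negative lb = uptake allowed in the default medium
    ("EX_glc__D_e", {"glc__D_e": -1}, -10, 1000, None, "exchange"),
    ("EX_xyl__D_e", {"xyl__D_e": -1}, 0, 1000, None, "exchange"),
    ("EX_fru_e", {"fru_e": -1}, 0, 1000, None, "exchange"),
    ("EX_man_e", {"man_e": -1}, 0, 1000, None, "exchange"),
    ("EX_gal_e", {"gal_e": -1}, 0, 1000, None, "exchange"),
    ("EX_rib__D_e", {"rib__D_e": -1}, 0, 1000, None, "exchange"),
    ("EX_arab__L_e", {"arab__L_e": -1}, 0, 1000, None, "exchange"),
    ("EX_srb_e", {"srb_e": -1}, 0, 1000, None, "exchange"),
    ("EX_cit_e", {"cit_e": -1}, 0, 1000, None, "exchange"),
    ("EX_pi_e", {"pi_e": -1}, -10, 1000, None, "exchange"),
    ("EX_nh4_e", {"nh4_e": -1}, -10, 1000, None, "exchange"),
    ("EX_o2_e", {"o2_e": -1}, -20, 1000, None, "exchange"),
    ("EX_co2_e", {"co2_e": -1}, 0, 1000, None, "exchange"),
    ("EX_h2o_e", {"h2o_e": -1}, -1000, 1000, None, "exchange"),
    ("EX_h_e", {"h_e": -1}, -1000, 1000, None, "exchange"),
    ("DM_biomass_c", {"biomass_c": -1}, 0, 1000, None, "demand"),
    # transport
    ("GLCt", {"glc__D_e": -1, "glc__D_c": 1}, 0, 1000, "g_hxt1 or g_hxt2", "transport"),
    ("FRUt", {"fru_e": -1, "fru_c": 1}, 0, 1000, "g_st1", "transport"),
    ("MANt", {"man_e": -1, "man_c": 1}, 0, 1000, "g_st1", "transport"),
    ("GALt", {"gal_e": -1, "gal_c": 1}, -1000, 1000, "g_st1", "transport"),
    ("RIBt", {"rib__D_e": -1, "rib__D_c": 1}, -1000, 1000, "g_st1", "transport"),
    ("ARAt", {"arab__L_e": -1, "arab__L_c": 1}, -1000, 1000, "g_st1", "transport"),
    ("SRBt", {"srb_e": -1, "srb_c": 1}, -1000, 1000, "g_st1", "transport"),
    ("CITt", {"cit_c": -1, "cit_e": 1}, 0, 1000, "g_cex", "transport"),
    ("PIt", {"pi_e": -1, "pi_c": 1}, 0, 1000, "g_pho84", "transport"),
    ("NH4t", {"nh4_e": -1, "nh4_c": 1}, 0, 1000, None, "transport"),
    ("O2t", {"o2_e": -1, "o2_c": 1}, 0, 1000, None, "transport"),
    ("O2tm", {"o2_c": -1, "o2_m": 1}, -1000, 1000, None, "transport"),
    ("O2tx", {"o2_c": -1, "o2_x": 1}, -1000, 1000, None, "transport"),
    ("CO2tm", {"co2_m": -1, "co2_c": 1}, -1000, 1000, None, "transport"),
    ("CO2t", {"co2_c": -1, "co2_e": 1}, 0, 1000, None, "transport"),
    ("H2Ot", {"h2o_c": -1, "h2o_e": 1}, -1000, 1000, None, "transport"),
    ("Ht", {"h_c": -1, "h_e": 1}, -1000, 1000, None, "transport"),
    ("H2Otm", {"h2o_c": -1, "h2o_m": 1}, -1000, 1000, None, "transport"),
    ("PYRtm", {"pyr_c": -1, "pyr_m": 1}, 0, 1000, "g_mpc1 and g_mpc2", "transport"),
    ("CITtm", {"cit_m": -1, "cit_c": 1}, 0, 1000, "g_ctp", "transport"),
    ("ATPtm", {"atp_m": -1, "adp_c": -1, "atp_c": 1, "adp_m": 1},
     -1000, 1000, "g_aac", "transport"),
    ("PItm", {"pi_c": -1, "pi_m": 1}, -1000, 1000, None, "transport"),
    ("NADHSHm", {"nadh_c": -1, "h_c": -1, "nad_m": -1,
                 "nad_c": 1, "nadh_m": 1, "h_m": 1}, 0, 1000, None, "transport"),
    ("LIPtx", {"lip_c": -1, "lip_x": 1}, 0, 1000, "g_pxa1", "transport"),
    ("ACtx", {"ac_x": -1, "ac_c": 1}, 0, 1000, None, "transport"),
    # core metabolism (all elementally balanced)
    ("GLYC", {"glc__D_c": -1, "nad_c": -2, "adp_c": -2, "pi_c": -2,
              "pyr_c": 2, "nadh_c": 2, "h_c": 2, "atp_c": 2, "h2o_c": 2},
     0, 1000, "g_glk and g_pfk", "glycolysis"),
    ("GNG", {"pyr_c": -2, "nadh_c": -2, "h_c": -2, "atp_c": -4, "h2o_c": -4,
             "glc__D_c": 1, "nad_c": 2, "adp_c": 4, "pi_c": 4},
     0, 1000, "g_fbp", "gluconeogenesis"),
    ("FRUISO", {"fru_c": -1, "glc__D_c": 1}, 0, 1000, "g_fri", "sugar catabolism"),
    ("MANISO", {"man_c": -1, "glc__D_c": 1}, 0, 1000, "g_mni", "sugar catabolism"),
    # isomerisations with no onward route: substrates that are transported
    # and interconverted but never catabolised (blocked, yet not dead ends)
    ("GALSRBI", {"gal_c": -1, "srb_c": 1}, -1000, 1000, "g_gsi", "sugar catabolism"),
    ("RIBARAI", {"rib__D_c": -1, "arab__L_c": 1}, -1000, 1000, "g_rai",
     "sugar catabolism"),
    ("TCA", {"pyr_m": -1, "h2o_m": -3, "nad_m": -5,
             "co2_m": 3, "nadh_m": 5, "h_m": 5}, 0, 1000, "g_tca", "TCA cycle"),
    ("OXPHOS", {"nadh_m": -2, "h_m": -2, "o2_m": -1, "adp_m": -4, "pi_m": -4,
                "nad_m": 2, "h2o_m": 6, "atp_m": 4},
     0, 1000, "g_nd1 and g_nd2 and g_atp5", "oxidative phosphorylation"),
    ("AASYN", {"pyr_c": -1, "nh4_c": -1, "nadh_c": -1,
               "aa_c": 1, "h2o_c": 1, "nad_c": 1}, 0, 1000, "g_aas", "amino acids"),
    ("NTSYN", {"glc__D_c": -2, "nh4_c": -5, "pi_c": -1, "nad_c": -12,
               "nt_c": 1, "co2_c": 2, "h2o_c": 5, "nadh_c": 12, "h_c": 11},
     0, 1000, "g_nts", "nucleotides"),
    # de novo nucleotide phosphorylation: lets the adenylate pool grow
    ("NTK", {"nt_c": -1, "pi_c": -2, "atp_c": 1, "h2o_c": 2}, 0, 1000,
     "g_ntk", "nucleotides"),
    ("LIPSYN", {"pyr_c": -8, "nadh_c": -6, "h_c": -6, "atp_c": -7, "h2o_c": -1,
                "lip_c": 1, "co2_c": 8, "nad_c": 6, "adp_c": 7, "pi_c": 7},
     0, 1000, "g_fas1 and g_fas2", "lipids"),
    ("CWSYN", {"glc__D_c": -1, "atp_c": -1, "cw_c": 1, "adp_c": 1, "pi_c": 1},
     0, 1000, "g_cws", "cell wall"),
    ("BOXx", {"lip_x": -1, "o2_x": -7, "ac_x": 8}, 0, 1000, "g_pox",
     "beta oxidation"),
    ("ACCAT", {"ac_c": -1, "o2_c": -2, "co2_c": 2, "h2o_c": 2}, 0, 1000,
     "g_acd", "acetate catabolism"),
    ("ATPM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1}, 0, 1000,
     None, "maintenance"),
]

_XYLOSE_REACTIONS: list[tuple] = [
    ("XYLt", {"xyl__D_e": -1, "xyl__D_c": 1}, 0, 1000, "g_xlt1", "transport"),
    ("XYLCAT", {"xyl__D_c": -3, "nad_c": -5, "adp_c": -5, "pi_c": -5,
                "pyr_c": 5, "nadh_c": 5, "h_c": 5, "atp_c": 5, "h2o_c": 5},
     0, 1000, "g_xr and g_xdh", "pentose catabolism"),
]

_CITRATE_REACTIONS: list[tuple] = [
    # 2 pyruvate + 1/2 O2 -> citrate (doubled for integer coefficients)
    ("CITSYN", {"pyr_m": -4, "o2_m": -1, "cit_m": 2}, 0, 1000,
     "g_cs1 or g_cs2", "citrate synthesis"),
]


def toy_monomer_table() -> MonomerTable:
    """Single pseudo-monomer per macromolecule, mapped onto toy metabolites."""
    return MonomerTable.single_monomer({
        "protein": ("aa_c", "C3H7NO2"),
        "DNA": ("nt_c", "C10H14N5O7P"),
        "RNA": ("nt_c", "C10H14N5O7P"),
        "lipid": ("lip_c", "C16H32O2"),
        "cell_wall": ("cw_c", "C6H10O5"),
        "ash": ("pi_c", "H3O4P"),
        "pool": ("glc__D_c", "C6H12O6"),
    })


def make_toy_model(spec: ToySpec | None = None) -> MetabolicModel:
    """Build the toy model. Deterministic for a fixed spec."""
    spec = spec or ToySpec()
    metabolites = [Metabolite(id=mid, name=mid, compartment=comp, formula=formula)
                   for mid, comp, formula in _TOY_METABOLITES]
    rows = list(_TOY_REACTIONS)
    if spec.include_xylose_path:
        rows += _XYLOSE_REACTIONS
    if spec.citrate_overflow:
        rows += _CITRATE_REACTIONS
    reactions = [
        Reaction(id=rid, name=rid, stoichiometry=dict(stoich),
                 lower_bound=float(lb), upper_bound=float(ub),
                 gpr=parse_gpr(gpr) if gpr else None, subsystem=subsystem)
        for rid, stoich, lb, ub, gpr, subsystem in rows]
    model = MetabolicModel(id=f"toy_seed{spec.seed}", metabolites=metabolites,
                           reactions=reactions)
    # decoy dead-end appendages: each a single cytosolic reaction whose
    # product nothing consumes
    for k in range(spec.n_decoy_deadends):
        dead = Metabolite(id=f"dead{k}_c", name=f"decoy dead end {k}",
                          compartment="c", formula="C6H8O7")
        model.metabolites.append(dead)
        model._met_index[dead.id] = dead
        model.add_reaction(Reaction(
            id=f"DEAD{k}", name=f"decoy dead-end reaction {k}",
            stoichiometry={"cit_c": -1, f"dead{k}_c": 1},
            lower_bound=0.0, upper_bound=1000.0, subsystem="decoy"))
    biomass = build_biomass_reaction(PELLETED_COMPOSITION, toy_monomer_table(),
                                     gam_atp=30.0)
    model.add_reaction(biomass)
    model.objective = "BIOMASS"
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Phenotype fixture
# ---------------------------------------------------------------------------

# source name -> (observed growth, category expected against the toy model)
_PHENOTYPE_DESIGN: list[tuple[str, bool, str]] = [
    ("glc__D", True, "TP"),    # grows, observed growth
    ("xyl__D", True, "TP"),
    ("man", True, "TP"),
    ("fru", False, "FP"),      # catabolised in silico, no observed growth
    ("gal", True, "FN"),       # observed growth, no catabolic route
    ("rib__D", False, "TN"),   # transported but not catabolised
    ("arab__L", False, "TN"),
    ("srb", False, "TN"),
    ("cit", False, "TN"),      # secretion-only transporter: no uptake route
    ("sucr", True, "no_exchange"),
    ("malt", False, "no_exchange"),
]


def make_phenotype_fixture(seed: int = 0) -> tuple[dict[str, bool],
                                                   PhenotypeComparison]:
    """Observations plus the comparison expected for the default toy model."""
    rng = np.random.default_rng(seed)
    design = list(_PHENOTYPE_DESIGN)
    rng.shuffle(design)
    observations = {name: observed for name, observed, _ in design}
    rows = []
    for name, observed, category in design:
        predicted: bool | None
        if category == "no_exchange":
            predicted = None
        elif category in ("TP", "FP"):
            predicted = True
        else:
            predicted = False
        rows.append({"source": name, "exchange": f"EX_{name}_e",
                     "observed": observed, "predicted": predicted,
                     "category": category})
    expected = PhenotypeComparison(records=pd.DataFrame(
        rows, columns=["source", "exchange", "observed", "predicted", "category"]))
    return observations, expected


def write_phenotype_csv(observations: dict[str, bool], path) -> None:
    pd.DataFrame({"source": list(observations),
                  "growth": [int(v) for v in observations.values()]}
                 ).to_csv(path, index=False)


def read_phenotype_csv(path) -> dict[str, bool]:
    df = pd.read_csv(path)
    return {str(s): bool(g) for s, g in zip(df["source"], df["growth"])}


# ---------------------------------------------------------------------------
# Fermentation dataset with known ground truth
# ---------------------------------------------------------------------------

def make_fermentation_dataset(p: KineticParameters | None = None,
                              noise_cv: float = 0.02, seed: int = 0,
                              t_end: float = 60.0, dt: float = 0.5,
                              n_points: int = 10, n_replicates: int = 3,
                              model: MetabolicModel | None = None,
                              ) -> tuple[pd.DataFrame, Trajectory]:
    """Noisy samples of a toy-model dFBA run (ground truth returned too).

    Multiplicative Gaussian noise with coefficient of variation
    ``noise_cv``, truncated at zero, mimicking replicate fermentation
    measurements. Deterministic for fixed (parameters, seed).
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be non-negative")
    p = p or KineticParameters()
    model = model or make_toy_model()
    initial = FermentationState(t=p.t_start, biomass=0.05, glucose=80.0,
                                xylose=40.0, citrate=0.0, phosphate=2.0)
    truth = run_dfba(model, p, initial, t_end=t_end, dt=dt)
    df = truth.to_dataframe()
    idx = np.unique(np.linspace(0, len(df) - 1, n_points).round().astype(int))
    sampled = df.iloc[idx].reset_index(drop=True)
    rng = np.random.default_rng(seed)
    species = ["biomass", "glucose", "xylose", "citrate", "phosphate"]
    rows = []
    for rep in range(n_replicates):
        noisy = sampled.copy()
        for s in species:
            factor = 1.0 + noise_cv * rng.standard_normal(len(noisy))
            noisy[s] = np.clip(noisy[s] * factor, 0.0, None)
        noisy["replicate"] = rep
        rows.append(noisy)
    samples = pd.concat(rows, ignore_index=True)
    return samples, truth


# ---------------------------------------------------------------------------
# Random networks for pruning-oracle tests
# ---------------------------------------------------------------------------

def make_random_network(seed: int, n_metabolites: int = 12,
                        n_reactions: int = 30,
                        p_reversible: float = 0.3,
                        n_exchanges: int = 3) -> MetabolicModel:
    """A random stoichiometric network (topology only, no objective).

    Used to exercise dead-end pruning against brute-force oracles;
    deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    mets = [Metabolite(id=f"m{i}_c", name=f"m{i}", compartment="c")
            for i in range(n_metabolites)]
    reactions = []
    for j in range(n_reactions):
        size = int(rng.integers(2, 5))
        members = rng.choice(n_metabolites, size=size, replace=False)
        n_sub = int(rng.integers(1, size))
        stoich = {}
        for k, m in enumerate(members):
            stoich[f"m{m}_c"] = -1.0 if k < n_sub else 1.0
        reversible = bool(rng.random() < p_reversible)
        reactions.append(Reaction(
            id=f"r{j}", name=f"r{j}", stoichiometry=stoich,
            lower_bound=-1000.0 if reversible else 0.0, upper_bound=1000.0))
    for k, m in enumerate(rng.choice(n_metabolites, size=n_exchanges,
                                     replace=False)):
        reactions.append(Reaction(
            id=f"EX{k}", name=f"EX{k}", stoichiometry={f"m{m}_c": -1.0},
            lower_bound=-1000.0, upper_bound=1000.0))
    return MetabolicModel(id=f"random{seed}", metabolites=mets,
                          reactions=reactions)
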