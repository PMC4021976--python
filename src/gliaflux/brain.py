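"""Builder for the four-compartment neuron-astrocyte energy-metabolism network.

The reconstruction covers, at pathway level: capillary glucose/oxygen supply
(glucose being the only pinned flux), stepwise glycolysis and lactate
dehydrogenase in both cells, the pentose phosphate shunt, pyruvate transport
and dehydrogenase, the full TCA cycle, lumped oxidative phosphorylation with a
ROS side reaction, the malate-aspartate and glycerol-3-phosphate shuttles,
astrocyte-only pyruvate carboxylase and glycogen turnover, the
glutamate-glutamine cycle with its Na+/K+ transporter stoichiometries,
Na/K-ATPase and ion channels, creatine/adenylate kinase buffering, and the
glutathione/ascorbate antioxidant system (synthesis confined to astrocytes).

Conventions and lumpings:

* only carbon and nitrogen are audited; water, protons and inorganic
  phosphate are untracked, and the CoA moiety is untracked (acetyl-CoA counts
  as C2, succinyl-CoA as C4);
* glutathione is tracked as its glutamyl-cysteine core (C8 N2), so the
  cystine supply reaction is its only precursor intake;
* adenine and nicotinamide (NADP) pools are cellular, NAD(H) and FAD(H2)
  pools are separated between cytosol and mitochondria (hence the shuttles);
* CO2 is pooled per cell and exported to the capillary through one lumped
  route per cell;
* cells communicate only through the extracellular space or the capillary.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Dict, List, Tuple

import numpy as np

from .network import (
    MetabolicNetwork,
    NetworkConstructionError,
    Reaction,
    Species,
    parse_equation,
)

__all__ = ["BrainOptions", "build_brain_network", "full_oxidation_flux", "CHEMISTRY"]

#: carbon / nitrogen counts per chemical identity (species id prefix)
CHEMISTRY: Dict[str, Tuple[int, int]] = {
    "GLC": (6, 0), "G6P": (6, 0), "F6P": (6, 0), "FBP": (6, 0),
    "DHAP": (3, 0), "GAP": (3, 0), "BPG": (3, 0), "PG3": (3, 0),
    "PG2": (3, 0), "PEP": (3, 0), "PYR": (3, 0), "LAC": (3, 0),
    "G3P": (3, 0), "RU5P": (5, 0), "CO2": (1, 0), "O2": (0, 0),
    "H2O2": (0, 0),
    # CoA moiety untracked
    "ACCOA": (2, 0), "SUCCOA": (4, 0),
    "CIT": (6, 0), "ICIT": (6, 0), "AKG": (5, 0), "SUC": (4, 0),
    "FUM": (4, 0), "MAL": (4, 0), "OAA": (4, 0),
    "ATP": (10, 5), "ADP": (10, 5), "AMP": (10, 5),
    "NAD": (21, 7), "NADH": (21, 7), "NADP": (21, 7), "NADPH": (21, 7),
    "FAD": (27, 9), "FADH2": (27, 9),
    "GLU": (5, 1), "GLN": (5, 2), "ASP": (4, 1), "NH4": (0, 1),
    "NA": (0, 0), "K": (0, 0),
    "CR": (4, 3), "PCR": (4, 3),
    # glutamyl-cysteine core of glutathione (glycine moiety untracked)
    "GSH": (8, 2), "GSSG": (16, 4), "CYS2": (6, 2),
    "ASC": (6, 0), "DHA": (6, 0), "GLYGN": (6, 0),
}

SPECIES_NAMES = {
    "GLC": "glucose", "G6P": "glucose-6-phosphate", "F6P": "fructose-6-phosphate",
    "FBP": "fructose-1,6-bisphosphate", "DHAP": "dihydroxyacetone phosphate",
    "GAP": "glyceraldehyde-3-phosphate", "BPG": "1,3-bisphosphoglycerate",
    "PG3": "3-phosphoglycerate", "PG2": "2-phosphoglycerate",
    "PEP": "phosphoenolpyruvate", "PYR": "pyruvate", "LAC": "lactate",
    "G3P": "glycerol-3-phosphate", "RU5P": "ribulose-5-phosphate",
    "CO2": "carbon dioxide", "O2": "oxygen", "H2O2": "hydrogen peroxide",
    "ACCOA": "acetyl-CoA", "SUCCOA": "succinyl-CoA", "CIT": "citrate",
    "ICIT": "isocitrate", "AKG": "alpha-ketoglutarate", "SUC": "succinate",
    "FUM": "fumarate", "MAL": "malate", "OAA": "oxaloacetate",
    "ATP": "ATP", "ADP": "ADP", "AMP": "AMP", "NAD": "NAD+", "NADH": "NADH",
    "NADP": "NADP+", "NADPH": "NADPH", "FAD": "FAD", "FADH2": "FADH2",
    "GLU": "glutamate", "GLN": "glutamine", "ASP": "aspartate",
    "NH4": "ammonium", "NA": "sodium", "K": "potassium",
    "CR": "creatine", "PCR": "phosphocreatine", "GSH": "glutathione",
    "GSSG": "glutathione disulfide", "CYS2": "cystine", "ASC": "ascorbate",
    "DHA": "dehydroascorbate", "GLYGN": "glycogen (glucosyl unit)",
}


@dataclass(frozen=True)
class BrainOptions:
    """Builder toggles; defaults include every described pathway.

    ``p_o_nadh``/``p_o_fadh`` are the P/O ratios of the lumped oxidative
    phosphorylation reactions (modern consensus 2.5 and 1.5).
    ``ros_nadh`` scales the prior relevance of the ROS side reaction only
    through its presence; its flux is sampled like any other.
    """

    include_glycogen: bool = True
    include_antioxidant: bool = True
    include_g3p_shuttle: bool = True
    p_o_nadh: Fraction = Fraction(5, 2)
    p_o_fadh: Fraction = Fraction(3, 2)


def build_brain_network(options: BrainOptions | None = None) -> MetabolicNetwork:
    """Reconstruct the neuron-astrocyte network; validate balances and roles."""
    opt = options or BrainOptions()
    rows: List[Tuple[str, str, str, bool, str, str]] = []

    def R(rid: str, name: str, eq: str, rev: bool, tag: str, scope: str) -> None:
        rows.append((rid, name, eq, rev, tag, scope))

    pon, pof = opt.p_o_nadh, opt.p_o_fadh

    # --- capillary supply and waste ------------------------------------
    R("GLC_in", "glucose supply to capillary", "-> GLC[c]", False, "intake", "capillary")
    R("O2_in", "oxygen supply to capillary", "-> O2[c]", False, "intake", "capillary")
    R("CO2_out", "CO2 clearance", "CO2[c] ->", False, "efflux", "capillary")
    # ammonia is exchanged with blood in both directions; with an efflux-only
    # route the amino-nitrogen pool would be closed net of its sinks, forcing
    # glutamate dehydrogenase and glutathione synthesis to zero identically
    R("NH4_in", "ammonia supply to capillary", "-> NH4[c]", False, "intake",
      "capillary")
    R("NH4T_e_c", "ammonia exchange capillary/interstitium", "NH4[c] <-> NH4[e]",
      True, "transport", "shared")
    R("NH4_out", "ammonia efflux", "NH4[c] ->", False, "efflux", "capillary")
    # capillary ion exchange: without it Na+ and K+ are closed pools, every
    # ion balance is forced to strict equality, and the astrocytic glutamate
    # uptake stoichiometry (3 Na+ in, 1 K+ out, pump return) becomes
    # infeasible -- the blood-brain barrier exchanges both ions in vivo
    R("NA_in", "sodium supply to capillary", "-> NA[c]", False, "intake",
      "capillary")
    R("NA_out", "sodium clearance", "NA[c] ->", False, "efflux", "capillary")
    R("NAT_c_e", "sodium exchange capillary/interstitium", "NA[c] <-> NA[e]",
      True, "ions", "shared")
    R("K_in", "potassium supply to capillary", "-> K[c]", False, "intake",
      "capillary")
    R("K_out", "potassium clearance", "K[c] ->", False, "efflux", "capillary")
    R("KT_c_e", "potassium exchange capillary/interstitium", "K[c] <-> K[e]",
      True, "ions", "shared")

    # --- glucose and oxygen routes (Fig 1 topology) --------------------
    R("GLCT_c_a", "glucose uptake capillary->astrocyte", "GLC[c] -> GLC[ac]",
      False, "transport", "astrocyte")
    R("GLCT_c_e", "glucose diffusion capillary->interstitium", "GLC[c] -> GLC[e]",
      False, "transport", "shared")
    R("GLCT_e_a", "glucose uptake interstitium->astrocyte", "GLC[e] -> GLC[ac]",
      False, "transport", "astrocyte")
    R("GLCT_e_n", "glucose uptake interstitium->neuron", "GLC[e] -> GLC[nc]",
      False, "transport", "neuron")
    R("O2T_c_n", "oxygen diffusion capillary->neuron", "O2[c] -> O2[nm]",
      False, "transport", "neuron")
    R("O2T_c_a", "oxygen diffusion capillary->astrocyte", "O2[c] -> O2[am]",
      False, "transport", "astrocyte")
    R("CO2T_n", "CO2 export neuron->capillary", "CO2[nc] -> CO2[c]",
      False, "transport", "neuron")
    R("CO2T_a", "CO2 export astrocyte->capillary", "CO2[ac] -> CO2[c]",
      False, "transport", "astrocyte")

    # --- per-cell core carbon metabolism -------------------------------
    for X, cy, mi, scope in (("n", "nc", "nm", "neuron"), ("a", "ac", "am", "astrocyte")):
        # stepwise glycolysis, hexokinase through pyruvate kinase
        R(f"HK_{X}", "hexokinase", f"GLC[{cy}] + ATP[{cy}] -> G6P[{cy}] + ADP[{cy}]",
          False, "glycolysis", scope)
        R(f"PGI_{X}", "phosphoglucose isomerase", f"G6P[{cy}] <-> F6P[{cy}]",
          True, "glycolysis", scope)
        R(f"PFK_{X}", "phosphofructokinase",
          f"F6P[{cy}] + ATP[{cy}] -> FBP[{cy}] + ADP[{cy}]", False, "glycolysis", scope)
        R(f"ALD_{X}", "aldolase", f"FBP[{cy}] <-> DHAP[{cy}] + GAP[{cy}]",
          True, "glycolysis", scope)
        R(f"TPI_{X}", "triose phosphate isomerase", f"DHAP[{cy}] <-> GAP[{cy}]",
          True, "glycolysis", scope)
        R(f"GAPDH_{X}", "GAP dehydrogenase",
          f"GAP[{cy}] + NAD[{cy}] <-> BPG[{cy}] + NADH[{cy}]", True, "glycolysis", scope)
        R(f"PGK_{X}", "phosphoglycerate kinase",
          f"BPG[{cy}] + ADP[{cy}] -> PG3[{cy}] + ATP[{cy}]", False, "glycolysis", scope)
        R(f"PGM_{X}", "phosphoglycerate mutase", f"PG3[{cy}] <-> PG2[{cy}]",
          True, "glycolysis", scope)
        R(f"ENO_{X}", "enolase", f"PG2[{cy}] <-> PEP[{cy}]", True, "glycolysis", scope)
        R(f"PK_{X}", "pyruvate kinase",
          f"PEP[{cy}] + ADP[{cy}] -> PYR[{cy}] + ATP[{cy}]", False, "glycolysis", scope)
        R(f"LDH_{X}", "lactate dehydrogenase",
          f"PYR[{cy}] + NADH[{cy}] <-> LAC[{cy}] + NAD[{cy}]", True, "glycolysis", scope)
        R(f"LACT_{X}", "lactate transport (MCT)", f"LAC[{cy}] <-> LAC[e]",
          True, "transport", scope)
        R(f"PYRT_{X}", "pyruvate transport (MCT)", f"PYR[{cy}] <-> PYR[e]",
          True, "transport", scope)

        # pentose phosphate shunt
        R(f"PPPOX_{X}", "PPP oxidative branch",
          f"G6P[{cy}] + 2 NADP[{cy}] -> RU5P[{cy}] + CO2[{cy}] + 2 NADPH[{cy}]",
          False, "ppp", scope)
        R(f"PPPNOX_{X}", "PPP non-oxidative return",
          f"3 RU5P[{cy}] <-> 2 F6P[{cy}] + GAP[{cy}]", True, "ppp", scope)

        # pyruvate to TCA
        R(f"PYRM_{X}", "mitochondrial pyruvate carrier", f"PYR[{cy}] -> PYR[{mi}]",
          False, "transport", scope)
        R(f"PDH_{X}", "pyruvate dehydrogenase",
          f"PYR[{mi}] + NAD[{mi}] -> ACCOA[{mi}] + CO2[{cy}] + NADH[{mi}]",
          False, "tca", scope)
        R(f"CS_{X}", "citrate synthase", f"ACCOA[{mi}] + OAA[{mi}] -> CIT[{mi}]",
          False, "tca", scope)
        R(f"ACO_{X}", "aconitase", f"CIT[{mi}] <-> ICIT[{mi}]", True, "tca", scope)
        R(f"IDH_{X}", "isocitrate dehydrogenase",
          f"ICIT[{mi}] + NAD[{mi}] -> AKG[{mi}] + CO2[{cy}] + NADH[{mi}]",
          False, "tca", scope)
        R(f"AKGDH_{X}", "alpha-ketoglutarate dehydrogenase",
          f"AKG[{mi}] + NAD[{mi}] -> SUCCOA[{mi}] + CO2[{cy}] + NADH[{mi}]",
          False, "tca", scope)
        R(f"SCS_{X}", "succinyl-CoA synthetase",
          f"SUCCOA[{mi}] + ADP[{cy}] -> SUC[{mi}] + ATP[{cy}]", False, "tca", scope)
        R(f"SDH_{X}", "succinate dehydrogenase",
          f"SUC[{mi}] + FAD[{mi}] -> FUM[{mi}] + FADH2[{mi}]", False, "tca", scope)
        R(f"FH_{X}", "fumarase", f"FUM[{mi}] <-> MAL[{mi}]", True, "tca", scope)
        R(f"MDHM_{X}", "malate dehydrogenase (mito)",
          f"MAL[{mi}] + NAD[{mi}] <-> OAA[{mi}] + NADH[{mi}]", True, "tca", scope)

        # lumped oxidative phosphorylation + ROS side production
        R(f"OXN_{X}", "oxidative phosphorylation (NADH)",
          f"NADH[{mi}] + 1/2 O2[{mi}] + {pon} ADP[{cy}] -> "
          f"NAD[{mi}] + {pon} ATP[{cy}]", False, "oxphos", scope)
        R(f"OXF_{X}", "oxidative phosphorylation (FADH2)",
          f"FADH2[{mi}] + 1/2 O2[{mi}] + {pof} ADP[{cy}] -> "
          f"FAD[{mi}] + {pof} ATP[{cy}]", False, "oxphos", scope)
        if opt.include_antioxidant:
            R(f"ROS_{X}", "mitochondrial ROS production",
              f"NADH[{mi}] + O2[{mi}] -> NAD[{mi}] + H2O2[{cy}]",
              False, "oxphos", scope)

        # malate-aspartate shuttle
        R(f"MDHC_{X}", "malate dehydrogenase (cytosolic)",
          f"MAL[{cy}] + NAD[{cy}] <-> OAA[{cy}] + NADH[{cy}]", True, "mas", scope)
        R(f"AATC_{X}", "aspartate aminotransferase (cytosolic)",
          f"ASP[{cy}] + AKG[{cy}] <-> OAA[{cy}] + GLU[{cy}]", True, "mas", scope)
        R(f"AATM_{X}", "aspartate aminotransferase (mito)",
          f"ASP[{mi}] + AKG[{mi}] <-> OAA[{mi}] + GLU[{mi}]", True, "mas", scope)
        R(f"MAKT_{X}", "malate/alpha-ketoglutarate antiporter",
          f"MAL[{cy}] + AKG[{mi}] <-> MAL[{mi}] + AKG[{cy}]", True, "mas", scope)
        R(f"AGC_{X}", "aspartate/glutamate carrier",
          f"ASP[{mi}] + GLU[{cy}] <-> ASP[{cy}] + GLU[{mi}]", True, "mas", scope)
        R(f"ASPT_{X}", "aspartate transport", f"ASP[{cy}] <-> ASP[e]",
          True, "transport", scope)

        # glycerol-3-phosphate shuttle
        if opt.include_g3p_shuttle:
            R(f"G3PDC_{X}", "G3P dehydrogenase (cytosolic)",
              f"DHAP[{cy}] + NADH[{cy}] <-> G3P[{cy}] + NAD[{cy}]",
              True, "g3p_shuttle", scope)
            R(f"G3PDM_{X}", "G3P dehydrogenase (mito)",
              f"G3P[{cy}] + FAD[{mi}] -> DHAP[{cy}] + FADH2[{mi}]",
              False, "g3p_shuttle", scope)

        # anaplerosis / cataplerosis
        R(f"MEC_{X}", "malic enzyme (cytosolic, NADP)",
          f"MAL[{cy}] + NADP[{cy}] -> PYR[{cy}] + CO2[{cy}] + NADPH[{cy}]",
          False, "tca", scope)
        R(f"MEM_{X}", "malic enzyme (mito, NAD)",
          f"MAL[{mi}] + NAD[{mi}] -> PYR[{mi}] + CO2[{cy}] + NADH[{mi}]",
          False, "tca", scope)

        # glutamate dehydrogenase (reversible; allows net Glu synthesis)
        R(f"GDH_{X}", "glutamate dehydrogenase",
          f"GLU[{mi}] + NAD[{mi}] <-> AKG[{mi}] + NADH[{mi}] + NH4[{cy}]",
          True, "glu_gln_cycle", scope)

        # ATP buffering
        R(f"CK_{X}", "creatine kinase",
          f"PCR[{cy}] + ADP[{cy}] <-> CR[{cy}] + ATP[{cy}]", True, "buffering", scope)
        R(f"AK_{X}", "adenylate kinase",
          f"2 ADP[{cy}] <-> ATP[{cy}] + AMP[{cy}]", True, "buffering", scope)

        # Na/K-ATPase: 1 ATP moves 3 Na+ out, 2 K+ in
        R(f"NKA_{X}", "Na/K-ATPase",
          f"3 NA[{cy}] + 2 K[e] + ATP[{cy}] -> 3 NA[e] + 2 K[{cy}] + ADP[{cy}]",
          False, "ions", scope)

        # ammonium exchange with interstitium
        R(f"NH4T_{X}", "ammonium transport", f"NH4[{cy}] <-> NH4[e]",
          True, "transport", scope)

        if opt.include_antioxidant:
            R(f"GPX_{X}", "glutathione peroxidase",
              f"2 GSH[{cy}] + H2O2[{cy}] -> GSSG[{cy}]", False, "antioxidant", scope)
            R(f"GR_{X}", "glutathione reductase",
              f"GSSG[{cy}] + NADPH[{cy}] -> 2 GSH[{cy}] + NADP[{cy}]",
              False, "antioxidant", scope)
            R(f"DHAR_{X}", "dehydroascorbate reductase (GSH)",
              f"DHA[{cy}] + 2 GSH[{cy}] -> ASC[{cy}] + GSSG[{cy}]",
              False, "antioxidant", scope)
            R(f"DHARN_{X}", "dehydroascorbate reductase (NADPH)",
              f"DHA[{cy}] + NADPH[{cy}] -> ASC[{cy}] + NADP[{cy}]",
              False, "antioxidant", scope)
            R(f"APX_{X}", "ascorbate peroxidation",
              f"ASC[{cy}] + H2O2[{cy}] -> DHA[{cy}]", False, "antioxidant", scope)
            R(f"ASCT_{X}", "ascorbate transport", f"ASC[{cy}] <-> ASC[e]",
              True, "transport", scope)
            R(f"DHAT_{X}", "dehydroascorbate transport", f"DHA[{cy}] <-> DHA[e]",
              True, "transport", scope)
            R(f"H2O2T_{X}", "peroxide diffusion", f"H2O2[{cy}] <-> H2O2[e]",
              True, "transport", scope)

    # --- astrocyte-only machinery --------------------------------------
    R("FBPASE_a", "fructose-1,6-bisphosphatase", "FBP[ac] -> F6P[ac]",
      False, "glycolysis", "astrocyte")
    R("PC_a", "pyruvate carboxylase",
      "PYR[am] + CO2[ac] + ATP[ac] -> OAA[am] + ADP[ac]", False, "tca", "astrocyte")
    if opt.include_glycogen:
        R("GLYSYN_a", "glycogen synthesis",
          "G6P[ac] + ATP[ac] -> GLYGN[ac] + ADP[ac]", False, "glycogen", "astrocyte")
        R("GLYDEG_a", "glycogen phosphorylase", "GLYGN[ac] -> G6P[ac]",
          False, "glycogen", "astrocyte")
    if opt.include_antioxidant:
        R("CYS2_in", "cystine supply (capillary->astrocyte, lumped)",
          "-> CYS2[ac]", False, "intake", "astrocyte")
        R("GSHSYN_a", "glutathione synthesis",
          "GLU[ac] + 1/2 CYS2[ac] + 2 ATP[ac] -> GSH[ac] + 2 ADP[ac]",
          False, "antioxidant", "astrocyte")
        R("GSHT_a_e", "glutathione release astrocyte->interstitium",
          "GSH[ac] -> GSH[e]", False, "transport", "astrocyte")
        R("GSHT_e_n", "glutathione uptake interstitium->neuron",
          "GSH[e] -> GSH[nc]", False, "transport", "neuron")

    # --- glutamatergic neurotransmission -------------------------------
    R("VGLUT_n", "vesicular glutamate loading (1 ATP)",
      "GLU[nc] + ATP[nc] -> GLU[nv] + ADP[nc]", False, "glu_gln_cycle", "neuron")
    R("GLUREL_n", "vesicular glutamate release", "GLU[nv] -> GLU[e]",
      False, "glu_gln_cycle", "neuron")
    R("EAAT_a", "astrocytic glutamate uptake (3 Na+ co, 1 K+ counter)",
      "GLU[e] + 3 NA[e] + K[ac] -> GLU[ac] + 3 NA[ac] + K[e]",
      False, "glu_gln_cycle", "astrocyte")
    R("EAAT_n", "neuronal glutamate uptake (minor route)",
      "GLU[e] + 3 NA[e] + K[nc] -> GLU[nc] + 3 NA[nc] + K[e]",
      False, "glu_gln_cycle", "neuron")
    R("GS_a", "glutamine synthetase (1 ATP)",
      "GLU[ac] + NH4[ac] + ATP[ac] -> GLN[ac] + ADP[ac]",
      False, "glu_gln_cycle", "astrocyte")
    R("GLNT_a_e", "glutamine release astrocyte->interstitium",
      "GLN[ac] -> GLN[e]", False, "glu_gln_cycle", "astrocyte")
    R("GLNT_e_n", "glutamine uptake interstitium->neuron",
      "GLN[e] -> GLN[nc]", False, "glu_gln_cycle", "neuron")
    R("GLS_n", "glutaminase (neuronal cytosol)",
      "GLN[nc] -> GLU[nc] + NH4[nc]", False, "glu_gln_cycle", "neuron")

    # --- ion channels and cotransport ----------------------------------
    R("NACH_n", "neuronal Na+ channel", "NA[e] -> NA[nc]", False, "ions", "neuron")
    R("KCH_n", "neuronal K+ channel", "K[nc] -> K[e]", False, "ions", "neuron")
    R("NKCC_a", "astrocytic Na-K cotransport", "NA[e] + K[e] -> NA[ac] + K[ac]",
      False, "ions", "astrocyte")
    R("KIR_a", "astrocytic inward K+ channel", "K[e] -> K[ac]", False, "ions",
      "astrocyte")

    # --- assemble ------------------------------------------------------
    reactions: List[Reaction] = []
    species_ids: Dict[str, None] = {}
    for rid, name, eq, rev, tag, scope in rows:
        reactants, products = parse_equation(eq)
        stoich = {sid: -c for sid, c in reactants.items()}
        for sid, c in products.items():
            stoich[sid] = stoich.get(sid, Fraction(0)) + c
        reactions.append(Reaction(rid, name, stoich, rev, tag, scope))
        for sid in stoich:
            species_ids.setdefault(sid, None)

    species: List[Species] = []
    for sid in species_ids:
        base, comp = sid[:-1].split("[")
        if base not in CHEMISTRY:
            raise NetworkConstructionError(f"no element counts for {base!r}")
        carbon, nitrogen = CHEMISTRY[base]
        species.append(
            Species(
                id=sid,
                name=SPECIES_NAMES.get(base, base),
                compartment=comp,
                carbon_count=carbon,
                nitrogen_count=nitrogen,
                is_intake=sid in ("GLC[c]", "O2[c]"),
            )
        )

    roles = {
        "GS_a": "GS_a",
        "PDH_n": "PDH_n",
        "GLC_to_c": "GLC_in",
        "O2_to_c": "O2_in",
        "GLC_c_to_a": "GLCT_c_a",
        "GLC_c_to_e": "GLCT_c_e",
        "GLC_e_to_a": "GLCT_e_a",
        "GLC_e_to_n": "GLCT_e_n",
        "O2_c_to_a": "O2T_c_a",
        "O2_c_to_n": "O2T_c_n",
        # positive flux of LACT_a exports lactate from the astrocyte toward
        # the shared pool, i.e. toward the neuron (astrocyte-side CCLS value)
        "LAC_a_to_n": "LACT_a",
        "LAC_n_to_e": "LACT_n",
    }
    net = MetabolicNetwork(species, reactions, roles, name="brain")
    net.validate()
    for role in roles.values():
        if not net.has_reaction(role):
            raise NetworkConstructionError(f"role target {role!r} missing")
    if net.n_reactions <= net.n_species:
        raise NetworkConstructionError(
            f"network not underdetermined: N={net.n_reactions} <= M={net.n_species}"
        )
    return net


def full_oxidation_flux(net: MetabolicNetwork, pin: float = 0.01) -> np.ndarray:
    """Flux vector routing all pinned glucose to complete oxidation.

    Glucose travels capillary -> interstitium -> neuron, is fully oxidized
    through glycolysis, the malate-aspartate shuttle, PDH, TCA and lumped
    oxidative phosphorylation; the oxygen intake is set by electron flux
    (6 O2 per glucose), and the ATP yield is dissipated by the Na/K-ATPase
    with matching channel fluxes.  Carbon leaves as CO2.  The result is a
    feasible flux configuration with OGI exactly 6.

    The largest component is the sodium channel flux (96 x pin); keep
    ``pin <= nu_max / 96`` so bounds are respected.
    """
    # ATP bookkeeping (per unit glucose): production 2 (glycolysis net)
    # + 2 (SCS) + 25 (10 NADH x 2.5) + 3 (2 FADH2 x 1.5) = 32 beyond HK/PFK,
    # all dissipated by the pump.
    values = {
        "GLC_in": 1.0, "GLCT_c_e": 1.0, "GLCT_e_n": 1.0,
        "HK_n": 1.0, "PGI_n": 1.0, "PFK_n": 1.0, "ALD_n": 1.0, "TPI_n": 1.0,
        "GAPDH_n": 2.0, "PGK_n": 2.0, "PGM_n": 2.0, "ENO_n": 2.0, "PK_n": 2.0,
        "PYRM_n": 2.0, "PDH_n": 2.0,
        "CS_n": 2.0, "ACO_n": 2.0, "IDH_n": 2.0, "AKGDH_n": 2.0, "SCS_n": 2.0,
        "SDH_n": 2.0, "FH_n": 2.0, "MDHM_n": 4.0,
        # malate-aspartate shuttle moving 2 cytosolic NADH into mitochondria
        "MDHC_n": -2.0, "MAKT_n": 2.0, "AATM_n": -2.0, "AGC_n": 2.0, "AATC_n": 2.0,
        "OXN_n": 10.0, "OXF_n": 2.0,
        "O2_in": 6.0, "O2T_c_n": 6.0,
        "CO2T_n": 6.0, "CO2_out": 6.0,
        "NKA_n": 32.0, "NACH_n": 96.0, "KCH_n": 64.0,
    }
    nu = np.zeros(net.n_reactions)
    for rid, v in values.items():
        nu[net.reaction_index(rid)] = v * pin
    return nu
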