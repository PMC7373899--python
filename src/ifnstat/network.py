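"""Reaction-network structure of the IFNα/JAK-STAT model.

The network follows the canonical topology of IFNα signaling in hepatocytes:
a lumped receptor pool (IFNAR1/2 + JAK1/TYK2) is activated by extracellular
IFNα, active receptor complexes drive the lumped phosphorylation/dimerization
of STAT1 and STAT2, the three transcription-factor complexes (pSTAT1
homodimer, pSTAT1:pSTAT2 heterodimer, ISGF3) shuttle to the nucleus and
occupy GAS- and GAS+ISRE-containing promoter binding sites, which drive the
transcription of seven feedback genes (STAT1, STAT2, IRF9, IRF2, USP18,
SOCS1, SOCS3).  Translation delays are represented by linear chains between
each mRNA and its protein.  Negative feedback: SOCS1/SOCS3 inhibit receptor
activation, USP18 inhibits STAT phosphorylation at the receptor, SOCS1 (and,
in the cooperative variants, SOCS1 together with USP18) catalyzes degradation
of active receptor complexes, and IRF2 represses SOCS1 transcription.

With the deposited chain configuration (two intermediates per gene) the
variant with both SOCS1- and SOCS1:USP18-mediated receptor degradation has
41 species and 75 reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import GENES, VARIANT_PARAMS, dynamic_names

VARIANTS = tuple(VARIANT_PARAMS)

#: default ("deposited") delay-chain configuration: two steps per gene
DEFAULT_CHAINS = {g: 2 for g in GENES}

#: species fed by each translation chain
_CHAIN_TARGET = {"STAT1": "STAT1c", "STAT2": "STAT2c", "IRF9": "IRF9c",
                 "IRF2": "IRF2", "USP18": "USP18", "SOCS1": "SOCS1",
                 "SOCS3": "SOCS3"}

#: translation-rate symbol per gene (SOCS1/SOCS3/IRF2 rates are derived from
#: their basal protein abundances by the steady-state transform)
TRANSLATION_RATE = {"STAT1": "synthSTAT1", "STAT2": "synthSTAT2",
                    "IRF9": "synthIRF9", "USP18": "synthUSP18",
                    "SOCS1": "synthSOCS1p", "SOCS3": "synthSOCS3p",
                    "IRF2": "synthIRF2p"}

#: steady-state-derived rate symbols appended to the runtime vector
DERIVED_PARAMS = (
    "synthRec",
    "tcrbSTAT1", "tcrbSTAT2", "tcrbIRF9", "tcrbIRF2", "tcrbUSP18",
    "tcrbSOCS1", "tcrbSOCS3",
    "synthSOCS1p", "synthSOCS3p", "synthIRF2p",
    "degSTAT1", "degSTAT2", "degIRF9",
)


@dataclass(frozen=True)
class Species:
    name: str
    compartment: str  # cytoplasm | nucleus | membrane | promoter
    role: str


@dataclass(frozen=True)
class Reaction:
    name: str
    reactants: tuple  # ((species, stoich), ...)
    products: tuple
    modifiers: tuple
    rate_law: str  # mass_action | michaelis_menten | hill_saturation |
    #               inhibited_mass_action
    rate: str      # expression over species/parameter names


@dataclass
class ReactionNetwork:
    variant: str
    species: list
    reactions: list
    chains: dict
    species_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        self.species_index = {n: i for i, n in enumerate(names)}

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def stoichiometry_matrix(self) -> np.ndarray:
        S = np.zeros((self.n_species, self.n_reactions))
        for j, rxn in enumerate(self.reactions):
            for name, nu in rxn.reactants:
                S[self.species_index[name], j] -= nu
            for name, nu in rxn.products:
                S[self.species_index[name], j] += nu
        return S

    def parameter_names(self) -> tuple:
        return dynamic_names(self.variant)

    def runtime_names(self) -> tuple:
        return dynamic_names(self.variant) + DERIVED_PARAMS

    def conserved_moiety(self, member_weights: dict) -> np.ndarray:
        """Weight vector over species for a stoichiometry-weighted moiety."""
        w = np.zeros(self.n_species)
        for name, weight in member_weights.items():
            w[self.species_index[name]] = weight
        return w


def _species_list(chains: dict) -> list:
    sp = [
        Species("Rec", "membrane", "receptor"),
        Species("aRecIFN", "membrane", "receptor"),
        Species("STAT1c", "cytoplasm", "transcription_factor"),
        Species("STAT1n", "nucleus", "transcription_factor"),
        Species("STAT2c", "cytoplasm", "transcription_factor"),
        Species("STAT2n", "nucleus", "transcription_factor"),
        Species("IRF9c", "cytoplasm", "transcription_factor"),
        Species("IRF9n", "nucleus", "transcription_factor"),
        Species("pSTAT1dimc", "cytoplasm", "transcription_factor"),
        Species("pSTAT1dimn", "nucleus", "transcription_factor"),
        Species("pSTAT1pSTAT2c", "cytoplasm", "transcription_factor"),
        Species("pSTAT1pSTAT2n", "nucleus", "transcription_factor"),
        Species("ISGF3c", "cytoplasm", "transcription_factor"),
        Species("ISGF3n", "nucleus", "transcription_factor"),
        Species("OccGASbs", "promoter", "occupancy"),
        Species("OccISREbs", "promoter", "occupancy"),
    ]
    for g in GENES:
        sp.append(Species(f"{g}mRNA", "cytoplasm", "mRNA"))
        for i in range(1, chains[g] + 1):
            sp.append(Species(f"{g}chain{i}", "cytoplasm",
                              "chain_intermediate"))
    for p in ("USP18", "SOCS1", "SOCS3", "IRF2"):
        sp.append(Species(p, "cytoplasm", "protein"))
    return sp


def _receptor_degradation(variant: str) -> list:
    socs1 = Reaction(
        "degaRec_SOCS1", (("aRecIFN", 1),), (), ("SOCS1",),
        "michaelis_menten",
        "VdegSOCS1*(SOCS1/(Kmdeg+SOCS1))*aRecIFN")
    usp18 = Reaction(
        "degaRec_USP18", (("aRecIFN", 1),), (), ("USP18",),
        "michaelis_menten",
        "VdegUSP18*(USP18/(Kmdeg+USP18))*aRecIFN")
    coop = Reaction(
        "degaRec_SOCS1xUSP18", (("aRecIFN", 1),), (), ("SOCS1", "USP18"),
        "michaelis_menten",
        "VdegCoop*(SOCS1/(Kmdeg+SOCS1))*(USP18/(Kmdeg+USP18))*aRecIFN")
    return {"SOCS1": [socs1], "USP18": [usp18], "SOCS1xUSP18": [coop],
            "SOCS1_or_SOCS1xUSP18": [socs1, coop]}[variant]


def _transcription(gene: str) -> list:
    basal_rate = {"USP18": "KD*tcrbUSP18 + OE*synthUSP18mRNAbasal_OE"}.get(
        gene, f"tcrb{gene}")
    induced = {
        "STAT1": ("mass_action", "synthSTAT1mRNA*OccISREbs", ("OccISREbs",)),
        "STAT2": ("mass_action", "synthSTAT2mRNA*OccISREbs", ("OccISREbs",)),
        "IRF9": ("hill_saturation",
                 "synthIRF9mRNA*OccISREbs/(KmIRF9occ+OccISREbs)",
                 ("OccISREbs",)),
        "IRF2": ("mass_action", "synthIRF2mRNA*OccISREbs", ("OccISREbs",)),
        "USP18": ("mass_action", "KD*synthUSP18mRNA*OccISREbs",
                  ("OccISREbs",)),
        "SOCS1": ("inhibited_mass_action",
                  "synthSOCS1mRNA*OccISREbs/(1.0+IRF2/KiIRF2)",
                  ("OccISREbs", "IRF2")),
        "SOCS3": ("mass_action", "synthSOCS3mRNA*OccGASbs", ("OccGASbs",)),
    }[gene]
    deg_rate = {"STAT1": "degSTATmRNA", "STAT2": "degSTATmRNA"}.get(
        gene, f"deg{gene}mRNA")
    kind, expr, mods = induced
    m = f"{gene}mRNA"
    return [
        Reaction(f"tcrb_{gene}", (), ((m, 1),), (), "mass_action",
                 basal_rate),
        Reaction(f"tcr_{gene}", (), ((m, 1),), mods, kind, expr),
        Reaction(f"degmRNA_{gene}", ((m, 1),), (), (), "mass_action",
                 f"{deg_rate}*{m}"),
    ]


def _translation(gene: str, length: int) -> list:
    rate = TRANSLATION_RATE[gene]
    m = f"{gene}mRNA"
    rxns = [Reaction(f"tl_{gene}", (), ((f"{gene}chain1", 1),), (m,),
                     "mass_action", f"{rate}*{m}")]
    step = f"({length}.0/delay{gene})"
    for i in range(1, length):
        rxns.append(Reaction(
            f"chain_{gene}_{i}", ((f"{gene}chain{i}", 1),),
            ((f"{gene}chain{i+1}", 1),), (), "mass_action",
            f"{step}*{gene}chain{i}"))
    rxns.append(Reaction(
        f"chain_{gene}_{length}", ((f"{gene}chain{length}", 1),),
        ((_CHAIN_TARGET[gene], 1),), (), "mass_action",
        f"{step}*{gene}chain{length}"))
    return rxns


def build_network(variant: str = "SOCS1_or_SOCS1xUSP18",
                  chains: dict | None = None) -> ReactionNetwork:
    """Assemble the reaction network for one receptor-degradation variant.

    Parameters
    ----------
    variant : one of ``SOCS1``, ``USP18``, ``SOCS1xUSP18``,
        ``SOCS1_or_SOCS1xUSP18`` (separate SOCS1-catalyzed plus cooperative
        SOCS1:USP18-catalyzed degradation of active receptor complexes).
    chains : per-gene translation delay-chain length (default: deposited
        configuration, two steps per gene).
    """
    if variant not in VARIANT_PARAMS:
        raise ValueError(f"unknown receptor variant {variant!r}")
    chains = dict(DEFAULT_CHAINS if chains is None else chains)
    if set(chains) != set(GENES) or any(v < 1 for v in chains.values()):
        raise ValueError("chain config must give length >= 1 per gene")

    rxns = [
        Reaction("synthRec", (), (("Rec", 1),), (), "mass_action",
                 "synthRec"),
        Reaction("degRec", (("Rec", 1),), (), (), "mass_action",
                 "degRec*Rec"),
        Reaction("actRec", (("Rec", 1),), (("aRecIFN", 1),),
                 ("SOCS1", "SOCS3"), "inhibited_mass_action",
                 "BindIFN*IFN*Rec/(1.0+(SOCS1+SOCS3)/KiSOCS)"),
        Reaction("deactRec", (("aRecIFN", 1),), (("Rec", 1),), (),
                 "mass_action", "deactRec*aRecIFN"),
        *_receptor_degradation(variant),
        Reaction("actSTAT1dim", (("STAT1c", 2),), (("pSTAT1dimc", 1),),
                 ("aRecIFN", "USP18"), "inhibited_mass_action",
                 "actSTAT1*aRecIFN*STAT1c*STAT1c/(1.0+USP18/KiUSP18)"),
        # two receptor-catalyzed phosphorylation events are lumped into one
        # reaction, hence second order in the active receptor complex
        Reaction("actSTAT1STAT2", (("STAT1c", 1), ("STAT2c", 1)),
                 (("pSTAT1pSTAT2c", 1),), ("aRecIFN", "USP18"),
                 "inhibited_mass_action",
                 "actSTAT2*aRecIFN*aRecIFN*STAT1c*STAT2c/(1.0+USP18/KiUSP18)"),
        Reaction("formISGF3", (("pSTAT1pSTAT2c", 1), ("IRF9c", 1)),
                 (("ISGF3c", 1),), (), "mass_action",
                 "formISGF3*pSTAT1pSTAT2c*IRF9c"),
        Reaction("impDim", (("pSTAT1dimc", 1),), (("pSTAT1dimn", 1),), (),
                 "mass_action", "impComplex*pSTAT1dimc"),
        Reaction("impHet", (("pSTAT1pSTAT2c", 1),), (("pSTAT1pSTAT2n", 1),),
                 (), "mass_action", "impComplex*pSTAT1pSTAT2c"),
        Reaction("impISGF3", (("ISGF3c", 1),), (("ISGF3n", 1),), (),
                 "mass_action", "impComplex*ISGF3c"),
        Reaction("dissDimn", (("pSTAT1dimn", 1),), (("STAT1n", 2),), (),
                 "mass_action", "dissDimHet*pSTAT1dimn"),
        Reaction("dissHetn", (("pSTAT1pSTAT2n", 1),),
                 (("STAT1n", 1), ("STAT2n", 1)), (), "mass_action",
                 "dissDimHet*pSTAT1pSTAT2n"),
        Reaction("dissISGF3n", (("ISGF3n", 1),),
                 (("STAT1n", 1), ("STAT2n", 1), ("IRF9n", 1)), (),
                 "mass_action", "dissISGF3*ISGF3n"),
        Reaction("impSTAT1", (("STAT1c", 1),), (("STAT1n", 1),), (),
                 "mass_action", "impSTAT1*STAT1c"),
        Reaction("expSTAT1", (("STAT1n", 1),), (("STAT1c", 1),), (),
                 "mass_action", "expMono*STAT1n"),
        Reaction("impSTAT2", (("STAT2c", 1),), (("STAT2n", 1),), (),
                 "mass_action", "impSTAT2*STAT2c"),
        Reaction("expSTAT2", (("STAT2n", 1),), (("STAT2c", 1),), (),
                 "mass_action", "expMono*STAT2n"),
        Reaction("impIRF9", (("IRF9c", 1),), (("IRF9n", 1),), (),
                 "mass_action", "impIRF9*IRF9c"),
        Reaction("expIRF9", (("IRF9n", 1),), (("IRF9c", 1),), (),
                 "mass_action", "expMono*IRF9n"),
        Reaction("occGAS", (), (("OccGASbs", 1),), ("pSTAT1dimn",),
                 "hill_saturation", "actGAS*pSTAT1dimn*(1.0-OccGASbs)"),
        Reaction("decayGAS", (("OccGASbs", 1),), (), (), "mass_action",
                 "decayOcc*OccGASbs"),
        Reaction("occISRE_het", (), (("OccISREbs", 1),), ("pSTAT1pSTAT2n",),
                 "hill_saturation",
                 "actISREhet*pSTAT1pSTAT2n*(1.0-OccISREbs)"),
        Reaction("occISRE_ISGF3", (), (("OccISREbs", 1),), ("ISGF3n",),
                 "hill_saturation",
                 "actISREISGF3*ISGF3n*(1.0-OccISREbs)"),
        Reaction("decayISRE", (("OccISREbs", 1),), (), (), "mass_action",
                 "decayOcc*OccISREbs"),
    ]
    for g in GENES:
        rxns.extend(_transcription(g))
    for g in GENES:
        rxns.extend(_translation(g, chains[g]))
    for p, rate in (("USP18", "degUSP18"), ("SOCS1", "degSOCS1"),
                    ("SOCS3", "degSOCS3"), ("IRF2", "degIRF2")):
        rxns.append(Reaction(f"degProt_{p}", ((p, 1),), (), (),
                             "mass_action", f"{rate}*{p}"))
    for mono, rate in (("STAT1c", "degSTAT1"), ("STAT2c", "degSTAT2"),
                       ("IRF9c", "degIRF9")):
        rxns.append(Reaction(f"degProt_{mono}", ((mono, 1),), (), (),
                             "mass_action", f"{rate}*{mono}"))

    return ReactionNetwork(variant=variant, species=_species_list(chains),
                           reactions=rxns, chains=chains)


#: weights of the STAT1 moiety (free + complexed, both compartments)
STAT1_MOIETY = {"STAT1c": 1, "STAT1n": 1, "pSTAT1dimc": 2, "pSTAT1dimn": 2,
                "pSTAT1pSTAT2c": 1, "pSTAT1pSTAT2n": 1,
                "ISGF3c": 1, "ISGF3n": 1}
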