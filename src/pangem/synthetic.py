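"""Synthetic pan-genome generator with planted ground truth.

Builds a miniature family of bacteria whose template reactome, strain gene
content, homology evidence, medium and niche structure are all known by
construction, so every pipeline stage can be tested end to end without any
genome downloads.

The mock chemistry is a deliberately small, fully balanced network (real
element symbols, toy metabolites) organised like a fermentative bacterium:

* a linear glucose -> pyruvate "glycolysis" that nets 2 ATP per glucose,
  with a configurable number of isomerase steps so the core can be padded
  to a target size;
* a biomass reaction draining pyruvate, five mock amino acids and ATP, plus
  an enforced ATP-maintenance (NGAM) flux — growth is therefore exactly
  ATP-limited, and with glucose uptake ``10 x scale`` the optimum growth
  rate is ``scale - NGAM/20`` in closed form;
* per-species accessory branches: one alternative carbon source (transporter
  + kinase feeding glycolysis) and one fermentation branch (lactate-,
  acetate- or ethanol-analogue) that disposes of overflow pyruvate — every
  strain needs its branch to grow, which is what makes deleted reactions
  gapfillable;
* knock-out-able two-step amino-acid biosynthesis modules; deleting a
  species' module per the auxotrophy plan makes that amino acid a planted
  auxotrophy;
* species-unique reactions, shared accessory reactions, per-strain private
  (rare) reactions, and one planted niche-enriched reaction per niche.

Every gene-associated reaction carries a multi-allelic GPR (configurable
number of alternatives); strains pick one allele set per carried reaction,
and the emitted similarity table gives carried alleles mutual-best
identities well above the 70% threshold and decoy hits well below it, so
noiseless recovery of the planted presence-absence matrix is exact.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
import pandas as pd

from . import io as pgio
from .model import GPRRule, Medium, Metabolite, PanReactome, Reaction, ValidationError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_reactome",
    "generate_strains",
    "generate_medium",
    "strain_medium",
    "emit_fixture_bundle",
]

_AA_FORMULA = "C3H7NO2"
_FERMENTATION_MODES = ("lac", "act", "eth")


@dataclass
class SyntheticConfig:
    """Study-population parameters for the synthetic family."""

    seed: int
    n_species: int = 3
    strains_per_species: int = 10
    n_core_reactions: int = 12  # gene-associated glycolysis reactions incl. transport
    n_accessory_reactions: int = 4  # extras shared between (not all) species
    n_unique_per_species: int = 2
    n_amino_acids: int = 5
    n_private_reactions: int = 3  # single-strain (rare) reactions
    allele_multiplicity: int = 2
    dropout_rate: float = 0.0
    glucose_uptake: float = 10.0  # mmol/gDCW/h, stand-in for a measured rate
    ngam: float = 1.0
    growth_scale_range: Tuple[float, float] = (0.5, 0.95)
    identity_present_range: Tuple[float, float] = (85.0, 100.0)
    identity_absent_range: Tuple[float, float] = (30.0, 60.0)
    auxotrophy_plan: Optional[Dict[str, Set[str]]] = None  # species -> amino-acid ids
    niche_plan: Optional[Dict[str, Dict[str, int]]] = None  # niche -> {size, n_enriched}

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate <= 1.0:
            raise ValidationError("dropout_rate must be a probability")
        if self.n_species < 1 or self.strains_per_species < 1:
            raise ValidationError("population counts must be positive")
        if self.allele_multiplicity < 1:
            raise ValidationError("allele_multiplicity must be >= 1")
        if self.n_core_reactions < 4:
            raise ValidationError("need at least 4 core reactions (transport, kinase, "
                                  "one isomerase, lumped lower glycolysis)")
        if self.auxotrophy_plan is None:
            plan: Dict[str, Set[str]] = {}
            for i, sp in enumerate(self.species_names[1:], start=1):
                aa_idx = 2 + (i - 1) % max(1, self.n_amino_acids - 2)
                plan[sp] = {f"aa{aa_idx + 1}"}
            self.auxotrophy_plan = plan
        if self.niche_plan is None:
            total = self.n_species * self.strains_per_species
            self.niche_plan = {
                "niche_A": {"size": total // 2, "n_enriched": 1},
                "niche_B": {"size": total - total // 2, "n_enriched": 1},
            }

    @property
    def species_names(self) -> List[str]:
        return [f"sp{i + 1}" for i in range(self.n_species)]

    @property
    def amino_acids(self) -> List[str]:
        return [f"aa{j + 1}" for j in range(self.n_amino_acids)]

    def fermentation_mode(self, species: str) -> str:
        return _FERMENTATION_MODES[self.species_names.index(species) % 3]


@dataclass
class GroundTruth:
    """Everything the generator planted, for assertions downstream."""

    pam: pd.DataFrame  # strains x reactions, 0/1
    core: Set[str] = field(default_factory=set)
    accessory: Set[str] = field(default_factory=set)
    rare: Set[str] = field(default_factory=set)
    unique: Dict[str, Set[str]] = field(default_factory=dict)
    essential_components: Dict[str, Set[str]] = field(default_factory=dict)
    planted_auxotrophies: Dict[str, Set[str]] = field(default_factory=dict)
    enriched: Dict[str, Set[str]] = field(default_factory=dict)  # niche -> reactions
    niche_of: Dict[str, str] = field(default_factory=dict)
    uptake_scale: Dict[str, float] = field(default_factory=dict)
    growth_rate: Dict[str, float] = field(default_factory=dict)  # closed-form optimum
    carbon_source_of: Dict[str, str] = field(default_factory=dict)  # species -> EX id
    csource_growth: Dict[str, Dict[str, bool]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "strains": list(self.pam.index),
            "reactions": list(self.pam.columns),
            "presence": {s: sorted(self.pam.columns[self.pam.loc[s] == 1])
                         for s in self.pam.index},
            "core": sorted(self.core),
            "accessory": sorted(self.accessory),
            "rare": sorted(self.rare),
            "unique": {k: sorted(v) for k, v in self.unique.items()},
            "essential_components": {k: sorted(v) for k, v in self.essential_components.items()},
            "planted_auxotrophies": {k: sorted(v) for k, v in self.planted_auxotrophies.items()},
            "enriched": {k: sorted(v) for k, v in self.enriched.items()},
            "niche_of": self.niche_of,
            "uptake_scale": self.uptake_scale,
            "growth_rate": self.growth_rate,
            "carbon_source_of": self.carbon_source_of,
            "csource_growth": self.csource_growth,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _met(rid: str, formula: str, charge: int, compartment: str = "c") -> Metabolite:
    return Metabolite(id=rid, name=rid, formula=formula, charge=charge,
                      compartment=compartment)


def generate_reactome(config: SyntheticConfig) -> PanReactome:
    """Build the template reactome (balanced, TIC-free, deterministic)."""
    rng = np.random.default_rng(config.seed)
    rx = PanReactome(name="synthetic_pan_reactome", biomass_id="BIOMASS", ngam_id="NGAM")

    def add_pair(base: str, formula: str, charge: int) -> None:
        rx.add_metabolite(_met(f"{base}_e", formula, charge, "e"))
        rx.add_metabolite(_met(f"{base}_c", formula, charge, "c"))

    # currency + core metabolites
    for mid, formula, charge in [
        ("g6_c", "C6H11O9P", -2), ("f6_c", "C6H11O9P", -2), ("pyr_c", "C3H5O3", -1),
        ("atp_c", "C10H12N5O13P3", -4), ("adp_c", "C10H12N5O10P2", -3),
        ("pi_c", "HO4P", -2),
    ]:
        rx.add_metabolite(_met(mid, formula, charge))
    add_pair("glc", "C6H12O6", 0)
    add_pair("h", "H", 1)
    add_pair("h2o", "H2O", 0)
    add_pair("nh4", "NH4", 1)
    add_pair("lac", "C3H5O3", -1)
    add_pair("act", "C2H3O2", -1)
    add_pair("c1", "CH2O", 0)
    add_pair("eth", "C2H6O", 0)
    add_pair("hco3", "CHO3", -1)
    for aa in config.amino_acids:
        add_pair(aa, _AA_FORMULA, 0)
        rx.add_metabolite(_met(f"{aa}int_c", "C3H9NO3", 0))
    for sp in config.species_names:
        add_pair(f"cs_{sp}", "C6H12O6", 0)

    def reaction(rid, stoich, rtype, lb=0.0, ub=1000.0, subsystem="", gpr=None):
        rx.add_reaction(Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                                 upper_bound=ub, rtype=rtype, subsystem=subsystem,
                                 gpr=gpr, name=rid))

    # exchanges (declared uptake limit -1000; media close or cap them)
    for base in (["glc", "h", "h2o", "nh4", "lac", "act", "c1", "eth", "hco3"]
                 + config.amino_acids + [f"cs_{sp}" for sp in config.species_names]):
        reaction(f"EX_{base}_e", {f"{base}_e": -1.0}, "exchange", lb=-1000.0,
                 subsystem="exchange")

    # universal plumbing
    reaction("NGAM", {"atp_c": -1, "h2o_c": -1, "adp_c": 1, "pi_c": 1, "h_c": 1},
             "orphan", lb=config.ngam, subsystem="maintenance")
    biomass = {"pyr_c": -10.0, "atp_c": -20.0, "h2o_c": -20.0,
               "adp_c": 20.0, "pi_c": 20.0, "h_c": 20.0}
    for aa in config.amino_acids:
        biomass[f"{aa}_c"] = -1.0
    reaction("BIOMASS", biomass, "biomass", subsystem="biomass")
    reaction("T_h2o", {"h2o_e": -1, "h2o_c": 1}, "spontaneous", lb=-1000.0,
             subsystem="transport")
    reaction("T_h", {"h_c": -1, "h_e": 1}, "spontaneous", subsystem="transport")
    reaction("T_nh4", {"nh4_e": -1, "nh4_c": 1}, "spontaneous", subsystem="transport")
    reaction("T_c1", {"c1_c": -1, "c1_e": 1}, "spontaneous", subsystem="transport")
    reaction("T_hco3", {"hco3_c": -1, "hco3_e": 1}, "spontaneous", subsystem="transport")

    gene_associated: List[Tuple[str, Dict[str, float], str]] = []

    # core glycolysis: transport, kinase, isomerase chain, lumped lower half
    gene_associated.append(("T_glc", {"glc_e": -1, "glc_c": 1}, "transport"))
    gene_associated.append(("HEX1", {"glc_c": -1, "atp_c": -1, "g6_c": 1,
                                     "adp_c": 1, "h_c": 1}, "glycolysis"))
    n_chain = config.n_core_reactions - 3  # isomerase steps g6 -> ... -> f6
    chain = ["g6_c"] + [f"pad{i + 1}_c" for i in range(n_chain - 1)] + ["f6_c"]
    for mid in chain[1:-1]:
        rx.add_metabolite(_met(mid, "C6H11O9P", -2))
    for i in range(len(chain) - 1):
        gene_associated.append((f"ISO{i + 1}", {chain[i]: -1, chain[i + 1]: 1},
                                "glycolysis"))
    gene_associated.append(("PFK_L", {"f6_c": -1, "adp_c": -3, "pi_c": -2, "h_c": -1,
                                      "pyr_c": 2, "atp_c": 3, "h2o_c": 2}, "glycolysis"))

    # amino-acid transport + two-step biosynthesis modules
    for aa in config.amino_acids:
        gene_associated.append((f"T_{aa}", {f"{aa}_e": -1, f"{aa}_c": 1}, "transport"))
        gene_associated.append((f"BS_{aa}_1", {"pyr_c": -1, "nh4_c": -1,
                                               f"{aa}int_c": 1}, "aa biosynthesis"))
        gene_associated.append((f"BS_{aa}_2", {f"{aa}int_c": -1, f"{aa}_c": 1,
                                               "h2o_c": 1}, "aa biosynthesis"))

    # per-species branches
    for sp in config.species_names:
        mode = config.fermentation_mode(sp)
        if mode == "lac":
            gene_associated.append((f"LDH_{sp}", {"pyr_c": -1, "lac_c": 1}, "fermentation"))
            gene_associated.append((f"T_lac_{sp}", {"lac_c": -1, "lac_e": 1}, "fermentation"))
        elif mode == "act":
            gene_associated.append((f"PTA_{sp}", {"pyr_c": -1, "act_c": 1, "c1_c": 1},
                                    "fermentation"))
            gene_associated.append((f"T_act_{sp}", {"act_c": -1, "act_e": 1}, "fermentation"))
        else:
            gene_associated.append((f"ADH_{sp}", {"pyr_c": -1, "h2o_c": -1,
                                                  "eth_c": 1, "hco3_c": 1}, "fermentation"))
            gene_associated.append((f"T_eth_{sp}", {"eth_c": -1, "eth_e": 1}, "fermentation"))
        gene_associated.append((f"T_cs_{sp}", {f"cs_{sp}_e": -1, f"cs_{sp}_c": 1},
                                "alt carbon"))
        gene_associated.append((f"CSK_{sp}", {f"cs_{sp}_c": -1, "atp_c": -1, "g6_c": 1,
                                              "adp_c": 1, "h_c": 1}, "alt carbon"))
        for k in range(config.n_unique_per_species):
            mid = f"umet_{sp}_{k + 1}_c"
            rx.add_metabolite(_met(mid, "C3H5O3", -1))
            gene_associated.append((f"UNQ_{sp}_{k + 1}", {"pyr_c": -1, mid: 1}, "unique"))

    # shared accessory extras, planted niche markers, per-strain private reactions
    for k in range(config.n_accessory_reactions):
        mid = f"amet_{k + 1}_c"
        rx.add_metabolite(_met(mid, "C3H5O3", -1))
        gene_associated.append((f"ACC_{k + 1}", {"pyr_c": -1, mid: 1}, "accessory"))
    for niche, plan in config.niche_plan.items():
        for k in range(plan.get("n_enriched", 1)):
            mid = f"nmet_{niche}_{k + 1}_c"
            rx.add_metabolite(_met(mid, "C3H5O3", -1))
            gene_associated.append((f"NICH_{niche}_{k + 1}", {"pyr_c": -1, mid: 1},
                                    "niche marker"))
    for k in range(config.n_private_reactions):
        mid = f"pmet_{k + 1}_c"
        rx.add_metabolite(_met(mid, "C3H5O3", -1))
        gene_associated.append((f"PRV_{k + 1}", {"pyr_c": -1, mid: 1}, "private"))

    # multi-allelic GPRs + mock allele catalog
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    for rid, stoich, subsystem in gene_associated:
        alternatives = []
        for k in range(config.allele_multiplicity):
            if k == 0 and config.allele_multiplicity > 1:
                alleles = [f"{rid}_a{k}g1", f"{rid}_a{k}g2"]  # 2-gene complex
            else:
                alleles = [f"{rid}_a{k}"]
            alternatives.append(alleles)
            for allele in alleles:
                seq = "".join(rng.choice(alphabet, size=30))
                rx.allele_catalog[allele] = seq
        reaction(rid, stoich, "gene_associated", subsystem=subsystem,
                 gpr=GPRRule.from_sets(alternatives))

    rx.validate()
    return rx


def generate_medium(reactome: PanReactome, config: SyntheticConfig) -> Medium:
    """The mock chemically defined medium.

    Glucose at ``glucose_uptake``; amino acids at 1 mmol/gDCW/h except the
    first two (the glutamate/aspartate analogues) at 2; ammonium and water
    freely available at 10.
    """
    limits = {"EX_glc_e": config.glucose_uptake, "EX_nh4_e": 10.0, "EX_h2o_e": 10.0}
    for j, aa in enumerate(config.amino_acids):
        limits[f"EX_{aa}_e"] = 2.0 if j < 2 else 1.0
    return Medium(limits, name="synthetic_cdm")


def _core_reaction_ids(config: SyntheticConfig) -> Set[str]:
    core = {"T_glc", "HEX1", "PFK_L"}
    core |= {f"ISO{i + 1}" for i in range(config.n_core_reactions - 4 + 1)}
    core |= {f"T_{aa}" for aa in config.amino_acids}
    return core


def generate_strains(
    reactome: PanReactome, config: SyntheticConfig
) -> Tuple[Dict[str, Set[str]], pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Plant strain gene content, homology evidence, metadata and truth.

    Returns ``(profiles, similarity_table, metadata, ground_truth)`` where
    ``profiles`` maps strain id to its set of present gene-associated
    reactions.  Dropout applies only to non-essential accessory content
    (alternative-carbon branches, shared accessory extras and species-unique
    reactions); fermentation branches, biosynthesis modules, niche markers
    and private reactions are planted exactly.
    """
    rng = np.random.default_rng(config.seed + 1)
    species = config.species_names
    strains = [f"{sp}_{i + 1:02d}" for sp in species for i in range(config.strains_per_species)]
    species_of = {s: s.rsplit("_", 1)[0] for s in strains}

    # interleave species when assigning niches so niches get a species mix
    interleaved = [f"{sp}_{i + 1:02d}" for i in range(config.strains_per_species)
                   for sp in species]
    niche_of: Dict[str, str] = {}
    cursor = 0
    for niche, plan in config.niche_plan.items():
        for s in interleaved[cursor:cursor + plan["size"]]:
            niche_of[s] = niche
        cursor += plan["size"]

    core_ids = _core_reaction_ids(config)
    droppable_of: Dict[str, Set[str]] = {}
    base_of: Dict[str, Set[str]] = {}
    for sp in species:
        mode = config.fermentation_mode(sp)
        ferm = {
            "lac": {f"LDH_{sp}", f"T_lac_{sp}"},
            "act": {f"PTA_{sp}", f"T_act_{sp}"},
            "eth": {f"ADH_{sp}", f"T_eth_{sp}"},
        }[mode]
        biosynth = set()
        deleted = config.auxotrophy_plan.get(sp, set())
        for aa in config.amino_acids:
            if aa not in deleted:
                biosynth |= {f"BS_{aa}_1", f"BS_{aa}_2"}
        base_of[sp] = core_ids | ferm | biosynth
        droppable = {f"T_cs_{sp}", f"CSK_{sp}"}
        droppable |= {f"UNQ_{sp}_{k + 1}" for k in range(config.n_unique_per_species)}
        droppable_of[sp] = droppable

    # shared accessory extras: each assigned to a proper, non-singleton subset
    # of species (so they are neither core nor unique when n_species >= 3)
    acc_species: Dict[str, List[str]] = {}
    for k in range(config.n_accessory_reactions):
        size = 2 if config.n_species >= 3 else 1
        chosen = sorted(rng.choice(species, size=size, replace=False))
        acc_species[f"ACC_{k + 1}"] = chosen

    enriched = {niche: {f"NICH_{niche}_{k + 1}" for k in range(plan.get("n_enriched", 1))}
                for niche, plan in config.niche_plan.items()}

    profiles: Dict[str, Set[str]] = {}
    for idx, s in enumerate(strains):
        sp = species_of[s]
        present = set(base_of[sp])
        for rid in sorted(droppable_of[sp]):
            if rng.random() >= config.dropout_rate:
                present.add(rid)
        for rid, members in acc_species.items():
            if sp in members and rng.random() >= config.dropout_rate:
                present.add(rid)
        if s in niche_of:
            present |= enriched[niche_of[s]]
        if idx < config.n_private_reactions:
            present.add(f"PRV_{idx + 1}")
        profiles[s] = present

    # homology evidence: one allele set per carried reaction, plus decoys
    lo_p, hi_p = config.identity_present_range
    lo_a, hi_a = config.identity_absent_range
    rows = []
    all_gpr = {rid: r.gpr for rid, r in reactome.reactions.items() if r.gpr is not None}
    for s in strains:
        gene_counter = 0
        carried_alleles: Set[str] = set()
        for rid in sorted(profiles[s]):
            alts = sorted(all_gpr[rid].alternatives, key=lambda a: sorted(a))
            choice = alts[int(rng.integers(len(alts)))]
            carried_alleles |= choice
        absent_alleles = sorted(set(reactome.allele_catalog) - carried_alleles)
        n_decoys = max(1, len(absent_alleles) // 10)
        decoys = rng.choice(absent_alleles, size=min(n_decoys, len(absent_alleles)),
                            replace=False)
        for allele in sorted(carried_alleles):
            gene_counter += 1
            rows.append({
                "strain_id": s, "strain_gene": f"{s}_g{gene_counter:04d}",
                "allele": allele,
                "pident_fwd": round(float(rng.uniform(lo_p, hi_p)), 2),
                "pident_rev": round(float(rng.uniform(lo_p, hi_p)), 2),
                "mutual_best": 1,
            })
        for allele in decoys:
            gene_counter += 1
            rows.append({
                "strain_id": s, "strain_gene": f"{s}_g{gene_counter:04d}",
                "allele": allele,
                "pident_fwd": round(float(rng.uniform(lo_a, hi_a)), 2),
                "pident_rev": round(float(rng.uniform(lo_a, hi_a)), 2),
                "mutual_best": int(rng.integers(2)),
            })
    similarity = pd.DataFrame(rows)

    scales = {s: round(float(rng.uniform(*config.growth_scale_range)), 3) for s in strains}
    genus_of = {sp: f"genus_{1 + i // 2}" for i, sp in enumerate(species)}
    metadata = pd.DataFrame({
        "species": [species_of[s] for s in strains],
        "genus": [genus_of[species_of[s]] for s in strains],
        "isolation_source": [niche_of.get(s, "") for s in strains],
        "uptake_scale": [scales[s] for s in strains],
    }, index=pd.Index(strains, name="strain"))

    truth = _ground_truth(reactome, config, profiles, species_of, niche_of,
                          enriched, scales)
    return profiles, similarity, metadata, truth


def _ground_truth(reactome, config, profiles, species_of, niche_of, enriched, scales):
    universal = [r.id for r in reactome.reactions.values() if r.rtype != "gene_associated"]
    strains = list(profiles)
    columns = list(reactome.reactions)
    pam = pd.DataFrame(0, index=pd.Index(strains, name="strain"), columns=columns,
                       dtype="int8")
    for s in strains:
        pam.loc[s, universal] = 1
        pam.loc[s, sorted(profiles[s])] = 1

    n = len(strains)
    freq = 100.0 * pam.sum(axis=0) / n
    core = set(freq.index[freq > 99.0])
    accessory = set(freq.index[(freq >= 15.0) & (freq <= 99.0)])
    rare = set(freq.index[(freq > 0.0) & (freq < 15.0)])

    unique: Dict[str, Set[str]] = {}
    for rid in columns:
        carriers = [s for s in strains if pam.loc[s, rid] == 1]
        sps = {species_of[s] for s in carriers}
        if carriers and len(sps) == 1:
            unique.setdefault(sps.pop(), set()).add(rid)

    planted_aux: Dict[str, Set[str]] = {}
    essential: Dict[str, Set[str]] = {}
    growth: Dict[str, float] = {}
    for s in strains:
        sp = species_of[s]
        deleted = config.auxotrophy_plan.get(sp, set())
        planted_aux[s] = {f"EX_{aa}_e" for aa in deleted}
        ess = {"EX_glc_e"} | planted_aux[s]
        if config.fermentation_mode(sp) == "eth":
            ess.add("EX_h2o_e")  # ethanol branch consumes water stoichiometrically
        essential[s] = ess
        growth[s] = scales[s] * config.glucose_uptake / 10.0 - config.ngam / 20.0

    carbon_source_of = {sp: f"EX_cs_{sp}_e" for sp in config.species_names}
    csource_growth = {
        s: {sp: (f"T_cs_{sp}" in profiles[s] and f"CSK_{sp}" in profiles[s])
            for sp in config.species_names}
        for s in strains
    }
    return GroundTruth(
        pam=pam, core=core, accessory=accessory, rare=rare, unique=unique,
        essential_components=essential, planted_auxotrophies=planted_aux,
        enriched=enriched, niche_of=dict(niche_of), uptake_scale=dict(scales),
        growth_rate=growth, carbon_source_of=carbon_source_of,
        csource_growth=csource_growth,
    )


def strain_medium(base: Medium, scale: float, glucose_exchange: str = "EX_glc_e") -> Medium:
    """Per-strain medium: the base CDM with glucose uptake scaled."""
    return base.scaled({glucose_exchange: scale})


def emit_fixture_bundle(config: SyntheticConfig, out_dir) -> Dict[str, str]:
    """Write every pipeline input plus ground truth; returns the manifest.

    Files: ``reactome.xml`` (SBML), ``gprs.tsv``, ``medium.tsv``,
    ``similarities.tsv``, ``metadata.tsv``, ``ground_truth.json`` and
    ``manifest.json`` (sha256 per file).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reactome = generate_reactome(config)
    medium = generate_medium(reactome, config)
    _, similarity, metadata, truth = generate_strains(reactome, config)

    pgio.write_reactome(reactome, out / "reactome.xml", out / "gprs.tsv")
    pgio.write_medium(medium, out / "medium.tsv")
    pgio.write_similarity_table(similarity, out / "similarities.tsv")
    metadata.to_csv(out / "metadata.tsv", sep="\t")
    truth.to_json(out / "ground_truth.json")

    manifest = {}
    for name in ["reactome.xml", "gprs.tsv", "medium.tsv", "similarities.tsv",
                 "metadata.tsv", "ground_truth.json"]:
        digest = hashlib.sha256((out / name).read_bytes()).hexdigest()
        manifest[name] = digest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
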