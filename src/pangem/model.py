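"""Core data model for pan-reactome constraint-based reconstruction.

A :class:`PanReactome` is the family-wide template network: metabolites,
reactions with flux bounds, multi-allelic gene-protein-reaction (GPR) rules,
a biomass objective and an ATP-maintenance (NGAM) reaction.  Strain-specific
models (:class:`StrainModel`) are subnetworks of the template carrying the
universal "plumbing" reactions (exchanges, orphans, spontaneous, demand,
sink, biomass, NGAM) plus whichever gene-associated reactions the strain's
gene content supports.

Sign conventions follow standard constraint-based practice: an exchange
reaction is written as a drain (metabolite -> nothing), so uptake is a
negative flux and secretion a positive one.  Flux units are mmol/gDCW/h
except the biomass reaction, whose flux is the specific growth rate in 1/h.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, FrozenSet, Iterable, Mapping, Optional

__all__ = [
    "Metabolite",
    "GPRRule",
    "Reaction",
    "PanReactome",
    "StrainModel",
    "Medium",
    "parse_formula",
    "FormulaError",
    "ValidationError",
    "REACTION_TYPES",
    "UNIVERSAL_RTYPES",
    "DEFAULT_BOUND",
]

#: reaction-type taxonomy of the template network
REACTION_TYPES = (
    "gene_associated",
    "exchange",
    "orphan",
    "spontaneous",
    "demand",
    "sink",
    "biomass",
)

#: reaction types added to every strain draft regardless of gene content
UNIVERSAL_RTYPES = frozenset({"exchange", "orphan", "spontaneous", "demand", "sink"})

#: default magnitude cap on any flux bound (mmol/gDCW/h)
DEFAULT_BOUND = 1000.0

#: pseudo-element symbols that make a formula unbalanceable (R-groups etc.)
PSEUDO_ELEMENTS = frozenset({"R", "X", "Z"})

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class ValidationError(ValueError):
    """A structural invariant of the data model is violated."""


class FormulaError(ValidationError):
    """An elemental formula string cannot be parsed."""


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-notation elemental formula into an element -> count map.

    Examples: ``C6H12O6`` -> ``{"C": 6, "H": 12, "O": 6}``; a bare element
    symbol counts once (``H`` -> ``{"H": 1}``).  Counts must be non-negative
    integers.  Raises :class:`FormulaError` on anything unparseable.
    """
    if formula is None or formula == "":
        raise FormulaError("empty formula")
    counts: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
        pos = m.end()
        element, digits = m.group(1), m.group(2)
        counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
    if pos != len(formula):
        raise FormulaError(f"cannot parse formula {formula!r} at position {pos}")
    return counts


def has_pseudo_elements(formula: str) -> bool:
    """True if the formula contains an R-group-style pseudo-element."""
    try:
        return bool(PSEUDO_ELEMENTS & parse_formula(formula).keys())
    except FormulaError:
        return True


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: Optional[str] = None
    charge: Optional[int] = None
    compartment: str = "c"

    def element_counts(self) -> Dict[str, int]:
        if self.formula is None:
            raise FormulaError(f"metabolite {self.id} has no formula")
        try:
            return parse_formula(self.formula)
        except FormulaError as exc:
            raise FormulaError(f"metabolite {self.id}: {exc}") from exc


@dataclass(frozen=True)
class GPRRule:
    """Gene-protein-reaction rule in disjunctive normal form.

    ``alternatives`` is a set of allele-sets: the reaction is available to a
    strain iff at least one allele-set is fully contained in the strain's
    present alleles.  Multiple alternatives represent distinct alleles (or
    isoenzyme complexes) catalysing the same reaction.
    """

    alternatives: FrozenSet[FrozenSet[str]]

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise ValidationError("GPR rule must have at least one alternative")
        if any(len(alt) == 0 for alt in self.alternatives):
            raise ValidationError("GPR alternative must not be empty")

    @classmethod
    def from_sets(cls, alternatives: Iterable[Iterable[str]]) -> "GPRRule":
        return cls(frozenset(frozenset(a) for a in alternatives))

    def evaluate(self, present_alleles: Iterable[str]) -> bool:
        present = set(present_alleles)
        return any(alt <= present for alt in self.alternatives)

    @property
    def alleles(self) -> FrozenSet[str]:
        out: set = set()
        for alt in self.alternatives:
            out |= alt
        return frozenset(out)


@dataclass
class Reaction:
    id: str
    stoichiometry: Dict[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    name: str = ""
    subsystem: str = ""
    rtype: str = "gene_associated"
    gpr: Optional[GPRRule] = None

    def __post_init__(self) -> None:
        if self.rtype not in REACTION_TYPES:
            raise ValidationError(f"reaction {self.id}: unknown rtype {self.rtype!r}")
        if self.lower_bound > self.upper_bound:
            raise ValidationError(
                f"reaction {self.id}: lower_bound {self.lower_bound} > "
                f"upper_bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ValidationError(f"reaction {self.id}: empty stoichiometry")
        # GPR rules travel in a sidecar table, so a gene_associated reaction
        # may exist transiently without its rule attached; the converse
        # (a rule on a non-genetic reaction) is always an error.
        if self.gpr is not None and self.rtype != "gene_associated":
            raise ValidationError(
                f"reaction {self.id}: a GPR implies rtype=gene_associated"
            )

    def copy(self) -> "Reaction":
        r = copy.copy(self)
        r.stoichiometry = dict(self.stoichiometry)
        return r


class _ReactionNetwork:
    """Shared behaviour of the template and of strain models."""

    metabolites: Dict[str, Metabolite]
    reactions: Dict[str, Reaction]
    biomass_id: str
    ngam_id: str

    @property
    def exchange_ids(self) -> list:
        return [r.id for r in self.reactions.values() if r.rtype == "exchange"]

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for met in rxn.stoichiometry:
                if met not in self.metabolites:
                    raise ValidationError(
                        f"reaction {rxn.id} references unknown metabolite {met}"
                    )
        n_biomass = sum(1 for r in self.reactions.values() if r.rtype == "biomass")
        if n_biomass != 1:
            raise ValidationError(f"expected exactly one biomass reaction, found {n_biomass}")
        if self.biomass_id not in self.reactions:
            raise ValidationError(f"biomass reaction {self.biomass_id} missing")
        if self.ngam_id not in self.reactions:
            raise ValidationError(f"NGAM reaction {self.ngam_id} missing")


@dataclass
class PanReactome(_ReactionNetwork):
    """The family-wide template reactome."""

    metabolites: Dict[str, Metabolite] = field(default_factory=dict)
    reactions: Dict[str, Reaction] = field(default_factory=dict)
    biomass_id: str = "BIOMASS"
    ngam_id: str = "NGAM"
    allele_catalog: Dict[str, str] = field(default_factory=dict)
    name: str = "pan_reactome"

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ValidationError(f"duplicate metabolite id {met.id}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ValidationError(f"duplicate reaction id {rxn.id}")
        self.reactions[rxn.id] = rxn

    def copy(self) -> "PanReactome":
        return PanReactome(
            metabolites={k: copy.copy(v) for k, v in self.metabolites.items()},
            reactions={k: v.copy() for k, v in self.reactions.items()},
            biomass_id=self.biomass_id,
            ngam_id=self.ngam_id,
            allele_catalog=dict(self.allele_catalog),
            name=self.name,
        )


@dataclass
class StrainModel(_ReactionNetwork):
    """A strain-specific subnetwork of the template."""

    strain_id: str
    metabolites: Dict[str, Metabolite]
    reactions: Dict[str, Reaction]
    biomass_id: str
    ngam_id: str
    species: str = ""
    provenance: Dict[str, str] = field(default_factory=dict)  # mapped|universal|gapfilled

    def copy(self) -> "StrainModel":
        return StrainModel(
            strain_id=self.strain_id,
            metabolites=self.metabolites,  # shared, immutable by convention
            reactions={k: v.copy() for k, v in self.reactions.items()},
            biomass_id=self.biomass_id,
            ngam_id=self.ngam_id,
            species=self.species,
            provenance=dict(self.provenance),
        )


@dataclass
class Medium:
    """Exchange-reaction uptake limits encoding a chemically defined medium.

    ``uptake_limits`` maps exchange-reaction id to the maximum uptake *rate
    magnitude* in mmol/gDCW/h; applying the medium sets that exchange's lower
    bound to minus the magnitude and closes uptake on every unlisted exchange.
    """

    uptake_limits: Dict[str, float]
    name: str = "medium"

    def __post_init__(self) -> None:
        for ex, mag in self.uptake_limits.items():
            if mag < 0:
                raise ValidationError(f"medium {self.name}: negative uptake for {ex}")

    def without(self, exchange_id: str) -> "Medium":
        """A copy with one component's uptake removed (single-omission)."""
        limits = {k: v for k, v in self.uptake_limits.items() if k != exchange_id}
        return Medium(limits, name=f"{self.name}-minus-{exchange_id}")

    def scaled(self, factors: Mapping[str, float]) -> "Medium":
        """A copy with per-exchange uptake magnitudes multiplied by ``factors``."""
        limits = {k: v * factors.get(k, 1.0) for k, v in self.uptake_limits.items()}
        return Medium(limits, name=self.name)


def stoichiometry_as_fractions(rxn: Reaction) -> Dict[str, Fraction]:
    """Reaction coefficients as exact rationals (for integer balance checks)."""
    return {m: Fraction(c).limit_denominator(10**6) for m, c in rxn.stoichiometry.items()}
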