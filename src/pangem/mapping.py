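"""Strain-specific draft reconstruction from homology evidence.

An allele of the template's reference proteome is called present in a strain
when the strain has a bidirectional best hit (BBH) against it at or above a
percent-identity threshold (70% by default, inclusive) in *both* directions.
Present alleles are pushed through the multi-allelic GPR rules to a reaction
presence vector, and a draft strain model is assembled as the mapped
gene-associated reactions plus the universal plumbing every draft receives:
all exchange, orphan, spontaneous, demand and sink reactions, the biomass
reaction and the NGAM reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Set, Union

import pandas as pd

from .model import (
    PanReactome,
    StrainModel,
    UNIVERSAL_RTYPES,
    ValidationError,
)

__all__ = [
    "HomologyHit",
    "PresenceAbsenceMatrix",
    "call_allele_presence",
    "hits_from_table",
    "reactions_from_alleles",
    "assemble_draft",
    "build_presence_matrix",
]

DEFAULT_IDENTITY_THRESHOLD = 70.0


@dataclass(frozen=True)
class HomologyHit:
    """One strain-protein vs reference-allele alignment result."""

    strain_gene: str
    allele: str
    identity_forward: float
    identity_reverse: float
    is_mutual_best: bool

    def __post_init__(self) -> None:
        for value in (self.identity_forward, self.identity_reverse):
            if not 0.0 <= value <= 100.0:
                raise ValidationError(
                    f"identity {value} outside [0, 100] for {self.strain_gene}->{self.allele}"
                )


def call_allele_presence(
    hits: Iterable[HomologyHit],
    threshold: float = DEFAULT_IDENTITY_THRESHOLD,
) -> Set[str]:
    """Alleles with a mutual-best hit whose weaker direction meets the threshold."""
    present: Set[str] = set()
    for hit in hits:
        if hit.is_mutual_best and min(hit.identity_forward, hit.identity_reverse) >= threshold:
            present.add(hit.allele)
    return present


def hits_from_table(similarities: pd.DataFrame) -> Dict[str, List[HomologyHit]]:
    """Group a similarity table into per-strain hit lists."""
    by_strain: Dict[str, List[HomologyHit]] = {}
    for row in similarities.itertuples(index=False):
        by_strain.setdefault(str(row.strain_id), []).append(
            HomologyHit(
                strain_gene=str(row.strain_gene),
                allele=str(row.allele),
                identity_forward=float(row.pident_fwd),
                identity_reverse=float(row.pident_rev),
                is_mutual_best=bool(int(row.mutual_best)),
            )
        )
    return by_strain


def reactions_from_alleles(
    present_alleles: Set[str], reactome: PanReactome
) -> Dict[str, bool]:
    """Evaluate every reaction's GPR against the present allele set.

    Gene-associated reactions are present iff some DNF alternative is fully
    covered; all other reaction types are present by definition.
    """
    presence: Dict[str, bool] = {}
    for rxn in reactome.reactions.values():
        if rxn.rtype == "gene_associated":
            if rxn.gpr is None:
                raise ValidationError(
                    f"reaction {rxn.id} is gene_associated but has no GPR attached; "
                    "load the reactome with its GPR sidecar table"
                )
            presence[rxn.id] = rxn.gpr.evaluate(present_alleles)
        else:
            presence[rxn.id] = True
    return presence


def assemble_draft(
    reactome: PanReactome,
    presence: Mapping[str, bool],
    strain_id: str,
    metadata: Optional[Mapping[str, str]] = None,
) -> StrainModel:
    """Assemble a draft strain model from a reaction presence vector."""
    if reactome.biomass_id not in reactome.reactions:
        raise ValidationError(f"reactome has no biomass reaction {reactome.biomass_id}")
    reactions = {}
    provenance: Dict[str, str] = {}
    for rxn in reactome.reactions.values():
        universal = (
            rxn.rtype in UNIVERSAL_RTYPES
            or rxn.id == reactome.biomass_id
            or rxn.id == reactome.ngam_id
        )
        if universal:
            reactions[rxn.id] = rxn.copy()
            provenance[rxn.id] = "universal"
        elif presence.get(rxn.id, False):
            reactions[rxn.id] = rxn.copy()
            provenance[rxn.id] = "mapped"
    model = StrainModel(
        strain_id=strain_id,
        metabolites=reactome.metabolites,
        reactions=reactions,
        biomass_id=reactome.biomass_id,
        ngam_id=reactome.ngam_id,
        species=(metadata or {}).get("species", ""),
        provenance=provenance,
    )
    model.validate()
    return model


@dataclass
class PresenceAbsenceMatrix:
    """Strains x reactions binary matrix with per-strain metadata.

    ``data`` is a 0/1 integer DataFrame indexed by strain with one column per
    reaction; ``metadata`` is indexed by strain (columns such as species,
    genus, isolation_source).
    """

    data: pd.DataFrame
    metadata: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate strain ids in presence-absence matrix")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate reaction ids in presence-absence matrix")
        values = self.data.to_numpy()
        if not ((values == 0) | (values == 1)).all():
            raise ValidationError("presence-absence matrix must be binary")
        self.data = self.data.astype("int8")

    @property
    def strains(self) -> List[str]:
        return list(self.data.index)

    @property
    def reactions(self) -> List[str]:
        return list(self.data.columns)

    def species_of(self, strain: str) -> str:
        return str(self.metadata.loc[strain, "species"])

    def to_csv(self, matrix_path, metadata_path=None) -> None:
        self.data.to_csv(matrix_path)
        if metadata_path is not None:
            self.metadata.to_csv(metadata_path, sep="\t")

    @classmethod
    def from_csv(cls, matrix_path, metadata_path=None) -> "PresenceAbsenceMatrix":
        data = pd.read_csv(matrix_path, index_col=0)
        metadata = (
            pd.read_csv(metadata_path, sep="\t", index_col=0)
            if metadata_path is not None
            else pd.DataFrame(index=data.index)
        )
        return cls(data=data, metadata=metadata)


def build_presence_matrix(
    models_or_vectors: Union[Iterable[StrainModel], Mapping[str, Mapping[str, bool]]],
    metadata: Optional[pd.DataFrame] = None,
    reaction_universe: Optional[List[str]] = None,
) -> PresenceAbsenceMatrix:
    """Build the strains x reactions matrix from models or presence vectors."""
    vectors: Dict[str, Mapping[str, bool]] = {}
    if isinstance(models_or_vectors, Mapping):
        for strain, vec in models_or_vectors.items():
            if strain in vectors:
                raise ValidationError(f"duplicate strain id {strain}")
            vectors[strain] = vec
    else:
        for model in models_or_vectors:
            if model.strain_id in vectors:
                raise ValidationError(f"duplicate strain id {model.strain_id}")
            vectors[model.strain_id] = {rid: True for rid in model.reactions}
    if reaction_universe is None:
        universe: Dict[str, None] = {}
        for vec in vectors.values():
            for rid in vec:
                universe.setdefault(rid)
        reaction_universe = list(universe)
    data = pd.DataFrame(
        [
            [1 if vectors[s].get(r, False) else 0 for r in reaction_universe]
            for s in vectors
        ],
        index=list(vectors),
        columns=reaction_universe,
        dtype="int8",
    )
    if metadata is None:
        metadata = pd.DataFrame(index=data.index)
    else:
        metadata = metadata.loc[data.index]
    return PresenceAbsenceMatrix(data=data, metadata=metadata)
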