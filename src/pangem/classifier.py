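"""Core / accessory / rare / unique partitioning of the pan-reactome.

Reaction frequency F is the percentage of strains carrying a reaction.
Family-wide classes follow the carriage-frequency convention: core F > 99
(strictly), accessory 15 <= F <= 99, rare 0 < F < 15; reactions carried by
no strain form a separate unclassified bin.  A reaction is *unique* to a
species when every strain carrying it belongs to that species (one or many
strains).  Intra-species partitions apply the same thresholds to each
species' strains alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import pandas as pd

from .mapping import PresenceAbsenceMatrix
from .model import ValidationError

__all__ = [
    "ReactomePartition",
    "reaction_frequency",
    "partition_reactome",
    "unique_reactions",
    "intra_species_partition",
    "CORE_MIN",
    "ACCESSORY_MIN",
]

CORE_MIN = 99.0  # percent; core is strictly above
ACCESSORY_MIN = 15.0  # percent; inclusive lower edge of accessory


@dataclass
class ReactomePartition:
    core: Set[str]
    accessory: Set[str]
    rare: Set[str]
    absent: Set[str] = field(default_factory=set)  # F = 0, reported separately
    thresholds: tuple = (CORE_MIN, ACCESSORY_MIN)

    def class_of(self, reaction: str) -> str:
        for name in ("core", "accessory", "rare", "absent"):
            if reaction in getattr(self, name):
                return name
        raise KeyError(reaction)

    def to_frame(self, freq: Optional[pd.Series] = None) -> pd.DataFrame:
        rows = []
        for name in ("core", "accessory", "rare", "absent"):
            for rid in sorted(getattr(self, name)):
                rows.append({
                    "reaction": rid,
                    "class": name,
                    "F": float(freq[rid]) if freq is not None else None,
                })
        return pd.DataFrame(rows, columns=["reaction", "class", "F"])


def reaction_frequency(
    pam: PresenceAbsenceMatrix, strain_subset: Optional[Sequence[str]] = None
) -> pd.Series:
    """F(r) = 100 x (strains carrying r) / (strains considered), per reaction."""
    data = pam.data
    if strain_subset is not None:
        strain_subset = list(strain_subset)
        if not strain_subset:
            raise ValidationError("empty strain subset")
        data = data.loc[strain_subset]
    if data.shape[0] == 0:
        raise ValidationError("presence-absence matrix has no strains")
    return 100.0 * data.sum(axis=0) / data.shape[0]


def partition_reactome(
    freq: pd.Series, core_min: float = CORE_MIN, accessory_min: float = ACCESSORY_MIN
) -> ReactomePartition:
    """Partition reactions by carriage frequency (boundaries land in accessory)."""
    if not 0.0 < accessory_min < core_min < 100.0:
        raise ValidationError("thresholds must satisfy 0 < accessory_min < core_min < 100")
    core = set(freq.index[freq > core_min])
    accessory = set(freq.index[(freq >= accessory_min) & (freq <= core_min)])
    rare = set(freq.index[(freq > 0.0) & (freq < accessory_min)])
    absent = set(freq.index[freq == 0.0])
    return ReactomePartition(core, accessory, rare, absent, (core_min, accessory_min))


def unique_reactions(pam: PresenceAbsenceMatrix) -> Dict[str, Set[str]]:
    """Reactions exclusive to one species, keyed by species."""
    if "species" not in pam.metadata.columns:
        raise ValidationError("presence-absence metadata lacks a 'species' column")
    species = pam.metadata["species"]
    if species.isna().any():
        missing = list(pam.metadata.index[species.isna()])
        raise ValidationError(f"strains missing species labels: {missing}")
    out: Dict[str, Set[str]] = {}
    for rid in pam.reactions:
        carriers = pam.data.index[pam.data[rid] == 1]
        if len(carriers) == 0:
            continue
        carrier_species = set(species.loc[carriers])
        if len(carrier_species) == 1:
            out.setdefault(carrier_species.pop(), set()).add(rid)
    return out


def intra_species_partition(
    pam: PresenceAbsenceMatrix,
    min_strains: int = 2,
    core_min: float = CORE_MIN,
    accessory_min: float = ACCESSORY_MIN,
) -> pd.DataFrame:
    """Per-species core/accessory/rare percentages of the observed reactome.

    Percentages are over reactions carried by at least one strain of the
    species; species with fewer than ``min_strains`` strains are skipped.
    Returns a DataFrame indexed by species with columns core/accessory/rare
    (percent) and n_strains / n_reactions.
    """
    if "species" not in pam.metadata.columns:
        raise ValidationError("presence-absence metadata lacks a 'species' column")
    rows = {}
    for sp, members in pam.metadata.groupby("species").groups.items():
        strains = list(members)
        if len(strains) < min_strains:
            import warnings

            warnings.warn(f"species {sp}: only {len(strains)} strain(s); skipped", stacklevel=2)
            continue
        freq = reaction_frequency(pam, strains)
        part = partition_reactome(freq, core_min, accessory_min)
        observed = len(part.core) + len(part.accessory) + len(part.rare)
        if observed == 0:
            continue
        rows[sp] = {
            "core": 100.0 * len(part.core) / observed,
            "accessory": 100.0 * len(part.accessory) / observed,
            "rare": 100.0 * len(part.rare) / observed,
            "n_strains": len(strains),
            "n_reactions": observed,
        }
    return pd.DataFrame.from_dict(rows, orient="index")
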