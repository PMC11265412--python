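"""Shared fixtures: synthetic bundles, toy networks and independent oracles."""

from __future__ import annotations

from itertools import combinations, product
from typing import Dict, List, Optional, Tuple

import numpy as np
import pytest
from hypothesis import settings

from pangem.model import GPRRule, Medium, Metabolite, PanReactome, Reaction, StrainModel
from pangem.mapping import (
    assemble_draft,
    build_presence_matrix,
    call_allele_presence,
    hits_from_table,
    reactions_from_alleles,
)
from pangem.synthetic import (
    SyntheticConfig,
    generate_medium,
    generate_reactome,
    generate_strains,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


# --- synthetic study population --------------------------------------------

@pytest.fixture(scope="session")
def config() -> SyntheticConfig:
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def reactome(config):
    return generate_reactome(config)


@pytest.fixture(scope="session")
def medium(reactome, config):
    return generate_medium(reactome, config)


@pytest.fixture(scope="session")
def population(reactome, config):
    """(profiles, similarity table, metadata, ground truth) for the default family."""
    return generate_strains(reactome, config)


@pytest.fixture(scope="session")
def recovered_pam(reactome, population):
    """Presence-absence matrix recovered through the homology-mapping path."""
    _, similarity, metadata, _ = population
    hits = hits_from_table(similarity)
    vectors = {
        strain: reactions_from_alleles(call_allele_presence(strain_hits), reactome)
        for strain, strain_hits in hits.items()
    }
    return build_presence_matrix(vectors, metadata=metadata,
                                 reaction_universe=list(reactome.reactions))


@pytest.fixture(scope="session")
def strain_models(reactome, population):
    _, similarity, metadata, _ = population
    hits = hits_from_table(similarity)
    models = {}
    for strain, strain_hits in hits.items():
        vec = reactions_from_alleles(call_allele_presence(strain_hits), reactome)
        models[strain] = assemble_draft(
            reactome, vec, strain, {"species": metadata.loc[strain, "species"]})
    return models


# --- toy-network construction ----------------------------------------------

def make_network(
    reactions: Dict[str, Tuple[Dict[str, float], str, float, float]],
    biomass_id: str,
    ngam_id: str,
    formulas: Optional[Dict[str, Tuple[str, int]]] = None,
    gprs: Optional[Dict[str, GPRRule]] = None,
) -> StrainModel:
    """Build a StrainModel from ``{id: (stoich, rtype, lb, ub)}`` specs."""
    mets: Dict[str, Metabolite] = {}
    rxns: Dict[str, Reaction] = {}
    for rid, (stoich, rtype, lb, ub) in reactions.items():
        for met in stoich:
            if met not in mets:
                formula, charge = (formulas or {}).get(met, ("C", 0))
                mets[met] = Metabolite(id=met, formula=formula, charge=charge,
                                       compartment="e" if met.endswith("_e") else "c")
        rxns[rid] = Reaction(id=rid, stoichiometry=dict(stoich), lower_bound=lb,
                             upper_bound=ub, rtype=rtype,
                             gpr=(gprs or {}).get(rid))
    return StrainModel(strain_id="toy", metabolites=mets, reactions=rxns,
                       biomass_id=biomass_id, ngam_id=ngam_id)


def linear_chain_model(uptake: float = 10.0, yield_per_substrate: float = 1.0) -> StrainModel:
    """EX_A -> A -> B -> biomass, unit yield; optimum = uptake x yield."""
    return make_network(
        {
            "EX_A": ({"A_e": -1.0}, "exchange", -uptake, 1000.0),
            "T_A": ({"A_e": -1.0, "A": 1.0}, "spontaneous", 0.0, 1000.0),
            "R1": ({"A": -1.0, "B": 1.0}, "gene_associated", 0.0, 1000.0),
            "BIOMASS": ({"B": -1.0 / yield_per_substrate}, "biomass", 0.0, 1000.0),
            "NGAM": ({"B": -1.0}, "sink", 0.0, 1000.0),
        },
        biomass_id="BIOMASS",
        ngam_id="NGAM",
        gprs={"R1": GPRRule.from_sets([["g1"]])},
    )


# --- independent LP oracle: exhaustive vertex enumeration -------------------

def enumerate_vertices(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                       tol: float = 1e-7) -> np.ndarray:
    """All vertices of {v : Sv = 0, lb <= v <= ub} by basis enumeration.

    Every vertex of the flux polytope has at least n - rank(S) coordinates
    at a bound with the remaining square system nonsingular; enumerating all
    such bound patterns therefore visits every vertex.  Only usable for tiny
    networks (n <= ~10).
    """
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S) if S.size else 0
    n_fixed = n - rank
    points: List[np.ndarray] = []
    for fixed in combinations(range(n), n_fixed):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for pattern in product((0, 1), repeat=n_fixed):
            x = np.zeros(n)
            for j, side in zip(fixed, pattern):
                x[j] = lb[j] if side == 0 else ub[j]
            b = -S[:, list(fixed)] @ x[list(fixed)]
            if free:
                sol, residuals, rk, _ = np.linalg.lstsq(A, b, rcond=None)
                x[free] = sol
            if np.max(np.abs(S @ x)) > tol:
                continue
            if np.any(x < lb - tol) or np.any(x > ub + tol):
                continue
            points.append(np.clip(x, lb, ub))
    if not points:
        return np.empty((0, n))
    return np.unique(np.round(np.asarray(points), 9), axis=0)


def brute_force_fba(model: StrainModel, objective_id: str) -> Tuple[float, np.ndarray]:
    """LP optimum by vertex enumeration; returns (optimum, optimal vertices)."""
    from pangem import lp

    problem = lp.build_problem(model)
    verts = enumerate_vertices(problem.S, problem.lb, problem.ub)
    assert verts.shape[0] > 0, "empty feasible set in oracle"
    j = problem.index[objective_id]
    values = verts[:, j]
    best = values.max()
    return float(best), verts[values >= best - 1e-9]


def random_toy_network(rng: np.random.Generator, max_reactions: int = 8) -> StrainModel:
    """Random small flux network with finite bounds (always feasible at v=0)."""
    n = int(rng.integers(3, max_reactions + 1))
    m = int(rng.integers(1, 5))
    mets = [f"m{i}" for i in range(m)]
    reactions: Dict[str, Tuple[Dict[str, float], str, float, float]] = {}
    for j in range(n):
        stoich: Dict[str, float] = {}
        for i in rng.choice(m, size=int(rng.integers(1, min(m, 3) + 1)), replace=False):
            coeff = float(rng.choice([-2.0, -1.0, 1.0, 2.0]))
            stoich[mets[i]] = coeff
        lb = float(rng.choice([0.0, -5.0]))
        ub = float(rng.choice([3.0, 5.0, 10.0]))
        rtype = "biomass" if j == 0 else "orphan"
        reactions[f"r{j}"] = (stoich, rtype, lb, ub)
    return make_network(reactions, biomass_id="r0", ngam_id="r0")
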