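"""Niche-association statistics over the presence-absence matrix.

Strain reactomes are compared by Jaccard distance on reaction sets; the
share of distance variation explained by a grouping factor (isolation
source, genus, ...) is quantified by PERMANOVA (pseudo-F on squared
distances with label permutation); per-reaction niche enrichment uses
2x2 contingency tables scored by Fisher's exact test, a chi-square test,
and the natural-log odds ratio with a Haldane-Anscombe 0.5 correction
whenever a cell is zero (exclusive reactions otherwise give infinite odds
ratios).  PCA (three components, as many embedding analyses of niche
structure use) and k-means clustering support visual exploration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sympy.utilities.iterables import multiset_permutations

from .mapping import PresenceAbsenceMatrix
from .model import ValidationError

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "ContingencyTable",
    "EnrichmentResult",
    "jaccard_distances",
    "permanova",
    "build_contingency",
    "fisher_exact",
    "log_odds_ratio",
    "chi_square",
    "compute_enrichment",
    "select_enriched",
    "pca_embed",
    "kmeans_clusters",
]

DEFAULT_MIN_NICHE_SIZE = 11  # "more than 10 strains", read strictly
DEFAULT_LOR_MIN = 5.0  # natural-log odds-ratio threshold for enrichment calls
EXACT_ENUMERATION_LIMIT = 10_000  # switch PERMANOVA to exhaustive labelings below this


@dataclass
class DistanceMatrix:
    labels: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValidationError("distance matrix must have a zero diagonal")
        if (v < -1e-12).any():
            raise ValidationError("distances must be non-negative")
        self.values = v


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: Optional[int]
    exact: bool = False


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 reaction-by-niche carriage table.

    a: strains in the niche carrying the reaction; b: in the niche, not
    carrying; c: outside the niche, carrying; d: outside, not carrying.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency cells must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass
class EnrichmentResult:
    reaction: str
    niche: str
    table: ContingencyTable
    log_odds_ratio: float
    fisher_p: float
    chi2_p: Optional[float]
    exclusive: bool = False


def jaccard_distances(pam: PresenceAbsenceMatrix) -> DistanceMatrix:
    """Pairwise Jaccard distances between strain reaction sets."""
    zero_rows = pam.data.index[pam.data.sum(axis=1) == 0]
    if len(zero_rows) > 0:
        raise ValidationError(f"strain(s) with empty reactome: {list(zero_rows)}")
    condensed = pdist(pam.data.to_numpy().astype(bool), metric="jaccard")
    return DistanceMatrix(labels=pam.strains, values=squareform(condensed))


def _pseudo_f(d2: np.ndarray, groups: np.ndarray, group_ids: np.ndarray) -> Tuple[float, float]:
    """Pseudo-F and R2 from squared distances and integer group labels."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in group_ids:
        members = np.flatnonzero(groups == g)
        if len(members) > 1:
            sub = d2[np.ix_(members, members)]
            ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
    ss_between = ss_total - ss_within
    a = len(group_ids)
    f = (ss_between / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else math.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _count_labelings(counts: Sequence[int]) -> int:
    total = math.factorial(sum(counts))
    for c in counts:
        total //= math.factorial(c)
    return total


def permanova(
    dist: DistanceMatrix,
    labels: Sequence[str],
    n_permutations: int = 999,
    seed: Optional[int] = None,
    method: str = "auto",
) -> PermanovaResult:
    """One-factor PERMANOVA on a distance matrix.

    With ``method="auto"`` (default), distinct labelings are enumerated
    exhaustively when their count is at most ``EXACT_ENUMERATION_LIMIT`` (the
    p-value is then exact); otherwise — or with ``method="permutation"`` —
    ``n_permutations`` random label permutations are drawn with ``seed`` and
    the p-value includes the observed labeling, so it is never below
    1/(n_permutations + 1).  ``method="exact"`` forces enumeration.
    """
    if method not in ("auto", "exact", "permutation"):
        raise ValidationError(f"unknown PERMANOVA method {method!r}")
    labels = np.asarray([str(x) for x in labels])
    if len(labels) != len(dist.labels):
        raise ValidationError("label vector length does not match distance matrix")
    uniq, groups = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValidationError("PERMANOVA needs at least 2 groups")
    counts = np.bincount(groups)
    if counts.min() < 2:
        raise ValidationError("every group needs at least 2 members")
    d2 = dist.values**2
    group_ids = np.arange(len(uniq))
    f_obs, r2 = _pseudo_f(d2, groups, group_ids)

    n_distinct = _count_labelings(counts.tolist())
    use_exact = method == "exact" or (method == "auto" and n_distinct <= EXACT_ENUMERATION_LIMIT)
    if use_exact:
        hits = 0
        total = 0
        for perm in multiset_permutations(groups.tolist()):
            f_perm, _ = _pseudo_f(d2, np.asarray(perm), group_ids)
            total += 1
            if f_perm >= f_obs - 1e-12:
                hits += 1
        return PermanovaResult(f_obs, r2, hits / total, total, seed, exact=True)

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        f_perm, _ = _pseudo_f(d2, perm, group_ids)
        if f_perm >= f_obs - 1e-12:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(f_obs, r2, p, n_permutations, seed, exact=False)


def build_contingency(
    pam: PresenceAbsenceMatrix,
    niche_labels: Mapping[str, str],
    min_niche_size: int = DEFAULT_MIN_NICHE_SIZE,
) -> Dict[Tuple[str, str], ContingencyTable]:
    """2x2 tables for every (reaction, niche) pair over labeled strains.

    Only niches with at least ``min_niche_size`` strains are considered
    (the default keeps niches with more than 10 strains); the comparison is
    one-vs-rest over strains that have a niche label.
    """
    labeled = [s for s in pam.strains if s in niche_labels and niche_labels[s]]
    niche_of = {s: niche_labels[s] for s in labeled}
    sizes: Dict[str, int] = {}
    for s in labeled:
        sizes[niche_of[s]] = sizes.get(niche_of[s], 0) + 1
    kept = {n for n, size in sizes.items() if size >= min_niche_size}
    data = pam.data.loc[labeled]
    tables: Dict[Tuple[str, str], ContingencyTable] = {}
    for niche in sorted(kept):
        in_niche = np.array([niche_of[s] == niche for s in labeled])
        carry = data.to_numpy()
        for j, rid in enumerate(pam.reactions):
            col = carry[:, j].astype(bool)
            a = int(np.sum(col & in_niche))
            b = int(np.sum(~col & in_niche))
            c = int(np.sum(col & ~in_niche))
            d = int(np.sum(~col & ~in_niche))
            tables[(rid, niche)] = ContingencyTable(a, b, c, d)
    return tables


def fisher_exact(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p-value (sum of tables as or less probable)."""
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(p)


def log_odds_ratio(table: ContingencyTable, pseudocount: float = 0.5) -> float:
    """Natural-log odds ratio, Haldane-Anscombe corrected when a cell is zero."""
    a, b, c, d = (float(x) for x in (table.a, table.b, table.c, table.d))
    if min(a, b, c, d) == 0.0:
        a, b, c, d = (x + pseudocount for x in (a, b, c, d))
    return math.log((a * d) / (b * c))


def chi_square(table: ContingencyTable) -> Tuple[float, float]:
    """Pearson chi-square statistic (no continuity correction) and chi2(1) p."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValidationError("chi-square undefined with a zero margin")
    statistic, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(statistic), float(p)


def compute_enrichment(
    pam: PresenceAbsenceMatrix,
    niche_labels: Mapping[str, str],
    min_niche_size: int = DEFAULT_MIN_NICHE_SIZE,
) -> List[EnrichmentResult]:
    """Full enrichment scan: log-OR, Fisher and chi-square per (reaction, niche)."""
    tables = build_contingency(pam, niche_labels, min_niche_size)
    results = []
    for (rid, niche), table in sorted(tables.items()):
        try:
            chi2_p: Optional[float] = chi_square(table)[1]
        except ValidationError:
            chi2_p = None
        results.append(
            EnrichmentResult(
                reaction=rid,
                niche=niche,
                table=table,
                log_odds_ratio=log_odds_ratio(table),
                fisher_p=fisher_exact(table),
                chi2_p=chi2_p,
            )
        )
    return results


def select_enriched(
    results: Iterable[EnrichmentResult],
    lor_min: float = DEFAULT_LOR_MIN,
    require_exclusive: bool = True,
) -> List[EnrichmentResult]:
    """Keep (reaction, niche) pairs with log-OR above the threshold.

    With ``require_exclusive``, a reaction is kept only if it passes the
    threshold in exactly one niche.
    """
    results = list(results)
    passing = [r for r in results if r.log_odds_ratio > lor_min]
    niches_passing: Dict[str, Set[str]] = {}
    for r in passing:
        niches_passing.setdefault(r.reaction, set()).add(r.niche)
    out = []
    for r in passing:
        exclusive = len(niches_passing[r.reaction]) == 1
        if require_exclusive and not exclusive:
            continue
        out.append(
            EnrichmentResult(r.reaction, r.niche, r.table, r.log_odds_ratio,
                             r.fisher_p, r.chi2_p, exclusive=exclusive)
        )
    return out


def enrichment_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    rows = [
        {
            "reaction": r.reaction, "niche": r.niche,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "log_or": r.log_odds_ratio, "fisher_p": r.fisher_p,
            "chi2_p": r.chi2_p, "exclusive": r.exclusive,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def pca_embed(
    pam: PresenceAbsenceMatrix, n_components: int = 3
) -> Tuple[pd.DataFrame, np.ndarray]:
    """PCA of the column-centered 0/1 matrix (no scaling).

    Returns per-strain coordinates and explained-variance fractions.  The
    sign of each component is fixed by making its largest-magnitude loading
    positive, so embeddings are deterministic.  If the matrix rank is below
    ``n_components``, fewer components are returned with a warning.
    """
    x = pam.data.to_numpy().astype(float)
    rank = np.linalg.matrix_rank(x - x.mean(axis=0))
    k = min(n_components, rank, x.shape[0], x.shape[1])
    if k < n_components:
        import warnings

        warnings.warn(f"matrix rank {k} < requested {n_components} components", stacklevel=2)
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(x)
    for j in range(k):
        loading = pca.components_[j]
        if loading[np.argmax(np.abs(loading))] < 0:
            coords[:, j] *= -1.0
    frame = pd.DataFrame(coords, index=pam.strains,
                         columns=[f"PC{i + 1}" for i in range(k)])
    return frame, pca.explained_variance_ratio_


def kmeans_clusters(
    coordinates: pd.DataFrame, k: int = 9, seed: int = 0
) -> pd.Series:
    """K-means cluster labels (deterministic given the seed)."""
    if k > coordinates.shape[0]:
        raise ValidationError(f"k={k} exceeds the number of points {coordinates.shape[0]}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(coordinates.to_numpy())
    return pd.Series(labels, index=coordinates.index, name="cluster")
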