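"""Distances, PERMANOVA, enrichment statistics, embedding and clustering."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pangem.mapping import PresenceAbsenceMatrix
from pangem.model import ValidationError
from pangem.niche_stats import (
    ContingencyTable,
    DistanceMatrix,
    build_contingency,
    chi_square,
    compute_enrichment,
    fisher_exact,
    jaccard_distances,
    kmeans_clusters,
    log_odds_ratio,
    pca_embed,
    permanova,
    select_enriched,
)


def _pam(matrix, strains, reactions, **meta):
    data = pd.DataFrame(matrix, index=strains, columns=reactions)
    return PresenceAbsenceMatrix(data=data, metadata=pd.DataFrame(meta, index=data.index))


class TestJaccard:
    def test_half_overlap(self):
        pam = _pam([[1, 1, 1, 0], [0, 1, 1, 1]], ["s", "t"], list("WXYZ"))
        assert jaccard_distances(pam).values[0, 1] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        pam = _pam([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1]],
                   list("abc"), list("WXYZ"))
        d = jaccard_distances(pam).values
        assert d[0, 1] == pytest.approx(0.0)
        assert d[0, 2] == pytest.approx(1.0)

    def test_empty_reactome_rejected(self):
        pam = _pam([[1], [0]], ["a", "b"], ["R"])
        with pytest.raises(ValidationError, match="b"):
            jaccard_distances(pam)

    def test_triangle_inequality(self, recovered_pam):
        d = jaccard_distances(recovered_pam).values
        n = d.shape[0]
        rng = np.random.default_rng(0)
        for i, j, k in rng.integers(0, n, size=(200, 3)):
            assert d[i, k] <= d[i, j] + d[j, k] + 1e-12


def _two_blob_distance(n_per=3, sep=1.0):
    labels = [f"p{i}" for i in range(2 * n_per)]
    coords = np.array([[0.0]] * n_per + [[sep]] * n_per)
    d = np.abs(coords - coords.T)
    return DistanceMatrix(labels=labels, values=d), ["A"] * n_per + ["B"] * n_per


class TestPermanova:
    def test_separated_groups_explain_everything(self):
        dist, labels = _two_blob_distance()
        res = permanova(dist, labels)
        assert res.R2 == pytest.approx(1.0)
        assert res.exact
        # only the observed split and its A/B mirror reach the maximal F,
        # so the exact p is 2 / C(6,3)
        assert res.p_value == pytest.approx(2 / len(list(combinations(range(6), 3))))

    def test_exact_agrees_with_permutation_for_small_n(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(8, 2))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        dist = DistanceMatrix(labels=[f"p{i}" for i in range(8)], values=d)
        labels = ["A"] * 4 + ["B"] * 4
        exact = permanova(dist, labels, method="exact")
        perm = permanova(dist, labels, method="permutation",
                         n_permutations=4999, seed=1)
        assert exact.pseudo_F == pytest.approx(perm.pseudo_F)
        assert exact.R2 == pytest.approx(perm.R2)
        assert perm.p_value == pytest.approx(exact.p_value, abs=0.03)

    def test_matches_reference_implementation(self):
        """Pseudo-F and p agree with scikit-bio's PERMANOVA."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(12, 3))
        coords[6:] += 1.5
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        labels = ["A"] * 6 + ["B"] * 6
        ids = [f"p{i}" for i in range(12)]
        ours = permanova(DistanceMatrix(labels=ids, values=d), labels)
        ref = skbio_stats.permanova(skbio_stats.DistanceMatrix(d, ids),
                                    grouping=labels, permutations=999)
        assert ours.pseudo_F == pytest.approx(ref["test statistic"], rel=1e-9)
        assert ours.p_value == pytest.approx(ref["p-value"], abs=0.05)

    def test_within_group_relabeling_leaves_f_unchanged(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(9, 2))
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        ids = [f"p{i}" for i in range(9)]
        labels = ["A", "A", "A", "B", "B", "B", "C", "C", "C"]
        shuffled = ["A", "A", "A", "B", "B", "B", "C", "C", "C"]
        f1 = permanova(DistanceMatrix(labels=ids, values=d), labels).pseudo_F
        f2 = permanova(DistanceMatrix(labels=ids, values=d), shuffled).pseudo_F
        assert f1 == pytest.approx(f2)

    def test_p_value_floor(self):
        dist, labels = _two_blob_distance(n_per=10, sep=3.0)
        res = permanova(dist, labels, n_permutations=99, seed=0,
                        method="permutation")
        assert res.p_value >= 1.0 / 100.0

    def test_singleton_group_rejected(self):
        dist, _ = _two_blob_distance()
        with pytest.raises(ValidationError):
            permanova(dist, ["A"] + ["B"] * 5)

    def test_null_p_values_have_no_gross_bias(self):
        """Exchangeable points with random labels: mean p near 0.5.

        The full 500-replicate Kolmogorov-Smirnov uniformity check runs with
        the statistics-oracle suite; here a cheaper moment check guards
        against gross miscalibration.
        """
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(60):
            coords = rng.normal(size=(10, 2))
            d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
            dist = DistanceMatrix(labels=[f"p{i}" for i in range(10)], values=d)
            labels = list(rng.permutation(["A"] * 5 + ["B"] * 5))
            pvals.append(permanova(dist, labels).p_value)
        assert 0.35 < float(np.mean(pvals)) < 0.65


class TestContingency:
    def test_worked_example(self):
        matrix = np.zeros((112, 1), dtype=int)
        matrix[:8] = 1          # 8 of 12 niche strains carry R
        matrix[12:22] = 1       # 10 of 100 outside
        strains = [f"s{i}" for i in range(112)]
        labels = {s: ("kefir" if i < 12 else "other") for i, s in enumerate(strains)}
        pam = _pam(matrix, strains, ["R"])
        tables = build_contingency(pam, labels)
        assert tables[("R", "kefir")] == ContingencyTable(8, 4, 10, 90)

    def test_small_niche_excluded(self):
        strains = [f"s{i}" for i in range(30)]
        labels = {s: ("tiny" if i < 10 else "big") for i, s in enumerate(strains)}
        pam = _pam(np.ones((30, 1), dtype=int), strains, ["R"])
        tables = build_contingency(pam, labels)
        assert all(niche != "tiny" for _, niche in tables)
        assert ("R", "big") in tables

    def test_margins_match_strain_count(self, recovered_pam, population):
        truth = population[3]
        tables = build_contingency(recovered_pam, truth.niche_of)
        n = recovered_pam.data.shape[0]
        assert tables and all(t.total == n for t in tables.values())

    def test_invariants(self):
        with pytest.raises(ValidationError):
            ContingencyTable(-1, 0, 0, 0)


class TestFisher:
    def test_tiny_table(self):
        assert fisher_exact(ContingencyTable(2, 0, 0, 2)) == pytest.approx(1 / 3)

    def test_balanced_table(self):
        assert fisher_exact(ContingencyTable(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        """Two-sided p equals the sum of hypergeometric probabilities of all
        tables with the same margins that are no more probable."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 7, size=4))
            if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
                continue
            table = ContingencyTable(a, b, c, d)
            n, r1, c1 = table.total, a + b, a + c
            dist = stats.hypergeom(n, c1, r1)
            support = range(max(0, r1 + c1 - n), min(r1, c1) + 1)
            p_obs = dist.pmf(a)
            expected = sum(dist.pmf(k) for k in support
                           if dist.pmf(k) <= p_obs * (1 + 1e-9))
            assert fisher_exact(table) == pytest.approx(min(1.0, expected), rel=1e-7)


class TestLogOddsRatio:
    def test_closed_form(self):
        assert log_odds_ratio(ContingencyTable(8, 2, 10, 80)) == pytest.approx(
            math.log(32.0))

    def test_haldane_correction_on_zero_cell(self):
        value = log_odds_ratio(ContingencyTable(5, 0, 2, 10))
        assert value == pytest.approx(math.log((5.5 * 10.5) / (0.5 * 2.5)))

    def test_symmetric_table_is_zero(self):
        assert log_odds_ratio(ContingencyTable(4, 4, 4, 4)) == pytest.approx(0.0)

    def test_direction_agrees_with_enrichment(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 20, size=4))
            lor = log_odds_ratio(ContingencyTable(a, b, c, d))
            assert (lor > 0) == (a / b > c / d) or a / b == c / d


class TestChiSquare:
    def test_independent_table(self):
        statistic, p = chi_square(ContingencyTable(10, 10, 10, 10))
        assert statistic == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_matches_closed_form(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 25, size=4))
            statistic, _ = chi_square(ContingencyTable(a, b, c, d))
            n = a + b + c + d
            expected = np.outer([a + b, c + d], [a + c, b + d]) / n
            observed = np.array([[a, b], [c, d]])
            assert statistic == pytest.approx(
                float(((observed - expected) ** 2 / expected).sum()))

    def test_transpose_invariance(self):
        s1, _ = chi_square(ContingencyTable(3, 7, 11, 2))
        s2, _ = chi_square(ContingencyTable(3, 11, 7, 2))
        assert s1 == pytest.approx(s2)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValidationError):
            chi_square(ContingencyTable(0, 0, 5, 5))


class TestSelectEnriched:
    def _results(self):
        from pangem.niche_stats import EnrichmentResult

        def res(rid, niche, lor):
            return EnrichmentResult(rid, niche, ContingencyTable(1, 1, 1, 1),
                                    lor, 1.0, 1.0)

        return [res("R1", "kefir", 6.0), res("R2", "kefir", 6.0),
                res("R2", "wine", 5.5), res("R3", "wine", 4.0)]

    def test_exclusive_reaction_kept(self):
        kept = select_enriched(self._results(), lor_min=5.0)
        assert [(r.reaction, r.niche) for r in kept] == [("R1", "kefir")]
        assert kept[0].exclusive

    def test_multi_niche_reaction_dropped_when_exclusive_required(self):
        kept = select_enriched(self._results(), lor_min=5.0, require_exclusive=False)
        assert {(r.reaction, r.niche) for r in kept} == {
            ("R1", "kefir"), ("R2", "kefir"), ("R2", "wine")}

    def test_output_subset_and_order_stable(self):
        results = self._results()
        kept1 = select_enriched(results)
        kept2 = select_enriched(list(reversed(results)))
        assert {(r.reaction, r.niche) for r in kept1} == \
               {(r.reaction, r.niche) for r in kept2}


class TestPlantedEnrichment:
    def test_planted_reactions_rank_first_by_log_or(self, recovered_pam, population):
        truth = population[3]
        results = compute_enrichment(recovered_pam, truth.niche_of)
        for niche, planted in truth.enriched.items():
            per_niche = sorted((r for r in results if r.niche == niche),
                               key=lambda r: -r.log_odds_ratio)
            assert per_niche[0].reaction in planted


class TestPCA:
    def test_single_varying_reaction(self):
        matrix = np.ones((6, 4), dtype=int)
        matrix[:3, 0] = 0
        pam = _pam(matrix, [f"s{i}" for i in range(6)], list("WXYZ"))
        _, evr = pca_embed(pam, n_components=2)
        assert evr[0] == pytest.approx(1.0)

    def test_full_rank_embedding_preserves_distances(self):
        rng = np.random.default_rng(10)
        matrix = rng.integers(0, 2, size=(8, 6))
        pam = _pam(matrix, [f"s{i}" for i in range(8)], [f"r{j}" for j in range(6)])
        x = matrix.astype(float)
        centered = x - x.mean(axis=0)
        k = np.linalg.matrix_rank(centered)
        coords, _ = pca_embed(pam, n_components=k)
        assert coords.shape[1] == k
        d_orig = np.linalg.norm(centered[:, None] - centered[None, :], axis=2)
        c = coords.to_numpy()
        d_emb = np.linalg.norm(c[:, None] - c[None, :], axis=2)
        assert np.allclose(d_orig, d_emb, atol=1e-8)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(11)
        matrix = rng.integers(0, 2, size=(10, 5))
        pam = _pam(matrix, [f"s{i}" for i in range(10)], [f"r{j}" for j in range(5)])
        c1, _ = pca_embed(pam)
        c2, _ = pca_embed(pam)
        assert np.allclose(c1.to_numpy(), c2.to_numpy())


class TestKMeans:
    def test_k_equals_one(self):
        coords = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 2)))
        assert set(kmeans_clusters(coords, k=1, seed=0)) == {0}

    def test_two_blobs_recovered(self):
        rng = np.random.default_rng(1)
        blob1 = rng.normal(0, 0.1, size=(10, 2))
        blob2 = rng.normal(5, 0.1, size=(10, 2))
        coords = pd.DataFrame(np.vstack([blob1, blob2]))
        labels = kmeans_clusters(coords, k=2, seed=0)
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels.iloc[0] != labels.iloc[10]

    def test_same_seed_same_labels(self):
        coords = pd.DataFrame(np.random.default_rng(2).normal(size=(20, 3)))
        l1 = kmeans_clusters(coords, k=4, seed=9)
        l2 = kmeans_clusters(coords, k=4, seed=9)
        assert l1.equals(l2)

    def test_k_larger_than_points_rejected(self):
        coords = pd.DataFrame(np.zeros((3, 2)))
        with pytest.raises(ValidationError):
            kmeans_clusters(coords, k=5, seed=0)
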