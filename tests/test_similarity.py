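import datetime as dt

import numpy as np
import pytest

from pksminer.records import PKSCluster, ProteinRecord
from pksminer.similarity import (
    nearest_characterized,
    novelty_fraction,
    pairwise_similarity,
    rediscovery_rate,
    remove_redundant,
    similarity_matrix,
)
from pksminer.synth import SynthSpec, generate_cluster, mutate_homolog
from .conftest import make_cluster, make_matrix


def _compact(seed, cluster_id="a", n_modules=3):
    spec = SynthSpec(n_modules=n_modules, rich_modules=False,
                     modules_per_protein=1, seed=seed)
    return generate_cluster(spec, cluster_id)[1]


def greedy_prune_oracle(ids_in_priority, get_score, threshold):
    retained, removed = [], {}
    for c in ids_in_priority:
        hit = next((r for r in retained if get_score(c, r) > threshold), None)
        if hit is None:
            retained.append(c)
        else:
            removed[c] = hit
    return retained, removed


class TestPairwiseSimilarity:
    def test_self_similarity_is_100(self):
        a = _compact(1)
        assert pairwise_similarity(a, a) == 100.0

    def test_five_percent_homolog_scores_at_least_90(self):
        a = _compact(2)
        b = mutate_homolog(a, subst_rate=0.05, seed=3, new_id="b")
        assert pairwise_similarity(a, b) >= 90.0

    def test_unrelated_random_proteins_score_below_15(self):
        rng = np.random.default_rng(5)
        aa = list("ACDEFGHIKLMNPQRSTVWY")

        def random_cluster(cid):
            prots = [
                ProteinRecord(f"{cid}_p{i}", "".join(rng.choice(aa, size=400)))
                for i in range(3)
            ]
            return PKSCluster(cid, cid, 0, 3600, proteins=prots)

        scores = [
            pairwise_similarity(random_cluster(f"x{i}"), random_cluster(f"y{i}"))
            for i in range(5)
        ]
        assert max(scores) < 15.0

    def test_symmetric_bounded_and_order_invariant(self):
        a, b = _compact(7), _compact(8, "b")
        s1 = pairwise_similarity(a, b)
        s2 = pairwise_similarity(b, a)
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert 0.0 <= s1 <= 100.0
        shuffled = PKSCluster(
            a.cluster_id, a.record_id, a.start, a.end,
            proteins=list(reversed(a.proteins)), sequence=a.sequence,
        )
        assert pairwise_similarity(shuffled, b) == pytest.approx(s1, abs=1e-9)

    def test_monotone_non_increasing_along_divergence_series(self):
        a = _compact(11)
        rates = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        scores = [
            pairwise_similarity(a, mutate_homolog(a, r, seed=13, new_id=f"m{r}"))
            for r in rates
        ]
        assert scores[0] == 100.0
        assert all(s1 >= s2 - 1e-9 for s1, s2 in zip(scores, scores[1:]))

    def test_heavy_divergence_with_indels_scores_below_50(self):
        a = _compact(17)
        far = mutate_homolog(a, subst_rate=0.5, indel_rate=0.02, seed=19, new_id="far")
        assert pairwise_similarity(a, far) < 50.0

    def test_macrolide_like_band(self):
        # families at moderate divergence should mostly fall in the
        # 46-89 % band seen for closely related macrolide assembly lines
        a = _compact(23)
        scores = [
            pairwise_similarity(a, mutate_homolog(a, r, seed=s, new_id=f"h{s}"))
            for s, r in enumerate([0.2, 0.25, 0.3, 0.35, 0.4])
        ]
        in_band = sum(46.0 <= s <= 89.0 for s in scores)
        assert in_band >= 4

    def test_empty_proteins_rejected(self):
        a = _compact(29)
        empty = PKSCluster("e", "e", 0, 10, proteins=[])
        with pytest.raises(ValueError):
            pairwise_similarity(a, empty)


class TestSimilarityMatrix:
    def test_single_cluster(self):
        m = similarity_matrix([_compact(31)])
        assert m.scores.shape == (1, 1) and m.scores[0, 0] == 100.0

    def test_three_clusters_symmetric_and_permutable(self):
        clusters = [_compact(37, "a"), _compact(41, "b"), _compact(43, "c")]
        m = similarity_matrix(clusters)
        assert np.allclose(m.scores, m.scores.T)
        assert np.allclose(np.diag(m.scores), 100.0)
        perm = [clusters[2], clusters[0], clusters[1]]
        m2 = similarity_matrix(perm)
        for x in "abc":
            for y in "abc":
                assert m.get(x, y) == pytest.approx(m2.get(x, y), abs=1e-9)


class TestRemoveRedundant:
    def _clusters(self, ids, dates=None):
        out = []
        for i, cid in enumerate(ids):
            c = make_cluster(cid, ("KS-AT-ACP",))
            c.deposit_date = (dates or {}).get(cid, dt.date(2000, 1, 1) + dt.timedelta(days=i))
            out.append(c)
        return out

    def test_worked_example(self):
        clusters = self._clusters(["A", "B", "C"])
        m = make_matrix(
            ["A", "B", "C"],
            {frozenset("AB"): 95, frozenset("AC"): 40, frozenset("BC"): 42},
        )
        cat = remove_redundant(clusters, m, 90)
        assert sorted(c.cluster_id for c in cat.clusters) == ["A", "C"]
        assert cat.removed == {"B": "A"}

    def test_non_transitive_chain(self):
        clusters = self._clusters(["A", "B", "C"])
        m = make_matrix(
            ["A", "B", "C"],
            {frozenset("AB"): 95, frozenset("BC"): 95, frozenset("AC"): 60},
        )
        cat = remove_redundant(clusters, m, 90)
        assert sorted(c.cluster_id for c in cat.clusters) == ["A", "C"]
        assert cat.removed == {"B": "A"}

    def test_all_dissimilar_all_retained(self):
        clusters = self._clusters(["A", "B", "C"])
        m = make_matrix(["A", "B", "C"], {})
        cat = remove_redundant(clusters, m, 90)
        assert len(cat) == 3 and cat.removed == {}

    def test_threshold_validation(self):
        clusters = self._clusters(["A"])
        m = make_matrix(["A"], {})
        with pytest.raises(ValueError):
            remove_redundant(clusters, m, 100.0)

    def test_matches_greedy_oracle_on_random_matrices(self):
        rng = np.random.default_rng(47)
        for trial in range(200):
            n = int(rng.integers(2, 15))
            ids = [f"t{trial}x{i:02d}" for i in range(n)]
            scores = rng.uniform(0, 100, size=(n, n))
            scores = (scores + scores.T) / 2
            np.fill_diagonal(scores, 100.0)
            from pksminer.records import SimilarityMatrix

            m = SimilarityMatrix(ids, scores)
            dates = {cid: dt.date(1995, 1, 1) + dt.timedelta(days=int(rng.integers(0, 9000))) for cid in ids}
            clusters = self._clusters(ids, dates)
            threshold = float(rng.uniform(30, 95))
            cat = remove_redundant(clusters, m, threshold)
            priority = sorted(
                clusters,
                key=lambda c: (c.deposit_date, -c.length_aa, c.cluster_id),
            )
            exp_ret, exp_rem = greedy_prune_oracle(
                [c.cluster_id for c in priority], m.get, threshold
            )
            assert {c.cluster_id for c in cat.clusters} == set(exp_ret)
            assert cat.removed == exp_rem
            # cover property: retained pairs <= threshold, removed > threshold
            off = cat.similarity.scores[~np.eye(len(cat), dtype=bool)]
            if off.size:
                assert off.max() <= threshold + 1e-9
            for gone, rep in cat.removed.items():
                assert m.get(gone, rep) > threshold


class TestRediscoveryAndNovelty:
    def test_hand_enumerable_series(self):
        ids = ["A", "B", "C", "D"]
        dates = {
            "A": dt.date(1999, 1, 1), "B": dt.date(2000, 1, 1),
            "C": dt.date(2001, 1, 1), "D": dt.date(2002, 1, 1),
        }
        clusters = []
        for cid in ids:
            c = make_cluster(cid, ("KS-AT-ACP",))
            c.deposit_date = dates[cid]
            clusters.append(c)
        m = make_matrix(ids, {frozenset("AC"): 95})
        rates = rediscovery_rate(clusters, m, 90)
        assert rates == {
            1999: 0.0, 2000: 0.0,
            2001: pytest.approx(100 / 3),
            2002: pytest.approx(25.0),
        }

    def test_all_dissimilar_all_zero(self):
        clusters = []
        for i, cid in enumerate("ABC"):
            c = make_cluster(cid, ("KS-AT-ACP",))
            c.deposit_date = dt.date(1999 + i, 1, 1)
            clusters.append(c)
        m = make_matrix(list("ABC"), {})
        assert set(rediscovery_rate(clusters, m, 90).values()) == {0.0}

    def test_missing_dates_listed(self):
        c = make_cluster("A", ("KS-AT-ACP",))
        c.deposit_date = None
        with pytest.raises(ValueError, match="A"):
            rediscovery_rate([c], make_matrix(["A"], {}), 90)

    def test_nearest_characterized_argmax_and_ties(self):
        orphan = make_cluster("o", ("KS-AT-ACP",))
        k1 = make_cluster("k1", ("KS-AT-ACP",))
        k2 = make_cluster("k2", ("KS-AT-ACP",))
        m = make_matrix(
            ["o", "k1", "k2"], {frozenset(["o", "k1"]): 30, frozenset(["o", "k2"]): 60}
        )
        assert nearest_characterized([orphan], [k1, k2], m) == {"o": ("k2", 60.0)}
        m_tie = make_matrix(
            ["o", "k1", "k2"], {frozenset(["o", "k1"]): 60, frozenset(["o", "k2"]): 60}
        )
        assert nearest_characterized([orphan], [k1, k2], m_tie)["o"][0] == "k1"
        with pytest.raises(ValueError):
            nearest_characterized([orphan], [], m)

    def test_novelty_fraction_strict_threshold(self):
        nm = {"a": ("k", 30.0), "b": ("k", 60.0), "c": ("k", 45.0)}
        assert novelty_fraction(nm, 50) == pytest.approx(200 / 3)
        assert novelty_fraction({"a": ("k", 55.0)}, 50) == 0.0
        # a score of exactly 50 is NOT novel (strictly-less-than rule)
        assert novelty_fraction({"a": ("k", 50.0)}, 50) == 0.0
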