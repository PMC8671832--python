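"""Information-content similarity: closed-form anchors on the toy
ontology, invariants, and the permutation p-value."""
import itertools
import math

import numpy as np
import pytest

from tadsv.core import DiseaseRecord
from tadsv.phenosim import OntologyGraph, UndefinedICError

from conftest import A1, A2, B1, B2, D1, D4, LN2, LN4, LN43, ROOT, TERM_A, TERM_B


class TestInformationContent:
    def test_leaf_annotating_one_of_four(self, ontology):
        assert ontology.information_content(A2) == pytest.approx(LN4)

    def test_root_is_zero(self, ontology):
        assert ontology.information_content(ROOT) == 0.0

    def test_term_annotating_two_of_four(self, ontology):
        assert ontology.information_content(A1) == pytest.approx(LN2)

    def test_unannotated_term_is_undefined(self, ontology):
        with pytest.raises(UndefinedICError):
            ontology.information_content("HP:0000030")

    def test_propagation_superset(self, ontology):
        # branch B unites its leaves' diseases: 3 of 4
        assert ontology.information_content(TERM_B) == pytest.approx(LN43)
        for child in ontology.terms:
            for parent in ontology._dag.successors(child):
                assert ontology.annotations[parent] >= ontology.annotations[child]


class TestPairwiseSim:
    def test_self_similarity_is_ic(self, ontology):
        for t in (A1, A2, B1, B2):
            assert ontology.pairwise_sim(t, t) == pytest.approx(
                ontology.information_content(t)
            )

    def test_cross_branch_shares_only_root(self, ontology):
        assert ontology.pairwise_sim(A1, B2) == 0.0

    def test_mica_within_branch(self, ontology):
        assert ontology.pairwise_sim(B1, B2) == pytest.approx(LN43)

    def test_symmetric(self, ontology):
        terms = sorted(ontology.annotated_pool())
        for t1, t2 in itertools.combinations(terms, 2):
            assert ontology.pairwise_sim(t1, t2) == ontology.pairwise_sim(t2, t1)

    def test_bounded_by_min_ic(self, ontology):
        for t1, t2 in itertools.product(ontology.annotated_pool(), repeat=2):
            assert ontology.pairwise_sim(t1, t2) <= min(
                ontology.information_content(t1), ontology.information_content(t2)
            ) + 1e-12


class TestListSim:
    def test_self_comparison_is_mean_ic(self, ontology):
        assert ontology.list_sim([A1, A2], [A1, A2]) == pytest.approx(
            (LN2 + LN4) / 2
        )

    def test_hand_computed_best_match(self, ontology):
        # {a1,b1} vs D4={b1,b2}: forward (0 + ln2)/2, reverse (ln2 + ln(4/3))/2
        expected = ((0 + LN2) / 2 + (LN2 + LN43) / 2) / 2
        assert ontology.list_sim([A1, B1], [B1, B2]) == pytest.approx(expected)
        assert expected == pytest.approx(0.4185, abs=1e-4)

    def test_exhaustive_pairwise_oracle(self, ontology):
        """Best-match average recomputed by exhaustive MICA enumeration."""
        rng = np.random.default_rng(2)
        pool = ontology.annotated_pool()
        for _ in range(100):
            a = list(rng.choice(pool, size=int(rng.integers(1, 4)), replace=False))
            b = list(rng.choice(pool, size=int(rng.integers(1, 4)), replace=False))

            def mica(x, y):
                common = ontology.ancestors(x) & ontology.ancestors(y)
                return max(
                    (ontology.information_content(t) for t in common
                     if ontology.annotations[t]),
                    default=0.0,
                )

            fwd = sum(max(mica(x, y) for y in b) for x in a) / len(a)
            rev = sum(max(mica(y, x) for x in a) for y in b) / len(b)
            assert ontology.list_sim(a, b) == pytest.approx((fwd + rev) / 2)

    def test_symmetric(self, ontology):
        assert ontology.list_sim([A1, B1], [B1, B2]) == pytest.approx(
            ontology.list_sim([B1, B2], [A1, B1])
        )

    def test_empty_set_rejected(self, ontology):
        with pytest.raises(ValueError):
            ontology.list_sim([], [A1])


class TestPhensscMaxssc:
    def test_identity_sets_equal_scores(self, ontology):
        d = ontology.diseases[D1]
        query = sorted(d.hpo_terms)
        assert ontology.phenssc(query, d) == pytest.approx(ontology.maxssc(query))

    def test_disjoint_branch_scores_zero(self, ontology):
        d3 = ontology.diseases["OMIM:300300"]  # {b2}
        assert ontology.phenssc([A1, A2], d3) == 0.0

    def test_phenssc_bounded_by_maxssc(self, ontology):
        """PhenSSc <= MaxSSc for random queries (sim <= min IC bound)."""
        rng = np.random.default_rng(17)
        pool = ontology.annotated_pool()
        for _ in range(500):
            k = int(rng.integers(1, len(pool) + 1))
            query = list(rng.choice(pool, size=k, replace=False))
            mx = ontology.maxssc(query)
            for d in ontology.diseases.values():
                assert ontology.phenssc(query, d) <= mx + 1e-12


class TestPermutationP:
    def test_observed_zero_gives_one(self, ontology):
        d = ontology.diseases[D1]
        assert ontology.permutation_p(2, d, 0.0, n=50, seed=1) == 1.0

    def test_matches_exact_enumeration(self, ontology):
        """Exhaustive enumeration over C(4,2)=6 same-size sets gives 1/6;
        only {a1,a2} reaches the observed score."""
        d = ontology.diseases[D1]
        observed = ontology.phenssc([A1, A2], d)
        pool = ontology.annotated_pool()
        assert len(pool) == 4
        exact = sum(
            1 for s in itertools.combinations(pool, 2)
            if ontology.list_sim(list(s), sorted(d.hpo_terms)) >= observed
        ) / 6
        assert exact == pytest.approx(1 / 6)
        n = 10_000
        p_hat = ontology.permutation_p(2, d, observed, n=n, seed=123)
        sigma = math.sqrt(exact * (1 - exact) / n)
        assert abs(p_hat - exact) <= 3 * sigma

    def test_deterministic_under_seed(self, ontology):
        d = ontology.diseases[D4]
        a = ontology.permutation_p(2, d, 0.3, n=100, seed=9)
        b = ontology.permutation_p(2, d, 0.3, n=100, seed=9)
        assert a == b

    def test_p_on_grid(self, ontology):
        d = ontology.diseases[D4]
        p = ontology.permutation_p(2, d, 0.3, n=100, seed=9)
        assert 0.0 <= p <= 1.0
        assert round(p * 100) == pytest.approx(p * 100)

    def test_pool_smaller_than_query_rejected(self, ontology):
        with pytest.raises(ValueError):
            ontology.permutation_p(5, ontology.diseases[D1], 0.1, n=10, seed=0)


def _random_ontology(rng, n_terms, n_diseases):
    """Random DAG ontology with random direct annotations."""
    terms = [f"T{i}" for i in range(n_terms)]
    parents = {terms[0]: set()}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(3, i) + 1))
        parents[terms[i]] = set(rng.choice(terms[:i], size=k, replace=False))
    diseases = {}
    for j in range(n_diseases):
        k = int(rng.integers(1, 4))
        ts = frozenset(rng.choice(terms, size=k, replace=False))
        diseases[f"D{j}"] = DiseaseRecord(f"D{j}", f"d{j}", "AD", ts)
    return OntologyGraph(parents, diseases, root=terms[0])


def test_ic_anti_monotone_on_random_ontologies():
    """IC never increases from child to parent along is_a edges; checked on
    10,000+ random edges across random DAG ontologies."""
    rng = np.random.default_rng(99)
    edges_checked = 0
    while edges_checked < 10_000:
        onto = _random_ontology(rng, n_terms=40, n_diseases=8)
        for child, parent in onto._dag.edges:
            if not onto.annotations[child]:
                continue
            assert (
                onto.information_content(parent)
                <= onto.information_content(child) + 1e-12
            )
            edges_checked += 1
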