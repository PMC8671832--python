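"""Information-content phenotype similarity between a patient term set and
each candidate disorder.

The ontology is a DAG of phenotype terms (HPO-style).  Disease annotations
propagate upward: a term's annotation set is the union of the diseases
annotated to it or to any descendant.  The information content of a term is

    IC(t) = -ln( |ann(t)| / N )

with N the number of distinct annotated diseases, so the root has IC 0 and
rarely-used terms have high IC (Resnik convention; only score ratios carry
interpretive weight).  Pairwise term similarity is the IC of the most
informative common ancestor (MICA).  Two term sets are compared with the
symmetric best-match average,

    sim(A, B) = 1/2 [ mean_a max_b s(a,b) + mean_b max_a s(a,b) ],

which guarantees the self-similarity of a set equals the mean IC of its
terms — the property the MaxSSc score relies on.

PhenSSc is sim(query, disorder terms); MaxSSc is sim(query, query), the
attainable ceiling for that query.  The permutation p-value draws random
same-size term sets from the annotated-term pool and reports the fraction
of simulated scores >= PhenSSc (ties count against significance).
"""
from __future__ import annotations

import hashlib
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np

from .core import DiseaseRecord, ValidationError

log = logging.getLogger(__name__)

DEFAULT_PERMUTATIONS = 100


class UndefinedICError(ValueError):
    """Term has no propagated disease annotation, so its IC is undefined."""


@dataclass(frozen=True)
class SimilarityResult:
    disease_id: str
    phenssc: float
    maxssc: float
    p_value: float
    n: int = DEFAULT_PERMUTATIONS


class OntologyGraph:
    """Phenotype-term DAG with propagated disease-annotation sets.

    ``parents`` maps child -> set of parents along is_a edges; the
    annotation set of a term is the union over its subtree of the directly
    annotated diseases, so ann(parent) always contains ann(child).
    """

    def __init__(
        self,
        parents: Mapping[str, set[str]],
        diseases: Mapping[str, DiseaseRecord],
        root: str,
    ):
        self.root = root
        self.diseases = dict(diseases)
        self._dag = nx.DiGraph()
        all_terms = set(parents) | {p for ps in parents.values() for p in ps}
        self._dag.add_nodes_from(all_terms)
        for child, ps in parents.items():
            for p in ps:
                self._dag.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(self._dag):
            raise ValidationError(
                f"ontology contains a cycle: {nx.find_cycle(self._dag)}"
            )
        # direct annotations
        self.direct_annotations: dict[str, set[str]] = {t: set() for t in self._dag.nodes}
        for d in self.diseases.values():
            for t in d.hpo_terms:
                if t not in self.direct_annotations:
                    raise ValidationError(
                        f"disease {d.disease_id} annotated to unknown term {t}"
                    )
                self.direct_annotations[t].add(d.disease_id)
        # upward propagation in reverse topological order of the child->parent DAG
        self.annotations: dict[str, set[str]] = {
            t: set(s) for t, s in self.direct_annotations.items()
        }
        for term in nx.topological_sort(self._dag):
            for parent in self._dag.successors(term):
                self.annotations[parent] |= self.annotations[term]
        self.total_diseases = len(self.diseases)
        self._ancestors_cache: dict[str, frozenset[str]] = {}

    @classmethod
    def from_dag(
        cls, dag: nx.DiGraph, diseases: Mapping[str, DiseaseRecord], root: str
    ) -> "OntologyGraph":
        parents = {n: set(dag.successors(n)) for n in dag.nodes}
        return cls(parents, diseases, root)

    @property
    def terms(self) -> set[str]:
        return set(self._dag.nodes)

    def ancestors(self, term: str) -> frozenset[str]:
        """Ancestors of a term, including the term itself."""
        cached = self._ancestors_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._dag, term)) | {term}
            self._ancestors_cache[term] = cached
        return cached

    def information_content(self, term: str) -> float:
        if term not in self._dag.nodes:
            raise KeyError(f"unknown term {term}")
        k = len(self.annotations[term])
        if k == 0:
            raise UndefinedICError(
                f"term {term} has no propagated disease annotation"
            )
        return -math.log(k / self.total_diseases)

    def annotated_pool(self) -> list[str]:
        """Terms with at least one *direct* disease annotation — the pool
        random permutation sets are drawn from."""
        return sorted(t for t, s in self.direct_annotations.items() if s)

    def pairwise_sim(self, t1: str, t2: str) -> float:
        """IC of the most informative common ancestor (each term is an
        ancestor of itself); symmetric in its arguments."""
        common = self.ancestors(t1) & self.ancestors(t2)
        best = 0.0
        for a in common:
            if self.annotations[a]:
                best = max(best, self.information_content(a))
        return best

    def _defined(self, terms: Iterable[str]) -> list[str]:
        kept = []
        for t in terms:
            if t not in self._dag.nodes:
                log.warning("dropping unknown term %s", t)
                continue
            if not self.annotations[t]:
                log.warning("dropping term %s with undefined IC", t)
                continue
            kept.append(t)
        return kept

    def list_sim(self, a: Sequence[str], b: Sequence[str]) -> float:
        """Symmetric best-match average similarity between two term sets."""
        a = self._defined(a)
        b = self._defined(b)
        if not a or not b:
            raise ValueError("both term sets must be non-empty (after dropping "
                             "terms with undefined IC)")
        fwd = np.mean([max(self.pairwise_sim(x, y) for y in b) for x in a])
        rev = np.mean([max(self.pairwise_sim(y, x) for x in a) for y in b])
        return float((fwd + rev) / 2.0)

    def maxssc(self, query: Sequence[str]) -> float:
        """Self-similarity of the query = mean IC of its terms; the ceiling
        against which PhenSSc is read."""
        return self.list_sim(query, query)

    def phenssc(self, query: Sequence[str], disease: DiseaseRecord) -> float:
        return self.list_sim(query, sorted(disease.hpo_terms))

    def permutation_p(
        self,
        query_size: int,
        disease: DiseaseRecord,
        observed: float,
        n: int = DEFAULT_PERMUTATIONS,
        seed: int = 0,
    ) -> float:
        """Fraction of n random same-size term sets whose similarity to the
        disorder meets or exceeds the observed PhenSSc.

        Sets are drawn uniformly without replacement from the annotated
        term pool; the random stream is derived deterministically from
        (seed, disease_id) so batch output is reproducible per disorder.
        """
        if query_size < 1:
            raise ValueError("query_size must be >= 1")
        pool = self.annotated_pool()
        if len(pool) < query_size:
            raise ValueError(
                f"annotated term pool ({len(pool)}) smaller than query size {query_size}"
            )
        rng = np.random.default_rng(_derive_seed(seed, disease.disease_id))
        disease_terms = sorted(disease.hpo_terms)
        hits = 0
        for _ in range(n):
            sample = rng.choice(len(pool), size=query_size, replace=False)
            random_set = [pool[i] for i in sample]
            if self.list_sim(random_set, disease_terms) >= observed:
                hits += 1
        return hits / n

    def score_disease(
        self,
        query: Sequence[str],
        disease: DiseaseRecord,
        n: int = DEFAULT_PERMUTATIONS,
        seed: int = 0,
    ) -> SimilarityResult:
        """PhenSSc, MaxSSc and permutation p for one disorder."""
        query = self._defined(query)
        phen = self.phenssc(query, disease)
        mx = self.maxssc(query)
        p = self.permutation_p(len(query), disease, phen, n=n, seed=seed)
        return SimilarityResult(disease.disease_id, phen, mx, p, n)


def _derive_seed(seed: int, disease_id: str) -> int:
    digest = hashlib.sha256(f"{seed}:{disease_id}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)
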