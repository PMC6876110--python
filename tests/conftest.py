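import math

import numpy as np
import pytest

from metnet.io import (
    GeneAnnotation,
    GeneFunctionalNetwork,
    OntologyDAG,
    unordered_pair,
)
from metnet.synth import generate_worked_example


@pytest.fixture(scope="session")
def worked_bundle():
    return generate_worked_example()


@pytest.fixture
def chain_dag():
    """c IS_A b IS_A a."""
    dag = OntologyDAG(
        terms={"a", "b", "c"},
        parents={"a": set(), "b": {"a"}, "c": {"b"}},
        labels={"a": "alpha", "b": "beta", "c": "gamma"},
    )
    dag.validate()
    return dag


def random_dag(rng, n_terms):
    """Random rooted DAG: term i picks parents among terms < i."""
    terms = [f"T{i:02d}" for i in range(n_terms)]
    parents = {terms[0]: set()}
    for i in range(1, n_terms):
        k = 1 + int(rng.integers(0, min(i, 2)))
        idx = rng.choice(i, size=min(k, i), replace=False)
        parents[terms[i]] = {terms[j] for j in np.atleast_1d(idx)}
    dag = OntologyDAG(terms=set(terms), parents=parents)
    dag.validate()
    return dag, terms


def random_gene_setup(rng, dag, terms, n_genes):
    genes = [f"g{i}" for i in range(n_genes)]
    ann = GeneAnnotation(
        disease2genes={
            t: {g for g in genes if rng.random() < 0.4} for t in terms
        }
    )
    edges = {}
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < 0.4:
                edges[unordered_pair(genes[i], genes[j])] = round(
                    float(rng.uniform(0.05, 1.0)), 6
                )
    return ann, GeneFunctionalNetwork(edges=edges)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (enumeration only, no shared code paths)
# ---------------------------------------------------------------------------


def oracle_ancestors(dag, term):
    out = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in dag.parents.get(t, ()):
            if p not in out:
                out.add(p)
                frontier.append(p)
    return out


def oracle_propagated_count(dag, ann, term):
    genes = set()
    for t in dag.terms:
        if term in oracle_ancestors(dag, t):
            genes |= set(ann.disease2genes.get(t, ()))
    return len(genes)


def oracle_fnsemsim(da, db, dag, ann, net):
    """Exhaustive recomputation: every ancestor and gene pair enumerated."""
    Ga, Gb = set(ann.disease2genes.get(da, ())), set(ann.disease2genes.get(db, ()))
    if not Ga and not Gb:
        return 0.0

    def r(g, G):
        if g in G:
            return 1.0
        return max(
            (net.edges.get(unordered_pair(g, h), 0.0) for h in sorted(G) if h != g),
            default=0.0,
        )

    terms = [r(g, Gb) for g in sorted(Ga)] + [r(g, Ga) for g in sorted(Gb)]
    base = math.fsum(terms) / (len(Ga) + len(Gb))
    if base == 0.0:
        return 0.0
    common = oracle_ancestors(dag, da) & oracle_ancestors(dag, db)
    counts = {t: oracle_propagated_count(dag, ann, t) for t in common}
    mica = min(common, key=lambda t: (counts[t], t))
    if counts[mica] == 0:
        return 0.0
    return base * (len(Ga) * len(Gb)) / (counts[mica] ** 2)


def oracle_dmn(assoc_pairs, dsim_lookup, threshold):
    """Nested-loop profile + cosine recomputation.

    ``assoc_pairs``: set of (disease, metabolite); ``dsim_lookup(a, b)``:
    normalized disease similarity with diagonal 1.
    """
    diseases = sorted({d for d, _ in assoc_pairs})
    mets = sorted({m for _, m in assoc_pairs})
    dr = {m: {d for d, mm in assoc_pairs if mm == m} for m in mets}
    vec = {}
    for m in mets:
        v = []
        for d in diseases:
            if d in dr[m]:
                v.append(1.0)
            else:
                v.append(max(dsim_lookup(di, d) for di in sorted(dr[m])))
        vec[m] = v
    edges = {}
    for i, a in enumerate(mets):
        for b in mets[i + 1 :]:
            dot = sum(x * y for x, y in zip(vec[a], vec[b]))
            na = math.sqrt(sum(x * x for x in vec[a]))
            nb = math.sqrt(sum(x * x for x in vec[b]))
            cos = dot / (na * nb)
            if cos > threshold:
                edges[(a, b)] = cos
    return vec, edges


def oracle_auc(scores, positives, negatives):
    """All-pairs concordance counting."""
    num = 0.0
    for p in positives:
        for n in negatives:
            if scores[p] > scores[n]:
                num += 1.0
            elif scores[p] == scores[n]:
                num += 0.5
    return num / (len(positives) * len(negatives))
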