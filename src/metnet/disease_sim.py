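"""Functional disease-disease similarity over a gene network and ontology DAG.

The score for a disease pair combines cross-connectivity of their gene sets
in a weighted gene functional network with a normalization by the annotation
count of the pair's most informative common ancestor (MICA).  Information
content is ``-log(|G_t| / |G_root|)`` with ``|G_t|`` the DAG-propagated
annotation count, so the argmax over common ancestors is the ancestor with
the fewest propagated genes.

All numeric loops iterate in sorted order so results are bit-reproducible
across processes.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import (
    DataFormatError,
    GeneAnnotation,
    GeneFunctionalNetwork,
    OntologyDAG,
    _data_lines,
)

logger = logging.getLogger(__name__)


@dataclass
class DiseaseSimilarityMatrix:
    """Symmetric disease similarity matrix (raw and max-normalized)."""

    diseases: list[str]
    sim: np.ndarray  # normalized, entries in [0, 1], diagonal 1
    raw: np.ndarray | None = None
    _index: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {d: i for i, d in enumerate(self.diseases)}

    def index(self, disease: str) -> int:
        return self._index[disease]

    def get(self, a: str, b: str) -> float:
        return float(self.sim[self._index[a], self._index[b]])


@dataclass
class MicaCache:
    """Memoized MICA lookups plus propagated annotation counts per term."""

    mica: dict[tuple[str, str], str]
    annotated_count: dict[str, int]


def propagated_gene_sets(dag: OntologyDAG, ann: GeneAnnotation) -> dict[str, frozenset[str]]:
    """Union of direct gene annotations over each term and all its descendants."""
    children = dag.children_map()
    result: dict[str, frozenset[str]] = {}
    # iterative post-order over the DAG
    state: dict[str, int] = {}
    for start in dag.terms:
        if start in result:
            continue
        stack = [start]
        while stack:
            t = stack[-1]
            if t in result:
                stack.pop()
                continue
            if state.get(t) == 1:
                genes = set(ann.disease2genes.get(t, ()))
                for c in children[t]:
                    genes |= result[c]
                result[t] = frozenset(genes)
                stack.pop()
            else:
                state[t] = 1
                for c in children[t]:
                    if c not in result:
                        stack.append(c)
        state.clear()
    return result


def propagated_counts(dag: OntologyDAG, ann: GeneAnnotation) -> dict[str, int]:
    return {t: len(s) for t, s in propagated_gene_sets(dag, ann).items()}


def gene_to_set_weight(g: str, G: Iterable[str], net: GeneFunctionalNetwork) -> float:
    """Best-match connection weight of gene ``g`` into gene set ``G``.

    1 on membership, otherwise the maximum edge weight from ``g`` into ``G``
    (0 when no edge exists).
    """
    genes = set(G)
    if g in genes:
        return 1.0
    best = 0.0
    for other in sorted(genes):
        w = net.weight(g, other)
        if w > best:
            best = w
    return best


def disease_fun_sim(
    Ga: Iterable[str], Gb: Iterable[str], net: GeneFunctionalNetwork
) -> float:
    """Average best-match connectivity between two gene sets; in [0, 1]."""
    sa, sb = set(Ga), set(Gb)
    if not sa and not sb:
        logger.warning("disease_fun_sim called with two empty gene sets; returning 0")
        return 0.0
    # fsum: exactly rounded and order-independent, so the score is
    # bit-identical under argument swap
    terms = [gene_to_set_weight(g, sb, net) for g in sorted(sa)]
    terms += [gene_to_set_weight(g, sa, net) for g in sorted(sb)]
    return math.fsum(terms) / (len(sa) + len(sb))


def information_content(term: str, counts: dict[str, int], root_count: int) -> float:
    c = counts.get(term, 0)
    if c == 0:
        return math.inf
    return -math.log(c / root_count)


def find_mica(
    da: str,
    db: str,
    dag: OntologyDAG,
    ann: GeneAnnotation,
    counts: dict[str, int] | None = None,
) -> tuple[str, int]:
    """Most informative common ancestor of two terms (terms themselves included).

    The MICA maximizes ``-log(|G_t|/|G_root|)`` over common ancestors, i.e.
    minimizes the propagated annotation count; ties break by smaller count
    then lexicographic term id.  A forest with no common ancestor is a hard
    error.
    """
    if counts is None:
        counts = propagated_counts(dag, ann)
    common = dag.ancestors(da) & dag.ancestors(db)
    if not common:
        raise DataFormatError(f"no common ancestor for {da!r} and {db!r}")
    best = min(common, key=lambda t: (counts.get(t, 0), t))
    return best, counts.get(best, 0)


def fnsemsim(
    da: str,
    db: str,
    dag: OntologyDAG,
    ann: GeneAnnotation,
    net: GeneFunctionalNetwork,
    counts: dict[str, int] | None = None,
    use_propagated_sets: bool = False,
    propagated: dict[str, frozenset[str]] | None = None,
) -> float:
    """Raw (un-normalized) functional-semantic similarity of two diseases.

    ``use_propagated_sets`` switches the per-disease gene sets from direct
    annotations to DAG-propagated ones; the MICA count is always propagated.
    The raw value may exceed 1; :func:`all_pairs_similarity` normalizes.
    """
    if use_propagated_sets:
        if propagated is None:
            propagated = propagated_gene_sets(dag, ann)
        Ga: set[str] = set(propagated.get(da, frozenset()))
        Gb: set[str] = set(propagated.get(db, frozenset()))
    else:
        Ga = ann.genes(da)
        Gb = ann.genes(db)
    if not Ga and not Gb:
        logger.warning("both %r and %r have empty gene sets; similarity 0", da, db)
        return 0.0
    base = disease_fun_sim(Ga, Gb, net)
    if base == 0.0:
        return 0.0
    _, mica_count = find_mica(da, db, dag, ann, counts=counts)
    if mica_count == 0:
        logger.warning("MICA of %r and %r has no propagated genes; similarity 0", da, db)
        return 0.0
    return base * (len(Ga) * len(Gb)) / (mica_count * mica_count)


def all_pairs_similarity(
    diseases: Sequence[str],
    dag: OntologyDAG,
    ann: GeneAnnotation,
    net: GeneFunctionalNetwork,
    normalization: str = "max",
    use_propagated_sets: bool = False,
) -> DiseaseSimilarityMatrix:
    """Raw similarities for all unordered pairs, then max-normalization.

    Every off-diagonal entry is divided by the maximum off-diagonal raw value;
    the diagonal is set to 1.  An all-zero raw matrix stays all-zero
    off-diagonal (with a warning).
    """
    if normalization != "max":
        raise ValueError(f"unknown normalization mode {normalization!r}")
    ds = list(diseases)
    if len(ds) < 2:
        raise ValueError("need at least 2 diseases")
    n = len(ds)
    counts = propagated_counts(dag, ann)
    propagated = propagated_gene_sets(dag, ann) if use_propagated_sets else None
    raw = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            s = fnsemsim(
                ds[i],
                ds[j],
                dag,
                ann,
                net,
                counts=counts,
                use_propagated_sets=use_propagated_sets,
                propagated=propagated,
            )
            raw[i, j] = raw[j, i] = s
        raw[i, i] = fnsemsim(
            ds[i],
            ds[i],
            dag,
            ann,
            net,
            counts=counts,
            use_propagated_sets=use_propagated_sets,
            propagated=propagated,
        )
    off = raw[~np.eye(n, dtype=bool)]
    maxval = float(off.max()) if off.size else 0.0
    norm = raw.copy()
    if maxval > 0:
        norm = norm / maxval
    else:
        logger.warning("all raw similarities are zero; normalized matrix is zero")
    np.fill_diagonal(norm, 1.0)
    return DiseaseSimilarityMatrix(diseases=ds, sim=norm, raw=raw)


def write_similarity_matrix(
    path: str | Path, dsm: DiseaseSimilarityMatrix, meta: dict[str, str] | None = None
) -> None:
    """Serialize as TSV rows (disease_a, disease_b, raw_sim, normalized_sim)."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
        fh.write("disease_a\tdisease_b\traw_sim\tnormalized_sim\n")
        ds = dsm.diseases
        order = sorted(range(len(ds)), key=lambda i: ds[i])
        for ii, i in enumerate(order):
            for j in order[ii:]:
                a, b = ds[i], ds[j]
                r = float(dsm.raw[i, j]) if dsm.raw is not None else float("nan")
                fh.write(f"{a}\t{b}\t{r!r}\t{float(dsm.sim[i, j])!r}\n")


def read_similarity_matrix(path: str | Path) -> DiseaseSimilarityMatrix:
    path = Path(path)
    entries: dict[tuple[str, str], tuple[float, float]] = {}
    names: set[str] = set()
    header = None
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if header is None:
            header = fields
            for col in ("disease_a", "disease_b", "raw_sim", "normalized_sim"):
                if col not in header:
                    raise DataFormatError(f"{path}: missing column {col!r}")
            continue
        a, b = fields[header.index("disease_a")], fields[header.index("disease_b")]
        r = float(fields[header.index("raw_sim")])
        s = float(fields[header.index("normalized_sim")])
        names.update((a, b))
        entries[(a, b)] = (r, s)
    if header is None:
        raise DataFormatError(f"{path}: empty file, header required")
    ds = sorted(names)
    idx = {d: i for i, d in enumerate(ds)}
    n = len(ds)
    raw = np.zeros((n, n))
    sim = np.zeros((n, n))
    for (a, b), (r, s) in entries.items():
        i, j = idx[a], idx[b]
        raw[i, j] = raw[j, i] = r
        sim[i, j] = sim[j, i] = s
    return DiseaseSimilarityMatrix(diseases=ds, sim=sim, raw=raw)
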