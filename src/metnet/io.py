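"""Core domain types and readers/writers for every file format the pipeline touches.

All edge stores key on unordered pairs (lexicographically sorted identifier
tuples) because every network in the pipeline is undirected.  All writers emit
deterministic, sorted row order and serialize weights with :func:`repr` so a
write/read round trip reproduces edge weights exactly.  Lines starting with
``#`` are treated as comments in every TSV format.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


class DataFormatError(ValueError):
    """Raised when an input file violates its format contract."""


class OntologyCycleError(DataFormatError):
    """Raised when the parsed ontology is not acyclic."""


def unordered_pair(a: str, b: str) -> Pair:
    """Canonical unordered key for an undirected edge. Rejects self-pairs."""
    if a == b:
        raise ValueError(f"self-pair not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class OntologyDAG:
    """Disease ontology: terms, IS_A parent links, names and synonyms.

    Invariants (checked by :meth:`validate`): the parent relation is acyclic,
    every referenced parent exists, and at least one root is present.
    """

    terms: set[str]
    parents: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)
    synonyms: dict[str, set[str]] = field(default_factory=dict)
    _anc_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def roots(self) -> set[str]:
        return {t for t in self.terms if not self.parents.get(t)}

    def children_map(self) -> dict[str, set[str]]:
        children: dict[str, set[str]] = {t: set() for t in self.terms}
        for t, ps in self.parents.items():
            for p in ps:
                children[p].add(t)
        return children

    def ancestors(self, term: str, include_self: bool = True) -> frozenset[str]:
        """All terms reachable from ``term`` by following parent links."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r}")
        cached = self._anc_cache.get(term)
        if cached is None:
            seen: set[str] = set()
            stack = [term]
            while stack:
                t = stack.pop()
                for p in self.parents.get(t, ()):
                    if p not in seen:
                        seen.add(p)
                        stack.append(p)
            cached = frozenset(seen)
            self._anc_cache[term] = cached
        return cached | {term} if include_self else cached

    def validate(self) -> None:
        for t, ps in self.parents.items():
            for p in ps:
                if p not in self.terms:
                    raise DataFormatError(
                        f"term {t!r} references unknown parent {p!r}"
                    )
        self._check_acyclic()
        if not self.roots():
            raise OntologyCycleError("ontology has no root term")

    def _check_acyclic(self) -> None:
        # Kahn's algorithm; any leftover node sits on a cycle.
        out_deg = {t: len(self.parents.get(t, ())) for t in self.terms}
        children = self.children_map()
        queue = [t for t, d in out_deg.items() if d == 0]
        seen = 0
        while queue:
            t = queue.pop()
            seen += 1
            for c in children[t]:
                out_deg[c] -= 1
                if out_deg[c] == 0:
                    queue.append(c)
        if seen == len(self.terms):
            return
        remaining = {t for t, d in out_deg.items() if d > 0}
        start = min(remaining)
        path = [start]
        positions = {start: 0}
        while True:
            nxt = min(p for p in self.parents[path[-1]] if p in remaining)
            if nxt in positions:
                raise OntologyCycleError(
                    f"cycle detected involving edge {path[-1]!r} IS_A {nxt!r}"
                )
            positions[nxt] = len(path)
            path.append(nxt)


@dataclass
class GeneAnnotation:
    """Mapping disease term -> set of gene identifiers (direct annotations)."""

    disease2genes: dict[str, set[str]]

    def genes(self, disease: str) -> set[str]:
        return self.disease2genes.get(disease, set())


@dataclass
class GeneFunctionalNetwork:
    """Weighted undirected gene network; weights in [0, 1], no self-loops."""

    edges: dict[Pair, float]

    def weight(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.edges.get(unordered_pair(a, b), 0.0)


@dataclass
class AssociationTable:
    """Bipartite disease<->metabolite association records with a version tag."""

    records: set[tuple[str, str]]
    version_tag: str = ""

    def diseases(self) -> set[str]:
        return {d for d, _ in self.records}

    def metabolites(self) -> set[str]:
        return {m for _, m in self.records}

    def by_metabolite(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for d, m in self.records:
            out[m].add(d)
        return dict(out)

    def by_disease(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = defaultdict(set)
        for d, m in self.records:
            out[d].add(m)
        return dict(out)


@dataclass
class TextMiningScores:
    """Symmetric metabolite-pair text-mining scores in [0, 1]."""

    scores: dict[Pair, float]

    def score(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.scores.get(unordered_pair(a, b), 0.0)


@dataclass
class WeightedMetaboliteNetwork:
    """Undirected weighted metabolite graph.

    ``kind_tag`` records which construction produced it (``DMN``,
    ``ST_SUBNET`` or ``FLDMN``).  Zero-weight edges are never stored; isolated
    nodes are allowed and preserved through serialization.
    """

    nodes: set[str]
    edges: dict[Pair, float]
    kind_tag: str = "DMN"

    def weight(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self.edges.get(unordered_pair(a, b), 0.0)

    def neighbors(self) -> dict[str, dict[str, float]]:
        adj: dict[str, dict[str, float]] = {n: {} for n in self.nodes}
        for (a, b), w in self.edges.items():
            adj[a][b] = w
            adj[b][a] = w
        return adj


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


_SYNONYM_QUOTE = '"'


def read_ontology(path: str | Path) -> OntologyDAG:
    """Parse an OBO-format ontology into a validated :class:`OntologyDAG`.

    Only ``id``, ``name``, ``synonym`` and ``is_a`` tags of ``[Term]`` stanzas
    are consumed; obsolete terms are skipped.  A cycle or a dangling ``is_a``
    target is a hard error.
    """
    path = Path(path)
    terms: set[str] = set()
    parents: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    synonyms: dict[str, set[str]] = defaultdict(set)

    cur_id: str | None = None
    cur: dict[str, object] = {}
    in_term = False

    def flush() -> None:
        nonlocal cur_id, cur
        if cur_id is not None and not cur.get("obsolete"):
            terms.add(cur_id)
            parents[cur_id] = set(cur.get("is_a", set()))  # type: ignore[arg-type]
            if "name" in cur:
                labels[cur_id] = cur["name"]  # type: ignore[assignment]
            for syn in cur.get("synonyms", ()):  # type: ignore[union-attr]
                synonyms[cur_id].add(syn)
        cur_id, cur = None, {}

    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                continue
            if not in_term or not line or line.startswith("!"):
                continue
            if ":" not in line:
                continue
            tag, _, value = line.partition(":")
            tag, value = tag.strip(), value.strip()
            if tag == "id":
                cur_id = value
            elif tag == "name":
                cur["name"] = value
            elif tag == "is_obsolete" and value.lower().startswith("true"):
                cur["obsolete"] = True
            elif tag == "is_a":
                target = value.split("!", 1)[0].strip()
                cur.setdefault("is_a", set()).add(target)  # type: ignore[union-attr]
            elif tag == "synonym":
                if value.startswith(_SYNONYM_QUOTE):
                    end = value.find(_SYNONYM_QUOTE, 1)
                    if end > 0:
                        cur.setdefault("synonyms", set()).add(value[1:end])  # type: ignore[union-attr]
    flush()

    if not terms:
        raise DataFormatError(f"{path}: no [Term] stanzas found")
    for t, ps in parents.items():
        for p in ps:
            if p not in terms:
                raise DataFormatError(
                    f"{path}: term {t!r} has dangling is_a target {p!r}"
                )
    dag = OntologyDAG(
        terms=terms, parents=parents, labels=labels, synonyms=dict(synonyms)
    )
    dag.validate()
    logger.info("read ontology %s: %d terms, %d roots", path, len(terms), len(dag.roots()))
    return dag


def read_association_table(path: str | Path, version_tag: str = "") -> AssociationTable:
    """Read a TSV with columns ``disease_id`` and ``metabolite_id``.

    Duplicate rows are collapsed; a missing column is a hard error.
    """
    path = Path(path)
    records: set[tuple[str, str]] = set()
    header: list[str] | None = None
    idx_d = idx_m = -1
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            header = [f.strip() for f in fields]
            for col in ("disease_id", "metabolite_id"):
                if col not in header:
                    raise DataFormatError(f"{path}: missing column {col!r}")
            idx_d = header.index("disease_id")
            idx_m = header.index("metabolite_id")
            continue
        if len(fields) <= max(idx_d, idx_m):
            raise DataFormatError(f"{path}:{lineno}: too few columns")
        records.add((fields[idx_d].strip(), fields[idx_m].strip()))
    if header is None:
        raise DataFormatError(f"{path}: empty file, header required")
    logger.info("read %d association records from %s", len(records), path)
    return AssociationTable(records=records, version_tag=version_tag)


def read_weighted_edges(path: str | Path, scale: float = 1.0) -> dict[Pair, float]:
    """Read a TSV edge list (``node_a``, ``node_b``, ``weight``).

    Weights are divided by ``scale`` on ingest and must land in [0, 1].
    Self-loop rows are skipped with a warning; a pair appearing twice with
    different weights is a hard error.
    """
    path = Path(path)
    edges: dict[Pair, float] = {}
    header_seen = False
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if not header_seen:
            if fields[:3] != ["node_a", "node_b", "weight"]:
                raise DataFormatError(
                    f"{path}:{lineno}: expected header node_a/node_b/weight, got {fields[:3]}"
                )
            header_seen = True
            continue
        if len(fields) < 3:
            raise DataFormatError(f"{path}:{lineno}: too few columns")
        a, b, wtxt = fields[0], fields[1], fields[2]
        try:
            w = float(wtxt) / scale
        except ValueError as exc:
            raise DataFormatError(f"{path}:{lineno}: unparseable weight {wtxt!r}") from exc
        if not 0.0 <= w <= 1.0:
            raise DataFormatError(
                f"{path}:{lineno}: weight {w!r} outside [0, 1]"
            )
        if a == b:
            logger.warning("%s:%d: self-loop row on %r skipped", path, lineno, a)
            continue
        key = unordered_pair(a, b)
        if key in edges and edges[key] != w:
            raise DataFormatError(
                f"{path}:{lineno}: conflicting weights for pair {key}: "
                f"{edges[key]!r} vs {w!r}"
            )
        edges[key] = w
    if not header_seen:
        raise DataFormatError(f"{path}: empty file, header required")
    return edges


def read_gene_network(path: str | Path, scale: float = 1.0) -> GeneFunctionalNetwork:
    return GeneFunctionalNetwork(edges=read_weighted_edges(path, scale=scale))


def read_textmining_scores(path: str | Path, scale: float = 1.0) -> TextMiningScores:
    """Read text-mining scores; pass ``scale=1000`` for raw 0-1000 integers."""
    return TextMiningScores(scores=read_weighted_edges(path, scale=scale))


def read_metabolite_network(
    path: str | Path, kind_tag: str = "DMN"
) -> WeightedMetaboliteNetwork:
    """Read a metabolite network edge list.

    A ``# nodes:`` comment line (written by :func:`write_metabolite_network`)
    restores isolated nodes; otherwise the node set is the set of edge
    endpoints.
    """
    path = Path(path)
    nodes: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("# nodes:"):
                listed = line.partition(":")[2].strip()
                if listed:
                    nodes.update(listed.split(","))
            if line.startswith("# kind:"):
                kind_tag = line.partition(":")[2].strip()
    edges = read_weighted_edges(path)
    for a, b in edges:
        nodes.add(a)
        nodes.add(b)
    if any(w == 0.0 for w in edges.values()):
        raise DataFormatError(f"{path}: zero-weight metabolite edge stored")
    return WeightedMetaboliteNetwork(nodes=nodes, edges=edges, kind_tag=kind_tag)


def read_gene_annotations(path: str | Path) -> GeneAnnotation:
    """Read a TSV with columns ``disease_id`` and ``gene_id`` (one row per pair)."""
    path = Path(path)
    d2g: dict[str, set[str]] = defaultdict(set)
    header = None
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if header is None:
            header = fields
            for col in ("disease_id", "gene_id"):
                if col not in header:
                    raise DataFormatError(f"{path}: missing column {col!r}")
            continue
        if len(fields) < 2:
            raise DataFormatError(f"{path}:{lineno}: too few columns")
        d2g[fields[header.index("disease_id")]].add(fields[header.index("gene_id")])
    if header is None:
        raise DataFormatError(f"{path}: empty file, header required")
    return GeneAnnotation(disease2genes=dict(d2g))


# ---------------------------------------------------------------------------
# Writers (deterministic row order, exact round-trip weights)
# ---------------------------------------------------------------------------


def _write_meta(fh, meta: Mapping[str, str] | None) -> None:
    if meta:
        for k in meta:
            fh.write(f"# {k}: {meta[k]}\n")


def write_weighted_edges(
    path: str | Path,
    edges: Mapping[Pair, float],
    meta: Mapping[str, str] | None = None,
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, meta)
        fh.write("node_a\tnode_b\tweight\n")
        for a, b in sorted(edges):
            fh.write(f"{a}\t{b}\t{edges[(a, b)]!r}\n")


def write_metabolite_network(
    path: str | Path,
    net: WeightedMetaboliteNetwork,
    meta: Mapping[str, str] | None = None,
) -> None:
    full_meta = {"kind": net.kind_tag, "nodes": ",".join(sorted(net.nodes))}
    if meta:
        full_meta.update(meta)
    write_weighted_edges(path, net.edges, meta=full_meta)


def write_association_table(
    path: str | Path,
    table: AssociationTable,
    meta: Mapping[str, str] | None = None,
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, meta)
        if table.version_tag:
            fh.write(f"# version: {table.version_tag}\n")
        fh.write("disease_id\tmetabolite_id\n")
        for d, m in sorted(table.records):
            fh.write(f"{d}\t{m}\n")


def write_gene_annotations(
    path: str | Path,
    ann: GeneAnnotation,
    meta: Mapping[str, str] | None = None,
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        _write_meta(fh, meta)
        fh.write("disease_id\tgene_id\n")
        for d in sorted(ann.disease2genes):
            for g in sorted(ann.disease2genes[d]):
                fh.write(f"{d}\t{g}\n")
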