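"""Synthetic fixture bundles with controllable planted module structure.

The generative model plants co-association modules: diseases and metabolites
are partitioned into modules, diseases within a module share overlapping gene
sets (so disease similarity is high within modules), associations fall mostly
within modules, and text-mining edges are concordant with modules at a
controllable rate.  The later association snapshot adds a fixed number of
held-out within-module associations whose identities are recorded as ground
truth.  All randomness flows from a single integer seed and all files are
written in sorted order, so the same spec yields byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (
    AssociationTable,
    GeneAnnotation,
    GeneFunctionalNetwork,
    OntologyDAG,
    TextMiningScores,
    unordered_pair,
    write_association_table,
    write_gene_annotations,
    write_weighted_edges,
)
from .vocab import MedicEntry


@dataclass(frozen=True)
class FixtureSpec:
    n_diseases: int = 12
    n_metabolites: int = 30
    n_genes: int = 40
    n_modules: int = 3
    within_module_assoc_prob: float = 0.6
    cross_module_assoc_prob: float = 0.05
    textmining_concordance: float = 0.9
    snapshot_delta: int = 10
    seed: int = 0
    gene_share_prob: float = 0.6
    st_edges_per_metabolite: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "within_module_assoc_prob",
            "cross_module_assoc_prob",
            "textmining_concordance",
            "gene_share_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v!r}")
        for name in ("n_diseases", "n_metabolites", "n_genes", "n_modules"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_modules > min(self.n_diseases, self.n_metabolites, self.n_genes):
            raise ValueError("more modules than entities to fill them")
        if self.snapshot_delta < 0:
            raise ValueError("snapshot_delta must be non-negative")

    @staticmethod
    def null(seed: int = 0, **kwargs) -> "FixtureSpec":
        """Structure-free variant: association probability and text-mining
        placement carry no module signal."""
        defaults = dict(
            n_modules=3,
            within_module_assoc_prob=0.25,
            cross_module_assoc_prob=0.25,
            textmining_concordance=1.0 / 3.0,
            seed=seed,
        )
        defaults.update(kwargs)
        return FixtureSpec(**defaults)


@dataclass
class FixtureBundle:
    """In-memory fixture plus writers for the on-disk bundle."""

    spec: FixtureSpec
    ontology: OntologyDAG
    annotations: GeneAnnotation
    gene_network: GeneFunctionalNetwork
    assoc_earlier: AssociationTable
    assoc_later: AssociationTable
    textmining: TextMiningScores
    truth: list[tuple[str, str, str]]  # (disease, metabolite, split)
    medic_entries: list[MedicEntry]
    raw_rows: list[tuple[str, str]]  # (disease name, metabolite id), earlier
    disease_module: dict[str, int] = field(default_factory=dict)
    metabolite_module: dict[str, int] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "ontology": out / "ontology.obo",
            "medic": out / "medic.tsv",
            "gene_annotations": out / "gene_annotations.tsv",
            "gene_network": out / "gene_network.tsv",
            "associations_earlier": out / "associations_earlier.tsv",
            "associations_later": out / "associations_later.tsv",
            "raw_associations": out / "raw_associations.tsv",
            "textmining": out / "textmining.tsv",
            "truth": out / "truth.tsv",
        }
        _write_obo(paths["ontology"], self.ontology)
        _write_medic(paths["medic"], self.medic_entries)
        write_gene_annotations(paths["gene_annotations"], self.annotations)
        write_weighted_edges(paths["gene_network"], self.gene_network.edges)
        write_association_table(paths["associations_earlier"], self.assoc_earlier)
        write_association_table(paths["associations_later"], self.assoc_later)
        _write_raw_associations(paths["raw_associations"], self.raw_rows)
        write_weighted_edges(paths["textmining"], self.textmining.scores)
        _write_truth(paths["truth"], self.truth)
        return paths


def _disease_id(i: int) -> str:
    return f"SD:{100 + i:07d}"


def _module_id(k: int) -> str:
    return f"SD:{1 + k:07d}"


ROOT_TERM = "SD:0000000"


def _metabolite_id(i: int) -> str:
    return f"SM{i:04d}"


def _gene_id(i: int) -> str:
    return f"G{i:04d}"


def _build_ontology(spec: FixtureSpec) -> tuple[OntologyDAG, dict[str, int]]:
    terms = {ROOT_TERM}
    parents: dict[str, set[str]] = {ROOT_TERM: set()}
    labels = {ROOT_TERM: "synthetic disease root"}
    synonyms: dict[str, set[str]] = {}
    disease_module: dict[str, int] = {}
    for k in range(spec.n_modules):
        mid = _module_id(k)
        terms.add(mid)
        parents[mid] = {ROOT_TERM}
        labels[mid] = f"synthetic disease group {k}"
    for i in range(spec.n_diseases):
        did = _disease_id(i)
        k = i % spec.n_modules
        terms.add(did)
        parents[did] = {_module_id(k)}
        labels[did] = f"synthetic disease {i}"
        synonyms[did] = {f"SynDisease-{i}"}
        disease_module[did] = k
    dag = OntologyDAG(terms=terms, parents=parents, labels=labels, synonyms=synonyms)
    dag.validate()
    return dag, disease_module


def generate_fixture(
    spec: FixtureSpec, out_dir: str | Path | None = None
) -> FixtureBundle:
    """Generate a complete, self-consistent fixture bundle.

    Raises ``ValueError`` when ``snapshot_delta`` exceeds the number of
    eligible held-out pairs.
    """
    rng = np.random.default_rng(spec.seed)
    dag, disease_module = _build_ontology(spec)
    diseases = [_disease_id(i) for i in range(spec.n_diseases)]
    metabolites = [_metabolite_id(i) for i in range(spec.n_metabolites)]
    met_module = {m: i % spec.n_modules for i, m in enumerate(metabolites)}
    genes = [_gene_id(i) for i in range(spec.n_genes)]
    gene_module = {g: i % spec.n_modules for i, g in enumerate(genes)}
    pools = {
        k: [g for g in genes if gene_module[g] == k] for k in range(spec.n_modules)
    }

    # gene annotations: each disease samples from its module pool
    d2g: dict[str, set[str]] = {}
    for d in diseases:
        pool = pools[disease_module[d]]
        mask = rng.random(len(pool)) < spec.gene_share_prob
        chosen = {g for g, keep in zip(pool, mask) if keep}
        if not chosen:
            chosen = {pool[int(rng.integers(len(pool)))]}
        d2g[d] = chosen
    annotations = GeneAnnotation(disease2genes=d2g)

    # gene functional network: dense and strong within modules, sparse/weak across
    gedges: dict[tuple[str, str], float] = {}
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = genes[i], genes[j]
            same = gene_module[a] == gene_module[b]
            p = 0.5 if same else 0.05
            if rng.random() < p:
                lo, hi = (0.6, 1.0) if same else (0.05, 0.3)
                gedges[unordered_pair(a, b)] = round(float(rng.uniform(lo, hi)), 6)
    gene_network = GeneFunctionalNetwork(edges=gedges)

    # associations
    earlier: set[tuple[str, str]] = set()
    for d in diseases:
        for m in metabolites:
            same = disease_module[d] == met_module[m]
            p = spec.within_module_assoc_prob if same else spec.cross_module_assoc_prob
            if rng.random() < p:
                earlier.add((d, m))
    for m in metabolites:  # every metabolite needs >= 1 association
        if not any(mm == m for _, mm in earlier):
            cands = [d for d in diseases if disease_module[d] == met_module[m]]
            earlier.add((cands[int(rng.integers(len(cands)))], m))
    for d in diseases:  # every disease needs >= 1 association
        if not any(dd == d for dd, _ in earlier):
            cands = [m for m in metabolites if met_module[m] == disease_module[d]]
            earlier.add((d, cands[int(rng.integers(len(cands)))]))

    # held-out within-module pairs promoted into the later snapshot
    eligible = sorted(
        (d, m)
        for d in diseases
        for m in metabolites
        if disease_module[d] == met_module[m] and (d, m) not in earlier
    )
    if spec.snapshot_delta > len(eligible):
        raise ValueError(
            f"snapshot_delta={spec.snapshot_delta} exceeds {len(eligible)} "
            "available held-out within-module pairs"
        )
    order = rng.permutation(len(eligible))
    promoted = [eligible[i] for i in order[: spec.snapshot_delta]]
    remaining_hidden = [eligible[i] for i in order[spec.snapshot_delta :]]
    later = earlier | set(promoted)

    truth = (
        [(d, m, "seed") for d, m in sorted(earlier)]
        + [(d, m, "positive") for d, m in sorted(promoted)]
        + [(d, m, "hidden") for d, m in sorted(remaining_hidden)]
    )

    # text-mining edges, concordant with modules at the requested rate
    st: dict[tuple[str, str], float] = {}
    n_st = int(round(spec.st_edges_per_metabolite * spec.n_metabolites))
    same_pairs = sorted(
        unordered_pair(a, b)
        for i, a in enumerate(metabolites)
        for b in metabolites[i + 1 :]
        if met_module[a] == met_module[b]
    )
    cross_pairs = sorted(
        unordered_pair(a, b)
        for i, a in enumerate(metabolites)
        for b in metabolites[i + 1 :]
        if met_module[a] != met_module[b]
    )
    for _ in range(n_st):
        concordant = rng.random() < spec.textmining_concordance
        pool = same_pairs if (concordant and same_pairs) else cross_pairs
        if not pool:
            continue
        pair = pool[int(rng.integers(len(pool)))]
        if pair not in st:
            st[pair] = round(float(rng.uniform(0.4, 0.95)), 6)
    textmining = TextMiningScores(scores=st)

    # raw name-based rows for the mapping stage: alternate label/synonym
    raw_rows: list[tuple[str, str]] = []
    for d, m in sorted(earlier):
        if rng.random() < 0.5:
            raw_rows.append((dag.labels[d], m))
        else:
            raw_rows.append((next(iter(dag.synonyms[d])), m))

    medic_entries = [
        MedicEntry(
            name=f"MEDIC {dag.labels[d]}",
            synonyms=(f"medic synonym {i}",),
            do_term=d,
        )
        for i, d in enumerate(diseases)
    ]

    bundle = FixtureBundle(
        spec=spec,
        ontology=dag,
        annotations=annotations,
        gene_network=gene_network,
        assoc_earlier=AssociationTable(records=earlier, version_tag="earlier"),
        assoc_later=AssociationTable(records=later, version_tag="later"),
        textmining=textmining,
        truth=truth,
        medic_entries=medic_entries,
        raw_rows=raw_rows,
        disease_module=disease_module,
        metabolite_module=met_module,
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# Worked example: a tiny fixed instance, fully derivable by hand
# ---------------------------------------------------------------------------

WORKED_DISEASES = ["WD:D1", "WD:D2", "WD:D3", "WD:D4"]
WORKED_METABOLITES = ["WM1", "WM2", "WM3", "WM4", "WM5"]


def generate_worked_example(out_dir: str | Path | None = None) -> FixtureBundle:
    """Fixed 4-disease / 5-metabolite / 6-gene instance.

    Every intermediate quantity (disease similarities, profile vectors,
    cosine weights, fused weights, walk scores) is small enough to verify by
    hand; the frozen expectations live in ``docs/worked_example.md`` and the
    acceptance suite.
    """
    terms = {"WD:R", "WD:A", "WD:B", *WORKED_DISEASES}
    parents = {
        "WD:R": set(),
        "WD:A": {"WD:R"},
        "WD:B": {"WD:R"},
        "WD:D1": {"WD:A"},
        "WD:D2": {"WD:A"},
        "WD:D3": {"WD:B"},
        "WD:D4": {"WD:B"},
    }
    labels = {
        "WD:R": "worked disease root",
        "WD:A": "worked group a",
        "WD:B": "worked group b",
        "WD:D1": "worked disease one",
        "WD:D2": "worked disease two",
        "WD:D3": "worked disease three",
        "WD:D4": "worked disease four",
    }
    synonyms = {d: {labels[d] + " syn"} for d in WORKED_DISEASES}
    dag = OntologyDAG(terms=terms, parents=parents, labels=labels, synonyms=synonyms)
    dag.validate()

    annotations = GeneAnnotation(
        disease2genes={
            "WD:D1": {"g1", "g2"},
            "WD:D2": {"g2", "g3"},
            "WD:D3": {"g4", "g5"},
            "WD:D4": {"g5", "g6"},
        }
    )
    gene_network = GeneFunctionalNetwork(
        edges={
            unordered_pair("g1", "g3"): 0.8,
            unordered_pair("g4", "g6"): 0.6,
            unordered_pair("g2", "g5"): 0.2,
            unordered_pair("g3", "g4"): 0.4,
        }
    )
    earlier = {
        ("WD:D1", "WM1"),
        ("WD:D1", "WM2"),
        ("WD:D2", "WM2"),
        ("WD:D2", "WM3"),
        ("WD:D3", "WM4"),
        ("WD:D3", "WM5"),
        ("WD:D4", "WM5"),
    }
    later = earlier | {("WD:D1", "WM3"), ("WD:D4", "WM4")}
    textmining = TextMiningScores(
        scores={
            unordered_pair("WM1", "WM2"): 0.5,
            unordered_pair("WM4", "WM5"): 0.9,
            unordered_pair("WM2", "WM4"): 0.3,
        }
    )
    truth = [(d, m, "seed") for d, m in sorted(earlier)] + [
        (d, m, "positive") for d, m in sorted(later - earlier)
    ]
    raw_rows = [(labels[d], m) for d, m in sorted(earlier)]
    medic_entries = [
        MedicEntry(name=f"MEDIC {labels[d]}", synonyms=(), do_term=d)
        for d in WORKED_DISEASES
    ]
    bundle = FixtureBundle(
        spec=FixtureSpec(
            n_diseases=4, n_metabolites=5, n_genes=6, n_modules=2, snapshot_delta=2
        ),
        ontology=dag,
        annotations=annotations,
        gene_network=gene_network,
        assoc_earlier=AssociationTable(records=earlier, version_tag="earlier"),
        assoc_later=AssociationTable(records=later, version_tag="later"),
        textmining=textmining,
        truth=truth,
        medic_entries=medic_entries,
        raw_rows=raw_rows,
        disease_module={"WD:D1": 0, "WD:D2": 0, "WD:D3": 1, "WD:D4": 1},
        metabolite_module={"WM1": 0, "WM2": 0, "WM3": 0, "WM4": 1, "WM5": 1},
    )
    if out_dir is not None:
        bundle.write(out_dir)
    return bundle


# ---------------------------------------------------------------------------
# bundle writers for formats owned by this module
# ---------------------------------------------------------------------------


def _write_obo(path: Path, dag: OntologyDAG) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            if term in dag.labels:
                fh.write(f"name: {dag.labels[term]}\n")
            for syn in sorted(dag.synonyms.get(term, ())):
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for parent in sorted(dag.parents.get(term, ())):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def _write_medic(path: Path, entries: list[MedicEntry]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("DiseaseName\tSynonyms\tDOID\n")
        for e in sorted(entries, key=lambda e: (e.name, e.do_term)):
            fh.write(f"{e.name}\t{'|'.join(e.synonyms)}\t{e.do_term}\n")


def _write_raw_associations(path: Path, rows: list[tuple[str, str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_name\tmetabolite_id\n")
        for name, met in sorted(rows):
            fh.write(f"{name}\t{met}\n")


def _write_truth(path: Path, truth: list[tuple[str, str, str]]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("disease_id\tmetabolite_id\tsplit\n")
        for d, m, split in truth:
            fh.write(f"{d}\t{m}\t{split}\n")
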