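"""Combined disease vocabulary and free-text name -> ontology term mapping.

Matching is exact on normalized strings; ambiguity (one name mapping to
several terms) is data, not an error, and is resolved by a configurable
policy.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .io import AssociationTable, DataFormatError, OntologyDAG, _data_lines

logger = logging.getLogger(__name__)

DO_NAME = "DO_NAME"
DO_SYNONYM = "DO_SYNONYM"
MEDIC_NAME = "MEDIC_NAME"
MEDIC_SYNONYM = "MEDIC_SYNONYM"

_NON_ALNUM = re.compile(r"[^0-9a-z]+")


def normalize_name(raw: str) -> str:
    """Lowercase, strip punctuation to spaces, collapse whitespace.

    Idempotent: ``normalize_name(normalize_name(x)) == normalize_name(x)``.
    """
    return _NON_ALNUM.sub(" ", raw.lower()).strip()


@dataclass
class MedicEntry:
    name: str
    synonyms: tuple[str, ...]
    do_term: str


@dataclass
class CombinedVocabulary:
    """Normalized disease name -> candidate ontology terms, with provenance."""

    name2term: dict[str, set[str]]
    provenance: dict[str, set[str]] = field(default_factory=dict)

    def lookup(self, raw_name: str) -> set[str]:
        return self.name2term.get(normalize_name(raw_name), set())


@dataclass
class MappingReport:
    """Accounting for one :func:`map_associations` run.

    Invariant: ``mapped + len(unmapped) + ambiguous_dropped`` equals the
    number of unique input rows.
    """

    n_input_rows: int
    n_unique_rows: int
    mapped: int
    unmapped: list[tuple[str, str]]
    ambiguous: list[tuple[str, str, tuple[str, ...]]]
    ambiguous_dropped: int
    policy: str


def read_medic(path: str | Path) -> list[MedicEntry]:
    """Read a MEDIC-style TSV: DiseaseName, Synonyms (pipe-separated), DOID."""
    path = Path(path)
    entries: list[MedicEntry] = []
    header: list[str] | None = None
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if header is None:
            header = fields
            for col in ("DiseaseName", "Synonyms", "DOID"):
                if col not in header:
                    raise DataFormatError(f"{path}: missing column {col!r}")
            continue
        if len(fields) < len(header):
            fields += [""] * (len(header) - len(fields))
        name = fields[header.index("DiseaseName")]
        syns = tuple(
            s.strip()
            for s in fields[header.index("Synonyms")].split("|")
            if s.strip()
        )
        entries.append(MedicEntry(name=name, synonyms=syns, do_term=fields[header.index("DOID")]))
    if header is None:
        raise DataFormatError(f"{path}: empty file, header required")
    return entries


def build_vocabulary(
    dag: OntologyDAG, medic: Iterable[MedicEntry] = ()
) -> CombinedVocabulary:
    """Union ontology names/synonyms with MEDIC names/synonyms.

    Collisions (one normalized name -> multiple terms) are retained as a set.
    MEDIC rows referencing unknown ontology terms are skipped with a warning.
    """
    name2term: dict[str, set[str]] = {}
    provenance: dict[str, set[str]] = {}

    def add(raw: str, term: str, source: str) -> None:
        key = normalize_name(raw)
        if not key:
            return
        name2term.setdefault(key, set()).add(term)
        provenance.setdefault(key, set()).add(source)

    for term in sorted(dag.terms):
        if term in dag.labels:
            add(dag.labels[term], term, DO_NAME)
        for syn in sorted(dag.synonyms.get(term, ())):
            add(syn, term, DO_SYNONYM)
    for entry in medic:
        if entry.do_term not in dag.terms:
            logger.warning(
                "MEDIC entry %r references unknown term %r; skipped",
                entry.name,
                entry.do_term,
            )
            continue
        add(entry.name, entry.do_term, MEDIC_NAME)
        for syn in entry.synonyms:
            add(syn, entry.do_term, MEDIC_SYNONYM)
    return CombinedVocabulary(name2term=name2term, provenance=provenance)


def read_raw_associations(path: str | Path) -> list[tuple[str, str]]:
    """Read a TSV of (disease_name, metabolite_id) rows, duplicates retained."""
    path = Path(path)
    rows: list[tuple[str, str]] = []
    header: list[str] | None = None
    for lineno, line in _data_lines(path):
        fields = [f.strip() for f in line.split("\t")]
        if header is None:
            header = fields
            for col in ("disease_name", "metabolite_id"):
                if col not in header:
                    raise DataFormatError(f"{path}: missing column {col!r}")
            continue
        if len(fields) < 2:
            raise DataFormatError(f"{path}:{lineno}: too few columns")
        rows.append(
            (fields[header.index("disease_name")], fields[header.index("metabolite_id")])
        )
    if header is None:
        raise DataFormatError(f"{path}: empty file, header required")
    return rows


def map_associations(
    raw: Iterable[tuple[str, str]],
    vocab: CombinedVocabulary,
    policy: str = "drop",
    version_tag: str = "",
) -> tuple[AssociationTable, MappingReport]:
    """Resolve (disease name, metabolite id) rows against the vocabulary.

    ``policy`` controls ambiguous names: ``"drop"`` discards them (reported),
    ``"first"`` picks the lexicographically smallest term id.  Mapping is
    deterministic given the same vocabulary.
    """
    if policy not in ("drop", "first"):
        raise ValueError(f"unknown ambiguity policy {policy!r}")
    rows = list(raw)
    unique_rows = sorted(set(rows))
    records: set[tuple[str, str]] = set()
    unmapped: list[tuple[str, str]] = []
    ambiguous: list[tuple[str, str, tuple[str, ...]]] = []
    mapped = 0
    ambiguous_dropped = 0
    for name, met in unique_rows:
        terms = vocab.lookup(name)
        if not terms:
            unmapped.append((name, met))
        elif len(terms) == 1:
            records.add((next(iter(terms)), met))
            mapped += 1
        else:
            ambiguous.append((name, met, tuple(sorted(terms))))
            if policy == "first":
                records.add((min(terms), met))
                mapped += 1
            else:
                ambiguous_dropped += 1
    report = MappingReport(
        n_input_rows=len(rows),
        n_unique_rows=len(unique_rows),
        mapped=mapped,
        unmapped=unmapped,
        ambiguous=ambiguous,
        ambiguous_dropped=ambiguous_dropped,
        policy=policy,
    )
    logger.info(
        "mapped %d/%d unique rows (%d unmapped, %d ambiguous under %r)",
        mapped,
        len(unique_rows),
        len(unmapped),
        len(ambiguous),
        policy,
    )
    return AssociationTable(records=records, version_tag=version_tag), report


def write_unmapped_report(path: str | Path, report: MappingReport) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# policy: {report.policy}\n")
        fh.write("disease_name\tmetabolite_id\tstatus\tcandidate_terms\n")
        for name, met in sorted(report.unmapped):
            fh.write(f"{name}\t{met}\tunmapped\t\n")
        for name, met, terms in sorted(report.ambiguous):
            fh.write(f"{name}\t{met}\tambiguous\t{'|'.join(terms)}\n")
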