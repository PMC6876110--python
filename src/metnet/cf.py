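"""Metabolite profile vectors by collaborative filtering and the cosine network.

Each metabolite gets a dense relevance vector over the disease set: 1 for its
direct associations, otherwise the maximum disease similarity from the query
disease to any disease the metabolite is directly associated with.  Pairwise
cosine similarity of those vectors, thresholded, yields the weighted
metabolite network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .disease_sim import DiseaseSimilarityMatrix
from .io import AssociationTable, DataFormatError, WeightedMetaboliteNetwork, _data_lines

logger = logging.getLogger(__name__)


@dataclass
class MetaboliteProfileMatrix:
    """|M| x |D| matrix of disease relevance scores, entries in [0, 1]."""

    metabolites: list[str]
    diseases: list[str]
    PA: np.ndarray
    _midx: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self._midx:
            self._midx = {m: i for i, m in enumerate(self.metabolites)}

    def vector(self, metabolite: str) -> np.ndarray:
        return self.PA[self._midx[metabolite]]


def relevance_score(
    d: str, m: str, assoc: AssociationTable, dsim: DiseaseSimilarityMatrix
) -> float:
    """Relevance of disease ``d`` to metabolite ``m``.

    1 for a direct association, otherwise the maximum similarity between
    ``d`` and any disease directly associated with ``m``.
    """
    dr = assoc.by_metabolite().get(m, set())
    if not dr:
        raise ValueError(f"metabolite {m!r} has no associated disease")
    if d in dr:
        return 1.0
    return max(dsim.get(di, d) for di in sorted(dr))


def build_profiles(
    assoc: AssociationTable, dsim: DiseaseSimilarityMatrix
) -> MetaboliteProfileMatrix:
    """Dense profile matrix over all metabolites with >= 1 associated disease.

    The disease axis is the (sorted) set of diseases appearing in the
    association table; every disease must be present in ``dsim``.
    """
    by_m = assoc.by_metabolite()
    diseases = sorted(assoc.diseases())
    if not diseases:
        raise ValueError("association table is empty")
    missing = [d for d in diseases if d not in dsim._index]
    if missing:
        raise DataFormatError(
            f"diseases absent from similarity matrix: {missing[:5]}"
        )
    metabolites = sorted(m for m, dr in by_m.items() if dr)
    dropped = sorted(set(by_m) - set(metabolites))
    if dropped:
        logger.warning("excluding %d metabolites with no associations", len(dropped))
    col_idx = np.array([dsim.index(d) for d in diseases])
    sub = dsim.sim[np.ix_(col_idx, col_idx)]  # similarity over the working set
    didx = {d: i for i, d in enumerate(diseases)}
    PA = np.zeros((len(metabolites), len(diseases)), dtype=float)
    for i, m in enumerate(metabolites):
        rows = [didx[d] for d in sorted(by_m[m])]
        PA[i] = sub[rows].max(axis=0)
        PA[i, rows] = 1.0
    return MetaboliteProfileMatrix(metabolites=metabolites, diseases=diseases, PA=PA)


def cosine_similarity(ma: np.ndarray, mb: np.ndarray) -> float:
    """Cosine of two nonnegative vectors; in [0, 1]."""
    ma = np.asarray(ma, dtype=float)
    mb = np.asarray(mb, dtype=float)
    if ma.shape != mb.shape:
        raise ValueError("profile vectors have different dimensions")
    na = float(np.sqrt(np.dot(ma, ma)))
    nb = float(np.sqrt(np.dot(mb, mb)))
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(ma, mb) / (na * nb))


def build_dmn(
    profiles: MetaboliteProfileMatrix,
    threshold: float = 0.01,
    strict: bool = True,
) -> WeightedMetaboliteNetwork:
    """Cosine-similarity network over profile vectors, weak edges filtered.

    An edge is retained iff its similarity exceeds ``threshold`` (strictly by
    default).  Zero-similarity pairs are never stored.  The node set is every
    profiled metabolite, so isolated nodes survive filtering.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold {threshold!r} outside [0, 1)")
    X = profiles.PA
    norms = np.linalg.norm(X, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("zero profile vector encountered")
    Xn = X / norms[:, None]
    S = Xn @ Xn.T
    mets = profiles.metabolites
    edges: dict[tuple[str, str], float] = {}
    n = len(mets)
    for i in range(n):
        for j in range(i + 1, n):
            s = float(S[i, j])
            if s <= 0.0:
                continue
            if (s > threshold) if strict else (s >= threshold):
                edges[(mets[i], mets[j])] = min(s, 1.0)
    logger.info(
        "DMN: %d nodes, %d edges retained at threshold %g", n, len(edges), threshold
    )
    return WeightedMetaboliteNetwork(nodes=set(mets), edges=edges, kind_tag="DMN")


def write_profiles(path: str | Path, profiles: MetaboliteProfileMatrix) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("metabolite_id\t" + "\t".join(profiles.diseases) + "\n")
        for i, m in enumerate(profiles.metabolites):
            vals = "\t".join(repr(float(v)) for v in profiles.PA[i])
            fh.write(f"{m}\t{vals}\n")


def read_profiles(path: str | Path) -> MetaboliteProfileMatrix:
    path = Path(path)
    header: list[str] | None = None
    mets: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if header is None:
            if fields[0] != "metabolite_id":
                raise DataFormatError(f"{path}: missing column 'metabolite_id'")
            header = fields
            continue
        mets.append(fields[0])
        rows.append([float(v) for v in fields[1:]])
    if header is None:
        raise DataFormatError(f"{path}: empty file, header required")
    return MetaboliteProfileMatrix(
        metabolites=mets, diseases=header[1:], PA=np.array(rows, dtype=float)
    )
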