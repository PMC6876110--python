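"""Two-snapshot validation: seeds from the earlier association table,
positives from associations that are new in the later one, AUC per disease.

The candidate pool for a disease is every network node that is not one of its
seeds; the negative set is the pool minus the positives.  AUC uses the
Mann-Whitney concordance statistic with ties counted as 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata

from .cf import MetaboliteProfileMatrix, build_dmn
from .io import AssociationTable, WeightedMetaboliteNetwork
from .rwr import RwrConfig, rwr_scores

logger = logging.getLogger(__name__)


@dataclass
class ValidationCase:
    disease: str
    seed_metabolites: set[str]
    positive_metabolites: set[str]
    candidate_pool: set[str]

    def __post_init__(self) -> None:
        if not self.positive_metabolites <= self.candidate_pool:
            raise ValueError("positives must be contained in the candidate pool")
        if self.seed_metabolites & self.positive_metabolites:
            raise ValueError("seed and positive sets overlap")


@dataclass
class EvaluationReport:
    per_case: dict[str, float]
    mean_auc: float
    per_case_counts: dict[str, tuple[int, int, int]]  # seeds, positives, pool


def build_validation_cases(
    earlier: AssociationTable,
    later: AssociationTable,
    net: WeightedMetaboliteNetwork,
) -> list[ValidationCase]:
    """One case per disease with >= 1 in-network seed and >= 1 novel in-network
    association in the later snapshot.  Earlier associations are never positives."""
    earlier_by_d = earlier.by_disease()
    later_by_d = later.by_disease()
    cases: list[ValidationCase] = []
    for disease in sorted(later_by_d):
        seeds = earlier_by_d.get(disease, set()) & net.nodes
        if not seeds:
            logger.info("disease %s skipped: no in-network seeds", disease)
            continue
        novel = later_by_d[disease] - earlier_by_d.get(disease, set())
        positives = (novel & net.nodes) - seeds
        if not positives:
            logger.info("disease %s skipped: no in-network novel associations", disease)
            continue
        pool = net.nodes - seeds
        cases.append(
            ValidationCase(
                disease=disease,
                seed_metabolites=seeds,
                positive_metabolites=positives,
                candidate_pool=pool,
            )
        )
    return cases


def auc(scores: Mapping[str, float], positives: set[str], pool: set[str]) -> float:
    """Mann-Whitney AUC of positives vs the rest of the pool; ties count 0.5."""
    if not positives:
        raise ValueError("positive set is empty")
    if not positives <= pool:
        raise ValueError("positives must be a subset of the pool")
    negatives = pool - positives
    if not negatives:
        raise ValueError("negative set is empty")
    pos = sorted(positives)
    neg = sorted(negatives)
    values = np.array([scores[m] for m in pos + neg], dtype=float)
    ranks = rankdata(values, method="average")
    n_pos, n_neg = len(pos), len(neg)
    u = float(ranks[:n_pos].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def evaluate_network(
    net: WeightedMetaboliteNetwork,
    cases: Sequence[ValidationCase],
    cfg: RwrConfig = RwrConfig(),
) -> EvaluationReport:
    """Run the seeded walk for every case and report per-case and mean AUC."""
    if not cases:
        raise ValueError("no validation cases")
    per_case: dict[str, float] = {}
    counts: dict[str, tuple[int, int, int]] = {}
    for case in cases:
        result = rwr_scores(net, case.seed_metabolites, cfg)
        per_case[case.disease] = auc(
            result.scores, case.positive_metabolites, case.candidate_pool
        )
        counts[case.disease] = (
            len(case.seed_metabolites),
            len(case.positive_metabolites),
            len(case.candidate_pool),
        )
    mean = sum(per_case.values()) / len(per_case)
    return EvaluationReport(per_case=per_case, mean_auc=mean, per_case_counts=counts)


def metabolite_seed_evaluation(
    net: WeightedMetaboliteNetwork,
    target: str,
    co_associated: set[str],
    cfg: RwrConfig = RwrConfig(),
) -> float:
    """AUC for ranking a metabolite's co-associated partners from a single seed."""
    if target not in net.nodes:
        raise ValueError(f"target {target!r} not in network")
    positives = (co_associated & net.nodes) - {target}
    if not positives:
        raise ValueError("no in-network co-associated metabolites")
    result = rwr_scores(net, {target}, cfg)
    pool = net.nodes - {target}
    return auc(result.scores, positives, pool)


def threshold_sweep(
    profiles: MetaboliteProfileMatrix,
    thresholds: Sequence[float],
    cases: Sequence[ValidationCase],
    cfg: RwrConfig = RwrConfig(),
) -> dict[float, float | None]:
    """Rebuild the cosine network per threshold and evaluate each one.

    Thresholds must be sorted ascending.  A threshold that leaves the network
    without edges is reported as ``None`` (cases cannot be scored).
    """
    ts = list(thresholds)
    if ts != sorted(ts):
        raise ValueError("thresholds must be sorted ascending")
    out: dict[float, float | None] = {}
    for t in ts:
        net = build_dmn(profiles, threshold=t)
        if not net.edges:
            logger.warning("threshold %g leaves an empty network; skipped", t)
            out[t] = None
            continue
        out[t] = evaluate_network(net, cases, cfg).mean_auc
    return out


def write_report(
    path: str | Path, report: EvaluationReport, meta: Mapping[str, str] | None = None
) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
        fh.write("disease\tn_seeds\tn_positives\tn_pool\tauc\n")
        for disease in sorted(report.per_case):
            s, p, n = report.per_case_counts[disease]
            fh.write(f"{disease}\t{s}\t{p}\t{n}\t{report.per_case[disease]!r}\n")
        fh.write(f"# mean_auc: {report.mean_auc!r}\n")
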