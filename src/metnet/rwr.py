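"""Random walk with restart over a weighted metabolite network.

Column-stochastic convention: the transition matrix is the weighted adjacency
with each nonzero-degree column scaled to sum 1; isolated nodes become
self-absorbing.  Iteration is ``p <- (1 - r) W p + r p0`` with ``p0`` uniform
over the seed set, stopped on an L1 residual below tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import WeightedMetaboliteNetwork

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the walk fails to converge within the iteration budget."""


@dataclass(frozen=True)
class RwrConfig:
    restart_probability: float = 0.7
    tolerance: float = 1e-10
    max_iterations: int = 10_000

    def __post_init__(self) -> None:
        if not 0.0 < self.restart_probability <= 1.0:
            raise ValueError("restart_probability must be in (0, 1]")
        if self.tolerance <= 0.0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass
class RankingResult:
    """Stationary scores plus a 1-based descending ranking of non-seed nodes."""

    scores: dict[str, float]
    rank: dict[str, int]
    iterations_used: int
    seeds: frozenset[str] = field(default_factory=frozenset)


def column_normalize(net: WeightedMetaboliteNetwork) -> tuple[list[str], np.ndarray]:
    """Node order (sorted) and the column-stochastic transition matrix."""
    if not net.nodes:
        raise ValueError("network has no nodes")
    nodes = sorted(net.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n), dtype=float)
    for (a, b), w in net.edges.items():
        A[idx[a], idx[b]] = w
        A[idx[b], idx[a]] = w
    colsums = A.sum(axis=0)
    W = np.zeros_like(A)
    nz = colsums > 0.0
    W[:, nz] = A[:, nz] / colsums[nz]
    for j in np.nonzero(~nz)[0]:
        W[j, j] = 1.0  # isolated node: self-absorbing
    return nodes, W


def _seed_vector(nodes: list[str], seeds: frozenset[str]) -> np.ndarray:
    p0 = np.zeros(len(nodes), dtype=float)
    pos = {n: i for i, n in enumerate(nodes)}
    for s in seeds:
        p0[pos[s]] = 1.0 / len(seeds)
    return p0


def _ranking(
    nodes: list[str], p: np.ndarray, seeds: frozenset[str], iterations: int
) -> RankingResult:
    scores = {n: float(p[i]) for i, n in enumerate(nodes)}
    non_seeds = sorted((n for n in nodes if n not in seeds), key=lambda n: (-scores[n], n))
    rank = {n: i + 1 for i, n in enumerate(non_seeds)}
    return RankingResult(scores=scores, rank=rank, iterations_used=iterations, seeds=seeds)


def rwr_scores(
    net: WeightedMetaboliteNetwork,
    seeds: set[str] | frozenset[str],
    cfg: RwrConfig = RwrConfig(),
) -> RankingResult:
    """Iterate the walk to stationarity and rank all non-seed nodes.

    Ties in score break by sorted metabolite id.  Unknown seeds and
    non-convergence are hard errors.
    """
    seeds = frozenset(seeds)
    if not seeds:
        raise ValueError("seed set is empty")
    unknown = seeds - net.nodes
    if unknown:
        raise ValueError(f"seeds not in network: {sorted(unknown)[:5]}")
    nodes, W = column_normalize(net)
    p0 = _seed_vector(nodes, seeds)
    r = cfg.restart_probability
    if r == 1.0:
        return _ranking(nodes, p0.copy(), seeds, 0)
    p = p0.copy()
    for it in range(1, cfg.max_iterations + 1):
        p_next = (1.0 - r) * (W @ p) + r * p0
        resid = float(np.abs(p_next - p).sum())
        p = p_next
        if resid < cfg.tolerance:
            return _ranking(nodes, p, seeds, it)
    raise ConvergenceError(
        f"random walk did not converge in {cfg.max_iterations} iterations "
        f"(last L1 residual {resid:.3e})"
    )


def rwr_solve_oracle(
    net: WeightedMetaboliteNetwork,
    seeds: set[str] | frozenset[str],
    cfg: RwrConfig = RwrConfig(),
) -> dict[str, float]:
    """Exact stationary solution ``p = r (I - (1 - r) W)^{-1} p0``.

    Dense linear solve; intended as an independent check for small networks.
    """
    seeds = frozenset(seeds)
    if not seeds or seeds - net.nodes:
        raise ValueError("invalid seed set")
    nodes, W = column_normalize(net)
    if len(nodes) > 2000:
        raise ValueError("oracle limited to networks of <= 2000 nodes")
    p0 = _seed_vector(nodes, seeds)
    r = cfg.restart_probability
    A = np.eye(len(nodes)) - (1.0 - r) * W
    p = r * np.linalg.solve(A, p0)
    return {n: float(p[i]) for i, n in enumerate(nodes)}


def restart_sweep(
    net: WeightedMetaboliteNetwork,
    seeds: set[str],
    restarts: list[float],
    tolerance: float = 1e-10,
    max_iterations: int = 10_000,
) -> dict[float, RankingResult]:
    """Sensitivity utility: rerun the walk for each restart probability."""
    out = {}
    for r in restarts:
        cfg = RwrConfig(
            restart_probability=r, tolerance=tolerance, max_iterations=max_iterations
        )
        out[r] = rwr_scores(net, seeds, cfg)
    return out


def write_ranking(path, result: RankingResult, meta: dict[str, str] | None = None) -> None:
    """Ranking TSV: metabolite, score, rank (empty for seeds), is_seed."""
    from pathlib import Path

    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if meta:
            for k, v in meta.items():
                fh.write(f"# {k}: {v}\n")
        fh.write("metabolite\tscore\trank\tis_seed\n")
        by_rank = sorted(
            result.scores, key=lambda n: (result.rank.get(n, 0), n)
        )
        seeds_first = [n for n in by_rank if n in result.seeds] + [
            n for n in by_rank if n not in result.seeds
        ]
        for n in seeds_first:
            rank = result.rank.get(n, "")
            fh.write(
                f"{n}\t{result.scores[n]!r}\t{rank}\t{int(n in result.seeds)}\n"
            )
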