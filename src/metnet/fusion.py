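"""Noisy-OR fusion of the cosine metabolite network with text-mining scores."""

from __future__ import annotations

import logging

from .io import TextMiningScores, WeightedMetaboliteNetwork

logger = logging.getLogger(__name__)


def fuse_edge(dmn_w: float, st_w: float) -> float:
    """Probabilistic-OR combination ``1 - (1 - a)(1 - b)``; inputs in [0, 1].

    Symmetric, monotone non-decreasing in each argument, and dominates
    ``max(a, b)``.  A missing edge contributes 0.
    """
    if not 0.0 <= dmn_w <= 1.0:
        raise ValueError(f"network weight {dmn_w!r} outside [0, 1]")
    if not 0.0 <= st_w <= 1.0:
        raise ValueError(f"text-mining weight {st_w!r} outside [0, 1]")
    return 1.0 - (1.0 - dmn_w) * (1.0 - st_w)


def build_fldmn(
    dmn: WeightedMetaboliteNetwork, st: TextMiningScores
) -> WeightedMetaboliteNetwork:
    """Fuse every edge of the union of the two evidence channels.

    The node set stays that of the cosine network; text-mining pairs with an
    endpoint outside it are skipped (count logged).
    """
    edges: dict[tuple[str, str], float] = {}
    skipped = 0
    for pair, w in dmn.edges.items():
        sw = st.scores.get(pair, 0.0)
        # keep the single-channel weight bit-exact when the other channel is 0
        edges[pair] = w if sw == 0.0 else fuse_edge(w, sw)
    for pair, w in st.scores.items():
        if pair in edges:
            continue
        a, b = pair
        if a not in dmn.nodes or b not in dmn.nodes:
            skipped += 1
            continue
        if w > 0.0:
            edges[pair] = w
    if skipped:
        logger.info("fusion skipped %d text-mining pairs outside the node set", skipped)
    return WeightedMetaboliteNetwork(
        nodes=set(dmn.nodes), edges=edges, kind_tag="FLDMN"
    )


def extract_st_subnet(
    st: TextMiningScores, nodes: set[str]
) -> WeightedMetaboliteNetwork:
    """Text-mining edges restricted to a node set (both endpoints retained)."""
    edges = {
        pair: w
        for pair, w in st.scores.items()
        if pair[0] in nodes and pair[1] in nodes and w > 0.0
    }
    return WeightedMetaboliteNetwork(
        nodes=set(nodes), edges=edges, kind_tag="ST_SUBNET"
    )
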