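"""Core gene sets and the overlap weighting of direct vs transposon routes.

H-CORE: genes differentially expressed in every strain x time-point contrast
(the strain/phase-independent heat-response core).  M-CORE: the
mutation-driven interaction-network gene list (an input).  T-CORE: the first
out-going network neighbors of the regulator-affected transposon nodes.
|H&M|/|H| measures the regulator's direct transcriptional weight and
|H&T|/|H| the transposon-mediated weight; their ratio does not depend on the
shared denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx

__all__ = ["OverlapWeights", "h_core", "t_core", "overlap_weights"]


@dataclass
class OverlapWeights:
    pct_direct: float
    pct_transposon: float
    ratio: Optional[float]  # None when pct_transposon is zero


def _clean(genes: Iterable[str]) -> set[str]:
    out = set()
    for g in genes:
        g = str(g).strip()
        if not g:
            raise ValueError("gene identifiers must be nonempty")
        out.add(g)
    return out


def h_core(
    deg_sets: Sequence[Iterable[str]],
    directions: Optional[Sequence[Mapping[str, str]]] = None,
) -> set[str]:
    """Intersection of differential-expression gene sets.

    With ``directions`` (one gene->direction mapping per set), strict mode
    additionally requires a gene's direction label to agree across all sets.
    """
    if len(deg_sets) == 0:
        raise ValueError("need at least one DEG set")
    sets = [_clean(s) for s in deg_sets]
    core = set.intersection(*sets)
    if directions is not None:
        if len(directions) != len(sets):
            raise ValueError("one direction mapping per DEG set required")
        core = {
            g for g in core
            if all(g in d for d in directions)
            and len({d[g] for d in directions}) == 1
        }
    return core


def t_core(network: nx.DiGraph, transposon_nodes: Iterable[str]) -> set[str]:
    """Union of distance-1 out-neighbors of the transposon nodes.

    The transposon nodes themselves are excluded; neighbors reached through
    several transposon nodes count once (set union).
    """
    ty = _clean(transposon_nodes)
    unknown = ty - set(network.nodes)
    if unknown:
        raise ValueError(f"unknown network node(s): {sorted(unknown)}")
    out: set[str] = set()
    for node in ty:
        out.update(network.successors(node))
    return out - ty


def overlap_weights(h: set[str], m: set[str], t: set[str]) -> OverlapWeights:
    """Percent overlaps with H-CORE and the direct:transposon weight ratio.

    pct_direct = 100*|H&M|/|H|, pct_transposon = 100*|H&T|/|H|; the ratio is
    their quotient (None when the transposon overlap is empty).
    """
    if not h:
        raise ValueError("H-CORE must be nonempty")
    pct_direct = 100.0 * len(h & m) / len(h)
    pct_transposon = 100.0 * len(h & t) / len(h)
    ratio = pct_direct / pct_transposon if pct_transposon > 0 else None
    return OverlapWeights(pct_direct=pct_direct, pct_transposon=pct_transposon, ratio=ratio)
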