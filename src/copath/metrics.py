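"""Consistency and similarity indices over matchings and control paths.

The central quantity is the conservative degree CV of a family of per-layer
matchings M_1 ... M_L with union chi:

    CV(chi) = (1/|chi|) * sum_{e in chi} ( (1/L) * sum_l 1[e in M_l] )^2

i.e. the mean, over union edges, of the squared fraction of layers whose
matching contains the edge.  CV = 1 when all layers share one matching and
CV = (1/L)^2 when the matchings are pairwise disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .controllability import Matching
from .core import CCPResult, ControlPath
from .netmodel import Edge

__all__ = ["CVReport", "cv", "overlap_ratio", "ccp_similarity", "ccp_overlap_profile"]


@dataclass
class CVReport:
    """CV value with its supporting per-edge layer-count histogram.

    ``count_histogram[k]`` is the number of union edges present in exactly
    k layers' matchings; the histogram determines cv:
    cv = (1/chi_size) * sum_k histogram[k] * (k/L)^2.
    """

    cv: float
    chi_size: int
    n_layers: int
    count_histogram: dict[int, int] = field(default_factory=dict)
    warning: str | None = None


def cv(matchings: Sequence[Matching]) -> CVReport:
    """Conservative degree of a sequence of per-layer matchings.

    For a nonempty union, (1/L)^2 <= cv <= 1.  If every matching is empty
    the division by |chi| is undefined; cv is reported as 0.0 with a
    warning flag.
    """
    if len(matchings) < 1:
        raise ValueError("need at least one matching")
    L = len(matchings)
    counts: dict[Edge, int] = {}
    for m in matchings:
        for e in m.edges:
            counts[e] = counts.get(e, 0) + 1
    if not counts:
        return CVReport(cv=0.0, chi_size=0, n_layers=L,
                        warning="all matchings empty; CV undefined, reported as 0")
    hist: dict[int, int] = {}
    for k in counts.values():
        hist[k] = hist.get(k, 0) + 1
    value = sum(n * (k / L) ** 2 for k, n in hist.items()) / len(counts)
    return CVReport(cv=value, chi_size=len(counts), n_layers=L,
                    count_histogram=dict(sorted(hist.items())))


def _path_edges(paths: Sequence[ControlPath]) -> set[Edge]:
    out: set[Edge] = set()
    for cp in paths:
        out.update(cp.edges)
    return out


def overlap_ratio(
    paths_a: Sequence[ControlPath], paths_b: Sequence[ControlPath]
) -> float:
    """Jaccard index of the edge sets induced by two control-path lists.

    Used to compare CCPs before and after a perturbation (e.g. weight
    noise).  Two empty path lists are identical, so the ratio is 1.0.
    """
    ea, eb = _path_edges(paths_a), _path_edges(paths_b)
    if not ea and not eb:
        return 1.0
    return len(ea & eb) / len(ea | eb)


def ccp_similarity(
    result: CCPResult, layer_i: str, layer_j: str, level: str = "edge"
) -> float:
    """Jaccard similarity between two layers' detected control paths.

    ``level='edge'`` (default) compares matching edge sets; ``level='gene'``
    compares the node sets touched by the matchings.  Both layers empty at
    the chosen level gives 1.0.
    """
    for lid in (layer_i, layer_j):
        if lid not in result.per_layer_matchings:
            raise KeyError(f"no layer {lid!r} in result")
    mi = result.per_layer_matchings[layer_i]
    mj = result.per_layer_matchings[layer_j]
    if level == "edge":
        a, b = mi.edges, mj.edges
    elif level == "gene":
        a = {n for e in mi.edges for n in e}
        b = {n for e in mj.edges for n in e}
    else:
        raise ValueError(f"level must be 'edge' or 'gene', got {level!r}")
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def ccp_overlap_profile(
    result: CCPResult, layer_i: str, layer_j: str, level: str = "edge"
) -> dict[str, float]:
    """Jaccard plus the two per-layer containment fractions.

    ``frac_i`` is |intersection| / |layer_i's set| (and likewise ``frac_j``),
    the 'x% of layer i's edges overlap' style of normalization; ``jaccard``
    normalizes by the union.
    """
    mi = result.per_layer_matchings[layer_i]
    mj = result.per_layer_matchings[layer_j]
    if level == "edge":
        a, b = mi.edges, mj.edges
    elif level == "gene":
        a = {n for e in mi.edges for n in e}
        b = {n for e in mj.edges for n in e}
    else:
        raise ValueError(f"level must be 'edge' or 'gene', got {level!r}")
    inter = len(a & b)
    union = len(a | b)
    return {
        "jaccard": 1.0 if union == 0 else inter / union,
        "frac_i": 1.0 if not a else inter / len(a),
        "frac_j": 1.0 if not b else inter / len(b),
        "intersection": float(inter),
        "size_i": float(len(a)),
        "size_j": float(len(b)),
    }
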