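"""Offline network-pharmacology analysis.

Given user-supplied exports — a compound target list, a disease target list,
a protein-protein interaction (PPI) edge list and pathway gene sets — this
module intersects the target sets, computes degree and closeness centrality
on the intersection subnetwork, selects key targets whose centralities both
exceed the subnetwork means, and tests pathway over-representation with the
exact hypergeometric upper tail plus Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import EmptySetError, InvalidPValueError, UniverseViolationError

logger = logging.getLogger(__name__)


def _normalize(ids: Iterable[str]) -> frozenset[str]:
    out = set()
    for ident in ids:
        s = str(ident).strip().upper()
        if not s:
            raise ValueError("empty identifier")
        out.add(s)
    return frozenset(out)


@dataclass(frozen=True)
class TargetSet:
    """A labelled, case-normalized set of gene/protein identifiers."""

    label: str
    targets: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", _normalize(self.targets))

    def __len__(self) -> int:
        return len(self.targets)

    def __contains__(self, item: str) -> bool:
        return str(item).strip().upper() in self.targets


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected PPI network with optional per-edge confidence scores."""

    graph: nx.Graph

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        extra_nodes: Iterable[str] = (),
        score_cutoff: Optional[float] = None,
    ) -> "InteractionNetwork":
        """Build from (a, b) or (a, b, score) tuples; identifiers normalized.

        Self-loops are rejected; duplicate edges collapse to one.  When
        ``score_cutoff`` is given, edges with a score below it are dropped
        (edges without a score are always kept).
        """
        g = nx.Graph()
        for node in extra_nodes:
            g.add_node(str(node).strip().upper())
        for edge in edges:
            a, b = str(edge[0]).strip().upper(), str(edge[1]).strip().upper()
            score = float(edge[2]) if len(edge) > 2 and edge[2] is not None else None
            if a == b:
                raise ValueError(f"self-loop on {a!r}")
            if score is not None and not (0.0 <= score <= 1.0):
                raise ValueError(f"confidence score outside [0,1]: {score}")
            if score_cutoff is not None and score is not None and score < score_cutoff:
                continue
            g.add_edge(a, b, **({"score": score} if score is not None else {}))
        return cls(graph=g)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subnetwork(self, nodes: Iterable[str]) -> "InteractionNetwork":
        keep = _normalize(nodes)
        return InteractionNetwork(graph=self.graph.subgraph(keep).copy())


def intersect_targets(compound: TargetSet, disease: TargetSet) -> TargetSet:
    """Common targets of the compound and disease sets (case-normalized)."""
    if not compound.targets:
        raise EmptySetError(f"target set {compound.label!r} is empty")
    if not disease.targets:
        raise EmptySetError(f"target set {disease.label!r} is empty")
    common = compound.targets & disease.targets
    if not common:
        logger.warning(
            "no common targets between %s and %s", compound.label, disease.label
        )
    return TargetSet(label=f"{compound.label}∩{disease.label}", targets=common)


def topology_metrics(
    network: InteractionNetwork,
    closeness: Literal["wf", "harmonic"] = "wf",
) -> pd.DataFrame:
    """Degree and closeness centrality per node.

    Closeness uses the Wasserman-Faust convention by default: within a
    connected component of size s in an n-node graph, a node's closeness is
    (s-1)/sum(distances) scaled by (s-1)/(n-1), which keeps disconnected
    graphs comparable.  ``closeness="harmonic"`` substitutes harmonic
    centrality normalized by (n-1).
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise EmptySetError("network has no nodes")
    degree = dict(g.degree())
    if closeness == "wf":
        close = nx.closeness_centrality(g, wf_improved=True)
    elif closeness == "harmonic":
        n = g.number_of_nodes()
        denom = max(n - 1, 1)
        close = {k: v / denom for k, v in nx.harmonic_centrality(g).items()}
    else:
        raise ValueError(f"unknown closeness convention {closeness!r}")
    df = pd.DataFrame(
        {
            "node": sorted(g.nodes),
            "degree": [degree[n] for n in sorted(g.nodes)],
            "closeness": [close[n] for n in sorted(g.nodes)],
        }
    ).set_index("node")
    return df


def select_key_targets(metrics: pd.DataFrame) -> list[str]:
    """Nodes whose degree AND closeness both exceed the subnetwork means.

    Returned ranked by degree, then closeness, descending (name ascending to
    break exact ties).  When every node has identical metrics nothing exceeds
    the mean and the selection is empty (with a warning).
    """
    mean_deg = float(metrics["degree"].mean())
    mean_clo = float(metrics["closeness"].mean())
    sel = metrics[(metrics["degree"] > mean_deg) & (metrics["closeness"] > mean_clo)]
    if sel.empty:
        logger.warning("no node exceeds both subnetwork means; empty key-target set")
        return []
    # stable sort on a name-sorted frame: exact metric ties stay name-ascending
    ranked = sel.sort_index().sort_values(
        by=["degree", "closeness"], ascending=[False, False], kind="mergesort"
    )
    return list(ranked.index)


@dataclass(frozen=True)
class EnrichmentResult:
    """Over-representation result for one pathway."""

    pathway_id: str
    pathway_size: int
    overlap_count: int
    overlap_ids: tuple[str, ...]
    p_value: float
    q_value: float


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, returned in the input
    order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        bad = p[(~np.isfinite(p)) | (p <= 0) | (p > 1)]
        raise InvalidPValueError(f"p-values outside (0, 1]: {bad.tolist()}")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def hypergeom_tail(N: int, K: int, n: int, k: int, ease: bool = False) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    With ``ease=True`` the tail is computed at k-1 successes (the conservative
    EASE variant used by some enrichment servers); k = 0 always yields 1.
    """
    if ease:
        k = max(k - 1, 0)
    if k <= 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_pathways(
    query: TargetSet,
    genesets: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    ease: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of the query in each pathway.

    Pathway memberships are intersected with the universe before testing;
    pathways with no member in the universe are skipped.  BH adjustment runs
    across all tested pathways and results are sorted by ascending p-value
    (ties by pathway id).
    """
    uni = _normalize(universe)
    q = query.targets
    if not q:
        raise EmptySetError("query target set is empty")
    offenders = sorted(q - uni)
    if offenders:
        raise UniverseViolationError(
            f"query identifiers outside the universe: {offenders}"
        )
    N, n = len(uni), len(q)
    rows: list[tuple[str, int, int, tuple[str, ...], float]] = []
    for pid, members in genesets.items():
        mem = _normalize(members) & uni
        if not mem:
            logger.warning("pathway %s has no member in the universe; skipped", pid)
            continue
        overlap = sorted(mem & q)
        k = len(overlap)
        p = hypergeom_tail(N, len(mem), n, k, ease=ease)
        rows.append((pid, len(mem), k, tuple(overlap), p))
    if not rows:
        return []
    qvals = bh_adjust([r[4] for r in rows])
    results = [
        EnrichmentResult(
            pathway_id=pid,
            pathway_size=size,
            overlap_count=k,
            overlap_ids=overlap,
            p_value=p,
            q_value=float(qv),
        )
        for (pid, size, k, overlap, p), qv in zip(rows, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.pathway_id))
    return results


def enrichment_table(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in results],
            "pathway_size": [r.pathway_size for r in results],
            "overlap_count": [r.overlap_count for r in results],
            "overlap_ids": ["|".join(r.overlap_ids) for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
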