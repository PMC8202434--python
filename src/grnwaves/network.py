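"""Wave-specific regulatory networks, TF dominance ranking, hierarchy.

Networks are built per transcriptional wave from a ChIP-seq-derived prior
edge list: every TF and target that is differentially expressed in the wave
becomes a node, and prior edges between such nodes become edges.
Perturbation-validated edges are layered on top with their signs. TFs are
ranked by averaging two min-max-normalized axes — hypergeometric enrichment
of DE genes among the TF's prior targets (as -log10 p) and closeness
centrality in the wave network. The TF-only backbone is layered into a
hierarchy (sources at the top, sinks at the bottom) after condensing
strongly connected components, and TFs differentially expressed in more
than one wave are flagged as bridging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import ConsensusDEResult
from .perturbation import ValidatedEdge
from .waves import Wave


@dataclass
class PriorEdgeSet:
    """Deduplicated TF->target prior relations, optionally signed."""

    edges: set[tuple[str, str]]
    signs: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def tf_universe(self) -> set[str]:
        return {tf for tf, _ in self.edges}

    @property
    def target_universe(self) -> set[str]:
        return {tg for _, tg in self.edges}

    def targets_of(self, tf: str) -> set[str]:
        return {tg for t, tg in self.edges if t == tf}


@dataclass
class EnrichmentUrn:
    """Hypergeometric urn: N genes, K of them DE, n prior targets of one
    TF, k of those DE."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self) -> None:
        if not (0 <= self.K <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"invalid urn {self}")
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValueError(f"invalid urn {self}")
        if self.k < self.n - (self.N - self.K):
            raise ValueError(f"invalid urn {self}: k below forced minimum")


@dataclass
class TFRanking:
    """Per-TF enrichment, centrality and combined rank table, ordered by
    descending rank_score (ties: smaller hg_p, then gene id)."""

    table: pd.DataFrame  # index TF; hg_p, centrality, hg_norm, cent_norm, rank_score, rank

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)


@dataclass
class HierarchyLayout:
    """TF backbone plus per-TF layer index (0 = top of the hierarchy)."""

    backbone: nx.DiGraph
    layers: dict[str, int]


@dataclass
class BridgingAnnotation:
    """Waves each TF is DE in, and whether it bridges (>= 2 waves)."""

    waves_of_tf: dict[str, set[str]]
    combined: nx.DiGraph

    def is_bridging(self, tf: str) -> bool:
        return len(self.waves_of_tf.get(tf, ())) >= 2

    @property
    def bridging_tfs(self) -> list[str]:
        return sorted(tf for tf, ws in self.waves_of_tf.items() if len(ws) >= 2)


def load_prior_edges(path) -> PriorEdgeSet:
    """Read a TSV edge list (tf, target[, sign]); header row optional."""
    edges: set[tuple[str, str]] = set()
    signs: dict[tuple[str, str], str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}:{lineno}: malformed prior row {line!r}")
            tf, tg = parts[0].strip(), parts[1].strip()
            if lineno == 1 and tf.lower() in ("tf", "from", "source"):
                continue  # header
            edges.add((tf, tg))
            if len(parts) >= 3 and parts[2].strip() in ("up", "down"):
                signs[(tf, tg)] = parts[2].strip()
    if not edges:
        warnings.warn(f"prior edge list {path} is empty")
    return PriorEdgeSet(edges, signs)


def build_wave_network(
    wave: Wave,
    consensus: ConsensusDEResult,
    tf_list: set[str],
    prior: PriorEdgeSet,
) -> nx.DiGraph:
    """Prior-constrained network over the wave's DE genes.

    Nodes: DE TFs of the wave plus DE genes reachable by a prior edge from
    a DE TF. Edges: prior edges between nodes, provenance "prior", sign
    from the prior if present else "unknown". Node attributes carry is_tf
    and the consensus direction; the graph's ``wave`` attribute holds the
    wave label. The wave's gene membership is taken from ``wave.gene_set``.
    """
    de = set(wave.gene_set)
    de_tfs = sorted(de & tf_list)
    g = nx.DiGraph(wave=wave.label)
    direction = consensus.table["direction"]
    for tf in de_tfs:
        g.add_node(tf, is_tf=True, de_direction=str(direction.get(tf, "none")))
    for tf in de_tfs:
        for tg in sorted(prior.targets_of(tf)):
            if tg == tf or tg not in de:
                continue
            if tg not in g:
                g.add_node(
                    tg,
                    is_tf=tg in tf_list,
                    de_direction=str(direction.get(tg, "none")),
                )
            g.add_edge(
                tf, tg, provenance="prior", sign=prior.signs.get((tf, tg), "unknown")
            )
    if g.number_of_nodes() == 0:
        warnings.warn(f"wave {wave.label!r}: empty regulatory network")
    return g


def integrate_validated_edges(
    net: nx.DiGraph,
    validated: list[ValidatedEdge],
    wave: Wave | None = None,
    consensus: ConsensusDEResult | None = None,
    tf_list: set[str] | None = None,
) -> nx.DiGraph:
    """Overlay perturbation-validated edges on a wave network.

    A validated edge already present as a prior edge gets provenance
    "both" and the validated sign (conflicts resolved toward validation and
    flagged). A new edge is added when its TF is a node and its target is
    either a node already or — when the wave context is given — DE in the
    wave, in which case the target node is created; otherwise the edge is
    dropped with a warning.
    """
    out = net.copy()
    wave_de = set(wave.gene_set) if wave is not None else set()
    n_dropped = 0
    for ve in validated:
        if ve.tf not in out:
            n_dropped += 1
            continue
        if ve.target not in out:
            if ve.target in wave_de:
                direction = (
                    str(consensus.table["direction"].get(ve.target, "none"))
                    if consensus is not None
                    else "none"
                )
                out.add_node(
                    ve.target,
                    is_tf=ve.target in (tf_list or set()),
                    de_direction=direction,
                )
            else:
                n_dropped += 1
                continue
        if out.has_edge(ve.tf, ve.target):
            data = out[ve.tf][ve.target]
            prior_sign = data.get("sign", "unknown")
            data["provenance"] = "both"
            data["sign_conflict"] = prior_sign not in ("unknown", ve.sign)
            data["sign"] = ve.sign
            data["fdr"] = ve.fdr
        else:
            out.add_edge(
                ve.tf, ve.target, provenance="validated", sign=ve.sign, fdr=ve.fdr
            )
    if n_dropped:
        warnings.warn(
            f"{n_dropped} validated edge(s) dropped: endpoint not DE in this wave"
        )
    return out


def tf_enrichment(urn: EnrichmentUrn) -> float:
    """One-sided over-representation tail P(X >= k) of the hypergeometric
    law with the urn's parameters."""
    return float(stats.hypergeom.sf(urn.k - 1, urn.N, urn.K, urn.n))


def tf_centrality(net: nx.Graph, tf: str, variant: str = "closeness") -> float:
    """Centrality of a node on the undirected projection of the network.

    "closeness" uses the component-scaled form ((m-1)/sum d)*((m-1)/(N-1));
    "harmonic" the harmonic mean of distances normalized by N-1. Isolated
    nodes score 0.
    """
    if tf not in net:
        raise KeyError(f"node {tf!r} not in network")
    und = net.to_undirected() if net.is_directed() else net
    n_total = und.number_of_nodes()
    if n_total <= 1:
        return 0.0
    if variant == "closeness":
        return float(nx.closeness_centrality(und, u=tf, wf_improved=True))
    if variant == "harmonic":
        lengths = nx.single_source_shortest_path_length(und, tf)
        return float(sum(1.0 / d for d in lengths.values() if d > 0) / (n_total - 1))
    raise ValueError(f"unknown centrality variant: {variant}")


def rank_tfs(
    net: nx.DiGraph,
    prior: PriorEdgeSet,
    universe: set[str],
    de_genes: set[str],
    centrality_variant: str = "closeness",
) -> TFRanking:
    """Dominance ranking of the network's TFs.

    For each TF an urn is built over ``universe``: K = DE genes in the
    universe, n = the TF's prior targets in the universe, k = those that
    are DE. The -log10 enrichment p and the centrality are each min-max
    normalized over the network's TFs (degenerate spread maps to 0.5) and
    averaged into rank_score.
    """
    tfs = sorted(n for n, d in net.nodes(data=True) if d.get("is_tf"))
    if not tfs:
        raise ValueError("network has no TF nodes to rank")
    N = len(universe)
    K = len(de_genes & universe)
    rows = []
    for tf in tfs:
        targets = prior.targets_of(tf) & universe
        n = len(targets)
        k = len(targets & de_genes)
        p = tf_enrichment(EnrichmentUrn(N, K, n, k))
        cent = tf_centrality(net, tf, centrality_variant)
        rows.append((tf, p, cent))
    df = pd.DataFrame(rows, columns=["tf", "hg_p", "centrality"]).set_index("tf")
    hg = -np.log10(np.maximum(df["hg_p"].to_numpy(), 1e-300))
    df["hg_norm"] = _minmax(hg)
    df["cent_norm"] = _minmax(df["centrality"].to_numpy())
    df["rank_score"] = (df["hg_norm"] + df["cent_norm"]) / 2.0
    df = df.sort_values(
        by=["rank_score", "hg_p", "tf"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return TFRanking(df)


def _minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-300:
        return np.full_like(np.asarray(x, float), 0.5)
    return (np.asarray(x, float) - lo) / (hi - lo)


def backbone_hierarchy(net: nx.DiGraph, tf_list: set[str]) -> HierarchyLayout:
    """Layer the TF-only backbone hierarchically.

    The backbone (subgraph induced on TF nodes) is condensed by strongly
    connected components; each super-node's layer is its longest-path depth
    from the sources, so TFs with only outgoing regulation sit at layer 0
    and pure sinks at the bottom. Members of one component share a layer.
    """
    tf_nodes = [n for n in net.nodes if n in tf_list]
    backbone = net.subgraph(tf_nodes).copy()
    cond = nx.condensation(backbone)
    layer_of_scc: dict[int, int] = {}
    for scc in nx.topological_sort(cond):
        preds = list(cond.predecessors(scc))
        layer_of_scc[scc] = 0 if not preds else 1 + max(layer_of_scc[p] for p in preds)
    layers = {
        node: layer_of_scc[scc]
        for scc, data in cond.nodes(data=True)
        for node in data["members"]
    }
    return HierarchyLayout(backbone, layers)


def bridging_tfs(
    wave_networks: dict[str, nx.DiGraph],
    de_tfs_per_wave: dict[str, set[str]],
) -> BridgingAnnotation:
    """Bridging annotation and the combined wave graph.

    A TF bridges when it is DE in two or more waves. The combined graph
    holds one meta-node per wave plus every TF with DE targets in any wave,
    with an edge TF -> wave meta-node weighted by the TF's target count in
    that wave's network.
    """
    if len(wave_networks) < 2:
        raise ValueError("bridging requires >= 2 waves")
    waves_of_tf: dict[str, set[str]] = {}
    for wave, tfs in de_tfs_per_wave.items():
        for tf in tfs:
            waves_of_tf.setdefault(tf, set()).add(wave)
    combined = nx.DiGraph()
    for wave in wave_networks:
        combined.add_node(f"wave:{wave}", kind="wave")
    for wave, net in wave_networks.items():
        for tf in sorted(n for n, d in net.nodes(data=True) if d.get("is_tf")):
            n_targets = net.out_degree(tf)
            if n_targets == 0:
                continue
            if tf not in combined:
                combined.add_node(
                    tf, kind="tf", bridging=len(waves_of_tf.get(tf, ())) >= 2
                )
            combined.add_edge(tf, f"wave:{wave}", n_targets=n_targets)
    return BridgingAnnotation(waves_of_tf, combined)
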