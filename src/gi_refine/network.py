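"""Gene networks, the refining process (RP) and synthetic partner networks.

The refining process keeps a synthetic partner (SP) of a mutated gene only
if another SP of the same gene lies within network distance k (RP1: k = 1,
RP2: k = 2).  It is a single pass against the initial SP set: whether an SP
survives depends only on its distance to the *initial* SPs, not on which of
them survive.  The SPN at distance k is the subnetwork over the retained
SPs; at k = 2 it additionally contains the non-SP connector nodes that
realize length-2 paths between retained SPs.

KEGG-derived networks are directed, PPI networks undirected.  On directed
networks three distance semantics are available: ``ignore`` (treat edges as
undirected), ``either`` (a directed path in either direction counts,
the default — adjacency of partners is a symmetric notion), and
``forward`` (source-to-target paths only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from gi_refine.exceptions import ConfigurationError, FormatError

logger = logging.getLogger(__name__)

DIRECTION_MODES = ("ignore", "either", "forward")

_HEADER_TOKENS = {"source", "target", "from", "to", "node1", "node2", "gene1", "gene2", "u", "v"}


@dataclass(frozen=True)
class GeneNetwork:
    """A gene-symbol graph with an explicit directedness flag."""

    graph: nx.Graph | nx.DiGraph
    directed: bool

    def __post_init__(self) -> None:
        if self.directed != self.graph.is_directed():
            raise ConfigurationError("directed flag does not match the graph type")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def from_edges(edges, directed: bool = False, nodes=()) -> GeneNetwork:
    """Build a :class:`GeneNetwork` from (u, v) pairs; self-loops are dropped."""
    g = nx.DiGraph() if directed else nx.Graph()
    g.add_nodes_from(nodes)
    n_self = 0
    for u, v in edges:
        if u == v:
            n_self += 1
            continue
        g.add_edge(str(u), str(v))
    if n_self:
        logger.info("dropped %d self-loop edge(s)", n_self)
    return GeneNetwork(g, directed)


def load_network(path, directed: bool) -> GeneNetwork:
    """Load an edge-list TSV (``source<TAB>target[<TAB>attr...]``).

    Duplicate edges are collapsed, self-loops dropped (count logged).  An
    optional header line with recognizable column names is skipped.  A line
    with fewer than two fields raises with its line number.
    """
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                fields = line.split()
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected at least two fields")
            u, v = fields[0].strip(), fields[1].strip()
            if lineno == 1 and u.lower() in _HEADER_TOKENS and v.lower() in _HEADER_TOKENS:
                continue
            if not u or not v:
                raise FormatError(f"{path}:{lineno}: empty node name")
            edges.append((u, v))
    return from_edges(edges, directed=directed)


def write_network(network: GeneNetwork, path) -> None:
    """Write the edge list as TSV; isolated nodes are not representable."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\n")
        for u, v in sorted(network.graph.edges):
            fh.write(f"{u}\t{v}\n")


def map_sps(gi_table, network: GeneNetwork, exclude_self: bool = False) -> dict[str, dict]:
    """Map each mutated gene's SPs onto the network nodes.

    Returns ``{Q: {"initial": set, "skipped": bool, "n_unmapped": int}}``.
    A mutated gene with fewer than two mapped SPs is flagged skipped (the RP
    needs at least two).  With ``exclude_self`` the mutated gene itself is
    removed from its own SP set; by default a self-GI keeps Q as an
    ordinary SP node.
    """
    nodes = network.nodes
    out: dict[str, dict] = {}
    records = gi_table.records
    for q, group in records.groupby("mutated_gene", sort=True):
        sps = set(group["target_gene"])
        if exclude_self:
            sps.discard(q)
        mapped = {s for s in sps if s in nodes}
        n_unmapped = len(sps) - len(mapped)
        if n_unmapped:
            logger.info("mutated gene %s: %d SP(s) not on the network", q, n_unmapped)
        out[q] = {"initial": mapped, "skipped": len(mapped) < 2, "n_unmapped": n_unmapped}
    return out


def _neighbor_sets(network: GeneNetwork, mode: str):
    """Return one or two successor functions realizing the distance semantics.

    ``either`` on a directed graph needs two independent BFS sweeps (all
    edges forward, or all edges backward); every other case is one sweep.
    """
    g = network.graph
    if not network.directed:
        return (g.neighbors,)
    if mode == "forward":
        return (g.successors,)
    if mode == "either":
        return (g.successors, g.predecessors)
    # ignore: mixed orientations allowed along a path
    def undirected(n):
        seen = set(g.successors(n))
        yield from seen
        for p in g.predecessors(n):
            if p not in seen:
                yield p

    return (undirected,)


def _bfs_reach(neighbors, source, k: int) -> set:
    """Nodes reachable from ``source`` within ``k`` hops (source excluded)."""
    frontier = {source}
    reached: set = set()
    for _ in range(k):
        nxt = set()
        for node in frontier:
            for nb in neighbors(node):
                if nb != source and nb not in reached:
                    nxt.add(nb)
        reached |= nxt
        frontier = nxt
        if not frontier:
            break
    return reached


def within_distance(
    network: GeneNetwork, source, targets, k: int, direction_mode: str = "either"
) -> bool:
    """True iff some target other than the source lies within distance k.

    Implemented as bounded breadth-first search.  A source absent from the
    network yields False (logged).
    """
    if k < 1:
        raise ConfigurationError("distance k must be >= 1")
    if direction_mode not in DIRECTION_MODES:
        raise ConfigurationError(f"unknown direction_mode {direction_mode!r}")
    if source not in network.graph:
        logger.info("source %r not in network", source)
        return False
    goal = {t for t in targets if t != source}
    if not goal:
        return False
    for neighbors in _neighbor_sets(network, direction_mode):
        if _bfs_reach(neighbors, source, k) & goal:
            return True
    return False


@dataclass(frozen=True)
class RefinementResult:
    """Outcome of the refining process for one mutated gene at one distance."""

    mutated_gene: str
    k: int
    initial_sps: frozenset
    retained_sps: frozenset
    removed_sps: frozenset
    skipped: bool = False
    direction_mode: str = "either"


def refine(
    initial_sps,
    network: GeneNetwork,
    k: int,
    direction_mode: str = "either",
    mutated_gene: str = "",
    fixed_point: bool = False,
) -> RefinementResult:
    """Apply the RP at distance k to one mutated gene's initial SP set.

    Default semantics are a single pass against the initial set.  With
    ``fixed_point`` the filter is iterated (an SP whose only near neighbors
    were themselves removed is removed in turn) until stable.
    """
    initial = frozenset(initial_sps)
    if len(initial) < 2:
        logger.info("mutated gene %s: fewer than 2 SPs, refinement skipped", mutated_gene or "?")
        return RefinementResult(mutated_gene, k, initial, frozenset(), initial, skipped=True,
                                direction_mode=direction_mode)
    current = set(initial)
    while True:
        retained = {
            s for s in current
            if within_distance(network, s, current - {s}, k, direction_mode)
        }
        if not fixed_point or retained == current:
            break
        current = retained
    return RefinementResult(
        mutated_gene=mutated_gene,
        k=k,
        initial_sps=initial,
        retained_sps=frozenset(retained),
        removed_sps=initial - frozenset(retained),
        direction_mode=direction_mode,
    )


@dataclass(frozen=True)
class SPN:
    """Synthetic partner network of one mutated gene at distance k.

    ``sp_nodes`` maps each retained SP to its GI annotation (direction,
    fdr); ``connector_nodes`` are the unlabeled non-SP genes realizing
    length-2 paths between SPs (empty for k = 1); ``edges`` are stored in
    the network's orientation (canonically sorted for undirected networks).
    """

    mutated_gene: str
    k: int
    sp_nodes: dict[str, dict] = field(default_factory=dict)
    connector_nodes: frozenset = frozenset()
    edges: tuple = ()
    directed: bool = False

    @property
    def nodes(self) -> set:
        return set(self.sp_nodes) | set(self.connector_nodes)

    def is_empty(self) -> bool:
        return not self.sp_nodes


def _adjacent_edges(network: GeneNetwork, u, v, mode: str):
    """Edges between SPs u and v realizing a 1-path between them.

    On a directed network any stored edge between the pair qualifies in
    every mode: a path from u to v or from v to u both connect the pair,
    and each SP is tested as a source in its own right.
    """
    g = network.graph
    if not network.directed:
        return [tuple(sorted((u, v)))] if g.has_edge(u, v) else []
    return [e for e in ((u, v), (v, u)) if g.has_edge(*e)]


def _two_path_edges(network: GeneNetwork, s1, w, s2, mode: str):
    """Edges realizing a 2-path s1 - w - s2 under ``mode`` (may be empty).

    For ``either`` and ``forward`` the two hops must share one direction
    (a genuine directed path between the SPs, in whichever orientation);
    ``ignore`` accepts any orientation combination.
    """
    g = network.graph
    if not network.directed:
        if g.has_edge(s1, w) and g.has_edge(w, s2):
            return [tuple(sorted((s1, w))), tuple(sorted((w, s2)))]
        return []
    if mode in ("either", "forward"):
        combos = [((s1, w), (w, s2)), ((s2, w), (w, s1))]
    else:  # ignore: any orientation of each hop
        combos = [
            (a, b)
            for a in ((s1, w), (w, s1))
            for b in ((w, s2), (s2, w))
        ]
    edges = []
    for a, b in combos:
        if g.has_edge(*a) and g.has_edge(*b):
            edges.extend([a, b])
    return edges


def build_spn(
    refinement_result: RefinementResult,
    network: GeneNetwork,
    gi_table=None,
) -> SPN:
    """Construct the SPN over a refinement result's retained SPs.

    Direction and FDR annotations are pulled from ``gi_table`` when given.
    For k = 2, a non-SP node w becomes a connector when it realizes a
    length-2 path between two distinct retained SPs under the refinement's
    direction mode; the realizing edges are included.
    """
    retained = sorted(refinement_result.retained_sps)
    k = refinement_result.k
    mode = refinement_result.direction_mode
    q = refinement_result.mutated_gene

    annot: dict[str, dict] = {}
    if gi_table is not None:
        rec = gi_table.records
        rec = rec[rec["mutated_gene"] == q]
        for _, row in rec.iterrows():
            annot[row["target_gene"]] = {
                "direction": row["direction"],
                "fdr": float(row["fdr"]),
            }
    sp_nodes = {s: annot.get(s, {"direction": "unknown", "fdr": None}) for s in retained}

    edges: set = set()
    for i, s1 in enumerate(retained):
        for s2 in retained[i + 1:]:
            edges.update(_adjacent_edges(network, s1, s2, mode))

    connectors = set()
    if k >= 2 and retained:
        g = network.graph
        sp_set = set(retained)
        # candidate connectors: any neighbor (either orientation) of an SP
        candidates = set()
        for s in retained:
            if s not in g:
                continue
            candidates.update(g.neighbors(s) if not network.directed else
                              set(g.successors(s)) | set(g.predecessors(s)))
        candidates -= sp_set
        for w in sorted(candidates):
            realized = []
            for i, s1 in enumerate(retained):
                for s2 in retained[i + 1:]:
                    realized.extend(_two_path_edges(network, s1, w, s2, mode))
            if realized:
                connectors.add(w)
                edges.update(realized)

    return SPN(
        mutated_gene=q,
        k=k,
        sp_nodes=sp_nodes,
        connector_nodes=frozenset(connectors),
        edges=tuple(sorted(edges)),
        directed=network.directed,
    )


def filter_gi_table(gi_table, refinement_results: dict[str, RefinementResult], label: str = ""):
    """Restrict a GI table to (Q, K) pairs whose K survived Q's refinement.

    Mutated genes absent from ``refinement_results`` or flagged skipped are
    dropped entirely (the RP applies only where at least two SPs mapped).
    """
    rec = gi_table.records
    keep = pd.Series(False, index=rec.index)
    for q, res in refinement_results.items():
        if getattr(res, "skipped", False):
            continue
        retained = res.retained_sps if isinstance(res, RefinementResult) else set(res)
        keep |= (rec["mutated_gene"] == q) & rec["target_gene"].isin(retained)
    return gi_table.subset(keep, label=label or gi_table.label)


def export_spn(spn: SPN, path, format: str = "tsv") -> None:
    """Write an SPN as ``sif``, ``tsv`` or ``graphml``.

    The TSV layout is re-importable (:func:`read_spn_tsv`): a metadata
    comment, one ``node`` line per gene with its role and FDR, and one
    ``edge`` line per edge.
    """
    if format == "sif":
        with open(path, "w") as fh:
            for u, v in spn.edges:
                fh.write(f"{u}\tinteracts\t{v}\n")
    elif format == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# spn mutated_gene={spn.mutated_gene} k={spn.k} directed={int(spn.directed)}\n")
            fh.write("record\tname\trole\tfdr\ttarget\n")
            for name in sorted(spn.sp_nodes):
                a = spn.sp_nodes[name]
                fdr = "" if a.get("fdr") is None else f"{a['fdr']:.17g}"
                fh.write(f"node\t{name}\t{a.get('direction', 'unknown')}\t{fdr}\t\n")
            for name in sorted(spn.connector_nodes):
                fh.write(f"node\t{name}\tconnector\t\t\n")
            for u, v in spn.edges:
                fh.write(f"edge\t{u}\t\t\t{v}\n")
    elif format == "graphml":
        g = nx.DiGraph() if spn.directed else nx.Graph()
        for name in sorted(spn.sp_nodes):
            a = spn.sp_nodes[name]
            attrs = {"role": a.get("direction", "unknown")}
            if a.get("fdr") is not None:
                attrs["fdr"] = float(a["fdr"])
            g.add_node(name, **attrs)
        for name in sorted(spn.connector_nodes):
            g.add_node(name, role="connector")
        g.add_edges_from(spn.edges)
        nx.write_graphml(g, path)
    else:
        raise ConfigurationError(f"unknown SPN export format {format!r}")


def read_spn_tsv(path) -> SPN:
    """Read back an SPN written by :func:`export_spn` with ``format="tsv"``."""
    mutated_gene, k, directed = "", 1, False
    sp_nodes: dict[str, dict] = {}
    connectors = set()
    edges = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("mutated_gene="):
                        mutated_gene = tok.split("=", 1)[1]
                    elif tok.startswith("k="):
                        k = int(tok.split("=", 1)[1])
                    elif tok.startswith("directed="):
                        directed = bool(int(tok.split("=", 1)[1]))
                continue
            if not line.strip() or line.startswith("record\t"):
                continue
            fields = line.split("\t")
            if fields[0] == "node":
                _, name, role, fdr, _ = fields
                if role == "connector":
                    connectors.add(name)
                else:
                    sp_nodes[name] = {"direction": role, "fdr": float(fdr) if fdr else None}
            elif fields[0] == "edge":
                edges.append((fields[1], fields[4]))
            else:
                raise FormatError(f"{path}: unknown record type {fields[0]!r}")
    return SPN(
        mutated_gene=mutated_gene,
        k=k,
        sp_nodes=sp_nodes,
        connector_nodes=frozenset(connectors),
        edges=tuple(edges),
        directed=directed,
    )
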