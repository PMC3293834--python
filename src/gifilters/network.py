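"""Canonical undirected interaction graph with alias resolution.

The :class:`GINetwork` is the substrate every filter queries: an undirected,
unweighted graph over canonical gene ids (genetic interactions carry no
sign or direction here), plus a case-insensitive alias index so that motif
source/target proteins named by any synonym resolve to graph nodes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx

from .errors import ValidationError
from .io import AliasRecord, GIEdge, canonical_id, canonical_pair

logger = logging.getLogger(__name__)


class GINetwork:
    """Undirected multi-source interaction graph with an alias index.

    Attributes
    ----------
    graph : networkx.Graph
        Nodes are canonical gene ids; edge attributes record
        ``species``, ``source_db`` and ``interaction_kind``.
    alias_index : dict[str, set[str]]
        Lowercased alias -> set of canonical ids. Every canonical id is its
        own alias; ambiguous aliases map to multiple ids.
    """

    def __init__(self) -> None:
        self.graph: nx.Graph = nx.Graph()
        self.alias_index: dict[str, set[str]] = {}

    # -- construction ---------------------------------------------------

    def add_edge(self, edge: GIEdge) -> None:
        a, b = edge.pair
        self.graph.add_edge(a, b, species=edge.species,
                            source_db=edge.source_db,
                            interaction_kind=edge.interaction_kind)
        self._register_alias(a, a)
        self._register_alias(b, b)

    def _register_alias(self, alias: str, canonical: str) -> None:
        self.alias_index.setdefault(canonical_id(alias), set()).add(
            canonical_id(canonical))

    # -- queries ---------------------------------------------------------

    def resolve_gene(self, name: str) -> set[str]:
        """All canonical gene ids whose alias set contains ``name``.

        Case-insensitive; returns the empty set for unknown names. Ambiguous
        names (more than one candidate) are resolved to the full candidate
        set — downstream filters succeed if ANY candidate interacts.
        """
        key = canonical_id(name)
        if not key:
            raise ValidationError("cannot resolve an empty gene name")
        result = set(self.alias_index.get(key, ()))
        if len(result) > 1:
            logger.info("ambiguous name %r -> %d candidates", name, len(result))
        return result

    def has_interaction(
        self, set_a: Iterable[str], set_b: Iterable[str]
    ) -> tuple[bool, list[tuple[str, str]]]:
        """Is any gene in ``set_a`` adjacent to any gene in ``set_b``?

        Returns ``(found, witness)`` where witness lists every qualifying
        canonical pair, sorted and deduplicated. Symmetric in its arguments;
        a gene paired with itself requires a self-loop edge.
        """
        sa = {canonical_id(g) for g in set_a}
        sb = {canonical_id(g) for g in set_b}
        if len(sb) < len(sa):
            sa, sb = sb, sa
        adj = self.graph.adj
        witness: set[tuple[str, str]] = set()
        for a in sa:
            if a not in adj:
                continue
            for nbr in adj[a]:
                if nbr in sb:
                    witness.add(canonical_pair(a, nbr))
        return (bool(witness), sorted(witness))

    def neighborhood(self, seed: Iterable[str], radius: int) -> set[str]:
        """The cumulative ball of graph distance <= ``radius`` around the seed.

        Seed ids are always retained, including ids absent from the graph
        (unknown genes contribute nothing but degrade gracefully rather than
        erroring). Monotone in ``radius``.
        """
        if radius < 0:
            raise ValidationError(f"radius must be >= 0, got {radius}")
        seeds = {canonical_id(g) for g in seed}
        adj = self.graph.adj
        ball = set(seeds)
        frontier = {g for g in seeds if g in adj}
        for _ in range(radius):
            new: set[str] = set()
            for g in frontier:
                new.update(adj[g])
            new -= ball
            if not new:
                break
            ball |= new
            frontier = new
        return ball

    # -- introspection ---------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, gene: str) -> bool:
        return canonical_id(gene) in self.graph

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def build_network(
    edges: Sequence[GIEdge], aliases: Sequence[AliasRecord] = ()
) -> GINetwork:
    """Assemble a :class:`GINetwork` from canonical edges and alias records.

    Alias records whose canonical id never appears as an edge endpoint are
    retained in the index (they may still resolve queries) and counted in a
    warning.
    """
    net = GINetwork()
    for edge in edges:
        net.add_edge(edge)
    n_orphan = 0
    for rec in aliases:
        canon = canonical_id(rec.canonical_id)
        if canon not in net.graph:
            n_orphan += 1
        net._register_alias(canon, canon)
        net._register_alias(rec.alias, canon)
    if n_orphan:
        logger.warning("%d alias record(s) reference genes absent from the "
                       "edge set (retained)", n_orphan)
    logger.info("network built: %d node(s), %d edge(s), %d alias key(s)",
                net.graph.number_of_nodes(), net.graph.number_of_edges(),
                len(net.alias_index))
    return net
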