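"""Homolog-cluster lookups backing the GI-HomoloGene filter.

A homolog cluster groups orthologous/paralogous genes across species under
one cluster id. The GI-HomoloGene filter extrapolates a genetic interaction
observed between homologs in one species to the query source/target pair in
another — the interolog idea applied to GI edges.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

from .io import HomologRecord, canonical_id, canonical_pair
from .network import GINetwork

logger = logging.getLogger(__name__)

#: Placeholder taxon for genes absent from the homolog map. It never
#: satisfies a same-species constraint.
UNKNOWN_TAXON = None


class HomologMap:
    """Bidirectional gene <-> homolog-cluster mapping.

    A gene belongs to at most one cluster; conflicting records keep the
    first cluster seen (with a warning). Genes absent from the map behave as
    singleton clusters of unknown taxon, so filters built on this map reduce
    to the basic direct-edge lookup for unmapped genes.
    """

    def __init__(self) -> None:
        self.gene_to_cluster: dict[str, str] = {}
        self.cluster_to_members: dict[str, set[tuple[str, str | None]]] = {}

    @classmethod
    def from_records(cls, records: Sequence[HomologRecord]) -> "HomologMap":
        hmap = cls()
        n_conflict = 0
        for rec in records:
            gene = canonical_id(rec.gene_id)
            prev = hmap.gene_to_cluster.get(gene)
            if prev is not None and prev != rec.cluster_id:
                n_conflict += 1
                continue
            hmap.gene_to_cluster[gene] = rec.cluster_id
            hmap.cluster_to_members.setdefault(rec.cluster_id, set()).add(
                (gene, rec.taxon or UNKNOWN_TAXON))
        if n_conflict:
            logger.warning("%d record(s) place a gene in a second cluster "
                           "(first membership kept)", n_conflict)
        return hmap

    def cluster_members(self, gene: str) -> set[tuple[str, str | None]]:
        """Members ``(gene id, taxon)`` of the gene's cluster, including the
        gene itself; unmapped genes yield ``{(gene, None)}``."""
        g = canonical_id(gene)
        cluster = self.gene_to_cluster.get(g)
        if cluster is None:
            return {(g, UNKNOWN_TAXON)}
        return set(self.cluster_to_members[cluster])

    def __len__(self) -> int:
        return len(self.gene_to_cluster)


def homologous_interaction(
    hmap: HomologMap,
    network: GINetwork,
    s: str,
    t: str,
    require_same_species: bool = True,
) -> tuple[bool, list[tuple[str, str]]]:
    """Does any member of s's cluster genetically interact with any member
    of t's cluster?

    With ``require_same_species`` (the default), a qualifying pair (A, B)
    must share a taxon; members of unknown taxon never satisfy the
    constraint. The interacting pair may be (s, t) themselves — on
    taxon-annotated data this makes the lookup a superset of the basic
    direct-edge check. Returns ``(found, witness pairs)``.
    """
    members_s = hmap.cluster_members(s)
    members_t = hmap.cluster_members(t)
    adj = network.graph.adj
    witness: set[tuple[str, str]] = set()
    for a, taxon_a in members_s:
        if a not in adj:
            continue
        nbrs = adj[a]
        for b, taxon_b in members_t:
            if b not in nbrs:
                continue
            if require_same_species and (
                taxon_a is UNKNOWN_TAXON or taxon_b is UNKNOWN_TAXON
                or taxon_a != taxon_b
            ):
                continue
            witness.add(canonical_pair(a, b))
    return (bool(witness), sorted(witness))
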