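"""The genetic-interaction filters and their composition.

Three GI filters reduce false-positive minimotif predictions by requiring
interaction evidence between a motif's source gene S and target gene T:

- **basic GI filter** — a direct GI edge between (any alias of) S and T;
- **GI-node filter** — iterative neighborhood expansion: at iteration
  ``i`` the radius-``i`` balls around S and T are checked for a joining
  edge, up to a node count N (equivalently, pass iff the shortest GI path
  between S and T is at most ``2N + 1``);
- **GI-HomoloGene filter** — a GI edge between homolog-cluster members of
  S and T, optionally constrained to a single species.

The same direct-edge lookup applied to a physical-interaction network is
the PPI filter (:func:`generic_network_filter`). Filters compose by union
("either-or") or intersection, and each can be run with exclude polarity
to examine the motifs *without* known interactions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, ValidationError
from .homology import HomologMap, homologous_interaction
from .io import MotifPrediction, canonical_id
from .network import GINetwork

logger = logging.getLogger(__name__)

#: Node counts above this produced very poor selectivity in practice; the
#: filter warns rather than refusing.
NODE_COUNT_WARN_ABOVE = 4

#: Default node count for the GI-node filter.
DEFAULT_NODE_COUNT = 2

FILTER_KINDS = ("gi", "gi_node", "gi_homologene", "network_generic",
                "external_flag")


@dataclass(frozen=True)
class FilterDecision:
    """Pass/fail verdict of one filter on one motif, with the witness
    edge(s) that justified a pass and a note explaining edge cases."""

    motif_id: str
    filter_name: str
    passed: bool
    witness: tuple[tuple[str, str], ...] = ()
    note: str = ""


@dataclass(frozen=True)
class FilterSpec:
    """Declarative description of one filter in a pipeline."""

    name: str
    kind: str
    node_count: int = DEFAULT_NODE_COUNT
    require_same_species: bool = True
    polarity: str = "include"

    def __post_init__(self) -> None:
        if self.kind not in FILTER_KINDS:
            raise ValidationError(f"unknown filter kind {self.kind!r}")
        if self.polarity not in ("include", "exclude"):
            raise ValidationError(f"polarity must be include/exclude, got "
                                  f"{self.polarity!r}")
        if self.kind == "gi_node" and self.node_count < 1:
            raise ValidationError("node_count must be >= 1")


def _resolve_endpoints(motif: MotifPrediction, network: GINetwork):
    """Resolve S and T; a failed resolution yields the fail note."""
    s_set = network.resolve_gene(motif.source_protein)
    t_set = network.resolve_gene(motif.target_protein)
    notes = []
    if not s_set:
        notes.append("source unresolved")
    if not t_set:
        notes.append("target unresolved")
    return s_set, t_set, "; ".join(notes)


def basic_gi_filter(
    motif: MotifPrediction, network: GINetwork, filter_name: str = "gi"
) -> FilterDecision:
    """Retain the motif iff a direct interaction joins its resolved source
    and target gene sets. Unresolvable endpoints fail (with a note) rather
    than erroring; a motif whose source equals its target passes only if a
    self-loop edge exists."""
    s_set, t_set, note = _resolve_endpoints(motif, network)
    if note:
        return FilterDecision(motif.motif_id, filter_name, False, (), note)
    passed, witness = network.has_interaction(s_set, t_set)
    return FilterDecision(motif.motif_id, filter_name, passed, tuple(witness))


def gi_node_filter(
    motif: MotifPrediction,
    network: GINetwork,
    node_count: int = DEFAULT_NODE_COUNT,
    filter_name: str = "gi_node",
) -> FilterDecision:
    """Neighborhood-expansion filter.

    For i = 1..node_count, grow the cumulative radius-``i`` balls around the
    resolved source and target sets and pass at the first ``i`` where an
    edge joins the two balls (witness taken from that iteration). Fails if
    no iteration finds a join.
    """
    if node_count < 1:
        raise ValidationError(f"node_count must be >= 1, got {node_count}")
    if node_count > NODE_COUNT_WARN_ABOVE:
        logger.warning("node_count=%d: expansions beyond %d give very poor "
                       "selectivity", node_count, NODE_COUNT_WARN_ABOVE)
    s_set, t_set, note = _resolve_endpoints(motif, network)
    if note:
        return FilterDecision(motif.motif_id, filter_name, False, (), note)
    for i in range(1, node_count + 1):
        ball_s = network.neighborhood(s_set, i)
        ball_t = network.neighborhood(t_set, i)
        passed, witness = network.has_interaction(ball_s, ball_t)
        if passed:
            return FilterDecision(motif.motif_id, filter_name, True,
                                  tuple(witness), f"iteration {i}")
    return FilterDecision(motif.motif_id, filter_name, False, ())


def gi_homologene_filter(
    motif: MotifPrediction,
    network: GINetwork,
    hmap: HomologMap,
    require_same_species: bool = True,
    filter_name: str = "gi_homologene",
) -> FilterDecision:
    """Ortholog-cluster extrapolation filter.

    The motif passes if any homolog of (any resolved candidate of) its
    source interacts with any homolog of its target, subject to the
    same-species constraint when requested. An endpoint absent from the GI
    sources falls back to its own canonical name: its homolog cluster can
    still carry the interaction.
    """
    s_set, t_set, _ = _resolve_endpoints(motif, network)
    s_set = s_set or {canonical_id(motif.source_protein)}
    t_set = t_set or {canonical_id(motif.target_protein)}
    witness: set[tuple[str, str]] = set()
    for s in s_set:
        for t in t_set:
            found, pairs = homologous_interaction(
                hmap, network, s, t, require_same_species=require_same_species)
            if found:
                witness.update(pairs)
    return FilterDecision(motif.motif_id, filter_name, bool(witness),
                          tuple(sorted(witness)))


def generic_network_filter(
    motif: MotifPrediction, network: GINetwork, filter_name: str = "ppi"
) -> FilterDecision:
    """Direct-edge lookup against an arbitrary interaction network —
    typically a physical (protein-protein) interaction network. Identical
    contract to :func:`basic_gi_filter`; only the name differs."""
    return basic_gi_filter(motif, network, filter_name=filter_name)


def combine_decisions(
    decisions: Sequence[FilterDecision], mode: str
) -> FilterDecision:
    """Combine per-motif decisions by ``"union"`` (either-or: pass iff any
    constituent passes) or ``"intersection"`` (pass iff all pass). The
    combined witness is the union of constituent witnesses; the combined
    name joins constituent names with ``|`` or ``&``."""
    if not decisions:
        raise ValidationError("cannot combine an empty decision list")
    motif_ids = {d.motif_id for d in decisions}
    if len(motif_ids) != 1:
        raise ValidationError(f"decisions reference multiple motifs: "
                              f"{sorted(motif_ids)}")
    if mode == "union":
        passed = any(d.passed for d in decisions)
        joiner = "|"
    elif mode == "intersection":
        passed = all(d.passed for d in decisions)
        joiner = "&"
    else:
        raise ValidationError(f"mode must be union/intersection, got {mode!r}")
    witness: set[tuple[str, str]] = set()
    if passed:
        for d in decisions:
            if d.passed:
                witness.update(d.witness)
    return FilterDecision(
        next(iter(motif_ids)),
        joiner.join(d.filter_name for d in decisions),
        passed,
        tuple(sorted(witness)),
    )


def _run_spec(
    motif: MotifPrediction,
    spec: FilterSpec,
    gi_network: GINetwork | None,
    ppi_network: GINetwork | None,
    hmap: HomologMap | None,
) -> FilterDecision:
    if spec.kind == "gi":
        return basic_gi_filter(motif, gi_network, filter_name=spec.name)
    if spec.kind == "gi_node":
        return gi_node_filter(motif, gi_network, node_count=spec.node_count,
                              filter_name=spec.name)
    if spec.kind == "gi_homologene":
        return gi_homologene_filter(
            motif, gi_network, hmap,
            require_same_species=spec.require_same_species,
            filter_name=spec.name)
    if spec.kind == "network_generic":
        return generic_network_filter(motif, ppi_network,
                                      filter_name=spec.name)
    # external_flag: spec.name keys into the precomputed flag map
    if spec.name in motif.external_flags:
        return FilterDecision(motif.motif_id, spec.name,
                              bool(motif.external_flags[spec.name]),
                              (), "external flag")
    return FilterDecision(motif.motif_id, spec.name, False, (),
                          f"flag {spec.name!r} absent")


def apply_filters(
    predictions: Sequence[MotifPrediction],
    specs: Sequence[FilterSpec],
    gi_network: GINetwork | None = None,
    ppi_network: GINetwork | None = None,
    hmap: HomologMap | None = None,
) -> list[FilterDecision]:
    """Run every filter spec over every prediction.

    Resource requirements are validated up front (a spec referencing a
    missing network/map raises :class:`ConfigurationError` before any
    filtering). Exclude polarity negates the verdict; the suppressed
    witness moves into the note so the report stays auditable.
    """
    for spec in specs:
        if spec.kind in ("gi", "gi_node", "gi_homologene") and gi_network is None:
            raise ConfigurationError(f"filter {spec.name!r} needs a GI network")
        if spec.kind == "gi_homologene" and hmap is None:
            raise ConfigurationError(f"filter {spec.name!r} needs a homolog map")
        if spec.kind == "network_generic" and ppi_network is None:
            raise ConfigurationError(f"filter {spec.name!r} needs a physical "
                                     f"interaction network")
    decisions: list[FilterDecision] = []
    for motif in predictions:
        for spec in specs:
            d = _run_spec(motif, spec, gi_network, ppi_network, hmap)
            if spec.polarity == "exclude":
                note = d.note
                if d.witness:
                    rendered = ";".join(f"{a}--{b}" for a, b in d.witness)
                    note = (note + "; " if note else "") + f"excluded witness: {rendered}"
                d = FilterDecision(d.motif_id, d.filter_name, not d.passed,
                                   (), note)
            decisions.append(d)
    for spec in specs:
        n_pass = sum(1 for d in decisions if d.filter_name == spec.name and d.passed)
        logger.info("filter %s: %d/%d passed", spec.name, n_pass, len(predictions))
    return decisions
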