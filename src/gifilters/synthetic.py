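"""Synthetic worlds with planted statistical structure.

A *world* bundles everything the filters and the evaluation harness consume
— a GI edge list, a PPI edge list, an alias table, a homolog-cluster file,
a table of positive (validated-style) minimotif predictions, and a set of
random-pair negatives — generated from a handful of planted rates:

- ``p_pos_gi_edge``: probability a true motif's (S, T) pair has a GI edge
  (default 0.212 — roughly one in five validated motif pairs has a known
  genetic interaction);
- ``p_neg_gi_edge``: probability a random gene pair collides with a GI edge
  (default 0.029);
- ``gi_conservation_rate``: probability a planted GI edge is replicated
  between the homologs of its endpoints in another species (default 0.29,
  the ballpark conservation of genetic interactions between closely
  related yeasts);
- ``p_ppi_given_gi`` / ``p_ppi_no_gi``: physical-interaction co-occurrence,
  chosen so that genetic and physical evidence overlap heavily but each
  retains motifs the other misses.

Because these rates are planted independently pair-by-pair, the basic
filter's sensitivity and selectivity on a generated world are binomial
around the configured rates — which is exactly what the evaluation harness
is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .evaluation import LabeledPair, possible_pair_count
from .io import AliasRecord, GIEdge, HomologRecord, MotifPrediction

#: Per-activity GI rates observed among validated motifs: about 56% of
#: posttranslational-modification motifs have a known GI versus about 19%
#: of binding motifs. Trafficking motifs are rare and binding-like; they
#: share the binding rate. Pass as ``per_activity_gi_rates`` to generate
#: activity-stratified worlds.
DEFAULT_ACTIVITY_GI_RATES = {"modifies": 0.56, "binds": 0.19, "traffics": 0.19}

_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass
class WorldConfig:
    """Parameters of a synthetic world. All probabilities are in [0, 1]."""

    n_genes: int = 1500
    n_species: int = 3
    background_edge_prob: float = 0.0
    n_positive_motifs: int = 3000
    p_pos_gi_edge: float = 0.212
    p_neg_gi_edge: float = 0.029
    n_negative_pairs: int = 27000
    homolog_cluster_rate: float = 0.5
    gi_conservation_rate: float = 0.29
    p_ppi_given_gi: float = 0.885
    p_ppi_no_gi: float = 0.13
    per_activity_gi_rates: dict[str, float] | None = None
    activity_proportions: dict[str, float] = field(
        default_factory=lambda: {"binds": 0.60, "modifies": 0.35,
                                 "traffics": 0.05})
    alias_rate: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 2 or self.n_species < 1:
            raise ValidationError("need n_genes >= 2 and n_species >= 1")
        if self.n_genes < 2 * self.n_species:
            raise ValidationError("need at least 2 genes per species")
        probs = {
            "background_edge_prob": self.background_edge_prob,
            "p_pos_gi_edge": self.p_pos_gi_edge,
            "p_neg_gi_edge": self.p_neg_gi_edge,
            "homolog_cluster_rate": self.homolog_cluster_rate,
            "gi_conservation_rate": self.gi_conservation_rate,
            "p_ppi_given_gi": self.p_ppi_given_gi,
            "p_ppi_no_gi": self.p_ppi_no_gi,
            "alias_rate": self.alias_rate,
            **{f"per_activity[{k}]": v
               for k, v in (self.per_activity_gi_rates or {}).items()},
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if self.n_positive_motifs < 0 or self.n_negative_pairs < 0:
            raise ValidationError("counts must be non-negative")
        if not self.activity_proportions or any(
                v < 0 for v in self.activity_proportions.values()):
            raise ValidationError("activity_proportions must be non-negative "
                                  "and non-empty")
        total_pairs = sum(possible_pair_count(n)
                          for n in self._genes_per_species())
        if self.n_positive_motifs + self.n_negative_pairs > total_pairs:
            raise ValidationError(
                f"{self.n_positive_motifs} motifs + {self.n_negative_pairs} "
                f"negatives exceed the {total_pairs} distinct same-species "
                f"pairs available")

    def _genes_per_species(self) -> list[int]:
        base, extra = divmod(self.n_genes, self.n_species)
        return [base + (1 if s < extra else 0) for s in range(self.n_species)]


@dataclass
class SyntheticWorld:
    """A fully materialized synthetic test bed plus its ground truth.

    ``ground_truth`` records every planting decision: per positive motif
    whether a GI edge / PPI edge was planted and how many conserved
    homolog copies were made; per negative pair whether it collided with a
    planted GI edge.
    """

    config: WorldConfig
    gi_edges: list[GIEdge]
    ppi_edges: list[GIEdge]
    alias_records: list[AliasRecord]
    homolog_records: list[HomologRecord]
    positive_motifs: list[MotifPrediction]
    negative_pairs: list[LabeledPair]
    ground_truth: dict

    @property
    def genes(self) -> list[str]:
        seen, out = set(), []
        for s, members in self.ground_truth["species_genes"].items():
            for g in members:
                if g not in seen:
                    seen.add(g)
                    out.append(g)
        return out


def _sample_distinct_pairs(rng, species_genes, n_total, forbidden):
    """Uniform distinct same-species (source, target) pairs, source != target.

    Species are chosen with probability proportional to their pair counts so
    the draw is uniform over all eligible same-species pairs.
    """
    weights = np.array([possible_pair_count(len(g)) for g in species_genes],
                       dtype=float)
    weights /= weights.sum()
    chosen: list[tuple[int, str, str]] = []
    taken: set[frozenset] = set(forbidden)
    while len(chosen) < n_total:
        s = int(rng.choice(len(species_genes), p=weights))
        genes = species_genes[s]
        i, j = rng.integers(0, len(genes), size=2)
        if i == j:
            continue
        key = frozenset((genes[i], genes[j]))
        if key in taken:
            continue
        taken.add(key)
        chosen.append((s, genes[i], genes[j]))
    return chosen


def simulate_world(config: WorldConfig) -> SyntheticWorld:
    """Generate a world from planted rates; reproducible from ``config.seed``.

    Genes are partitioned across species; positive motifs and negative
    pairs are distinct uniform same-species pairs (so the planted GI rates
    translate directly into filter pass rates); background edges follow an
    Erdős–Rényi model within each species; homolog clusters span species
    (every gene gets a cluster — singleton when not cross-clustered — so
    the homolog map is taxon-complete); planted positive edges are copied
    to homologous pairs in other species with the conservation rate.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    per_species = config._genes_per_species()
    species = [f"sp{s}" for s in range(config.n_species)]
    species_genes = [[f"g{s}_{i}" for i in range(per_species[s])]
                     for s in range(config.n_species)]
    gene_species = {g: species[s]
                    for s in range(config.n_species)
                    for g in species_genes[s]}
    # gene index within its species, for homolog pairing across species
    gene_rank = {g: i for members in species_genes
                 for i, g in enumerate(members)}

    # --- homolog clusters (taxon-complete) -----------------------------
    max_rank = max(per_species)
    cross_cluster = rng.random(max_rank) < config.homolog_cluster_rate
    homolog_records: list[HomologRecord] = []
    in_cross: set[str] = set()
    for i in range(max_rank):
        members = [species_genes[s][i] for s in range(config.n_species)
                   if i < per_species[s]]
        if cross_cluster[i] and len(members) > 1:
            for g in members:
                homolog_records.append(
                    HomologRecord(f"HG{i}", gene_species[g], g, g.upper()))
                in_cross.add(g)
        else:
            for g in members:
                homolog_records.append(
                    HomologRecord(f"HG_{g}", gene_species[g], g, g.upper()))

    # --- positive motifs and negative pairs (distinct pairs) -----------
    pairs = _sample_distinct_pairs(
        rng, species_genes, config.n_positive_motifs + config.n_negative_pairs,
        forbidden=())
    pos_pairs = pairs[:config.n_positive_motifs]
    neg_pairs = pairs[config.n_positive_motifs:]

    act_labels = sorted(config.activity_proportions)
    act_p = np.array([config.activity_proportions[a] for a in act_labels],
                     dtype=float)
    act_p /= act_p.sum()

    gi_edges: dict[tuple[str, str], GIEdge] = {}

    def plant_gi(a: str, b: str, source_db: str) -> None:
        edge = GIEdge(a, b, species=gene_species[a], source_db=source_db)
        gi_edges.setdefault(edge.pair, edge)

    positive_motifs: list[MotifPrediction] = []
    ppi_edges: dict[tuple[str, str], GIEdge] = {}
    truth_pos: dict[str, dict] = {}
    for k, (s_idx, src, tgt) in enumerate(pos_pairs):
        activity = act_labels[int(rng.choice(len(act_labels), p=act_p))]
        rate = config.p_pos_gi_edge
        if config.per_activity_gi_rates is not None:
            rate = config.per_activity_gi_rates.get(activity, rate)
        planted_gi = bool(rng.random() < rate)
        if planted_gi:
            plant_gi(src, tgt, "synthetic")
        p_ppi = config.p_ppi_given_gi if planted_gi else config.p_ppi_no_gi
        planted_ppi = bool(rng.random() < p_ppi)
        if planted_ppi:
            edge = GIEdge(src, tgt, species=species[s_idx],
                          source_db="synthetic", interaction_kind="physical")
            ppi_edges.setdefault(edge.pair, edge)
        # conserved copies in other species, where both endpoints have
        # cross-species homologs
        n_conserved = n_conservable = 0
        if planted_gi and src in in_cross and tgt in in_cross:
            ri, rj = gene_rank[src], gene_rank[tgt]
            for s2 in range(config.n_species):
                if s2 == s_idx:
                    continue
                if ri < per_species[s2] and rj < per_species[s2]:
                    n_conservable += 1
                    if rng.random() < config.gi_conservation_rate:
                        plant_gi(species_genes[s2][ri], species_genes[s2][rj],
                                 "synthetic_conserved")
                        n_conserved += 1
        motif_id = f"pos{k:05d}"
        seq = "".join(rng.choice(_AA, size=8))
        positive_motifs.append(MotifPrediction(
            motif_id=motif_id, source_protein=src, target_protein=tgt,
            sequence=seq, activity=activity,
            sub_activity=f"{activity}_generic"))
        truth_pos[motif_id] = {
            "source": src, "target": tgt, "species": species[s_idx],
            "activity": activity, "gi": planted_gi, "ppi": planted_ppi,
            "conserved_copies": n_conserved,
            "conservation_opportunities": n_conservable,
        }

    negative_pairs: list[LabeledPair] = []
    truth_neg: list[dict] = []
    for s_idx, a, b in neg_pairs:
        activity = act_labels[int(rng.choice(len(act_labels), p=act_p))]
        collided = bool(rng.random() < config.p_neg_gi_edge)
        if collided:
            plant_gi(a, b, "synthetic_collision")
        negative_pairs.append(LabeledPair(a, b, "negative", activity=activity,
                                          sub_activity=f"{activity}_generic"))
        truth_neg.append({"source": a, "target": b, "gi": collided})

    # --- background Erdős–Rényi edges within each species --------------
    if config.background_edge_prob > 0:
        for s in range(config.n_species):
            genes = species_genes[s]
            n_pairs = possible_pair_count(len(genes))
            k = int(rng.binomial(n_pairs, config.background_edge_prob))
            added = 0
            while added < k:
                i, j = rng.integers(0, len(genes), size=2)
                if i == j:
                    continue
                edge = GIEdge(genes[i], genes[j], species=species[s],
                              source_db="synthetic_background")
                if edge.pair in gi_edges:
                    continue
                gi_edges[edge.pair] = edge
                added += 1

    # --- aliases --------------------------------------------------------
    alias_records: list[AliasRecord] = []
    for members in species_genes:
        for g in members:
            if rng.random() < config.alias_rate:
                alias_records.append(
                    AliasRecord(g, f"alt-{g.upper()}", gene_species[g]))

    ground_truth = {
        "positives": truth_pos,
        "negatives": truth_neg,
        "species_genes": {species[s]: list(species_genes[s])
                          for s in range(config.n_species)},
        "cross_cluster_genes": sorted(in_cross),
    }
    return SyntheticWorld(
        config=config,
        gi_edges=[gi_edges[p] for p in sorted(gi_edges)],
        ppi_edges=[ppi_edges[p] for p in sorted(ppi_edges)],
        alias_records=alias_records,
        homolog_records=homolog_records,
        positive_motifs=positive_motifs,
        negative_pairs=negative_pairs,
        ground_truth=ground_truth,
    )


#: Conventional file names inside a world directory.
WORLD_FILES = {
    "gi_edges": "gi_edges.tsv",
    "ppi_edges": "ppi_edges.tsv",
    "aliases": "aliases.tsv",
    "homologene": "homologene.tsv",
    "predictions": "predictions.tsv",
    "negatives": "negative_pairs.tsv",
}


def world_to_files(world: SyntheticWorld, directory: str | Path) -> dict[str, Path]:
    """Write every world component in its on-disk format.

    Output is deterministic: two worlds generated from the same config
    produce byte-identical directories. Reading the files back through the
    format readers reproduces the in-memory world.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {key: directory / name for key, name in WORLD_FILES.items()}

    with paths["gi_edges"].open("w") as fh:
        fh.write("# gene_a\tgene_b\tspecies\tkind\n")
        for e in world.gi_edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.species}\t{e.interaction_kind}\n")
    with paths["ppi_edges"].open("w") as fh:
        fh.write("# gene_a\tgene_b\tspecies\tkind\n")
        for e in world.ppi_edges:
            fh.write(f"{e.gene_a}\t{e.gene_b}\t{e.species}\t{e.interaction_kind}\n")
    with paths["aliases"].open("w") as fh:
        for r in world.alias_records:
            fh.write(f"{r.canonical_id}\t{r.alias}\t{r.species}\n")
    with paths["homologene"].open("w") as fh:
        for r in world.homolog_records:
            fh.write(f"{r.cluster_id}\t{r.taxon}\t{r.gene_id}\t{r.symbol}\n")
    with paths["predictions"].open("w") as fh:
        fh.write("motif_id\tsequence\tsource_protein\ttarget_protein\t"
                 "activity\tsub_activity\n")
        for m in world.positive_motifs:
            fh.write(f"{m.motif_id}\t{m.sequence}\t{m.source_protein}\t"
                     f"{m.target_protein}\t{m.activity}\t{m.sub_activity}\n")
    with paths["negatives"].open("w") as fh:
        fh.write("source\ttarget\tlabel\tactivity\tsub_activity\n")
        for p in world.negative_pairs:
            fh.write(f"{p.source}\t{p.target}\t{p.label}\t{p.activity}\t"
                     f"{p.sub_activity}\n")
    return paths
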