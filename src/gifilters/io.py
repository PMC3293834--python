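"""Readers and writers for the toolkit's tab-separated formats.

Heterogeneous genetic-interaction (GI) sources are normalized into a single
canonical edge representation (:class:`GIEdge`): identifiers are trimmed and
lowercased, and the gene pair is stored in lexicographic order so that
``(a, b)`` and ``(b, a)`` denote the same undirected edge.

Supported formats
-----------------
- generic edge list: TSV ``gene_a, gene_b[, species[, kind]]``; ``#`` lines
  are comments.
- BioGRID TAB-style: header-bearing TSV; only the official-symbol interactor
  columns and the experimental-system-type column are consulted.
- HomoloGene-style flat file: headerless TSV
  ``(cluster_id, taxon_id, gene_id, gene_symbol, ...)``.
- minimotif prediction table: header-bearing TSV (see
  :func:`read_minimotif_table`).
- alias table: TSV ``canonical_id, alias[, species]``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

#: Closed activity vocabulary for minimotif predictions.
ACTIVITIES = frozenset({"binds", "modifies", "traffics"})

#: BioGRID TAB column names this reader consults.
BIOGRID_SYMBOL_A = "Official Symbol Interactor A"
BIOGRID_SYMBOL_B = "Official Symbol Interactor B"
BIOGRID_SYSTEM_TYPE = "Experimental System Type"

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def canonical_id(name: str) -> str:
    """Trim and lowercase an identifier (all comparisons are case-insensitive)."""
    return str(name).strip().lower()


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Lexicographically ordered canonical gene pair."""
    a, b = canonical_id(a), canonical_id(b)
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GIEdge:
    """One undirected interaction edge between two canonical gene ids.

    ``interaction_kind`` is ``"genetic"`` for GI edges and ``"physical"`` for
    protein-protein interaction (PPI) edges; both flow through the same
    machinery and differ only in which filter consumes them.
    """

    gene_a: str
    gene_b: str
    species: str = ""
    source_db: str = ""
    interaction_kind: str = "genetic"

    def __post_init__(self) -> None:
        a, b = canonical_id(self.gene_a), canonical_id(self.gene_b)
        if not a or not b:
            raise ValidationError("GIEdge endpoints must be non-empty")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        object.__setattr__(self, "species", str(self.species).strip())

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    @property
    def is_self_loop(self) -> bool:
        return self.gene_a == self.gene_b


@dataclass
class MotifPrediction:
    """One putative minimotif: source protein S carries the motif, target
    protein T engages it. ``external_flags`` holds precomputed verdicts of
    filters whose internals live elsewhere (e.g. frequency score)."""

    motif_id: str
    source_protein: str
    target_protein: str
    sequence: str = ""
    activity: str = "binds"
    sub_activity: str = ""
    external_flags: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not str(self.source_protein).strip():
            raise ValidationError(f"motif {self.motif_id!r}: empty source_protein")
        if not str(self.target_protein).strip():
            raise ValidationError(f"motif {self.motif_id!r}: empty target_protein")
        if self.activity not in ACTIVITIES:
            raise ValidationError(
                f"motif {self.motif_id!r}: activity {self.activity!r} not in "
                f"{sorted(ACTIVITIES)}"
            )


@dataclass(frozen=True)
class AliasRecord:
    """One (canonical id, alias) pairing; lookups are case-insensitive."""

    canonical_id: str
    alias: str
    species: str = ""


@dataclass(frozen=True)
class HomologRecord:
    """One gene's membership in a homolog cluster."""

    cluster_id: str
    taxon: str
    gene_id: str
    symbol: str = ""


def _require_file(path: str | Path) -> Path:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"no such file: {p}")
    return p


def read_edge_list(
    path: str | Path,
    dialect: str = "generic",
    kind: str | None = None,
) -> list[GIEdge]:
    """Read an interaction edge list and normalize it to canonical edges.

    Parameters
    ----------
    path : file path
    dialect : ``"generic"`` or ``"biogrid_tab"``
    kind : optionally keep only edges of one interaction kind
        (``"genetic"`` or ``"physical"``).

    Duplicate edges (including reversed duplicates) are collapsed, keeping
    the first occurrence's metadata. Rows with a blank interactor are skipped
    and counted in a warning; self-loops are retained but logged.
    """
    p = _require_file(path)
    if dialect == "generic":
        raw = _read_generic_rows(p)
    elif dialect == "biogrid_tab":
        raw = _read_biogrid_rows(p)
    else:
        raise ValidationError(f"unknown edge-list dialect: {dialect!r}")

    edges: list[GIEdge] = []
    seen: set[tuple[str, str, str]] = set()
    n_blank = n_self = 0
    for gene_a, gene_b, species, edge_kind, source_db in raw:
        if not gene_a.strip() or not gene_b.strip():
            n_blank += 1
            continue
        edge = GIEdge(gene_a, gene_b, species=species, source_db=source_db,
                      interaction_kind=edge_kind)
        if kind is not None and edge.interaction_kind != kind:
            continue
        key = (*edge.pair, edge.interaction_kind)
        if key in seen:
            continue
        seen.add(key)
        if edge.is_self_loop:
            n_self += 1
        edges.append(edge)
    if n_blank:
        logger.warning("%s: skipped %d row(s) with blank interactors", p, n_blank)
    if n_self:
        logger.info("%s: retained %d self-loop edge(s)", p, n_self)
    logger.info("%s: %d edge(s) read (dialect=%s)", p, len(edges), dialect)
    return edges


def _read_generic_rows(p: Path):
    rows = []
    with p.open(newline="") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{p}: generic edge list needs >=2 columns, "
                                  f"got {len(cols)}: {line!r}")
            species = cols[2].strip() if len(cols) > 2 else ""
            edge_kind = cols[3].strip().lower() if len(cols) > 3 and cols[3].strip() else "genetic"
            rows.append((cols[0], cols[1], species, edge_kind, "generic"))
    return rows


def _read_biogrid_rows(p: Path):
    df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    for col in (BIOGRID_SYMBOL_A, BIOGRID_SYMBOL_B, BIOGRID_SYSTEM_TYPE):
        if col not in df.columns:
            raise FormatError(f"{p}: biogrid_tab file lacks required column {col!r}")
    species_col = "Organism Interactor A" if "Organism Interactor A" in df.columns else None
    rows = []
    for rec in df.to_dict("records"):
        species = rec[species_col] if species_col else ""
        rows.append((rec[BIOGRID_SYMBOL_A], rec[BIOGRID_SYMBOL_B], species,
                     str(rec[BIOGRID_SYSTEM_TYPE]).strip().lower(), "biogrid"))
    return rows


def read_minimotif_table(path: str | Path) -> list[MotifPrediction]:
    """Read a minimotif prediction table.

    Required columns: ``source_protein``, ``target_protein``. Optional:
    ``motif_id``, ``sequence``, ``activity``, ``sub_activity``, plus any
    number of boolean columns prefixed ``flag_`` which land in
    ``external_flags`` with the prefix stripped. A missing/blank activity
    defaults to ``"binds"`` with a warning; activity tokens outside the
    closed vocabulary abort with a :class:`ValidationError` naming the rows.
    """
    p = _require_file(path)
    df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    for col in ("source_protein", "target_protein"):
        if col not in df.columns:
            raise FormatError(f"{p}: minimotif table lacks required column {col!r}")
    flag_cols = [c for c in df.columns if c.startswith("flag_")]

    bad_rows: list[tuple[int, str]] = []
    n_defaulted = 0
    preds: list[MotifPrediction] = []
    for i, rec in enumerate(df.to_dict("records")):
        activity = rec.get("activity", "").strip().lower()
        if not activity:
            activity = "binds"
            n_defaulted += 1
        if activity not in ACTIVITIES:
            bad_rows.append((i + 2, activity))  # +2: header line + 1-based
            continue
        flags = {}
        for c in flag_cols:
            v = rec[c].strip().lower()
            if v in _TRUTHY:
                flags[c[len("flag_"):]] = True
            elif v in _FALSY:
                flags[c[len("flag_"):]] = False
            else:
                raise FormatError(f"{p}: row {i + 2}: flag column {c!r} has "
                                  f"non-boolean value {rec[c]!r}")
        preds.append(MotifPrediction(
            motif_id=rec.get("motif_id", "").strip() or f"row{i + 1}",
            sequence=rec.get("sequence", "").strip(),
            source_protein=rec["source_protein"],
            target_protein=rec["target_protein"],
            activity=activity,
            sub_activity=rec.get("sub_activity", "").strip(),
            external_flags=flags,
        ))
    if bad_rows:
        detail = "; ".join(f"line {ln}: {tok!r}" for ln, tok in bad_rows)
        raise ValidationError(
            f"{p}: {len(bad_rows)} row(s) with unrecognized activity ({detail})")
    if n_defaulted:
        logger.warning("%s: %d row(s) missing activity, defaulted to 'binds'",
                       p, n_defaulted)
    return preds


def read_alias_table(path: str | Path) -> list[AliasRecord]:
    """Read a TSV alias table ``(canonical_id, alias[, species])``.

    Rows whose alias equals the canonical id (case-insensitively) are
    dropped: the identity alias is implicit.
    """
    p = _require_file(path)
    records: list[AliasRecord] = []
    with p.open(newline="") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise FormatError(f"{p}: alias table needs >=2 columns: {line!r}")
            canon, alias = canonical_id(cols[0]), cols[1].strip()
            if not canon or not alias:
                continue
            if canonical_id(alias) == canon:
                continue
            species = cols[2].strip() if len(cols) > 2 else ""
            records.append(AliasRecord(canon, alias, species))
    return records


def read_homologene(path: str | Path) -> list[HomologRecord]:
    """Read a HomoloGene-style headerless flat file.

    Columns: ``cluster_id, taxon_id, gene_id, gene_symbol`` (extra columns
    ignored). Duplicate ``(cluster_id, gene_id)`` pairs are collapsed.
    """
    p = _require_file(path)
    records: list[HomologRecord] = []
    seen: set[tuple[str, str]] = set()
    with p.open(newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(
                    f"{p}: row {lineno}: homolog file needs >=4 columns, got {len(cols)}")
            cluster, taxon = cols[0].strip(), cols[1].strip()
            gene = canonical_id(cols[2])
            key = (cluster, gene)
            if key in seen:
                continue
            seen.add(key)
            records.append(HomologRecord(cluster, taxon, gene, cols[3].strip()))
    return records


def read_labeled_pairs(path: str | Path) -> list:
    """Read a labeled pair table (TSV with header): required columns
    ``source``, ``target``; optional ``label`` (default ``negative``),
    ``activity``, ``sub_activity``. Used for negative sets on disk."""
    from .evaluation import LabeledPair  # local import: avoid a cycle

    p = _require_file(path)
    df = pd.read_csv(p, sep="\t", dtype=str, keep_default_na=False)
    for col in ("source", "target"):
        if col not in df.columns:
            raise FormatError(f"{p}: labeled pair table lacks column {col!r}")
    pairs = []
    for rec in df.to_dict("records"):
        pairs.append(LabeledPair(
            canonical_id(rec["source"]), canonical_id(rec["target"]),
            rec.get("label", "").strip() or "negative",
            activity=rec.get("activity", "").strip() or None,
            sub_activity=rec.get("sub_activity", "").strip() or None,
        ))
    return pairs


def write_filter_report(decisions: Sequence, path: str | Path) -> None:
    """Write filter decisions as a TSV: one row per motif, per filter a
    ``<name>_passed`` boolean column and a ``<name>_witness`` column with
    supporting edges rendered ``geneA--geneB;...``.

    All motifs must have been run through the same set of filters.
    """
    by_motif: dict[str, dict[str, object]] = {}
    filter_names: list[str] = []
    for d in decisions:
        if d.filter_name not in filter_names:
            filter_names.append(d.filter_name)
        by_motif.setdefault(d.motif_id, {})[d.filter_name] = d
    for motif_id, row in by_motif.items():
        missing = set(filter_names) - set(row)
        if missing:
            raise ValidationError(
                f"motif {motif_id!r} lacks decisions for filter(s) {sorted(missing)}")

    header = ["motif_id"]
    for name in filter_names:
        header += [f"{name}_passed", f"{name}_witness"]
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for motif_id in by_motif:
            row: list[str] = [motif_id]
            for name in filter_names:
                d = by_motif[motif_id][name]
                row.append("true" if d.passed else "false")
                row.append(";".join(f"{a}--{b}" for a, b in d.witness))
            writer.writerow(row)
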