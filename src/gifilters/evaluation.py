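"""Evaluation harness: negative sets, sensitivity/selectivity, ROC/AUC.

Metric conventions (deliberately nonstandard, and worth reading twice):

- **sensitivity** — percentage of true-positive motifs *retained* by a
  filter (the usual recall, times 100).
- **selectivity** — percentage of true negatives *accepted* by the filter.
  This is a false-positive rate, NOT specificity: lower is better.
- **discrimination ratio (DR)** — sensitivity / selectivity; values above 1
  are favorable, and higher is better.

Because true-negative minimotifs cannot be observed directly, negatives are
random source/target gene pairs: among all possible pairs the known
interactions are a negligible fraction, so a random pair is almost surely a
non-interaction.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ValidationError
from .homology import HomologMap
from .io import MotifPrediction, canonical_id, canonical_pair
from .network import GINetwork

logger = logging.getLogger(__name__)

#: Strata smaller than this get a low-n warning in their report notes.
MIN_STRATUM_COUNT = 5


@dataclass(frozen=True)
class LabeledPair:
    """A source/target gene pair with a ground-truth label."""

    source: str
    target: str
    label: str  # "positive" | "negative"
    activity: str | None = None
    sub_activity: str | None = None

    def __post_init__(self) -> None:
        if self.label not in ("positive", "negative"):
            raise ValidationError(f"label must be positive/negative, got "
                                  f"{self.label!r}")


@dataclass(frozen=True)
class FilterOutcome:
    """One labeled verdict: did the filter pass this positive/negative?"""

    label: str
    passed: bool
    activity: str | None = None
    sub_activity: str | None = None


@dataclass
class EvalReport:
    """Evaluation metrics for one filter (optionally one stratum).

    ``sensitivity`` and ``selectivity`` are percentages held at full
    precision; ``summary()`` rounds to one decimal for display. The DR is
    ``math.inf`` when selectivity is zero (flagged in ``notes``).
    """

    filter_name: str
    n_pos: int
    n_neg: int
    sensitivity: float
    selectivity: float
    discrimination_ratio: float
    roc: list[tuple[float, float]] = field(default_factory=list)
    auc: float | None = None
    strata: dict[str, "EvalReport"] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def summary(self) -> str:
        dr = ("inf" if math.isinf(self.discrimination_ratio)
              else f"{self.discrimination_ratio:.1f}")
        lines = [
            f"filter: {self.filter_name}",
            f"  positives: {self.n_pos}  negatives: {self.n_neg}",
            f"  sensitivity: {self.sensitivity:.1f}%  "
            f"selectivity: {self.selectivity:.1f}%  DR: {dr}",
        ]
        if self.auc is not None:
            lines.append(f"  AUC: {self.auc:.3f}")
        for note in self.notes:
            lines.append(f"  note: {note}")
        for label in sorted(self.strata):
            sub = self.strata[label]
            sub_dr = ("inf" if math.isinf(sub.discrimination_ratio)
                      else f"{sub.discrimination_ratio:.1f}")
            lines.append(f"  [{label}] sensitivity {sub.sensitivity:.1f}% "
                         f"selectivity {sub.selectivity:.1f}% DR {sub_dr}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "filter_name": self.filter_name,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "sensitivity": self.sensitivity,
            "selectivity": self.selectivity,
            "discrimination_ratio": (
                None if math.isinf(self.discrimination_ratio)
                else self.discrimination_ratio),
            "auc": self.auc,
            "roc": [list(p) for p in self.roc],
            "notes": list(self.notes),
            "strata": {k: v.to_dict() for k, v in self.strata.items()},
        }
        return d


def possible_pair_count(n_genes: int) -> int:
    """Number of unordered gene pairs, n(n-1)/2. The denominator that makes
    random pairing a safe negative model: e.g. 25,000 genes admit
    ~312 million possible pairwise interactions."""
    if n_genes < 0:
        raise ValidationError("n_genes must be >= 0")
    return n_genes * (n_genes - 1) // 2


def discrimination_ratio(sensitivity: float, selectivity: float) -> float:
    """Sensitivity / selectivity; ``inf`` when selectivity is zero."""
    if selectivity == 0:
        return math.inf
    return sensitivity / selectivity


def evaluate_filter(
    pos_passed: Sequence[bool],
    neg_passed: Sequence[bool],
    filter_name: str = "filter",
) -> EvalReport:
    """Compute sensitivity/selectivity/DR from per-item verdicts."""
    n_pos, n_neg = len(pos_passed), len(neg_passed)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("need at least one positive and one negative "
                              f"verdict (got {n_pos}/{n_neg})")
    sens = 100.0 * sum(map(bool, pos_passed)) / n_pos
    sel = 100.0 * sum(map(bool, neg_passed)) / n_neg
    dr = discrimination_ratio(sens, sel)
    notes = []
    if math.isinf(dr):
        notes.append("selectivity is zero; DR reported as infinite")
    return EvalReport(filter_name, n_pos, n_neg, sens, sel, dr, notes=notes)


def sensitivity_gain(base_pass_count: int, combined_pass_count: int) -> float:
    """Percent increase in retained motifs from combining filters,
    100 * (combined - base) / base."""
    if base_pass_count <= 0:
        raise ValidationError("base pass count must be > 0")
    if combined_pass_count < base_pass_count:
        raise ValidationError("combined pass count cannot be below base "
                              "(a union never loses passes)")
    return 100.0 * (combined_pass_count - base_pass_count) / base_pass_count


def generate_negative_pairs(
    genes: Sequence[str],
    n: int,
    seed: int,
    policy: str = "pure_random",
    known_pairs: Iterable[tuple[str, str]] | None = None,
    network: GINetwork | None = None,
) -> list[LabeledPair]:
    """Sample ``n`` distinct random gene pairs as a negative set.

    Pairs are drawn uniformly without replacement (source != target);
    reproducible from ``seed``. Policy ``"pure_random"`` accepts any pair
    (the default: known interactions are a negligible fraction of all
    pairs); ``"exclude_known"`` rejects pairs present in ``known_pairs``
    or as edges of ``network``.
    """
    if policy not in ("pure_random", "exclude_known"):
        raise ValidationError(f"unknown policy {policy!r}")
    if n < 0:
        raise ValidationError("n must be >= 0")
    pool: list[str] = []
    seen: set[str] = set()
    for g in genes:
        c = canonical_id(g)
        if c and c not in seen:
            seen.add(c)
            pool.append(c)
    if len(pool) < 2:
        raise ValidationError("need at least 2 distinct genes")

    excluded: set[tuple[str, str]] = set()
    if policy == "exclude_known":
        for a, b in known_pairs or ():
            excluded.add(canonical_pair(a, b))
        if network is not None:
            for a, b in network.graph.edges:
                excluded.add(canonical_pair(a, b))

    total = possible_pair_count(len(pool))
    n_excluded_in_pool = sum(
        1 for p in excluded if p[0] in seen and p[1] in seen and p[0] != p[1])
    available = total - n_excluded_in_pool
    if n > available:
        raise ValidationError(f"requested {n} pairs but only {available} "
                              f"distinct pairs are available")

    rng = np.random.default_rng(seed)
    chosen: list[tuple[str, str]] = []
    if n > available // 2:
        # dense request: enumerate eligible pairs and take a random subset
        eligible = [p for p in itertools.combinations(sorted(pool), 2)
                    if p not in excluded]
        idx = rng.choice(len(eligible), size=n, replace=False)
        chosen = [eligible[i] for i in sorted(idx)]
    else:
        taken: set[tuple[str, str]] = set()
        m = len(pool)
        while len(chosen) < n:
            i, j = rng.integers(0, m, size=2)
            if i == j:
                continue
            pair = canonical_pair(pool[i], pool[j])
            if pair in taken or pair in excluded:
                continue
            taken.add(pair)
            chosen.append(pair)
    return [LabeledPair(a, b, "negative") for a, b in chosen]


def gi_evidence_score(
    motif: MotifPrediction,
    network: GINetwork,
    hmap: HomologMap | None = None,
) -> float:
    """Graded GI support for a motif, used to rank motifs for ROC analysis.

    Score = ``1 / (1 + d)`` where ``d`` is the shortest GI-path length
    between the resolved source and target candidate sets (0 if either
    endpoint is unresolved or the sets are disconnected), plus a bounded
    bonus ``1e-6 * m / (m + 1)`` where ``m`` counts target candidates at
    distance ``d`` — more independent witnesses at the same distance rank
    marginally higher without ever outranking a shorter path. When a
    homolog map is supplied, candidate sets are expanded to cluster
    members, so homolog-supported motifs score above unsupported ones.
    Deterministic; higher = more supported.
    """
    try:
        s_set = network.resolve_gene(motif.source_protein)
        t_set = network.resolve_gene(motif.target_protein)
    except ValidationError:
        return 0.0
    if hmap is not None:
        s_set = {m for g in s_set for m, _ in hmap.cluster_members(g)}
        t_set = {m for g in t_set for m, _ in hmap.cluster_members(g)}
    s_set = {g for g in s_set if g in network.graph}
    t_set = {g for g in t_set if g in network.graph}
    if not s_set or not t_set:
        return 0.0

    # multi-source BFS from the S candidates over the whole component
    adj = network.graph.adj
    dist: dict[str, int] = {g: 0 for g in s_set}
    frontier = set(s_set)
    d = 0
    while frontier:
        d += 1
        new: set[str] = set()
        for g in frontier:
            for nbr in adj[g]:
                if nbr not in dist:
                    dist[nbr] = d
                    new.add(nbr)
        frontier = new

    # per-target path length; a target that is itself a source candidate
    # needs a self-loop to count as interaction evidence (length 1)
    per_target: dict[str, float] = {}
    for t in t_set:
        if t in s_set:
            per_target[t] = 1.0 if t in adj[t] else math.inf
        else:
            per_target[t] = float(dist.get(t, math.inf))
    best = min(per_target.values(), default=math.inf)
    if math.isinf(best):
        return 0.0
    m = sum(1 for v in per_target.values() if v == best)
    return 1.0 / (1.0 + best) + 1e-6 * m / (m + 1.0)


def roc_auc(
    scores: Sequence[float], labels: Sequence[bool | int]
) -> tuple[list[tuple[float, float]], float]:
    """Empirical ROC curve and trapezoidal AUC from a threshold sweep.

    Each distinct score value is one threshold (ties collapse onto a single
    operating point); the curve is anchored at (0, 0) and (1, 1) and is
    monotone nondecreasing in both coordinates. The resulting AUC equals
    the Mann-Whitney estimate P(score+ > score-) + 0.5 * P(tie).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValidationError("scores and labels must be equal-length 1-D")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present")

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    l_sorted = labels[order]
    tp = np.cumsum(l_sorted)
    fp = np.cumsum(~l_sorted)
    # keep only the last index of each tied score block
    distinct = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tpr = np.r_[0.0, tp[distinct] / n_pos, 1.0]
    fpr = np.r_[0.0, fp[distinct] / n_neg, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist()))
    return points, auc


def stratify_metrics(
    outcomes: Sequence[FilterOutcome],
    key: str = "activity",
    min_count: int = MIN_STRATUM_COUNT,
    filter_name: str = "filter",
) -> dict[str, EvalReport]:
    """Per-label evaluation reports, stratified by activity or sub-activity.

    Every outcome must carry the stratification label. Strata missing one
    of the two classes cannot be scored and are omitted with a warning;
    strata below ``min_count`` items per class carry a low-n note.
    """
    if key not in ("activity", "sub_activity"):
        raise ValidationError(f"unknown stratification key {key!r}")
    groups: dict[str, list[FilterOutcome]] = {}
    for out in outcomes:
        label = getattr(out, key)
        if label is None or label == "":
            raise ValidationError(f"outcome lacks the {key!r} label")
        groups.setdefault(label, []).append(out)

    reports: dict[str, EvalReport] = {}
    for label, group in groups.items():
        pos = [o.passed for o in group if o.label == "positive"]
        neg = [o.passed for o in group if o.label == "negative"]
        if not pos or not neg:
            logger.warning("stratum %r has a single class (%d pos / %d neg); "
                           "skipped", label, len(pos), len(neg))
            continue
        report = evaluate_filter(pos, neg,
                                 filter_name=f"{filter_name}[{label}]")
        if min(len(pos), len(neg)) < min_count:
            report.notes.append(f"low n: {len(pos)} pos / {len(neg)} neg")
        reports[label] = report
    return reports
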