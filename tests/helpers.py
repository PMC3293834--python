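"""Test-only helpers, including the paired reader for filter reports."""

from __future__ import annotations

import csv
from pathlib import Path

from gifilters.filters import FilterDecision


def read_filter_report(path) -> set[tuple]:
    """Inverse of ``write_filter_report`` (decision-set level): returns
    ``{(motif_id, filter_name, passed, witness), ...}``."""
    decisions = set()
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        names = [c[:-len("_passed")] for c in header if c.endswith("_passed")]
        for row in reader:
            rec = dict(zip(header, row))
            for name in names:
                witness = tuple(
                    tuple(p.split("--")) for p in rec[f"{name}_witness"].split(";")
                    if p)
                decisions.add((rec["motif_id"], name,
                               rec[f"{name}_passed"] == "true", witness))
    return decisions


def decision_key(d: FilterDecision) -> tuple:
    return (d.motif_id, d.filter_name, d.passed, tuple(d.witness))
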