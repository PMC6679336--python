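"""Decision-rule fusion of the offline 1-NN label and the online activity level.

A RuleTable maps every (knn_label, level) cell to an output behaviour.
Cells left unassigned resolve through a fallback policy (default: pass the
KNN label through). Tables can be written down literally or learned from
labelled (knn_label, level, truth) triples by per-cell majority vote —
with two 3-level categorical predictors a fully grown decision tree
partitions exactly into the 9 cells, so majority-per-cell is equivalent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .features import extract_features
from .online_kmeans import LEVELS, CentroidState, km_step
from .prototype import PrototypeModel, knn_predict
from .signals import BEHAVIOURS, DEFAULT_PRIORITY, SampleStream, validate_behaviour

FALLBACK_POLICIES = ("knn_passthrough",)


@dataclass
class LabelledPair:
    """One fused observation: offline label, online level, ground truth."""

    knn_label: str
    level: str
    truth: str

    def __post_init__(self) -> None:
        validate_behaviour(self.knn_label)
        validate_behaviour(self.truth)
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")


@dataclass
class RuleTable:
    """(knn_label × level) -> behaviour mapping; None cells use the fallback."""

    mapping: dict[tuple[str, str], str | None]
    fallback: str = "knn_passthrough"
    provenance: str = "literal"

    def __post_init__(self) -> None:
        for cell in _all_cells():
            if cell not in self.mapping:
                raise ValueError(f"rule table missing cell {cell}")
        for cell, out in self.mapping.items():
            if out is not None:
                validate_behaviour(out)
        if self.fallback not in FALLBACK_POLICIES:
            raise ValueError(f"unknown fallback policy {self.fallback!r}")


def _all_cells() -> list[tuple[str, str]]:
    return [(b, l) for b in BEHAVIOURS for l in LEVELS]


def default_rules(lying_low: str = "lying") -> RuleTable:
    """The literal rule grid.

    Walking KNN always maps to walking; standing KNN with high activity is
    promoted to walking; standing with medium/low stays standing; lying with
    medium maps to lying. The (lying, low) cell is claimed by both the
    standing and the lying clauses of the source rules — ``lying_low``
    selects the resolution (default lying). (lying, high) is unassigned and
    resolves through the fallback.
    """
    validate_behaviour(lying_low)
    mapping: dict[tuple[str, str], str | None] = {
        ("walking", "high"): "walking",
        ("walking", "medium"): "walking",
        ("walking", "low"): "walking",
        ("standing", "high"): "walking",
        ("standing", "medium"): "standing",
        ("standing", "low"): "standing",
        ("lying", "high"): None,
        ("lying", "medium"): "lying",
        ("lying", "low"): lying_low,
    }
    return RuleTable(mapping=mapping, provenance="literal")


def apply_rules(table: RuleTable, knn_label: str, level: str) -> str:
    """Pure table lookup; unassigned cells resolve per the fallback policy."""
    out = table.mapping[(knn_label, level)]
    if out is None:
        # knn_passthrough is the only policy
        out = knn_label
    return out


def learn_rules(
    pairs: Sequence[LabelledPair],
    min_support: int = 1,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> RuleTable:
    """Per-cell majority vote over truth labels; sparse cells fall back.

    Ties break by the fixed ``priority`` order; cells with fewer than
    ``min_support`` examples are left unassigned.
    """
    if not pairs:
        raise ValueError("no labelled pairs")
    rank = {b: i for i, b in enumerate(priority)}
    votes: dict[tuple[str, str], Counter] = {cell: Counter() for cell in _all_cells()}
    for p in pairs:
        votes[(p.knn_label, p.level)][p.truth] += 1
    mapping: dict[tuple[str, str], str | None] = {}
    for cell, counter in votes.items():
        if sum(counter.values()) < min_support or not counter:
            mapping[cell] = None
            continue
        mapping[cell] = min(counter, key=lambda b: (-counter[b], rank[b]))
    return RuleTable(mapping=mapping, provenance="learned")


def run_combined(
    stream: SampleStream,
    model: PrototypeModel,
    state: CentroidState,
    table: RuleTable,
    window_s: float = 7.0,
    cadence_s: float = 10.0,
    gravity: float = 1.0,
    step: float = 0.1,
) -> tuple[list[dict], CentroidState]:
    """Run the full per-window pipeline over a stream.

    Per window: features -> offline 1-NN label -> online level from the
    activity index (predict-then-update) -> fused label. Returns one record
    per window with (timestamp, knn_label, level, mean_amag, combined) and
    the final centroid state (with history).
    """
    fvs = extract_features(
        stream, window_s=window_s, cadence_s=cadence_s, gravity=gravity, step=step
    )
    records: list[dict] = []
    cur = state
    for fv in fvs:
        knn_label = knn_predict(model, fv)
        level, cur = km_step(cur, float(fv.mean_amag))
        cur.history.append(cur.sorted_centres())
        records.append(
            {
                "timestamp": fv.window_start_t,
                "knn_label": knn_label,
                "level": level,
                "mean_amag": fv.mean_amag,
                "combined": apply_rules(table, knn_label, level),
            }
        )
    return records, cur


def records_to_frame(records: Sequence[dict]) -> pd.DataFrame:
    return pd.DataFrame(
        records, columns=["timestamp", "knn_label", "level", "mean_amag", "combined"]
    )


def write_records_csv(records: Sequence[dict], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def write_rules(table: RuleTable, path: str | Path) -> None:
    """9 data rows (knn_label, level, output or '-') plus a fallback line."""
    lines = ["knn_label,level,output"]
    for (b, l) in _all_cells():
        out = table.mapping[(b, l)]
        lines.append(f"{b},{l},{out if out is not None else '-'}")
    lines.append(f"fallback,{table.fallback}")
    lines.append(f"provenance,{table.provenance}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_rules(path: str | Path) -> RuleTable:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    mapping: dict[tuple[str, str], str | None] = {}
    fallback = "knn_passthrough"
    provenance = "literal"
    for ln in lines[1:]:
        parts = ln.split(",")
        if parts[0] == "fallback":
            fallback = parts[1]
        elif parts[0] == "provenance":
            provenance = parts[1]
        else:
            b, l, out = parts
            mapping[(b, l)] = None if out == "-" else out
    return RuleTable(mapping=mapping, fallback=fallback, provenance=provenance)
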