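"""Directional reporting: which networks the causal components drive.

For every selected causal component the targets carrying its top fraction of
outgoing influence are listed, the union forms a directed edge table with
per-target incoming sums, and region labels turn the tables into
cortical/subcortical summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregate import RULES, AggregateScores, CausalSelection

CLASSES = ("cortical", "subcortical", "artifact")


@dataclass
class RegionLabelMap:
    """Component id -> (region name, class) lookup.

    Classes are ``cortical``, ``subcortical`` or ``artifact``; every id in
    scope must appear exactly once.  Anatomical localization is user input —
    the pipeline never infers it.
    """

    table: pd.DataFrame  # columns: component_id, region, class

    def __post_init__(self) -> None:
        required = {"component_id", "region", "class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"label table is missing columns: {sorted(missing)}")
        if self.table["component_id"].duplicated().any():
            dup = self.table.loc[self.table["component_id"].duplicated(), "component_id"]
            raise ValueError(f"duplicate component ids in label map: {dup.tolist()}")
        bad = set(self.table["class"]) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown classes {sorted(bad)}; expected one of {CLASSES}")

    def klass(self, component_id: int) -> str:
        row = self.table.loc[self.table["component_id"] == component_id]
        if row.empty:
            raise KeyError(component_id)
        return str(row["class"].iloc[0])

    def covered(self, ids) -> list[int]:
        known = set(self.table["component_id"])
        return [i for i in ids if i not in known]


@dataclass
class EdgeTable:
    """Directed (source, target, weight) edges surviving the per-source threshold.

    ``per_target_sum`` totals the listed incoming weights of each target;
    ``affected`` lists the distinct targets by descending incoming sum.
    """

    edges: list[tuple[int, int, float]]
    per_target_sum: dict[int, float]
    affected: list[int]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.edges, columns=["source", "target", "weight"])

    def to_wide(self) -> pd.DataFrame:
        """Wide layout: rows = affected targets, columns = sources, plus Sum."""
        frame = self.to_frame()
        wide = frame.pivot(index="target", columns="source", values="weight")
        wide = wide.reindex(self.affected)
        wide["Sum"] = [self.per_target_sum[t] for t in self.affected]
        return wide


def select_targets(
    agg: AggregateScores,
    source: int,
    fraction: float = 0.2,
    rule: str = "value_threshold",
) -> list[tuple[int, float]]:
    """Targets carrying the top fraction of a source's outgoing influence.

    Operates on the source's row of the aggregated matrix with the diagonal
    excluded.  ``value_threshold`` keeps targets whose weight exceeds
    (1 - fraction) * row maximum; ``rank_count`` keeps the
    ceil(fraction * (K - 1)) largest.  Output is sorted by descending weight,
    ties by ascending target id.  An all-zero row yields an empty list with
    a warning (that source influences nothing measurably).
    """
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ids = agg.component_ids
    try:
        si = ids.index(source)
    except ValueError:
        raise KeyError(f"source {source} is not among the component ids") from None
    row = agg.agg_matrix[si].astype(float)
    targets = [(ids[j], float(row[j])) for j in range(len(ids)) if j != si]
    weights = np.array([w for _, w in targets])
    if np.all(weights == 0):
        warnings.warn(f"source {source} has an all-zero outgoing row", stacklevel=2)
        return []
    targets.sort(key=lambda tw: (-tw[1], tw[0]))
    if rule == "value_threshold":
        cutoff = (1.0 - fraction) * float(weights.max())
        return [(t, w) for t, w in targets if w > cutoff]
    n_sel = int(np.ceil(fraction * len(targets)))
    return targets[:n_sel]


def build_edge_table(
    selection: CausalSelection,
    agg: AggregateScores,
    fraction: float = 0.2,
    rule: str = "value_threshold",
) -> EdgeTable:
    """Union of per-source surviving targets, with per-target incoming sums.

    A selected source may itself appear as a target of another source;
    self-edges are impossible because the diagonal is excluded.
    """
    if not selection.selected:
        raise ValueError("selection is empty; nothing to build an edge table from")
    edges: list[tuple[int, int, float]] = []
    sums: dict[int, float] = {}
    for source in selection.selected:
        for target, weight in select_targets(agg, source, fraction=fraction, rule=rule):
            edges.append((source, target, weight))
            sums[target] = sums.get(target, 0.0) + weight
    affected = sorted(sums, key=lambda t: (-sums[t], t))
    return EdgeTable(edges=edges, per_target_sum=sums, affected=affected)


def summarize_by_class(
    component_ids,
    labels: RegionLabelMap,
    scores: dict[int, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Per-class component counts and (optionally) score totals.

    ``scores`` maps component id -> score; when given, each class row also
    carries the full-precision total and its nearest-integer display value.
    Class totals partition the grand total exactly.
    """
    component_ids = list(component_ids)
    uncovered = labels.covered(component_ids)
    if uncovered:
        raise ValueError(f"label map does not cover component ids: {uncovered}")
    rows = []
    for klass in CLASSES:
        members = [i for i in component_ids if labels.klass(i) == klass]
        if not members:
            continue
        row = {"class": klass, "count": len(members)}
        if scores is not None:
            total = float(sum(scores[i] for i in members))
            row["total"] = total
            row["total_rounded"] = int(round(total))
        rows.append(row)
    return pd.DataFrame(rows).set_index("class")
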