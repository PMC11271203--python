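"""Cross-subject aggregation of causality matrices and causal-network selection.

Three aggregation approaches are supported: ``split`` keeps excitatory
(positive) and inhibitory (negative) sums separately, ``signed`` sums the raw
coefficients, and ``absolute`` (the default) sums absolute values so
excitatory and inhibitory influences both count toward a component's total
outgoing effect.  A component's score is its row sum over targets with the
self-coupling diagonal excluded.

The "top 20%" selection is a *value* threshold: components whose score
exceeds 80% of the maximum score.  This is distinct from taking the top 20%
of components by rank (which is available as the ``rank_count`` rule) and
typically selects far fewer components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .granger import CausalityMatrix

APPROACHES = ("split", "signed", "absolute")
RULES = ("value_threshold", "rank_count")


@dataclass
class AggregateScores:
    """Group-level aggregated matrix plus per-component outgoing scores.

    ``scores[i]`` sums row i of ``agg_matrix`` over all targets j != i;
    ``ranking`` lists component ids by descending score (ties broken by
    ascending id).  For the ``split`` approach, ``pos_matrix``/``neg_matrix``
    hold the separate excitatory/inhibitory sums and ``agg_matrix`` their
    absolute total.
    """

    agg_matrix: np.ndarray
    scores: np.ndarray
    component_ids: list[int]
    approach: str
    ranking: list[int] = field(default_factory=list)
    pos_matrix: np.ndarray | None = None
    neg_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.ranking:
            order = sorted(
                range(len(self.component_ids)),
                key=lambda i: (-self.scores[i], self.component_ids[i]),
            )
            self.ranking = [self.component_ids[i] for i in order]

    def scores_series(self) -> pd.Series:
        return pd.Series(self.scores, index=self.component_ids, name="score")


@dataclass
class CausalSelection:
    """Outcome of the top-fraction selection of causal components."""

    cutoff: float
    selected: list[int]
    fraction: float
    rule: str


def aggregate_matrices(
    matrices: list[CausalityMatrix],
    approach: str = "absolute",
    include_diagonal: bool = False,
    component_ids: list[int] | None = None,
) -> AggregateScores:
    """Combine per-subject causality matrices across the group."""
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}; expected one of {APPROACHES}")
    if not matrices:
        raise ValueError("no causality matrices to aggregate")
    k = matrices[0].n_components
    for m in matrices:
        if m.n_components != k:
            raise ValueError(
                f"mixed matrix sizes: {k} vs {m.n_components} "
                f"(subject {m.subject_id!r})"
            )
    stack = np.stack([m.coeffs for m in matrices])
    pos = neg = None
    if approach == "absolute":
        agg = np.abs(stack).sum(axis=0)
    elif approach == "signed":
        agg = stack.sum(axis=0)
    else:  # split
        pos = np.clip(stack, 0, None).sum(axis=0)
        neg = np.clip(stack, None, 0).sum(axis=0)
        agg = pos - neg  # absolute total of the two halves
    score_matrix = agg if include_diagonal else agg - np.diag(np.diag(agg))
    scores = score_matrix.sum(axis=1)
    if component_ids is None:
        component_ids = list(range(1, k + 1))
    return AggregateScores(
        agg_matrix=agg,
        scores=scores,
        component_ids=list(component_ids),
        approach=approach,
        pos_matrix=pos,
        neg_matrix=neg,
    )


def _as_series(scores: AggregateScores | pd.Series | dict) -> pd.Series:
    if isinstance(scores, AggregateScores):
        return scores.scores_series()
    if isinstance(scores, pd.Series):
        return scores
    return pd.Series(scores)


def select_top(
    scores: AggregateScores | pd.Series | dict,
    fraction: float = 0.2,
    rule: str = "value_threshold",
) -> CausalSelection:
    """Select the causal components carrying the top fraction of influence.

    ``value_threshold`` (default): cutoff = (1 - fraction) * max(score);
    components strictly above the cutoff are selected, so the arg-max is
    always in and boundary-equal scores are out.  ``rank_count``: the
    ceil(fraction * K) highest-scoring components, ties broken by ascending
    component id.  Selected ids are ordered by descending score.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")
    s = _as_series(scores)
    # descending score, ties broken by ascending component id
    order = s.iloc[np.lexsort((s.index, -s.values))]
    if rule == "value_threshold":
        max_score = float(s.max())
        if max_score <= 0:
            raise ValueError("no causal signal: all aggregated scores are <= 0")
        cutoff = (1.0 - fraction) * max_score
        selected = [int(i) for i, v in order.items() if v > cutoff]
        return CausalSelection(cutoff=cutoff, selected=selected, fraction=fraction, rule=rule)
    n_sel = math.ceil(fraction * len(s))
    chosen = order.iloc[:n_sel]
    return CausalSelection(
        cutoff=float(chosen.iloc[-1]),
        selected=[int(i) for i in chosen.index],
        fraction=fraction,
        rule=rule,
    )


def format_cutoff(selection: CausalSelection) -> str:
    """Human-readable cutoff, rounded to 2 decimals for display."""
    return f"{selection.cutoff:.2f}"
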