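"""Bundled worked-example tables for a 114-component resting-state analysis.

Three small TSVs ship with the package: the twelve causal components with
their full-precision aggregated scores and anatomical labels, the 28 x 12
grid of surviving directed influences onto the affected networks, and the
region label map classing every referenced component as cortical or
subcortical (white matter, putamen and cerebellum are classed subcortical in
the shipped map; the classing lives in the data file, not in code).

These tables let the selection, edge-table and class-summary stages be
exercised end to end without any raw imaging data.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .directionality import EdgeTable, RegionLabelMap

#: Maximum aggregated score and top-20% cutoff of the worked example,
#: as displayed at 2 decimals.
WORKED_EXAMPLE_MAX = 4413.19
WORKED_EXAMPLE_CUTOFF = 3530.55


def _data_path(name: str):
    return resources.files("restcause.data").joinpath(name)


def load_causal_components() -> pd.DataFrame:
    """Twelve causal components: id, full-precision score, region, class."""
    with resources.as_file(_data_path("causal_components.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
    frame["component_id"] = frame["component_id"].astype(int)
    return frame


def causal_scores() -> pd.Series:
    """The twelve aggregated outgoing-influence scores, indexed by id."""
    frame = load_causal_components()
    return pd.Series(frame["score"].to_numpy(), index=frame["component_id"].to_numpy())


def load_affected_networks() -> pd.DataFrame:
    """The 28-row affected-network grid; source columns named by source id.

    Empty cells mean the influence did not survive that source's threshold.
    ``printed_sum`` preserves the published row totals, which differ from
    the sum of the printed cells by up to 0.05 due to pre-rounding
    arithmetic; downstream code recomputes sums from the cells.
    """
    with resources.as_file(_data_path("affected_networks.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
    frame["component_id"] = frame["component_id"].astype(int)
    return frame


def load_region_labels() -> RegionLabelMap:
    """Label map covering the 12 causal sources and 28 affected targets."""
    with resources.as_file(_data_path("region_labels.tsv")) as p:
        frame = pd.read_csv(p, sep="\t")
    frame["component_id"] = frame["component_id"].astype(int)
    return RegionLabelMap(table=frame)


def affected_edge_table() -> EdgeTable:
    """The worked-example grid as an :class:`EdgeTable`.

    Edges are the filled cells (source -> target with the printed weight);
    per-target sums are recomputed from the cells at full precision.
    """
    grid = load_affected_networks()
    source_cols = [c for c in grid.columns if c not in ("component_id", "region", "printed_sum")]
    edges: list[tuple[int, int, float]] = []
    sums: dict[int, float] = {}
    for _, row in grid.iterrows():
        target = int(row["component_id"])
        for col in source_cols:
            value = row[col]
            if pd.notna(value):
                edges.append((int(col), target, float(value)))
                sums[target] = sums.get(target, 0.0) + float(value)
    affected = sorted(sums, key=lambda t: (-sums[t], t))
    return EdgeTable(edges=edges, per_target_sum=sums, affected=affected)


def embedded_score_vector(
    n_components: int = 114,
    filler_low: float = 1300.0,
    filler_high: float = 3000.0,
    seed: int = 0,
) -> pd.Series:
    """Score vector embedding the twelve known scores among synthetic fillers.

    The remaining ids receive scores drawn uniformly from
    ``[filler_low, filler_high)`` — all below the worked example's selection
    cutoff, mimicking the long tail of non-causal components.
    """
    known = causal_scores()
    if n_components < len(known):
        raise ValueError("n_components smaller than the number of known scores")
    rng = np.random.default_rng(seed)
    all_ids = [i for i in range(1, n_components + 1)]
    filler_ids = [i for i in all_ids if i not in set(known.index)][: n_components - len(known)]
    fillers = pd.Series(
        rng.uniform(filler_low, filler_high, size=len(filler_ids)), index=filler_ids
    )
    return pd.concat([known, fillers]).sort_index()
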