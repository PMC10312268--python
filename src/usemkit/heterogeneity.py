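"""Group-to-individual generalizability summaries.

How well does a single network describe everyone? These helpers count the
overlap between an aggregate network and each subject's idiographic
network, tabulate how prevalent each discovered path is across subjects,
and partition path sets discovered by different procedures into shared and
procedure-specific parts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .usem_core import NetworkModel, PathSpec

__all__ = ["OverlapSummary", "path_overlap", "prevalence",
           "compare_path_sets", "discovered_paths"]


@dataclass
class OverlapSummary:
    """Per-subject counts of aggregate paths also present idiographically."""

    shared: pd.Series          # subject_id -> |E_agg intersect E_i|
    aggregate_count: int
    median_shared: float
    mean_shared: float
    below_half_count: int
    below_half_fraction: float
    max_subject: str
    median_subject: str
    min_subject: str

    @classmethod
    def from_counts(cls, shared: pd.Series, aggregate_count: int
                    ) -> "OverlapSummary":
        half = math.ceil(aggregate_count / 2)
        below = shared < half
        order = shared.sort_values(kind="stable")
        med_pos = (len(order) - 1) // 2
        return cls(
            shared=shared,
            aggregate_count=aggregate_count,
            median_shared=float(shared.median()),
            mean_shared=float(shared.mean()),
            below_half_count=int(below.sum()),
            below_half_fraction=float(below.mean()),
            max_subject=str(order.index[-1]),
            median_subject=str(order.index[med_pos]),
            min_subject=str(order.index[0]),
        )


def discovered_paths(model: NetworkModel,
                     include_ar_base: bool = False) -> set[PathSpec]:
    """A model's data-driven paths; auto-freed AR base paths are excluded
    by default since they were never discovered by the search."""
    return {p for p in model.free_paths
            if include_ar_base or p.level != "null_base"}


def path_overlap(aggregate: NetworkModel,
                 individuals: dict[str, NetworkModel] | list[NetworkModel],
                 include_ar_base: bool = False) -> OverlapSummary:
    """Overlap of each idiographic network with the aggregate network,
    matching paths on (from, to, lag) and ignoring estimates.

    "Sharing less than half" means a shared count strictly below
    ceil(|E_agg| / 2).
    """
    if isinstance(individuals, list):
        individuals = {f"sub{i + 1:03d}": m_
                       for i, m_ in enumerate(individuals)}
    vocab = set(aggregate.node_names) | set(aggregate.exog_names)
    for sid, model in individuals.items():
        v = set(model.node_names) | set(model.exog_names)
        if v != vocab:
            raise ValueError(
                f"node vocabulary mismatch for {sid}: {sorted(v ^ vocab)}")
    agg = discovered_paths(aggregate, include_ar_base)
    counts = {}
    for sid, model in individuals.items():
        counts[sid] = len(agg & discovered_paths(model, include_ar_base))
    shared = pd.Series(counts, name="shared").sort_index()
    return OverlapSummary.from_counts(shared, len(agg))


def prevalence(individuals: dict[str, NetworkModel],
               min_fraction: float = 0.20,
               exclude_levels: tuple[str, ...] = ("null_base", "group",
                                                  "subgroup")) -> pd.DataFrame:
    """Count, per non-group path, the subjects whose final model retains
    it; keep paths present for at least ceil(min_fraction * n) subjects.

    Returns a DataFrame (from_node, to_node, lag, count) sorted by count
    descending, ties broken lexicographically.
    """
    if not individuals:
        raise ValueError("no individual models supplied")
    n = len(individuals)
    threshold = math.ceil(min_fraction * n)
    counts: dict[tuple, int] = {}
    for model in individuals.values():
        for pth in model.free_paths:
            if pth.level in exclude_levels:
                continue
            key = (pth.from_node, pth.to_node, pth.lag)
            counts[key] = counts.get(key, 0) + 1
    rows = [dict(from_node=k[0], to_node=k[1], lag=k[2], count=v)
            for k, v in counts.items() if v >= threshold]
    df = pd.DataFrame(rows, columns=["from_node", "to_node", "lag", "count"])
    return df.sort_values(["count", "from_node", "to_node", "lag"],
                          ascending=[False, True, True, True]
                          ).reset_index(drop=True)


def compare_path_sets(set_a: set[PathSpec], set_b: set[PathSpec]
                      ) -> tuple[set[PathSpec], set[PathSpec], set[PathSpec]]:
    """Partition two path sets into (shared, only_a, only_b), matching on
    (from, to, lag)."""
    shared = set_a & set_b
    return shared, set_a - set_b, set_b - set_a
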