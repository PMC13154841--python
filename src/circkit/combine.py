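"""Multi-tool combination strategies over clustered circles.

Circles reported by several detection tools are first grouped into identity
clusters (both junction coordinates within the matching threshold); each
cluster's *support* is the number of distinct tools contributing to it. A
combination strategy then selects clusters by support ``s`` out of ``n``
tools:

==========  =====================
union       s >= 1 (any tool)
unique      s == 1 (one tool only)
intersect   s == n (all tools)
double      2 <= s < n
rosette     s >= 2 (requires n >= 3)
==========  =====================

These satisfy the partition law ``union = unique + double + intersect`` and
``rosette = double + intersect``. The *Rosette* consensus — circles seen by
at least two of three-or-more tools — is the recommended trade-off between
the permissive union and the overly strict intersection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    Circle,
    CircleCluster,
    DEFAULT_MATCH_THRESHOLD,
    cluster_circles,
)

STRATEGIES = ("union", "rosette", "intersect", "double", "unique")


@dataclass
class CombinationResult:
    """Selected clusters for one strategy.

    ``circles`` are the cluster representatives (highest split support,
    then longest member), which is what downstream metrics receive.
    """

    strategy: str
    n_tools: int
    clusters: list[CircleCluster]

    @property
    def circles(self) -> list[Circle]:
        return [cl.representative for cl in self.clusters]

    @property
    def support_map(self) -> dict[Circle, int]:
        return {cl.representative: cl.support for cl in self.clusters}

    def __len__(self) -> int:
        return len(self.clusters)


def _selected(support: int, n_tools: int, strategy: str) -> bool:
    if strategy == "union":
        return support >= 1
    if strategy == "unique":
        return support == 1
    if strategy == "intersect":
        return support == n_tools
    if strategy == "double":
        return 2 <= support < n_tools
    if strategy == "rosette":
        return support >= 2
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")


def combine(
    per_tool_sets: Mapping[str, Iterable[Circle]],
    strategy: str,
    threshold: int = DEFAULT_MATCH_THRESHOLD,
) -> CombinationResult:
    """Apply one combination strategy to per-tool circle sets.

    Raises ``ValueError`` for fewer than 2 tools, or fewer than 3 for the
    rosette strategy.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    n_tools = len(per_tool_sets)
    if n_tools < 2:
        raise ValueError("combination requires at least 2 tools")
    if strategy == "rosette" and n_tools < 3:
        raise ValueError("rosette requires a combination of at least 3 tools")
    clusters = cluster_circles(per_tool_sets, threshold)
    selected = [cl for cl in clusters if _selected(cl.support, n_tools, strategy)]
    return CombinationResult(strategy=strategy, n_tools=n_tools, clusters=selected)


def support_table(
    per_tool_sets: Mapping[str, Iterable[Circle]],
    threshold: int = DEFAULT_MATCH_THRESHOLD,
) -> pd.DataFrame:
    """Cluster-by-tool membership table (UpSet-plot style).

    One row per cluster: representative coordinates, support count, and a
    boolean column per tool.
    """
    tools = sorted(per_tool_sets)
    rows = []
    for cl in cluster_circles(per_tool_sets, threshold):
        rep = cl.representative
        row = {
            "chrom": rep.chrom,
            "start": rep.start,
            "end": rep.end,
            "support": cl.support,
        }
        member_tools = cl.tools
        for t in tools:
            row[t] = t in member_tools
        rows.append(row)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "support", *tools])
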