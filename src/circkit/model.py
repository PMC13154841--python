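"""Core circle data model and the endpoint-threshold identity used everywhere.

A *circle* is a circular DNA/RNA element described by the genomic interval
between its two circular-junction (CJ) coordinates. All coordinates are
0-based half-open (BED convention); 1-based inputs must be converted at the
I/O boundary. Two circles from different tools are deemed the same when both
junction coordinates agree within a base-pair threshold (20 bp by default),
which is the identity notion every downstream filter, consensus strategy and
benchmark metric relies on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

#: Default endpoint tolerance (bp) for deciding two circles are the same.
DEFAULT_MATCH_THRESHOLD = 20


@dataclass(frozen=True)
class Circle:
    """One predicted or simulated circular element.

    Parameters
    ----------
    chrom:
        Reference sequence name.
    start, end:
        Junction coordinates, 0-based half-open; ``end > start``.
    split_reads:
        Number of split reads supporting the junction, or ``None`` when the
        source tool does not report split support.
    tool:
        Label of the detection tool that produced this circle, or ``None``.
    name:
        Optional identifier (e.g. BED name column, simulated-circle id).
    """

    chrom: str
    start: int
    end: int
    split_reads: Optional[int] = None
    tool: Optional[str] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"circle end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.split_reads is not None and self.split_reads < 0:
            raise ValueError(f"split_reads must be >= 0, got {self.split_reads}")

    @property
    def length(self) -> int:
        """Circle length in base pairs (``end - start``)."""
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def circles_match(a: Circle, b: Circle, threshold: int = DEFAULT_MATCH_THRESHOLD) -> bool:
    """True when ``a`` and ``b`` are the same circle under the bp threshold.

    Both junction coordinates must agree: same chromosome, and each of the
    start and end offsets is at most ``threshold`` bases. The relation is
    symmetric and reflexive but not transitive.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return (
        a.chrom == b.chrom
        and abs(a.start - b.start) <= threshold
        and abs(a.end - b.end) <= threshold
    )


def _representative_key(c: Circle):
    # Highest split support first, then longest, then smallest coordinates.
    support = c.split_reads if c.split_reads is not None else -1
    return (-support, -c.length, c.chrom, c.start, c.end)


@dataclass
class CircleCluster:
    """A group of circles from one or more tools deemed identical.

    The representative is the member with the highest split-read support
    (ties: longest, then smallest coordinates); matching of new candidates is
    anchored on the representative, which bounds within-cluster spread to the
    threshold and avoids transitive chaining of circles further apart.
    """

    members: list[Circle] = field(default_factory=list)

    @property
    def representative(self) -> Circle:
        return min(self.members, key=_representative_key)

    @property
    def support(self) -> int:
        """Number of distinct tools contributing at least one member."""
        return len({m.tool for m in self.members})

    @property
    def tools(self) -> frozenset:
        return frozenset(m.tool for m in self.members)


def cluster_circles(
    per_tool_sets: Mapping[str, Iterable[Circle]],
    threshold: int = DEFAULT_MATCH_THRESHOLD,
) -> list[CircleCluster]:
    """Group circles across tools into identity clusters.

    Circles are processed sorted by (chrom, start, end, tool); each joins the
    first existing cluster whose *representative* it matches under
    ``threshold``, otherwise it seeds a new cluster. Every input circle lands
    in exactly one cluster and the result depends only on the input content,
    not on dict ordering.
    """
    labelled: list[Circle] = []
    for tool, circles in per_tool_sets.items():
        for c in circles:
            labelled.append(c if c.tool == tool else replace(c, tool=tool))
    labelled.sort(key=lambda c: (c.chrom, c.start, c.end, c.tool))

    by_chrom: dict[str, list[CircleCluster]] = {}
    for c in labelled:
        clusters = by_chrom.setdefault(c.chrom, [])
        for cluster in clusters:
            if circles_match(c, cluster.representative, threshold):
                cluster.members.append(c)
                break
        else:
            clusters.append(CircleCluster(members=[c]))

    out: list[CircleCluster] = []
    for chrom in sorted(by_chrom):
        out.extend(by_chrom[chrom])
    return out
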