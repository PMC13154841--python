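"""Filtering strategies for predicted circles.

Four strategies reduce false positives in a single tool's output:

``unfilter``
    Keep everything (identity; exists so pipelines can name the baseline).
``filter_split``
    Keep circles with at least ``min_split`` supporting split reads.
    Circles that carry no split-read information pass unchanged — the
    filter is inapplicable, not failed (some tools never report split
    counts).
``filter_duplicates``
    Remove overlapping circles: among circles whose intervals share at
    least one base on the same chromosome, keep the one with the most
    split reads (longest when split info is absent).
``filter_both``
    ``filter_split`` first, then ``filter_duplicates``.

Duplicate removal uses a greedy priority sweep (split reads desc, length
desc, coordinates asc): deterministic, idempotent, and reproduces the
pairwise rule on overlap chains.
"""

from __future__ import annotations

from typing import Sequence

from intervaltree import IntervalTree

from .model import Circle


def unfilter(circles: Sequence[Circle]) -> list[Circle]:
    """All raw detections, unchanged."""
    return list(circles)


def filter_split(circles: Sequence[Circle], min_split: int = 2) -> list[Circle]:
    """Keep circles supported by at least ``min_split`` split reads.

    Circles lacking a split-read count are retained unchanged.
    """
    return [
        c for c in circles if c.split_reads is None or c.split_reads >= min_split
    ]


def _priority(c: Circle):
    support = c.split_reads if c.split_reads is not None else -1
    return (-support, -c.length, c.chrom, c.start, c.end)


def filter_duplicates(circles: Sequence[Circle]) -> list[Circle]:
    """Remove overlapping circles, keeping the best-supported one.

    Overlap means sharing >= 1 base on the same chromosome. Priority is
    split-read support (descending), then length, then coordinate order;
    the retained set is overlap-free. Output preserves coordinate order.
    """
    kept: list[Circle] = []
    trees: dict[str, IntervalTree] = {}
    for c in sorted(circles, key=_priority):
        tree = trees.setdefault(c.chrom, IntervalTree())
        if not tree.overlaps(c.start, c.end):
            tree.addi(c.start, c.end)
            kept.append(c)
    kept.sort(key=lambda c: (c.chrom, c.start, c.end))
    return kept


def filter_both(circles: Sequence[Circle], min_split: int = 2) -> list[Circle]:
    """Split-read filter followed by duplicate removal, in that order."""
    return filter_duplicates(filter_split(circles, min_split))


#: Strategy name -> callable, for the CLI and pipelines.
STRATEGIES = {
    "unfilter": unfilter,
    "split": filter_split,
    "duplicates": filter_duplicates,
    "both": filter_both,
}
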