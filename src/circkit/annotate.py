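"""Repeat-element and genomic-element annotation of circle junctions.

Circle junction coordinates are labelled against two reference layers:

* repeat elements (RepeatMasker output or BED): classes LINE, SINE, DNA,
  satellite and other (LTR, simple repeats, low complexity, snRNA,
  unknown); junctions overlapping no repeat are non-repetitive ("Ø");
* genomic elements (GFF3): a cascading priority of 3'-UTR / 5'-UTR /
  other (start codon, stop codon, selenocysteine), then exon, then
  intron, then intergenic — each tier consulted only when the previous
  one gave no label.

Benchmark metrics can then be stratified by the truth circles' annotation
class to expose per-region detection performance (repeats are where
detection typically degrades).
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence, Union

import gffutils
from intervaltree import IntervalTree

from .metrics import BenchmarkReport, match_predictions
from .model import Circle, DEFAULT_MATCH_THRESHOLD

REPEAT_CLASSES = ("LINE", "SINE", "DNA", "satellite", "other")
#: Label for junctions overlapping no annotated repeat.
NON_REPETITIVE = "Ø"

GENOMIC_CLASSES = ("3'-UTR", "5'-UTR", "other", "exon", "intron", "intergenic")

#: Priority when a junction overlaps several repeat classes.
_REPEAT_PRIORITY = {c: i for i, c in enumerate(REPEAT_CLASSES)}


def _normalize_repeat_class(raw: str) -> str:
    """Map a RepeatMasker class/family string onto the fixed vocabulary."""
    head = raw.split("/")[0].strip().lower()
    if head.startswith("line"):
        return "LINE"
    if head.startswith("sine"):
        return "SINE"
    if head.startswith("dna"):
        return "DNA"
    if head.startswith("satellite"):
        return "satellite"
    return "other"


class AnnotationIntervals:
    """Per-chromosome labelled intervals with priority-aware point lookup."""

    def __init__(self, priority: Optional[Mapping[str, int]] = None) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._priority = dict(priority) if priority else None
        self._warned: set[str] = set()

    def add(self, chrom: str, start: int, end: int, label: str) -> None:
        if end <= start:
            return
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, label)

    def labels_at(self, chrom: str, pos: int) -> list[str]:
        tree = self._trees.get(chrom)
        if tree is None:
            if chrom not in self._warned:
                self._warned.add(chrom)
                warnings.warn(f"chromosome {chrom!r} absent from annotation")
            return []
        return [iv.data for iv in tree.at(pos)]

    def classify(self, chrom: str, pos: int, default: str) -> str:
        labels = self.labels_at(chrom, pos)
        if not labels:
            return default
        if self._priority is None:
            return sorted(labels)[0]
        return min(labels, key=lambda l: self._priority.get(l, len(self._priority)))

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_repeatmasker_out(cls, path: Union[str, Path]) -> "AnnotationIntervals":
        """Parse RepeatMasker ``.out`` (whitespace table, 3 header lines).

        Coordinates in ``.out`` are 1-based inclusive and are converted to
        0-based half-open.
        """
        self = cls(priority=_REPEAT_PRIORITY)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if lineno <= 3 or not line.strip():
                    continue
                fields = line.split()
                if len(fields) < 11:
                    raise ValueError(
                        f"{path}:{lineno}: expected >= 11 whitespace fields"
                    )
                chrom, begin, end = fields[4], int(fields[5]), int(fields[6])
                self.add(chrom, begin - 1, end, _normalize_repeat_class(fields[10]))
        return self

    @classmethod
    def from_bed(cls, path: Union[str, Path]) -> "AnnotationIntervals":
        """Repeat intervals from BED; the name column is the class label."""
        self = cls(priority=_REPEAT_PRIORITY)
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: need >= 4 BED columns")
                label = fields[3]
                if label not in REPEAT_CLASSES:
                    label = _normalize_repeat_class(label)
                self.add(fields[0], int(fields[1]), int(fields[2]), label)
        return self


def annotate_repeat(
    chrom: str, pos: int, repeats: AnnotationIntervals
) -> str:
    """Repeat class at a junction coordinate; ``Ø`` when none overlaps.

    Multiple overlapping repeats resolve by the fixed priority
    LINE > SINE > DNA > satellite > other.
    """
    return repeats.classify(chrom, pos, default=NON_REPETITIVE)


# ---------------------------------------------------------------------------
# genomic features (GFF3)

_PRIORITY_FEATURES = {
    "three_prime_UTR": "3'-UTR",
    "five_prime_UTR": "5'-UTR",
    "start_codon": "other",
    "stop_codon": "other",
    "Selenocysteine": "other",
}
_TIER1_ORDER = {"3'-UTR": 0, "5'-UTR": 1, "other": 2}


class GenomicAnnotation:
    """Tiered genomic-feature lookup built from a GFF3 file.

    Tier 1 holds UTRs and codon-level features, tier 2 exons, tier 3
    introns (explicit ``intron`` features, or derived from the exon
    structure of each transcript when absent). A coordinate is labelled by
    the first tier that covers it; otherwise it is intergenic.
    """

    def __init__(self) -> None:
        self.tier1 = AnnotationIntervals(priority=_TIER1_ORDER)
        self.exons = AnnotationIntervals()
        self.introns = AnnotationIntervals()

    @classmethod
    def from_gff3(cls, path: Union[str, Path]) -> "GenomicAnnotation":
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        self = cls()
        featuretypes = set(db.featuretypes())
        for ftype, label in _PRIORITY_FEATURES.items():
            if ftype not in featuretypes:
                continue
            for feat in db.features_of_type(ftype):
                self.tier1.add(feat.seqid, feat.start - 1, feat.end, label)
        if "exon" in featuretypes:
            for feat in db.features_of_type("exon"):
                self.exons.add(feat.seqid, feat.start - 1, feat.end, "exon")
        if "intron" in featuretypes:
            for feat in db.features_of_type("intron"):
                self.introns.add(feat.seqid, feat.start - 1, feat.end, "intron")
        else:
            for feat in db.create_introns():
                self.introns.add(feat.seqid, feat.start - 1, feat.end, "intron")
        return self

    def classify(self, chrom: str, pos: int) -> str:
        label = self.tier1.classify(chrom, pos, default="")
        if label:
            return label
        if self.exons.labels_at(chrom, pos):
            return "exon"
        if self.introns.labels_at(chrom, pos):
            return "intron"
        return "intergenic"


def annotate_genomic(chrom: str, pos: int, annotation: GenomicAnnotation) -> str:
    """Genomic-element class at a junction coordinate (cascading priority)."""
    return annotation.classify(chrom, pos)


# ---------------------------------------------------------------------------
# stratified benchmarking


def annotate_circle(
    circle: Circle, classify: Callable[[str, int], str]
) -> tuple[str, str]:
    """Class labels of a circle's two junction coordinates (start, end).

    The start-coordinate class is treated as *the* circle's class; the end
    class is reported alongside.
    """
    return classify(circle.chrom, circle.start), classify(circle.chrom, circle.end)


def stratified_benchmark(
    predicted: Sequence[Circle],
    truth: Sequence[Circle],
    classify: Callable[[str, int], str],
    threshold: int = DEFAULT_MATCH_THRESHOLD,
) -> dict[str, BenchmarkReport]:
    """Per-annotation-class benchmark against ground truth.

    Matching is performed once, globally; each truth circle contributes its
    TP/FN to the class of its start junction, and each unmatched prediction
    contributes its FP to its own start-junction class. Classes without any
    truth circle are omitted (with a warning) since recall is undefined
    there.
    """
    if not truth:
        raise ValueError("truth set must be non-empty")
    matches = match_predictions(predicted, truth, threshold)
    matched_truth = {m.truth_index for m in matches}
    matched_pred = {m.pred_index for m in matches}

    truth_class = [classify(t.chrom, t.start) for t in truth]
    tp: dict[str, int] = {}
    fn: dict[str, int] = {}
    fp: dict[str, int] = {}
    for i, cls in enumerate(truth_class):
        bucket = tp if i in matched_truth else fn
        bucket[cls] = bucket.get(cls, 0) + 1
    for i, p in enumerate(predicted):
        if i in matched_pred:
            continue
        cls = classify(p.chrom, p.start)
        fp[cls] = fp.get(cls, 0) + 1

    classes_with_truth = set(truth_class)
    for cls in set(fp) - classes_with_truth:
        warnings.warn(
            f"class {cls!r} has predictions but no truth circles; omitted"
        )
    return {
        cls: BenchmarkReport.from_counts(
            tp.get(cls, 0), fp.get(cls, 0), fn.get(cls, 0)
        )
        for cls in sorted(classes_with_truth)
    }
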