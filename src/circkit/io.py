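"""Readers, writers and data-source adapters.

File formats are plain text throughout: BED for circle lists (0-based
half-open, score column = split-read count), paired FASTQ (Phred+33) for
simulated reads, FASTA for references, key-value manifests for simulation
parameters. Alignment and mappability access go through the small
``AlignmentSource`` / ``MappabilityTrack`` contracts from
:mod:`circkit.deltacj`; adapters are provided for indexed BAM (pysam) and
bigWig (pyBigWig), plus deterministic in-memory fixtures so the full ΔCJ
statistic is testable without any binary file.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

from Bio import SeqIO

from .deltacj import AlignmentRecord
from .model import Circle
from .simulate import ReadPairRecord

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# BED


def read_bed(path: PathLike, tool: Optional[str] = None) -> list[Circle]:
    """Read circles from a BED(3/4/6) file.

    The score column becomes ``split_reads`` when numeric ("." or absence
    means no split information). Malformed lines are reported with their
    line number.
    """
    circles: list[Circle] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: unparseable coordinates {fields[1]!r}, "
                    f"{fields[2]!r}"
                ) from exc
            if start < 0:
                raise ValueError(f"{path}:{lineno}: negative start {start}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            split: Optional[int] = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    split = int(float(fields[4]))
                except ValueError:
                    split = None
            circles.append(
                Circle(fields[0], start, end, split_reads=split, name=name, tool=tool)
            )
    return circles


def write_bed(circles: Sequence[Circle], path: PathLike) -> None:
    """Write circles as BED6 (score = split reads, "." when absent)."""
    with open(path, "w") as fh:
        for c in circles:
            score = "." if c.split_reads is None else str(c.split_reads)
            name = c.name if c.name is not None else "."
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t{score}\t.\n")


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def read_fasta(path: PathLike) -> dict[str, str]:
    """Reference sequences as ``{name: uppercase sequence}``."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(seqs: Mapping[str, str], path: PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(
    records: Iterable[ReadPairRecord], r1_path: PathLike, r2_path: PathLike
) -> None:
    """Write paired reads as two mate-synchronized Phred+33 FASTQ files."""
    with open(r1_path, "w") as fh1, open(r2_path, "w") as fh2:
        for rec in records:
            if len(rec.seq1) != len(rec.qual1) or len(rec.seq2) != len(rec.qual2):
                raise ValueError(f"sequence/quality length mismatch in {rec.name}")
            fh1.write(f"@{rec.name}\n{rec.seq1}\n+\n{rec.qual1}\n")
            fh2.write(f"@{rec.name}\n{rec.seq2}\n+\n{rec.qual2}\n")


def read_fastq_pairs(r1_path: PathLike, r2_path: PathLike) -> list[ReadPairRecord]:
    """Read two mate FASTQ files back into paired records.

    The truth class is recovered from the ``id|index|class`` read-name
    convention when present; mismatched mate names or counts are an error.
    """
    r1 = list(SeqIO.parse(str(r1_path), "fastq"))
    r2 = list(SeqIO.parse(str(r2_path), "fastq"))
    if len(r1) != len(r2):
        raise ValueError(
            f"unpaired FASTQ input: {len(r1)} records in R1, {len(r2)} in R2"
        )
    out = []
    for a, b in zip(r1, r2):
        if a.id != b.id:
            raise ValueError(f"mate name mismatch: {a.id!r} vs {b.id!r}")
        cls = a.id.rsplit("|", 1)[-1] if "|" in a.id else "linear"
        qual1 = "".join(chr(q + 33) for q in a.letter_annotations["phred_quality"])
        qual2 = "".join(chr(q + 33) for q in b.letter_annotations["phred_quality"])
        out.append(ReadPairRecord(a.id, str(a.seq), str(b.seq), qual1, qual2, cls))
    return out


def merge_fastq_files(
    pairs: Sequence[tuple[PathLike, PathLike]],
    out_r1: PathLike,
    out_r2: PathLike,
) -> int:
    """Concatenate several paired FASTQ files, preserving pairing.

    Returns the total number of read pairs written; input files whose mate
    record counts disagree raise an error.
    """
    total = 0
    with open(out_r1, "w") as o1, open(out_r2, "w") as o2:
        for r1_path, r2_path in pairs:
            n1 = _copy_fastq(r1_path, o1)
            n2 = _copy_fastq(r2_path, o2)
            if n1 != n2:
                raise ValueError(
                    f"unpaired input: {r1_path} has {n1} records, {r2_path} has {n2}"
                )
            total += n1
    return total


def _copy_fastq(path: PathLike, out_fh) -> int:
    n_lines = 0
    with open(path) as fh:
        for line in fh:
            out_fh.write(line)
            n_lines += 1
    if n_lines % 4 != 0:
        raise ValueError(f"{path}: truncated FASTQ ({n_lines} lines)")
    return n_lines // 4


# ---------------------------------------------------------------------------
# manifests


def write_manifest(params: Mapping[str, object], path: PathLike) -> None:
    """Plain-text ``key = value`` manifest, keys in insertion order."""
    with open(path, "w") as fh:
        for key, value in params.items():
            fh.write(f"{key} = {value}\n")


def read_manifest(path: PathLike) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or "=" not in line:
                continue
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# alignment / mappability adapters


class FixtureAlignmentSource:
    """Deterministic in-memory ``AlignmentSource`` for tests and examples.

    Holds per-chromosome alignment records with explicit reference spans;
    ``fetch`` returns records overlapping the query window, in coordinate
    order, identically on every call.
    """

    def __init__(self, records: Mapping[str, Sequence[AlignmentRecord]]) -> None:
        self._records = {
            chrom: sorted(
                recs, key=lambda r: (r.reference_start or 0, r.name)
            )
            for chrom, recs in records.items()
        }

    @classmethod
    def from_window_spec(
        cls, windows: Mapping[tuple[str, int, int], Sequence[int]]
    ) -> "FixtureAlignmentSource":
        """Build from ``{(chrom, start, end): [mapq, ...]}`` window specs.

        Each MAPQ becomes one uniquely named read aligned exactly across its
        window.
        """
        per_chrom: dict[str, list[AlignmentRecord]] = {}
        idx = 0
        for (chrom, start, end), mapqs in windows.items():
            for mq in mapqs:
                per_chrom.setdefault(chrom, []).append(
                    AlignmentRecord(f"read{idx:05d}", mq, start, end)
                )
                idx += 1
        return cls(per_chrom)

    def fetch(self, chrom: str, start: int, end: int) -> list[AlignmentRecord]:
        hits = []
        for rec in self._records.get(chrom, []):
            rs = rec.reference_start if rec.reference_start is not None else start
            re = rec.reference_end if rec.reference_end is not None else end
            if rs < end and re > start:
                hits.append(rec)
        return hits


class BamAlignmentSource:
    """``AlignmentSource`` over a coordinate-sorted indexed BAM (pysam).

    Unmapped, secondary and supplementary records are skipped; each primary
    alignment yields its query name, MAPQ and reference span.
    """

    def __init__(self, path: PathLike) -> None:
        import pysam

        self._bam = pysam.AlignmentFile(str(path), "rb")

    def fetch(self, chrom: str, start: int, end: int) -> list[AlignmentRecord]:
        hits = []
        for aln in self._bam.fetch(chrom, max(0, start), end):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            hits.append(
                AlignmentRecord(
                    aln.query_name,
                    aln.mapping_quality,
                    aln.reference_start,
                    aln.reference_end,
                )
            )
        return hits

    def close(self) -> None:
        self._bam.close()


class FixtureMappabilityTrack:
    """In-memory ``MappabilityTrack``: constant default plus interval overrides.

    ``values`` maps ``(chrom, start, end)`` to a mappability in [0, 1];
    queries are answered with the length-weighted mean of overridden and
    default stretches, or ``None`` when ``default`` is ``None`` and no
    override overlaps.
    """

    def __init__(
        self,
        default: Optional[float] = 1.0,
        values: Optional[Mapping[tuple[str, int, int], float]] = None,
    ) -> None:
        if default is not None and not 0.0 <= default <= 1.0:
            raise ValueError("default mappability must be in [0, 1]")
        self._default = default
        self._values = dict(values or {})
        for (_, s, e), v in self._values.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError("mappability values must be in [0, 1]")
            if e <= s:
                raise ValueError("empty mappability interval")

    def mean(self, chrom: str, start: int, end: int) -> Optional[float]:
        if end <= start:
            raise ValueError("empty query interval")
        length = end - start
        covered = 0
        total = 0.0
        for (c, s, e), v in self._values.items():
            if c != chrom:
                continue
            ov = min(e, end) - max(s, start)
            if ov > 0:
                covered += ov
                total += ov * v
        rest = length - covered
        if rest > 0:
            if self._default is None:
                return None if covered == 0 else total / covered
            total += rest * self._default
        return total / length


class BigWigMappabilityTrack:
    """``MappabilityTrack`` over a bigWig file (pyBigWig mean stats)."""

    def __init__(self, path: PathLike) -> None:
        import pyBigWig

        self._bw = pyBigWig.open(str(path))

    def mean(self, chrom: str, start: int, end: int) -> Optional[float]:
        if chrom not in self._bw.chroms():
            return None
        chrom_len = self._bw.chroms()[chrom]
        start, end = max(0, start), min(end, chrom_len)
        if end <= start:
            return None
        value = self._bw.stats(chrom, start, end, type="mean")[0]
        return None if value is None else float(value)

    def close(self) -> None:
        self._bw.close()
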