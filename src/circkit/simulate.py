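"""Paired-end read simulator for circular and linear molecules.

The simulator has three stages, mirroring how circular-element read data is
produced in practice:

``coordinates``
    Sample circle positions on a reference: chromosome chosen with
    probability proportional to its length, circle length drawn from a
    uniform or truncated lognormal distribution, start uniform given the
    length fits.
``reads``
    Generate paired-end reads from each circle treated as a circular
    template. Fragments that wrap around the junction yield split reads
    (read crosses the junction internally) or discordant pairs (junction
    falls between the mates); everything else is concordant. Linear
    background reads are drawn from plain genomic regions and are always
    concordant.
``join``
    Merge circular and linear read streams into one paired FASTQ dataset.

Biological divergence is modelled with a Kimura two-parameter substitution
process applied once per molecule; sequencing noise as an independent
per-base substitution applied per read. The read-pair count per molecule
inverts ``coverage = n_reads * read_length * 2 / molecule_length`` (ceiling),
so realized coverage is never below the requested fold-coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np

from .model import Circle

RngLike = Union[int, np.random.Generator, None]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class LengthDistribution:
    """Circle length model: uniform or lognormal truncated to [min_len, max_len].

    The lognormal is parameterised as ``loc + scale * exp(s * Z)`` with
    ``Z ~ N(0, 1)`` (the scipy ``lognorm(s, loc, scale)`` convention), so its
    untruncated median is ``loc + scale``. Truncation is enforced by
    rejection, not clipping, to avoid probability-mass spikes at the bounds.
    """

    kind: str = "lognormal"
    min_len: int = 175
    max_len: int = 10_000
    s: float = 1.0
    loc: float = 0.0
    scale: float = 1000.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "lognormal"):
            raise ValueError(f"unknown length distribution kind: {self.kind!r}")
        if self.min_len < 1 or self.max_len < self.min_len:
            raise ValueError("require 1 <= min_len <= max_len")
        if self.kind == "lognormal" and (self.s <= 0 or self.scale <= 0):
            raise ValueError("lognormal requires s > 0 and scale > 0")


@dataclass(frozen=True)
class SimulationParams:
    """All simulator knobs.

    ``near_cj_fraction`` is the fraction of fragments whose start is forced
    into the window one insert length upstream of the junction, enriching
    junction-spanning reads; 0 means uniform fragment placement.
    """

    n_circles: int = 1000
    coverage: float = 30.0
    read_length: int = 150
    insert_length: int = 500
    seq_error_rate: float = 0.001
    mutation_rate: float = 0.01
    kimura_kappa: float = 2.0
    near_cj_fraction: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.read_length > self.insert_length:
            raise ValueError("read_length must be <= insert_length")
        for name in ("seq_error_rate", "mutation_rate", "near_cj_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class SimulatedCircle:
    """A simulated circle: coordinates plus (optionally) its sequence."""

    id: str
    chrom: str
    start: int
    end: int
    sequence: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def as_circle(self) -> Circle:
        return Circle(self.chrom, self.start, self.end, name=self.id, tool="truth")


@dataclass(frozen=True)
class ReadPairRecord:
    """One paired-end read with its ground-truth class.

    ``truth_class`` is one of ``concordant``, ``discordant``, ``split`` or
    ``linear`` and is also encoded in the read name as
    ``moleculeID|pairIndex|class`` so evaluation needs no side file.
    """

    name: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    truth_class: str


TRUTH_CLASSES = ("concordant", "discordant", "split", "linear")


# ---------------------------------------------------------------------------
# coordinates


def sample_lengths(dist: LengthDistribution, n: int, rng: RngLike = None) -> np.ndarray:
    """Draw ``n`` integer circle lengths from ``dist`` (rejection-truncated)."""
    rng = _as_rng(rng)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if dist.kind == "uniform":
        return rng.integers(dist.min_len, dist.max_len + 1, size=n)
    out: list[np.ndarray] = []
    got = 0
    while got < n:
        m = max(2 * (n - got), 64)
        draw = dist.loc + dist.scale * np.exp(dist.s * rng.standard_normal(m))
        lens = np.rint(draw).astype(np.int64)
        keep = lens[(lens >= dist.min_len) & (lens <= dist.max_len)]
        out.append(keep)
        got += keep.size
    return np.concatenate(out)[:n]


def sample_coordinates(
    genome: Mapping[str, int],
    n: int,
    dist: LengthDistribution,
    rng: RngLike = None,
) -> list[SimulatedCircle]:
    """Sample ``n`` circle coordinates on a genome of ``{name: length}``.

    Chromosomes are chosen with probability proportional to their length
    (among those that can host ``dist.min_len``); the circle length is drawn
    by rejection until it fits the chromosome, then the start is uniform over
    the admissible positions. Reproducible under a fixed seed.
    """
    rng = _as_rng(rng)
    eligible = [(name, length) for name, length in genome.items() if length >= dist.min_len]
    if not eligible:
        raise ValueError(
            f"no chromosome can host a circle of min_len={dist.min_len}"
        )
    names = [e[0] for e in eligible]
    lengths = np.array([e[1] for e in eligible], dtype=float)
    probs = lengths / lengths.sum()

    circles: list[SimulatedCircle] = []
    for i in range(n):
        chrom_idx = int(rng.choice(len(names), p=probs))
        chrom, chrom_len = names[chrom_idx], int(lengths[chrom_idx])
        while True:
            clen = int(sample_lengths(dist, 1, rng)[0])
            if clen <= chrom_len:
                break
        start = int(rng.integers(0, chrom_len - clen + 1))
        circles.append(SimulatedCircle(f"sim{i:05d}", chrom, start, start + clen))
    return circles


def attach_sequences(
    circles: Sequence[SimulatedCircle], genome_seqs: Mapping[str, str]
) -> list[SimulatedCircle]:
    """Fill each circle's sequence from the reference sequences."""
    out = []
    for c in circles:
        seq = genome_seqs[c.chrom][c.start : c.end]
        out.append(replace(c, sequence=seq.upper()))
    return out


# ---------------------------------------------------------------------------
# mutation & sequencing error

# base codes 0=A 1=C 2=G 3=T; transitions are A<->G and C<->T
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = np.array([2, 3, 0, 1], dtype=np.int8)
# the two transversion partners per base
_TRANSVERSION = np.array([[1, 3], [0, 2], [1, 3], [0, 2]], dtype=np.int8)


def mutate_sequence(
    seq: str, mutation_rate: float, kappa: float = 2.0, rng: RngLike = None
) -> str:
    """Apply Kimura two-parameter substitutions to ``seq``.

    Each A/C/G/T base mutates independently with probability
    ``mutation_rate``; given a mutation, a transition occurs with probability
    ``kappa / (kappa + 2)`` and each transversion with ``1 / (kappa + 2)``.
    ``N`` (and anything non-ACGT) is never touched; length is preserved.
    """
    if mutation_rate == 0 or not seq:
        return seq
    rng = _as_rng(rng)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = _CODE[arr]
    hit = (rng.random(arr.size) < mutation_rate) & (codes >= 0)
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return seq
    p_transition = 1.0 if math.isinf(kappa) else kappa / (kappa + 2.0)
    u = rng.random(idx.size)
    is_ts = u < p_transition
    old = codes[idx]
    new = np.where(
        is_ts,
        _TRANSITION[old],
        _TRANSVERSION[old, (rng.random(idx.size) < 0.5).astype(np.int8)],
    )
    arr[idx] = _DECODE[new]
    return arr.tobytes().decode("ascii")


def apply_sequencing_error(seq: str, seq_error_rate: float, rng: RngLike = None) -> str:
    """Substitute each base with a uniformly random *different* base at the
    given per-base error rate; length preserved, non-ACGT left alone."""
    if seq_error_rate == 0 or not seq:
        return seq
    rng = _as_rng(rng)
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    codes = _CODE[arr]
    hit = (rng.random(arr.size) < seq_error_rate) & (codes >= 0)
    idx = np.nonzero(hit)[0]
    if idx.size == 0:
        return seq
    # shift by 1..3 modulo 4 guarantees a different base
    shift = rng.integers(1, 4, size=idx.size)
    arr[idx] = _DECODE[(codes[idx] + shift) % 4]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# reads


def reads_for_coverage(coverage: float, molecule_length: int, read_length: int) -> int:
    """Read-pair count achieving at least the requested fold-coverage.

    Inverts ``coverage = n_reads * read_length * 2 / molecule_length`` and
    takes the ceiling, so the result is >= 1 and realized coverage is never
    below the request.
    """
    if coverage <= 0 or molecule_length <= 0 or read_length <= 0:
        raise ValueError("coverage, molecule_length and read_length must be > 0")
    return math.ceil(coverage * molecule_length / (2.0 * read_length))


def _classify_pair(start: int, insert: int, read_len: int, circle_len: int) -> str:
    """Truth class of a fragment at linear offset ``start`` on the unrolled
    circular template: split if either read internally crosses a junction
    (multiples of the circle length), discordant if a junction lies inside
    the fragment but outside both reads, else concordant."""
    end = start + insert
    first = (start // circle_len + 1) * circle_len
    for j in range(first, end, circle_len):
        if start < j < start + read_len or end - read_len < j < end:
            return "split"
    for j in range(first, end, circle_len):
        if start < j < end:
            return "discordant"
    return "concordant"


def simulate_circle_reads(
    circle: SimulatedCircle,
    params: SimulationParams,
    rng: RngLike = None,
    apply_mutation: bool = True,
) -> list[ReadPairRecord]:
    """Generate paired-end reads from one circle treated as circular template.

    Fragment starts are uniform on the circle, except that a
    ``near_cj_fraction`` share is forced to start within one insert length
    upstream of the junction. Read 1 is the first ``read_length`` bases of
    the fragment; read 2 the reverse complement of its last ``read_length``
    bases. Fragments longer than the circle wrap as many times as needed.
    """
    if circle.sequence is None:
        raise ValueError("circle has no sequence attached")
    L = len(circle.sequence)
    if L != circle.length:
        raise ValueError("sequence length does not match coordinates")
    if L < params.read_length:
        raise ValueError(f"circle {circle.id} shorter than read length")
    rng = _as_rng(rng)

    template = circle.sequence
    if apply_mutation and params.mutation_rate > 0:
        template = mutate_sequence(template, params.mutation_rate, params.kimura_kappa, rng)

    insert = params.insert_length
    rl = params.read_length
    reps = insert // L + 2
    tiled = template * reps
    n_pairs = reads_for_coverage(params.coverage, L, rl)
    qual = "I" * rl

    records: list[ReadPairRecord] = []
    window = min(insert, L)
    for j in range(n_pairs):
        if params.near_cj_fraction > 0 and rng.random() < params.near_cj_fraction:
            s = (L - window + int(rng.integers(0, window))) % L
        else:
            s = int(rng.integers(0, L))
        frag = tiled[s : s + insert]
        cls = _classify_pair(s, insert, rl, L)
        r1 = apply_sequencing_error(frag[:rl], params.seq_error_rate, rng)
        r2 = apply_sequencing_error(
            reverse_complement(frag[-rl:]), params.seq_error_rate, rng
        )
        records.append(
            ReadPairRecord(f"{circle.id}|{j}|{cls}", r1, r2, qual, qual, cls)
        )
    return records


def simulate_linear_reads(
    name: str,
    sequence: str,
    params: SimulationParams,
    rng: RngLike = None,
    apply_mutation: bool = True,
) -> list[ReadPairRecord]:
    """Concordant background read pairs from a linear region.

    Fragment starts are uniform on ``[0, region_length - insert_length]`` so
    no fragment runs off the end; every pair's truth class is ``linear``.
    """
    L = len(sequence)
    if L < params.insert_length:
        raise ValueError("region shorter than insert length")
    rng = _as_rng(rng)
    template = sequence.upper()
    if apply_mutation and params.mutation_rate > 0:
        template = mutate_sequence(template, params.mutation_rate, params.kimura_kappa, rng)
    insert, rl = params.insert_length, params.read_length
    n_pairs = reads_for_coverage(params.coverage, L, rl)
    qual = "I" * rl
    records = []
    for j in range(n_pairs):
        s = int(rng.integers(0, L - insert + 1))
        frag = template[s : s + insert]
        r1 = apply_sequencing_error(frag[:rl], params.seq_error_rate, rng)
        r2 = apply_sequencing_error(reverse_complement(frag[-rl:]), params.seq_error_rate, rng)
        records.append(ReadPairRecord(f"{name}|{j}|linear", r1, r2, qual, qual, "linear"))
    return records


def join_fastqs(
    *record_sets: Iterable[ReadPairRecord],
) -> list[ReadPairRecord]:
    """Merge read-pair streams (e.g. circular + linear) preserving order."""
    merged: list[ReadPairRecord] = []
    for rs in record_sets:
        merged.extend(rs)
    return merged


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(
    genome_seqs: Mapping[str, str],
    params: SimulationParams,
    dist: LengthDistribution,
    rng: RngLike = None,
) -> tuple[list[SimulatedCircle], list[ReadPairRecord]]:
    """Full circular-read simulation: coordinates, sequences, reads.

    Returns the truth circles and all read pairs; byte-identical outputs for
    a fixed seed.
    """
    rng = _as_rng(rng if rng is not None else params.seed)
    genome_lengths = {name: len(seq) for name, seq in genome_seqs.items()}
    circles = sample_coordinates(genome_lengths, params.n_circles, dist, rng)
    circles = attach_sequences(circles, genome_seqs)
    records: list[ReadPairRecord] = []
    for c in circles:
        records.extend(simulate_circle_reads(c, params, rng))
    return circles, records
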