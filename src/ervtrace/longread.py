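"""KoRV integration calling from inverse-PCR long reads.

Viral segments are located in each read by k-mer similarity search against
the provided KoRV strain sequences and excised; the remaining host flanks
are aligned to the host assembly, filtered (length > 50 bp, identity >= 90%,
mapq >= 30), and their junction-side termini binned into breakpoint peaks
(support > 10 reads). Left/right peaks pair within the 10 bp TSD window, or
across up to 1,411 bp of annotation-masked sequence (the recKoRV allowance).
Paired integrations are classified endogenous vs somatic by read support
against a per-sample threshold (default 500 reads).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io import Interval

DEFAULT_MIN_FLANK_LEN = 50  # strict: matches must exceed this
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_MAPQ = 30
DEFAULT_MIN_PEAK = 10  # strict: peaks need more reads than this
DEFAULT_TSD_WINDOW = 10
DEFAULT_MAX_MASKED_GAP = 1411
DEFAULT_ENDOGENOUS_MIN = 500


@dataclass(frozen=True)
class Flank:
    read_id: str
    sequence: str
    read_start: int  # offset of the flank within the original read
    read_end: int
    side: str  # "left": host left of the virus in the read; else "right"


@dataclass(frozen=True)
class FlankAlignment:
    read_id: str
    host_contig: str
    host_start0: int
    host_end0: int
    match_length: int
    identity: float
    mapq: int
    side: str

    @property
    def terminus0(self) -> int:
        """Junction-side terminus: end for left flanks, start for right."""
        return self.host_end0 if self.side == "left" else self.host_start0


@dataclass(frozen=True)
class BreakpointPeak:
    contig: str
    pos0: int
    support: int
    side: str


@dataclass
class PairedIntegration:
    contig: str
    left: BreakpointPeak
    right: BreakpointPeak
    via_masked_gap: bool = False
    label: str | None = None

    def support(self, aggregate: str = "sum") -> int:
        a, b = self.left.support, self.right.support
        if aggregate == "sum":
            return a + b
        if aggregate == "max":
            return max(a, b)
        if aggregate == "min":
            return min(a, b)
        raise ValueError(f"unknown aggregation {aggregate!r}")


@dataclass
class SampleThresholds:
    endogenous_min_reads: int = DEFAULT_ENDOGENOUS_MIN
    per_sample_overrides: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.endogenous_min_reads <= 0 or any(
            v <= 0 for v in self.per_sample_overrides.values()
        ):
            raise ValueError("thresholds must be > 0")

    def for_sample(self, sample_id: str | None) -> int:
        if sample_id in self.per_sample_overrides:
            return self.per_sample_overrides[sample_id]
        return self.endogenous_min_reads


# ------------------------------------------------- viral-segment excision


def _kmer_set(seqs: Iterable[str], k: int) -> set[str]:
    kmers: set[str] = set()
    for seq in seqs:
        seq = seq.upper()
        for i in range(len(seq) - k + 1):
            kmers.add(seq[i : i + k])
    return kmers


def find_viral_segments(
    read_seq: str,
    viral_kmers: set[str],
    k: int = 21,
    merge_gap: int = 50,
    min_len: int = 50,
) -> list[tuple[int, int]]:
    """Maximal viral-matching intervals (half-open) within a read."""
    seq = read_seq.upper()
    hits = [
        i for i in range(len(seq) - k + 1) if seq[i : i + k] in viral_kmers
    ]
    intervals: list[tuple[int, int]] = []
    for i in hits:
        if intervals and i <= intervals[-1][1] + merge_gap:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], i + k))
        else:
            intervals.append((i, i + k))
    return [(s, e) for s, e in intervals if e - s >= min_len]


def excise_viral_segments(
    read_id: str,
    read_seq: str,
    viral_references: Mapping[str, str] | set[str],
    k: int = 21,
) -> list[Flank]:
    """Remove viral segments from a read, keeping host flanks with offsets.

    Reads without any viral match are discarded (empty list). A flank's side
    records where the virus lay relative to it in the read.
    """
    if isinstance(viral_references, set):
        viral_kmers = viral_references
    else:
        viral_kmers = _kmer_set(viral_references.values(), k)
    segments = find_viral_segments(read_seq, viral_kmers, k=k)
    if not segments:
        return []
    flanks: list[Flank] = []
    prev_end = 0
    for vi, (s, e) in enumerate(segments):
        if s - prev_end >= 1:
            flanks.append(
                Flank(read_id, read_seq[prev_end:s], prev_end, s, "left")
            )
        prev_end = e
    if len(read_seq) - prev_end >= 1:
        flanks.append(
            Flank(read_id, read_seq[prev_end:], prev_end, len(read_seq), "right")
        )
    return flanks


def build_viral_kmers(
    viral_references: Mapping[str, str], k: int = 21
) -> set[str]:
    return _kmer_set(viral_references.values(), k)


# ------------------------------------------------- flank alignment


class HostIndex:
    """Exact k-mer index over host contigs for seeding flank placement."""

    def __init__(self, reference: Mapping[str, str], k: int = 21):
        self.k = k
        self.reference = {c: s.upper() for c, s in reference.items()}
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for contig, seq in self.reference.items():
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].append((contig, i))

    def locate(self, seq: str) -> tuple[str, int, int, float] | None:
        """Best placement (contig, start, matched bases, identity)."""
        seq = seq.upper()
        if len(seq) < self.k:
            return None
        hits = self.index.get(seq[: self.k])
        for contig, pos in hits or ():
            ref = self.reference[contig]
            window = ref[pos : pos + len(seq)]
            if len(window) < len(seq):
                continue
            matches = sum(a == b for a, b in zip(seq, window))
            return contig, pos, len(seq), matches / len(seq)
        return None


def align_flanks(
    flanks: Sequence[Flank], host_index: HostIndex, mapq: int = 60
) -> list[FlankAlignment]:
    out = []
    for fl in flanks:
        placed = host_index.locate(fl.sequence)
        if placed is None:
            continue
        contig, start, length, identity = placed
        out.append(
            FlankAlignment(
                read_id=fl.read_id,
                host_contig=contig,
                host_start0=start,
                host_end0=start + length,
                match_length=length,
                identity=identity,
                mapq=mapq,
                side=fl.side,
            )
        )
    return out


def filter_flanks(
    alignments: Sequence[FlankAlignment],
    min_len: int = DEFAULT_MIN_FLANK_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> list[FlankAlignment]:
    """Length strictly > 50 bp; identity >= 0.90; mapq >= 30."""
    return [
        a
        for a in alignments
        if a.match_length > min_len
        and a.identity >= min_identity
        and a.mapq >= min_mapq
    ]


# ------------------------------------------------- peaks and pairing


def call_breakpoint_peaks(
    flanks: Sequence[FlankAlignment],
    min_support: int = DEFAULT_MIN_PEAK,
    merge_radius: int = 5,
) -> list[BreakpointPeak]:
    """Bin junction-side flank termini into coverage peaks (support > 10).

    Termini within ``merge_radius`` bp on the same side merge into a single
    peak at the modal position — junction base ambiguity jitters termini by
    a few bases.
    """
    by_group: dict[tuple[str, str], Counter] = defaultdict(Counter)
    for f in flanks:
        by_group[(f.host_contig, f.side)][f.terminus0] += 1
    peaks: list[BreakpointPeak] = []
    for (contig, side), counts in by_group.items():
        positions = sorted(counts)
        chain: list[int] = []
        for pos in positions + [None]:
            if chain and (pos is None or pos - chain[-1] > merge_radius):
                support = sum(counts[p] for p in chain)
                if support > min_support:
                    modal = max(chain, key=lambda p: (counts[p], -p))
                    peaks.append(BreakpointPeak(contig, modal, support, side))
                chain = []
            if pos is not None:
                chain.append(pos)
    return sorted(peaks, key=lambda p: (p.contig, p.pos0, p.side))


def _masked_gap_allowed(
    left: int, right: int, masked: Sequence[Interval], contig: str, tol: int
) -> bool:
    lo, hi = min(left, right), max(left, right)
    for iv in masked:
        if iv.contig == contig and iv.start0 <= lo + tol and iv.end0 >= hi - tol:
            return True
    return False


def pair_breakpoints(
    peaks: Sequence[BreakpointPeak],
    tsd_window: int = DEFAULT_TSD_WINDOW,
    max_masked_gap: int = DEFAULT_MAX_MASKED_GAP,
    masked_intervals: Sequence[Interval] = (),
) -> tuple[list[PairedIntegration], list[BreakpointPeak]]:
    """Pair left and right peaks into integrations.

    A pair forms when the breakpoints overlap within the TSD window, or when
    separated by at most ``max_masked_gap`` bp of annotation-masked sequence.
    Returns (paired integrations, unpaired peaks).
    """
    lefts = [p for p in peaks if p.side == "left"]
    rights = [p for p in peaks if p.side == "right"]
    used_right: set[int] = set()
    pairs: list[PairedIntegration] = []
    for lp in lefts:
        best = None
        for idx, rp in enumerate(rights):
            if idx in used_right or rp.contig != lp.contig:
                continue
            gap = abs(lp.pos0 - rp.pos0)
            if gap <= tsd_window:
                via_mask = False
            elif gap <= max_masked_gap and _masked_gap_allowed(
                lp.pos0, rp.pos0, masked_intervals, lp.contig, tsd_window
            ):
                via_mask = True
            else:
                continue
            if best is None or gap < best[0]:
                best = (gap, idx, via_mask)
        if best is not None:
            _, idx, via_mask = best
            used_right.add(idx)
            pairs.append(
                PairedIntegration(
                    contig=lp.contig,
                    left=lp,
                    right=rights[idx],
                    via_masked_gap=via_mask,
                )
            )
    paired_left_ids = {id(p.left) for p in pairs}
    unpaired = [p for p in lefts if id(p) not in paired_left_ids]
    unpaired += [p for i, p in enumerate(rights) if i not in used_right]
    return pairs, unpaired


def classify_endogenous(
    integrations: Sequence[PairedIntegration],
    thresholds: SampleThresholds,
    sample_id: str | None = None,
    aggregate: str = "min",
) -> list[PairedIntegration]:
    """Label each paired integration endogenous or somatic by read support.

    The default aggregation is ``min``: the threshold must hold at both
    breakpoints. ``sum`` and ``max`` are available for sensitivity checks.
    """
    cutoff = thresholds.for_sample(sample_id)
    for integ in integrations:
        integ.label = (
            "endogenous" if integ.support(aggregate) >= cutoff else "somatic"
        )
    return list(integrations)
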