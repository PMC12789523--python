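"""Short-read integration-site discovery.

Evidence comes in two classes: *anchored mates* (read pairs with one mate on
a viral reference and the other on the masked host assembly) and *soft-clips*
(host-aligned clipped segments longer than 20 bp from reads partially aligned
to a viral reference). Evidence is clustered per family and contig by
single-linkage chaining on sorted positions, and soft-clip termini vote for
the exact breakpoint.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pysam

from .io import Interval

DEFAULT_MIN_CLUSTER_READS = 20
DEFAULT_GAP_KORV = 500
DEFAULT_GAP_OTHER = 9000
DEFAULT_MIN_CLIP = 20
DEFAULT_MIN_MAPQ = 30

KORV_FAMILY = "KoRV"


class UnknownReferenceError(KeyError):
    pass


@dataclass(frozen=True)
class ViralEvidence:
    read_id: str
    evidence_class: str  # "anchored_mate" | "softclip"
    family: str
    host_contig: str
    host_pos0: int  # leftmost aligned host base
    clip_length: int | None = None  # softclip only
    mapq: int = 0
    terminus0: int | None = None  # junction-side terminus, softclip only


@dataclass
class EvidenceCluster:
    family: str
    contig: str
    min_pos0: int
    max_pos0: int
    n_reads: int
    read_ids: list[str]
    softclip_terminus_histogram: Counter = field(default_factory=Counter)


@dataclass
class IntegrationSite:
    site_id: str
    family: str
    contig: str
    novel_flag: bool
    breakpoint0: int | None = None  # novel sites
    start0: int | None = None  # known sites
    end0: int | None = None
    support: int = 0
    low_confidence: bool = False
    span_start0: int | None = None  # evidence-cluster span, used for sharing
    span_end0: int | None = None

    def position0(self) -> int:
        return self.breakpoint0 if self.novel_flag else self.start0

    def span(self) -> tuple[int, int]:
        if self.span_start0 is not None:
            return self.span_start0, self.span_end0
        if self.novel_flag:
            return self.breakpoint0, self.breakpoint0 + 1
        return self.start0, self.end0


@dataclass
class RegistryEntry:
    site_id: str
    family: str
    contig: str
    start0: int
    end0: int
    carriers: list[str]
    representative: IntegrationSite


def collapse_family(
    reference_name: str, reference_families: Mapping[str, str]
) -> tuple[str, str]:
    """Map a viral reference name to (family, sub-strain).

    All KoRV strains collapse to the single "KoRV" family; the strain name is
    retained for reporting only.
    """
    if reference_name not in reference_families:
        raise UnknownReferenceError(
            f"unknown viral reference {reference_name!r}; configured: "
            f"{sorted(reference_families)}"
        )
    return reference_families[reference_name], reference_name


def substrain_fractions(counts: Mapping[str, int]) -> dict[str, float]:
    total = sum(counts.values())
    if total == 0:
        return {}
    return {k: v / total for k, v in counts.items()}


def _clip_info(rec: pysam.AlignedSegment) -> tuple[int, int]:
    """(leading clip, trailing clip) lengths from the CIGAR."""
    cig = rec.cigartuples or []
    lead = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
    trail = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
    return lead, trail


def extract_evidence(
    virus_alignments: Iterable[pysam.AlignedSegment],
    host_alignments: Iterable[pysam.AlignedSegment],
    reference_families: Mapping[str, str],
    min_clip: int = DEFAULT_MIN_CLIP,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[list[ViralEvidence], int]:
    """Pair viral-side and host-side alignments into evidence records.

    Returns (evidence, n_skipped) where n_skipped counts virus-side records
    lacking usable mate or host information.
    """
    host_by_read: dict[str, pysam.AlignedSegment] = {}
    for rec in host_alignments:
        if rec.is_unmapped:
            continue
        host_by_read[rec.query_name] = rec

    evidence: list[ViralEvidence] = []
    skipped = 0
    virus_list = list(virus_alignments)
    mapped_mates = {}  # read_id -> viral reference of the mapped mate
    for rec in virus_list:
        if not rec.is_unmapped and rec.is_paired:
            mapped_mates[rec.query_name] = rec.reference_name

    for rec in virus_list:
        if rec.is_unmapped:
            # anchored-mate candidate: this read is unmapped on the viral
            # reference but its mate aligned to a virus
            ref = mapped_mates.get(rec.query_name)
            if ref is None:
                skipped += 1
                continue
            host = host_by_read.get(rec.query_name + "/host") or host_by_read.get(
                rec.query_name
            )
            if host is None or host.mapping_quality < min_mapq:
                continue
            family, _ = collapse_family(ref, reference_families)
            evidence.append(
                ViralEvidence(
                    read_id=rec.query_name,
                    evidence_class="anchored_mate",
                    family=family,
                    host_contig=host.reference_name,
                    host_pos0=host.reference_start,
                    mapq=host.mapping_quality,
                )
            )
        else:
            lead, trail = _clip_info(rec)
            clip = max(lead, trail)
            if clip <= min_clip:  # "exceeding 20 bp" is strict
                continue
            host = host_by_read.get(rec.query_name + "/clip") or host_by_read.get(
                rec.query_name
            )
            if host is None or host.mapping_quality < min_mapq:
                continue
            family, _ = collapse_family(rec.reference_name, reference_families)
            # the clipped segment's junction-side terminus: if the host part
            # precedes the virus in the read (leading clip on the viral
            # alignment), the junction is at the host segment's end
            terminus = (
                host.reference_end if lead >= trail else host.reference_start
            )
            evidence.append(
                ViralEvidence(
                    read_id=rec.query_name,
                    evidence_class="softclip",
                    family=family,
                    host_contig=host.reference_name,
                    host_pos0=host.reference_start,
                    clip_length=clip,
                    mapq=host.mapping_quality,
                    terminus0=terminus,
                )
            )
    return evidence, skipped


def gap_for_family(family: str, gap_by_family: Mapping[str, int] | None = None) -> int:
    gaps = dict(gap_by_family or {})
    if family in gaps:
        return gaps[family]
    return DEFAULT_GAP_KORV if family == KORV_FAMILY else gaps.get(
        "*", DEFAULT_GAP_OTHER
    )


def cluster_evidence(
    evidence: Sequence[ViralEvidence],
    min_reads: int = DEFAULT_MIN_CLUSTER_READS,
    gap_by_family: Mapping[str, int] | None = None,
) -> list[EvidenceCluster]:
    """Single-linkage chaining of evidence positions per (family, contig).

    Consecutive sorted positions at most ``gap`` apart join one cluster;
    clusters supported by fewer than ``min_reads`` records are discarded.
    """
    by_group: dict[tuple[str, str], list[ViralEvidence]] = defaultdict(list)
    for ev in evidence:
        by_group[(ev.family, ev.host_contig)].append(ev)

    clusters: list[EvidenceCluster] = []
    for (family, contig), group in sorted(by_group.items()):
        gap = gap_for_family(family, gap_by_family)
        group.sort(key=lambda e: e.host_pos0)
        chain: list[ViralEvidence] = []
        for ev in group:
            if chain and ev.host_pos0 - chain[-1].host_pos0 > gap:
                clusters.extend(
                    _finalize_chain(family, contig, chain, min_reads)
                )
                chain = []
            chain.append(ev)
        clusters.extend(_finalize_chain(family, contig, chain, min_reads))
    return clusters


def _finalize_chain(
    family: str, contig: str, chain: list[ViralEvidence], min_reads: int
) -> list[EvidenceCluster]:
    if len(chain) < min_reads:
        return []
    hist = Counter(
        ev.terminus0
        for ev in chain
        if ev.evidence_class == "softclip" and ev.terminus0 is not None
    )
    return [
        EvidenceCluster(
            family=family,
            contig=contig,
            min_pos0=chain[0].host_pos0,
            max_pos0=chain[-1].host_pos0,
            n_reads=len(chain),
            read_ids=[ev.read_id for ev in chain],
            softclip_terminus_histogram=hist,
        )
    ]


def resolve_breakpoint(
    cluster: EvidenceCluster,
    known_intervals: Sequence[Interval] = (),
    site_id: str | None = None,
) -> IntegrationSite:
    """Resolve a cluster to an integration site.

    A cluster overlapping a known-ERV annotation interval becomes a known
    site with the annotated start/end; otherwise the modal soft-clip terminus
    is the novel breakpoint (ties break toward the smaller coordinate).
    """
    sid = site_id or f"{cluster.family}:{cluster.contig}:{cluster.min_pos0}"
    for iv in known_intervals:
        if iv.contig == cluster.contig and not (
            cluster.max_pos0 + 1 <= iv.start0 or iv.end0 <= cluster.min_pos0
        ):
            return IntegrationSite(
                site_id=sid,
                family=cluster.family,
                contig=cluster.contig,
                novel_flag=False,
                start0=iv.start0,
                end0=iv.end0,
                support=cluster.n_reads,
                span_start0=min(cluster.min_pos0, iv.start0),
                span_end0=max(cluster.max_pos0 + 1, iv.end0),
            )
    hist = cluster.softclip_terminus_histogram
    if hist:
        best = max(hist.items(), key=lambda kv: (kv[1], -kv[0]))[0]
        low_conf = False
    else:
        best = (cluster.min_pos0 + cluster.max_pos0) // 2
        low_conf = True
    return IntegrationSite(
        site_id=sid,
        family=cluster.family,
        contig=cluster.contig,
        novel_flag=True,
        breakpoint0=best,
        support=cluster.n_reads,
        low_confidence=low_conf,
        span_start0=cluster.min_pos0,
        span_end0=cluster.max_pos0 + 1,
    )


def merge_sites_across_individuals(
    per_individual: Mapping[str, Sequence[IntegrationSite]],
) -> list[RegistryEntry]:
    """Collapse overlapping same-family sites into a shared registry.

    Entries are maximal: the transitive closure of pairwise span overlap.
    """
    items: list[tuple[str, IntegrationSite]] = []
    for indiv, sites in per_individual.items():
        for site in sites:
            items.append((indiv, site))

    by_group: dict[tuple[str, str], list[tuple[str, IntegrationSite]]] = defaultdict(
        list
    )
    for indiv, site in items:
        by_group[(site.family, site.contig)].append((indiv, site))

    registry: list[RegistryEntry] = []
    for (family, contig), group in sorted(by_group.items()):
        group.sort(key=lambda t: t[1].span())
        current: list[tuple[str, IntegrationSite]] = []
        cur_end = None
        for indiv, site in group:
            s, e = site.span()
            if current and s >= cur_end:  # half-open: touching does not overlap
                registry.append(_registry_entry(family, contig, current))
                current = []
                cur_end = None
            current.append((indiv, site))
            cur_end = e if cur_end is None else max(cur_end, e)
        if current:
            registry.append(_registry_entry(family, contig, current))
    return registry


def _registry_entry(
    family: str, contig: str, members: list[tuple[str, IntegrationSite]]
) -> RegistryEntry:
    start = min(s.span()[0] for _, s in members)
    end = max(s.span()[1] for _, s in members)
    rep = max(members, key=lambda t: t[1].support)[1]
    carriers = sorted({indiv for indiv, _ in members})
    return RegistryEntry(
        site_id=f"{family}:{contig}:{start}-{end}",
        family=family,
        contig=contig,
        start0=start,
        end0=end,
        carriers=carriers,
        representative=rep,
    )
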