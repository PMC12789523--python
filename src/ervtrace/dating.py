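"""Germline SNV mutation-rate estimation and LTR-divergence dating.

Per-generation rate: total de novo SNVs over trios divided by
(n_trios x haploid assembly length x 2) — the x2 yields the diploid length.
Per-year rate: each trio's de novo count is first divided by the arithmetic
mean parental age. Colonization time of a provirus follows from the
p-distance between its 5' and 3' LTRs, which were identical at integration:
time = divergence / (2 x per-year rate).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import pysam
from Bio import Align


@dataclass(frozen=True)
class TrioSnvRecord:
    contig: str
    pos1: int  # 1-based, VCF convention
    sire_gt: tuple[int, int]
    dam_gt: tuple[int, int]
    joey_gt: tuple[int, int]
    depth: int | None
    genotype_quality: float | None
    allele_balance: float | None


@dataclass
class MutationRateEstimate:
    per_generation: float
    per_year: float | None
    n_trios: int
    n_denovo_total: int
    haploid_length: int


@dataclass
class ColonizationEstimate:
    ltr_divergence: float
    per_year_rate: float
    time_years: float


DEFAULT_MIN_DP = 20
DEFAULT_MIN_GQ = 20
DEFAULT_MIN_AB = 0.4

_HOM_REF = (0, 0)


def _is_het(gt: tuple[int, int]) -> bool:
    return gt[0] != gt[1]


def filter_de_novo_snvs(
    records: Sequence[TrioSnvRecord],
    min_dp: int = DEFAULT_MIN_DP,
    min_gq: float = DEFAULT_MIN_GQ,
    min_ab: float = DEFAULT_MIN_AB,
) -> tuple[list[TrioSnvRecord], int]:
    """De novo candidates passing the trio quality filter.

    Keeps records where the joey is heterozygous for an allele absent from
    both (hom-ref) parents and DP/GQ/AB all meet their inclusive thresholds.
    Records missing any quality field are excluded and counted; returns
    (passing records, n_excluded_missing).
    """
    passing = []
    n_missing = 0
    for rec in records:
        if not (
            _is_het(rec.joey_gt)
            and rec.sire_gt == _HOM_REF
            and rec.dam_gt == _HOM_REF
        ):
            continue
        if rec.depth is None or rec.genotype_quality is None or rec.allele_balance is None:
            n_missing += 1
            continue
        if (
            rec.depth >= min_dp
            and rec.genotype_quality >= min_gq
            and rec.allele_balance >= min_ab
        ):
            passing.append(rec)
    return passing, n_missing


def rate_per_generation(
    n_denovo_by_trio: Sequence[int], haploid_length: int
) -> float:
    if haploid_length <= 0:
        raise ValueError("haploid_length must be > 0")
    n_trios = len(n_denovo_by_trio)
    if n_trios == 0:
        raise ValueError("at least one trio required")
    return sum(n_denovo_by_trio) / (n_trios * haploid_length * 2)


def rate_per_year(
    n_denovo_by_trio: Sequence[int],
    parental_ages: Sequence[tuple[float, float]],
    haploid_length: int,
) -> float:
    """Per-year rate: per-trio counts scaled by mean parental age."""
    if haploid_length <= 0:
        raise ValueError("haploid_length must be > 0")
    n_trios = len(n_denovo_by_trio)
    if n_trios == 0 or len(parental_ages) != n_trios:
        raise ValueError("one (sire age, dam age) pair per trio required")
    total = 0.0
    for n, (age_sire, age_dam) in zip(n_denovo_by_trio, parental_ages):
        if age_sire <= 0 or age_dam <= 0:
            raise ValueError("parental ages must be > 0")
        total += n / ((age_sire + age_dam) / 2)
    return total / (n_trios * haploid_length * 2)


def estimate_mutation_rates(
    n_denovo_by_trio: Sequence[int],
    parental_ages: Sequence[tuple[float, float]] | None,
    haploid_length: int,
) -> MutationRateEstimate:
    return MutationRateEstimate(
        per_generation=rate_per_generation(n_denovo_by_trio, haploid_length),
        per_year=rate_per_year(n_denovo_by_trio, parental_ages, haploid_length)
        if parental_ages is not None
        else None,
        n_trios=len(n_denovo_by_trio),
        n_denovo_total=int(sum(n_denovo_by_trio)),
        haploid_length=haploid_length,
    )


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    # concave-ish gap cost keeps indels contiguous, which matters because a
    # contiguous indel counts as a single difference
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -0.5
    return aligner


def ltr_divergence(ltr5_seq: str, ltr3_seq: str) -> float:
    """p-distance between the two LTRs of one provirus.

    Global pairwise alignment; differences = substitution columns plus one
    per contiguous indel; length = matched/mismatched columns plus one per
    indel event (a 1-bp indel in 999 identical bases gives 1/1000 = 0.001).
    """
    if not ltr5_seq or not ltr3_seq:
        raise ValueError("empty LTR sequence")
    s5, s3 = ltr5_seq.upper(), ltr3_seq.upper()
    aln = _pairwise_aligner().align(s5, s3)[0]
    a, b = aln[0], aln[1]
    subs = aligned_cols = gap_events = 0
    in_gap = False
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            if not in_gap:
                gap_events += 1
                in_gap = True
            continue
        in_gap = False
        aligned_cols += 1
        if x != y:
            subs += 1
    length = aligned_cols + gap_events
    if length == 0:
        raise ValueError("no aligned columns")
    return (subs + gap_events) / length


def colonization_time(divergence: float, per_year_rate: float) -> float:
    """Years since germline colonization: divergence / (2 x per-year rate)."""
    if per_year_rate <= 0:
        raise ValueError("per_year_rate must be > 0")
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    return divergence / (2 * per_year_rate)


def estimate_colonization(
    divergence: float, per_year_rate: float
) -> ColonizationEstimate:
    return ColonizationEstimate(
        ltr_divergence=divergence,
        per_year_rate=per_year_rate,
        time_years=colonization_time(divergence, per_year_rate),
    )


# ---------------------------------------------------------------- VCF I/O


def read_trio_vcf(
    path: str | os.PathLike, sire: str, dam: str, joey: str
) -> list[TrioSnvRecord]:
    """Load trio SNV records from a VCF with GT/DP/GQ and AD or AB fields.

    Allele balance for joey-het calls is taken from AB when present,
    otherwise computed as alt depth / total AD depth.
    """
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            def gt(sample):
                g = rec.samples[sample].get("GT")
                if g is None or any(x is None for x in g):
                    return None
                return tuple(int(x) for x in g)

            gts = {s: gt(s) for s in (sire, dam, joey)}
            if any(v is None for v in gts.values()):
                continue
            fmt = rec.samples[joey]
            ab = fmt.get("AB")
            if isinstance(ab, tuple):
                ab = ab[0] if ab else None
            if ab is None:
                ad = fmt.get("AD")
                if ad is not None and sum(a or 0 for a in ad) > 0:
                    ab = (ad[1] or 0) / sum(a or 0 for a in ad)
            out.append(
                TrioSnvRecord(
                    contig=rec.chrom,
                    pos1=rec.pos,
                    sire_gt=gts[sire],
                    dam_gt=gts[dam],
                    joey_gt=gts[joey],
                    depth=fmt.get("DP"),
                    genotype_quality=fmt.get("GQ"),
                    allele_balance=float(ab) if ab is not None else None,
                )
            )
    return out


def write_trio_vcf(
    records: Sequence[TrioSnvRecord],
    contig_lengths,
    sire: str,
    dam: str,
    joey: str,
    path: str | os.PathLike,
) -> None:
    hdr = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        hdr.contigs.add(contig, length=length)
    hdr.formats.add("GT", 1, "String", "Genotype")
    hdr.formats.add("DP", 1, "Integer", "Read depth")
    hdr.formats.add("GQ", 1, "Integer", "Genotype quality")
    hdr.formats.add("AD", "R", "Integer", "Allelic depths")
    for s in (sire, dam, joey):
        hdr.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=hdr) as vcf:
        for rec in sorted(records, key=lambda r: (r.contig, r.pos1)):
            vrec = vcf.new_record(
                contig=rec.contig, start=rec.pos1 - 1, alleles=("A", "G")
            )
            for sample, gt in (
                (sire, rec.sire_gt),
                (dam, rec.dam_gt),
                (joey, rec.joey_gt),
            ):
                vrec.samples[sample]["GT"] = gt
            fmt = vrec.samples[joey]
            if rec.depth is not None:
                fmt["DP"] = int(rec.depth)
                ab = rec.allele_balance if rec.allele_balance is not None else 0.5
                alt = int(round(rec.depth * ab))
                fmt["AD"] = (int(rec.depth) - alt, alt)
            if rec.genotype_quality is not None:
                fmt["GQ"] = int(rec.genotype_quality)
            vcf.write(vrec)
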