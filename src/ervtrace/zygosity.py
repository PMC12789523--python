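"""Read-ratio zygosity genotyping and population genotype QC.

The integration is the alternative allele; its absence is the reference
allele. At a novel site, reads soft-clipped within the TSD margin of the
breakpoint support the integration and reads spanning beyond the margin
support the pre-integration allele. With f the soft-clipped fraction,
f > 0.7 calls homozygous-alt, 0.3 <= f <= 0.7 heterozygous, and f < 0.3
undetermined (-1). At known sites (the reference assembly carries the ERV)
the orientation flips: crossing reads support the integration allele.

Ratio comparisons use exact integer arithmetic so the inclusive 30/70%
boundaries are never blurred by floating point.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy.stats import binom

from .io import Pedigree

DEFAULT_TSD_MARGIN = 10
HET_LOW = Fraction(3, 10)
HET_HIGH = Fraction(7, 10)
DEFAULT_UNDET_MAX = 0.1
DEFAULT_MENDEL_MAX = 0.05

HOM_REF, HET, HOM_ALT, UNDETERMINED = 0, 1, 2, -1


@dataclass(frozen=True)
class SiteTally:
    n_softclip: int
    n_crossing: int

    def __post_init__(self):
        if self.n_softclip < 0 or self.n_crossing < 0:
            raise ValueError("negative tally")

    @property
    def total(self) -> int:
        return self.n_softclip + self.n_crossing


@dataclass
class SiteQCStats:
    aaf: float
    undetermined_fraction: float
    mendel_error_rate: float


def tally_site_reads(
    host_alignments: Iterable[pysam.AlignedSegment],
    contig: str,
    position0: int,
    contig_length: int | None = None,
    tsd_margin: int = DEFAULT_TSD_MARGIN,
) -> SiteTally:
    """Count soft-clipped vs crossing reads at one integration position.

    A read is soft-clipped if the aligner clipped it and the clip terminus
    lies within +/- ``tsd_margin`` of the position (inclusive); crossing if
    its aligned interval extends strictly beyond the margin on both sides.
    """
    if contig_length is not None and not (0 <= position0 < contig_length):
        raise ValueError(f"site {contig}:{position0} outside contig bounds")
    n_soft = n_cross = 0
    for rec in host_alignments:
        if rec.is_unmapped or rec.reference_name != contig:
            continue
        cig = rec.cigartuples or []
        lead = cig[0][0] == 4 if cig else False
        trail = cig[-1][0] == 4 if cig else False
        if lead or trail:
            termini = []
            if lead:
                termini.append(rec.reference_start)
            if trail:
                termini.append(rec.reference_end)
            if any(abs(t - position0) <= tsd_margin for t in termini):
                n_soft += 1
            continue
        # crossing: first aligned base before pos-margin, last aligned base
        # after pos+margin (reference_end is half-open)
        if (
            rec.reference_start < position0 - tsd_margin
            and rec.reference_end > position0 + tsd_margin + 1
        ):
            n_cross += 1
    return SiteTally(n_soft, n_cross)


def _classify_fraction(num: int, den: int) -> int:
    """Genotype from the supporting-read fraction num/den (exact)."""
    f = Fraction(num, den)
    if f > HET_HIGH:
        return HOM_ALT
    if f >= HET_LOW:
        return HET
    return UNDETERMINED


def call_genotype_novel(tally: SiteTally) -> int:
    """Zygosity at a novel site from its soft-clip/crossing tally."""
    if tally.total == 0:
        return UNDETERMINED
    return _classify_fraction(tally.n_softclip, tally.total)


def call_genotype_known(
    tally_start: SiteTally | None, tally_end: SiteTally | None
) -> int:
    """Zygosity at a known site from tallies at its two breakpoints.

    Crossing reads support the ERV allele here, since the reference assembly
    contains the ERV. The mean crossing fraction over the available
    breakpoints is classified with the same inclusive 30-70% window.
    """
    fractions = []
    for t in (tally_start, tally_end):
        if t is not None and t.total > 0:
            fractions.append(Fraction(t.n_crossing, t.total))
    if not fractions:
        return UNDETERMINED
    g = sum(fractions) / len(fractions)
    if g > HET_HIGH:
        return HOM_ALT
    if g >= HET_LOW:
        return HET
    return UNDETERMINED


def consensus_call(calls: Sequence[int]) -> int:
    """Per-animal consensus across replicates: unanimity or undetermined."""
    calls = list(calls)
    if not calls:
        return UNDETERMINED
    return calls[0] if len(set(calls)) == 1 else UNDETERMINED


def build_population_matrix(
    calls: Mapping[str, Mapping[str, int | Sequence[int]]],
    site_ids: Sequence[str],
    individuals: Sequence[str],
) -> pd.DataFrame:
    """Assemble the individuals x sites genotype matrix.

    ``calls[individual][site]`` is a call code or a sequence of replicate
    codes. Any (individual, site) with no evidence is assumed homozygous
    reference; replicate disagreement collapses to -1.
    """
    if len(set(individuals)) != len(individuals):
        dupes = [i for i, c in Counter(individuals).items() if c > 1]
        raise ValueError(f"duplicate individual ids: {dupes}")
    matrix = pd.DataFrame(
        HOM_REF, index=list(individuals), columns=list(site_ids), dtype=np.int8
    )
    for indiv, site_calls in calls.items():
        for site, call in site_calls.items():
            if site not in matrix.columns or indiv not in matrix.index:
                continue
            if isinstance(call, (list, tuple, np.ndarray)):
                call = consensus_call([int(c) for c in call])
            matrix.at[indiv, site] = int(call)
    return matrix


def compute_aaf(genotypes: Iterable[int]) -> float:
    """Alternative-allele frequency over non-missing calls."""
    counts = Counter(g for g in genotypes if g != UNDETERMINED)
    n = counts[HOM_REF] + counts[HET] + counts[HOM_ALT]
    if n == 0:
        return 0.0
    return (2 * counts[HOM_ALT] + counts[HET]) / (2 * n)


_ALLELES = {HOM_REF: (0,), HET: (0, 1), HOM_ALT: (1,)}


def mendelian_consistent(
    offspring: int, sire: int | None, dam: int | None
) -> bool | None:
    """Biallelic Mendelian check; None when undecidable (missing calls)."""
    if offspring == UNDETERMINED:
        return None
    parents = [p for p in (sire, dam) if p is not None and p != UNDETERMINED]
    if not parents:
        return None
    if len(parents) == 2:
        possible = {
            a + b for a in _ALLELES[parents[0]] for b in _ALLELES[parents[1]]
        }
    else:
        possible = {a + b for a in _ALLELES[parents[0]] for b in (0, 1)}
    return offspring in possible


def site_qc(
    matrix: pd.DataFrame, pedigree: Pedigree
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-site QC stats and per-animal Mendelian error rates.

    AAF = (2*n2 + n1) / (2*(n0+n1+n2)); the undetermined fraction is over
    all individuals; Mendelian errors are assessed on every available triad
    or parent-offspring duo with -1 calls excluded.
    """
    n_ind = len(matrix.index)
    stats = {}
    duos = []
    for iid in matrix.index:
        if iid not in pedigree:
            continue
        ind = pedigree[iid]
        sire = ind.sire if ind.sire in pedigree and ind.sire in matrix.index else None
        dam = ind.dam if ind.dam in pedigree and ind.dam in matrix.index else None
        if sire or dam:
            duos.append((iid, sire, dam))

    animal_err = Counter()
    animal_n = Counter()
    for site in matrix.columns:
        col = matrix[site]
        aaf = compute_aaf(col)
        undet = float((col == UNDETERMINED).sum()) / n_ind if n_ind else 0.0
        errs = checks = 0
        for joey, sire, dam in duos:
            ok = mendelian_consistent(
                col[joey],
                col[sire] if sire else None,
                col[dam] if dam else None,
            )
            if ok is None:
                continue
            checks += 1
            animal_n[joey] += 1
            if not ok:
                errs += 1
                animal_err[joey] += 1
        stats[site] = SiteQCStats(
            aaf=aaf,
            undetermined_fraction=undet,
            mendel_error_rate=errs / checks if checks else 0.0,
        )
    qc = pd.DataFrame(
        {
            "aaf": {s: v.aaf for s, v in stats.items()},
            "undetermined_fraction": {
                s: v.undetermined_fraction for s, v in stats.items()
            },
            "mendel_error_rate": {
                s: v.mendel_error_rate for s, v in stats.items()
            },
        }
    ).loc[list(matrix.columns)]
    per_animal = pd.Series(
        {
            joey: animal_err[joey] / animal_n[joey] if animal_n[joey] else 0.0
            for joey, _, _ in duos
        },
        dtype=float,
        name="mendel_error_rate",
    )
    return qc, per_animal


def apply_site_filters(
    matrix: pd.DataFrame,
    qc: pd.DataFrame,
    aaf_min: float = 0.0,
    undet_max: float = DEFAULT_UNDET_MAX,
    mendel_max: float = DEFAULT_MENDEL_MAX,
) -> pd.DataFrame:
    """Keep sites with AAF > aaf_min, undetermined fraction <= undet_max and
    Mendelian error rate <= mendel_max. Idempotent."""
    keep = [
        s
        for s in matrix.columns
        if qc.at[s, "aaf"] > aaf_min
        and qc.at[s, "undetermined_fraction"] <= undet_max
        and qc.at[s, "mendel_error_rate"] <= mendel_max
    ]
    return matrix[keep]


def het_window_counts(coverage: int) -> tuple[int, int]:
    """Inclusive integer soft-clip-count window [0.3c, 0.7c]."""
    lo = math.ceil(Fraction(3 * coverage, 10))
    hi = math.floor(Fraction(7 * coverage, 10))
    return lo, hi


def miss_probability(
    coverage: int, window: tuple[float, float] = (0.3, 0.7), p: float = 0.5
) -> float:
    """Probability a true heterozygote falls outside the inclusive ratio
    window at the given junction coverage, under Binomial(coverage, p).

    coverage 40 -> 0.00643 (prints as 0.6%); coverage 10 -> 0.1094.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if coverage == 0:
        return 1.0
    lo = math.ceil(Fraction(window[0]).limit_denominator(10**6) * coverage)
    hi = math.floor(Fraction(window[1]).limit_denominator(10**6) * coverage)
    if lo > hi:
        return 1.0
    inside = binom.cdf(hi, coverage, p) - (
        binom.cdf(lo - 1, coverage, p) if lo > 0 else 0.0
    )
    return float(1.0 - inside)
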