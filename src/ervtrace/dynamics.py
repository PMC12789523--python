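"""Triad-based detection of new germline integrations, F2 validation,
per-generation integration rates, and eliminated-integration reports."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .io import Pedigree, Triad
from .zygosity import HET, HOM_REF, UNDETERMINED, compute_aaf, miss_probability

DEFAULT_MIN_JOEY_COVERAGE = 40
DEFAULT_F2_COVERAGE = 10
DEFAULT_HIGH_FREQ_AAF = 0.05

VALIDATED = "validated"
NOT_VALIDATED = "not_validated"
NOT_ASSESSED = "not_assessed"


@dataclass
class DeNovoCandidate:
    site_id: str
    triad: Triad
    joey_coverage: int
    validated_in_f2: str = NOT_ASSESSED


@dataclass
class EliminationReport:
    site_id: str
    aaf_deceased: float
    aaf_living: float
    carriers: list[str]
    high_frequency: bool = False


def find_de_novo(
    matrix: pd.DataFrame,
    coverage: pd.DataFrame,
    triads: Sequence[Triad],
    min_joey_coverage: int = DEFAULT_MIN_JOEY_COVERAGE,
) -> list[DeNovoCandidate]:
    """Joey-specific integrations: heterozygous high-coverage calls unique
    to the joey with both parents called homozygous reference.

    A parent called -1 cannot exclude inheritance, so such sites are not
    candidates. Triads with members absent from the matrix are skipped with
    a warning.
    """
    out: list[DeNovoCandidate] = []
    for triad in triads:
        members = (triad.sire_id, triad.dam_id, triad.joey_id)
        if any(m not in matrix.index for m in members):
            warnings.warn(
                f"triad {triad.joey_id}: member missing from matrix, skipped",
                stacklevel=2,
            )
            continue
        for site in matrix.columns:
            if matrix.at[triad.joey_id, site] != HET:
                continue
            cov = int(coverage.at[triad.joey_id, site])
            if cov < min_joey_coverage:
                continue
            if (
                matrix.at[triad.sire_id, site] == HOM_REF
                and matrix.at[triad.dam_id, site] == HOM_REF
            ):
                out.append(DeNovoCandidate(site, triad, cov))
    return out


def validate_f2(
    candidate: DeNovoCandidate,
    matrix: pd.DataFrame,
    coverage: pd.DataFrame,
    pedigree: Pedigree,
    min_offspring_coverage: int = DEFAULT_F2_COVERAGE,
) -> str:
    """F2 validation: one copy in any genotyped offspring at >= 10 reads."""
    offspring = [
        o for o in pedigree.offspring_of(candidate.triad.joey_id)
        if o in matrix.index
    ]
    if not offspring:
        candidate.validated_in_f2 = NOT_ASSESSED
        return NOT_ASSESSED
    for o in offspring:
        if (
            matrix.at[o, candidate.site_id] == HET
            and int(coverage.at[o, candidate.site_id]) >= min_offspring_coverage
        ):
            candidate.validated_in_f2 = VALIDATED
            return VALIDATED
    candidate.validated_in_f2 = NOT_VALIDATED
    return NOT_VALIDATED


def integration_rate(n_new: int, n_triads: int) -> float:
    """New germline integrations per generation, to two decimals."""
    if n_triads < 1:
        raise ValueError("n_triads must be >= 1")
    return round(n_new / n_triads, 2)


def expected_transmissions(
    n_new: int, offspring_coverage_threshold: int = DEFAULT_F2_COVERAGE
) -> tuple[int, float]:
    """Expected transmitted new integrations and the inheritance rate.

    Mendelian transmission (0.5) discounted by the binomial probability of
    missing a heterozygote at the offspring coverage threshold; the expected
    count rounds to the nearest integer (16 x 0.445 -> 7).
    """
    if n_new < 0:
        raise ValueError("n_new must be >= 0")
    rate = 0.5 * (1.0 - miss_probability(offspring_coverage_threshold))
    return int(round(n_new * rate)), rate


def find_eliminated(
    matrix: pd.DataFrame,
    vital_status: Mapping[str, str],
    high_freq_aaf: float = DEFAULT_HIGH_FREQ_AAF,
) -> list[EliminationReport]:
    """Sites carried only by deceased individuals.

    Eliminated iff AAF among deceased > 0 and AAF among living = 0; entries
    with AAF_deceased above ``high_freq_aaf`` are flagged high-frequency.
    """
    living = [i for i in matrix.index if vital_status.get(i) == "living"]
    deceased = [i for i in matrix.index if vital_status.get(i) == "deceased"]
    if not living:
        raise ValueError("cannot assess elimination: no living individuals")
    reports: list[EliminationReport] = []
    for site in matrix.columns:
        col = matrix[site]
        aaf_dec = compute_aaf(col[deceased]) if deceased else 0.0
        aaf_liv = compute_aaf(col[living])
        if aaf_dec > 0 and aaf_liv == 0:
            carriers = sorted(
                i for i in deceased if col[i] not in (HOM_REF, UNDETERMINED)
            )
            # living carriers and eliminated sites are disjoint by construction
            assert not any(
                col[i] not in (HOM_REF, UNDETERMINED) for i in living
            )
            reports.append(
                EliminationReport(
                    site_id=site,
                    aaf_deceased=aaf_dec,
                    aaf_living=aaf_liv,
                    carriers=carriers,
                    high_frequency=aaf_dec > high_freq_aaf,
                )
            )
    return reports


def elimination_rate(
    n_eliminated: int, n_triads: int, haploid_length: int
) -> float:
    """Eliminated integrations per base pair per generation.

    Denominator mirrors the mutation-rate formula: n_triads x haploid
    length x 2 (the diploid genome length).
    """
    if n_triads <= 0 or haploid_length <= 0:
        raise ValueError("n_triads and haploid_length must be > 0")
    if n_eliminated < 0:
        raise ValueError("n_eliminated must be >= 0")
    return n_eliminated / (n_triads * haploid_length * 2)
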