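"""Synthetic cohort generator.

Produces reference contigs, viral reference sequences, multi-generation
pedigrees with Mendelian ERV transmission and Poisson de novo integrations,
per-site junction-read tallies, full short-read alignment records (viral,
masked-host and unmasked-host SAM), long-read iPCR junction reads, trio SNV
calls and phenotypes — each with an exact truth table, so every downstream
stage is testable without external data.

Determinism: a fixed :class:`SimConfig.seed` yields byte-identical outputs.
All randomness flows through numpy Generators fanned out per stage.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from ._seeds import child_rng
from .dating import TrioSnvRecord
from .io import Individual, Interval, Pedigree, Triad, alignment_header
from .zygosity import SiteTally

BASES = np.frombuffer(b"ACGT", dtype="S1")

CALL_MARGIN = 10  # breakpoint calling margin (bp), distinct from the TSD


@dataclass(frozen=True)
class FamilyModel:
    """One ERV family: its provirus geometry, clustering gap and founder
    allele-frequency distribution.

    ``founder_aaf`` is a distribution spec: ``("fixed", v)``,
    ``("uniform", lo, hi)`` or ``("beta", a, b)``.
    """

    name: str
    ltr_length: int = 500
    internal_length: int = 7000
    cluster_gap: int | None = None  # None -> 500 for KoRV, 9000 otherwise
    founder_aaf: tuple = ("beta", 0.5, 2.0)
    known_in_reference: bool = False
    n_sites: int = 10

    def __post_init__(self):
        if self.ltr_length < 50:
            raise ValueError("ltr_length must be >= 50")
        if self.cluster_gap is not None and self.cluster_gap <= 0:
            raise ValueError("cluster_gap must be > 0")

    @property
    def gap(self) -> int:
        if self.cluster_gap is not None:
            return self.cluster_gap
        return 500 if self.name == "KoRV" else 9000

    def sample_aaf(self, rng: np.random.Generator, n: int) -> np.ndarray:
        kind = self.founder_aaf[0]
        if kind == "fixed":
            return np.full(n, float(self.founder_aaf[1]))
        if kind == "uniform":
            return rng.uniform(self.founder_aaf[1], self.founder_aaf[2], n)
        if kind == "beta":
            return rng.beta(self.founder_aaf[1], self.founder_aaf[2], n)
        raise ValueError(f"unknown founder AAF distribution {kind!r}")


def default_families() -> tuple[FamilyModel, ...]:
    return (
        FamilyModel(name="KoRV", known_in_reference=False),
        FamilyModel(name="phaCin-beta", known_in_reference=True),
    )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 200_000
    read_length: int = 150
    mean_coverage: float = 30.0
    insert_size: int = 300
    tsd_length: int = 5
    families: tuple[FamilyModel, ...] = field(default_factory=default_families)
    denovo_integration_rate: float = 0.0
    snv_mutation_rate: float = 0.0
    snv_false_positive_rate: float = 0.0
    softclip_noise_rate: float = 0.0

    def __post_init__(self):
        for name in (
            "denovo_integration_rate",
            "snv_mutation_rate",
            "snv_false_positive_rate",
            "softclip_noise_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.softclip_noise_rate <= 1):
            raise ValueError("softclip_noise_rate must be in [0, 1]")
        if self.contig_length <= 10 * self.read_length:
            raise ValueError("contig_length must exceed 10x read_length")

    @property
    def haploid_length(self) -> int:
        return self.n_contigs * self.contig_length

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["families"] = [dataclasses.asdict(f) for f in self.families]
        for f in d["families"]:
            f["founder_aaf"] = list(f["founder_aaf"])
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        fams = []
        for f in d.get("families", []):
            f = dict(f)
            f["founder_aaf"] = tuple(f["founder_aaf"])
            fams.append(FamilyModel(**f))
        if fams:
            d["families"] = tuple(fams)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class TruthIntegration:
    site_id: str
    family: str
    contig: str
    position0: int
    known_flag: bool
    founder_aaf: float


@dataclass
class SimIndividual:
    studbook_id: str
    sire_id: str | None
    dam_id: str | None
    sex: str
    birth_year: int
    vital_status: str = "living"
    cause_of_death: str | None = None
    genotypes: dict[str, int] = field(default_factory=dict)
    phenotypes: dict[str, float] = field(default_factory=dict)


@dataclass
class Cohort:
    """Full truth bundle produced by :func:`generate_cohort`."""

    config: SimConfig
    reference: dict[str, str]
    viral_refs: dict[str, str]
    reference_families: dict[str, str]
    known_intervals: list[Interval]
    sites: list[TruthIntegration]
    individuals: dict[str, SimIndividual]
    denovo_events: list[tuple[str, str]]  # (site_id, joey_id)

    def pedigree(self) -> Pedigree:
        return Pedigree(
            Individual(
                id=ind.studbook_id,
                sire=ind.sire_id,
                dam=ind.dam_id,
                sex=ind.sex,
                birth_year=ind.birth_year,
                vital_status=ind.vital_status,
                cause_of_death=ind.cause_of_death,
            )
            for ind in self.individuals.values()
        )

    def genotype_frame(self) -> pd.DataFrame:
        ids = [s.site_id for s in self.sites]
        data = {
            iid: [ind.genotypes.get(s, 0) for s in ids]
            for iid, ind in self.individuals.items()
        }
        return pd.DataFrame.from_dict(
            data, orient="index", columns=ids, dtype=np.int8
        )

    def site_by_id(self, site_id: str) -> TruthIntegration:
        return next(s for s in self.sites if s.site_id == site_id)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(BASES, size=length).tobytes().decode()


def _place_sites(
    config: SimConfig, rng: np.random.Generator
) -> list[tuple[str, str, int]]:
    """Assign (family, contig, position) slots so sites never co-cluster.

    Each contig is split into equal slots wider than twice the largest
    clustering gap; one site per slot, jittered within its middle third.
    """
    total = sum(f.n_sites for f in config.families)
    per_contig = -(-total // config.n_contigs)
    slot = config.contig_length // max(per_contig, 1)
    max_gap = max(f.gap for f in config.families)
    if slot < 2 * max_gap + 4 * config.read_length:
        raise ValueError(
            "contig_length too small for the requested site count and "
            f"clustering gaps (slot {slot} bp, need >= "
            f"{2 * max_gap + 4 * config.read_length})"
        )
    labels = [f.name for f in config.families for _ in range(f.n_sites)]
    placements = []
    for i, fam in enumerate(labels):
        contig = f"contig{i % config.n_contigs + 1}"
        slot_idx = i // config.n_contigs
        lo = slot_idx * slot + slot // 3
        hi = slot_idx * slot + 2 * slot // 3
        placements.append((fam, contig, int(rng.integers(lo, hi))))
    return placements


def _viral_references(
    config: SimConfig, rng: np.random.Generator
) -> tuple[dict[str, str], dict[str, str]]:
    """Viral reference sequences and the name -> family collapse map."""
    refs: dict[str, str] = {}
    fam_map: dict[str, str] = {}
    for fam in config.families:
        length = 2 * fam.ltr_length + fam.internal_length
        seq = _random_sequence(rng, length)
        if fam.name == "KoRV":
            # two strains differing by a sprinkle of substitutions; short
            # reads cannot tell them apart, so both collapse to "KoRV"
            refs["KoRV-A"] = seq
            b = list(seq)
            for pos in rng.choice(length, size=length // 200, replace=False):
                b[pos] = "ACGT"[(("ACGT".index(b[pos])) + 1) % 4]
            refs["KoRV-B"] = "".join(b)
            fam_map["KoRV-A"] = fam_map["KoRV-B"] = "KoRV"
        else:
            refs[fam.name] = seq
            fam_map[fam.name] = fam.name
    return refs, fam_map


def generate_cohort(
    config: SimConfig, n_founders: int, n_generations: int
) -> Cohort:
    """Simulate a pedigreed cohort with known ERV genotypes.

    Founder genotypes are drawn per site from the family's founder AAF
    distribution under Hardy-Weinberg; each offspring receives one allele
    per parent per site; de novo integrations arrive per joey per family as
    Poisson(``denovo_integration_rate``) at uniform positions and are always
    heterozygous in the joey.
    """
    if n_founders == 0:
        raise ValueError("empty pedigree")
    if n_founders < 2:
        raise ValueError("n_founders must be >= 2")
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")

    rng_ref = child_rng(config.seed, "reference")
    rng_ped = child_rng(config.seed, "pedigree")
    rng_geno = child_rng(config.seed, "genotypes")
    rng_dnv = child_rng(config.seed, "denovo")

    reference = {
        f"contig{i + 1}": _random_sequence(rng_ref, config.contig_length)
        for i in range(config.n_contigs)
    }
    viral_refs, fam_map = _viral_references(config, rng_ref)

    fam_by_name = {f.name: f for f in config.families}
    placements = _place_sites(config, rng_ref)
    sites: list[TruthIntegration] = []
    known_intervals: list[Interval] = []
    counters: dict[str, int] = {}
    for fam_name, contig, pos in placements:
        fam = fam_by_name[fam_name]
        counters[fam_name] = counters.get(fam_name, 0) + 1
        sid = f"{fam_name}_{counters[fam_name]:03d}"
        aaf = float(fam.sample_aaf(rng_geno, 1)[0])
        sites.append(
            TruthIntegration(sid, fam_name, contig, pos, fam.known_in_reference, aaf)
        )
        if fam.known_in_reference:
            end = min(
                pos + 2 * fam.ltr_length + fam.internal_length,
                config.contig_length,
            )
            known_intervals.append(Interval(contig, pos, end, sid))

    individuals: dict[str, SimIndividual] = {}
    denovo_events: list[tuple[str, str]] = []
    next_id = 1

    def new_id() -> str:
        nonlocal next_id
        sid = f"SB{next_id:04d}"
        next_id += 1
        return sid

    # founders: unrelated, HW genotypes, alternating sex so pairs exist
    founders = []
    for i in range(n_founders):
        iid = new_id()
        ind = SimIndividual(
            studbook_id=iid,
            sire_id=None,
            dam_id=None,
            sex="M" if i % 2 == 0 else "F",
            birth_year=2000,
        )
        for site in sites:
            ind.genotypes[site.site_id] = int(
                rng_geno.binomial(2, site.founder_aaf)
            )
        individuals[iid] = ind
        founders.append(iid)

    prev_gen = founders
    denovo_counter = 0
    for gen in range(1, n_generations + 1):
        males = [i for i in prev_gen if individuals[i].sex == "M"]
        females = [i for i in prev_gen if individuals[i].sex == "F"]
        if not males or not females:
            raise ValueError("cannot pair: a generation lacks one sex")
        this_gen = []
        for j in range(n_founders):
            iid = new_id()
            sire = str(rng_ped.choice(males))
            dam = str(rng_ped.choice(females))
            ind = SimIndividual(
                studbook_id=iid,
                sire_id=sire,
                dam_id=dam,
                sex="M" if j % 2 == 0 else "F",
                birth_year=2000 + gen,
            )
            for site in sites:
                a = int(
                    rng_geno.random() < individuals[sire].genotypes.get(site.site_id, 0) / 2
                )
                b = int(
                    rng_geno.random() < individuals[dam].genotypes.get(site.site_id, 0) / 2
                )
                ind.genotypes[site.site_id] = a + b
            individuals[iid] = ind
            this_gen.append(iid)
            # de novo germline integrations, always heterozygous in the joey
            for fam in config.families:
                k = rng_dnv.poisson(config.denovo_integration_rate)
                for _ in range(k):
                    denovo_counter += 1
                    contig = f"contig{int(rng_dnv.integers(config.n_contigs)) + 1}"
                    pos = int(
                        rng_dnv.integers(
                            2 * config.read_length,
                            config.contig_length - 2 * config.read_length,
                        )
                    )
                    dn_id = f"{fam.name}_dn{denovo_counter:03d}"
                    sites.append(
                        TruthIntegration(dn_id, fam.name, contig, pos, False, 0.0)
                    )
                    ind.genotypes[dn_id] = 1
                    denovo_events.append((dn_id, iid))
        prev_gen = this_gen

    return Cohort(
        config=config,
        reference=reference,
        viral_refs=viral_refs,
        reference_families=fam_map,
        known_intervals=known_intervals,
        sites=sites,
        individuals=individuals,
        denovo_events=denovo_events,
    )


# ------------------------------------------------------- site evidence


def simulate_site_evidence(
    genotype: int,
    coverage: int,
    noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> SiteTally:
    """Junction-read tally for one genotype at one site.

    Heterozygotes split reads Binomial(coverage, 0.5); homozygous-alt sites
    soft-clip everything except noise; non-carriers soft-clip only noise.
    """
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if coverage == 0:
        return SiteTally(0, 0)
    if genotype == 1:
        n_soft = int(rng.binomial(coverage, 0.5))
    elif genotype == 2:
        n_soft = coverage - int(rng.binomial(coverage, noise))
    else:
        n_soft = int(rng.binomial(coverage, noise))
    return SiteTally(n_soft, coverage - n_soft)


def simulate_cohort_tallies(
    cohort: Cohort, label: str = "tallies"
) -> tuple[dict[str, dict[str, SiteTally]], pd.DataFrame]:
    """Per-(individual, site) junction tallies and the coverage matrix.

    Junction coverage is drawn Poisson(mean_coverage) independently per
    individual and site.
    """
    cfg = cohort.config
    rng = child_rng(cfg.seed, label)
    site_ids = [s.site_id for s in cohort.sites]
    tallies: dict[str, dict[str, SiteTally]] = {}
    cov = pd.DataFrame(
        0, index=list(cohort.individuals), columns=site_ids, dtype=int
    )
    for iid, ind in cohort.individuals.items():
        tallies[iid] = {}
        for sid in site_ids:
            c = int(rng.poisson(cfg.mean_coverage))
            cov.at[iid, sid] = c
            tallies[iid][sid] = simulate_site_evidence(
                ind.genotypes.get(sid, 0), c, cfg.softclip_noise_rate, rng
            )
    return tallies, cov


# ------------------------------------------------- alignment emission


@dataclass
class ShortReadRecords:
    header: pysam.AlignmentHeader
    virus: list[pysam.AlignedSegment]
    masked_host: list[pysam.AlignedSegment]
    genome: list[pysam.AlignedSegment]
    truth: dict[str, str]  # read_id -> site_id


def _segment(
    header: pysam.AlignmentHeader,
    name: str,
    ref: str | None,
    pos: int,
    cigar: str | None,
    length: int,
    mapq: int = 60,
    flag: int = 0,
) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = "A" * length
    a.flag = flag
    if ref is None:
        a.reference_id = -1
        a.reference_start = -1
    else:
        a.reference_name = ref
        a.reference_start = pos
        a.cigarstring = cigar
    a.mapping_quality = mapq
    return a


def emit_alignment_records(
    cohort: Cohort,
    individual_id: str,
    mode: str = "short_read",
    tallies: Mapping[str, SiteTally] | None = None,
    ipcr_support: Mapping[str, int] | None = None,
) -> "ShortReadRecords | LongReadSet":
    """Emit read-level evidence for one individual.

    ``short_read`` mode produces three alignment-record sets: reads against
    the viral references (anchored-mate pairs and partially aligned
    soft-clipped reads), the host-side alignments of their anchors/clipped
    segments against the masked assembly, and unmasked-genome alignments
    (soft-clipped + crossing reads) for zygosity tallies.
    """
    if individual_id not in cohort.individuals:
        raise KeyError(individual_id)
    if mode == "short_read":
        return _emit_short_read(cohort, individual_id, tallies)
    if mode == "long_read":
        return emit_ipcr_reads(cohort, individual_id, ipcr_support or {})
    raise ValueError(f"unknown mode {mode!r}; expected short_read or long_read")


def _emit_short_read(
    cohort: Cohort,
    individual_id: str,
    tallies: Mapping[str, SiteTally] | None,
) -> ShortReadRecords:
    cfg = cohort.config
    rng = child_rng(cfg.seed, f"reads:{individual_id}")
    ind = cohort.individuals[individual_id]
    contig_lengths = {c: len(s) for c, s in cohort.reference.items()}
    viral_lengths = {v: len(s) for v, s in cohort.viral_refs.items()}
    header = alignment_header(contig_lengths, viral_lengths)

    virus: list[pysam.AlignedSegment] = []
    masked: list[pysam.AlignedSegment] = []
    genome: list[pysam.AlignedSegment] = []
    truth: dict[str, str] = {}
    rl = cfg.read_length
    fam_refs: dict[str, list[str]] = {}
    for ref, fam in cohort.reference_families.items():
        fam_refs.setdefault(fam, []).append(ref)

    for site in cohort.sites:
        g = ind.genotypes.get(site.site_id, 0)
        if tallies is not None and site.site_id in tallies:
            tally = tallies[site.site_id]
        else:
            c = int(rng.poisson(cfg.mean_coverage))
            tally = simulate_site_evidence(g, c, cfg.softclip_noise_rate, rng)
        pos = site.position0
        n = 0

        # unmasked-genome records for zygosity
        for _ in range(tally.n_softclip):
            n += 1
            name = f"{individual_id}:{site.site_id}:z{n}"
            aln = int(rng.integers(40, rl - 20))  # clip > 20 bp
            clip = rl - aln
            if rng.random() < 0.5:  # host flank left of the breakpoint
                genome.append(
                    _segment(header, name, site.contig, pos - aln,
                             f"{aln}M{clip}S", rl)
                )
            else:
                genome.append(
                    _segment(header, name, site.contig, pos,
                             f"{clip}S{aln}M", rl)
                )
        for _ in range(tally.n_crossing):
            n += 1
            name = f"{individual_id}:{site.site_id}:z{n}"
            offset = int(rng.integers(CALL_MARGIN + 1, rl - CALL_MARGIN - 1))
            genome.append(
                _segment(header, name, site.contig, pos - offset, f"{rl}M", rl)
            )

        # discovery evidence for every insertion-supporting junction read
        refs = fam_refs.get(site.family, [])
        if not refs:
            continue
        vlen = viral_lengths[refs[0]]
        for k in range(tally.n_softclip):
            name = f"{individual_id}:{site.site_id}:e{k}"
            truth[name] = site.site_id
            vref = refs[int(rng.integers(len(refs)))]
            left = bool(rng.random() < 0.5)
            if rng.random() < 0.5:  # soft-clip class
                hostlen = int(rng.integers(25, 80))
                viruslen = rl - hostlen
                if left:
                    virus.append(
                        _segment(header, name, vref, 0,
                                 f"{hostlen}S{viruslen}M", rl)
                    )
                    masked.append(
                        _segment(header, name, site.contig, pos - hostlen,
                                 f"{hostlen}M", hostlen)
                    )
                else:
                    virus.append(
                        _segment(header, name, vref, vlen - viruslen,
                                 f"{viruslen}M{hostlen}S", rl)
                    )
                    masked.append(
                        _segment(header, name, site.contig, pos,
                                 f"{hostlen}M", hostlen)
                    )
            else:  # anchored-mate class: mates share the query name per SAM
                virus.append(
                    _segment(header, name, vref,
                             int(rng.integers(0, max(vlen - rl, 1))),
                             f"{rl}M", rl, flag=0x1 | 0x8 | 0x40)
                )
                unmapped = _segment(header, name, None, -1, None, rl,
                                    mapq=0, flag=0x1 | 0x4 | 0x80)
                virus.append(unmapped)
                if left:
                    start = pos - int(rng.integers(rl, cfg.insert_size + 1))
                else:
                    start = pos + int(rng.integers(5, cfg.insert_size - rl))
                masked.append(
                    _segment(header, name, site.contig, max(start, 0),
                             f"{rl}M", rl)
                )
    return ShortReadRecords(header, virus, masked, genome, truth)


@dataclass
class LongReadSet:
    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth: pd.DataFrame  # site_id, contig, position0, support, label


def emit_ipcr_reads(
    cohort: Cohort,
    individual_id: str,
    support_by_site: Mapping[str, int],
    somatic_sites: Sequence[tuple[str, int, int]] = (),
    min_flank: int = 60,
    max_flank: int = 300,
) -> LongReadSet:
    """Long-read iPCR junction reads for one individual.

    Each read carries a viral LTR-anchored segment flanked on both sides by
    host sequence (>= ``min_flank`` bp). ``support_by_site`` sets reads per
    carried germline site; ``somatic_sites`` adds (contig, position, support)
    integrations labelled somatic in the truth table.
    """
    cfg = cohort.config
    rng = child_rng(cfg.seed, f"ipcr:{individual_id}")
    viral = cohort.viral_refs[next(iter(cohort.viral_refs))]
    reads: list[tuple[str, str]] = []
    rows = []
    ind = cohort.individuals[individual_id]

    def emit_site(contig: str, pos: int, support: int, label: str, sid: str):
        ref = cohort.reference[contig]
        tsd = cfg.tsd_length
        for r in range(support):
            fl = int(rng.integers(min_flank, max_flank))
            fr = int(rng.integers(min_flank, max_flank))
            vl = int(rng.integers(200, min(800, len(viral))))
            seq = ref[pos - fl : pos + tsd] + viral[:vl] + ref[pos : pos + fr]
            reads.append((f"{individual_id}:{sid}:lr{r}", seq))
        rows.append(
            {
                "site_id": sid,
                "contig": contig,
                "position0": pos,
                "support": support,
                "label": label,
            }
        )

    for sid, support in support_by_site.items():
        site = cohort.site_by_id(sid)
        if ind.genotypes.get(sid, 0) <= 0:
            continue
        emit_site(site.contig, site.position0, support, "endogenous", sid)
    for i, (contig, pos, support) in enumerate(somatic_sites):
        emit_site(contig, pos, support, "somatic", f"somatic_{i + 1:03d}")
    return LongReadSet(reads=reads, truth=pd.DataFrame(rows))


# ------------------------------------------------------- trio SNV calls


def simulate_trio_snv_calls(
    cohort: Cohort, trio: Triad, label: str = "snv"
) -> tuple[list[TrioSnvRecord], list[tuple[str, int]]]:
    """VCF-style trio SNV candidates plus the exact de novo truth list.

    True de novo SNVs arrive Poisson(rate x haploid length x 2) with clean
    quality fields; false positives (``snv_false_positive_rate``) are joey-het
    records that each fail at least one of the DP/GQ/AB thresholds.
    """
    cfg = cohort.config
    for member in (trio.sire_id, trio.dam_id):
        if member is None or member not in cohort.individuals:
            raise ValueError("not a triad: missing parent")
    rng = child_rng(cfg.seed, f"{label}:{trio.joey_id}")
    records: list[TrioSnvRecord] = []
    truth: list[tuple[str, int]] = []
    hom_ref = (0, 0)

    n_true = int(rng.poisson(cfg.snv_mutation_rate * cfg.haploid_length * 2))
    for _ in range(n_true):
        contig = f"contig{int(rng.integers(cfg.n_contigs)) + 1}"
        pos1 = int(rng.integers(1, cfg.contig_length + 1))
        records.append(
            TrioSnvRecord(
                contig=contig,
                pos1=pos1,
                sire_gt=hom_ref,
                dam_gt=hom_ref,
                joey_gt=(0, 1),
                depth=20 + int(rng.poisson(10)),
                genotype_quality=99,
                allele_balance=float(rng.uniform(0.4, 0.6)),
            )
        )
        truth.append((contig, pos1))

    n_fp = int(rng.poisson(cfg.snv_false_positive_rate))
    for _ in range(n_fp):
        contig = f"contig{int(rng.integers(cfg.n_contigs)) + 1}"
        pos1 = int(rng.integers(1, cfg.contig_length + 1))
        failure = int(rng.integers(3))
        records.append(
            TrioSnvRecord(
                contig=contig,
                pos1=pos1,
                sire_gt=hom_ref,
                dam_gt=hom_ref,
                joey_gt=(0, 1),
                depth=int(rng.integers(3, 20)) if failure == 0 else 30,
                genotype_quality=int(rng.integers(3, 20)) if failure == 1 else 99,
                allele_balance=float(rng.uniform(0.05, 0.35))
                if failure == 2
                else 0.5,
            )
        )
    records.sort(key=lambda r: (r.contig, r.pos1))
    return records, truth


# ------------------------------------------------------- phenotypes


def simulate_phenotypes(
    genotypes: pd.DataFrame,
    effects: Mapping[str, float],
    kind: str = "binary",
    intercept: float = 0.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> pd.Series:
    """Phenotypes with configurable additive marker effects.

    Binary traits are Bernoulli(sigmoid(intercept + sum beta*g)); continuous
    traits add Gaussian noise to the linear predictor.
    """
    rng = np.random.default_rng(seed)
    eta = np.full(len(genotypes), float(intercept))
    for marker, beta in effects.items():
        g = genotypes[marker].to_numpy(dtype=float)
        g[g < 0] = 0.0
        eta += beta * g
    if kind == "binary":
        p = 1.0 / (1.0 + np.exp(-eta))
        vals = (rng.random(len(eta)) < p).astype(int)
    elif kind == "continuous":
        vals = eta + rng.normal(0.0, noise_sd, len(eta))
    else:
        raise ValueError(f"unknown phenotype kind {kind!r}")
    return pd.Series(vals, index=genotypes.index, name="trait")
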