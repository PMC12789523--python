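"""Shared readers and writers: pedigree TSV, BED intervals, sites VCF, SAM.

Internal coordinates are 0-based half-open throughout; VCF and SAM are
converted to 1-based at this boundary, BED is native.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

PEDIGREE_COLUMNS = [
    "id",
    "sire",
    "dam",
    "sex",
    "birth_year",
    "vital_status",
    "cause_of_death",
]


@dataclass
class Individual:
    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = "U"
    birth_year: int | None = None
    vital_status: str = "living"
    cause_of_death: str | None = None


@dataclass
class Triad:
    sire_id: str
    dam_id: str
    joey_id: str


class PedigreeError(ValueError):
    pass


class Pedigree:
    """Directed acyclic sire/dam graph over :class:`Individual` records."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self.individuals:
                raise PedigreeError(f"duplicate individual id: {ind.id}")
            self.individuals[ind.id] = ind
        self._check_acyclic()

    def _parents(self, iid: str) -> list[str]:
        ind = self.individuals[iid]
        return [p for p in (ind.sire, ind.dam) if p and p in self.individuals]

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(iid: str, stack: list[str]) -> None:
            if state.get(iid) == 1:
                return
            if state.get(iid) == 0:
                cycle = stack[stack.index(iid):] + [iid]
                raise PedigreeError(
                    "cyclic parentage: " + " -> ".join(cycle)
                )
            state[iid] = 0
            stack.append(iid)
            for p in self._parents(iid):
                visit(p, stack)
            stack.pop()
            state[iid] = 1

        for iid in self.individuals:
            visit(iid, [])

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self.individuals

    def __getitem__(self, iid: str) -> Individual:
        return self.individuals[iid]

    def ids(self) -> list[str]:
        return list(self.individuals)

    def founders(self) -> list[str]:
        return [i for i in self.individuals if not self._parents(i)]

    def offspring_of(self, iid: str) -> list[str]:
        return [
            o
            for o, ind in self.individuals.items()
            if iid in (ind.sire, ind.dam)
        ]

    def triads(self) -> list[Triad]:
        """All trios with both parents present in the pedigree."""
        out = []
        for iid, ind in self.individuals.items():
            if (
                ind.sire
                and ind.dam
                and ind.sire in self.individuals
                and ind.dam in self.individuals
            ):
                out.append(Triad(ind.sire, ind.dam, iid))
        return out

    def generation_depth(self) -> int:
        """Longest founder-to-leaf chain, counted in generations."""
        memo: dict[str, int] = {}

        def depth(iid: str) -> int:
            if iid not in memo:
                parents = self._parents(iid)
                memo[iid] = 1 + (max(depth(p) for p in parents) if parents else 0)
            return memo[iid]

        return max((depth(i) for i in self.individuals), default=0)

    def vital_status(self) -> dict[str, str]:
        return {i: ind.vital_status for i, ind in self.individuals.items()}


def read_pedigree(path: str | os.PathLike) -> Pedigree:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PEDIGREE_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise PedigreeError(f"pedigree TSV missing columns: {missing}")
    inds = []
    for row in df.itertuples(index=False):
        inds.append(
            Individual(
                id=row.id,
                sire=row.sire or None,
                dam=row.dam or None,
                sex=row.sex or "U",
                birth_year=int(row.birth_year)
                if getattr(row, "birth_year", "") not in ("", None)
                else None,
                vital_status=getattr(row, "vital_status", "") or "living",
                cause_of_death=getattr(row, "cause_of_death", "") or None,
            )
        )
    return Pedigree(inds)


def write_pedigree(pedigree: Pedigree, path: str | os.PathLike) -> None:
    rows = []
    for ind in pedigree.individuals.values():
        rows.append(
            {
                "id": ind.id,
                "sire": ind.sire or "",
                "dam": ind.dam or "",
                "sex": ind.sex,
                "birth_year": "" if ind.birth_year is None else ind.birth_year,
                "vital_status": ind.vital_status,
                "cause_of_death": ind.cause_of_death or "",
            }
        )
    pd.DataFrame(rows, columns=PEDIGREE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------- BED


@dataclass(frozen=True)
class Interval:
    contig: str
    start0: int
    end0: int  # half-open
    name: str = "."


def read_bed(path: str | os.PathLike) -> list[Interval]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            out.append(
                Interval(
                    parts[0],
                    int(parts[1]),
                    int(parts[2]),
                    parts[3] if len(parts) > 3 else ".",
                )
            )
    return out


def write_bed(intervals: Iterable[Interval], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.contig}\t{iv.start0}\t{iv.end0}\t{iv.name}\n")


# ---------------------------------------------------------------- FASTA


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if line.startswith(">"):
                name = line[1:].split()[0]
                seqs[name] = []
            elif name is not None:
                seqs[name].append(line)
    return {n: "".join(parts) for n, parts in seqs.items()}


# ---------------------------------------------------------------- sites VCF

_GT_TO_CODE = {(None, None): -1, (0, 0): 0, (0, 1): 1, (1, 0): 1, (1, 1): 2}
_CODE_TO_GT = {-1: (None, None), 0: (0, 0), 1: (0, 1), 2: (1, 1)}


def symbolic_alt(family: str) -> str:
    """Symbolic mobile-element ALT allele for a family label."""
    tag = re.sub(r"[^A-Za-z0-9]", "", family).upper()
    return f"<INS:ME:{tag}>"


def _sites_header(
    contig_lengths: Mapping[str, int], samples: Sequence[str], families: Iterable[str]
) -> pysam.VariantHeader:
    hdr = pysam.VariantHeader()
    for contig, length in contig_lengths.items():
        hdr.contigs.add(contig, length=length)
    for fam in sorted(set(families)):
        alt_id = symbolic_alt(fam).strip("<>")
        hdr.add_meta(
            "ALT", items=[("ID", alt_id), ("Description", f"{fam} integration")]
        )
    hdr.info.add("FAM", 1, "String", "ERV family")
    hdr.info.add("SUPPORT", 1, "Integer", "Supporting evidence reads")
    hdr.info.add("NOVEL", 0, "Flag", "Integration absent from the reference assembly")
    hdr.formats.add("GT", 1, "String", "Genotype")
    for s in samples:
        hdr.add_sample(s)
    return hdr


def write_sites_vcf(
    sites: Sequence,
    matrix: pd.DataFrame | None,
    contig_lengths: Mapping[str, int],
    path: str | os.PathLike,
) -> None:
    """Write integration sites (and optional genotype matrix) as VCF 4.2.

    ``sites`` are :class:`ervtrace.discovery.IntegrationSite`-like objects.
    Genotype codes map 0/1/2 to 0/0, 0/1, 1/1 and -1 to ``./.``.
    """
    samples = list(matrix.index) if matrix is not None else []
    hdr = _sites_header(contig_lengths, samples, (s.family for s in sites))
    ordered = sorted(sites, key=lambda s: (s.contig, s.position0(), s.site_id))
    with pysam.VariantFile(str(path), "w", header=hdr) as vcf:
        for site in ordered:
            pos0 = site.position0()
            if pos0 >= contig_lengths[site.contig]:
                raise ValueError(
                    f"site {site.site_id} at {site.contig}:{pos0} outside reference"
                )
            stop = (
                site.end0
                if not site.novel_flag and site.end0 is not None
                else pos0 + 1
            )
            rec = vcf.new_record(
                contig=site.contig,
                start=pos0,
                stop=stop,
                alleles=("N", symbolic_alt(site.family)),
                id=site.site_id,
            )
            rec.info["FAM"] = site.family
            rec.info["SUPPORT"] = int(site.support)
            if site.novel_flag:
                rec.info["NOVEL"] = True
            if matrix is not None:
                for sample in samples:
                    code = int(matrix.at[sample, site.site_id])
                    rec.samples[sample]["GT"] = _CODE_TO_GT[code]
            vcf.write(rec)


def read_sites_vcf(path: str | os.PathLike):
    """Read a sites VCF back into (sites, genotype matrix or None)."""
    from .discovery import IntegrationSite

    sites = []
    rows: dict[str, dict[str, int]] = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            novel = rec.info.get("NOVEL", False)
            site = IntegrationSite(
                site_id=rec.id,
                family=rec.info["FAM"],
                contig=rec.chrom,
                novel_flag=bool(novel),
                breakpoint0=rec.start if novel else None,
                start0=None if novel else rec.start,
                end0=None if novel else rec.stop,
                support=int(rec.info["SUPPORT"]),
            )
            sites.append(site)
            for sample in samples:
                gt = tuple(rec.samples[sample]["GT"])
                rows.setdefault(sample, {})[rec.id] = _GT_TO_CODE.get(gt, -1)
    matrix = None
    if samples:
        matrix = pd.DataFrame.from_dict(rows, orient="index").loc[samples]
        matrix = matrix[[s.site_id for s in sites]]
    return sites, matrix


# ---------------------------------------------------------------- SAM


def alignment_header(
    contig_lengths: Mapping[str, int], viral_lengths: Mapping[str, int] | None = None
) -> pysam.AlignmentHeader:
    refs = dict(contig_lengths)
    if viral_lengths:
        refs.update(viral_lengths)
    return pysam.AlignmentHeader.from_references(
        list(refs), [int(v) for v in refs.values()]
    )


def write_sam(
    records: Iterable[pysam.AlignedSegment],
    header: pysam.AlignmentHeader,
    path: str | os.PathLike,
) -> None:
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for rec in records:
            fh.write(rec)


def read_sam(path: str | os.PathLike) -> list[pysam.AlignedSegment]:
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        return list(fh)
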