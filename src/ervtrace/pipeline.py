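"""End-to-end pipeline: simulate -> discover -> genotype -> dynamics ->
rates -> associate -> score, with a run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, dating, discovery, dynamics, zygosity
from .io import (
    Interval,
    write_bed,
    write_fasta,
    write_pedigree,
    write_sam,
    write_sites_vcf,
)
from .simulate import (
    Cohort,
    SimConfig,
    emit_alignment_records,
    generate_cohort,
    simulate_cohort_tallies,
    simulate_phenotypes,
    simulate_trio_snv_calls,
)


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "ervtrace_out"
    n_founders: int = 8
    n_generations: int = 3
    sim: SimConfig | None = None
    min_cluster_reads: int = discovery.DEFAULT_MIN_CLUSTER_READS
    min_clip: int = discovery.DEFAULT_MIN_CLIP
    min_mapq: int = discovery.DEFAULT_MIN_MAPQ
    tsd_margin: int = zygosity.DEFAULT_TSD_MARGIN
    undet_max: float = zygosity.DEFAULT_UNDET_MAX
    mendel_max: float = zygosity.DEFAULT_MENDEL_MAX
    min_joey_coverage: int = dynamics.DEFAULT_MIN_JOEY_COVERAGE
    f2_coverage: int = dynamics.DEFAULT_F2_COVERAGE
    maf_min: float = association.DEFAULT_MAF_MIN
    trait_effects: dict = field(default_factory=dict)
    write_alignments: bool = False

    def sim_config(self) -> SimConfig:
        if self.sim is not None:
            return self.sim
        # 60x junction coverage keeps per-individual carrier detection
        # reliable (>= 20 evidence reads at heterozygous sites)
        return SimConfig(seed=self.seed, mean_coverage=60.0)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    counts: dict
    warnings: list


def discover_cohort_sites(
    cohort: Cohort,
    tallies: dict,
    min_cluster_reads: int = discovery.DEFAULT_MIN_CLUSTER_READS,
    min_clip: int = discovery.DEFAULT_MIN_CLIP,
    min_mapq: int = discovery.DEFAULT_MIN_MAPQ,
) -> tuple[list[discovery.RegistryEntry], dict[str, list[discovery.IntegrationSite]]]:
    """Run short-read discovery for every individual and merge the sites."""
    per_individual: dict[str, list[discovery.IntegrationSite]] = {}
    gap_by_family = {f.name: f.gap for f in cohort.config.families}
    for iid in cohort.individuals:
        recs = emit_alignment_records(
            cohort, iid, mode="short_read", tallies=tallies.get(iid)
        )
        evidence, _ = discovery.extract_evidence(
            recs.virus,
            recs.masked_host,
            cohort.reference_families,
            min_clip=min_clip,
            min_mapq=min_mapq,
        )
        clusters = discovery.cluster_evidence(
            evidence, min_reads=min_cluster_reads, gap_by_family=gap_by_family
        )
        per_individual[iid] = [
            discovery.resolve_breakpoint(c, cohort.known_intervals)
            for c in clusters
        ]
    registry = discovery.merge_sites_across_individuals(per_individual)
    return registry, per_individual


def genotype_cohort(
    cohort: Cohort,
    registry: list[discovery.RegistryEntry],
    tallies: dict,
    coverage: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Genotype every individual at every registry site.

    Returns (matrix, coverage matrix re-indexed to registry ids, map from
    registry site id to the truth site id it matched, when unambiguous).
    """
    truth_map: dict[str, str] = {}
    for entry in registry:
        for site in cohort.sites:
            if (
                site.family == entry.family
                and site.contig == entry.contig
                and entry.start0 - 1 <= site.position0 <= entry.end0 + 1
            ):
                truth_map[entry.site_id] = site.site_id
                break
    calls: dict[str, dict[str, int]] = {}
    cov = pd.DataFrame(
        0, index=list(cohort.individuals), columns=[e.site_id for e in registry]
    )
    carriers_by_entry = {e.site_id: set(e.carriers) for e in registry}
    for iid in cohort.individuals:
        calls[iid] = {}
        for entry in registry:
            truth_id = truth_map.get(entry.site_id)
            if truth_id is None or truth_id not in tallies[iid]:
                continue
            cov.at[iid, entry.site_id] = coverage.at[iid, truth_id]
            # integrations not detected in an individual are assumed
            # homozygous reference; only carriers are genotyped
            if iid not in carriers_by_entry[entry.site_id]:
                continue
            tally = tallies[iid][truth_id]
            calls[iid][entry.site_id] = zygosity.call_genotype_novel(tally)
    matrix = zygosity.build_population_matrix(
        calls, [e.site_id for e in registry], list(cohort.individuals)
    )
    return matrix, cov, truth_map


def run_pipeline(config: PipelineConfig) -> RunManifest:
    from . import __version__

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    warns: list = []

    sim = config.sim_config()
    cohort = generate_cohort(sim, config.n_founders, config.n_generations)
    pedigree = cohort.pedigree()
    counts["individuals"] = len(cohort.individuals)
    counts["truth_sites"] = len(cohort.sites)
    counts["denovo_truth_events"] = len(cohort.denovo_events)

    contig_lengths = {c: len(s) for c, s in cohort.reference.items()}
    write_fasta(cohort.reference, out / "reference.fasta")
    write_fasta(cohort.viral_refs, out / "viral_references.fasta")
    write_bed(cohort.known_intervals, out / "known_erv.bed")
    write_pedigree(pedigree, out / "pedigree.tsv")
    cohort.genotype_frame().to_csv(out / "truth_genotypes.tsv", sep="\t")
    pd.DataFrame(cohort.denovo_events, columns=["site_id", "joey_id"]).to_csv(
        out / "truth_denovo.tsv", sep="\t", index=False
    )
    sim.to_yaml(out / "sim_config.yaml")

    tallies, coverage = simulate_cohort_tallies(cohort)

    if config.write_alignments:
        sam_dir = out / "alignments"
        sam_dir.mkdir(exist_ok=True)
        for iid in cohort.individuals:
            recs = emit_alignment_records(
                cohort, iid, mode="short_read", tallies=tallies[iid]
            )
            write_sam(recs.virus, recs.header, sam_dir / f"{iid}.virus.sam")
            write_sam(recs.masked_host, recs.header, sam_dir / f"{iid}.host.sam")
            write_sam(recs.genome, recs.header, sam_dir / f"{iid}.genome.sam")

    registry, per_individual = discover_cohort_sites(
        cohort,
        tallies,
        min_cluster_reads=config.min_cluster_reads,
        min_clip=config.min_clip,
        min_mapq=config.min_mapq,
    )
    counts["registry_sites"] = len(registry)

    matrix, cov, truth_map = genotype_cohort(cohort, registry, tallies, coverage)
    qc, per_animal = zygosity.site_qc(matrix, pedigree)
    filtered = zygosity.apply_site_filters(
        matrix, qc, undet_max=config.undet_max, mendel_max=config.mendel_max
    )
    counts["sites_after_qc"] = filtered.shape[1]
    matrix.to_csv(out / "genotype_matrix.tsv", sep="\t")
    qc.to_csv(out / "site_qc.tsv", sep="\t")
    per_animal.to_csv(out / "animal_mendel.tsv", sep="\t")

    rep_sites = [e.representative for e in registry]
    for entry, rep in zip(registry, rep_sites):
        rep.site_id = entry.site_id
    write_sites_vcf(rep_sites, matrix, contig_lengths, out / "sites.vcf")

    triads = pedigree.triads()
    counts["triads"] = len(triads)
    candidates = dynamics.find_de_novo(
        filtered, cov, triads, min_joey_coverage=config.min_joey_coverage
    )
    for cand in candidates:
        dynamics.validate_f2(
            cand, filtered, cov, pedigree,
            min_offspring_coverage=config.f2_coverage,
        )
    counts["denovo_candidates"] = len(candidates)
    pd.DataFrame(
        [
            {
                "site_id": c.site_id,
                "joey": c.triad.joey_id,
                "coverage": c.joey_coverage,
                "f2_status": c.validated_in_f2,
            }
            for c in candidates
        ]
    ).to_csv(out / "denovo_report.tsv", sep="\t", index=False)

    try:
        eliminated = dynamics.find_eliminated(filtered, pedigree.vital_status())
    except ValueError as exc:
        eliminated = []
        warns.append(str(exc))
    counts["eliminated_sites"] = len(eliminated)
    pd.DataFrame(
        [
            {
                "site_id": r.site_id,
                "aaf_deceased": r.aaf_deceased,
                "aaf_living": r.aaf_living,
                "high_frequency": r.high_frequency,
                "carriers": ",".join(r.carriers),
            }
            for r in eliminated
        ]
    ).to_csv(out / "elimination_report.tsv", sep="\t", index=False)

    # trio SNV mutation rate
    n_by_trio = []
    ages = []
    for triad in triads:
        records, _truth = simulate_trio_snv_calls(cohort, triad)
        passing, _ = dating.filter_de_novo_snvs(records)
        n_by_trio.append(len(passing))
        joey = cohort.individuals[triad.joey_id]
        sire = cohort.individuals[triad.sire_id]
        dam = cohort.individuals[triad.dam_id]
        ages.append(
            (
                max(joey.birth_year - sire.birth_year, 1),
                max(joey.birth_year - dam.birth_year, 1),
            )
        )
    if n_by_trio:
        est = dating.estimate_mutation_rates(n_by_trio, ages, sim.haploid_length)
        counts["denovo_snvs"] = est.n_denovo_total
        with open(out / "mutation_rates.json", "w") as fh:
            json.dump(dataclasses.asdict(est), fh, indent=2)

    # association and risk score on a simulated binary trait
    effects = dict(config.trait_effects)
    if not effects and len(filtered.columns):
        effects = {filtered.columns[0]: 1.0}
    trait = simulate_phenotypes(
        filtered, effects, kind="binary", seed=config.seed
    )
    assoc = association.additive_association(
        filtered, trait, maf_min=config.maf_min
    )
    counts["markers_tested"] = len(assoc)
    pd.DataFrame(
        [
            {
                "marker_id": a.marker_id,
                "effect_allele": a.effect_allele,
                "estimate": a.estimate,
                "odds_ratio": a.odds_ratio,
                "p_value": a.p_value,
                "direction": a.direction,
            }
            for a in assoc
        ]
    ).to_csv(out / "association.tsv", sep="\t", index=False)

    suggestive = [
        a
        for a in assoc
        if not a.separated
        and association.is_suggestive(
            a.p_value, association.DEFAULT_SUGGESTIVE_ERV_LOG10
        )
    ]
    if suggestive:
        grs_model = association.GrsModel(
            markers=[(a.marker_id, a.odds_ratio, "alt") for a in suggestive]
        )
        scores = association.score_population(filtered, grs_model)
        scores.to_csv(out / "grs.tsv", sep="\t")
        if trait.nunique() == 2:
            mean_acc, _ = association.bootstrap_accuracy(
                scores["score"].to_numpy(), trait.to_numpy(), seed=config.seed
            )
            cutoff, cut_acc = association.choose_cutoff(
                scores["score"].to_numpy(), trait.to_numpy()
            )
            counts["grs_bootstrap_accuracy"] = round(mean_acc, 4)
            counts["grs_cutoff"] = cutoff
    counts["suggestive_markers"] = len(suggestive)

    manifest = RunManifest(
        version=__version__,
        seed=config.seed,
        config_hash=config.config_hash(),
        counts=counts,
        warnings=warns,
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(dataclasses.asdict(manifest), fh, indent=2)
    return manifest
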