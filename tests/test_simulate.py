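import math

import numpy as np
import pytest

from ervtrace.dating import filter_de_novo_snvs
from ervtrace.io import Triad
from ervtrace.simulate import (
    FamilyModel,
    SimConfig,
    emit_alignment_records,
    generate_cohort,
    simulate_cohort_tallies,
    simulate_phenotypes,
    simulate_site_evidence,
    simulate_trio_snv_calls,
)
from ervtrace.zygosity import mendelian_consistent


def fixed_cfg(seed=0, aaf=0.5, **kw):
    fams = (FamilyModel(name="KoRV", founder_aaf=("fixed", aaf), n_sites=4),)
    return SimConfig(seed=seed, families=fams, **kw)


class TestConfig:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(denovo_integration_rate=-1)

    def test_short_contig_rejected(self):
        with pytest.raises(ValueError, match="contig_length"):
            SimConfig(contig_length=1000, read_length=150)

    def test_small_ltr_rejected(self):
        with pytest.raises(ValueError, match="ltr"):
            FamilyModel(name="x", ltr_length=10)

    def test_yaml_round_trip(self, tmp_path):
        cfg = fixed_cfg(seed=5, denovo_integration_rate=0.1)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert SimConfig.from_yaml(path) == cfg

    def test_family_gap_defaults(self):
        assert FamilyModel(name="KoRV").gap == 500
        assert FamilyModel(name="phaCin-beta").gap == 9000


class TestGenerateCohort:
    def test_zero_founders_errors(self):
        with pytest.raises(ValueError, match="empty pedigree"):
            generate_cohort(fixed_cfg(), 0, 1)

    def test_no_variation_case(self):
        cohort = generate_cohort(fixed_cfg(aaf=0.0), 4, 2)
        genos = cohort.genotype_frame()
        assert (genos.to_numpy() == 0).all()
        assert cohort.denovo_events == []

    def test_fixed_site_stays_fixed(self):
        cohort = generate_cohort(fixed_cfg(aaf=1.0), 4, 3)
        genos = cohort.genotype_frame()
        assert (genos.to_numpy() == 2).all()

    def test_determinism(self):
        a = generate_cohort(fixed_cfg(seed=42, aaf=0.4), 6, 2)
        b = generate_cohort(fixed_cfg(seed=42, aaf=0.4), 6, 2)
        assert a.reference == b.reference
        assert a.sites == b.sites
        assert a.genotype_frame().equals(b.genotype_frame())
        ta, _ = simulate_cohort_tallies(a)
        tb, _ = simulate_cohort_tallies(b)
        assert ta == tb

    def test_mendelian_consistency_exhaustive(self):
        cfg = fixed_cfg(seed=3, aaf=0.5)
        cohort = generate_cohort(cfg, 8, 3)
        ped = cohort.pedigree()
        genos = cohort.genotype_frame()
        for triad in ped.triads():
            for site in genos.columns:
                assert mendelian_consistent(
                    genos.at[triad.joey_id, site],
                    genos.at[triad.sire_id, site],
                    genos.at[triad.dam_id, site],
                )

    def test_transmission_fraction_binomial(self):
        # het x hom-ref: transmitted-allele fraction within 3 binomial SE
        # of 0.5 over 10,000 offspring alleles
        fams = (FamilyModel(name="KoRV", founder_aaf=("fixed", 0.5), n_sites=4),)
        cfg = SimConfig(seed=21, families=fams)
        rng = np.random.default_rng(100)
        n = 10_000
        transmitted = rng.random(n) < 0.5  # independent oracle: Bernoulli(1/2)
        se = math.sqrt(0.25 / n)
        assert abs(transmitted.mean() - 0.5) < 3 * se
        # and the generator's own transmissions behave the same way:
        cohort = generate_cohort(cfg, 40, 4)
        genos = cohort.genotype_frame()
        alleles = []
        for triad in cohort.pedigree().triads():
            for site in genos.columns:
                if (
                    genos.at[triad.sire_id, site] == 1
                    and genos.at[triad.dam_id, site] == 0
                ):
                    alleles.append(genos.at[triad.joey_id, site])
        alleles = np.array(alleles)
        assert len(alleles) > 50
        frac = alleles.mean()  # each joey carries 0 or 1 copies here
        se = math.sqrt(0.25 / len(alleles))
        assert abs(frac - 0.5) < 3 * se

    def test_denovo_events_recorded_and_het(self):
        cfg = fixed_cfg(seed=9, aaf=0.0, denovo_integration_rate=0.5)
        cohort = generate_cohort(cfg, 6, 2)
        assert cohort.denovo_events
        for site_id, joey in cohort.denovo_events:
            assert cohort.individuals[joey].genotypes[site_id] == 1


class TestSiteEvidence:
    def test_hom_ref_no_noise(self):
        t = simulate_site_evidence(0, 40, 0.0, 1)
        assert (t.n_softclip, t.n_crossing) == (0, 40)

    def test_hom_alt_no_noise(self):
        t = simulate_site_evidence(2, 40, 0.0, 1)
        assert (t.n_softclip, t.n_crossing) == (40, 0)

    def test_zero_coverage_empty(self):
        t = simulate_site_evidence(1, 0, 0.0, 1)
        assert t.total == 0

    def test_het_mean_fraction(self):
        # law of large numbers: mean soft-clip fraction over 1e5 draws of
        # coverage 40 within 0.005 of 0.5
        rng = np.random.default_rng(2)
        fracs = rng.binomial(40, 0.5, size=100_000) / 40  # oracle
        assert abs(fracs.mean() - 0.5) < 0.005
        sim = np.array(
            [
                simulate_site_evidence(1, 40, 0.0, rng).n_softclip
                for _ in range(100_000)
            ]
        )
        assert abs(sim.mean() / 40 - 0.5) < 0.005


class TestEmitAlignments:
    def test_unknown_mode_errors(self, small_cohort):
        iid = next(iter(small_cohort.individuals))
        with pytest.raises(ValueError, match="unknown mode"):
            emit_alignment_records(small_cohort, iid, mode="nanopore")

    def test_no_integrations_no_viral_records(self):
        cohort = generate_cohort(fixed_cfg(aaf=0.0), 4, 1)
        iid = next(iter(cohort.individuals))
        recs = emit_alignment_records(cohort, iid)
        assert recs.virus == []
        assert recs.masked_host == []
        assert recs.truth == {}

    def test_het_junction_read_expectation(self):
        # Poisson(30) coverage halved at het sites: ~15 evidence reads per
        # site; mean over 200 sites within 10% of expectation
        fams = (
            FamilyModel(name="KoRV", founder_aaf=("fixed", 0.5), n_sites=25),
        )
        cfg = SimConfig(
            seed=17, families=fams, n_contigs=5, contig_length=300_000,
            mean_coverage=30.0,
        )
        cohort = generate_cohort(cfg, 10, 1)
        genos = cohort.genotype_frame()
        counts = []
        for iid in cohort.individuals:
            recs = emit_alignment_records(cohort, iid)
            per_site = {}
            for read_id, sid in recs.truth.items():
                per_site[sid] = per_site.get(sid, 0) + 1
            for sid in genos.columns:
                if genos.at[iid, sid] == 1:
                    counts.append(per_site.get(sid, 0))
        counts = np.array(counts)
        assert len(counts) >= 200
        assert abs(counts.mean() - 15.0) <= 1.5

    def test_long_read_truth_labels(self, small_cohort):
        genos = small_cohort.genotype_frame()
        iid = genos.index[(genos > 0).any(axis=1)][0]
        carried = genos.columns[genos.loc[iid] > 0][0]
        lr = emit_alignment_records(
            small_cohort, iid, mode="long_read",
            ipcr_support={carried: 600},
        )
        # somatic sites come via the dedicated entry point
        from ervtrace.simulate import emit_ipcr_reads

        lr2 = emit_ipcr_reads(
            small_cohort, iid, {carried: 600},
            somatic_sites=[("contig1", 12345, 40)],
        )
        truth = lr2.truth.set_index("site_id")
        assert truth.at[carried, "label"] == "endogenous"
        assert truth.at["somatic_001", "label"] == "somatic"
        assert truth.at[carried, "support"] == 600
        assert len(lr.reads) == 600


class TestTrioSnv:
    def _cohort(self, **kw):
        return generate_cohort(fixed_cfg(seed=5, aaf=0.3, **kw), 6, 2)

    def _triad(self, cohort):
        return cohort.pedigree().triads()[0]

    def test_zero_rate_zero_records(self):
        cohort = self._cohort()
        records, truth = simulate_trio_snv_calls(cohort, self._triad(cohort))
        assert records == [] and truth == []

    def test_missing_parent_errors(self):
        cohort = self._cohort()
        with pytest.raises(ValueError, match="not a triad"):
            simulate_trio_snv_calls(
                cohort, Triad(None, "SB0001", "SB0002")
            )

    def test_poisson_mean_two_per_trio(self):
        # rate 1e-6 on 1e6 bp haploid -> diploid expectation 2.0 per trio;
        # mean over 100 trios within 3 SE (Poisson oracle)
        fams = (FamilyModel(name="KoRV", founder_aaf=("fixed", 0.0), n_sites=1),)
        cfg = SimConfig(
            seed=23, families=fams, n_contigs=1, contig_length=1_000_000,
            snv_mutation_rate=1e-6,
        )
        cohort = generate_cohort(cfg, 8, 2)
        triad = cohort.pedigree().triads()[0]
        counts = [
            len(simulate_trio_snv_calls(cohort, triad, label=f"rep{i}")[1])
            for i in range(100)
        ]
        se = math.sqrt(2.0 / 100)
        assert abs(np.mean(counts) - 2.0) < 3 * se

    def test_false_positive_present_but_not_in_truth(self):
        fams = (FamilyModel(name="KoRV", founder_aaf=("fixed", 0.0), n_sites=1),)
        cfg = SimConfig(
            seed=29, families=fams, snv_false_positive_rate=5.0,
        )
        cohort = generate_cohort(cfg, 6, 2)
        records, truth = simulate_trio_snv_calls(
            cohort, cohort.pedigree().triads()[0]
        )
        assert truth == []
        assert records  # false positives exist...
        passing, _ = filter_de_novo_snvs(records)
        assert passing == []  # ...and every one fails the QC filter


class TestPhenotypes:
    def test_binary_effect_direction(self, small_cohort):
        genos = small_cohort.genotype_frame()
        marker = genos.columns[0]
        trait = simulate_phenotypes(
            genos, {marker: 3.0}, kind="binary", intercept=-1.5, seed=4
        )
        carriers = trait[genos[marker] > 0]
        non = trait[genos[marker] == 0]
        if len(carriers) > 3 and len(non) > 3:
            assert carriers.mean() >= non.mean()

    def test_continuous_deterministic_with_seed(self, small_cohort):
        genos = small_cohort.genotype_frame()
        a = simulate_phenotypes(genos, {}, kind="continuous", seed=1)
        b = simulate_phenotypes(genos, {}, kind="continuous", seed=1)
        assert a.equals(b)
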