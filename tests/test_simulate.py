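import io

import numpy as np
import pytest

from arsenicqtl.pedigree import classify_relationships, kinship_matrix, load_pedigree, write_pedigree
from arsenicqtl.simulate import (
    FamilyTemplate,
    QTLSpec,
    SimulationConfig,
    gene_drop_genotypes,
    generate_map,
    generate_pedigrees,
    generate_study,
    simulate_arsenic_composition,
    simulate_trait,
)


class TestConfigValidation:
    def test_variance_fractions_bounded(self):
        with pytest.raises(ValueError, match="exceed 1"):
            SimulationConfig(seed=1, h2={"iAs": 0.8, "MMA": 0.5},
                             qtl=QTLSpec(chrom=1, pos_cm=10, variance_fraction=0.3,
                                         trait="iAs"))

    def test_too_few_alleles(self):
        with pytest.raises(ValueError, match="alleles"):
            SimulationConfig(seed=1, n_alleles=1)

    def test_template_consistency(self):
        with pytest.raises(ValueError):
            FamilyTemplate(generations=2, n_sibs=3, n_married=1).validate()


class TestGeneratePedigrees:
    def test_two_generation_census(self):
        cfg = SimulationConfig(seed=1, n_families=1,
                               template=FamilyTemplate(generations=2, n_sibs=3,
                                                       n_married=0,
                                                       half_sib_kid=False))
        ped = generate_pedigrees(cfg)
        census = classify_relationships(ped)
        assert census["parent_offspring"] == 6
        assert census["siblings"] == 3

    def test_default_template_size_range(self):
        cfg = SimulationConfig(seed=2, n_families=40)
        ped = generate_pedigrees(cfg)
        assert 400 <= len(ped) <= 800

    def test_named_relationship_classes_present(self):
        cfg = SimulationConfig(seed=3, n_families=5)
        census = classify_relationships(generate_pedigrees(cfg))
        for cls in ("parent_offspring", "siblings", "avuncular",
                    "half_siblings", "first_cousins"):
            assert census[cls] > 0, cls

    def test_same_seed_identical_file_bytes(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_families=6)
        for name in ("a.ped", "b.ped"):
            write_pedigree(generate_pedigrees(cfg), tmp_path / name)
        assert (tmp_path / "a.ped").read_bytes() == (tmp_path / "b.ped").read_bytes()

    def test_outbred(self):
        cfg = SimulationConfig(seed=4, n_families=10)
        ped = generate_pedigrees(cfg)
        kin = kinship_matrix(ped)
        assert np.allclose(np.diag(kin.phi), 0.5)


class TestGeneDrop:
    def test_map_spacing_in_range(self):
        cfg = SimulationConfig(seed=5, n_chromosomes=3, markers_per_chrom=12)
        summary = generate_map(cfg).spacing_summary()
        assert summary["min_spacing_cm"] >= 2.4
        assert summary["max_spacing_cm"] <= 24.1

    def test_equifrequent_heterozygosity(self):
        """k = 4 equifrequent alleles give founder heterozygosity 1 - 1/k
        = 0.75 within +-0.03 at 500 founders."""
        cfg = SimulationConfig(seed=6, n_families=250,
                               template=FamilyTemplate(generations=2, n_sibs=1,
                                                       n_married=0,
                                                       half_sib_kid=False),
                               n_chromosomes=1, markers_per_chrom=6, n_alleles=4)
        ped = generate_pedigrees(cfg)
        gmap = generate_map(cfg)
        genos, _ = gene_drop_genotypes(ped, gmap, cfg)
        founders = ped.founders
        assert len(founders) == 500
        het = np.mean([
            np.mean(arr[founders, 0] != arr[founders, 1])
            for arr in genos.data.values()
        ])
        assert abs(het - 0.75) < 0.03

    def test_zero_distance_complete_linkage(self):
        """At 0 cM separation no meiosis recombines: every transmitted
        two-locus haplotype matches one parental haplotype exactly."""
        from arsenicqtl.simulate import _drop_loci_with_unique

        cfg = SimulationConfig(seed=7, n_families=20,
                               template=FamilyTemplate(generations=2, n_sibs=2,
                                                       n_married=0,
                                                       half_sib_kid=False))
        ped = generate_pedigrees(cfg)
        rng = np.random.default_rng(7)
        # huge allele space makes founder haplotypes unique w.h.p.
        hap = _drop_loci_with_unique(ped, np.array([5.0, 5.0]), 10**6, None, rng)
        for i in range(len(ped)):
            for which, parent in ((0, ped.father[i]), (1, ped.mother[i])):
                if parent < 0:
                    continue
                child_hap = (hap[i, 0, which], hap[i, 1, which])
                parental = {(hap[parent, 0, k], hap[parent, 1, k]) for k in (0, 1)}
                assert child_hap in parental

    def test_sib_pair_mean_pihat_half(self):
        """Mendelian expectation: sib IBD sharing at one marker averages 0.5."""
        cfg = SimulationConfig(seed=8, n_families=2500,
                               template=FamilyTemplate(generations=2, n_sibs=2,
                                                       n_married=0,
                                                       half_sib_kid=False),
                               n_chromosomes=1, markers_per_chrom=1)
        ped = generate_pedigrees(cfg)
        rng = np.random.default_rng(8)
        from arsenicqtl.simulate import _drop_loci_with_unique

        hap = _drop_loci_with_unique(ped, np.array([0.0]), 4, 0, rng)
        lab = hap[:, 0, :]
        shares = []
        for fam in ped.families():
            a, b = fam[2], fam[3]
            s = (np.isin(lab[a], lab[b]).sum()) / 2.0
            shares.append(s)
        shares = np.array(shares)
        se = shares.std(ddof=1) / np.sqrt(len(shares))
        assert abs(shares.mean() - 0.5) <= 3 * se


class TestSimulateTrait:
    def test_null_structure_family_independence(self):
        """With h2 = 0 family means vary only as independence predicts."""
        cfg = SimulationConfig(seed=10, n_families=120,
                               template=FamilyTemplate(generations=2, n_sibs=3,
                                                       n_married=0,
                                                       half_sib_kid=False))
        ped = generate_pedigrees(cfg)
        rng = np.random.default_rng(10)
        y, _ = simulate_trait(ped, h2=0.0, rng=rng)
        fams = ped.families()
        k = len(fams[0])
        means = np.array([y[f].mean() for f in fams])
        # Var(family mean) = sigma2/k under independence
        ratio = means.var(ddof=1) / (y.var(ddof=1) / k)
        assert 0.6 < ratio < 1.5

    def test_sib_correlation_no_noise(self):
        """sigma2_e = 0, no QTL: sib trait correlation ~0.5."""
        cfg = SimulationConfig(seed=11, n_families=1000,
                               template=FamilyTemplate(generations=2, n_sibs=2,
                                                       n_married=0,
                                                       half_sib_kid=False))
        ped = generate_pedigrees(cfg)
        rng = np.random.default_rng(11)
        y, _ = simulate_trait(ped, h2=1.0, rng=rng)
        a = np.array([y[f[2]] for f in ped.families()])
        b = np.array([y[f[3]] for f in ped.families()])
        r = np.corrcoef(a, b)[0, 1]
        assert abs(r - 0.5) < 0.05

    def test_qtl_variance_realized(self):
        cfg = SimulationConfig(seed=12, n_families=60, n_chromosomes=1,
                               qtl=QTLSpec(chrom=1, pos_cm=30.0,
                                           variance_fraction=0.3, trait="iAs"))
        ped = generate_pedigrees(cfg)
        gmap = generate_map(cfg)
        _, labels = gene_drop_genotypes(ped, gmap, cfg, qtl=cfg.qtl)
        rng = np.random.default_rng(12)
        y, comps = simulate_trait(ped, h2=0.3, rng=rng, qtl_labels=labels,
                                  qtl_fraction=0.3)
        frac = comps["qtl"].var() / y.var()
        assert 0.15 < frac < 0.45


class TestComposition:
    def test_sums_to_100(self):
        cfg = SimulationConfig(seed=13, n_families=10)
        ped = generate_pedigrees(cfg)
        records, _ = simulate_arsenic_composition(ped, cfg)
        from arsenicqtl.phenotype import compute_percentages

        pcts = compute_percentages(records)
        assert np.allclose(pcts.sum(axis=1), 100.0, atol=1e-9)

    def test_male_mma_effect_direction(self):
        cfg = SimulationConfig(seed=14, n_families=60)
        ped = generate_pedigrees(cfg)
        records, _ = simulate_arsenic_composition(ped, cfg)
        from arsenicqtl.phenotype import compute_percentages

        pcts = compute_percentages(records)
        male = records["sex"] == "M"
        assert pcts.loc[male.to_numpy(), "pct_MMA"].median() > \
            pcts.loc[(~male).to_numpy(), "pct_MMA"].median()

    def test_truth_record_fractions(self):
        cfg = SimulationConfig(seed=15, n_families=40)
        ped = generate_pedigrees(cfg)
        _, truth = simulate_arsenic_composition(ped, cfg)
        frac = truth.realized_fractions("iAs")
        assert abs(sum(frac.values()) - 1.0) < 1e-9
        assert frac["genetic"] > 0.2


class TestStudyRoundTrip:
    def test_write_then_read_identical(self, tmp_path):
        cfg = SimulationConfig(seed=16, n_families=5, markers_per_chrom=4)
        study = generate_study(cfg)
        study.write(tmp_path)
        from arsenicqtl.ibd import load_genotypes, load_map

        ped2 = load_pedigree(tmp_path / "pedigree.tsv")
        assert ped2.ids == study.pedigree.ids
        assert ped2.household == study.pedigree.household
        gmap2 = load_map(tmp_path / "markers.map")
        assert list(gmap2.table["marker"]) == list(study.gmap.table["marker"])
        genos2 = load_genotypes(tmp_path / "genotypes.tsv")
        for m in study.genotypes.data:
            assert np.array_equal(genos2.data[m], study.genotypes.data[m])
        import pandas as pd

        rec2 = pd.read_csv(tmp_path / "phenotypes.csv").set_index("iid")
        assert np.allclose(rec2["iAs"], study.records["iAs"])

    def test_reproducible_from_seed(self):
        a = generate_study(SimulationConfig(seed=17, n_families=4))
        b = generate_study(SimulationConfig(seed=17, n_families=4))
        assert np.allclose(a.records["iAs"], b.records["iAs"])
        assert a.pedigree.ids == b.pedigree.ids
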