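import numpy as np
import pytest

from bsamap import synthio
from bsamap.synthio import (
    BulkReadConfig,
    F2SimConfig,
    PanelSimConfig,
    PHENO_NEG,
    PHENO_POS,
    simulate_bulk_reads,
    simulate_f2,
    simulate_panel,
)


def _config(**kw):
    base = dict(chrom_name="chr1", chrom_length_bp=1_000_000, n_individuals=50,
                snp_positions=[10_000, 500_000, 900_000], causal_pos_bp=500_000, seed=0)
    base.update(kw)
    return F2SimConfig(**base)


class TestF2SimConfig:
    def test_rejects_unsorted_snps(self):
        with pytest.raises(ValueError):
            _config(snp_positions=[500, 400])

    def test_rejects_snp_outside_chromosome(self):
        with pytest.raises(ValueError):
            _config(snp_positions=[10, 2_000_000])

    def test_rejects_causal_outside_chromosome(self):
        with pytest.raises(ValueError):
            _config(causal_pos_bp=2_000_000)

    def test_rejects_negative_recomb_rate(self):
        with pytest.raises(ValueError):
            _config(recomb_rate_cM_per_Mb=-1.0)


class TestSimulateF2:
    def test_deterministic_under_seed(self):
        a = simulate_f2(_config(seed=5))
        b = simulate_f2(_config(seed=5))
        assert all(np.array_equal(x.dosage, y.dosage) for x, y in zip(a, b))
        assert [x.phenotype for x in a] == [y.phenotype for y in b]

    def test_seed_changes_output(self):
        a = simulate_f2(_config(seed=5))
        b = simulate_f2(_config(seed=6))
        assert any(not np.array_equal(x.dosage, y.dosage) for x, y in zip(a, b))

    def test_three_to_one_segregation(self):
        # 3:1 dominance segregation at n = 4000
        inds = simulate_f2(_config(n_individuals=4000, seed=11))
        frac = np.mean([i.phenotype == PHENO_POS for i in inds])
        se = np.sqrt(0.75 * 0.25 / 4000)
        assert abs(frac - 0.75) < 3 * se

    def test_one_two_one_causal_genotypes(self):
        inds = simulate_f2(_config(n_individuals=4000, seed=13))
        counts = np.bincount([i.causal_dosage for i in inds], minlength=3) / 4000
        assert np.allclose(counts, [0.25, 0.5, 0.25], atol=0.03)

    def test_zero_recomb_rate_gives_constant_genotype_vectors(self):
        inds = simulate_f2(_config(recomb_rate_cM_per_Mb=0.0, seed=3))
        for ind in inds:
            assert len(set(ind.dosage.tolist())) == 1

    def test_genotype_codes(self):
        ind = simulate_f2(_config(seed=1))[0]
        assert set(ind.genotypes) <= {"AA", "AB", "BB"}

    def test_phenotype_follows_dominance(self):
        for ind in simulate_f2(_config(seed=2)):
            expected = PHENO_POS if ind.causal_dosage >= 1 else PHENO_NEG
            assert ind.phenotype == expected

    def test_error_when_phenotype_requested_without_causal(self):
        with pytest.raises(ValueError, match="no causal locus"):
            simulate_f2(_config(causal_pos_bp=None))

    def test_no_phenotypes_without_causal_is_allowed(self):
        inds = simulate_f2(_config(causal_pos_bp=None), assign_phenotypes=False)
        assert all(i.phenotype is None for i in inds)

    def test_recombinant_count_matches_haldane_expectation(self):
        # two markers 1.67 cM apart in an F2 of 1109: expected code-difference
        # count is N * (1 - (1-r)^2 - r^2/2) ~ 2*N*r ~ 37
        pos = [100_000, 517_500]  # 0.4175 Mb * 4 cM/Mb = 1.67 cM
        d_morgans = 0.0167
        r = (1 - np.exp(-2 * d_morgans)) / 2
        p_diff = 1 - (1 - r) ** 2 - r ** 2 / 2
        expected = 1109 * p_diff
        counts = []
        for seed in range(8):
            cfg = _config(chrom_length_bp=1_000_000, n_individuals=1109,
                          snp_positions=pos, causal_pos_bp=300_000, seed=seed)
            inds = simulate_f2(cfg)
            counts.append(sum(ind.dosage[0] != ind.dosage[1] for ind in inds))
        se = np.sqrt(expected / 8)  # Poisson-scale error of the mean over 8 seeds
        assert abs(np.mean(counts) - expected) < 3 * se
        assert 30 < expected < 40  # sanity: the closed form itself is ~37


class TestSimulateBulkReads:
    def test_deterministic(self, small_f2):
        cfg, inds = small_f2
        a = simulate_bulk_reads(inds, BulkReadConfig(seed=9), cfg.chrom_name, cfg.snp_positions)
        b = simulate_bulk_reads(inds, BulkReadConfig(seed=9), cfg.chrom_name, cfg.snp_positions)
        assert a == b

    def test_monomorphic_bulk_gives_zero_alt_depth(self):
        inds = [synthio.F2Individual(id=f"i{k}", dosage=np.zeros(1, dtype=np.int8))
                for k in range(8)]
        calls = simulate_bulk_reads(inds, BulkReadConfig(n_per_bulk=4, mean_depth=20, seed=0),
                                    "chr1", [100], split="random")
        assert calls[0].alt_depth_pool1 == 0
        assert calls[0].alt_depth_pool2 == 0

    def test_causal_snp_frequency_two_thirds_in_positive_bulk(self):
        # prickly F2 are 1/3 BB + 2/3 AB, so the bulk B-allele frequency is 2/3
        cfg = _config(n_individuals=2000, snp_positions=[500_000], seed=21)
        inds = simulate_f2(cfg)
        calls = simulate_bulk_reads(
            inds, BulkReadConfig(n_per_bulk=400, mean_depth=5000, seed=2),
            cfg.chrom_name, cfg.snp_positions)
        idx1 = calls[0].alt_depth_pool1 / calls[0].depth_pool1
        idx2 = calls[0].alt_depth_pool2 / calls[0].depth_pool2
        assert abs(idx1 - 2 / 3) < 0.05
        assert idx2 < 0.02  # negative bulk is homozygous A at the causal SNP

    def test_null_mean_index_half(self):
        # random bulks at fixed depth 40: per-bulk SNP-index averages 0.5
        rng = np.random.default_rng(0)
        snps = np.sort(rng.choice(np.arange(1, 10_000_001), 10_000, replace=False)).tolist()
        cfg = _config(chrom_length_bp=10_000_000, n_individuals=200, snp_positions=snps,
                      causal_pos_bp=None, recomb_rate_cM_per_Mb=5000.0, seed=17)
        inds = simulate_f2(cfg, assign_phenotypes=False)
        calls = simulate_bulk_reads(inds, BulkReadConfig(mean_depth=40, seed=3),
                                    cfg.chrom_name, snps, split="random")
        idx1 = np.array([c.alt_depth_pool1 / c.depth_pool1 for c in calls])
        idx2 = np.array([c.alt_depth_pool2 / c.depth_pool2 for c in calls])
        # near-unlinked SNPs: per-SNP indices are ~iid, SE ~ 0.001
        assert abs(idx1.mean() - 0.5) < 0.01
        assert abs(idx2.mean() - 0.5) < 0.01

    def test_insufficient_individuals_raises(self, small_f2):
        cfg, inds = small_f2
        with pytest.raises(ValueError, match="insufficient"):
            simulate_bulk_reads(inds, BulkReadConfig(n_per_bulk=1000, seed=0),
                                cfg.chrom_name, cfg.snp_positions)

    def test_default_quality_above_filter_floor(self, small_f2):
        cfg, inds = small_f2
        calls = simulate_bulk_reads(inds, BulkReadConfig(seed=1), cfg.chrom_name,
                                    cfg.snp_positions)
        assert all(c.mapping_quality >= 20 and c.base_quality >= 20 for c in calls)

    def test_decoys_fail_the_filter(self, small_f2):
        from bsamap.variantio import filter_variants
        cfg, inds = small_f2
        calls = simulate_bulk_reads(
            inds, BulkReadConfig(seed=1, decoy_fraction=0.2), cfg.chrom_name,
            cfg.snp_positions)
        result = filter_variants(calls)
        n_rejected = len(calls) - len(result.retained)
        assert n_rejected > 0
        assert sum(result.tallies.values()) >= n_rejected

    def test_negative_binomial_depth_law(self, small_f2):
        cfg, inds = small_f2
        calls = simulate_bulk_reads(
            inds, BulkReadConfig(mean_depth=40, depth_dispersion=0.2, seed=5),
            cfg.chrom_name, cfg.snp_positions)
        depths = np.array([c.depth_pool1 for c in calls])
        assert abs(depths.mean() - 40) < 5
        assert depths.var() > depths.mean()  # overdispersed


class TestSimulatePanel:
    def test_default_marginals(self):
        panel = simulate_panel(PanelSimConfig(seed=0))
        pos = panel[panel.phenotype == PHENO_POS]
        neg = panel[panel.phenotype == PHENO_NEG]
        assert len(pos) == 18 and set(pos.genotype) <= {"D", "H"}
        assert (neg.genotype == "R").sum() == 166
        assert (neg.genotype == "D").sum() == 6

    def test_deterministic(self):
        a = simulate_panel(PanelSimConfig(seed=3))
        b = simulate_panel(PanelSimConfig(seed=3))
        assert a.equals(b)

    def test_no_discordant_gives_perfect_association(self):
        from bsamap import assoc
        panel = simulate_panel(PanelSimConfig(n_discordant_prickleless_D=0, seed=1))
        table = assoc.carrier_table(panel)
        assert table.b == 0 and table.c == 0

    def test_discordant_bound_enforced(self):
        with pytest.raises(ValueError):
            PanelSimConfig(n_prickleless=5, n_discordant_prickleless_D=6)


class TestFixtureSequences:
    def test_haplotypes_differ_at_position_16_only(self):
        fx = synthio.fixture_sequences()
        assert len(fx.prickly) == len(fx.prickleless) == 31
        diffs = [i for i, (a, b) in enumerate(zip(fx.prickly, fx.prickleless), start=1)
                 if a != b]
        assert diffs == [16]

    def test_positive_haplotype_has_one_sspi_site(self, sspi):
        fx = synthio.fixture_sequences()
        assert fx.prickly.count(sspi.recognition) == 1
        assert fx.prickly.find(sspi.recognition) == 12  # 1-based positions 13-18

    def test_negative_haplotype_has_no_sspi_site(self, sspi):
        fx = synthio.fixture_sequences()
        assert sspi.recognition not in fx.prickleless

    def test_embed_places_snp_at_requested_offset(self):
        fx = synthio.fixture_sequences()
        amp = fx.embed(fx.prickly, 391, 153)
        assert len(amp) == 391
        assert amp[152] == "A"  # the SNP base, 1-based offset 153

    def test_embed_rejects_incompatible_offset(self):
        fx = synthio.fixture_sequences()
        with pytest.raises(ValueError, match="incompatible"):
            fx.embed(fx.prickly, 40, 5)


class TestMarkerTable:
    def test_codes_match_dosage(self, small_f2):
        cfg, inds = small_f2
        markers = cfg.snp_positions[:3]
        df = synthio.marker_table_from_f2(inds, cfg.snp_positions, markers)
        for j, ind in enumerate(inds[:20]):
            expected = {0: "A", 1: "H", 2: "B"}[int(ind.dosage[0])]
            assert df.iloc[j, 2] == expected

    def test_rejects_position_not_in_snps(self, small_f2):
        cfg, inds = small_f2
        with pytest.raises(ValueError, match="subset"):
            synthio.marker_table_from_f2(inds, cfg.snp_positions, [123])
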