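import itertools

import numpy as np
import pytest

from paradoxcna import paradox
from paradoxcna.cna_integration import AberrantRegion
from paradoxcna.formats_io import GenomicInterval

from conftest import make_matrix


def region(chrom, start, end, direction, name="r"):
    return AberrantRegion(interval=GenomicInterval(chrom, start, end, name),
                          direction=direction, peak_frequency=0.3, peak_p=0.001)


class TestGeneRegionAssignment:
    def test_simple_overlap(self):
        genes = [GenomicInterval("chr1", 100, 200, "G")]
        assert paradox.assign_genes_to_regions(
            genes, [region("chr1", 150, 300, 1)]) == {"G": 1}

    def test_no_overlap_absent(self):
        genes = [GenomicInterval("chr1", 100, 200, "G")]
        assert paradox.assign_genes_to_regions(
            genes, [region("chr1", 500, 600, 1)]) == {}

    def test_larger_overlap_wins(self):
        genes = [GenomicInterval("chr1", 100, 200, "G")]
        regions = [region("chr1", 150, 300, 1, "gain"),     # 50 bp
                   region("chr1", 90, 110, -1, "loss")]     # 10 bp
        assert paradox.assign_genes_to_regions(genes, regions) == {"G": 1}

    def test_exact_tie_dropped(self):
        genes = [GenomicInterval("chr1", 100, 200, "G")]
        regions = [region("chr1", 150, 300, 1, "gain"),     # 50 bp
                   region("chr1", 50, 150, -1, "loss")]     # 50 bp
        assert paradox.assign_genes_to_regions(genes, regions) == {}


class TestAssociationChiSquare:
    def test_perfect_association(self):
        de = {f"u{i}": 1 for i in range(50)} | {f"d{i}": -1 for i in range(50)}
        regions = {f"u{i}": 1 for i in range(50)} | {f"d{i}": -1 for i in range(50)}
        chi2, p, table = paradox.association_chi_square(de, regions)
        assert chi2 == pytest.approx(100.0)       # chi2 = N for a perfect 2x2
        assert p < 1.6e-23
        np.testing.assert_array_equal(table, [[50, 0], [0, 50]])

    def test_independence(self):
        de, regions = {}, {}
        k = 0
        for d in (1, -1):
            for r in (1, -1):
                for _ in range(25):
                    de[f"g{k}"], regions[f"g{k}"] = d, r
                    k += 1
        chi2, p, _ = paradox.association_chi_square(de, regions)
        assert chi2 == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_zero_marginal_advises_exact_test(self):
        de = {"a": 1, "b": 1}
        regions = {"a": 1, "b": -1}
        with pytest.raises(ValueError, match="exact test"):
            paradox.association_chi_square(de, regions)


class TestParadoxClassification:
    def test_quadrants(self):
        de = {"down_in_gain": -1, "up_in_gain": 1, "down_nowhere": -1}
        regions = {"down_in_gain": 1, "up_in_gain": 1}
        records = {r.gene: r for r in paradox.identify_paradoxical(de, regions)}
        assert records["down_in_gain"].is_paradoxical
        assert not records["up_in_gain"].is_paradoxical
        assert "down_nowhere" not in records

    def test_flipping_regions_is_an_involution(self):
        rng = np.random.default_rng(0)
        de = {f"g{i}": int(d) for i, d in
              enumerate(rng.choice([-1, 1], size=40))}
        regions = {f"g{i}": int(d) for i, d in
                   enumerate(rng.choice([-1, 1], size=40))}
        flipped = {g: -d for g, d in regions.items()}
        a = {r.gene: r.is_paradoxical
             for r in paradox.identify_paradoxical(de, regions)}
        b = {r.gene: r.is_paradoxical
             for r in paradox.identify_paradoxical(de, flipped)}
        assert all(a[g] != b[g] for g in a)


class TestZScores:
    def test_tumor_at_normal_mean_is_zero(self):
        m = make_matrix(np.full((1, 3), 5.0), np.array([[4.0, 5.0, 6.0]]))
        z = paradox.zscore_expression(m)
        assert np.allclose(z.to_numpy(), 0.0)

    def test_hand_computation_with_sample_sd(self):
        m = make_matrix(np.array([[3.0]]), np.array([[0.0, 0.0, 2.0, 2.0]]))
        z = paradox.zscore_expression(m)
        # normals: mean 1, sd(ddof=1) = 1.1547 -> z = 2/1.1547 = 1.7320
        assert z.iloc[0, 0] == pytest.approx(1.7320508, abs=1e-6)

    def test_constant_normals_give_missing(self):
        m = make_matrix(np.array([[3.0]]), np.array([[1.0, 1.0, 1.0]]))
        z = paradox.zscore_expression(m)
        assert np.isnan(z.iloc[0, 0])


class TestSampleFrequencies:
    def test_hand_counted_frequencies(self):
        rec = paradox.ParadoxRecord(gene="G", de_direction=-1, region_direction=1)
        # 10 samples: 4 paradoxical (down & gained), 1 regular (down & lost),
        # 2 deregulated but copy-neutral, 3 unremarkable
        z = np.array([-2, -2, -2, -2, -2, -2, -2, 0, 0, 0], dtype=float)
        cna = np.array([0.5, 0.5, 0.5, 0.5, -0.5, 0.0, 0.0, 0.5, 0, 0])
        rec = paradox.sample_paradox_frequencies(z, cna, rec)
        assert rec.freq_paradoxical == pytest.approx(0.4)
        assert rec.freq_regular == pytest.approx(0.1)
        assert rec.freq_paradoxical > rec.freq_regular
        assert rec.freq_down == pytest.approx(0.7)
        assert rec.freq_gain == pytest.approx(0.5)

    def test_subthreshold_z_is_no_event(self):
        rec = paradox.ParadoxRecord(gene="G", de_direction=-1, region_direction=1)
        z = np.full(6, -1.0)              # inside the 1.647 cutoff
        cna = np.full(6, 0.9)
        rec = paradox.sample_paradox_frequencies(z, cna, rec)
        assert rec.freq_paradoxical == 0.0 and rec.freq_regular == 0.0

    def test_frequencies_sum_below_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            rec = paradox.ParadoxRecord(gene="G", de_direction=1,
                                        region_direction=-1)
            z = rng.normal(size=30) * 2
            cna = rng.normal(size=30) * 0.4
            rec = paradox.sample_paradox_frequencies(z, cna, rec)
            assert rec.freq_paradoxical + rec.freq_regular <= 1.0 + 1e-12


def exhaustive_validation_p(z, cna, rec, th):
    """Exact permutation p for the co-occurrence excess by enumerating every
    ordering of the CNA vector against the z vector."""
    def stat(c):
        dereg = z * rec.de_direction > th.z_cut
        par = dereg & (c * rec.region_direction > th.cna_cut)
        reg = dereg & (c * rec.region_direction < -th.cna_cut)
        return par.sum() - reg.sum()

    t_obs = stat(cna)
    perms = list(itertools.permutations(cna))
    hits = sum(stat(np.array(p)) >= t_obs for p in perms)
    return hits / len(perms)


class TestValidationRandomization:
    def test_perfect_coupling_reaches_floor(self):
        rec = paradox.ParadoxRecord(gene="G", de_direction=-1, region_direction=1)
        n = 200
        z = np.where(np.arange(n) < 80, -3.0, 0.0)
        cna = np.where(np.arange(n) < 80, 0.6, 0.0)
        rec = paradox.sample_paradox_frequencies(z, cna, rec)
        rec = paradox.validate_gene_randomization(z, cna, rec, n_rand=999, seed=0)
        assert rec.validation_p == pytest.approx(1 / 1000)
        th = paradox.AnalysisThresholds(validation_alpha=0.01)
        rec = paradox.validate_gene_randomization(z, cna, rec, n_rand=999,
                                                  seed=0, th=th)
        assert rec.validated

    def test_matches_exhaustive_toy_enumeration(self):
        th = paradox.AnalysisThresholds()
        rec = paradox.ParadoxRecord(gene="G", de_direction=-1, region_direction=1)
        z = np.array([-3.0, -2.0, 0.0, -2.5, 1.0])
        cna = np.array([0.6, -0.4, 0.0, 0.5, 0.3])
        rec = paradox.sample_paradox_frequencies(z, cna, rec, th)
        exact = exhaustive_validation_p(z, cna, rec, th)
        n_rand = 40_000
        rec = paradox.validate_gene_randomization(z, cna, rec, n_rand=n_rand,
                                                  seed=5, th=th)
        expected = (exact * n_rand + 1) / (n_rand + 1)
        mc_sd = np.sqrt(exact * (1 - exact) / n_rand)
        assert abs(rec.validation_p - expected) <= 3 * mc_sd

    def test_negative_excess_never_validates(self):
        rec = paradox.ParadoxRecord(gene="G", de_direction=-1, region_direction=1)
        n = 50
        z = np.where(np.arange(n) < 20, -3.0, 0.0)
        cna = np.where(np.arange(n) < 20, -0.6, 0.6)   # deregulated samples lost
        rec = paradox.sample_paradox_frequencies(z, cna, rec)
        rec = paradox.validate_gene_randomization(z, cna, rec, n_rand=999, seed=1)
        assert rec.freq_paradoxical < rec.freq_regular
        assert not rec.validated

    def test_rejects_zero_randomizations(self):
        rec = paradox.ParadoxRecord(gene="G", de_direction=1, region_direction=-1)
        with pytest.raises(ValueError):
            paradox.validate_gene_randomization(np.zeros(4), np.zeros(4), rec,
                                                n_rand=0)


class TestThresholds:
    def test_defaults_follow_the_reported_convention(self):
        th = paradox.AnalysisThresholds()
        assert th.z_cut == 1.647 and th.cna_cut == 0.2

    @pytest.mark.parametrize("kwargs", [dict(z_cut=-1), dict(cna_cut=0),
                                        dict(validation_alpha=0),
                                        dict(gene_alpha=1.0)])
    def test_invalid_thresholds_rejected(self, kwargs):
        with pytest.raises(ValueError):
            paradox.AnalysisThresholds(**kwargs)
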