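import numpy as np
import pandas as pd
import pytest

from refgraft import popgen_stats as pg


class TestSelectBiallelic:
    def _matrix(self, col, samples=None):
        samples = samples or [f"s{i}" for i in range(len(col))]
        return pd.DataFrame({"i1": col}, index=samples)

    def test_call_rate_above_threshold_passes(self):
        col = [1] * 96 + [np.nan] * 4  # 96% called in {0,1,2}
        m = self._matrix(col)
        assert pg.select_biallelic(m, "s0", 0) == ["i1"]

    def test_call_rate_exactly_at_threshold_fails(self):
        col = [1] * 95 + [np.nan] * 5  # exactly 95%: strict > required
        m = self._matrix(col)
        assert pg.select_biallelic(m, "s0", 0) == []

    def test_copy_number_above_two_breaks_biallelic_rate(self):
        col = [1] * 90 + [3] * 10  # multi-copy genotypes are not in {0,1,2}
        m = self._matrix(col)
        assert pg.select_biallelic(m, "s0", 0) == []

    def test_anchor_without_insertion_fails(self):
        col = [0] + [1] * 99
        m = self._matrix(col)
        assert pg.select_biallelic(m, "s0", 0) == []

    def test_unique_read_support_required(self):
        col = [1] * 100
        m = self._matrix(col)
        assert pg.select_biallelic(m, "s0", 5, {"i1": 4}) == []
        assert pg.select_biallelic(m, "s0", 5, {"i1": 5}) == ["i1"]

    def test_missing_anchor_sample_errors(self):
        with pytest.raises(KeyError):
            pg.select_biallelic(self._matrix([1, 1]), "nope", 0)


class TestAlleleFrequencies:
    def test_all_homozygous_freq_one(self):
        m = pd.DataFrame({"i1": [2, 2, 2]}, index=["a", "b", "c"])
        (rec,) = pg.allele_frequencies(m, {"a": "P", "b": "P", "c": "P"})
        assert rec.alt_freq == 1.0

    def test_counting_oracle(self):
        col = [0] * 50 + [1] * 30 + [2] * 20
        m = pd.DataFrame({"i1": col}, index=[f"s{i}" for i in range(100)])
        (rec,) = pg.allele_frequencies(m, {f"s{i}": "P" for i in range(100)})
        assert rec.alt_freq == pytest.approx((30 + 40) / 200)
        assert (rec.n_null, rec.n_het, rec.n_hom) == (50, 30, 20)

    def test_all_missing(self):
        m = pd.DataFrame({"i1": [np.nan, np.nan]}, index=["a", "b"])
        (rec,) = pg.allele_frequencies(m, {"a": "P", "b": "P"})
        assert rec.call_rate == 0.0
        assert np.isnan(rec.alt_freq)

    def test_counts_conserved_per_record(self, rng):
        n = 60
        vals = rng.choice([0, 1, 2, np.nan], n)
        m = pd.DataFrame({"i1": vals}, index=[f"s{i}" for i in range(n)])
        pops = {f"s{i}": ("X" if i < 30 else "Y") for i in range(n)}
        for rec in pg.allele_frequencies(m, pops):
            assert rec.n_null + rec.n_het + rec.n_hom + rec.n_missing == 30


def uniform_spectrum():
    return pg.FrequencySpectrumModel(
        "tabulated", np.linspace(1e-9, 1 - 1e-9, 2001), np.ones(2001)
    )


class TestDiscoveryRate:
    def test_uniform_spectrum_closed_form_two_chromosomes(self):
        # P = int_0^1 (2q - q^2) dq = 2/3
        p = pg.discovery_rate(uniform_spectrum(), 2, 1e-6)
        assert p == pytest.approx(2 / 3, abs=1e-4)

    @pytest.mark.parametrize("k", [2, 4, 8])
    def test_uniform_spectrum_closed_form_general(self, k):
        # int_0^1 (1 - (1-q)^k) dq = k / (k+1)
        p = pg.discovery_rate(uniform_spectrum(), k, 1e-6)
        assert p == pytest.approx(k / (k + 1), abs=1e-4)

    def test_saturates_for_large_sample(self):
        p = pg.discovery_rate(pg.FrequencySpectrumModel(), 10**6, 0.01)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_neutral_spectrum_common_variants_round_to_100(self):
        model = pg.FrequencySpectrumModel()
        for q_min in (0.30, 0.40):
            assert round(100 * pg.discovery_rate(model, 20, q_min)) == 100

    def test_monotone_in_sample_size_and_maf(self):
        model = pg.FrequencySpectrumModel()
        rates_n = [pg.discovery_rate(model, k, 0.05) for k in (2, 6, 12, 20)]
        assert rates_n == sorted(rates_n)
        rates_q = [pg.discovery_rate(model, 20, q) for q in (0.01, 0.05, 0.2, 0.4)]
        assert rates_q == sorted(rates_q)

    def test_quadrature_converged_at_default_resolution(self):
        model = pg.FrequencySpectrumModel()
        p1 = pg.discovery_rate(model, 20, 0.01, n_points=pg.QUADRATURE_POINTS)
        p2 = pg.discovery_rate(model, 20, 0.01, n_points=2 * pg.QUADRATURE_POINTS - 1)
        assert abs(p1 - p2) < 1e-6

    @pytest.mark.parametrize("bad_q", [0.0, 0.5, -0.1])
    def test_invalid_qmin_rejected(self, bad_q):
        with pytest.raises(ValueError):
            pg.discovery_rate(pg.FrequencySpectrumModel(), 20, bad_q)

    def test_incremental_gain_nonnegative_and_saturating(self):
        model = pg.FrequencySpectrumModel()
        g10 = pg.incremental_discovery_gain(model, 10, 0.01)
        g100 = pg.incremental_discovery_gain(model, 100, 0.01)
        assert g10 >= g100 >= 0

    def test_incremental_gain_uniform_closed_form(self):
        # P(4) - P(2) = 4/5 - 2/3
        g = pg.incremental_discovery_gain(uniform_spectrum(), 1, 1e-6)
        assert g == pytest.approx(4 / 5 - 2 / 3, abs=1e-4)


class TestClusterPopulations:
    def test_identical_populations_merge_first_at_zero(self):
        t = pd.DataFrame(
            [[0.1, 0.2], [0.1, 0.2], [0.9, 0.9]], index=["a", "b", "c"]
        )
        Z, _ = pg.cluster_populations(t)
        assert set(Z[0, :2]) == {0, 1}
        assert Z[0, 2] == 0.0

    def test_hand_computed_l1_distances(self):
        # pairwise L1: ab = 1, ac = 5, bc = 4 -> (a, b) merges first at 1
        t = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [2.0, 3.0]], index=list("abc"))
        Z, _ = pg.cluster_populations(t)
        assert set(Z[0, :2]) == {0, 1}
        assert Z[0, 2] == pytest.approx(1.0)
        assert Z[1, 2] == pytest.approx((5 + 4) / 2)  # average linkage

    def test_merge_heights_invariant_to_population_order(self, rng):
        t = pd.DataFrame(rng.random((5, 8)), index=list("abcde"))
        Z1, _ = pg.cluster_populations(t)
        perm = ["c", "a", "e", "b", "d"]
        Z2, _ = pg.cluster_populations(t.loc[perm])
        assert np.allclose(sorted(Z1[:, 2]), sorted(Z2[:, 2]))

    def test_single_population_errors(self):
        with pytest.raises(ValueError):
            pg.cluster_populations(pd.DataFrame([[0.1]], index=["a"]))

    def test_newick_output_contains_all_leaves(self):
        t = pd.DataFrame(
            [[0.0, 0.0], [1.0, 0.0], [2.0, 3.0]], index=["popA", "popB", "popC"]
        )
        Z, _ = pg.cluster_populations(t)
        nwk = pg.dendrogram_newick(Z, list(t.index))
        assert nwk.endswith(";")
        for leaf in t.index:
            assert leaf in nwk


class TestRepeatEnrichment:
    GENOME = {"chr1": 100_000}

    def test_empty_annotation_nothing_enriched(self):
        res = pg.repeat_enrichment([("chr1", 10, 200)], [], self.GENOME, 50, 1)
        assert res == []

    def test_saturated_class_not_enriched(self):
        ann = [("chr1", 0, 100_000, "X")]
        ins = [("chr1", i * 1000, i * 1000 + 150) for i in range(10)]
        (res,) = pg.repeat_enrichment(ins, ann, self.GENOME, 100, 1)
        assert res.observed_count == 10
        assert not res.enriched  # every random placement also hits X

    def test_planted_enrichment_detected(self):
        # class X covers 10% of the genome; all insertions placed inside it
        ann = [("chr1", 0, 10_000, "X")]
        ins = [("chr1", 100 + i * 800, 250 + i * 800) for i in range(10)]
        (res,) = pg.repeat_enrichment(ins, ann, self.GENOME, 200, 1)
        assert res.observed_count == 10
        assert res.enriched

    def test_uniform_fixture_not_enriched(self, rng):
        ann = [("chr1", 0, 10_000, "X")]
        ins = []
        for start in rng.integers(0, 99_000, 40):
            ins.append(("chr1", int(start), int(start) + 200))
        (res,) = pg.repeat_enrichment(ins, ann, self.GENOME, 200, 1)
        assert not res.enriched

    def test_seeded_null_reproducible(self):
        ann = [("chr1", 0, 30_000, "X"), ("chr1", 50_000, 60_000, "Y")]
        ins = [("chr1", 100, 400), ("chr1", 55_000, 55_300)]
        r1 = pg.repeat_enrichment(ins, ann, self.GENOME, 300, seed=42)
        r2 = pg.repeat_enrichment(ins, ann, self.GENOME, 300, seed=42)
        assert r1 == r2

    def test_multiple_records_counted_multiply(self):
        ann = [("chr1", 0, 1000, "X"), ("chr1", 100, 500, "X")]
        ins = [("chr1", 200, 300)]
        (res,) = pg.repeat_enrichment(ins, ann, self.GENOME, 10, 1)
        assert res.observed_count == 2


class TestGcEntropy:
    def test_homopolymer(self):
        assert pg.gc_entropy("AAAAAA") == (0.0, 0.0)

    def test_two_equiprobable_dinucleotides(self):
        # odd length so AT and TA each occur exactly 4 times
        gc, ent = pg.gc_entropy("ATATATATA")
        assert gc == 0.0
        assert ent == pytest.approx(1.0)

    def test_uniform_16_patterns_maximum_entropy(self):
        # de Bruijn B(4,2) linearisation: every dinucleotide exactly once
        seq = "AACAGATCCGCTGGTTA"
        counts = {seq[i : i + 2] for i in range(len(seq) - 1)}
        assert len(counts) == 16  # fixture self-check
        _, ent = pg.gc_entropy(seq)
        assert ent == pytest.approx(4.0)

    def test_ambiguous_bases_skipped(self):
        # N-containing dinucleotides drop out: ATA twice -> AT:2, TA:2
        _, ent = pg.gc_entropy("ATANNATA")
        assert ent == pytest.approx(1.0)

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            pg.gc_entropy("A")


class TestDistanceBins:
    def test_nearest_site_binning(self):
        catalog = {"chr1": [1000, 5000]}
        exclusive, cumulative = pg.distance_bins(
            [("chr1", 1050), ("chr1", 1905), ("chr1", 60_000)], catalog
        )
        assert exclusive["<100"] == 1  # 50 away
        assert exclusive["<1K"] == 1  # min(905, 3095) = 905
        assert exclusive["<100K"] == 1
        assert cumulative["<100K"] == 3

    def test_chromosome_without_catalog_is_na(self):
        exclusive, _ = pg.distance_bins([("chrY", 100)], {"chr1": [5]})
        assert exclusive["NA"] == 1

    def test_two_sites_nearest_wins(self):
        exclusive, _ = pg.distance_bins([("chr1", 0)], {"chr1": [90, 900]})
        assert exclusive["<100"] == 1
        assert exclusive["<1K"] == 0


class TestVariantsInRegions:
    VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\n"

    def _vcf(self, tmp_path, body):
        p = tmp_path / "in.vcf"
        p.write_text(self.VCF_HEADER + body)
        return str(p)

    def test_empty_vcf(self, tmp_path):
        total, _ = pg.variants_in_regions(self._vcf(tmp_path, ""), [("chr1", 0, 100)])
        assert total == 0

    def test_direct_count(self, tmp_path):
        body = (
            "chr1\t50\t.\tA\tG\n"  # inside [0, 100)
            "chr1\t150\t.\tA\tG\n"  # outside
            "chr1\t250\t.\tA\tG\n"  # inside [200, 300)
        )
        total, per = pg.variants_in_regions(
            self._vcf(tmp_path, body), [("chr1", 0, 100), ("chr1", 200, 300)]
        )
        assert total == 2
        assert per["chr1:0-100"] == 1

    def test_region_start_boundary_counted(self, tmp_path):
        # VCF POS 201 = 0-based 200 = region start: inside half-open interval
        total, _ = pg.variants_in_regions(
            self._vcf(tmp_path, "chr1\t201\t.\tA\tG\n"), [("chr1", 200, 300)]
        )
        assert total == 1

    def test_malformed_line_names_line_number(self, tmp_path):
        with pytest.raises(ValueError, match=":3"):
            pg.variants_in_regions(
                self._vcf(tmp_path, "chr1\tXX\t.\tA\tG\n"), [("chr1", 0, 100)]
            )
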