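import numpy as np
import pandas as pd
import pytest

from sweepscan import (AutozygosityTruth, GenotypeMatrix, ROHParams,
                       classify_roh, correlate_inbreeding, detect_roh, f_roh,
                       make_inbred_genotypes, min_snp_threshold, roh_islands,
                       simulate_neutral_haplotypes, SimConfig,
                       snp_roh_incidence)
from sweepscan.errors import DomainError
from sweepscan.roh import SEGMENT_COLUMNS, validate_segments

import oracles


def _segments(rows):
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


class TestMinSnpThreshold:
    def test_study_scale_inputs_give_41(self):
        assert min_snp_threshold(0.05, 45_943, 514, 0.388) == 41

    def test_raw_value_before_ceiling(self):
        # independently: ln(0.05/23614702)/ln(0.612) = 40.6765...
        raw = min_snp_threshold(0.05, 45_943, 514, 0.388, raw=True)
        assert raw == pytest.approx(40.6765, abs=1e-3)

    def test_degenerate_unit_case(self):
        assert min_snp_threshold(0.5, 1, 1, 0.5) == 1

    @pytest.mark.parametrize("het", [0.0, 1.0, -0.1])
    def test_het_domain(self, het):
        with pytest.raises(DomainError):
            min_snp_threshold(0.05, 100, 10, het)


def _grid_geno(row, spacing=25_000, chrom="1", grid_loci=None):
    loci = grid_loci(len(row), spacing=spacing, chrom=chrom)
    g = GenotypeMatrix(["i0"], np.asarray([row], dtype=np.int8))
    return g, loci


PARAMS = ROHParams(min_snps=40)


class TestDetectRoh:
    def test_all_het_individual_has_no_runs(self, grid_loci):
        g, loci = _grid_geno([1] * 300, grid_loci=grid_loci)
        assert len(detect_roh(g, loci, PARAMS)) == 0

    def test_short_homozygous_stretch_filtered_by_length(self, grid_loci):
        # 20 homozygous SNPs at 25 kb spacing = 0.5 Mb < 1 Mb floor
        row = [1] * 140 + [0] * 20 + [1] * 140
        g, loci = _grid_geno(row, grid_loci=grid_loci)
        assert len(detect_roh(g, loci, PARAMS)) == 0

    def test_planted_tract_recovered_within_window_width(self, grid_loci):
        # 3 Mb / 120 SNPs at 25 kb spacing, flanked by heterozygous noise
        rng = np.random.default_rng(5)
        row = rng.integers(0, 3, size=500)
        row[200:320] = np.where(rng.random(120) < 0.5, 0, 2)
        g, loci = _grid_geno(row.tolist(), grid_loci=grid_loci)
        segs = detect_roh(g, loci, PARAMS)
        assert len(segs) == 1
        window_bp = PARAMS.min_snps * 25_000
        assert abs(segs["start"].iloc[0] - loci.pos[200]) <= window_bp
        assert abs(segs["end"].iloc[0] - loci.pos[319]) <= window_bp

    def test_run_split_at_large_gap(self):
        # two 1.5 Mb homozygous blocks separated by a 5 Mb gap
        pos = np.concatenate([np.arange(1, 61) * 25_000,
                              np.arange(1, 61) * 25_000 + 6_500_000])
        from sweepscan import LocusMap
        loci = LocusMap(chrom=np.full(120, "1", dtype=object),
                        name=np.asarray([f"s{p}" for p in pos], dtype=object),
                        pos=pos,
                        allele_a=np.full(120, "A", dtype=object),
                        allele_b=np.full(120, "B", dtype=object))
        g = GenotypeMatrix(["i0"], np.zeros((1, 120), dtype=np.int8))
        segs = detect_roh(g, loci, ROHParams(min_snps=40))
        assert len(segs) == 2
        assert (segs["length"] < 2_000_000).all()

    def test_chromosome_smaller_than_window_skipped(self, grid_loci):
        g, loci = _grid_geno([0] * 20, grid_loci=grid_loci)
        with pytest.warns(UserWarning, match="fewer"):
            segs = detect_roh(g, loci, PARAMS)
        assert len(segs) == 0

    def test_matches_bruteforce_oracle_on_random_fixtures(self, grid_loci):
        rng = np.random.default_rng(77)
        params = ROHParams(min_snps=25)
        for rep in range(10):
            n = int(rng.integers(60, 300))
            row = rng.choice([0, 1, 2, -1], size=n,
                             p=[0.42, 0.12, 0.42, 0.04]).astype(np.int8)
            # embed a homozygous block to make hits likely
            b = int(rng.integers(0, n - 50))
            row[b:b + 50] = rng.choice([0, 2], size=50)
            loci = grid_loci(n, spacing=30_000)
            g = GenotypeMatrix(["i0"], row[None, :])
            got = detect_roh(g, loci, params)
            want = oracles.roh_segments(row, loci.pos, "1", "i0", params)
            assert [tuple(r) for r in got.itertuples(index=False)] == want

    def test_emitted_segments_revalidate(self, grid_loci):
        rng = np.random.default_rng(3)
        n = 400
        row = rng.choice([0, 1, 2], size=n, p=[0.45, 0.1, 0.45]).astype(np.int8)
        loci = grid_loci(n)
        g = GenotypeMatrix(["i0"], row[None, :])
        segs = detect_roh(g, loci, PARAMS)
        validate_segments(segs, g, loci, PARAMS)  # raises on violation


class TestClassifyRoh:
    def test_class_counts(self):
        segs = _segments([("i0", "1", 1, 2_000_000, 80, 2_000_000),
                          ("i0", "1", 1, 7_000_000, 280, 7_000_000),
                          ("i1", "2", 1, 55_000_000, 2200, 55_000_000)])
        table = classify_roh(segs)
        assert table["count"].tolist() == [1, 1, 0, 0, 1]

    def test_single_class_holds_all(self):
        segs = _segments([("i0", "1", 1, 3_000_000, 120, 3_000_000)] * 4)
        table = classify_roh(segs)
        assert table.loc["1-5", "percent"] == pytest.approx(100.0)

    def test_percent_sums_to_100(self):
        rng = np.random.default_rng(1)
        lengths = rng.integers(1_000_000, 60_000_000, size=30)
        segs = _segments([("i0", "1", 1, l, 100, int(l)) for l in lengths])
        assert classify_roh(segs)["percent"].sum() == pytest.approx(100.0)

    def test_empty_input_zero_table(self):
        table = classify_roh(_segments([]))
        assert table["count"].sum() == 0


class TestFRoh:
    def test_no_segments_zero(self, grid_loci):
        loci = grid_loci(100)
        vals = f_roh(_segments([]), loci, ["i0", "i1"])
        assert (vals == 0.0).all()

    def test_full_genome_run_is_one(self, grid_loci):
        loci = grid_loci(100)
        start, end = int(loci.pos[0]), int(loci.pos[-1])
        segs = _segments([("i0", "1", start, end, 100, end - start + 1)])
        vals = f_roh(segs, loci, ["i0"])
        assert vals["i0"] == pytest.approx(1.0)

    def test_monotone_in_added_tracts(self, grid_loci):
        loci = grid_loci(200)
        seg1 = ("i0", "1", 25_000, 1_525_000, 61, 1_500_001)
        seg2 = ("i0", "1", 3_000_000, 4_500_000, 61, 1_500_001)
        assert (f_roh(_segments([seg1]), loci, ["i0"])["i0"]
                < f_roh(_segments([seg1, seg2]), loci, ["i0"])["i0"])


class TestCorrelateInbreeding:
    def test_perfect_positive_and_negative(self):
        x = np.asarray([0.0, 0.1, 0.2, 0.35])
        assert correlate_inbreeding(x, x) == pytest.approx(1.0)
        assert correlate_inbreeding(x, -x) == pytest.approx(-1.0)

    def test_zero_variance_is_nan(self):
        with pytest.warns(UserWarning):
            r = correlate_inbreeding(np.asarray([0.1, 0.1, 0.1]),
                                     np.asarray([0.0, 0.5, 1.0]))
        assert np.isnan(r)


class TestIncidenceAndIslands:
    def test_single_carrier_incidence(self, grid_loci):
        loci = grid_loci(100)
        segs = _segments([("i0", "1", 1_000_000, 2_000_000, 41, 1_000_001)])
        inc = snp_roh_incidence(segs, loci, n_individuals=10)
        inside = (loci.pos >= 1_000_000) & (loci.pos <= 2_000_000)
        assert np.allclose(inc[inside], 0.1)
        assert np.allclose(inc[~inside], 0.0)
        assert (inc <= 1.0).all()

    def test_threshold_inclusive(self, grid_loci):
        loci = grid_loci(10)
        inc = np.zeros(10)
        inc[4] = 0.10
        islands = roh_islands(inc, loci, threshold=0.10)
        assert len(islands) == 1
        assert islands["n_snps"].iloc[0] == 1

    def test_all_below_threshold_empty(self, grid_loci):
        loci = grid_loci(10)
        assert len(roh_islands(np.full(10, 0.09), loci)) == 0

    def test_shared_tract_becomes_island(self):
        cfg = SimConfig(n_individuals=40, n_snps_per_chrom=800, n_chroms=1,
                        chrom_length=40_000_000, maf_floor=0.05, seed=13)
        haps, loci = simulate_neutral_haplotypes(cfg)
        tracts = [AutozygosityTruth(ind, "1", 10_000_000, 16_000_000)
                  for ind in haps.individuals[:12]]  # 30% of individuals
        g = make_inbred_genotypes(haps, loci, tracts, missing_rate=0.0)
        segs = detect_roh(g, loci, ROHParams.from_data(g))
        inc = snp_roh_incidence(segs, loci, g.n_individuals)
        islands = roh_islands(inc, loci, threshold=0.10)
        mid = 13_000_000
        assert any(r["start"] <= mid <= r["end"] for _, r in islands.iterrows())
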