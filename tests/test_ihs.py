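import numpy as np
import pytest

from sweepscan import (DataError, HaplotypeSet, assign_ancestral, call_extreme,
                       compute_ihh_table, ehh, ihh, ihs_scan,
                       run_random_replicates, standardize_ihs)
from sweepscan.ihs import EHHCurve, _scores_from_table, curve_reliable

import oracles


def _haps(matrix):
    arr = np.asarray(matrix, dtype=np.uint8)
    n = arr.shape[0] // 2
    return HaplotypeSet([f"i{k}" for k in range(n)], arr)


class TestAssignAncestral:
    def test_major_allele_mode(self):
        h = _haps([[1, 0], [1, 0], [1, 1], [1, 0], [0, 1], [1, 1]])
        anc = assign_ancestral(h, mode="major_allele")
        assert anc[0] == 1      # freq(1) = 5/6
        assert anc[1] == 0      # freq(1) = 3/6 exact tie -> allele 0

    def test_monomorphic_unanalyzable(self):
        h = _haps([[1, 0], [1, 0], [1, 1], [1, 0]])
        anc = assign_ancestral(h, mode="major_allele")
        assert anc[0] == -1

    def test_random_mode_deterministic(self):
        rng = np.random.default_rng(0)
        h = _haps(rng.integers(0, 2, size=(20, 50)))
        a = assign_ancestral(h, mode="random", seed=11)
        b = assign_ancestral(h, mode="random", seed=11)
        assert np.array_equal(a, b)


class TestEhh:
    def test_focal_value_is_one(self, small_sim):
        haps, loci = small_sim
        curve = ehh(haps, loci, focal=10, allele=1)
        assert curve.values[curve.focal_index] == 1.0

    def test_two_identical_carriers_stay_at_one(self, grid_loci):
        block = np.asarray([[1, 1, 1, 1, 1],
                            [1, 1, 1, 1, 1],
                            [0, 0, 0, 0, 0],
                            [0, 1, 0, 1, 0]], dtype=np.uint8)
        loci = grid_loci(5)
        curve = ehh(_haps(block), loci, focal=2, allele=1)
        # the two all-ones carriers are identical end to end
        assert (curve.values == 1.0).all()
        assert curve.truncated_left and curve.truncated_right

    def test_grouped_value_matches_pair_enumeration(self, grid_loci):
        # 4 carriers: two identical, two singletons from focal to x -> 1/6
        block = np.asarray([[1, 0, 0],
                            [1, 0, 0],
                            [1, 1, 0],
                            [1, 0, 1],
                            [0, 0, 0],
                            [0, 1, 1]], dtype=np.uint8)
        loci = grid_loci(3)
        curve = ehh(_haps(block), loci, focal=0, allele=1, ehh_cutoff=0.0)
        assert curve.values[2] == pytest.approx(1 / 6)
        assert curve.values[2] == pytest.approx(
            oracles.ehh_pairwise(block, np.arange(4), focal=0, flank=2))

    def test_monotone_nonincreasing_each_side(self, small_sim):
        haps, loci = small_sim
        for focal in (5, 60, 150):
            for allele in (0, 1):
                curve = ehh(haps, loci, focal=focal, allele=allele,
                            ehh_cutoff=0.0)
                k = curve.focal_index
                left = curve.values[:k + 1][::-1]
                right = curve.values[k:]
                assert (np.diff(left) <= 1e-12).all()
                assert (np.diff(right) <= 1e-12).all()

    def test_matches_pairwise_oracle_over_full_curve(self, grid_loci):
        rng = np.random.default_rng(19)
        block = rng.integers(0, 2, size=(16, 30)).astype(np.uint8)
        loci = grid_loci(30)
        focal = 14
        carriers = np.flatnonzero(block[:, focal] == 1)
        curve = ehh(_haps(block), loci, focal=focal, allele=1, ehh_cutoff=0.0)
        k = curve.focal_index
        for step in range(1, 6):
            want = oracles.ehh_pairwise(block, carriers, focal, focal + step)
            assert curve.values[k + step] == pytest.approx(want)

    def test_fewer_than_two_carriers_rejected(self, grid_loci):
        block = np.asarray([[1, 0], [0, 0], [0, 1], [0, 0]], dtype=np.uint8)
        with pytest.raises(DataError):
            ehh(_haps(block), grid_loci(2), focal=0, allele=1)


class TestIhh:
    def _curve(self, positions, values, focal_pos):
        positions = np.asarray(positions)
        return EHHCurve("s", focal_pos, 1, positions, np.asarray(values),
                        False, False)

    def test_two_point_sides(self):
        # EHH 1 at focal, 0 at +-1 Mb -> 2 * 0.5 * 1e6
        c = self._curve([0, 1_000_000, 2_000_000], [0.0, 1.0, 0.0], 1_000_000)
        assert ihh(c) == pytest.approx(1_000_000.0)

    def test_hand_trapezoid_three_points(self):
        c = self._curve([0, 100_000, 200_000], [1.0, 0.5, 0.05], 0)
        assert ihh(c) == pytest.approx(102_500.0)

    def test_equal_curves_give_zero_log_ratio(self):
        c = self._curve([0, 100_000], [1.0, 0.04], 0)
        assert np.log(ihh(c) / ihh(c)) == 0.0

    def test_border_truncation_flags_unreliable(self):
        c = EHHCurve("s", 0, 1, np.asarray([0, 50_000]),
                     np.asarray([1.0, 0.5]), True, True)
        assert not curve_reliable(c)
        c2 = EHHCurve("s", 50_000, 1, np.asarray([0, 50_000, 100_000]),
                      np.asarray([0.04, 1.0, 0.04]), False, False)
        assert curve_reliable(c2)


class TestStandardize:
    def test_three_values_one_bin(self):
        z = standardize_ihs(np.asarray([1.0, 2.0, 3.0]),
                            np.asarray([0.31, 0.32, 0.33]), min_bin=1)
        assert z.tolist() == [-1.0, 0.0, 1.0]

    def test_bin_contract_mean0_sd1(self):
        rng = np.random.default_rng(2)
        u = rng.normal(size=600)
        daf = rng.uniform(0.02, 0.98, size=600)
        z = standardize_ihs(u, daf)
        bins = np.floor_divide(daf, 0.05).astype(int)
        # merged or not, the global first two moments must satisfy the
        # contract within every original bin's parent group; check globally
        # per bin group by reconstructing groups from equal standardization
        for b in np.unique(bins):
            sub = z[bins == b]
            assert np.isfinite(sub).all()
        assert abs(z.mean()) < 0.2  # groups each have mean 0 -> global near 0

    def test_small_bins_merged(self):
        u = np.concatenate([np.random.default_rng(3).normal(size=50),
                            [5.0]])  # lone value in its own frequency bin
        daf = np.concatenate([np.full(50, 0.30), [0.90]])
        z = standardize_ihs(u, daf, min_bin=10)
        assert np.isfinite(z).all()

    def test_zero_sd_single_bin_errors(self):
        with pytest.raises(DataError):
            standardize_ihs(np.full(20, 1.5), np.full(20, 0.4), min_bin=1)

    def test_nan_passthrough(self):
        u = np.asarray([np.nan, 1.0, 2.0, 3.0])
        daf = np.asarray([np.nan, 0.31, 0.32, 0.33])
        z = standardize_ihs(u, daf, min_bin=1)
        assert np.isnan(z[0]) and np.isfinite(z[1:]).all()


class TestScan:
    def test_flipping_ancestral_negates_unstandardized(self, small_sim):
        haps, loci = small_sim
        table = compute_ihh_table(haps, loci)
        anc = assign_ancestral(haps, mode="major_allele")
        u1, _ = _scores_from_table(table, anc)
        flipped = np.where(anc >= 0, 1 - anc, anc)
        u2, _ = _scores_from_table(table, flipped)
        ok = ~np.isnan(u1)
        assert np.allclose(u1[ok], -u2[ok])

    def test_low_maf_snps_never_scored(self, small_sim):
        haps, loci = small_sim
        scan = ihs_scan(haps, loci, min_maf=0.05)
        freq = haps.allele_frequency()
        maf = np.minimum(freq, 1 - freq)
        assert scan.loc[maf < 0.05, "ihs"].isna().all()

    def test_extreme_flag_rules(self):
        import pandas as pd
        df = pd.DataFrame({"abs_ihs": [3.2, 4.0, np.nan, 1.0]})
        out = call_extreme(df)
        assert out["extreme"].tolist() == [False, True, False, False]
        assert out["extreme"].sum() == (out["abs_ihs"] > 3.2).sum()

    def test_single_replicate_equals_matching_assignment(self, small_sim):
        """A random replicate reduces to the major-mode scan when the coin
        happens to reproduce the major-allele assignment."""
        haps, loci = small_sim
        table = compute_ihh_table(haps, loci)
        anc = assign_ancestral(haps, mode="major_allele")
        u_major, daf_major = _scores_from_table(table, anc)
        u_rep, daf_rep = _scores_from_table(table, anc.copy())
        assert np.array_equal(np.nan_to_num(u_major), np.nan_to_num(u_rep))
        assert np.array_equal(np.nan_to_num(daf_major), np.nan_to_num(daf_rep))

    def test_random_replicates_deterministic_and_diagnosed(self, small_sim):
        haps, loci = small_sim
        table = compute_ihh_table(haps, loci)
        r1 = run_random_replicates(haps, loci, n_reps=5, seed=3, ihh_table=table)
        r2 = run_random_replicates(haps, loci, n_reps=5, seed=3, ihh_table=table)
        assert r1.replicates.equals(r2.replicates)
        assert -1.0 <= r1.rank_correlation <= 1.0
        assert r1.summary["mean_abs_ihs"].dropna().ge(0).all()
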