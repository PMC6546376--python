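import itertools

import numpy as np
import pytest

from evoscales import popgen_stats as ps


# ---------------------------------------------------------------------------
# naive O(n^2) reference implementations (kept deliberately dumb)
# ---------------------------------------------------------------------------


def naive_r2(a, b):
    pa, pb = a.mean(), b.mean()
    if pa in (0, 1) or pb in (0, 1):
        return np.nan
    p11 = np.mean(a * b)
    d = p11 - pa * pb
    return d * d / (pa * (1 - pa) * pb * (1 - pb))


def naive_pi_per_site(col):
    n = col.size
    diffs = sum(
        int(col[i] != col[j]) for i, j in itertools.combinations(range(n), 2)
    )
    return diffs / (n * (n - 1) / 2)


def naive_ehhs(alleles, focal, extent_idx):
    """Fraction of haplotype pairs identical over sites focal..extent_idx."""
    lo, hi = min(focal, extent_idx), max(focal, extent_idx)
    segs = [tuple(row[lo : hi + 1]) for row in alleles]
    n = len(segs)
    same = sum(
        int(segs[i] == segs[j]) for i, j in itertools.combinations(range(n), 2)
    )
    return same / (n * (n - 1) / 2)


def naive_ies(hm, truncation=0.05):
    """Trapezoid-integrated EHHS per focal site, bp units."""
    out = np.empty(hm.n_sites)
    for s in range(hm.n_sites):
        total = 0.0
        for direction, edge in ((-1, hm.positions[0]), (1, hm.length - hm.positions[-1])):
            offs, vals = [0.0], [1.0]
            j = s + direction
            while 0 <= j < hm.n_sites:
                offs.append(abs(float(hm.positions[j] - hm.positions[s])))
                vals.append(naive_ehhs(hm.alleles, s, j))
                j += direction
            below = [i for i, v in enumerate(vals) if v < truncation]
            if below:
                offs, vals = offs[: below[0]], vals[: below[0]]
                tail = 0.0
            else:
                tail = vals[-1] * edge
            total += np.trapezoid(vals, offs) + tail if len(offs) >= 2 else tail
        out[s] = total
    return out


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------


class TestPairwiseR2:
    def test_worked_two_locus_counts(self):
        # haplotype counts (00,01,10,11) = (3,1,1,3): D=0.125, r2=0.25
        a = np.array([[0, 0]] * 3 + [[0, 1]] + [[1, 0]] + [[1, 1]] * 3, np.uint8)
        hm = ps.HaplotypeMatrix(a, [10, 20], length=100)
        assert ps.pairwise_r2(hm, 0, 1) == pytest.approx(0.25)

    def test_self_ld_is_one(self, random_hm):
        assert ps.pairwise_r2(random_hm, 3, 3) == 1.0

    def test_independent_loci(self):
        a = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], np.uint8)
        hm = ps.HaplotypeMatrix(a, [5, 50], length=100)
        assert ps.pairwise_r2(hm, 0, 1) == pytest.approx(0.0, abs=1e-15)

    def test_monomorphic_masked(self):
        a = np.array([[0, 0], [0, 1], [0, 0], [0, 1]], np.uint8)
        hm = ps.HaplotypeMatrix(a, [5, 50], length=100)
        assert np.isnan(ps.pairwise_r2(hm, 0, 1))

    def test_matches_naive_on_random_matrix(self, random_hm):
        for i, j in [(0, 1), (2, 17), (5, 29), (11, 12)]:
            ref = naive_r2(
                random_hm.alleles[:, i].astype(float),
                random_hm.alleles[:, j].astype(float),
            )
            assert ps.pairwise_r2(random_hm, i, j) == pytest.approx(ref, abs=1e-10)

    def test_allele_relabel_invariance(self, random_hm):
        flipped = ps.HaplotypeMatrix(
            1 - random_hm.alleles, random_hm.positions, length=random_hm.length
        )
        assert ps.pairwise_r2(random_hm, 2, 9) == pytest.approx(
            ps.pairwise_r2(flipped, 2, 9), abs=1e-12
        )


class TestHudsonFst:
    @staticmethod
    def gm_from_freqs(p1, p2, n_per_pop=25, seed=0):
        rng = np.random.default_rng(seed)
        d1 = rng.binomial(2, p1, size=(n_per_pop, np.size(p1)))
        d2 = rng.binomial(2, p2, size=(n_per_pop, np.size(p2)))
        dos = np.vstack([d1, d2]).astype(np.int16)
        labels = np.array(["a"] * n_per_pop + ["b"] * n_per_pop)
        return ps.GenotypeMatrix(
            dos, np.arange(np.size(p1)) * 10, pop_labels=labels
        )

    def test_worked_value(self):
        # 50 haploid genomes per pop, p1=0.6, p2=0.4 -> 0.0581
        d1 = np.array([2] * 15 + [0] * 10)
        d2 = np.array([2] * 10 + [0] * 15)
        gm = ps.GenotypeMatrix(
            np.concatenate([d1, d2]).reshape(-1, 1).astype(np.int16),
            [0],
            pop_labels=np.array(["a"] * 25 + ["b"] * 25),
        )
        expected = (0.2**2 - 2 * (0.6 * 0.4 / 49)) / (0.6 * 0.6 + 0.4 * 0.4)
        fst = ps.hudson_fst_per_snp(gm, "a", "b").raw[0]
        assert fst == pytest.approx(expected, abs=1e-12)
        assert fst == pytest.approx(0.0581, abs=2e-4)

    def test_fixed_difference_is_one(self):
        d = np.array([2] * 10 + [0] * 10).reshape(-1, 1).astype(np.int16)
        gm = ps.GenotypeMatrix(d, [0], pop_labels=np.array(["a"] * 10 + ["b"] * 10))
        assert ps.hudson_fst_per_snp(gm, "a", "b").raw[0] == pytest.approx(1.0)

    def test_null_sites_average_to_zero_or_below(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0.2, 0.8, 4000)
        gm = self.gm_from_freqs(p, p, n_per_pop=50, seed=5)
        vals = ps.hudson_fst_per_snp(gm, "a", "b").raw
        assert np.nanmean(vals) < 0.01
        assert abs(np.nanmean(vals)) < 0.01

    def test_relabel_invariance(self):
        gm = self.gm_from_freqs(
            np.array([0.3, 0.6]), np.array([0.5, 0.2]), n_per_pop=40, seed=6
        )
        a = ps.hudson_fst_per_snp(gm, "a", "b").raw
        flipped = ps.GenotypeMatrix(
            (2 - gm.dosages).astype(np.int16), gm.positions, pop_labels=gm.pop_labels
        )
        b = ps.hudson_fst_per_snp(flipped, "a", "b").raw
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_missing_genotypes_excluded(self):
        d = np.array([[1], [2], [-1], [0], [1], [-1]], dtype=np.int16)
        gm = ps.GenotypeMatrix(d, [0], pop_labels=np.array(["a"] * 3 + ["b"] * 3))
        ac, an = gm.allele_counts(np.array([0, 1, 2]))
        assert ac[0] == 3 and an[0] == 4


class TestPiWindows:
    def test_worked_value(self):
        a = np.array([[0, 0], [0, 0], [1, 1], [1, 1]], np.uint8)
        hm = ps.HaplotypeMatrix(a, [10, 20], length=1000)
        track = ps.pi_windows(hm, window=1000)
        assert track.raw[0] == pytest.approx(8 / 6 / 1000)

    def test_monomorphic_window_is_zero(self):
        a = np.array([[0, 1], [0, 1], [0, 1], [1, 1]], np.uint8)
        hm = ps.HaplotypeMatrix(a, [10, 1500], length=2000)
        track = ps.pi_windows(hm, window=1000)
        assert track.raw[1] == 0.0  # second window holds only the fixed site

    def test_matches_naive_per_site_enumeration(self, random_hm):
        track = ps.pi_windows(random_hm, window=random_hm.length)
        ref = sum(
            naive_pi_per_site(random_hm.alleles[:, j])
            for j in range(random_hm.n_sites)
        ) / random_hm.length
        assert track.raw[0] == pytest.approx(ref, abs=1e-12)

    def test_windows_sum_to_chromosome_pi(self, random_hm):
        track = ps.pi_windows(random_hm, window=17_000)
        sizes = np.diff(
            np.append(np.arange(0, random_hm.length, 17_000), random_hm.length)
        )
        weighted = np.sum(track.raw * sizes) / random_hm.length
        assert weighted == pytest.approx(ps.chromosome_pi(random_hm), rel=1e-12)

    def test_truncated_final_window_uses_own_length(self):
        a = np.array([[0], [1]], np.uint8)
        hm = ps.HaplotypeMatrix(a, [1450], length=1500)
        track = ps.pi_windows(hm, window=1000)
        # second window spans [1000, 1500): one 1/1 site over 500 bp
        assert track.raw[1] == pytest.approx(1.0 / 500)


class TestEhhsIes:
    def test_distance_zero_is_one_and_monotone(self, random_hm):
        for focal in (0, 7, 29):
            c = ps.ehhs_curve(random_hm, focal)
            assert c.values_left[0] == 1.0 and c.values_right[0] == 1.0
            assert (np.diff(c.values_left) <= 1e-12).all()
            assert (np.diff(c.values_right) <= 1e-12).all()

    def test_group_split_example(self):
        a = np.array([[0, 0], [0, 0], [0, 1], [1, 0]], np.uint8)
        hm = ps.HaplotypeMatrix(a, [10, 500], length=1000)
        c = ps.ehhs_curve(hm, 0)
        assert c.values_right[1] == pytest.approx(1 / 6)

    def test_matches_naive_enumeration(self, random_hm):
        for focal in (0, 11, 29):
            c = ps.ehhs_curve(random_hm, focal)
            for step, (offs, vals) in (
                (-1, (c.offsets_left, c.values_left)),
                (1, (c.offsets_right, c.values_right)),
            ):
                for k in range(1, len(vals)):
                    ref = naive_ehhs(random_hm.alleles, focal, focal + step * k)
                    assert vals[k] == pytest.approx(ref, abs=1e-12)

    def test_monomorphic_focal_rejected(self):
        a = np.array([[0, 1], [0, 0]], np.uint8)
        hm = ps.HaplotypeMatrix(a, [1, 2], length=10)
        with pytest.raises(ValueError, match="monomorphic"):
            ps.ehhs_curve(hm, 0)

    def test_identical_haplotypes_integrate_to_chromosome_length(self):
        hm = ps.HaplotypeMatrix(
            np.zeros((6, 4), np.uint8), [100, 200, 300, 400], length=2_000_000
        )
        track = ps.ies_scan(hm)
        np.testing.assert_allclose(track.raw, 2.0)  # 2 Mb -> 2.0 per Mb

    @pytest.mark.parametrize("use_kernel", [True, False])
    def test_matches_naive_trapezoid(self, random_hm, use_kernel):
        track = ps.ies_scan(random_hm, per_mb=False, use_kernel=use_kernel)
        ref = naive_ies(random_hm)
        ref[ref == 0] = np.nan
        np.testing.assert_allclose(track.raw, ref, atol=1e-8)

    def test_kernel_and_fallback_agree(self, random_hm):
        a = ps.ies_scan(random_hm, use_kernel=True).raw
        b = ps.ies_scan(random_hm, use_kernel=False).raw
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestLdTracks:
    def test_single_pair_bin_mean(self):
        a = np.array([[0, 0]] * 4 + [[1, 1]] * 4, np.uint8)  # r2 = 1
        hm = ps.HaplotypeMatrix(a, [100, 600], length=10_000)
        track = ps.ld_decay_curve(hm, max_dist=1000, n_bins=5)
        vals = track.raw[np.isfinite(track.raw)]
        assert vals.size == 1 and vals[0] == pytest.approx(1.0)
        assert track.meta["n_pairs"].sum() == 1

    def test_long_distance_track_hand_average(self):
        rng = np.random.default_rng(11)
        n_hap, n_sites = 20, 15
        a = (rng.random((n_hap, n_sites)) < 0.5).astype(np.uint8)
        pos = np.sort(rng.choice(400_000, n_sites, replace=False)).astype(np.int64)
        hm = ps.HaplotypeMatrix(a, pos, length=400_000)
        track = ps.long_distance_ld_track(
            hm, window=400_000, step=400_000, min_sep=20_000, max_sep=200_000,
            min_maf=0.0,
        )
        m = hm.filter_maf(0.0)
        vals = []
        for i in range(n_sites):
            for j in range(i + 1, n_sites):
                sep = pos[j] - pos[i]
                if 20_000 <= sep <= 200_000:
                    r2 = ps.pairwise_r2(hm, i, j)
                    if np.isfinite(r2):
                        vals.append(r2)
        assert track.raw[0] == pytest.approx(np.mean(vals), abs=1e-10)

    def test_all_pairs_too_close_gives_missing_track(self):
        a = np.array([[0, 1], [1, 0], [0, 0], [1, 1]], np.uint8)
        hm = ps.HaplotypeMatrix(a, [100, 200], length=300_000)
        track = ps.long_distance_ld_track(hm, min_maf=0.0)
        assert np.isnan(track.raw).all()

    def test_neutral_coalescent_decay_is_monotone(self):
        """msprime oracle: mean r2 decreases with distance (Spearman < 0)."""
        import msprime
        from scipy.stats import spearmanr

        ts = msprime.sim_ancestry(
            samples=25, sequence_length=2e5, recombination_rate=1e-7,
            population_size=1e4, random_seed=7,
        )
        ts = msprime.sim_mutations(ts, rate=2e-7, random_seed=8)
        alleles = ts.genotype_matrix().T.astype(np.uint8)
        pos = ts.tables.sites.position.astype(np.int64)
        keep = np.concatenate([[True], np.diff(pos) > 0])
        hm = ps.HaplotypeMatrix(
            np.clip(alleles[:, keep], 0, 1), pos[keep], length=200_000
        )
        track = ps.ld_decay_curve(hm, max_dist=100_000, n_bins=12)
        ok = np.isfinite(track.raw)
        rho, _ = spearmanr(track.positions[ok], track.raw[ok])
        assert rho < 0


class TestEigenGWAS:
    def test_perfect_separator_snp_attains_max_chi2(self):
        """With two genuine clusters, the one SNP that separates them
        perfectly scores highest."""
        from evoscales.synthetic_data import (
            StructuredPopConfig,
            generate_structured_genotypes,
        )

        gm, _ = generate_structured_genotypes(
            StructuredPopConfig(n_per_pop=30, n_snps=200, fst_target=0.15, seed=3)
        )
        dos = gm.dosages.copy()
        dos[:, 77] = np.array([0] * 30 + [2] * 30, np.int16)  # fixed difference
        gm2 = ps.GenotypeMatrix(dos, gm.positions)
        res = ps.eigengwas_scan(gm2)
        kept_col = np.where(res.kept == 77)[0][0]
        assert res.chi2.argmax() == kept_col

    def test_individual_order_and_eigenvector_sign_invariance(self):
        rng = np.random.default_rng(9)
        dos = rng.binomial(2, rng.uniform(0.1, 0.9, 300), size=(50, 300)).astype(
            np.int16
        )
        gm = ps.GenotypeMatrix(dos, np.arange(300) * 5)
        res = ps.eigengwas_scan(gm)
        perm = rng.permutation(50)
        gm2 = ps.GenotypeMatrix(dos[perm], gm.positions)
        res2 = ps.eigengwas_scan(gm2)
        np.testing.assert_allclose(res.chi2, res2.chi2, atol=1e-8)
        np.testing.assert_allclose(res.lambda_gc, res2.lambda_gc, atol=1e-8)

    def test_too_few_snps_rejected(self):
        gm = ps.GenotypeMatrix(
            np.array([[1], [0], [2]], np.int16), [0]
        )
        with pytest.raises(ValueError, match="SNP"):
            ps.eigengwas_scan(gm)


class TestSmoothTrack:
    def test_constant_track_unchanged(self):
        track = ps.ScanTrack("x", np.arange(10) * 1e5, np.full(10, 2.0))
        sm = ps.smooth_track(track)
        np.testing.assert_allclose(sm.smoothed, 2.0)

    def test_linear_track_reproduced_exactly(self):
        x = np.arange(20) * 1e5
        track = ps.ScanTrack("x", x, 1.0 + 3e-6 * x)
        sm = ps.smooth_track(track, degree=1)
        np.testing.assert_allclose(sm.smoothed, track.raw, rtol=1e-9)

    def test_elevated_region_detected_in_noisy_step_track(self):
        rng = np.random.default_rng(12)
        x = np.arange(0, 8_000_000, 50_000).astype(float)
        raw = rng.normal(0.1, 0.03, x.size)
        inside = (x >= 3_200_000) & (x < 4_800_000)  # 1.6 Mb elevated region
        raw[inside] += 0.2
        sm = ps.smooth_track(ps.ScanTrack("x", x, raw))
        assert sm.smoothed[inside].mean() > sm.smoothed[~inside].mean() + 0.1

    def test_nan_positions_ignored_for_fit(self):
        x = np.arange(12) * 1e5
        raw = np.full(12, 1.0)
        raw[4] = np.nan
        sm = ps.smooth_track(ps.ScanTrack("x", x, raw))
        assert np.isnan(sm.smoothed[4])
        np.testing.assert_allclose(sm.smoothed[~np.isnan(raw)], 1.0)
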