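import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from genarch import polar


class TestWhiten:
    def test_zero_correlation_is_identity(self):
        z1, z2 = np.array([1.2, -0.5]), np.array([0.3, 2.0])
        u1, u2 = polar.whiten(z1, z2, 0.0)
        np.testing.assert_array_equal(u1, z1)
        np.testing.assert_array_equal(u2, z2)

    def test_hand_cholesky_solve(self):
        u1, u2 = polar.whiten(np.array([1.0]), np.array([1.0]), 0.5)
        assert u1[0] == pytest.approx(1.0)
        assert u2[0] == pytest.approx(0.57735, abs=1e-5)

    def test_null_simulation_whitens_to_identity(self):
        rng = np.random.default_rng(41)
        c = 0.3
        L = np.linalg.cholesky([[1, c], [c, 1]])
        z = rng.standard_normal((100_000, 2)) @ L.T
        u1, u2 = polar.whiten(z[:, 0], z[:, 1], c)
        cov = np.cov(u1, u2)
        np.testing.assert_allclose(cov, np.eye(2), atol=0.01)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            polar.whiten(np.array([1.0]), np.array([1.0]), 1.0)


class TestPolarTransform:
    def test_pythagorean_triple(self):
        r, theta, _ = polar.polar_transform(np.array([3.0]), np.array([4.0]))
        assert r[0] == pytest.approx(5.0)
        assert theta[0] == pytest.approx(np.arctan(4 / 3), abs=1e-12)

    def test_equal_effects_sit_exactly_on_diagonal(self):
        for x in (0.1, 1.0, 7.5):
            _, theta, _ = polar.polar_transform(np.array([x]), np.array([x]))
            assert theta[0] == np.pi / 4

    def test_single_trait_axis_and_origin(self):
        r, theta, _ = polar.polar_transform(np.array([2.0, 0.0]),
                                            np.array([0.0, 0.0]))
        assert theta[0] == 0.0
        assert np.isnan(theta[1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_angle_always_folded_into_first_quadrant(self, u1, u2):
        r, theta, _ = polar.polar_transform(np.array([u1]), np.array([u2]))
        if r[0] > 0:
            assert 0.0 <= theta[0] <= np.pi / 2


class TestPvalues:
    def test_radial_p_closed_forms(self):
        assert polar.p_radius(np.array([2.0]))[0] == pytest.approx(np.exp(-2))
        assert polar.p_radius(np.array([0.0]))[0] == 1.0

    def test_radial_p_uniform_under_complete_null(self):
        rng = np.random.default_rng(42)
        u = rng.standard_normal((100_000, 2))
        r, _, _ = polar.polar_transform(u[:, 0], u[:, 1])
        d = stats.kstest(polar.p_radius(r), "uniform").statistic
        assert d < 0.01

    def test_null_most_angle_has_p_near_one(self):
        p_r, p_t = polar.polar_pvalues(np.array([3.0]), np.array([0.0]), seed=1)
        assert p_t[0] > 0.99

    def test_theta_p_calibrated_under_single_trait_null(self):
        rng = np.random.default_rng(43)
        n = 5000
        u1 = 6.0 + rng.standard_normal(n)
        u2 = rng.standard_normal(n)
        r, theta, _ = polar.polar_transform(u1, u2)
        _, p_t = polar.polar_pvalues(r, theta, seed=2, n_draws=40_000)
        assert (p_t < 0.05).mean() == pytest.approx(0.05, abs=0.015)

    def test_detection_rate_monotone_in_spike_magnitude(self):
        rng = np.random.default_rng(44)
        rates = []
        for mag in (2.0, 4.0, 6.0, 8.0):
            u1 = mag / np.sqrt(2) + rng.standard_normal(2000)
            u2 = mag / np.sqrt(2) + rng.standard_normal(2000)
            r, theta, _ = polar.polar_transform(u1, u2)
            p_r, p_t = polar.polar_pvalues(r, theta, seed=3, n_draws=20_000)
            rates.append(((p_r < 1e-4) & (p_t < 0.05)).mean())
        assert all(b >= a - 0.02 for a, b in zip(rates, rates[1:]))

    def test_spiked_equal_effect_angle_approaches_diagonal(self):
        rng = np.random.default_rng(45)
        for mag, tol in ((5.0, 0.3), (50.0, 0.03)):
            u1 = mag / np.sqrt(2) + rng.standard_normal(500)
            u2 = mag / np.sqrt(2) + rng.standard_normal(500)
            _, theta, _ = polar.polar_transform(u1, u2)
            assert np.abs(theta - np.pi / 4).mean() < tol


class TestBhFdr:
    def test_hand_example(self):
        np.testing.assert_allclose(polar.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_inputs(self):
        assert polar.bh_fdr([]).size == 0
        np.testing.assert_array_equal(polar.bh_fdr([1.0, 1.0]), [1.0, 1.0])
        assert polar.bh_fdr([0.2])[0] == pytest.approx(0.2)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_and_stays_in_unit_interval(self, ps):
        q = polar.bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-12)
        assert np.all(q <= 1.0 + 1e-12)


class TestSelectShared:
    def _records(self, q_r, q_t):
        return pd.DataFrame({"SNP": [f"s{i}" for i in range(len(q_r))],
                             "q_r": q_r, "q_theta": q_t})

    def test_conjunction_required(self):
        rec = self._records([0.01, 0.04, 0.2], [0.2, 0.04, 0.01])
        out = polar.select_shared(rec)
        assert list(out["SNP"]) == ["s1"]

    def test_empty_input_empty_output(self):
        assert len(polar.select_shared(self._records([], []))) == 0


def brute_force_clump(selected, ld, cfg):
    """Independent re-implementation of the greedy clump semantics: walk SNPs
    by ascending p, found clumps, absorb eligible neighbours, then merge
    overlapping intervals and collapse everything touching the MHC."""
    rows = selected.sort_values(["p_r", "SNP"], kind="mergesort")
    rows = list(rows.itertuples(index=False))
    taken = set()
    raw = []
    for lead in rows:
        if lead.SNP in taken or not lead.p_r < cfg.lead_p_max:
            continue
        taken.add(lead.SNP)
        members = [lead]
        for other in rows:
            if other.SNP in taken or not other.p_r < cfg.member_p_max:
                continue
            if other.CHR == lead.CHR \
                    and abs(other.BP - lead.BP) <= cfg.max_distance_kb * 1000 \
                    and ld.r2(lead.SNP, other.SNP) >= cfg.r2_threshold:
                taken.add(other.SNP)
                members.append(other)
        raw.append((lead, members))
    intervals = sorted(
        [(lead.CHR, min(m.BP for m in members), max(m.BP for m in members),
          {m.SNP for m in members}, {lead.SNP})
         for lead, members in raw])
    merged = []
    for chrom, lo, hi, mem, leads in intervals:
        if merged and merged[-1][0] == chrom and lo <= merged[-1][2]:
            prev = merged.pop()
            merged.append((chrom, prev[1], max(hi, prev[2]),
                           prev[3] | mem, prev[4] | leads))
        else:
            merged.append((chrom, lo, hi, mem, leads))
    mhc_c, mhc_lo, mhc_hi = cfg.mhc_interval
    mhc = [iv for iv in merged
           if iv[0] == mhc_c and iv[1] <= mhc_hi and iv[2] >= mhc_lo]
    keep = [iv for iv in merged if iv not in mhc]
    if mhc:
        keep.append((mhc_c, min(iv[1] for iv in mhc), max(iv[2] for iv in mhc),
                     set().union(*[iv[3] for iv in mhc]),
                     set().union(*[iv[4] for iv in mhc])))
    return sorted((c, lo, hi, frozenset(m), frozenset(l))
                  for c, lo, hi, m, l in keep)


class TestClump:
    def _cfg(self):
        return polar.ClumpConfig()

    def test_single_snp_single_zero_width_locus(self):
        sel = pd.DataFrame({"SNP": ["a"], "CHR": [2], "BP": [500],
                            "p_r": [1e-10]})
        ld = polar.LDMatrix(snp_ids=["a"], matrix=np.eye(1))
        leads, loci = polar.clump(sel, ld)
        assert leads == ["a"]
        assert loci[0].start == loci[0].end == 500

    def test_hand_enumerated_toy_panel(self):
        sel = pd.DataFrame({
            "SNP": ["A", "B", "C"], "CHR": [1, 1, 1],
            "BP": [1_000_000, 1_200_000, 2_000_000],
            "p_r": [1e-9, 1e-4, 2e-8]})
        ld = polar.LDMatrix(snp_ids=["A", "B", "C"], matrix=np.array(
            [[1.0, 0.5, 0.01], [0.5, 1.0, 0.01], [0.01, 0.01, 1.0]]))
        leads, loci = polar.clump(sel, ld)
        assert set(leads) == {"A", "C"}
        assert len(loci) == 2
        assert set(loci[0].members) == {"A", "B"}

    def test_mhc_region_collapses_to_one_locus(self):
        sel = pd.DataFrame({"SNP": ["x", "y"], "CHR": [6, 6],
                            "BP": [26_000_000, 26_010_000],
                            "p_r": [1e-9, 1e-10]})
        ld = polar.LDMatrix(snp_ids=["x", "y"], matrix=np.eye(2))
        leads, loci = polar.clump(sel, ld)
        assert len(loci) == 1 and loci[0].is_mhc
        assert set(leads) == {"x", "y"}

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_brute_force_on_random_small_panels(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(2, 21))
        ids = [f"s{i}" for i in range(n)]
        chrom = rng.choice([1, 6], size=n, p=[0.7, 0.3])
        bp = np.where(chrom == 6,
                      rng.integers(24_000_000, 36_000_000, n),
                      rng.integers(1, 5_000_000, n))
        p = 10.0 ** rng.uniform(-12, -1, n)
        half = rng.uniform(0, 1, (n, n))
        r2 = np.triu(half, 1) + np.triu(half, 1).T + np.eye(n)
        sel = pd.DataFrame({"SNP": ids, "CHR": chrom, "BP": bp, "p_r": p})
        cfg = polar.ClumpConfig()
        _, loci = polar.clump(sel, polar.LDMatrix(snp_ids=ids, matrix=r2), cfg)
        got = sorted((L.chrom, L.start, L.end, frozenset(L.members),
                      frozenset(L.leads)) for L in loci)
        expected = brute_force_clump(sel, polar.LDMatrix(snp_ids=ids, matrix=r2),
                                     cfg)
        assert got == expected

    def test_missing_ld_pairs_count_as_zero(self):
        sel = pd.DataFrame({"SNP": ["a", "b"], "CHR": [1, 1],
                            "BP": [100, 200], "p_r": [1e-9, 1e-9]})
        ld = polar.LDMatrix(pairs=pd.DataFrame(
            {"snpA": ["a"], "snpB": ["zz"], "r2": [0.9]}))
        leads, loci = polar.clump(sel, ld)
        assert len(loci) == 2
        assert ld.misses > 0


class TestGenomicInflation:
    def test_reference_median_gives_unit_lambda(self):
        out = polar.genomic_inflation(p=np.full(1000, 0.5))
        assert out["lambda"] == pytest.approx(1.0)

    def test_null_uniform_p_lambda_near_one(self):
        rng = np.random.default_rng(46)
        out = polar.genomic_inflation(p=rng.uniform(size=100_000))
        assert out["lambda"] == pytest.approx(1.0, abs=0.01)

    def test_halved_p_inflates(self):
        rng = np.random.default_rng(47)
        p = rng.uniform(size=10_000)
        assert polar.genomic_inflation(p=p / 2)["lambda"] \
            > polar.genomic_inflation(p=p)["lambda"]

    def test_lambda_1000_rescaling(self):
        out = polar.genomic_inflation(p=np.full(1000, 0.5),
                                      cases=1000, controls=1000)
        assert out["lambda_1000"] == pytest.approx(1.0)

    def test_too_few_statistics_rejected(self):
        with pytest.raises(ValueError):
            polar.genomic_inflation(p=np.full(50, 0.5))
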