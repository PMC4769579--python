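import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quartetscan import popgen
from quartetscan.simulate import make_fixture_frequencies
from conftest import make_matrix, quartet_samples
from quartetscan.genotype_io import QuartetSpec


def _freqs(tuples):
    return make_fixture_frequencies(tuples)


freq_tables = st.lists(
    st.tuples(*[st.floats(0, 1, allow_nan=False) for _ in range(4)]),
    min_size=1, max_size=30).map(_freqs)


class TestSiteFrequencies:
    def _matrix_and_quartet(self, rows):
        mat = make_matrix(list(range(len(rows))), rows,
                          samples=quartet_samples())
        q = QuartetSpec(tuple(f"P1_{i}" for i in range(4)),
                        tuple(f"P2_{i}" for i in range(4)),
                        tuple(f"P3_{i}" for i in range(4)), ("O_0",))
        return mat, q

    def test_outgroup_homozygous_ref_makes_alt_derived(self):
        row = [0, 1, 1, 2] + [0] * 4 + [2] * 4 + [0]
        mat, q = self._matrix_and_quartet([row])
        fr = popgen.site_frequencies(mat, q)
        assert fr.n_sites == 1
        assert fr.derived_is_alt[0]
        # population of 4 diploids with dosages (0,1,1,2) -> 4/8
        assert fr.freqs[0, 0] == pytest.approx(0.5)

    def test_heterozygous_outgroup_excluded_by_default(self):
        row = [0] * 12 + [1]  # single diploid O heterozygous
        mat, q = self._matrix_and_quartet([row])
        assert popgen.site_frequencies(mat, q).n_sites == 0
        kept = popgen.site_frequencies(mat, q, polarization="ref-ancestral")
        assert kept.n_sites == 1

    def test_outgroup_homozygous_alt_flips_polarity(self):
        row = [2, 2, 2, 2] + [0] * 8 + [2]
        mat, q = self._matrix_and_quartet([row])
        fr = popgen.site_frequencies(mat, q)
        assert not fr.derived_is_alt[0]
        assert fr.freqs[0, 0] == pytest.approx(0.0)   # P1 all-alt = all-ancestral
        assert fr.freqs[0, 1] == pytest.approx(1.0)

    def test_population_with_no_calls_has_undefined_frequency(self):
        row = [0] * 4 + [-1] * 4 + [0] * 4 + [0]
        mat, q = self._matrix_and_quartet([row])
        fr = popgen.site_frequencies(mat, q)
        assert np.isnan(fr.freqs[0, 1])
        assert popgen.valid_snp_count(fr) == 0


class TestDStatistic:
    def test_pure_abba_gives_one(self):
        assert popgen.d_statistic(_freqs([(0, 1, 1, 0)] * 5)) == pytest.approx(1.0)

    def test_pure_baba_gives_minus_one(self):
        assert popgen.d_statistic(_freqs([(1, 0, 1, 0)] * 5)) == pytest.approx(-1.0)

    def test_hand_computed_mixture(self):
        # numerator 0.5 - 0.5 + 0.30 = 0.3; denominator 0.5 + 0.5 + 0.34 = 1.34
        fr = _freqs([(0, 0.5, 1, 0), (0.5, 0, 1, 0), (0.2, 0.8, 0.5, 0)])
        assert popgen.d_statistic(fr) == pytest.approx(0.3 / 1.34, abs=1e-12)

    def test_zero_denominator_is_undefined(self):
        assert np.isnan(popgen.d_statistic(_freqs([(0, 0, 0, 0)])))

    @settings(max_examples=200, deadline=None)
    @given(freq_tables)
    def test_antisymmetric_under_p1_p2_swap(self, fr):
        swapped = make_fixture_frequencies(fr.freqs[:, [1, 0, 2, 3]])
        d1, d2 = popgen.d_statistic(fr), popgen.d_statistic(swapped)
        if np.isnan(d1):
            assert np.isnan(d2)
        else:
            assert d1 == pytest.approx(-d2, abs=1e-12)


class TestFd:
    def test_equal_p2_p3_gives_one(self):
        fr = _freqs([(0, 0.8, 0.8, 0), (0.1, 0.6, 0.6, 0)])
        assert popgen.f_d_statistic(fr) == pytest.approx(1.0)

    def test_single_site_p3_donor(self):
        assert popgen.f_d_statistic(_freqs([(0, 0.5, 1.0, 0)])) == \
            pytest.approx(0.5, abs=1e-12)

    def test_single_site_p2_donor(self):
        assert popgen.f_d_statistic(_freqs([(0, 0.8, 0.4, 0)])) == \
            pytest.approx(0.5, abs=1e-12)

    def test_undefined_for_non_positive_d(self):
        assert np.isnan(popgen.f_d_statistic(_freqs([(1, 0, 1, 0)])))


class TestDxy:
    def test_identical_monomorphic_zero(self):
        fr = _freqs([(0, 0, 0, 0)] * 3)
        assert popgen.dxy(fr, "P2", "P3") == 0.0

    def test_fixed_difference_one(self):
        fr = _freqs([(0, 1, 0, 0)])
        assert popgen.dxy(fr, "P1", "P2") == pytest.approx(1.0)

    def test_hand_computed_mean(self):
        fr = _freqs([(0, 0.2, 0.6, 0), (0, 1.0, 1.0, 0)])
        assert popgen.dxy(fr, "P2", "P3") == pytest.approx(0.28, abs=1e-12)

    def test_window_length_normalization(self):
        fr = _freqs([(0, 0.2, 0.6, 0), (0, 1.0, 1.0, 0)])
        assert popgen.dxy(fr, "P2", "P3", normalization=100) == \
            pytest.approx(0.56 / 100, abs=1e-15)

    @settings(max_examples=100, deadline=None)
    @given(freq_tables)
    def test_symmetric(self, fr):
        for a, b in (("P1", "P2"), ("P2", "P3")):
            d1, d2 = popgen.dxy(fr, a, b), popgen.dxy(fr, b, a)
            assert (np.isnan(d1) and np.isnan(d2)) or d1 == pytest.approx(d2)


def brute_force_wc_fst(dosages, cols_x, cols_y):
    """Independent textbook Weir-Cockerham (1984) oracle, site by site."""
    a_sum = b_sum = c_sum = 0.0
    for row in dosages:
        pops = []
        for cols in (cols_x, cols_y):
            g = [row[c] for c in cols if row[c] >= 0]
            if not g:
                pops = None
                break
            pops.append(g)
        if pops is None:
            continue
        r = 2
        n = [len(g) for g in pops]
        p = [sum(g) / (2 * len(g)) for g in pops]
        h = [sum(1 for x in g if x == 1) / len(g) for g in pops]
        nbar = sum(n) / r
        if nbar <= 1:
            continue
        pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
        if pbar in (0.0, 1.0):
            continue
        nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
        s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
        hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
        a_sum, b_sum, c_sum = a_sum + a, b_sum + b, c_sum + c
    tot = a_sum + b_sum + c_sum
    return float("nan") if tot == 0 else a_sum / tot


class TestFst:
    def test_identical_frequencies_near_zero(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 3, size=(30, 4))
        dosages = np.hstack([block, block])  # two identical populations
        mat = make_matrix(list(range(30)), dosages)
        val = popgen.fst_weir_cockerham(mat, mat.samples[:4], mat.samples[4:])
        assert val == pytest.approx(brute_force_wc_fst(dosages, range(4),
                                                       range(4, 8)), abs=1e-12)
        assert val < 0.05

    def test_fixed_difference_is_one(self):
        dosages = np.array([[0] * 4 + [2] * 4])
        mat = make_matrix([0], dosages)
        assert popgen.fst_weir_cockerham(mat, mat.samples[:4],
                                         mat.samples[4:]) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            dosages = rng.integers(-1, 3, size=(20, 8))
            mat = make_matrix(list(range(20)), dosages)
            got = popgen.fst_weir_cockerham(mat, mat.samples[:4], mat.samples[4:])
            want = brute_force_wc_fst(dosages, range(4), range(4, 8))
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-12)


class TestWindowBookkeeping:
    def test_valid_snp_count_applies_polarization(self):
        rows = [[0, 1, 1, 2] + [0] * 8 + [0]] * 5 \
            + [[0] * 12 + [1]] * 2          # two sites dropped: O heterozygous
        mat = make_matrix(list(range(7)), rows, samples=quartet_samples())
        q = QuartetSpec(tuple(f"P1_{i}" for i in range(4)),
                        tuple(f"P2_{i}" for i in range(4)),
                        tuple(f"P3_{i}" for i in range(4)), ("O_0",))
        fr = popgen.site_frequencies(mat, q)
        assert popgen.valid_snp_count(fr) == 5

    def test_depth_summary_means(self, quartet13):
        depths = np.full((2, 13), 20)
        depths[0, 0], depths[1, 0] = 10, 30
        mat = make_matrix([0, 1], np.zeros((2, 13), dtype=int),
                          samples=quartet_samples(), depths=depths)
        out = popgen.window_depth_summary(mat, quartet13, np.array([0, 1]))
        assert out["P1"] == pytest.approx((10 + 30 + 6 * 20) / 8)
        assert out["O"] == pytest.approx(20)

    def test_no_dp_field_warns_and_returns_nan(self, quartet13):
        mat = make_matrix([0], np.zeros((1, 13), dtype=int),
                          samples=quartet_samples())
        with pytest.warns(UserWarning):
            out = popgen.window_depth_summary(mat, quartet13, np.array([0]))
        assert all(np.isnan(v) for v in out.values())
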