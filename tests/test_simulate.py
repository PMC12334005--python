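import numpy as np
import pytest

from apcbayes import (
    APCGrid,
    centered_index,
    decompose,
    draw_sim2,
    draw_sim3,
    enumerate_sim1_cases,
    generate_data,
    make_trig_params,
    polynomial_params,
)
from apcbayes.simulate import COMPONENT_SD


class TestTrigParams:
    def test_even_blocks_need_no_intercept_correction(self):
        p = make_trig_params(APCGrid(10, 10), (0.1, 0, 0), (0.05, 0, 0))
        assert p.intercepts[0] == 0.0  # I = 10 even
        assert p.intercepts[1] == 0.0

    def test_odd_cohort_block_correction(self):
        # K = 19 odd: beta0C = amp / K
        p = make_trig_params(APCGrid(10, 10), (0, 0, 0), (0, 0, 0.05))
        assert p.intercepts[2] == pytest.approx(0.05 / 19)
        assert abs(p.beta_c.sum()) < 1e-12

    def test_zero_spec_gives_zero_vectors(self):
        p = make_trig_params(APCGrid(7, 5))
        assert np.all(p.beta_a == 0) and np.all(p.beta_c == 0)

    @pytest.mark.parametrize("I,J", [(3, 3), (10, 10), (4, 9)])
    def test_zero_sum_exact_and_components_recoverable(self, I, J):
        g = APCGrid(I, J)
        slopes, amps = (0.1, -0.2, 0.07), (0.05, 0.04, -0.03)
        p = make_trig_params(g, slopes, amps)
        for b, M, slope, amp in zip(
            (p.beta_a, p.beta_p, p.beta_c), (I, J, g.K), slopes, amps
        ):
            assert abs(b.sum()) < 1e-10
            d = decompose(b, centered_index(M))
            # slope recovery up to the documented cosine leakage bound
            v = centered_index(M)
            cos = np.where(np.arange(1, M + 1) % 2 == 0, 1.0, -1.0)
            leak = abs(amp) * abs(v @ cos) / (v @ v)
            assert abs(d.slope - slope) <= leak + 1e-12

    def test_effects_view_matches_vectors(self):
        p = make_trig_params(APCGrid(4, 4), (0.1, 0, 0), (0, 0.05, 0))
        e = p.effects()
        assert e.b0 == 0.0
        assert np.array_equal(e.bP, p.beta_p)


class TestGenerateData:
    def test_noise_free_limit_reproduces_cell_sums(self):
        g = APCGrid(4, 4)
        p = make_trig_params(g, (0.1, -0.1, 0.05), (0.02, 0.0, 0.04), gamma=0.0)
        data = generate_data(p, replicates=2, seed=0)
        i, j, k = data.indices()
        expected = p.beta_a[i - 1] + p.beta_p[j - 1] + p.beta_c[k - 1]
        assert np.allclose(data.y, expected)

    def test_study_scale(self):
        p = make_trig_params(APCGrid(10, 10), gamma=0.1)
        assert generate_data(p, replicates=10, seed=1).N == 1000

    def test_deterministic_given_seed(self):
        p = make_trig_params(APCGrid(5, 5), (0.1, 0, 0), (0, 0, 0.05))
        a = generate_data(p, 3, seed=99)
        b = generate_data(p, 3, seed=99)
        assert np.array_equal(a.y, b.y)

    def test_cell_means_concentrate_at_truth(self):
        # law of large numbers: cell averages over 10^4 replicates sit within
        # 3*gamma/100 of the true cell values
        g = APCGrid(3, 3)
        p = make_trig_params(g, (0.1, 0, -0.1), (0.05, 0.05, 0.0), gamma=0.1)
        data = generate_data(p, replicates=10_000, seed=4)
        means = data.df.groupby(["i", "j"])["y"].mean().unstack().to_numpy()
        assert np.all(np.abs(means - p.cell_means()) < 3 * 0.1 / 100)


class TestSim1Cases:
    def test_thirteen_cases_in_table_order(self):
        cases = enumerate_sim1_cases()
        assert len(cases) == 13
        assert [c.signs for c in cases[:3]] == [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        assert cases[12].signs == (1, -1, 1)

    def test_case3_is_pure_cohort(self):
        c = enumerate_sim1_cases()[2]
        assert c.slopes == (0.0, 0.0, 0.1)
        assert c.amps == (0.0, 0.0, 0.05)

    def test_no_null_and_no_sign_flip_duplicates(self):
        signs = [c.signs for c in enumerate_sim1_cases()]
        assert (0, 0, 0) not in signs
        flipped = {tuple(-s for s in t) for t in signs}
        assert flipped.isdisjoint(signs)

    def test_magnitudes_follow_signs(self):
        for c in enumerate_sim1_cases():
            assert c.slopes == tuple(0.1 * s for s in c.signs)
            assert c.amps == tuple(0.05 * s for s in c.signs)


class TestComponentDraws:
    def test_sim2_moments(self):
        draws = np.array(
            [
                draw_sim2(np.random.default_rng(i)).slopes
                + draw_sim2(np.random.default_rng(i)).amps
                for i in range(20_000)
            ]
        )
        assert np.all(np.abs(draws.mean(axis=0)) < 0.01)
        assert np.all(np.abs(draws.std(axis=0) - COMPONENT_SD) < 0.01)

    def test_sim2_reproducible(self):
        assert draw_sim2(7) == draw_sim2(7)

    def test_sim3_conditional_variance_matches_amplitude(self):
        rng = np.random.default_rng(12)
        draws = [draw_sim3(rng) for _ in range(30_000)]
        amps = np.array([d.amps for d in draws]).ravel()
        slopes = np.array([d.slopes for d in draws]).ravel()
        # E[slope^2 | amp] = amp^2, checked within |amp| bins
        bins = np.quantile(np.abs(amps), [0.0, 0.25, 0.5, 0.75, 1.0])
        for lo, hi in zip(bins[:-1], bins[1:]):
            sel = (np.abs(amps) >= lo) & (np.abs(amps) < hi)
            ratio = np.mean(slopes[sel] ** 2) / np.mean(amps[sel] ** 2)
            assert 0.9 < ratio < 1.1

    def test_sim3_avoids_near_pure_linear_draws(self):
        rng = np.random.default_rng(3)
        gray = 0
        for n, budget in ((500, 0), (30_000, 3)):
            count = 0
            for _ in range(n):
                d = draw_sim3(rng)
                for L, NL in zip(d.slopes, d.amps):
                    if (L, NL) != (0.0, 0.0) and abs(NL) <= 0.2 * abs(L):
                        count += 1
            assert count <= budget, (n, count)

    def test_sim3_literal_coupling_uses_age_amplitude(self):
        a = draw_sim3(42, literal_coupling=False)
        b = draw_sim3(42, literal_coupling=True)
        # same nonlinear draws, same age slope, different period/cohort scaling
        assert a.amps == b.amps
        assert a.slopes[0] == b.slopes[0]
        assert a.slopes[1] != b.slopes[1]


class TestPolynomialParams:
    def test_degree_one_is_purely_linear(self):
        spec = polynomial_params(M=12, H=1, seed=0)
        assert spec.sd_nl == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(spec.eta_nl, 0.0, atol=1e-12)

    def test_unit_weight_on_single_power_recovers_standardized_column(self):
        # with w = e_h the polynomial equals the standardized power column,
        # which has zero mean and unit population SD by construction
        v = centered_index(9)
        for h in range(1, 6):
            w = np.zeros(5)
            w[h - 1] = 1.0
            spec = polynomial_params(M=9, H=5, weights=w)
            assert spec.eta.mean() == pytest.approx(0.0, abs=1e-12)
            assert spec.eta.std() == pytest.approx(1.0)

    def test_slope_matches_regression_oracle(self):
        spec = polynomial_params(M=20, H=8, seed=17)
        v = centered_index(20)
        oracle = np.polyfit(v, spec.eta, 1)[0]
        assert spec.eta_l == pytest.approx(oracle)
        assert np.allclose(spec.eta_l * v + spec.eta_nl, spec.eta)
        assert abs(spec.eta.sum()) < 1e-10

    def test_high_degree_rarely_near_pure_linear(self):
        rng = np.random.default_rng(8)
        in_gray = {2: 0, 8: 0}
        n = 500
        for H in (2, 8):
            for _ in range(n):
                if polynomial_params(M=20, H=H, seed=rng).in_gray_area():
                    in_gray[H] += 1
        assert in_gray[2] >= 15         # near-pure-linear draws occur at H=2
        assert in_gray[8] <= 2          # and are essentially absent at H=8
        assert in_gray[2] > 10 * max(in_gray[8], 1)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            polynomial_params(M=2, H=2)
        with pytest.raises(ValueError):
            polynomial_params(M=5, H=0)
        with pytest.raises(ValueError):
            polynomial_params(M=5, H=2, weights=np.zeros(3))
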