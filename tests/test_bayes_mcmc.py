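from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pytest
from scipy import stats

from dombayes import bayes_mcmc as bm


def round_half_up(x: float, digits: int) -> float:
    """Decimal half-up rounding as used for printed values."""
    q = Decimal(1).scaleb(-digits)
    return float(Decimal(f"{x:.12f}").quantize(q, rounding=ROUND_HALF_UP))


class TestPldSchedule:
    @pytest.mark.parametrize(
        "t,printed",
        [(1, 0.116), (2, 0.040), (3, 0.014), (4.8, 0.0021)],
    )
    def test_printed_values(self, t, printed):
        digits = len(str(printed).split(".")[1])
        assert round_half_up(bm.pld_schedule(t), digits) == printed

    @pytest.mark.parametrize("t,snps", [(1, 3.85), (2, 2.70), (3, 1.89)])
    def test_snps_per_qtl(self, t, snps):
        m = 250 * 2**t
        assert round_half_up(bm.pld_schedule(t) * m / 15, 2) == snps

    def test_rejects_nonpositive_exponent(self):
        with pytest.raises(ValueError):
            bm.pld_schedule(0)


def _toy_inputs(rng, n=120, m=60, **kw):
    p = rng.uniform(0.1, 0.9, m)
    x = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    y = rng.normal(0, 1, n)
    kw.setdefault("v_a_in", 1.0)
    kw.setdefault("v_e_in", 1.0)
    return bm.ModelInputs(y=y, X=x, **kw)


class TestModelInputs:
    def test_w_derived_from_heterozygotes(self, small_rng):
        inputs = _toy_inputs(small_rng)
        assert np.array_equal(inputs.W == 1, inputs.X == 1)

    def test_rejects_bad_genotypes(self, small_rng):
        with pytest.raises(ValueError):
            bm.ModelInputs(
                y=np.zeros(2), X=np.array([[3, 0], [1, 1]]),
                v_a_in=1.0, v_e_in=1.0,
            )

    def test_rejects_nonfinite_phenotypes(self, small_rng):
        with pytest.raises(ValueError):
            bm.ModelInputs(
                y=np.array([np.nan, 0.0]), X=np.zeros((2, 1), int),
                v_a_in=1.0, v_e_in=1.0,
            )


class TestCalibration:
    def test_additive_scale_closed_form(self, small_rng):
        """pld = 1, df = 2.5, sum H = 1, v_a = 5 gives s_a^2 = 1."""
        x = np.array([[0], [1], [2], [1]], dtype=np.int8)  # p = 0.5, H = 0.5
        y = np.zeros(4)
        inputs = bm.ModelInputs(y=y, X=x, v_a_in=5.0, v_e_in=1.0)
        prior = bm.calibrate_priors(
            inputs, pld=1.0 - 1e-12, freqs=np.array([0.5]),
        )
        # sum H = 0.5 here; rescale the check to sum H = 1
        assert prior.s_a**2 * 0.5 == pytest.approx(1.0, rel=1e-6)

    def test_zero_dominance_degenerates(self, small_rng):
        inputs = _toy_inputs(small_rng, v_d_in=0.0, inb_dep_in=0.0)
        prior = bm.calibrate_priors(inputs, pld=0.1, model="D")
        assert prior.mu_h == 0.0 and prior.sigma_h == 0.0

    def test_infeasible_moment_system_falls_back(self, small_rng):
        # huge inbreeding depression with tiny dominance variance cannot
        # be moment-matched; the dominance prior falls back to (0.2, 0.3)
        inputs = _toy_inputs(
            small_rng, v_d_in=1e-6, inb_dep_in=100.0
        )
        prior = bm.calibrate_priors(inputs, pld=0.1, model="D")
        assert prior.calibration_fallback
        assert (prior.mu_h, prior.sigma_h) == (0.2, 0.3)

    def test_prior_monte_carlo_matches_inputs(self, small_rng):
        """Drawing effects from the calibrated prior reproduces the input
        additive variance (robustly, via the psi-conditional variance)."""
        inputs = _toy_inputs(small_rng, n=200, m=40, v_a_in=3.0)
        pld = 0.2
        prior = bm.calibrate_priors(inputs, pld)
        p = inputs.freqs()
        H = 2 * p * (1 - p)
        # E[a^2] = s_a^2 * df/(df-2) * (pld + (1-pld) eps^2), analytically
        ea2 = (
            prior.s_a**2 * 2.5 / 0.5
            * (pld + (1 - pld) * prior.epsilon**2)
        )
        assert (H * ea2).sum() == pytest.approx(3.0, rel=1e-9)

    def test_rejects_bad_hyperparams(self, small_rng):
        inputs = _toy_inputs(small_rng)
        with pytest.raises(ValueError):
            bm.calibrate_priors(inputs, pld=0.1, df_t=2.0)
        with pytest.raises(ValueError):
            bm.calibrate_priors(inputs, pld=1.5)


class TestMCMCConfig:
    def test_stored_sample_count(self):
        mc = bm.MCMCConfig()
        assert mc.n_stored == 100
        with pytest.raises(ValueError):
            bm.MCMCConfig(n_cycles=100, burn_in=200)


@pytest.fixture(scope="module")
def prior_chain():
    """BayesD chain with the likelihood switched off: samples the prior."""
    rng = np.random.default_rng(5)
    n, m = 50, 250
    p = rng.uniform(0.1, 0.9, m)
    x = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    inputs = bm.ModelInputs(
        y=rng.normal(0, 1, n), X=x,
        v_a_in=2.0, v_e_in=1.0, v_d_in=0.4, inb_dep_in=0.3,
    )
    prior = bm.calibrate_priors(inputs, pld=0.3, model="D")
    mc = bm.MCMCConfig(n_cycles=4100, burn_in=100, thin=4, seed=11)
    return bm.run_bayesd(inputs, prior, mc, likelihood=False), prior


class TestPriorReproduction:
    def test_inclusion_rate(self, prior_chain):
        s, prior = prior_chain
        n_draws = s.gamma_s.size
        rate = s.gamma_s.mean()
        # thinned draws are nearly independent; allow 4 binomial SE
        se = np.sqrt(prior.pld * (1 - prior.pld) / n_draws)
        assert abs(rate - prior.pld) < 4 * se

    def test_additive_t_distribution(self, prior_chain):
        """a | gamma=1 follows the folded-t scale: compare quantiles of
        |a|/s_a against the half-t with 2.5 df (moments are too heavy-
        tailed for a variance check)."""
        s, prior = prior_chain
        a1 = np.abs(s.a_s[s.gamma_s.astype(bool)]) / prior.s_a
        for q in (0.25, 0.5, 0.75, 0.9):
            target = stats.t.ppf(0.5 + q / 2, df=2.5)
            obs = np.quantile(a1, q)
            # quantile SE via the asymptotic formula
            dens = 2 * stats.t.pdf(target, df=2.5)
            se = np.sqrt(q * (1 - q) / len(a1)) / dens
            assert abs(obs - target) < 5 * se, (q, obs, target)

    def test_small_component_scaled_by_epsilon(self, prior_chain):
        s, prior = prior_chain
        g = s.gamma_s.astype(bool)
        med1 = np.median(np.abs(s.a_s[g]))
        med0 = np.median(np.abs(s.a_s[~g]))
        assert med0 / med1 == pytest.approx(prior.epsilon, rel=0.1)

    def test_dominance_coefficient_prior(self, prior_chain):
        """d/|a| ~ N(mu_h, sigma_h^2) independent of a."""
        s, prior = prior_chain
        ratio = (s.d_s / np.abs(s.a_s)).ravel()
        se = prior.sigma_h / np.sqrt(len(ratio))
        assert abs(ratio.mean() - prior.mu_h) < 4 * se
        assert ratio.std() == pytest.approx(prior.sigma_h, rel=0.05)


class TestSamplers:
    def _signal_inputs(self, seed=1, n=500, m=200, h2_qtl=0.5):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.1, 0.9, m)
        x = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        j0 = m // 2
        bv = (x[:, j0] - 2 * p[j0]) * 1.0
        va = bv.var()
        ve = va * (1 - h2_qtl) / h2_qtl
        y = bv + rng.normal(0, np.sqrt(ve), n)
        return bm.ModelInputs(y=y, X=x, v_a_in=va, v_e_in=ve), j0

    def test_null_data_calibration(self):
        """Pure-noise phenotypes: small effects, inclusion rate ~ pld."""
        rng = np.random.default_rng(4)
        n, m = 300, 150
        p = rng.uniform(0.1, 0.9, m)
        x = rng.binomial(2, p, size=(n, m)).astype(np.int8)
        y = rng.normal(0, 1, n)
        inputs = bm.ModelInputs(y=y, X=x, v_a_in=0.05, v_e_in=1.0)
        pld = 0.01
        prior = bm.calibrate_priors(inputs, pld)
        mc = bm.MCMCConfig(n_cycles=3000, burn_in=1000, thin=2, seed=2)
        s = bm.run_bayesc(inputs, prior, mc)
        assert np.abs(s.a_s).mean() < 0.1 * y.std()
        rate = s.gamma_s.mean()
        # gamma draws are correlated across cycles; allow a loose band
        assert rate < 5 * pld

    def test_strong_signal_recovered(self):
        """A QTL explaining half the variance gets inclusion prob > 0.9."""
        inputs, j0 = self._signal_inputs()
        prior = bm.calibrate_priors(inputs, pld=0.05)
        mc = bm.MCMCConfig(n_cycles=3000, burn_in=1000, thin=10, seed=3)
        s = bm.run_bayesc(inputs, prior, mc)
        pi = s.gamma_s.mean(axis=0)
        assert pi[j0 - 1:j0 + 2].max() > 0.9

    def test_determinism(self):
        inputs, _ = self._signal_inputs(n=100, m=50)
        prior = bm.calibrate_priors(inputs, pld=0.1)
        mc = bm.MCMCConfig(n_cycles=500, burn_in=100, thin=4, seed=9)
        s1 = bm.run_bayesc(inputs, prior, mc)
        s2 = bm.run_bayesc(inputs, prior, mc)
        assert np.array_equal(s1.a_s, s2.a_s)
        assert np.array_equal(s1.gamma_s, s2.gamma_s)
        d1 = bm.run_bayesd(inputs, prior, mc)
        d2 = bm.run_bayesd(inputs, prior, mc)
        assert np.array_equal(d1.d_s, d2.d_s)

    def test_monomorphic_column_pinned_at_zero(self):
        rng = np.random.default_rng(8)
        n = 100
        x = rng.binomial(2, 0.5, size=(n, 3)).astype(np.int8)
        x[:, 1] = 2  # constant column
        y = rng.normal(0, 1, n)
        inputs = bm.ModelInputs(y=y, X=x, v_a_in=1.0, v_e_in=1.0)
        prior = bm.calibrate_priors(inputs, pld=0.5)
        mc = bm.MCMCConfig(n_cycles=400, burn_in=100, thin=2, seed=1)
        s = bm.run_bayesc(inputs, prior, mc)
        assert np.all(s.a_s[:, 1] == 0.0)

    def test_bayesd_zero_dominance_matches_bayesc(self):
        """With v_d = 0 the dominance prior degenerates and BayesD's
        additive draws coincide with BayesC's on the same seed."""
        inputs, j0 = self._signal_inputs(n=200, m=80)
        inputs.v_d_in = 0.0
        prior = bm.calibrate_priors(inputs, pld=0.1, model="D")
        assert prior.sigma_h == 0.0
        mc = bm.MCMCConfig(n_cycles=800, burn_in=200, thin=4, seed=5)
        sc = bm.run_bayesc(inputs, prior, mc)
        sd = bm.run_bayesd(inputs, prior, mc)
        assert np.all(sd.d_s == 0.0)
        np.testing.assert_allclose(sc.a_s, sd.a_s)

    def test_posterior_contraction_in_n(self):
        """Doubling N does not reduce the top QTL's inclusion."""
        pis = []
        for n in (150, 600):
            inputs, j0 = self._signal_inputs(seed=21, n=n, m=60)
            prior = bm.calibrate_priors(inputs, pld=0.05)
            mc = bm.MCMCConfig(n_cycles=1500, burn_in=500, thin=5, seed=6)
            s = bm.run_bayesc(inputs, prior, mc)
            pis.append(s.gamma_s.mean(axis=0)[j0 - 1:j0 + 2].max())
        assert pis[1] >= pis[0] - 0.05

    def test_snp_order_exchangeability(self):
        """Fitting a column-permuted panel recovers the same signal:
        the QTL's posterior inclusion is unchanged within MC error."""
        inputs, j0 = self._signal_inputs(seed=31, n=200, m=60)
        prior = bm.calibrate_priors(inputs, pld=0.05)
        mc = bm.MCMCConfig(n_cycles=2000, burn_in=500, thin=5, seed=17)
        s_plain = bm.run_bayesc(inputs, prior, mc)
        rng = np.random.default_rng(1)
        perm = rng.permutation(inputs.m)
        inputs_p = bm.ModelInputs(
            y=inputs.y, X=inputs.X[:, perm],
            v_a_in=inputs.v_a_in, v_e_in=inputs.v_e_in,
        )
        s_perm = bm.run_bayesc(inputs_p, prior, mc)
        pi_plain = s_plain.gamma_s.mean(axis=0)[j0]
        pi_perm = s_perm.gamma_s.mean(axis=0)[np.argmax(perm == j0)]
        assert abs(pi_plain - pi_perm) < 0.1

    def test_overdominant_qtl_found_by_bayesd_not_bayesc(self):
        """A QTL with a tiny additive but large dominance effect is picked
        up by the dominance-aware window scan and missed by the additive
        one in most replicates."""
        from dombayes import wppa as wp

        n, m = 600, 100
        positions = np.arange(m) * 0.1  # 10 cM, 0.1 cM spacing
        j0 = m // 2
        a_true, d_true = 0.07, 1.4
        c_hit, d_hit = 0, 0
        n_rep = 6
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            p = rng.uniform(0.1, 0.9, m)
            p[j0] = 0.5
            x = rng.binomial(2, p, size=(n, m)).astype(np.int8)
            w = (x[:, j0] == 1).astype(float)
            gv = a_true * x[:, j0] + d_true * w
            y = gv + rng.normal(0, 1.0, n)
            alpha = a_true  # p = q = 0.5
            bv = (x[:, j0] - 2 * p[j0]) * alpha
            dv = d_true * (
                -x[:, j0] * (x[:, j0] - 1 - 2 * p[j0]) - 2 * p[j0] ** 2
            )
            inputs = bm.ModelInputs(
                y=y, X=x,
                v_a_in=max(bv.var(), 1e-4), v_d_in=dv.var(),
                v_e_in=1.0, inb_dep_in=2 * p[j0] * (1 - p[j0]) * d_true,
            )
            pld = bm.pld_schedule(1.0)
            mc = bm.MCMCConfig(seed=rep)
            sc = bm.run_bayesc(
                inputs, bm.calibrate_priors(inputs, pld, model="C"), mc
            )
            sd = bm.run_bayesd(
                inputs, bm.calibrate_priors(inputs, pld, model="D"), mc
            )
            va, vd = inputs.v_a_in, inputs.v_d_in
            scan_c = wp.scan_windows(sc, positions, va, vd, 0.5)
            scan_d = wp.scan_windows(sd, positions, va, vd, 0.5)
            near = slice(max(j0 - 10, 0), j0 + 10)
            if np.nanmax(scan_d.wppa[near]) > 0.95:
                d_hit += 1
            if np.nanmax(scan_c.wppa[near]) > 0.95:
                c_hit += 1
        assert d_hit >= 0.7 * n_rep, (d_hit, c_hit)
        assert d_hit > c_hit

    def test_samples_roundtrip_hdf5(self, tmp_path, small_rng):
        inputs = _toy_inputs(small_rng, v_d_in=0.2, inb_dep_in=0.05)
        prior = bm.calibrate_priors(inputs, pld=0.2, model="D")
        mc = bm.MCMCConfig(n_cycles=200, burn_in=100, thin=2, seed=4)
        s = bm.run_bayesd(inputs, prior, mc)
        path = tmp_path / "samples.h5"
        s.save(path)
        s2 = bm.PosteriorSamples.load(path)
        assert s2.model == "bayesd"
        np.testing.assert_array_equal(s.a_s, s2.a_s)
        np.testing.assert_array_equal(s.d_s, s2.d_s)
        assert s2.prior.s_a == pytest.approx(prior.s_a)
        assert s2.mcmc.seed == 4
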