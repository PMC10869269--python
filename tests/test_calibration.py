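"""Gumbel fitting, the E-value model and the TP-probability mixtures."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import spearmanr

import foldscan as fs
from foldscan.calibration import (ConfigError, DegenerateFitError,
                                  GammaMixture, GammaMixturePair, evalue_from_params,
                                  fit_evalue_correction, fit_gamma_mixture, fit_gumbel,
                                  p_tp, query_features, shuffle_entry,
                                  train_evalue_net)


def _gumbel_samples(mu, lam, n, seed):
    rng = np.random.default_rng(seed)
    return mu - np.log(-np.log(rng.uniform(size=n))) / lam


class TestFitGumbel:
    def test_parameter_recovery_from_large_sample(self):
        x = _gumbel_samples(10.0, 0.4, 50_000, seed=0)
        fit = fit_gumbel(x)
        assert fit.mu == pytest.approx(10.0, abs=0.05)
        assert fit.lam == pytest.approx(0.4, abs=0.01)

    def test_affine_equivariance(self):
        x = _gumbel_samples(5.0, 0.7, 2_000, seed=1)
        base = fit_gumbel(x)
        a, b = 2.5, -3.0
        scaled = fit_gumbel(a * x + b)
        assert scaled.mu == pytest.approx(a * base.mu + b, rel=1e-6)
        assert scaled.lam == pytest.approx(base.lam / a, rel=1e-6)

    def test_identical_scores_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_gumbel(np.full(30, 7.0))

    def test_too_few_scores_rejected(self):
        with pytest.raises(ConfigError):
            fit_gumbel(np.arange(10.0))


class TestCalibrationTable:
    def test_shuffle_preserves_length_and_composition(self, small_entries):
        rng = np.random.default_rng(0)
        for entry in small_entries[:5]:
            shuf = shuffle_entry(entry, rng)
            assert len(shuf) == len(entry)
            assert sorted(shuf.aa_seq) == sorted(entry.aa_seq)
            assert sorted(shuf.tdi_seq) == sorted(entry.tdi_seq)
            # the same permutation moves both strings
            perm_pairs = sorted(zip(shuf.aa_seq, shuf.tdi_seq))
            assert perm_pairs == sorted(zip(entry.aa_seq, entry.tdi_seq))

    def test_feature_vector_contract(self, small_entries, default_matrix):
        feats = query_features(small_entries[0], default_matrix.letters)
        assert feats.shape == (22,)
        L = len(small_entries[0])
        assert feats[20] == L
        assert feats[21] == pytest.approx(np.log(L + 1))
        assert feats[:20].sum() <= 1.0 + 1e-9  # 'X' takes the rest

    def test_table_deterministic_and_mu_grows_with_length(self, small_entries,
                                                          default_alphabet,
                                                          default_matrix):
        # queries spanning a range of lengths so the EVD location can track L
        chains = [fs.make_chain((("helix", h), ("coil", 4), ("strand", s)),
                                seed=40 + h)
                  for h, s in ((5, 4), (8, 6), (12, 8), (16, 10), (20, 12),
                               (26, 14), (32, 18), (40, 24))]
        queries = fs.make_entries(chains, default_alphabet)
        t1 = fs.build_calibration_table(queries, small_entries, default_matrix,
                                        n_align=60, seed=5)
        t2 = fs.build_calibration_table(queries, small_entries, default_matrix,
                                        n_align=60, seed=5)
        assert [r["mu"] for r in t1] == [r["mu"] for r in t2]
        assert [r["lam"] for r in t1] == [r["lam"] for r in t2]
        rho = spearmanr([len(q) for q in queries],
                        [r["mu"] for r in t1]).statistic
        assert rho > 0.5

    def test_small_n_align_rejected(self, small_entries, default_matrix):
        with pytest.raises(ConfigError):
            fs.build_calibration_table(small_entries[:1], small_entries,
                                       default_matrix, n_align=10)


def _linear_table(rng, n=400):
    rows = []
    for _ in range(n):
        feats = np.zeros(22)
        feats[:20] = rng.dirichlet(np.ones(20))
        L = rng.integers(20, 200)
        feats[20] = L
        feats[21] = np.log(L + 1)
        mu = 5.0 + 0.3 * L + 10.0 * feats[0]
        lam = 0.5 - 0.001 * L + 0.1 * feats[1]
        rows.append({"features": feats, "mu": mu, "lam": lam})
    return rows


class TestEvalueNet:
    def test_learns_linear_targets(self):
        rng = np.random.default_rng(7)
        table = _linear_table(rng)
        model = train_evalue_net(table, seed=0)
        held = _linear_table(rng, n=50)
        rel = []
        for row in held:
            mu, lam = model.predict(row["features"])
            rel.append(abs(mu - row["mu"]) / abs(row["mu"]))
            rel.append(abs(lam - row["lam"]) / abs(row["lam"]))
        assert np.mean(rel) < 0.05

    def test_row_order_does_not_change_weights(self):
        rng = np.random.default_rng(8)
        table = _linear_table(rng, n=150)
        m1 = train_evalue_net(table, seed=4)
        m2 = train_evalue_net(list(reversed(table)), seed=4)
        f = table[0]["features"]
        assert m1.predict(f) == pytest.approx(m2.predict(f), rel=1e-6)

    def test_predicted_lambda_clamped_positive(self):
        rng = np.random.default_rng(9)
        table = _linear_table(rng, n=150)
        model = train_evalue_net(table, seed=1)
        crazy = np.zeros(22)
        crazy[20] = 100000.0
        crazy[21] = np.log(100001.0)
        _, lam = model.predict(crazy)
        assert lam > 0

    def test_too_few_rows_rejected(self):
        rng = np.random.default_rng(10)
        with pytest.raises(ConfigError):
            train_evalue_net(_linear_table(rng, n=20))


class TestEvalue:
    def test_unit_raw_evalue_is_fixed_point_of_powering(self):
        # s chosen so db_size * exp(-lam (s - mu)) == 1
        mu, lam, db = 20.0, 0.3, 1000
        s = mu + np.log(db) / lam
        for exponent in (0.32, 0.7, 1.0):
            assert evalue_from_params(mu, lam, s, db, exponent) == pytest.approx(1.0)

    def test_score_at_mu_gives_db_size_to_the_exponent(self):
        assert evalue_from_params(12.0, 0.4, 12.0, 50, 0.32) == \
            pytest.approx(50 ** 0.32)

    def test_strictly_decreasing_in_score_increasing_in_db_size(self):
        es = [evalue_from_params(10, 0.5, s, 100, 0.32) for s in (10, 20, 30)]
        assert es[0] > es[1] > es[2]
        ed = [evalue_from_params(10, 0.5, 25, n, 0.32) for n in (10, 100, 1000)]
        assert ed[0] < ed[1] < ed[2]

    def test_correction_fit_recovers_power_law(self):
        rng = np.random.default_rng(11)
        # construct raw E-values whose counts follow count = 2 * E^0.5
        raws = []
        for _ in range(200):
            u = rng.uniform(size=500)
            # P(E <= x) = (2/500) x^0.5 for x in [0, ~]; invert the cdf
            raws.append((500.0 / 2.0 * u) ** 2.0)
        exponent, scale = fit_evalue_correction(raws)
        assert exponent == pytest.approx(0.5, abs=0.05)
        assert scale == pytest.approx(2.0, rel=0.25)


class TestGammaMixtures:
    def test_single_gamma_recovery(self):
        rng = np.random.default_rng(0)
        x = rng.gamma(shape=3.0, scale=2.0, size=4000)
        mix = fit_gamma_mixture(x, seed=0)
        assert mix.mean() == pytest.approx(6.0, rel=0.05)
        # the fitted density reproduces the generating gamma: EM may split
        # the mass over two overlapping components, but the resulting
        # density must still match the truth closely
        from scipy.stats import gamma as gamma_dist
        grid = np.linspace(0.1, 25, 300)
        truth = gamma_dist.pdf(grid, 3.0, scale=2.0)
        assert np.abs(mix.pdf(grid) - truth).max() < 0.05 * truth.max()

    def test_two_component_fit_converges(self):
        from foldscan.calibration import _fit_two_gamma
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.gamma(2.0, 1.0, 500), rng.gamma(8.0, 1.5, 500)])
        mix, ll = _fit_two_gamma(x, np.random.default_rng(0))
        assert np.isfinite(ll)
        assert mix.mean() == pytest.approx(x.mean(), rel=0.1)

    def test_fits_deterministic(self):
        rng = np.random.default_rng(2)
        x = rng.gamma(4.0, 1.0, 800)
        m1 = fit_gamma_mixture(x, seed=3)
        m2 = fit_gamma_mixture(x, seed=3)
        assert m1 == m2

    def test_nonpositive_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma_mixture(np.array([1.0, -0.5, 2.0]))


class TestPTp:
    def _mixtures(self, prior=0.5):
        tp = GammaMixture(0.6, 9.0, 0.25, 20.0, 0.4)   # high scores
        fp = GammaMixture(0.7, 2.0, 0.25, 4.0, 0.35)   # low scores
        return GammaMixturePair(tp=tp, fp=fp, prior_tp=prior)

    def test_equal_density_point_gives_half(self):
        mixtures = self._mixtures(prior=0.5)

        def diff(s):
            return (mixtures.prior_tp * mixtures.tp.pdf(s)
                    - (1 - mixtures.prior_tp) * mixtures.fp.pdf(s))
        crossing = brentq(diff, 5.0, 60.0)
        assert p_tp(crossing, mixtures) == pytest.approx(0.5, abs=1e-9)

    def test_monotone_tail_approaches_one(self):
        mixtures = self._mixtures()
        values = [p_tp(s, mixtures) for s in (60, 90, 120)]
        assert values[0] < values[-1] or values[0] > 0.99
        assert values[-1] > 0.99

    def test_zero_prior_gives_zero(self):
        mixtures = self._mixtures(prior=0.0)
        assert p_tp(30.0, mixtures) == 0.0
        assert p_tp(100.0, mixtures) == 0.0


def test_em_loglik_trajectory_nondecreasing():
    """EM's defining property, checked on the actual update loop."""
    from scipy.stats import gamma as gamma_dist
    from foldscan.calibration import _gamma_mle
    rng = np.random.default_rng(5)
    x = np.concatenate([rng.gamma(2.0, 1.0, 400), rng.gamma(10.0, 1.2, 400)])
    weight = 0.5
    comps = [_gamma_mle(x[x < np.median(x)], np.ones((x < np.median(x)).sum())),
             _gamma_mle(x[x >= np.median(x)], np.ones((x >= np.median(x)).sum()))]
    lls = []
    for _ in range(40):
        p1 = weight * gamma_dist.pdf(x, comps[0][0], scale=1 / comps[0][1])
        p2 = (1 - weight) * gamma_dist.pdf(x, comps[1][0], scale=1 / comps[1][1])
        total = p1 + p2 + 1e-300
        lls.append(np.log(total).sum())
        r1 = p1 / total
        weight = float(np.clip(r1.mean(), 1e-4, 1 - 1e-4))
        comps = [_gamma_mle(x, r1 + 1e-12), _gamma_mle(x, 1 - r1 + 1e-12)]
    diffs = np.diff(lls)
    assert (diffs >= -1e-6).all()
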