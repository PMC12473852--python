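"""Detection: slot windows, Gaussian symbol model, DER and demodulation."""

import itertools
import math

import numpy as np
import pytest

from phytomc import (
    AbsorbedStats,
    ChannelParams,
    ConfigurationError,
    DEMODULATION_ERROR,
    MoleculeSpec,
    NoiseSpec,
    SlotScheme,
    StressAlphabet,
    demodulate,
    der,
    gaussian_symbol_model,
    hit_probability,
    noise_from_snr,
    peak_time,
    qfunc,
    slot_hit_prob,
    symbol_moments,
)


class TestSlotHitProb:
    def test_vanishing_window(self, fast_channel):
        assert slot_hit_prob(1, 1, SlotScheme(T_s=1e-9), fast_channel) < 1e-8

    def test_causality_rejected(self, fast_channel, scheme):
        with pytest.raises(ValueError):
            slot_hit_prob(1, 2, scheme, fast_channel)

    def test_first_window_clamped_at_zero(self, fast_channel, scheme):
        # t_peak ~ 0.33 < T_s/2 = 1, so window 1 is [0, t_peak + 1]
        t_pk = peak_time(fast_channel)
        q1 = slot_hit_prob(1, 1, scheme, fast_channel)
        assert q1 == pytest.approx(hit_probability(t_pk + 1.0, fast_channel), rel=1e-9)

    def test_telescoping_sum(self, fast_channel, scheme):
        # contiguous windows: sum of q over slots = F(top of last) - F(bottom of first)
        K = 4
        total = sum(slot_hit_prob(k, 1, scheme, fast_channel) for k in range(1, K + 1))
        t_pk = peak_time(fast_channel)
        lo, _ = scheme.window(1, t_pk)
        _, hi = scheme.window(K, t_pk)
        expected = hit_probability(hi, fast_channel) - hit_probability(lo, fast_channel)
        assert total == pytest.approx(expected, abs=1e-9)
        assert total <= fast_channel.R / (fast_channel.R + fast_channel.d) + 1e-9

    def test_elapsed_time_indexing(self, fast_channel, scheme):
        # emission at slot lambda observed at slot k only depends on k - lambda
        assert slot_hit_prob(3, 2, scheme, fast_channel) == pytest.approx(
            slot_hit_prob(2, 1, scheme, fast_channel), rel=1e-12
        )


class TestNoiseFromSnr:
    def test_forced_values(self):
        ns = noise_from_snr(10.0, 500.0, 0.2)
        assert ns.sigma_n == pytest.approx(100.0 / math.sqrt(10.0))
        assert ns.mu_n == ns.sigma_n

    def test_unit_snr(self):
        ns = noise_from_snr(1.0, 500.0, 0.2)
        assert ns.sigma_n == pytest.approx(100.0)

    def test_noiseless_limit(self):
        ns = noise_from_snr(1e12, 500.0, 0.2)
        assert ns.sigma_n < 1e-3

    def test_nonpositive_snr_rejected(self):
        with pytest.raises(ConfigurationError):
            noise_from_snr(0.0, 500.0, 0.2)


class TestSymbolMoments:
    def test_binomial_moments_no_isi(self):
        mu, var, mu_hat, var_hat = symbol_moments(
            1000.0, [0.2], 0.5, NoiseSpec(0.0, 0.0)
        )
        assert mu == pytest.approx(200.0)
        assert var == pytest.approx(160.0)
        assert mu_hat == 0.0 and var_hat == 0.0

    def test_isi_terms_accumulate(self):
        mu, var, mu_hat, var_hat = symbol_moments(
            1000.0, [0.2, 0.1, 0.05], 0.5, NoiseSpec(3.0, 2.0)
        )
        assert mu_hat == pytest.approx(0.5 * 1000 * 0.15 + 3.0)
        assert var_hat == pytest.approx(0.5 * 1000 * (0.1 * 0.9 + 0.05 * 0.95) + 4.0)
        assert mu == pytest.approx(200.0 + mu_hat)
        assert var == pytest.approx(160.0 + var_hat)

    def test_invalid_q_rejected(self):
        with pytest.raises(ConfigurationError):
            symbol_moments(1000.0, [1.2], 0.5, NoiseSpec(0.0, 0.0))

    def test_empirical_moments_match(self, rng):
        """Direct sampling (binomial signal + coin*binomial ISI + normal noise)
        reproduces the closed-form moments within 3 standard errors."""
        M, q, p = 2000, [0.2, 0.08], 0.5
        noise = NoiseSpec(30.0, 12.0)
        n = 100_000
        samples = (
            rng.binomial(M, q[0], size=n)
            + (rng.random(n) < p) * rng.binomial(M, q[1], size=n)
            + rng.normal(noise.mu_n, noise.sigma_n, size=n)
        )
        mu, var, _, _ = symbol_moments(M, q, p, noise)
        # the closed form folds the transmit coin into the binomial moments, so
        # allow the mixture's extra variance p(1-p)(Mq)^2 on top of sampling error
        coin_var = p * (1 - p) * (M * q[1]) ** 2
        assert samples.mean() == pytest.approx(mu, abs=3 * samples.std() / math.sqrt(n))
        assert samples.var() == pytest.approx(var + coin_var, rel=0.05)


class TestGaussianSymbolModel:
    def test_absorbed_scaling(self, detection_setup):
        s = detection_setup
        mol = s["alphabet"][0]
        ch = s["channel_base"].replace(D=mol.D)
        noise = NoiseSpec(10.0, 5.0)
        _, abs1 = gaussian_symbol_model(5000.0, mol, s["scheme"], ch, s["leaf"], noise, 1)
        lp2 = s["leaf"].replace(phi=s["leaf"].phi / 2)  # doubles the scale factor
        _, abs2 = gaussian_symbol_model(5000.0, mol, s["scheme"], ch, lp2, noise, 1)
        assert abs2.mu == pytest.approx(2 * abs1.mu, rel=1e-9)
        assert abs2.var == pytest.approx(4 * abs1.var, rel=1e-9)

    def test_small_count_warns(self, detection_setup):
        s = detection_setup
        mol = s["alphabet"][0]
        ch = s["channel_base"].replace(D=mol.D)
        with pytest.warns(UserWarning, match="Gaussian approximation"):
            gaussian_symbol_model(10.0, mol, s["scheme"], ch, s["leaf"],
                                  NoiseSpec(0.0, 0.0), 1)

    def test_mismatched_diffusion_rejected(self, detection_setup):
        s = detection_setup
        mol = s["alphabet"][0]
        ch = s["channel_base"].replace(D=mol.D * 2)
        with pytest.raises(ConfigurationError):
            gaussian_symbol_model(5000.0, mol, s["scheme"], ch, s["leaf"],
                                  NoiseSpec(0.0, 0.0), 1)


def _stats(mu, var, mu_hat=0.0, var_hat=1e-12):
    return AbsorbedStats(mu=mu, var=var, mu_hat=mu_hat, var_hat=var_hat, scale=1.0)


class TestDer:
    def test_threshold_at_mean_gives_half(self):
        absorbed = {"b1": _stats(100.0, 25.0), "b2": _stats(0.0, 1e-12, 0.0, 1e-12)}
        res = der("b1", absorbed, {"b1": 100.0, "b2": 50.0})
        assert res.p_error == pytest.approx(0.5, abs=1e-9)

    def test_tail_limits(self):
        absorbed = {"b1": _stats(100.0, 25.0), "b2": _stats(0.0, 1e-12)}
        assert der("b1", absorbed, {"b1": 1e9, "b2": 50.0}).p_error == pytest.approx(1.0)
        assert der("b1", absorbed, {"b1": -1e9, "b2": 50.0}).p_error == pytest.approx(0.0)

    def test_degenerate_variance_is_a_step(self):
        absorbed = {"b1": AbsorbedStats(100.0, 0.0, 0.0, 0.0, 1.0),
                    "b2": AbsorbedStats(0.0, 0.0, 0.0, 0.0, 1.0)}
        assert der("b1", absorbed, {"b1": 100.0, "b2": 1.0}).p_error == 0.0
        assert der("b1", absorbed, {"b1": 100.001, "b2": 1.0}).p_error == 1.0

    def test_qfunc_basic_identities(self):
        assert qfunc(0.0) == pytest.approx(0.5)
        assert float(qfunc(3.0)) == pytest.approx(1.0 - 0.9986501, abs=1e-6)


class TestDemodulate:
    @pytest.fixture
    def two_mol(self):
        return StressAlphabet([
            MoleculeSpec("b1", D=0.007, threshold=1.0, stress="pest"),
            MoleculeSpec("b2", D=0.009, threshold=2.0, stress="heat"),
        ])

    def test_unique_detection(self, two_mol):
        assert demodulate({"b1": 1.1, "b2": 1.9}, two_mol) == "pest"
        assert demodulate({"b1": 0.9, "b2": 2.0}, two_mol) == "heat"

    def test_error_branches(self, two_mol):
        assert demodulate({"b1": 1.0, "b2": 2.0}, two_mol) == DEMODULATION_ERROR
        assert demodulate({"b1": 0.0, "b2": 0.0}, two_mol) == DEMODULATION_ERROR

    def test_missing_molecule_rejected(self, two_mol):
        with pytest.raises(ConfigurationError):
            demodulate({"b1": 1.0}, two_mol)

    @pytest.mark.parametrize("n", [2, 3, 4])
    def test_agrees_with_exhaustive_truth_table(self, n):
        mols = [
            MoleculeSpec(f"b{i}", D=0.005 + 0.001 * i, threshold=float(i + 1),
                         stress=f"s{i}")
            for i in range(n)
        ]
        alphabet = StressAlphabet(mols)
        for pattern in itertools.product([False, True], repeat=n):
            masses = {
                m.name: m.threshold + 0.5 if above else m.threshold - 0.5
                for m, above in zip(mols, pattern)
            }
            expected = (
                mols[pattern.index(True)].stress
                if sum(pattern) == 1
                else DEMODULATION_ERROR
            )
            assert demodulate(masses, alphabet) == expected
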