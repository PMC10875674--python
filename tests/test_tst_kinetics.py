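"""TST rate constants, Eckart tunneling, entropies and Arrhenius fits."""

import numpy as np
import pytest

from xylokin.constants import HC_K, H_PLANCK, K_B, R
from xylokin.synthetic_data import make_arrhenius_samples
from xylokin.tst_kinetics import (
    ArrheniusParams,
    ChannelError,
    DEFAULT_FIT_GRID,
    ReactionChannel,
    StationaryPoint,
    arrhenius_eval,
    arrhenius_fit,
    eckart_kappa,
    eyring_rate,
    load_stationary_points,
    qh_entropy,
    rrho_partition,
    scaled_zpe,
    tst_rate,
    vibrational_factor,
)


def make_point(name="sp", freqs=(1000.0, 1500.0, 2000.0), **kw):
    defaults = dict(
        frequencies=freqs,
        rot_constants=(1.0, 0.5, 0.3),
        mass=150.0,
        freq_scale=1.0,
    )
    defaults.update(kw)
    return StationaryPoint(name=name, **defaults)


class TestScaledZpe:
    def test_single_mode(self):
        # 0.5*h*c*1000 cm^-1 * N_A = 5.9813 kJ/mol
        assert scaled_zpe([1000.0], 1.0) == pytest.approx(5.98133, abs=1e-4)

    def test_empty(self):
        assert scaled_zpe([]) == 0.0

    def test_scale_linearity(self):
        freqs = [500.0, 1200.0, 3000.0]
        assert scaled_zpe(freqs, 0.970) == pytest.approx(
            0.970 * scaled_zpe(freqs, 1.0), rel=1e-14
        )


class TestRrhoPartition:
    def test_vibrational_factor_low_temperature_limit(self):
        # ZPE-referenced: each mode's factor tends to 1 as T -> 0+.
        assert vibrational_factor(1000.0, 10.0) == pytest.approx(1.0, abs=1e-10)

    def test_vibrational_factor_closed_form(self):
        # 1/(1 - exp(-h*c*1000cm^-1/(k_B*673.15 K)))
        x = HC_K * 1000.0 / 673.15
        assert vibrational_factor(1000.0, 673.15) == pytest.approx(
            1.0 / (1.0 - np.exp(-x)), rel=1e-12
        )
        assert vibrational_factor(1000.0, 673.15) == pytest.approx(1.13374, abs=1e-5)

    def test_symmetry_number_not_folded_in(self):
        a = make_point(sigma_ext=1)
        b = make_point(sigma_ext=2)
        assert rrho_partition(a, 673.15) == rrho_partition(b, 673.15)

    def test_vibrational_part_is_mode_product(self):
        sp = make_point(freq_scale=0.970)
        empty = make_point(freqs=())
        T = 673.15
        product = np.prod(
            [vibrational_factor(nu, T, 0.970) for nu in sp.frequencies]
        )
        assert rrho_partition(sp, T) / rrho_partition(empty, T) == pytest.approx(
            product, rel=1e-12
        )


class TestQhEntropy:
    def test_omega0_zero_is_pure_rrho(self):
        sp = make_point(freqs=(30.0, 300.0, 1200.0))
        s_qh = qh_entropy(sp, 298.15, omega0=0.0)
        # Independent harmonic-oscillator sum for the vibrational part.
        theta = HC_K * np.asarray(sp.frequencies) * sp.freq_scale
        x = theta / 298.15
        s_vib = R * np.sum(x / (np.exp(x) - 1.0) - np.log(1.0 - np.exp(-x)))
        s_rigid = qh_entropy(make_point(freqs=()), 298.15)
        assert s_qh == pytest.approx(s_rigid + s_vib, rel=1e-10)

    def test_high_frequency_limit_matches_rrho(self):
        sp = make_point(freqs=(800.0, 1200.0, 2500.0))  # all >> omega0
        s_qh = qh_entropy(sp, 298.15, omega0=100.0)
        s_ho = qh_entropy(sp, 298.15, omega0=0.0)
        assert s_qh == pytest.approx(s_ho, rel=1e-3)

    def test_low_frequency_mode_capped_below_harmonic(self):
        # A 20 cm^-1 torsion's harmonic entropy diverges ~ -ln(nu); the
        # free-rotor interpolation caps it.
        lo = make_point(freqs=(20.0,), freq_scale=1.0)
        s_damped = qh_entropy(lo, 298.15, omega0=100.0)
        s_harmonic = qh_entropy(lo, 298.15, omega0=0.0)
        assert s_damped < s_harmonic


class TestEckartKappa:
    def test_classical_limit_small_imaginary_frequency(self):
        assert eckart_kappa(40.0, 40.0, 1e-3, 300.0) == pytest.approx(1.0, abs=1e-6)

    def test_high_temperature_limit_from_above(self):
        kappas = [eckart_kappa(40.0, 40.0, 1000.0, T) for T in (300, 600, 1200, 5000)]
        assert all(k >= 1.0 for k in kappas)
        assert np.all(np.diff(kappas) < 0)
        assert kappas[-1] == pytest.approx(1.0, abs=0.01)

    @pytest.mark.parametrize(
        "nu, T",
        [(300.0, 300.0), (1000.0, 600.0)],
    )
    def test_mild_tunneling_matches_wigner(self, nu, T):
        """Wigner's leading-order estimate holds below ~3 quanta of u*."""
        wigner = 1.0 + (HC_K * nu / T) ** 2 / 24.0
        kappa = eckart_kappa(40.0, 40.0, nu, T)
        assert kappa == pytest.approx(wigner, rel=0.15)

    def test_deep_tunneling_exceeds_wigner(self):
        # u* = 4.8 quanta: the truncated Wigner expansion underestimates.
        wigner = 1.0 + (HC_K * 1000.0 / 300.0) ** 2 / 24.0
        assert eckart_kappa(40.0, 40.0, 1000.0, 300.0) > wigner

    def test_packaged_channels_kappa_above_unity_and_decreasing(self, barrier_table):
        # The published tables carry no imaginary frequencies; a
        # representative 1000 cm^-1 synthetic value probes the bounds.
        for rid in ("R1", "R4", "R5"):
            row = barrier_table.loc[rid]
            kappas = [
                eckart_kappa(row["dh0_f"], row["dh0_r"], 1000.0, T)
                for T in np.linspace(300.0, 1000.0, 8)
            ]
            assert all(k >= 1.0 for k in kappas)
            assert np.all(np.diff(kappas) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            eckart_kappa(-1.0, 40.0, 1000.0, 300.0)
        with pytest.raises(ValueError):
            eckart_kappa(40.0, 40.0, 0.0, 300.0)


class TestTstRate:
    def test_identity_case_gives_kbt_over_h(self):
        sp = make_point()
        ts = make_point(name="ts", imaginary_freq=800.0)
        channel = ReactionChannel(reactants=[sp], ts=ts, E0=0.0, E0_reverse=0.0)
        k = tst_rate(channel, 673.15, tunneling=False)
        assert k == pytest.approx(K_B * 673.15 / H_PLANCK, rel=1e-12)
        assert k == pytest.approx(1.4025e13, rel=1e-3)

    def test_enantiomer_ratio_linearity(self):
        sp = make_point()
        ts1 = make_point(name="ts", imaginary_freq=800.0, m_enantiomers=1)
        ts2 = make_point(name="ts", imaginary_freq=800.0, m_enantiomers=2)
        c1 = ReactionChannel(reactants=[sp], ts=ts1, E0=100.0, E0_reverse=80.0)
        c2 = ReactionChannel(reactants=[sp], ts=ts2, E0=100.0, E0_reverse=80.0)
        assert tst_rate(c2, 673.15) == pytest.approx(
            2.0 * tst_rate(c1, 673.15), rel=1e-12
        )

    def test_missing_imaginary_frequency_raises(self):
        sp = make_point()
        not_ts = make_point(name="min2")
        channel = ReactionChannel(reactants=[sp], ts=not_ts, E0=100.0, E0_reverse=80.0)
        with pytest.raises(ChannelError):
            tst_rate(channel, 673.15)

    def test_reduces_to_eyring_for_unit_partition_ratio(self):
        """With Z_ts = Z and E0 = dG_act the rate is the Eyring closed form."""
        sp = make_point()
        ts = make_point(name="ts", imaginary_freq=800.0)
        channel = ReactionChannel(reactants=[sp], ts=ts, E0=191.2, E0_reverse=179.1)
        k = tst_rate(channel, 673.15, tunneling=False)
        assert k == pytest.approx(eyring_rate(191.2, 673.15), rel=1e-12)
        assert k == pytest.approx(2.04e-2, rel=5e-3)


class TestEyringRate:
    def test_ring_opening_barrier(self):
        assert eyring_rate(191.2, 673.15) == pytest.approx(2.0447e-2, rel=1e-3)

    def test_zero_barrier(self):
        assert eyring_rate(0.0, 673.15) == pytest.approx(
            K_B * 673.15 / H_PLANCK, rel=1e-12
        )

    def test_cc_fission_barrier(self):
        assert eyring_rate(153.2, 673.15) == pytest.approx(1.8166e1, rel=1e-3)


class TestArrhenius:
    def test_noiseless_recovery_to_six_figures(self):
        k = make_arrhenius_samples(2.53e12, 181.8, DEFAULT_FIT_GRID)
        p = arrhenius_fit(DEFAULT_FIT_GRID, k)
        assert p.A == pytest.approx(2.53e12, rel=1e-6)
        assert p.Ea == pytest.approx(181.8, rel=1e-6)
        assert p.fit_rss < 1e-20

    def test_noisy_recovery_monte_carlo(self):
        """With 5% log-normal noise Ea is recovered within 2 kJ/mol."""
        errors = []
        for seed in range(100):
            k = make_arrhenius_samples(
                2.53e12, 181.8, DEFAULT_FIT_GRID, sigma_ln=0.05, seed=seed
            )
            p = arrhenius_fit(DEFAULT_FIT_GRID, k)
            errors.append(p.Ea - 181.8)
        errors = np.asarray(errors)
        assert np.max(np.abs(errors)) < 2.0
        assert abs(np.mean(errors)) < 0.5  # unbiased in ln-space

    def test_degenerate_fit_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            arrhenius_fit([300.0, 400.0], [1.0, 2.0])

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            arrhenius_fit([300.0, 400.0, 500.0], [1.0, 0.0, 2.0])

    @pytest.mark.parametrize(
        "T, expected, rel",
        [(673.15, 1.9779e-2, 1e-3), (773.15, 1.3207, 1e-3)],
    )
    def test_ring_opening_evaluation(self, T, expected, rel):
        p = ArrheniusParams(A=2.53e12, Ea=181.8)
        assert arrhenius_eval(p, T) == pytest.approx(expected, rel=rel)

    def test_zero_activation_energy(self):
        p = ArrheniusParams(A=7.0, Ea=0.0)
        for T in (300.0, 700.0, 1100.0):
            assert arrhenius_eval(p, T) == 7.0


class TestStationaryPointIO:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "points.yaml"
        path.write_text(
            "# frequencies and rot_constants in cm^-1, mass in amu,\n"
            "# energies in kJ/mol\n"
            "reactant:\n"
            "  frequencies: [100.0, 500.0, 1500.0]\n"
            "  rot_constants: [1.0, 0.5, 0.3]\n"
            "  mass: 150.1\n"
            "  sigma_ext: 1\n"
            "ts:\n"
            "  frequencies: [120.0, 480.0]\n"
            "  rot_constants: [0.9, 0.45, 0.28]\n"
            "  mass: 150.1\n"
            "  imaginary_freq: 1250.0\n"
        )
        points = load_stationary_points(path)
        assert set(points) == {"reactant", "ts"}
        assert not points["reactant"].is_ts
        assert points["ts"].is_ts
        assert points["ts"].imaginary_freq == 1250.0

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            make_point(freqs=(-10.0, 500.0))
        with pytest.raises(ValueError):
            make_point(sigma_ext=0)
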