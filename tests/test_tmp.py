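"""Gabor dictionary, multichannel atom fitting, reference atoms, correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photodrive import tmp
from photodrive.preproc import AveragedBlock


def naive_oracle(window, dictionary):
    """Independent exhaustive search: per-atom least-squares projection.

    Re-implements the selection criterion with plain per-atom loops and
    ``np.linalg.lstsq``, sharing no code path with ``fit_atom``.
    """
    x = np.atleast_2d(window)
    best = (-1.0, None)
    for i in range(dictionary.n_atoms):
        basis = np.vstack([dictionary.cos_part[i], dictionary.sin_part[i]]).T
        total = 0.0
        for c in range(x.shape[0]):
            coef, _, rank, _ = np.linalg.lstsq(basis, x[c], rcond=None)
            proj = basis @ coef
            total += float(proj @ proj)
        if total > best[0] + 1e-12:
            best = (total, i)
    return best[1], best[0]


@pytest.fixture(scope="module")
def dictionary():
    return tmp.build_dictionary(64, 1000.0)


class TestDictionary:
    def test_atoms_are_unit_norm(self, dictionary):
        norms = np.sqrt(
            (dictionary.cos_part**2).sum(axis=1)
            + (dictionary.sin_part**2).sum(axis=1)
        )
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_modulation_grid_covers_10_hz(self):
        dic = tmp.build_dictionary(125, 1000.0)
        assert np.min(np.abs(dic.modulations - 2 * np.pi * 10 / 1000.0)) <= dic.mod_step

    def test_atom_count_is_grid_product(self, dictionary):
        n_su = sum(
            len(range(0, dictionary.window_len, max(1, int(s) // 4)))
            for s in dictionary.scales
        )
        assert dictionary.n_atoms == n_su * len(dictionary.modulations)

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            tmp.build_dictionary(4, 1000.0)


class TestFitAtom:
    def test_planted_dictionary_atom_recovered_exactly(self, dictionary):
        rng = np.random.default_rng(0)
        for _ in range(10):
            i = int(rng.integers(dictionary.n_atoms))
            s, u, xi = dictionary.params[i]
            planted = tmp.TMPAtom(
                s=s, u=u, xi=xi,
                amps=rng.uniform(0.5, 2.0, 4),
                phases=rng.uniform(-np.pi + 0.1, np.pi - 0.1, 4),
                window_len=dictionary.window_len,
            )
            fit = tmp.fit_atom(tmp.reconstruct(planted), dictionary)
            assert (fit.s, fit.u, fit.xi) == (s, u, xi)
            np.testing.assert_allclose(fit.amps, planted.amps, atol=1e-6)
            np.testing.assert_allclose(fit.phases, planted.phases, atol=1e-6)

    def test_matches_exhaustive_oracle_on_random_windows(self):
        dic = tmp.build_dictionary(32, 1000.0)
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.standard_normal((4, 32))
            fit = tmp.fit_atom(x, dic)
            idx, crit = naive_oracle(x, dic)
            s, u, xi = dic.params[idx]
            assert (fit.s, fit.u, fit.xi) == (s, u, xi)
            assert fit.criterion == pytest.approx(crit, abs=1e-9)

    def test_sine_modulation_recovered_on_125ms_window(self):
        f0, fs, n = 10.0, 1000.0, 125
        dic = tmp.build_dictionary(n, fs, min_scale=n // 2)
        t = np.arange(n) / fs
        for phase in (0.0, 1.0, 2.5):
            fit = tmp.fit_atom(np.sin(2 * np.pi * f0 * t + phase)[None, :], dic)
            step_hz = dic.mod_step * fs / (2 * np.pi)
            assert abs(fit.freq_hz(fs) - f0) <= step_hz + 1e-9

    def test_amplitude_ratio_preserved(self, dictionary):
        t = np.arange(dictionary.window_len) / 1000.0
        wave = np.sin(2 * np.pi * 15 * t) * np.hanning(dictionary.window_len)
        fit = tmp.fit_atom(np.vstack([wave, 2 * wave]), dictionary)
        assert fit.amps[1] / fit.amps[0] == pytest.approx(2.0, rel=1e-6)

    def test_all_zero_window_flagged_degenerate(self, dictionary):
        fit = tmp.fit_atom(np.zeros((3, dictionary.window_len)), dictionary)
        assert fit.degenerate
        np.testing.assert_allclose(fit.amps, 0.0)

    def test_energy_bound(self, dictionary):
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.standard_normal((3, dictionary.window_len))
            fit = tmp.fit_atom(x, dictionary)
            assert (fit.amps**2).sum() <= (x**2).sum() + 1e-9

    def test_planted_atom_modulation_recovered_under_noise(self):
        res = __import__("photodrive.experiments", fromlist=["x"]).planted_atom_recovery(
            40, snr=3.0, seed=0, window_len=64, n_channels=8
        )
        assert res["rate"] >= 0.9


class TestAtomSequence:
    def _block(self, signal_fn, n_channels=3, period=100, n_flash=6, post=10):
        fs = 1000.0
        onsets = 500 + period * np.arange(n_flash)
        n = int(onsets[-1] + period * (post + 2) + 500)
        t = np.arange(n) / fs
        data = np.vstack([signal_fn(t) for _ in range(n_channels)])
        return AveragedBlock(
            multiplier=1.0, stim_freq_hz=fs / period, data=data, sfreq_hz=fs,
            flash_onset_samples=onsets, stim_end_sample=int(onsets[-1] + period),
            n_trains_averaged=30,
        )

    def test_sequence_length_is_flashes_plus_ten(self):
        blk = self._block(lambda t: np.sin(2 * np.pi * 10 * t))
        atoms = tmp.atom_sequence(blk)
        assert len(atoms) == 6 + 10

    def test_stationary_sinusoid_gives_constant_modulation(self):
        blk = self._block(lambda t: np.sin(2 * np.pi * 10 * t))
        atoms = tmp.atom_sequence(blk)
        xis = np.array([a.xi for a in atoms])
        dic_step = 2 * np.pi * 0.5 / 1000.0
        assert np.ptp(xis) <= dic_step + 1e-12

    def test_zero_post_signal_gives_near_zero_post_amplitudes(self):
        def sig(t):
            out = np.sin(2 * np.pi * 10 * t)
            out[t > 1.1] = 0.0  # stimulation ends at 1.1 s
            return out

        blk = self._block(sig)
        atoms = tmp.atom_sequence(blk)
        stim_amp = np.mean([a.amps.mean() for a in atoms[:6]])
        post_amp = np.mean([a.amps.mean() for a in atoms[-8:]])
        assert post_amp < 0.05 * stim_amp

    def test_insufficient_post_window_rejected(self):
        blk = self._block(lambda t: np.sin(2 * np.pi * 10 * t), post=10)
        blk.data = blk.data[:, : blk.stim_end_sample + 100]
        with pytest.raises(ValueError):
            tmp.atom_sequence(blk)


class TestReferenceAtom:
    def _atom(self, amps, phases, s=32.0, u=16.0, xi=0.06, n=64):
        return tmp.TMPAtom(s=s, u=u, xi=xi, amps=np.asarray(amps, float),
                           phases=np.asarray(phases, float), window_len=n)

    def test_identical_atoms_average_to_themselves(self):
        atoms = [self._atom([1.0, 2.0], [0.5, -0.5]) for _ in range(40)]
        ref = tmp.reference_atom(atoms)
        np.testing.assert_allclose(ref.amps, [1.0, 2.0])
        np.testing.assert_allclose(ref.phases, [0.5, -0.5])
        assert (ref.s, ref.u, ref.xi) == (32.0, 16.0, 0.06)

    def test_phases_near_pi_average_circularly(self):
        a = self._atom([1.0], [np.pi - 0.1])
        b = self._atom([1.0], [-np.pi + 0.1])
        ref = tmp.reference_atom([a, b])
        assert abs(ref.phases[0]) == pytest.approx(np.pi, abs=1e-9)

    def test_alternating_amplitudes_average_arithmetically(self):
        atoms = [self._atom([1.0 if i % 2 == 0 else 3.0], [0.0]) for i in range(40)]
        assert tmp.reference_atom(atoms).amps[0] == pytest.approx(2.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tmp.reference_atom([])


class TestCorrelationSequence:
    def _atom(self, xi_hz, phase=0.0, s=48.0, u=32.0, n=64, amp=1.0):
        return tmp.TMPAtom(
            s=s, u=u, xi=2 * np.pi * xi_hz / 1000.0,
            amps=np.array([amp]), phases=np.array([phase]), window_len=n,
        )

    def test_identical_atom_scores_one(self):
        ref = self._atom(10.0)
        seq = tmp.correlation_sequence(ref, [ref] * 3)
        np.testing.assert_allclose(seq.coefficients, 1.0, atol=1e-9)

    def test_small_time_shift_absorbed_by_lag_search(self):
        ref = self._atom(10.0, u=32.0)
        shifted = self._atom(10.0, u=37.0)  # 5-sample shift
        seq = tmp.correlation_sequence(ref, [shifted], max_lag=63)
        assert seq.coefficients[0, 0] > 0.99

    def test_distant_modulation_scores_low(self):
        # Envelopes wide enough to hold several cycles of the 10 Hz atom;
        # the 2 Hz atom then shares almost no waveform structure with it.
        ref = self._atom(10.0, s=128.0, u=128.0, n=256)
        far = self._atom(2.0, s=128.0, u=128.0, n=256)
        seq = tmp.correlation_sequence(ref, [far])
        assert seq.coefficients[0, 0] < 0.3

    def test_zero_energy_channel_scores_zero(self):
        ref = self._atom(10.0)
        dead = self._atom(10.0, amp=0.0)
        seq = tmp.correlation_sequence(ref, [dead])
        assert seq.coefficients[0, 0] == 0.0

    def test_channel_count_mismatch_rejected(self):
        ref = self._atom(10.0)
        bad = tmp.TMPAtom(s=48.0, u=32.0, xi=0.06, amps=np.ones(2),
                          phases=np.zeros(2), window_len=64)
        with pytest.raises(ValueError):
            tmp.correlation_sequence(ref, [bad])

    @settings(max_examples=30, deadline=None)
    @given(
        xi1=st.floats(2.0, 30.0), xi2=st.floats(2.0, 30.0),
        ph1=st.floats(-3.1, 3.1), ph2=st.floats(-3.1, 3.1),
        s1=st.floats(12.0, 64.0), s2=st.floats(12.0, 64.0),
        u1=st.floats(0.0, 63.0), u2=st.floats(0.0, 63.0),
    )
    def test_coefficients_always_within_unit_interval(
        self, xi1, xi2, ph1, ph2, s1, s2, u1, u2
    ):
        ref = self._atom(xi1, phase=ph1, s=s1, u=u1)
        atom = self._atom(xi2, phase=ph2, s=s2, u=u2)
        seq = tmp.correlation_sequence(ref, [atom])
        assert np.all(seq.coefficients >= 0.0)
        assert np.all(seq.coefficients <= 1.0)


def test_atoms_serialize_to_tabular_frame():
    rng = np.random.default_rng(0)
    atoms = [
        tmp.TMPAtom(s=32.0, u=16.0, xi=0.06, amps=rng.uniform(0, 1, 2),
                    phases=rng.uniform(-np.pi, np.pi, 2), window_len=64)
        for _ in range(5)
    ]
    df = tmp.atoms_to_frame(atoms, 1000.0, ["chA", "chB"], subject="S01",
                            multiplier=1.0)
    assert len(df) == 5
    assert {"s", "u", "xi", "amp_chA", "phase_chB"} <= set(df.columns)
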