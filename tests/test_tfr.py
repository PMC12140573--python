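"""Morlet transform, log-normalization and portrait extraction."""

import numpy as np
import pytest
from scipy import stats

from oscportraits.elements import BandEpochSpec, element_columns
from oscportraits.tfr import (
    TFMap,
    WaveletConfig,
    morlet_transform,
    normalize_power,
    portraits_from_signals,
)

FS = 256.0


def _tone(freq, seconds=4.0, amp=1.0):
    t = np.arange(0.0, seconds, 1 / FS)
    return t, amp * np.sin(2 * np.pi * freq * t)


def test_tone_power_is_selective_and_matches_spectral_profile():
    """Response to a pure tone follows the wavelet's own Gaussian spectral
    profile, evaluated independently by quadrature of the kernel."""
    wc = WaveletConfig(fs=FS, freqs=np.arange(4.0, 30.5, 0.5))
    t, x = _tone(10.0)
    m = morlet_transform(x, wc)
    interior = ~m.edge_mask
    measured = np.array(
        [m.power[interior[:, j], j].mean() for j in range(wc.freqs.size)]
    )
    expected = []
    for f0 in wc.freqs:
        w = wc.kernel(f0)
        tk = (np.arange(w.size) - w.size // 2) / FS
        # |w-hat(f_s)|^2 / 4: analytic response of |conv|^2 to a unit sine
        resp = np.abs(np.vdot(w, np.exp(2j * np.pi * 10.0 * tk))) ** 2 / 4.0
        expected.append(resp)
    expected = np.asarray(expected)
    # compare over the meaningful part of the profile; far tails are
    # dominated by finite-window leakage rather than the kernel shape
    core = expected > 1e-6 * expected.max()
    np.testing.assert_allclose(measured[core], expected[core], rtol=3e-2)
    i10 = np.argmin(np.abs(wc.freqs - 10.0))
    i20 = np.argmin(np.abs(wc.freqs - 20.0))
    assert measured[i10] / measured[i20] > 100


def test_zero_signal_and_quadratic_amplitude_scaling():
    wc = WaveletConfig(fs=FS, freqs=np.arange(4.0, 20.5, 1.0))
    t, x = _tone(10.0)
    zero = morlet_transform(np.zeros_like(x), wc)
    assert np.allclose(zero.power, 0.0)
    p1 = morlet_transform(x, wc).power
    p2 = morlet_transform(2.0 * x, wc).power
    np.testing.assert_allclose(p2, 4.0 * p1, rtol=1e-10, atol=1e-20)


def test_short_signal_rejected_with_minimum_length():
    wc = WaveletConfig(fs=FS)
    with pytest.raises(ValueError, match=str(wc.min_samples())):
        morlet_transform(np.zeros(wc.min_samples() - 1), wc)


def test_matches_mne_morlet_up_to_constant_per_frequency():
    mne_tf = pytest.importorskip("mne.time_frequency")
    rng = np.random.default_rng(0)
    t, x = _tone(10.0)
    x = x + 0.3 * rng.normal(size=x.size)
    wc = WaveletConfig(fs=FS, freqs=np.arange(4.0, 30.5, 0.5))
    ours = morlet_transform(x, wc)
    theirs = mne_tf.tfr_array_morlet(
        x[None, None, :], FS, wc.freqs, n_cycles=wc.f0_over_sigma_f, output="power"
    )[0, 0]
    interior = slice(300, x.size - 300)
    diff = np.log(ours.power[interior].T) - np.log(theirs[:, interior])
    # identical kernel family: offsets constant per frequency
    assert diff.std(axis=1).max() < 1e-3


def _flat_map(value, n_t=600, freqs=None, log_normalized=True):
    freqs = np.arange(2.0, 60.5, 0.5) if freqs is None else freqs
    times = -1.5 + np.arange(n_t) / FS
    return TFMap(
        trial_id=0,
        region="IC1",
        times=times,
        freqs=freqs,
        power=np.full((n_t, freqs.size), float(value)),
        onset=0.0,
        offset=0.5,
        log_normalized=log_normalized,
    )


def test_normalization_centers_and_ignores_global_scale():
    rng = np.random.default_rng(1)
    maps = []
    for i in range(5):
        m = _flat_map(1.0, log_normalized=False)
        m.power = np.exp(rng.normal(size=m.power.shape))
        m.trial_id = i
        maps.append(m)
    normed = normalize_power(maps)
    pooled = np.vstack([m.power for m in normed])
    np.testing.assert_allclose(pooled.mean(axis=0), 0.0, atol=1e-12)
    # global multiplicative constant cancels
    scaled = []
    for m in maps:
        m2 = _flat_map(1.0, log_normalized=False)
        m2.power = 7.3 * m.power
        m2.trial_id = m.trial_id
        scaled.append(m2)
    normed2 = normalize_power(scaled)
    for a, b in zip(normed, normed2):
        np.testing.assert_allclose(a.power, b.power, atol=1e-12)


def test_normalization_shift_of_one_trial_is_one_minus_one_over_n():
    rng = np.random.default_rng(2)
    maps = []
    for i in range(4):
        m = _flat_map(1.0, log_normalized=False)
        m.power = np.exp(rng.normal(size=m.power.shape))
        m.trial_id = i
        maps.append(m)
    ref = normalize_power(maps)
    boosted = []
    for m in maps:
        m2 = _flat_map(1.0, log_normalized=False)
        m2.power = m.power * (np.e if m.trial_id == 0 else 1.0)
        m2.trial_id = m.trial_id
        boosted.append(m2)
    out = normalize_power(boosted)
    shift = out[0].power - ref[0].power
    np.testing.assert_allclose(shift, 1.0 - 1.0 / 4.0, atol=1e-12)


def test_nonpositive_power_rejected():
    m = _flat_map(0.0, log_normalized=False)
    with pytest.raises(ValueError, match="nonpositive power"):
        normalize_power([m])


def test_extract_constant_and_indicator_maps():
    from oscportraits.tfr import extract_portrait

    spec = BandEpochSpec()
    m = _flat_map(3.25)
    cells = extract_portrait(m, spec)
    assert len(cells) == 12
    assert all(v == pytest.approx(3.25) for v in cells.values())

    m = _flat_map(0.0)
    tmask = spec.epoch_mask(m.times, "Pre", m.onset, m.offset)
    fmask = spec.band_mask(m.freqs, "theta")
    m.power[np.ix_(tmask, fmask)] = 1.0
    cells = extract_portrait(m, spec)
    # brute-force mean over the explicit index sets
    expected = m.power[np.ix_(tmask, fmask)].mean()
    assert cells[("Pre", "theta")] == pytest.approx(expected) == 1.0
    others = [v for k, v in cells.items() if k != ("Pre", "theta")]
    assert np.allclose(others, 0.0)


def test_extract_rejects_bad_epochs():
    from oscportraits.tfr import extract_portrait

    m = _flat_map(1.0)
    m.offset = -1.0
    with pytest.raises(ValueError, match="precedes"):
        extract_portrait(m)


def test_extraction_recovers_generating_elements(extraction_signals):
    """End-to-end: synthetic signals -> portraits correlate with the
    element values that generated them (r > 0.7 per element)."""
    _, signals = extraction_signals
    table = portraits_from_signals(signals)
    rs = [
        stats.pearsonr(signals.table[c], table[c])[0] for c in element_columns()
    ]
    assert min(rs) > 0.7
    assert np.mean(rs) > 0.85


def test_wavelet_power_scales_linearly_with_noise_variance():
    """Total raw power of white noise grows linearly in signal variance."""
    wc = WaveletConfig(fs=FS, freqs=np.arange(4.0, 40.5, 2.0))
    rng = np.random.default_rng(3)
    base = rng.normal(size=int(4 * FS))
    variances = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    totals = []
    for v in variances:
        m = morlet_transform(np.sqrt(v) * base, wc)
        totals.append(m.power.sum())
    r = stats.pearsonr(variances, totals)[0]
    assert r**2 > 0.99
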