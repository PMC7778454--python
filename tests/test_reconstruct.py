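"""Preprocessing, the three reconstruction schemes, and the spatial priors."""

import numpy as np
import pytest

from eegdot.reconstruct import (
    PreprocessingError,
    PriorWeights,
    ReconstructionMap,
    build_dot_prior,
    butterworth_lowpass,
    mbll_hbo,
    preprocess_dot,
    preprocess_eeg,
    projection_prior,
    reconstruct_dot,
    reconstruct_eeg,
    smoothness_kernel,
)
from eegdot.simulate import (
    BackgroundConfig,
    SNRConfig,
    generate_design,
    generate_recordings,
    simulate_sources,
)

NOISELESS = BackgroundConfig(0.0, 0.0, 0.0)
NO_SENSOR_NOISE = SNRConfig(eeg=np.inf, dot={750.0: np.inf, 850.0: np.inf})


def _fake_recordings(eeg=None, dod=None, fs_eeg=1000.0, fs_dod=10.0):
    import types

    return types.SimpleNamespace(eeg=eeg, dod=dod, fs_eeg=fs_eeg, fs_dod=fs_dod)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def test_trial_average_noise_reduction():
    """Averaging 100 trials of i.i.d. noise reduces its std ~10x."""
    rng = np.random.default_rng(0)
    design = generate_design()
    eeg = rng.normal(size=(8, design.n_samples_electrical))
    avg = preprocess_eeg(_fake_recordings(eeg=eeg), design)
    assert avg.shape == (8, design.trial_n_samples)
    ratio = avg.std() / eeg.std()
    assert abs(ratio - 0.1) < 0.015


def test_trial_average_single_trial_identity():
    design = generate_design(n_trials=1, block_duration=0.2)
    eeg = np.random.default_rng(1).normal(size=(4, design.n_samples_electrical))
    avg = preprocess_eeg(_fake_recordings(eeg=eeg), design)
    assert np.array_equal(avg, eeg[:, : design.trial_n_samples])


def test_trial_average_recovers_clean_periodic_signal():
    design = generate_design()
    t = np.arange(design.trial_n_samples) / design.fs_electrical
    template = np.sin(2 * np.pi * 20 * t)
    eeg = np.zeros((1, design.n_samples_electrical))
    for onset in design.trial_onsets:
        i = int(round(onset * design.fs_electrical))
        eeg[0, i : i + template.size] = template
    avg = preprocess_eeg(_fake_recordings(eeg=eeg), design)
    assert np.allclose(avg[0], template, atol=1e-12)


def test_trial_average_requires_complete_trial():
    design = generate_design()
    with pytest.raises(PreprocessingError):
        preprocess_eeg(_fake_recordings(eeg=np.zeros((2, 10))), design)


def test_lowpass_dc_gain_unity():
    x = np.full((3, 400), 2.5)
    assert np.allclose(butterworth_lowpass(x, fs=10.0), 2.5, atol=1e-9)


def test_lowpass_attenuation_matches_analytic_response():
    """Zero-phase order-2 Butterworth: amplitude scaled by the single-pass
    factor 1/sqrt(1+(f/fc)^4) applied twice."""
    fs = 100.0
    t = np.arange(int(200 * fs)) / fs
    for freq, tol in ((5.0, 0.05), (0.05, 0.01)):
        x = np.sin(2 * np.pi * freq * t)
        y = butterworth_lowpass(x, fs=fs, cutoff=1.0)
        mid = slice(len(t) // 4, 3 * len(t) // 4)  # steady state
        measured = np.abs(y[mid]).max()
        expected = 1.0 / (1.0 + (freq / 1.0) ** 4)
        if freq < 1.0:
            assert measured > 1.0 - tol
        else:
            assert abs(measured - expected) / expected < tol


def test_lowpass_rejects_low_sampling_rate():
    with pytest.raises(PreprocessingError):
        butterworth_lowpass(np.zeros(100), fs=1.5, cutoff=1.0)


def test_block_average_constant_input():
    design = generate_design()
    dod = np.full((6, design.n_samples_hemodynamic), 3.0)
    avg = preprocess_dot(_fake_recordings(dod=dod), design)
    assert np.allclose(avg, 3.0, atol=1e-9)


# ---------------------------------------------------------------------------
# EEG reconstruction
# ---------------------------------------------------------------------------


def test_eeg_only_localizes_within_point_spread(assets):
    """A noiseless single-voxel source is reconstructed with the map
    argmax within the cm-scale EEG point spread of the true voxel."""
    v = _voxel_under_patch(assets)
    y = assets.leadfield.matrix[:, v]
    rmap = reconstruct_eeg(y[:, None], assets.leadfield, assets.sources)
    err = np.linalg.norm(
        assets.sources.positions[np.argmax(np.abs(rmap.values))]
        - assets.sources.positions[v]
    )
    assert err < 25.0


def test_concentrated_prior_pins_the_source(assets):
    v = _voxel_under_patch(assets)
    y = assets.leadfield.matrix[:, v]
    q = np.full(assets.sources.n_voxels, 0.05)
    q[v] = 1.0
    prior = PriorWeights(q_diag=q, params={})
    rmap = reconstruct_eeg(y[:, None], assets.leadfield, assets.sources, prior=prior)
    assert np.argmax(np.abs(rmap.values)) == v


def test_all_zero_data_all_zero_map(assets):
    rmap = reconstruct_eeg(np.zeros((32, 2)), assets.leadfield, assets.sources)
    assert np.all(rmap.values == 0)


def test_uniform_prior_identical_to_eeg_only_path(assets):
    """Uniform PriorWeights must not diverge from the no-prior scheme."""
    v = _voxel_under_patch(assets)
    rng = np.random.default_rng(2)
    y = assets.leadfield.matrix[:, v] + 1e-6 * rng.normal(size=32)
    m1 = reconstruct_eeg(y[:, None], assets.leadfield, assets.sources)
    m2 = reconstruct_eeg(y[:, None], assets.leadfield, assets.sources,
                         prior=PriorWeights.uniform(assets.sources.n_voxels))
    assert np.max(np.abs(m1.values - m2.values)) < 1e-10


def _voxel_under_patch(assets):
    d = assets.sources.positions @ assets.frame.centre_dir
    return int(np.argmax(d))


# ---------------------------------------------------------------------------
# DOT reconstruction
# ---------------------------------------------------------------------------


def test_dot_localizes_single_spot(assets):
    """Noiseless single-spot dHbO increase: HbO map argmax within 10 mm."""
    from eegdot.scenarios import _spot_from_uv

    spot = _spot_from_uv(assets, (5.0, -5.0), "A")
    V = assets.sources.n_voxels
    x = np.zeros(2 * V)
    x[spot.voxel_ids] = 1.0
    x[V + spot.voxel_ids] = -1.0 / 3.0
    dod = assets.jacobian.matrix @ x
    hbo, hb = reconstruct_dot(dod, assets.jacobian, assets.sources)
    pos = assets.sources.positions
    err = np.linalg.norm(pos[np.argmax(np.abs(hbo.values))] - spot.center)
    assert err < 10.0


def test_dot_zero_data_zero_maps(assets):
    with pytest.warns(UserWarning):
        hbo, hb = reconstruct_dot(np.zeros(48), assets.jacobian, assets.sources)
    assert np.all(hbo.values == 0) and np.all(hb.values == 0)


def test_smoothness_kernel_identity_limit(assets):
    """sigma -> 0 reduces the smoothness prior to the identity and the
    reconstruction to the unsmoothed one."""
    G = smoothness_kernel(assets.sources, 1e-3)
    assert np.allclose(G, np.eye(assets.sources.n_voxels))
    from eegdot.scenarios import _spot_from_uv

    spot = _spot_from_uv(assets, (0.0, 0.0), "A")
    V = assets.sources.n_voxels
    x = np.zeros(2 * V)
    x[spot.voxel_ids] = 1.0
    dod = assets.jacobian.matrix @ x
    h1, _ = reconstruct_dot(dod, assets.jacobian, assets.sources)
    h2, _ = reconstruct_dot(dod, assets.jacobian, assets.sources,
                            smoothing_sigma=1e-3)
    assert np.max(np.abs(h1.values - h2.values)) < 1e-6


def test_dot_shape_error(assets):
    with pytest.raises(ValueError, match="channel-wavelength"):
        reconstruct_dot(np.zeros(47), assets.jacobian, assets.sources)


# ---------------------------------------------------------------------------
# priors
# ---------------------------------------------------------------------------


def test_prior_weight_closed_form(assets):
    """Baseline and maximum weights of the variance mapping
    q = 1 - exp(-(beta' + a)/b) at the default a=0.1, b=1."""
    pos = assets.sources.positions[:3]
    rmap = ReconstructionMap(values=np.array([0.0, 1.0, 0.05]), positions=pos,
                             normalized=True, modality="dot_hbo")
    pw = build_dot_prior(rmap, k=0.1, a=0.1, b=1.0)
    assert np.isclose(pw.q_diag[0], 1.0 - np.exp(-0.1))   # ~0.09516
    assert np.isclose(pw.q_diag[1], 1.0 - np.exp(-1.1))   # ~0.66713
    # sub-threshold amplitude is clipped to the baseline weight
    assert np.isclose(pw.q_diag[2], pw.q_diag[0])


def test_prior_weight_parameter_validation(assets):
    rmap = ReconstructionMap(values=np.array([0.0, 1.0]),
                             positions=np.zeros((2, 3)),
                             normalized=True, modality="dot_hbo")
    with pytest.raises(ValueError):
        build_dot_prior(rmap, b=0.0)
    with pytest.raises(ValueError):
        build_dot_prior(rmap, k=1.0)


def test_mbll_recovers_channel_concentrations(assets):
    """The MBLL inversion is the exact inverse of the extinction system it
    assumes."""
    J = assets.jacobian
    opt = assets.optodes
    dists = opt.channel_distances()
    rng = np.random.default_rng(3)
    hbo_true = rng.normal(size=J.n_channels)
    hb_true = -hbo_true / 3.0
    dod = np.empty(2 * J.n_channels)
    from eegdot.reconstruct import DEFAULT_DPF

    for i, wl in enumerate(J.wavelengths):
        eps = J.extinction_coeffs[wl]
        dod[i * J.n_channels : (i + 1) * J.n_channels] = (
            (eps["HbO"] * hbo_true + eps["Hb"] * hb_true)
            * DEFAULT_DPF[float(wl)] * dists
        )
    assert np.allclose(mbll_hbo(dod, opt, J), hbo_true, rtol=1e-10)


def test_projection_prior_peaks_at_active_channel(assets):
    """A single active channel yields a projection prior maximal near that
    channel's source-detector midpoint on the cortex."""
    J = assets.jacobian
    C = J.n_channels
    ch = 10
    dod = np.zeros(2 * C)
    from eegdot.reconstruct import DEFAULT_DPF

    dists = assets.optodes.channel_distances()
    for i, wl in enumerate(J.wavelengths):
        eps = J.extinction_coeffs[wl]
        dod[i * C + ch] = eps["HbO"] * DEFAULT_DPF[float(wl)] * dists[ch]
    pw, pmap = projection_prior(dod, assets.optodes, assets.head,
                                assets.sources, J)
    mid = assets.optodes.channel_midpoints()[ch]
    mid = mid / np.linalg.norm(mid) * assets.head.cortex_radius
    best = assets.sources.positions[np.argmax(np.abs(pmap.values))]
    assert np.linalg.norm(best - mid) < 10.0


def test_projection_prior_two_channel_quasi_symmetry(assets):
    """Two equally active channels produce near-equal prior amplitude at
    their two projected midpoints (symmetry up to grid discreteness)."""
    J = assets.jacobian
    C = J.n_channels
    from eegdot.reconstruct import DEFAULT_DPF
    from scipy.spatial.distance import cdist

    dists = assets.optodes.channel_distances()
    cha, chb = 0, C - 1
    dod = np.zeros(2 * C)
    for i, wl in enumerate(J.wavelengths):
        eps = J.extinction_coeffs[wl]
        for ch in (cha, chb):
            dod[i * C + ch] = eps["HbO"] * DEFAULT_DPF[float(wl)] * dists[ch]
    pw, pmap = projection_prior(dod, assets.optodes, assets.head,
                                assets.sources, J)
    mids = assets.optodes.channel_midpoints()[[cha, chb]]
    mids = mids / np.linalg.norm(mids, axis=1, keepdims=True) * 80.0
    near = np.argmin(cdist(mids, assets.sources.positions), axis=1)
    va, vb = np.abs(pmap.values[near])
    assert abs(va - vb) / max(va, vb) < 0.15
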