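"""Co-localised electrical and hemodynamic source activity and noisy
sensor recordings.

A block of stimulation contains a train of brief activation events; every
event drives, at the same cortical voxels, (i) a bell-shaped electrical
response at millisecond scale and (ii) a canonical hemodynamic response at
second scale.  The same impulse train is convolved with the two kernels,
which encodes the neurovascular-coupling assumption the joint
reconstruction relies on.  Gaussian background activity is added to every
voxel and Gaussian sensor noise to every channel at configured
signal-to-noise ratios (SNR = squared maximum clean amplitude over noise
variance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .forward import DOTJacobian, EEGLeadfield
from .phantom import SourceSpace

__all__ = [
    "StimulusDesign",
    "ActivationSpot",
    "Kernels",
    "SourceActivity",
    "Recordings",
    "BackgroundConfig",
    "SNRConfig",
    "DesignError",
    "generate_design",
    "simulate_sources",
    "generate_recordings",
    "make_spot",
    "neural_kernel",
    "hrf_kernel",
]


class DesignError(ValueError):
    """Raised when a stimulus design is internally inconsistent."""


@dataclass(frozen=True)
class StimulusDesign:
    """Block design: repeated trials, each with per-spot stimulus offsets.

    Defaults: a 30 s block whose first 20 s contain 100 trials at 200 ms
    spacing; within each trial spot A is stimulated at 0 ms and spot B
    50 ms later.
    """

    block_duration: float = 30.0
    n_trials: int = 100
    trial_spacing: float = 0.2
    within_trial_offsets: dict = field(default_factory=lambda: {"A": 0.0, "B": 0.05})
    fs_electrical: float = 1000.0
    fs_hemodynamic: float = 10.0

    def __post_init__(self):
        if self.block_duration <= 0 or self.trial_spacing <= 0:
            raise DesignError("durations must be positive")
        if self.fs_electrical <= 0 or self.fs_hemodynamic <= 0:
            raise DesignError("sampling rates must be positive")
        if self.n_trials < 0:
            raise DesignError("n_trials must be >= 0")
        if self.n_trials * self.trial_spacing > self.block_duration:
            raise DesignError("trials overflow the block")

    @property
    def trial_onsets(self) -> np.ndarray:
        return np.arange(self.n_trials) * self.trial_spacing

    def event_times(self, spot_label: str) -> np.ndarray:
        return self.trial_onsets + self.within_trial_offsets[spot_label]

    @property
    def n_samples_electrical(self) -> int:
        return int(round(self.block_duration * self.fs_electrical))

    @property
    def n_samples_hemodynamic(self) -> int:
        return int(round(self.block_duration * self.fs_hemodynamic))

    @property
    def trial_n_samples(self) -> int:
        return int(round(self.trial_spacing * self.fs_electrical))


def generate_design(**overrides) -> StimulusDesign:
    """Stimulus design with the default block structure, overridable."""
    return StimulusDesign(**overrides)


@dataclass(frozen=True)
class ActivationSpot:
    """~8 mm diameter cortical activation: all voxels within ``radius`` of
    the centre, plus the nearest voxel so the spot is never empty."""

    center: np.ndarray
    voxel_ids: np.ndarray
    label: str


def make_spot(sources: SourceSpace, center, label: str, radius: float = 4.0) -> ActivationSpot:
    center = np.asarray(center, float)
    d = cdist(center[None, :], sources.positions)[0]
    ids = np.flatnonzero(d <= radius)
    if ids.size == 0:
        ids = np.array([int(np.argmin(d))])
    return ActivationSpot(center=center, voxel_ids=ids, label=label)


def neural_kernel(fs: float, peak: float = 0.05, fwhm: float = 0.04) -> np.ndarray:
    """Unit-peak Gaussian bell; peaks ``peak`` seconds after the stimulus."""
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = np.arange(0.0, peak + 4.0 * sigma, 1.0 / fs)
    k = np.exp(-0.5 * ((t - peak) / sigma) ** 2)
    return k / k.max()


def hrf_kernel(fs: float, peak: float = 6.0, undershoot: float = 16.0,
               ratio: float = 1.0 / 6.0, duration: float = 32.0) -> np.ndarray:
    """Unit-peak canonical double-gamma hemodynamic response."""
    from scipy.stats import gamma

    t = np.arange(0.0, duration, 1.0 / fs)
    # shape parameters chosen so the modes sit at `peak` and `undershoot`
    h = gamma.pdf(t, a=peak + 1.0, scale=1.0) - ratio * gamma.pdf(
        t, a=undershoot + 1.0, scale=1.0
    )
    return h / h.max()


@dataclass(frozen=True)
class Kernels:
    """Response kernels shared by all activation events.

    dHb mirrors dHbO with opposite sign and one third of the amplitude
    (180 deg out of phase, 3:1 peak ratio).
    """

    neural: np.ndarray
    hrf: np.ndarray
    hb_ratio: float = 3.0

    @staticmethod
    def default(design: StimulusDesign) -> "Kernels":
        return Kernels(
            neural=neural_kernel(design.fs_electrical),
            hrf=hrf_kernel(design.fs_hemodynamic),
        )


@dataclass(frozen=True)
class BackgroundConfig:
    """Background-activity standard deviations, relative to the maximum
    amplitude of the corresponding evoked signal."""

    electrical_rel: float = 1.0 / 20.0
    hbo_rel: float = 4.0
    hb_rel: float = 2.0


@dataclass(frozen=True)
class SourceActivity:
    electrical: np.ndarray  # (V, T_e)
    hbo: np.ndarray         # (V, T_h)
    hb: np.ndarray          # (V, T_h)
    event_trains: dict      # {label: onset times (s)}
    spots: tuple


def _impulse_train(times, fs, n_samples):
    train = np.zeros(n_samples)
    idx = np.round(np.asarray(times) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n_samples)]
    np.add.at(train, idx, 1.0)
    return train


def simulate_sources(
    design: StimulusDesign,
    spots,
    kernels: Kernels | None = None,
    sources: SourceSpace | None = None,
    n_voxels: int | None = None,
    background: BackgroundConfig | None = None,
    seed=None,
    amplitude: float = 1.0,
) -> SourceActivity:
    """Evoked + background activity at every source voxel.

    Evoked electrical activity is the per-spot impulse train convolved with
    the neural kernel, applied to the spot's voxels; evoked dHbO is the
    same train convolved with the canonical HRF, and dHb = -dHbO / 3.
    I.i.d. Gaussian background is added to all voxels with standard
    deviations expressed relative to the global maxima of the evoked
    signals.
    """
    if sources is None and n_voxels is None:
        raise ValueError("provide either a SourceSpace or n_voxels")
    V = sources.n_voxels if sources is not None else int(n_voxels)
    kernels = kernels or Kernels.default(design)
    background = background or BackgroundConfig()
    rng = np.random.default_rng(seed)

    labels = [s.label for s in spots]
    if len(set(labels)) != len(labels):
        raise ValueError("spot labels must be unique")
    seen = set()
    for s in spots:
        ids = set(int(i) for i in s.voxel_ids)
        if seen & ids:
            raise ValueError("activation spots must not overlap")
        seen |= ids

    Te = design.n_samples_electrical
    Th = design.n_samples_hemodynamic
    elec = np.zeros((V, Te))
    hbo = np.zeros((V, Th))
    trains = {}
    for spot in spots:
        times = design.event_times(spot.label)
        trains[spot.label] = times
        tr_e = _impulse_train(times, design.fs_electrical, Te)
        ev_e = np.convolve(tr_e, kernels.neural)[:Te] * amplitude
        tr_h = _impulse_train(times, design.fs_hemodynamic, Th)
        ev_h = np.convolve(tr_h, kernels.hrf)[:Th] * amplitude
        elec[spot.voxel_ids] += ev_e[None, :]
        hbo[spot.voxel_ids] += ev_h[None, :]
    hb = -hbo / kernels.hb_ratio

    # Background std is expressed relative to the maximum amplitude of the
    # evoked response to a single activation event (the kernel peak), not
    # of the superposed train: for the electrical responses the two
    # coincide (no overlap at 200 ms spacing), and for the slow
    # hemodynamics the single-event response is the physiologically
    # meaningful scale.
    has_evoked = np.abs(elec).max() > 0
    max_e = amplitude * np.abs(kernels.neural).max() if has_evoked else 0.0
    max_hbo = amplitude * np.abs(kernels.hrf).max() if has_evoked else 0.0
    max_hb = max_hbo / kernels.hb_ratio
    if background.electrical_rel > 0 and max_e > 0:
        elec = elec + rng.normal(0.0, background.electrical_rel * max_e, elec.shape)
    if background.hbo_rel > 0 and max_hbo > 0:
        hbo = hbo + rng.normal(0.0, background.hbo_rel * max_hbo, hbo.shape)
    if background.hb_rel > 0 and max_hb > 0:
        hb = hb + rng.normal(0.0, background.hb_rel * max_hb, hb.shape)

    return SourceActivity(
        electrical=elec, hbo=hbo, hb=hb, event_trains=trains, spots=tuple(spots)
    )


@dataclass(frozen=True)
class SNRConfig:
    """Per-modality SNRs: squared maximum clean amplitude / noise variance.
    ``np.inf`` disables the corresponding sensor noise."""

    eeg: float = 10.0
    dot: dict = field(default_factory=lambda: {750.0: 10.0, 850.0: 20.0})


@dataclass(frozen=True)
class Recordings:
    eeg: np.ndarray          # (E, T_e)
    dod: np.ndarray          # (C*W, T_h)
    eeg_clean: np.ndarray
    dod_clean: np.ndarray
    fs_eeg: float
    fs_dod: float
    n_dot_channels: int
    wavelengths: tuple
    snr: SNRConfig
    seed: object


def generate_recordings(
    activity: SourceActivity,
    leadfield: EEGLeadfield,
    jacobian: DOTJacobian,
    snr: SNRConfig | None = None,
    design: StimulusDesign | None = None,
    seed=None,
) -> Recordings:
    """Project source activity through the forward models and add sensor
    noise at the configured SNRs.

    Noise variance is set per modality (and per DOT wavelength) as
    (max |clean signal|)^2 / SNR over that block of channels.
    """
    snr = snr or SNRConfig()
    rng = np.random.default_rng(seed)
    L = leadfield.matrix
    J = jacobian.matrix
    if L.shape[1] != activity.electrical.shape[0]:
        raise ValueError("leadfield/source-space size mismatch")
    if J.shape[1] != 2 * activity.hbo.shape[0]:
        raise ValueError("jacobian/source-space size mismatch")

    eeg_clean = L @ activity.electrical
    dod_clean = J @ np.vstack([activity.hbo, activity.hb])

    eeg = eeg_clean.copy()
    if np.isfinite(snr.eeg):
        var = np.max(np.abs(eeg_clean)) ** 2 / snr.eeg
        eeg = eeg + rng.normal(0.0, np.sqrt(var), eeg.shape)

    C = jacobian.n_channels
    dod = dod_clean.copy()
    for i, wl in enumerate(jacobian.wavelengths):
        s = snr.dot[float(wl)]
        if np.isfinite(s):
            block = slice(i * C, (i + 1) * C)
            var = np.max(np.abs(dod_clean[block])) ** 2 / s
            dod[block] = dod[block] + rng.normal(0.0, np.sqrt(var), dod[block].shape)

    fs_e = design.fs_electrical if design else 1000.0
    fs_h = design.fs_hemodynamic if design else 10.0
    return Recordings(
        eeg=eeg,
        dod=dod,
        eeg_clean=eeg_clean,
        dod_clean=dod_clean,
        fs_eeg=fs_e,
        fs_dod=fs_h,
        n_dot_channels=C,
        wavelengths=tuple(jacobian.wavelengths),
        snr=snr,
        seed=seed,
    )
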