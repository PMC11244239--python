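"""Two-class synthetic multichannel EEG with controllable phase coupling
and signal complexity.

The generator emulates the study conditions the downstream pipeline
exploits: stroke and control cohorts that differ in (a) inter-channel
phase-coupling strength (controls more synchronized) and (b) broadband
signal complexity. Per channel the signal is a sum of band-limited
oscillators (delta/theta/alpha/beta) in which a fraction
``coupling_strength`` of the oscillatory power is shared across channels
with a fixed, nonzero per-channel phase lag (so the phase lag index can
detect it), plus a fixed 1/f background, a flat-spectrum broadband
component scaled by ``complexity_scale`` (the entropy-raising term), and
band-limited white sensor noise. A fixed per-channel coupling profile
makes synchrony spatially uneven, so channel pairs differ in how well
they separate the classes -- the structure correlation weighting targets.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import signal as sig
from scipy.signal import hilbert

from .data import EegRecording
from .errors import ConfigurationError
from .io import write_edf, write_labels_csv
from .montage import CHANNELS

#: (low, high) edges in Hz of the delta/theta/alpha/beta bands.
BANDS: tuple[tuple[float, float], ...] = ((1.0, 4.0), (4.0, 8.0), (8.0, 13.0), (13.0, 30.0))

#: relative oscillator amplitude per band (alpha-dominant, beta weakest)
BAND_MIX = np.array([0.8, 0.9, 1.2, 0.6])

#: fixed 1/f background amplitude in microvolts
PINK_AMPLITUDE_UV = 5.0

#: flat-spectrum broadband (1-35 Hz) amplitude in uV at complexity_scale = 1;
#: this is the component that raises sample entropy
BROADBAND_AMPLITUDE_UV = 6.0

_LAG_SEED = 1020   # montage-level constants, independent of cohort seed
_GAIN_SEED = 1021
_PROFILE_SEED = 1022
_AFFECTED_SEED = 1023

#: fraction of channels whose coupling differs between classes; the rest
#: keep a class-independent coupling level (an ischemic lesion perturbs
#: part of the network, not all of it)
AFFECTED_FRACTION = 0.5


def channel_lags(n_channels: int) -> np.ndarray:
    """Fixed per-channel phase lags, evenly spaced on (0.1, pi-0.1).

    Even spacing keeps every pairwise lag difference bounded away from
    zero (min gap ~0.16 rad for 19 channels), so no channel pair of a
    fully coupled cohort sits at the zero-lag point that PLI discards.
    The assignment of lag to channel is a fixed-seed permutation.
    """
    lags = np.linspace(0.1, np.pi - 0.1, n_channels)
    perm = np.random.default_rng(_LAG_SEED).permutation(n_channels)
    return lags[perm]


def channel_gains(n_channels: int) -> np.ndarray:
    """Fixed per-channel oscillatory gains in [0.7, 1.3].

    Heterogeneous gains give channel pairs different signal-to-noise
    ratios, hence heterogeneous (and differentially informative) PLI --
    the structure the correlation weights are designed to pick up.
    """
    return np.random.default_rng(_GAIN_SEED).uniform(0.7, 1.3, n_channels)


def coupling_profile(n_channels: int) -> np.ndarray:
    """Fixed per-channel coupling attenuation in [0.35, 1.0].

    Scalp synchrony is spatially uneven; attenuating the shared-power
    fraction per channel makes some channel pairs strongly informative
    about the class difference and others barely so. This is the regime
    in which per-pair correlation weighting is meaningful (with uniform
    coupling all pairs separate equally well and every weight saturates).
    """
    return np.random.default_rng(_PROFILE_SEED).uniform(0.35, 1.0, n_channels)


def affected_channels(n_channels: int) -> np.ndarray:
    """Fixed boolean mask of channels whose coupling tracks the class.

    Connections among the complementary (unaffected) channels vary
    between subjects but carry no class information -- exactly the
    connections the correlation weighting is designed to discount.
    """
    n_aff = max(1, int(round(AFFECTED_FRACTION * n_channels)))
    idx = np.random.default_rng(_AFFECTED_SEED).choice(n_channels, n_aff, replace=False)
    mask = np.zeros(n_channels, dtype=bool)
    mask[idx] = True
    return mask


@dataclass
class SynthConfig:
    """Study-condition parameters for the synthetic cohorts.

    Defaults emulate the target recording setup: 19 channels at 256 Hz,
    one minute per subject, with the control group more strongly
    phase-coupled than the stroke group and the stroke group showing
    higher broadband complexity.
    """

    n_channels: int = 19
    fs: float = 256.0
    duration_s: float = 60.0
    n_subjects_per_class: int = 10
    coupling_control: float = 0.6
    coupling_stroke: float = 0.3
    complexity_control: float = 1.0
    complexity_stroke: float = 1.5
    noise_sd: float = 2.0          # microvolts, band-limited sensor noise
    osc_amplitude: float = 20.0    # microvolts, total oscillatory scale
    subject_coupling_sd: float = 0.05   # between-subject coupling jitter
    confound_coupling_sd: float = 0.16  # jitter of class-independent coupling
    subject_complexity_rel_sd: float = 0.08  # relative complexity jitter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels <= 0:
            raise ConfigurationError("n_channels must be positive")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ConfigurationError("fs and duration_s must be positive")
        if self.n_subjects_per_class <= 0:
            raise ConfigurationError("n_subjects_per_class must be positive")
        for name in ("coupling_control", "coupling_stroke"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.complexity_control < 0 or self.complexity_stroke < 0:
            raise ConfigurationError("complexity scales must be non-negative")
        if self.noise_sd < 0 or self.osc_amplitude < 0:
            raise ConfigurationError("noise_sd and osc_amplitude must be >= 0")
        if min(self.subject_coupling_sd, self.confound_coupling_sd,
               self.subject_complexity_rel_sd) < 0:
            raise ConfigurationError("between-subject jitter SDs must be >= 0")

    def coupling_for(self, label: int) -> float:
        return self.coupling_stroke if label == 1 else self.coupling_control

    def complexity_for(self, label: int) -> float:
        return self.complexity_stroke if label == 1 else self.complexity_control

    def amplitude_bound_uv(self) -> float:
        """Hard bound on |sample|; generation clips to it (8 sigma)."""
        cmax = max(self.complexity_control, self.complexity_stroke)
        total_sd = (
            self.osc_amplitude * 1.3
            + (PINK_AMPLITUDE_UV + BROADBAND_AMPLITUDE_UV * cmax if cmax > 0 else 0.0)
            + self.noise_sd
        )
        return 8.0 * max(total_sd, 1e-12)


def _band_sos(low: float, high: float, fs: float):
    return sig.butter(2, [low, min(high, 0.49 * fs)], btype="band", fs=fs, output="sos")


def _unit_analytic(rng: np.random.Generator, n: int, fs: float,
                   band: tuple[float, float]) -> np.ndarray:
    """Unit-SD analytic narrowband noise in the given band."""
    x = sig.sosfiltfilt(_band_sos(*band, fs), rng.standard_normal(n))
    sd = x.std()
    if sd == 0:
        return np.zeros(n, dtype=complex)
    return hilbert(x / sd)


def _pink(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-SD 1/f-shaped noise, band-limited to 1-35 Hz."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    shaping = np.zeros_like(freqs)
    nz = freqs > 0
    shaping[nz] = 1.0 / np.sqrt(freqs[nz])
    x = np.fft.irfft(spec * shaping, n=n)
    x = sig.sosfiltfilt(sig.butter(4, [1.0, min(35.0, 0.49 * fs)], btype="band",
                                   fs=fs, output="sos"), x)
    sd = x.std()
    return x / sd if sd > 0 else x


def _bandlimited_white(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    x = sig.sosfiltfilt(sig.butter(4, [1.0, min(35.0, 0.49 * fs)], btype="band",
                                   fs=fs, output="sos"), rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _subject_rng(config: SynthConfig, class_label: int, subject_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, int(class_label), int(subject_index)))
    )


def _channel_names(n: int) -> list[str]:
    if n == len(CHANNELS):
        return list(CHANNELS)
    return [f"Ch{i:02d}" for i in range(n)]


def _render(config: SynthConfig, class_label: int, rng: np.random.Generator,
            coupling_per_channel: np.ndarray, complexity: float,
            subject_id: str) -> EegRecording:
    n = int(round(config.fs * config.duration_s))
    C = config.n_channels
    lags = channel_lags(C)
    gains = channel_gains(C)

    # cohort-shared analytic oscillator (fixed band mixture)
    common = np.zeros(n, dtype=complex)
    for amp, band in zip(BAND_MIX, BANDS):
        common += amp * _unit_analytic(rng, n, config.fs, band)
    sd = common.real.std()
    if sd > 0:
        common = common / sd

    data = np.empty((C, n))
    for c in range(C):
        kappa = coupling_per_channel[c]
        indep = np.zeros(n)
        if kappa < 1.0:
            zc = np.zeros(n, dtype=complex)
            for amp, band in zip(BAND_MIX, BANDS):
                zc += amp * _unit_analytic(rng, n, config.fs, band)
            sdc = zc.real.std()
            if sdc > 0:
                zc = zc / sdc
            indep = zc.real
        osc = (np.sqrt(kappa) * (common * np.exp(1j * lags[c])).real
               + np.sqrt(1.0 - kappa) * indep)
        x = config.osc_amplitude * gains[c] * osc
        if complexity > 0:
            # fixed 1/f background plus complexity-scaled flat broadband noise
            x = x + PINK_AMPLITUDE_UV * _pink(rng, n, config.fs)
            x = x + complexity * BROADBAND_AMPLITUDE_UV * _bandlimited_white(rng, n, config.fs)
        if config.noise_sd > 0:
            x = x + config.noise_sd * _bandlimited_white(rng, n, config.fs)
        data[c] = x

    bound = config.amplitude_bound_uv()
    np.clip(data, -bound, bound, out=data)
    return EegRecording(data=data, channel_names=_channel_names(C), fs=config.fs,
                        subject_id=subject_id, label=int(class_label))


def generate_subject(config: SynthConfig, class_label: int,
                     subject_index: int = 0,
                     subject_id: str | None = None) -> EegRecording:
    """Generate one subject's recording; deterministic given config seed.

    ``class_label`` 1 = ischemic stroke, 0 = non-stroke control; the
    class selects the coupling strength and complexity scale.
    """
    if class_label not in (0, 1):
        raise ConfigurationError("class_label must be 0 or 1")
    rng = _subject_rng(config, class_label, subject_index)
    affected = affected_channels(config.n_channels)
    base = np.where(affected, config.coupling_for(class_label),
                    0.5 * (config.coupling_control + config.coupling_stroke))
    if config.subject_coupling_sd > 0 or config.confound_coupling_sd > 0:
        # unaffected channels carry a stronger subject-specific (but
        # class-independent) synchrony offset: a confound the
        # correlation weighting is meant to discount
        jitter = rng.standard_normal(2)
        base = np.clip(base + np.where(affected,
                                       config.subject_coupling_sd * jitter[0],
                                       config.confound_coupling_sd * jitter[1]),
                       0.0, 1.0)
    # spatially uneven coupling: kappa^(1/p) keeps the endpoints 0 and 1
    # exact while attenuating intermediate coupling on low-profile channels
    profile = coupling_profile(config.n_channels)
    kappa = base ** (1.0 / profile)
    complexity = config.complexity_for(class_label)
    if config.subject_complexity_rel_sd > 0:
        complexity *= max(0.0, 1.0 + rng.normal(0.0, config.subject_complexity_rel_sd))
    if subject_id is None:
        subject_id = f"S{class_label}{subject_index:02d}"
    return _render(config, class_label, rng, kappa, complexity, subject_id)


def generate_subject_pair_coupled(config: SynthConfig, class_label: int,
                                  pair: tuple[int, int], pair_coupling: float,
                                  subject_index: int = 0,
                                  subject_id: str | None = None) -> EegRecording:
    """Generate a subject where only one channel pair is phase-coupled.

    All channels are independent except the two in ``pair``, which share
    the common oscillator with strength ``pair_coupling``. Used to test
    that the correlation weights localize a differential coupling.
    """
    rng = _subject_rng(config, class_label, subject_index)
    kappa = np.zeros(config.n_channels)
    kappa[list(pair)] = pair_coupling
    if subject_id is None:
        subject_id = f"P{class_label}{subject_index:02d}"
    return _render(config, class_label, rng, kappa,
                   config.complexity_for(class_label), subject_id)


def generate_cohort(config: SynthConfig) -> list[EegRecording]:
    """Generate the full two-class cohort (stroke label 1, control 0)."""
    cohort = []
    for label in (1, 0):
        for i in range(config.n_subjects_per_class):
            cohort.append(generate_subject(config, label, subject_index=i))
    return cohort


def write_cohort(config: SynthConfig, out_dir: str | os.PathLike) -> list[Path]:
    """Write one EDF per synthetic subject plus a labels CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(config)
    paths = []
    for rec in cohort:
        p = out / f"{rec.subject_id}.edf"
        write_edf(rec, p)
        paths.append(p)
    write_labels_csv(out / "labels.csv",
                     [r.subject_id for r in cohort], [r.label for r in cohort])
    return paths
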