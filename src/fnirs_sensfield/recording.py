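"""Synthetic continuous-wave fNIRS recordings with a block task design.

The generative model runs the forward chain in reverse order of the
analysis: a boxcar block design convolved with a canonical double-gamma
HRF scales a cortical activation map into oxy-/deoxy-hemoglobin
concentration changes; the molar-absorption relation turns these into
per-vertex absorption changes at each wavelength; the sensitivity
matrix maps them to channel optical-density changes; and intensities
follow the Beer-Lambert relation I = I0 * exp(-dOD), with additive
sinusoidal physiological interference, white noise and optional motion
spikes for testing artifact correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as gamma_dist

from .mc import SensitivityMatrix

#: molar extinction coefficients, 1/(mM cm), external constants from a
#: standard published hemoglobin compilation (not fitted here)
EXTINCTION_MM_CM = {
    760: {"HbO2": 0.5864, "HbR": 1.5485},
    850: {"HbO2": 1.0581, "HbR": 0.6910},
}


def extinction_matrix(wavelengths_nm=(760, 850),
                      table: dict | None = None) -> np.ndarray:
    """Rows = wavelengths, columns = (HbO2, HbR), units 1/(mM cm)."""
    table = table or EXTINCTION_MM_CM
    return np.array([[table[w]["HbO2"], table[w]["HbR"]]
                     for w in wavelengths_nm])


def canonical_hrf(t_s: np.ndarray, peak_s: float = 6.0,
                  undershoot_s: float = 16.0, ratio: float = 6.0) -> np.ndarray:
    """Double-gamma hemodynamic response function, peak-normalized."""
    t = np.asarray(t_s, dtype=float)
    h = (gamma_dist.pdf(t, peak_s, scale=1.0)
         - gamma_dist.pdf(t, undershoot_s, scale=1.0) / ratio)
    h[t < 0] = 0.0
    peak = h.max()
    return h / peak if peak > 0 else h


@dataclass
class Events:
    onsets_s: np.ndarray
    durations_s: np.ndarray
    conditions: list[str] = field(default_factory=list)


@dataclass
class NoiseSpec:
    white_sd: float = 0.0  # additive intensity noise SD (fraction of baseline)
    physio_amp: float = 0.0  # sinusoidal interference amplitude
    physio_freqs_hz: tuple = (0.25, 1.1)  # respiratory, cardiac
    spike_prob: float = 0.0  # per-sample motion spike probability
    spike_amp: float = 0.0  # spike amplitude (fraction of baseline)


@dataclass
class Recording:
    intensities: np.ndarray  # (channels, wavelengths, time), > 0
    sampling_rate_hz: float
    events: Events
    wavelengths_nm: tuple = (760, 850)

    def __post_init__(self):
        if np.any(self.intensities <= 0):
            raise ValueError("intensities must be > 0")
        dur = self.intensities.shape[-1] / self.sampling_rate_hz
        if np.any(self.events.onsets_s + self.events.durations_s > dur):
            raise ValueError("events extend beyond the record duration")


def design_regressor(n_samples: int, fs_hz: float, events: Events) -> np.ndarray:
    """Boxcar design convolved with the canonical HRF, peak-normalized."""
    box = np.zeros(n_samples)
    for t0, d in zip(events.onsets_s, events.durations_s):
        i0, i1 = int(round(t0 * fs_hz)), int(round((t0 + d) * fs_hz))
        box[i0:min(i1, n_samples)] = 1.0
    t = np.arange(0, 32.0, 1.0 / fs_hz)
    hrf = canonical_hrf(t)
    reg = np.convolve(box, hrf)[:n_samples]
    m = np.abs(reg).max()
    return reg / m if m > 0 else reg


def simulate_recording(A: dict[int, SensitivityMatrix] | SensitivityMatrix,
                       activation: np.ndarray, events: Events,
                       duration_s: float, sampling_rate_hz: float = 5.0,
                       noise: NoiseSpec | None = None, seed: int = 0,
                       baseline_intensity: float = 1.0,
                       hbr_ratio: float = -0.33,
                       amplitude_mm: float = 1e-3) -> Recording:
    """Forward-generate a recording from a cortical activation map.

    ``activation`` is a per-vertex spatial map (unitless weights) shared
    by both chromophores; HbO2 follows the design regressor scaled by
    ``amplitude_mm`` (peak dHbO2 in mM) and HbR by ``hbr_ratio`` times
    that, the usual anticorrelated deoxygenation. ``A`` maps per-vertex
    absorption changes (1/mm) to channel dOD per wavelength.
    """
    if noise is None:
        noise = NoiseSpec()
    if baseline_intensity <= 0:
        raise ValueError("baseline intensity must be > 0")
    if isinstance(A, SensitivityMatrix):
        A = {A.wavelength_nm: A}
    wavelengths = tuple(sorted(A))
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sampling_rate_hz))
    reg = design_regressor(n, sampling_rate_hz, events)

    activation = np.asarray(activation, dtype=float)
    ext = extinction_matrix(wavelengths)  # 1/(mM cm)
    ext_mm = ext * 0.1  # -> 1/(mM mm), matching mua in 1/mm
    # chromophore time courses per vertex: (2, J, T)
    hbo = amplitude_mm * activation[:, None] * reg[None, :]
    hbr = hbr_ratio * hbo
    n_ch = next(iter(A.values())).A.shape[0]
    od = np.zeros((n_ch, len(wavelengths), n))
    for k, wl in enumerate(wavelengths):
        dmua = ext_mm[k, 0] * hbo + ext_mm[k, 1] * hbr  # (J, T), 1/mm
        od[:, k, :] = A[wl].A @ dmua
    intensities = baseline_intensity * np.exp(-od)

    t = np.arange(n) / sampling_rate_hz
    if noise.physio_amp > 0:
        physio = np.zeros(n)
        for f in noise.physio_freqs_hz:
            physio += np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        intensities = intensities * (1.0 + noise.physio_amp * physio)
    if noise.white_sd > 0:
        intensities = intensities + rng.normal(
            0.0, noise.white_sd * baseline_intensity, size=intensities.shape)
    if noise.spike_prob > 0 and noise.spike_amp > 0:
        spikes = rng.random(intensities.shape) < noise.spike_prob
        intensities = intensities + spikes * noise.spike_amp * baseline_intensity
    intensities = np.clip(intensities, 1e-9 * baseline_intensity, None)
    return Recording(intensities=intensities, sampling_rate_hz=sampling_rate_hz,
                     events=events, wavelengths_nm=wavelengths)
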