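"""Sensor selection, trial segmentation and instantaneous phase/amplitude extraction.

The analysis targets two sensor groups with distinct dominant rhythms: a frontal
(F) group oscillating in the theta band (5-6 Hz, centred at 6 Hz) and a
parieto-occipital (PO) group oscillating in the upper-alpha band (alpha2,
10-13 Hz).  Phase and amplitude are extracted along two routes:

* Morlet wavelet transform over a small grid of scales per band, feeding the
  phase-locking estimators (:mod:`cfcausal.coupling`);
* zero-phase FIR band-pass followed by the Hilbert transform, feeding the
  envelope-based estimators (:mod:`cfcausal.causal`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "SensorMontage",
    "BandDefinition",
    "TrialSegment",
    "AnalyticRepresentation",
    "THETA_BAND",
    "ALPHA2_BAND",
    "DEFAULT_MONTAGE",
    "select_sensors",
    "segment_trial",
    "morlet_phase",
    "hilbert_analytic",
    "bandpass_filter",
    "read_raw",
]

#: Frontal sensors of the default montage, in analysis order.
F_SENSORS = (
    "FZ", "FP1", "AF3", "F3", "F7", "FC5", "FC1",
    "FC6", "FC2", "F4", "F8", "FP2", "AF4",
)

#: Parieto-occipital sensors of the default montage, in analysis order.
PO_SENSORS = (
    "PZ", "P7", "P8", "P5", "P6", "PO7", "PO8",
    "PO3", "O1", "OZ", "O2", "PO4",
)

#: Right-hemisphere parieto-occipital subset used for the zero-lag analysis.
RIGHT_PO_SENSORS = ("P6", "P8", "PO8", "PO4", "O2")


def _hemisphere(label: str) -> str:
    trailing = label[-1]
    if not trailing.isdigit():
        return "midline"
    return "left" if int(trailing) % 2 == 1 else "right"


@dataclass(frozen=True)
class SensorMontage:
    """Ordered channel labels with region (F/PO) and hemisphere tags."""

    labels: tuple[str, ...]
    regions: tuple[str, ...]
    hemispheres: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.labels) != len(self.regions):
            raise ValueError("labels and regions must have equal length")
        if not all(r in ("F", "PO") for r in self.regions):
            raise ValueError("regions must be 'F' or 'PO'")
        if not self.hemispheres:
            object.__setattr__(
                self, "hemispheres", tuple(_hemisphere(l) for l in self.labels)
            )

    @classmethod
    def default(cls) -> "SensorMontage":
        labels = F_SENSORS + PO_SENSORS
        regions = ("F",) * len(F_SENSORS) + ("PO",) * len(PO_SENSORS)
        return cls(labels=labels, regions=regions)

    def subset(self, labels: Sequence[str]) -> "SensorMontage":
        """Montage restricted to ``labels`` (kept in the requested order)."""
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"labels not in montage: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return SensorMontage(
            labels=tuple(self.labels[i] for i in idx),
            regions=tuple(self.regions[i] for i in idx),
            hemispheres=tuple(self.hemispheres[i] for i in idx),
        )

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def f_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.regions) if r == "F"])

    @property
    def po_indices(self) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.regions) if r == "PO"])

    @property
    def right_po_indices(self) -> np.ndarray:
        return np.array(
            [
                i
                for i, (r, h) in enumerate(zip(self.regions, self.hemispheres))
                if r == "PO" and h == "right"
            ]
        )

    def index(self, label: str) -> int:
        return self.labels.index(label)


DEFAULT_MONTAGE = SensorMontage.default()


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band with its wavelet scale grid.

    ``n_scales`` linearly spaced wavelet centre frequencies span ``low``..
    ``high``; ``n_cycles`` sets the Gaussian envelope width of the Morlet
    wavelet (sigma_t = n_cycles / (2 pi f)).
    """

    name: str
    low: float
    high: float
    center: float | None = None
    n_scales: int = 2
    n_cycles: float = 7.0

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise ValueError(f"invalid band edges [{self.low}, {self.high}]")
        if self.n_scales < 1:
            raise ValueError("n_scales must be >= 1")
        if self.center is None:
            object.__setattr__(self, "center", 0.5 * (self.low + self.high))

    @property
    def freqs(self) -> np.ndarray:
        if self.n_scales == 1:
            return np.array([self.center])
        return np.linspace(self.low, self.high, self.n_scales)


THETA_BAND = BandDefinition("theta", 5.0, 6.0, center=6.0, n_scales=2)
ALPHA2_BAND = BandDefinition("alpha2", 10.0, 13.0, n_scales=4)


@dataclass
class TrialSegment:
    """One trial: channels x samples, with condition labels.

    The trial width ``W`` is variable (stimulus onset to the last theta peak
    before the response), but must cover at least one full theta cycle.
    """

    samples: np.ndarray
    fs: float
    subject: int = 0
    cwl: int = 1
    response: str = "correct"
    labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (channels x time)")
        if self.labels and len(self.labels) != self.samples.shape[0]:
            raise ValueError("label count must match channel count")
        if not 1 <= self.cwl <= 5:
            raise ValueError("cwl must be in 1..5")
        if self.response not in ("correct", "wrong"):
            raise ValueError("response must be 'correct' or 'wrong'")
        if self.width < self.fs / 6.0:
            raise ValueError("trial shorter than one theta cycle")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def width(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.width / self.fs


@dataclass
class AnalyticRepresentation:
    """Instantaneous phase/amplitude per channel and scale.

    ``phase`` and ``amplitude`` have shape (n_channels, n_scales, n_samples);
    the Hilbert route uses a single 'scale'.  ``valid`` flags interior samples
    outside the wavelet/filter support at the trial edges.
    """

    phase: np.ndarray
    amplitude: np.ndarray
    method: str
    band: BandDefinition
    fs: float
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.phase.shape != self.amplitude.shape:
            raise ValueError("phase/amplitude shape mismatch")
        if self.method not in ("morlet", "hilbert"):
            raise ValueError("method must be 'morlet' or 'hilbert'")
        if self.valid is None:
            self.valid = np.ones(self.phase.shape[-1], dtype=bool)
        if not np.all(self.amplitude >= 0):
            raise ValueError("amplitudes must be non-negative")


def select_sensors(
    samples: np.ndarray,
    labels: Sequence[str],
    montage: SensorMontage = DEFAULT_MONTAGE,
) -> np.ndarray:
    """Reorder a labelled multichannel record to montage order, dropping extras.

    Raises ``KeyError`` naming every montage label absent from ``labels``.
    """
    samples = np.asarray(samples)
    labels = list(labels)
    missing = [l for l in montage.labels if l not in labels]
    if missing:
        raise KeyError(f"record is missing montage channels: {missing}")
    idx = [labels.index(l) for l in montage.labels]
    return samples[idx]


def read_raw(path) -> tuple[np.ndarray, list[str], float]:
    """Read a continuous multichannel recording.

    Supports EDF/BDF (via mne) and ``.npz`` array containers holding
    ``data`` (channels x samples), ``labels`` and ``fs``.  Returns
    ``(samples, channel labels, sampling rate)``; pair with
    :func:`select_sensors` to reduce to the analysis montage.
    """
    from pathlib import Path

    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".edf", ".bdf"):
        import mne

        reader = mne.io.read_raw_edf if suffix == ".edf" else mne.io.read_raw_bdf
        raw = reader(path, preload=True, verbose="error")
        return raw.get_data(), list(raw.ch_names), float(raw.info["sfreq"])
    if suffix == ".npz":
        npz = np.load(path, allow_pickle=False)
        for key in ("data", "labels", "fs"):
            if key not in npz:
                raise KeyError(f"array container missing {key!r}")
        return (
            np.asarray(npz["data"], dtype=float),
            [str(l) for l in npz["labels"]],
            float(npz["fs"]),
        )
    raise ValueError(f"unsupported recording format: {path.suffix!r}")


def bandpass_filter(
    x: np.ndarray,
    low: float,
    high: float,
    fs: float,
    transition: float = 1.0,
) -> np.ndarray:
    """Zero-phase (forward-backward) FIR band-pass along the last axis.

    ``low`` and ``high`` are passband edges: the transition bands lie outside
    the nominal band (cutoffs at low - transition/2 and high + transition/2),
    so a tone at a band edge is passed at full amplitude.
    """
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(f"band edges ({low}, {high}) outside (0, {nyq})")
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    n = x.shape[-1]
    # keep the kernel applicable to short trials
    max_taps = max(((n - 1) // 3) | 1, 5)
    numtaps = min(numtaps, max_taps)
    # the achievable transition width is set by the kernel length; place the
    # cutoffs so the nominal passband sits fully inside the flat region
    eff_transition = 3.3 * fs / numtaps
    lo_c = max(low - eff_transition / 2.0, eff_transition / 8.0)
    hi_c = min(high + eff_transition / 2.0, nyq - eff_transition / 8.0)
    if lo_c >= hi_c:
        raise ValueError("band too narrow for the achievable filter")
    b = signal.firwin(numtaps, [lo_c, hi_c], pass_zero=False, fs=fs)
    padlen = min(3 * numtaps, n - 1)
    return signal.filtfilt(b, [1.0], x, axis=-1, padlen=padlen)


def _filter_halfwidth(fs: float, transition: float, n: int) -> int:
    numtaps = int(np.ceil(3.3 * fs / transition)) | 1
    numtaps = min(numtaps, max(((n - 1) // 3) | 1, 5))
    return numtaps // 2


def segment_trial(
    record: np.ndarray,
    stimulus_onset: int,
    response_time: int,
    fs: float,
    reference_channel: int = 0,
    theta_band: BandDefinition = THETA_BAND,
) -> np.ndarray:
    """Cut one trial from a continuous record.

    The segment starts at ``stimulus_onset`` and ends at the last local
    maximum of the theta-band-filtered reference channel strictly before
    ``response_time`` (half-open interval ``[onset, peak)``; a peak exactly at
    the response sample is excluded).  Raises ``ValueError`` when no theta
    peak falls inside the interval.
    """
    record = np.atleast_2d(np.asarray(record, dtype=float))
    n = record.shape[-1]
    if not (0 <= stimulus_onset < response_time <= n):
        raise ValueError("need 0 <= onset < response_time <= record length")
    ref = bandpass_filter(record[reference_channel], theta_band.low,
                          theta_band.high, fs)
    peaks, _ = signal.find_peaks(ref)
    peaks = peaks[(peaks > stimulus_onset) & (peaks < response_time)]
    if peaks.size == 0:
        raise ValueError(
            "trial too short: no theta peak between onset and response"
        )
    end = int(peaks[-1])
    return record[:, stimulus_onset:end]


def morlet_phase(trial: TrialSegment, band: BandDefinition) -> AnalyticRepresentation:
    """Morlet-wavelet instantaneous phase/amplitude over the band's scale grid.

    Edge samples within one wavelet half-support of either trial edge are
    flagged invalid and excluded from averaged estimators downstream.
    """
    from mne.time_frequency import tfr_array_morlet

    sigma_t = band.n_cycles / (2.0 * np.pi * band.low)
    wavelet_len = 2 * int(np.ceil(5.0 * sigma_t * trial.fs)) + 1
    if trial.width < wavelet_len:
        raise ValueError(
            f"trial of {trial.width} samples shorter than the wavelet support "
            f"({wavelet_len} samples at {band.low} Hz, {band.n_cycles} cycles)"
        )
    half_support = int(np.ceil(trial.fs * band.n_cycles / (2.0 * band.low)))
    data = trial.samples[np.newaxis]  # (1, n_ch, n_times)
    out = tfr_array_morlet(
        data,
        sfreq=trial.fs,
        freqs=band.freqs,
        n_cycles=band.n_cycles,
        output="complex",
        zero_mean=True,
    )[0]
    valid = np.zeros(trial.width, dtype=bool)
    lo = min(half_support, trial.width // 2)
    valid[lo: trial.width - lo] = True
    if not valid.any():
        valid[:] = True
    return AnalyticRepresentation(
        phase=np.angle(out),
        amplitude=np.abs(out),
        method="morlet",
        band=band,
        fs=trial.fs,
        valid=valid,
    )


def hilbert_analytic(
    trial: TrialSegment,
    band: BandDefinition,
    transition: float = 1.0,
) -> AnalyticRepresentation:
    """Zero-phase band-pass then analytic-signal amplitude/phase per channel."""
    filtered = bandpass_filter(trial.samples, band.low, band.high, trial.fs,
                               transition=transition)
    nfft = int(2 ** np.ceil(np.log2(max(trial.width, 2))))
    analytic = signal.hilbert(filtered, N=nfft, axis=-1)[..., : trial.width]
    half = _filter_halfwidth(trial.fs, transition, trial.width)
    valid = np.zeros(trial.width, dtype=bool)
    lo = min(half, trial.width // 2)
    valid[lo: trial.width - lo] = True
    if not valid.any():
        valid[:] = True
    return AnalyticRepresentation(
        phase=np.angle(analytic)[:, np.newaxis, :],
        amplitude=np.abs(analytic)[:, np.newaxis, :],
        method="hilbert",
        band=band,
        fs=trial.fs,
        valid=valid,
    )
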